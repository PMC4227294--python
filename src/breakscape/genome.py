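"""Genome model: ordered chromosomes with lengths.

Coordinates are 0-based, half-open throughout the package.  The default
genome is hg19 (chromosome lengths hard-coded below); a "scaled" genome —
every chromosome multiplied by a common factor — is used to run realistic
whole-genome simulations at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GenomeModel", "hg19", "HG19_LENGTHS"]

# UCSC hg19 chromosome sizes (bp).
HG19_LENGTHS: dict[str, int] = {
    "chr1": 249_250_621,
    "chr2": 243_199_373,
    "chr3": 198_022_430,
    "chr4": 191_154_276,
    "chr5": 180_915_260,
    "chr6": 171_115_067,
    "chr7": 159_138_663,
    "chr8": 146_364_022,
    "chr9": 141_213_431,
    "chr10": 135_534_747,
    "chr11": 135_006_516,
    "chr12": 133_851_895,
    "chr13": 115_169_878,
    "chr14": 107_349_540,
    "chr15": 102_531_392,
    "chr16": 90_354_753,
    "chr17": 81_195_210,
    "chr18": 78_077_248,
    "chr19": 59_128_983,
    "chr20": 63_025_520,
    "chr21": 48_129_895,
    "chr22": 51_304_566,
    "chrX": 155_270_560,
    "chrY": 59_373_566,
}


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosome names with integer lengths in bp.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp.  Insertion order defines
        the canonical chromosome order used for sorting and output.
    name
        Free-text label (e.g. ``"hg19"`` or ``"hg19-x0.1"``).
    """

    lengths: dict[str, int]
    name: str = "custom"
    _order: tuple[str, ...] = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        names = list(self.lengths)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for chrom, length in self.lengths.items():
            if int(length) <= 0:
                raise ValueError(f"non-positive length for {chrom}: {length}")
        object.__setattr__(self, "_order", tuple(names))

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return self._order

    @property
    def total_bp(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __len__(self) -> int:
        return len(self.lengths)

    def length(self, chrom: str) -> int:
        return self.lengths[chrom]

    def rank(self, chrom: str) -> int:
        """Position of *chrom* in the canonical order (for sorting)."""
        return self._order.index(chrom)

    def scaled(self, factor: float) -> "GenomeModel":
        """Return a genome with every length multiplied by ``factor``.

        ``factor`` must lie in (0, 1]; lengths are rounded to the nearest
        bp with a floor of 1.
        """
        if not (0.0 < factor <= 1.0):
            raise ValueError(f"scale factor must be in (0, 1], got {factor}")
        lengths = {c: max(1, int(round(l * factor))) for c, l in self.lengths.items()}
        return GenomeModel(lengths, name=f"{self.name}-x{factor:g}")

    def subset(self, chromosomes: list[str] | tuple[str, ...]) -> "GenomeModel":
        missing = [c for c in chromosomes if c not in self.lengths]
        if missing:
            raise KeyError(f"chromosomes not in genome: {missing}")
        return GenomeModel({c: self.lengths[c] for c in chromosomes}, name=self.name)


def hg19(include_x: bool = True, include_y: bool = False) -> GenomeModel:
    """The hg19 reference genome.

    chrY is excluded by default: whether Y probes are analyzed is a
    platform/cohort choice (the reference DNA is sex-matched), so it is
    exposed as a switch rather than assumed.
    """
    lengths = {c: l for c, l in HG19_LENGTHS.items() if c not in ("chrX", "chrY")}
    if include_x:
        lengths["chrX"] = HG19_LENGTHS["chrX"]
    if include_y:
        lengths["chrY"] = HG19_LENGTHS["chrY"]
    return GenomeModel(lengths, name="hg19")
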