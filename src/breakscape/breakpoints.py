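"""Breakpoints and instability statistics derived from segmentations.

A breakpoint is a locus where the copy-number state changes between two
consecutive intervals of a tiled chromosome.  Candidates arise only at
boundaries where at least one flank is a called aberration; they are kept
when the difference in mean log2 ratio between the flanks exceeds a
filter (default |delta| > 0.5).  Chromosome-terminal boundaries never
produce breakpoints.

From the filtered breakpoints the module computes the per-sample
instability statistics:

* BPI (breakpoint instability index) — total breakpoints per genome;
* breaks per chromosome and break density per 100 Mb of chromosome;
* PGA (proportion of genome altered) — summed length of called
  amplifications/deletions divided by genome length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import MaskRegions
from .genome import GenomeModel
from .segmentation import Segment

__all__ = [
    "Breakpoint",
    "InstabilityStats",
    "extract_breakpoints",
    "mask_germline",
    "subtract_matched_normal",
    "compute_instability",
]


@dataclass(frozen=True)
class Breakpoint:
    """A copy-number state change between two adjacent intervals.

    ``position`` is the midpoint of the inter-probe gap between the flanks;
    the platform resolves breakpoint *regions*, so ``uncertainty_bp``
    records the half-gap.
    """

    chrom: str
    position: int
    left_mean_log2: float
    right_mean_log2: float
    uncertainty_bp: int = 0

    @property
    def delta(self) -> float:
        return self.right_mean_log2 - self.left_mean_log2


@dataclass
class InstabilityStats:
    """Per-sample breakage statistics."""

    sample: str
    bpi: int
    breaks_per_chromosome: dict[str, int]
    density_per_100mb: dict[str, float]
    pga: float
    altered_bp: int = 0

    def __post_init__(self) -> None:
        assert self.bpi == sum(self.breaks_per_chromosome.values())
        assert 0.0 <= self.pga <= 1.0 + 1e-12


def extract_breakpoints(
    segments: dict[str, list[Segment]] | list[Segment],
    delta_filter: float = 0.5,
) -> list[Breakpoint]:
    """Candidate breakpoints at state changes, filtered by |delta|.

    ``segments`` is a complete tiling per chromosome (from
    :func:`breakscape.segmentation.segment_track`).  A boundary yields a
    candidate only when at least one flank is an aberration, and the
    candidate is retained iff ``|delta| > delta_filter`` (strict).
    """
    if isinstance(segments, list):
        by_chrom: dict[str, list[Segment]] = {}
        for seg in segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        segments = by_chrom
    out: list[Breakpoint] = []
    for chrom, tiles in segments.items():
        tiles = sorted(tiles, key=lambda s: s.start)
        for a, b in zip(tiles[:-1], tiles[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping segments on {chrom}: {a.start}-{a.end} / {b.start}-{b.end}"
                )
            if not (a.is_aberrant or b.is_aberrant):
                continue
            delta = b.mean_log2 - a.mean_log2
            if abs(delta) > delta_filter:
                gap = b.start - a.end
                out.append(
                    Breakpoint(
                        chrom=chrom,
                        position=int(a.end + gap // 2),
                        left_mean_log2=a.mean_log2,
                        right_mean_log2=b.mean_log2,
                        uncertainty_bp=int(max(gap // 2, 0)),
                    )
                )
    return out


def mask_germline(
    breakpoints: list[Breakpoint],
    mask: MaskRegions,
    slop_bp: int = 10_000,
) -> list[Breakpoint]:
    """Drop breakpoints within ``slop_bp`` of a germline-CNV mask interval."""
    return [
        bp for bp in breakpoints if not mask.contains(bp.chrom, bp.position, slop_bp)
    ]


def subtract_matched_normal(
    tumor: list[Breakpoint],
    normal: list[Breakpoint],
    tolerance_bp: int = 10_000,
) -> list[Breakpoint]:
    """Remove tumor breakpoints near any matched normal-fraction breakpoint.

    The non-aberrant (e.g. stromal 2N) fraction of the same specimen serves
    as a negative control: breaks it shares with the tumor fraction are
    treated as germline or platform artifacts.
    """
    normal_by_chrom: dict[str, np.ndarray] = {}
    for bp in normal:
        normal_by_chrom.setdefault(bp.chrom, [])
    for bp in normal:
        normal_by_chrom[bp.chrom].append(bp.position)  # type: ignore[union-attr]
    normal_by_chrom = {c: np.sort(np.asarray(p)) for c, p in normal_by_chrom.items()}
    out = []
    for bp in tumor:
        positions = normal_by_chrom.get(bp.chrom)
        if positions is not None and len(positions):
            i = int(np.searchsorted(positions, bp.position))
            near = min(
                (abs(int(positions[j]) - bp.position) for j in (i - 1, i) if 0 <= j < len(positions)),
                default=None,
            )
            if near is not None and near <= tolerance_bp:
                continue
        out.append(bp)
    return out


def compute_instability(
    sample: str,
    breakpoints: list[Breakpoint],
    segments: dict[str, list[Segment]],
    genome: GenomeModel,
) -> InstabilityStats:
    """BPI, per-chromosome break counts/densities, and PGA for one sample."""
    counts = {chrom: 0 for chrom in genome.chromosomes}
    for bp in breakpoints:
        if bp.chrom not in counts:
            raise KeyError(f"breakpoint on chromosome absent from genome: {bp.chrom}")
        counts[bp.chrom] += 1
    density = {
        chrom: counts[chrom] * 1e8 / genome.length(chrom) for chrom in genome.chromosomes
    }
    altered = 0
    for tiles in segments.values():
        for seg in tiles:
            if seg.is_aberrant:
                altered += seg.length_bp
    pga = altered / genome.total_bp
    return InstabilityStats(
        sample=sample,
        bpi=sum(counts.values()),
        breaks_per_chromosome=counts,
        density_per_100mb=density,
        pga=min(pga, 1.0),
        altered_bp=altered,
    )
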