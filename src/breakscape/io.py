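"""Readers and writers for probe tables, BED intervals, and metadata.

All genomic records are 0-based half-open.  Probe tables are TSV with
header ``sample chrom start end log2``; segment/breakpoint/mask files are
BED-like TSV whose name/score columns carry the segment mean log2 or the
breakpoint delta.  Output ordering is bit-stable: chromosomes in genome
order, then start coordinate.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .breakpoints import Breakpoint, InstabilityStats
from .containers import MaskRegions, ProbeTrack, SampleMeta
from .genome import GenomeModel
from .segmentation import Segment

__all__ = [
    "ProbeTableError",
    "read_probe_table",
    "write_probe_table",
    "read_mask_bed",
    "write_mask_bed",
    "write_segments_bed",
    "read_segments_bed",
    "write_breakpoints_bed",
    "read_breakpoints_bed",
    "read_cohort_meta",
    "write_cohort_meta",
    "write_stats_table",
    "read_stats_table",
]

PROBE_COLUMNS = ["sample", "chrom", "start", "end", "log2"]


class ProbeTableError(ValueError):
    """Malformed probe table (carries the offending line number)."""


def _chrom_sort_key(genome: GenomeModel | None):
    if genome is None:
        return lambda chrom: chrom
    return genome.rank


def read_probe_table(path: str | Path, genome: GenomeModel) -> ProbeTrack:
    """Read a single-sample probe table, validating against ``genome``.

    Unsorted rows are sorted; duplicated probe coordinates, inverted
    intervals, unknown chromosomes, or non-numeric fields are errors (the
    parse error names the 1-based file line).
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PROBE_COLUMNS:
            raise ProbeTableError(
                f"{path}:1: expected header {PROBE_COLUMNS}, got {header}"
            )
        rows: dict[str, list[tuple[int, int, float]]] = {}
        samples: set[str] = set()
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise ProbeTableError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            sample, chrom, start_s, end_s, log2_s = parts
            try:
                start, end, log2 = int(start_s), int(end_s), float(log2_s)
            except ValueError as exc:
                raise ProbeTableError(f"{path}:{lineno}: {exc}") from None
            if chrom not in genome:
                raise ProbeTableError(
                    f"{path}:{lineno}: chromosome {chrom!r} not in genome {genome.name}"
                )
            if start < 0 or end <= start:
                raise ProbeTableError(
                    f"{path}:{lineno}: invalid probe interval {start}..{end}"
                )
            samples.add(sample)
            rows.setdefault(chrom, []).append((start, end, log2))
    if len(samples) > 1:
        raise ProbeTableError(f"{path}: multiple samples in one probe table: {sorted(samples)}")
    track = ProbeTrack(sample=samples.pop() if samples else path.stem)
    for chrom in sorted(rows, key=genome.rank):
        arr = np.asarray(rows[chrom], dtype=np.float64)
        track.add_chromosome(chrom, arr[:, 0], arr[:, 1], arr[:, 2])
    return track


def write_probe_table(track: ProbeTrack, path: str | Path, genome: GenomeModel | None = None) -> None:
    path = Path(path)
    chroms = track.chromosomes
    if genome is not None:
        chroms = sorted(chroms, key=genome.rank)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PROBE_COLUMNS)
        for chrom in chroms:
            start, end, log2 = track.chromosome(chrom)
            for s, e, l in zip(start, end, log2):
                writer.writerow([track.sample, chrom, int(s), int(e), repr(float(l))])


def read_mask_bed(path: str | Path) -> MaskRegions:
    """Read a >= 3-column BED of excluded regions; overlaps are merged."""
    path = Path(path)
    intervals: list[tuple[str, int, int]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative coordinate {start}")
            intervals.append((parts[0], start, end))
    return MaskRegions(intervals)


def write_mask_bed(mask: MaskRegions, path: str | Path, genome: GenomeModel | None = None) -> None:
    chroms = mask.chromosomes
    if genome is not None:
        chroms = sorted(chroms, key=genome.rank)
    with Path(path).open("w") as fh:
        for chrom in chroms:
            for s, e in mask.intervals(chrom):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\n")


def write_segments_bed(
    segments: dict[str, list[Segment]] | list[Segment],
    path: str | Path,
    genome: GenomeModel | None = None,
) -> None:
    """BED with columns chrom, start, end, name, mean_log2, n_probes, score, aberrant."""
    if isinstance(segments, dict):
        flat = [s for tiles in segments.values() for s in tiles]
    else:
        flat = list(segments)
    key = _chrom_sort_key(genome)
    flat.sort(key=lambda s: (key(s.chrom), s.start))
    with Path(path).open("w") as fh:
        for i, s in enumerate(flat):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tseg{i}\t{s.mean_log2:.6f}\t"
                f"{s.n_probes}\t{s.score:.6f}\t{int(s.is_aberrant)}\n"
            )


def read_segments_bed(path: str | Path) -> dict[str, list[Segment]]:
    out: dict[str, list[Segment]] = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            chrom, start, end, _name, mean, n, score, ab = parts
            out.setdefault(chrom, []).append(
                Segment(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    n_probes=int(n),
                    mean_log2=float(mean),
                    score=float(score),
                    is_aberrant=bool(int(ab)),
                )
            )
    for tiles in out.values():
        tiles.sort(key=lambda s: s.start)
    return out


def write_breakpoints_bed(
    breakpoints: list[Breakpoint],
    path: str | Path,
    genome: GenomeModel | None = None,
) -> None:
    """1-bp BED records; name packs the flanking means, score the delta."""
    key = _chrom_sort_key(genome)
    bps = sorted(breakpoints, key=lambda b: (key(b.chrom), b.position))
    with Path(path).open("w") as fh:
        for b in bps:
            name = f"left={b.left_mean_log2:.6f};right={b.right_mean_log2:.6f};pm={b.uncertainty_bp}"
            fh.write(f"{b.chrom}\t{b.position}\t{b.position + 1}\t{name}\t{b.delta:.6f}\n")


def read_breakpoints_bed(path: str | Path) -> list[Breakpoint]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            chrom, start, _end, name, _score = parts
            fields = dict(kv.split("=") for kv in name.split(";"))
            out.append(
                Breakpoint(
                    chrom=chrom,
                    position=int(start),
                    left_mean_log2=float(fields["left"]),
                    right_mean_log2=float(fields["right"]),
                    uncertainty_bp=int(fields["pm"]),
                )
            )
    return out


def read_cohort_meta(path: str | Path) -> list[SampleMeta]:
    """TSV with header ``sample subtype ploidy``."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "subtype", "ploidy"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: metadata needs columns {sorted(needed)}")
    metas = [
        SampleMeta(sample=str(r["sample"]), subtype=str(r["subtype"]), ploidy=str(r["ploidy"]))
        for _, r in df.iterrows()
    ]
    ids = [m.sample for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sample ids")
    return metas


def write_cohort_meta(metas: list[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [{"sample": m.sample, "subtype": m.subtype, "ploidy": m.ploidy} for m in metas]
    ).to_csv(path, sep="\t", index=False)


def write_stats_table(
    stats: list[InstabilityStats], genome: GenomeModel, path: str | Path
) -> None:
    """One row per sample: sample, BPI, PGA, then per-chromosome counts and densities."""
    rows = []
    for s in stats:
        row: dict[str, object] = {"sample": s.sample, "bpi": s.bpi, "pga": s.pga}
        for c in genome.chromosomes:
            row[f"breaks_{c}"] = s.breaks_per_chromosome.get(c, 0)
        for c in genome.chromosomes:
            row[f"density_{c}"] = s.density_per_100mb.get(c, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_stats_table(path: str | Path, genome: GenomeModel) -> list[InstabilityStats]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        counts = {c: int(r[f"breaks_{c}"]) for c in genome.chromosomes}
        density = {c: float(r[f"density_{c}"]) for c in genome.chromosomes}
        out.append(
            InstabilityStats(
                sample=str(r["sample"]),
                bpi=int(r["bpi"]),
                breaks_per_chromosome=counts,
                density_per_100mb=density,
                pga=float(r["pga"]),
            )
        )
    return out
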