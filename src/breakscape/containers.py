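"""Core in-memory containers: probe tracks, sample metadata, interval masks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel

__all__ = ["ProbeTrack", "SampleMeta", "MaskRegions", "SUBTYPES", "PLOIDY_CLASSES"]

SUBTYPES = ("ER+", "HER2+", "TNBC")
PLOIDY_CLASSES = ("A", "D", "T", "D/T")


@dataclass
class ProbeTrack:
    """Ordered probe-level log2 ratios for one sample.

    ``probes`` maps chromosome name -> record array-like of three numpy
    arrays ``(start, end, log2)`` with 0-based half-open coordinates,
    sorted by start.  Log2 ratios measure tumor/reference fluorescence on
    a diploid baseline (0 = copy-neutral, 1 = two-fold gain).
    """

    sample: str
    probes: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def add_chromosome(
        self,
        chrom: str,
        start: np.ndarray,
        end: np.ndarray,
        log2: np.ndarray,
        *,
        validate: bool = True,
    ) -> None:
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        log2 = np.asarray(log2, dtype=np.float64)
        if validate:
            if not (len(start) == len(end) == len(log2)):
                raise ValueError(f"{chrom}: column lengths differ")
            if len(start) and start.min() < 0:
                raise ValueError(f"{chrom}: negative probe coordinate")
            if np.any(end <= start):
                bad = int(np.argmax(end <= start))
                raise ValueError(
                    f"{chrom}: probe end <= start at index {bad} "
                    f"({start[bad]}..{end[bad]})"
                )
            if not np.all(np.isfinite(log2)):
                raise ValueError(f"{chrom}: non-finite log2 ratio")
            order = np.argsort(start, kind="stable")
            start, end, log2 = start[order], end[order], log2[order]
            if len(start) > 1 and np.any(np.diff(start) == 0):
                raise ValueError(f"{chrom}: duplicated probe start coordinate")
        self.probes[chrom] = (start, end, log2)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.probes)

    @property
    def n_probes(self) -> int:
        return sum(len(s) for s, _, _ in self.probes.values())

    def chromosome(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self.probes[chrom]

    def all_log2(self) -> np.ndarray:
        if not self.probes:
            return np.empty(0)
        return np.concatenate([l for _, _, l in self.probes.values()])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns sample, chrom, start, end, log2."""
        rows = []
        for chrom, (s, e, l) in self.probes.items():
            rows.append(
                pd.DataFrame(
                    {"sample": self.sample, "chrom": chrom, "start": s, "end": e, "log2": l}
                )
            )
        if not rows:
            return pd.DataFrame(columns=["sample", "chrom", "start", "end", "log2"])
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class SampleMeta:
    """Clinical annotation for one tumor sample.

    ``subtype`` is the clinical receptor subtype; ``ploidy`` the flow-sorting
    class (A aneuploid, D diploid, T tetraploid, D/T ambiguous).
    """

    sample: str
    subtype: str
    ploidy: str

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}")
        if self.ploidy not in PLOIDY_CLASSES:
            raise ValueError(f"unknown ploidy {self.ploidy!r}; expected one of {PLOIDY_CLASSES}")


class MaskRegions:
    """Sorted, merged genomic intervals flagged as germline CNV / excluded."""

    def __init__(self, intervals: list[tuple[str, int, int]] | None = None):
        self._by_chrom: dict[str, np.ndarray] = {}
        if intervals:
            self._build(intervals)

    def _build(self, intervals: list[tuple[str, int, int]]) -> None:
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start < 0:
                raise ValueError(f"negative coordinate in mask: {chrom}:{start}-{end}")
            if end <= start:
                raise ValueError(f"empty/inverted mask interval: {chrom}:{start}-{end}")
            grouped.setdefault(chrom, []).append((start, end))
        for chrom, ivs in grouped.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._by_chrom[chrom] = np.asarray(merged, dtype=np.int64)

    @property
    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) array of merged intervals on *chrom* (empty if none)."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def total_bp(self) -> int:
        return int(sum((iv[:, 1] - iv[:, 0]).sum() for iv in self._by_chrom.values()))

    def contains(self, chrom: str, pos: int, slop_bp: int = 0) -> bool:
        """True if ``pos`` lies within ``slop_bp`` of a masked interval."""
        iv = self.intervals(chrom)
        if not len(iv):
            return False
        lo = iv[:, 0] - slop_bp
        hi = iv[:, 1] + slop_bp
        i = int(np.searchsorted(lo, pos, side="right")) - 1
        # intervals are merged/sorted, but slop can bridge neighbours; check
        # the insertion neighbourhood explicitly.
        for j in (i, i + 1):
            if 0 <= j < len(iv) and lo[j] <= pos < hi[j]:
                return True
        return False

    def as_tuples(self) -> list[tuple[str, int, int]]:
        return [
            (chrom, int(s), int(e))
            for chrom, iv in self._by_chrom.items()
            for s, e in iv
        ]
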