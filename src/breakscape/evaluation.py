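"""Recovery metrics against simulated ground truth."""

from __future__ import annotations

import numpy as np

from .breakpoints import Breakpoint, extract_breakpoints
from .containers import ProbeTrack
from .segmentation import Segment, SegmentationParams, segment_track
from .simulate import GroundTruth

__all__ = ["call_sample", "breakpoint_recovery"]


def call_sample(
    track: ProbeTrack,
    params: SegmentationParams | None = None,
    delta_filter: float = 0.5,
) -> tuple[dict[str, list[Segment]], list[Breakpoint]]:
    """Segment a track and extract filtered breakpoints in one step."""
    segments = segment_track(track, params)
    return segments, extract_breakpoints(segments, delta_filter)


def breakpoint_recovery(
    truth: GroundTruth,
    called: list[Breakpoint],
    tolerance_bp: float,
    delta_filter: float = 0.5,
) -> dict[str, float]:
    """One-to-one matching of called against planted breakpoints.

    A true breakpoint (with expected |delta| above ``delta_filter``) is
    recovered when an unused called breakpoint on the same chromosome lies
    within ``tolerance_bp``; matching is greedy by distance.  Returns
    recall, precision, and counts.
    """
    true_by_chrom: dict[str, list[int]] = {}
    for chrom, pos, _ in truth.all_breakpoints(delta_filter):
        true_by_chrom.setdefault(chrom, []).append(pos)
    called_by_chrom: dict[str, np.ndarray] = {}
    for bp in called:
        called_by_chrom.setdefault(bp.chrom, []).append(bp.position)  # type: ignore[arg-type]
    called_by_chrom = {c: np.asarray(v) for c, v in called_by_chrom.items()}

    n_true = sum(len(v) for v in true_by_chrom.values())
    n_called = len(called)
    tp = 0
    for chrom, positions in true_by_chrom.items():
        cand = called_by_chrom.get(chrom)
        if cand is None or not len(cand):
            continue
        pairs = sorted(
            (abs(int(c) - t), ti, ci)
            for ti, t in enumerate(positions)
            for ci, c in enumerate(cand)
            if abs(int(c) - t) <= tolerance_bp
        )
        used_t: set[int] = set()
        used_c: set[int] = set()
        for _, ti, ci in pairs:
            if ti not in used_t and ci not in used_c:
                used_t.add(ti)
                used_c.add(ci)
                tp += 1
    return {
        "recall": tp / n_true if n_true else 1.0,
        "precision": tp / n_called if n_called else 1.0,
        "n_true": float(n_true),
        "n_called": float(n_called),
        "n_matched": float(tp),
    }
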