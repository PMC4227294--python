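"""Score-based detection of copy-number aberrations from probe log2 ratios.

The segmenter is an interval-score changepoint method in the spirit of
Agilent's ADM-2: the statistic for a run of probes is the deviation of its
average log2 ratio from zero, in units of standard deviation,

    score(i, j) = mean(x[i:j]) * sqrt(j - i) / sigma,

and aberrant intervals are those whose |score| exceeds a threshold
(default 10, a deliberately conservative choice).  Detection is a
recursive top-down search: the maximal-|score| interval is fixed, the
search recurses to its left, to its right, and *within* it (relative to
the interval's own mean) so that internal steps of amplicons and
deletions are found as well.  Candidate boundaries are refined by greedy
single-probe moves while the |score| increases, and a final pass tests
every tile for internal splits with a two-sample statistic at the same
threshold (see :func:`_split_boundaries`).

Called aberrations are additionally filtered to >= 5 probes and absolute
mean log2 ratio > 0.3 (``call_aberrations``); everything else is merged
back into the neutral state so that each chromosome is tiled by
alternating neutral and aberrant segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as _stats

from .containers import ProbeTrack

__all__ = [
    "Segment",
    "SegmentationParams",
    "estimate_noise_sd",
    "interval_score",
    "max_score_interval",
    "segment_chromosome",
    "call_aberrations",
    "segment_track",
]

SIGMA_FLOOR = 0.05  # guards against infinite scores on noise-free input


@dataclass(frozen=True)
class Segment:
    """A contiguous run of probes with a common copy-number state.

    ``start``/``end`` span the first probe's start to the last probe's end
    (0-based half-open).  ``score`` is the interval score against a zero
    baseline; ``is_aberrant`` marks segments that survive the calling
    filters.
    """

    chrom: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    score: float
    is_aberrant: bool
    first_probe: int = -1  # index range into the chromosome's probe arrays
    last_probe: int = -1   # inclusive

    @property
    def length_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SegmentationParams:
    """Calling parameters.

    ``score_threshold`` — minimum |interval score| (default 10).
    ``min_probes`` — minimum probes per called aberration (default 5).
    ``min_abs_mean_log2`` — minimum |mean log2| per called aberration
    (default 0.3).
    """

    score_threshold: float = 10.0
    min_probes: int = 5
    min_abs_mean_log2: float = 0.3

    def __post_init__(self) -> None:
        if self.score_threshold <= 0:
            raise ValueError("score_threshold must be > 0")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if self.min_abs_mean_log2 < 0:
            raise ValueError("min_abs_mean_log2 must be >= 0")


def estimate_noise_sd(track: ProbeTrack, floor: float = SIGMA_FLOOR) -> float:
    """Robust per-sample noise SD from first differences of log2 ratios.

    Adjacent-probe differences within a chromosome are differences of two
    iid noise terms except at the (sparse) true segment boundaries, so a
    MAD-based scale of the differences divided by sqrt(2) estimates the
    probe-level SD while ignoring boundary outliers.
    """
    diffs = []
    n_probes = 0
    for chrom in track.chromosomes:
        _, _, log2 = track.chromosome(chrom)
        n_probes += len(log2)
        if len(log2) > 1:
            diffs.append(np.diff(log2))
    if n_probes < 10:
        raise ValueError(f"need >= 10 probes to estimate noise SD, got {n_probes}")
    d = np.concatenate(diffs)
    sigma = float(_stats.median_abs_deviation(d, scale="normal") / np.sqrt(2.0))
    return max(sigma, floor)


def interval_score(ratios: np.ndarray, sigma: float) -> float:
    """Signed deviation of the interval mean from zero, in SD units."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    ratios = np.asarray(ratios, dtype=np.float64)
    n = len(ratios)
    if n < 1:
        raise ValueError("empty interval")
    return float(ratios.mean() * np.sqrt(n) / sigma)


def max_score_interval(
    x: np.ndarray, sigma: float, baseline: float = 0.0
) -> tuple[int, int, float]:
    """Interval maximizing |score| relative to ``baseline``.

    Returns ``(i, j, score)`` with the half-open probe index range and the
    signed score.  Ties in |score| are broken by longer interval, then by
    leftmost start, so the result is deterministic and matches exhaustive
    search under the same rule.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    x = np.asarray(x, dtype=np.float64) - baseline
    n = len(x)
    if n == 0:
        raise ValueError("empty chromosome")
    cs = np.concatenate(([0.0], np.cumsum(x)))
    best = (-1.0, -1, -1, 0.0)  # (|score|, length, -start is implicit, signed)
    best_len = -1
    best_start = -1
    for length in range(1, n + 1):
        sums = cs[length:] - cs[:-length]  # sums of all windows of this length
        absscores = np.abs(sums) / (np.sqrt(length) * sigma)
        k = int(np.argmax(absscores))  # leftmost on ties
        s = float(absscores[k])
        if s > best[0] or (s == best[0] and length > best_len):
            signed = float(sums[k] / (np.sqrt(length) * sigma))
            best = (s, length, k, signed)
            best_len = length
            best_start = k
    return best_start, best_start + best_len, best[3]


def _refine(
    x: np.ndarray, i: int, j: int, lo: int, hi: int, sigma: float, baseline: float
) -> tuple[int, int]:
    """Greedy single-probe boundary moves while |score| strictly increases."""
    cs = np.concatenate(([0.0], np.cumsum(np.asarray(x, dtype=np.float64) - baseline)))

    def absscore(a: int, b: int) -> float:
        return abs(cs[b] - cs[a]) / (np.sqrt(b - a) * sigma)

    improved = True
    while improved:
        improved = False
        cur = absscore(i, j)
        for di, dj in ((-1, 0), (1, 0), (0, 1), (0, -1)):
            a, b = i + di, j + dj
            if a < lo or b > hi or b - a < 1:
                continue
            if absscore(a, b) > cur:
                i, j = a, b
                improved = True
                break
    return i, j


def _find_boundaries(
    x: np.ndarray,
    lo: int,
    hi: int,
    sigma: float,
    baseline: float,
    threshold: float,
    boundaries: set[int],
    depth: int = 0,
) -> None:
    if hi - lo < 1 or depth > 64:
        return
    i, j, score = max_score_interval(x[lo:hi], sigma, baseline)
    if abs(score) < threshold:
        return
    i, j = _refine(x, lo + i, lo + j, lo, hi, sigma, baseline)
    if i == lo and j == hi and depth > 0 and baseline != 0.0:
        # the whole sub-region deviates from its parent's mean: nothing to split
        return
    boundaries.add(i)
    boundaries.add(j)
    inner_mean = float(np.mean(x[i:j]))
    _find_boundaries(x, lo, i, sigma, baseline, threshold, boundaries, depth + 1)
    _find_boundaries(x, j, hi, sigma, baseline, threshold, boundaries, depth + 1)
    if j - i > 1 and not (i == lo and j == hi and inner_mean == baseline):
        _find_boundaries(x, i, j, sigma, inner_mean, threshold, boundaries, depth + 1)


def _split_boundaries(
    x: np.ndarray,
    a: int,
    b: int,
    sigma: float,
    threshold: float,
    boundaries: set[int],
    depth: int = 0,
) -> None:
    """Recursive binary splitting by the two-sample boundary statistic.

    The top-down interval search can fix a composite interval whose
    internal oscillation is strong at each boundary yet weak relative to
    the composite mean.  Each candidate split point is therefore tested
    directly: |mean_L - mean_R| / (sigma * sqrt(1/n_L + 1/n_R)), an
    abrupt-change score in the same SD units, against the same threshold.
    """
    n = b - a
    if n < 2 or depth > 64:
        return
    cs = np.concatenate(([0.0], np.cumsum(x[a:b], dtype=np.float64)))
    n_left = np.arange(1, n)
    n_right = n - n_left
    mean_left = cs[1:-1] / n_left
    mean_right = (cs[-1] - cs[1:-1]) / n_right
    stat = np.abs(mean_left - mean_right) / (sigma * np.sqrt(1.0 / n_left + 1.0 / n_right))
    k = int(np.argmax(stat))
    if stat[k] < threshold:
        return
    cut = a + k + 1
    boundaries.add(cut)
    _split_boundaries(x, a, cut, sigma, threshold, boundaries, depth + 1)
    _split_boundaries(x, cut, b, sigma, threshold, boundaries, depth + 1)


def segment_chromosome(
    chrom: str,
    start: np.ndarray,
    end: np.ndarray,
    log2: np.ndarray,
    sigma: float,
    params: SegmentationParams | None = None,
) -> list[Segment]:
    """Tile one chromosome's probes into candidate segments.

    Every probe belongs to exactly one returned segment; ``is_aberrant``
    reflects the score threshold only (apply :func:`call_aberrations` for
    the full probe-count / amplitude filters).
    """
    params = params or SegmentationParams()
    n = len(log2)
    if n == 0:
        return []
    x = np.asarray(log2, dtype=np.float64)
    boundaries: set[int] = set()
    _find_boundaries(x, 0, n, sigma, 0.0, params.score_threshold, boundaries)
    for a, b in zip(
        sorted(boundaries | {0, n})[:-1], sorted(boundaries | {0, n})[1:]
    ):
        _split_boundaries(x, a, b, sigma, params.score_threshold, boundaries)
    cuts = sorted(boundaries | {0, n})
    segments = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        mean = float(np.mean(x[a:b]))
        score = float(mean * np.sqrt(b - a) / sigma)
        segments.append(
            Segment(
                chrom=chrom,
                start=int(start[a]),
                end=int(end[b - 1]),
                n_probes=b - a,
                mean_log2=mean,
                score=score,
                is_aberrant=abs(score) >= params.score_threshold,
                first_probe=a,
                last_probe=b - 1,
            )
        )
    return segments


def call_aberrations(
    segments: list[Segment],
    params: SegmentationParams | None = None,
    probe_log2: np.ndarray | None = None,
) -> list[Segment]:
    """Apply the aberration filters and merge rejected runs into neutral.

    A segment is kept as aberrant iff ``n_probes >= min_probes`` and
    ``|mean_log2| > min_abs_mean_log2`` and ``|score| >= score_threshold``.
    Consecutive non-kept segments are merged into single neutral segments
    (mean recomputed from probes when ``probe_log2`` is given, otherwise
    probe-count weighted).

    Returns the complete tiling; aberrant-only output is
    ``[s for s in result if s.is_aberrant]``.
    """
    params = params or SegmentationParams()
    if not segments:
        return []
    sigma_implied = None  # recover sigma from any segment: score = mean*sqrt(n)/sigma
    for s in segments:
        if s.score != 0 and s.mean_log2 != 0:
            sigma_implied = s.mean_log2 * np.sqrt(s.n_probes) / s.score
            break
    out: list[Segment] = []
    pending: list[Segment] = []

    def flush() -> None:
        if not pending:
            return
        first, last = pending[0], pending[-1]
        n = sum(p.n_probes for p in pending)
        if probe_log2 is not None and first.first_probe >= 0:
            mean = float(np.mean(probe_log2[first.first_probe : last.last_probe + 1]))
        else:
            mean = float(sum(p.mean_log2 * p.n_probes for p in pending) / n)
        score = float(mean * np.sqrt(n) / sigma_implied) if sigma_implied else 0.0
        out.append(
            Segment(
                chrom=first.chrom,
                start=first.start,
                end=last.end,
                n_probes=n,
                mean_log2=mean,
                score=score,
                is_aberrant=False,
                first_probe=first.first_probe,
                last_probe=last.last_probe,
            )
        )
        pending.clear()

    for seg in segments:
        keep = (
            seg.n_probes >= params.min_probes
            and abs(seg.mean_log2) > params.min_abs_mean_log2
            and abs(seg.score) >= params.score_threshold
        )
        if keep:
            flush()
            out.append(replace(seg, is_aberrant=True))
        else:
            pending.append(seg)
    flush()
    return out


def segment_track(
    track: ProbeTrack,
    params: SegmentationParams | None = None,
    sigma: float | None = None,
) -> dict[str, list[Segment]]:
    """Segment every chromosome of a sample; returns tilings per chromosome."""
    params = params or SegmentationParams()
    if sigma is None:
        sigma = estimate_noise_sd(track)
    result: dict[str, list[Segment]] = {}
    for chrom in track.chromosomes:
        start, end, log2 = track.chromosome(chrom)
        tiles = segment_chromosome(chrom, start, end, log2, sigma, params)
        result[chrom] = call_aberrations(tiles, params, probe_log2=log2)
    return result
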