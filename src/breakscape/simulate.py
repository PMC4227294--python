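"""Synthetic aCGH profiles with known ground truth.

Emulates the 244K oligonucleotide-array setting: a jittered probe grid at
~12.7 kb mean spacing over hg19-proportioned chromosomes, planted
segmental gains/losses (integer copy states on a diploid baseline,
>= 100 kb — the platform's stated confident detection floor), nested
amplicons with internal steps, chromothriptic chromosomes oscillating
among 2–3 copy-number states, Gaussian probe noise, and stromal
admixture.  A probe over ``c`` tumor copies with normal-cell
contamination fraction ``p`` reads

    log2( (p * 2 + (1 - p) * c) / 2 ) + N(0, sigma_probe),

clamped at a floor (default -4) for homozygous deletions in pure tumor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from .containers import ProbeTrack, SampleMeta
from .genome import GenomeModel

__all__ = [
    "GroundTruth",
    "SubtypeSpec",
    "expected_log2",
    "make_probe_grid",
    "plant_stepwise_cna",
    "plant_chromothripsis",
    "render_profile",
    "simulate_cohort",
    "DEFAULT_COHORT_SPECS",
]

logger = logging.getLogger(__name__)

LOG2_FLOOR = -4.0
NEUTRAL_COPIES = 2

# Copy-state sets for chromothriptic oscillation.  Sets are restricted to
# states separated pairwise by >= 1.0 in expected log2 — well above the 0.5
# breakpoint filter — so every oscillation transition is both filterable
# and resolvable at the conservative score threshold with ~20-probe
# segments (an alternation of amplitude d deviates only ±d/2 from the
# regional mean, which is what the segmenter must detect).
STATE_SETS_2 = ((1, 3), (2, 4), (1, 4), (2, 5), (1, 5))
STATE_SETS_3 = ((1, 2, 4), (1, 2, 5))


def expected_log2(
    copies: float, contamination: float = 0.0, floor: float = LOG2_FLOOR
) -> float:
    """Noise-free log2 ratio for ``copies`` tumor copies at admixture ``p``."""
    mix = contamination * 2.0 + (1.0 - contamination) * copies
    if mix <= 0:
        return floor
    return max(math.log2(mix / 2.0), floor)


@dataclass
class GroundTruth:
    """Planted copy-number truth for one simulated sample.

    ``events`` holds, per chromosome, sorted non-overlapping
    ``(start, end, copies)`` intervals with ``copies != 2``; everything
    else is neutral diploid.  True breakpoints are the boundaries between
    consecutive distinct states in the implied full tiling (chromosome
    ends excluded).
    """

    genome: GenomeModel
    events: dict[str, list[tuple[int, int, int]]] = dc_field(default_factory=dict)
    chromothripsis: set[str] = dc_field(default_factory=set)
    contamination: float = 0.0
    sigma_probe: float = 0.2
    min_len_bp: int = 100_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination < 1.0):
            raise ValueError("contamination must be in [0, 1)")

    def add_event(self, chrom: str, start: int, end: int, copies: int) -> None:
        if chrom not in self.genome:
            raise KeyError(f"chromosome {chrom} not in genome")
        if copies == NEUTRAL_COPIES or copies < 0:
            raise ValueError(f"event copies must be a non-negative integer != 2, got {copies}")
        if not (0 <= start < end <= self.genome.length(chrom)):
            raise ValueError(f"event out of bounds: {chrom}:{start}-{end}")
        evs = self.events.setdefault(chrom, [])
        for s, e, _ in evs:
            if start < e and s < end:
                raise ValueError(f"event overlaps existing event on {chrom}")
        evs.append((start, end, copies))
        evs.sort()

    def overlaps(self, chrom: str, start: int, end: int, margin: int = 0) -> bool:
        for s, e, _ in self.events.get(chrom, []):
            if start - margin < e and s < end + margin:
                return True
        return False

    def state_tiling(self, chrom: str) -> list[tuple[int, int, int]]:
        """Full (start, end, copies) tiling of the chromosome, neutral gaps included."""
        length = self.genome.length(chrom)
        tiles: list[tuple[int, int, int]] = []
        pos = 0
        for s, e, c in self.events.get(chrom, []):
            if s > pos:
                tiles.append((pos, s, NEUTRAL_COPIES))
            tiles.append((s, e, c))
            pos = e
        if pos < length:
            tiles.append((pos, length, NEUTRAL_COPIES))
        return tiles

    def true_breakpoints(
        self, chrom: str, delta_filter: float | None = None
    ) -> list[tuple[int, float]]:
        """(position, expected delta log2) at each state change on ``chrom``."""
        tiles = self.state_tiling(chrom)
        out = []
        for (s1, e1, c1), (s2, e2, c2) in zip(tiles[:-1], tiles[1:]):
            if c1 == c2:
                continue
            delta = expected_log2(c2, self.contamination) - expected_log2(
                c1, self.contamination
            )
            if delta_filter is None or abs(delta) > delta_filter:
                out.append((e1, delta))
        return out

    def all_breakpoints(self, delta_filter: float | None = None) -> list[tuple[str, int, float]]:
        return [
            (chrom, pos, delta)
            for chrom in self.genome.chromosomes
            for pos, delta in self.true_breakpoints(chrom, delta_filter)
        ]

    def bpi(self, delta_filter: float = 0.5) -> int:
        """Ground-truth breakpoint instability index (filterable breaks)."""
        return len(self.all_breakpoints(delta_filter))

    def altered_bp(self) -> int:
        return sum(e - s for evs in self.events.values() for s, e, _ in evs)

    def pga(self) -> float:
        return self.altered_bp() / self.genome.total_bp


def make_probe_grid(
    genome: GenomeModel,
    mean_spacing_bp: float = 12_700.0,
    seed: int = 0,
    probe_len: int = 60,
    jitter_frac: float = 0.4,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Jittered, sorted probe coordinates covering each chromosome.

    Per chromosome the probe count is ``round(length / mean_spacing_bp)``
    (floor 2) and each probe sits on a regular grid displaced by a uniform
    jitter of ±``jitter_frac`` spacings, which avoids aliasing between the
    grid and planted segment boundaries.
    """
    if mean_spacing_bp <= 0:
        raise ValueError("mean_spacing_bp must be > 0")
    rng = np.random.default_rng(seed)
    grid: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome.chromosomes:
        length = genome.length(chrom)
        n = int(round(length / mean_spacing_bp))
        if n < 2:
            logger.warning(
                "spacing %.0f exceeds half of %s (%d bp); flooring at 2 probes",
                mean_spacing_bp, chrom, length,
            )
            n = 2
        step = length / n
        centers = (np.arange(n) + 0.5) * step
        jitter = rng.uniform(-jitter_frac, jitter_frac, size=n) * step
        start = np.round(centers + jitter).astype(np.int64)
        start = np.clip(start, 0, max(length - probe_len, 1))
        # enforce strictly increasing starts (min step 1 bp)
        start = np.maximum.accumulate(start - np.arange(n)) + np.arange(n)
        end = np.minimum(start + probe_len, length)
        grid[chrom] = (start, end)
    return grid


def _place_interval(
    rng: np.random.Generator,
    truth: GroundTruth,
    length: int,
    margin: int,
    chrom: str | None = None,
    tries: int = 200,
) -> tuple[str, int] | None:
    genome = truth.genome
    chroms = [chrom] if chrom else list(genome.chromosomes)
    weights = np.array([genome.length(c) for c in chroms], dtype=float)
    weights /= weights.sum()
    for _ in range(tries):
        c = chroms[int(rng.choice(len(chroms), p=weights))]
        space = genome.length(c) - length
        if space <= 0:
            continue
        s = int(rng.integers(0, space))
        if not truth.overlaps(c, s, s + length, margin=margin):
            return c, s
    return None


def plant_stepwise_cna(
    genome: GenomeModel,
    n_events: int,
    min_len_bp: int = 100_000,
    seed: int = 0,
    *,
    max_len_bp: int = 2_000_000,
    states: tuple[int, ...] = (0, 1, 3, 4, 5),
    nested_prob: float = 0.0,
    gap_bp: int = 500_000,
    truth: GroundTruth | None = None,
    sigma_probe: float = 0.2,
    contamination: float = 0.0,
) -> GroundTruth:
    """Plant sporadic, non-overlapping gain/loss segments.

    Event lengths are log-uniform on [min_len_bp, max_len_bp]; copy states
    are drawn uniformly from ``states`` (diploid baseline 2).  With
    ``nested_prob`` an event long enough receives an internal step (a
    further gain inside a gain, or homozygous loss inside a loss),
    producing intra-amplicon breakpoints.
    """
    if n_events < 0:
        raise ValueError("n_events must be >= 0")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = GroundTruth(
            genome, sigma_probe=sigma_probe, contamination=contamination, min_len_bp=min_len_bp
        )
    for k in range(n_events):
        length = int(
            math.exp(rng.uniform(math.log(min_len_bp), math.log(max_len_bp)))
        )
        placed = _place_interval(rng, truth, length, margin=gap_bp)
        if placed is None:
            raise ValueError(
                f"could not place event {k + 1} of {n_events}: genome too crowded "
                f"(placed {k}, total event span so far {truth.altered_bp()} bp "
                f"of {genome.total_bp} bp)"
            )
        chrom, s = placed
        copies = int(rng.choice(states))
        e = s + length
        if (
            rng.random() < nested_prob
            and length >= 3 * min_len_bp
            and copies in (1, 3, 4)
        ):
            inner_c = copies + 1 if copies >= 3 else 0
            inner_len = int(rng.uniform(min_len_bp, length / 2))
            inner_s = s + int(rng.uniform(min_len_bp, length - inner_len - min_len_bp))
            truth.add_event(chrom, s, inner_s, copies)
            truth.add_event(chrom, inner_s, inner_s + inner_len, inner_c)
            truth.add_event(chrom, inner_s + inner_len, e, copies)
        else:
            truth.add_event(chrom, s, e, copies)
    return truth


def _oscillation_sequence(
    rng: np.random.Generator,
    states: tuple[int, ...],
    n_segments: int,
    return_prob: float = 0.75,
) -> list[int]:
    """Oscillating adjacent-distinct walk over ``states``.

    Oscillation means returning: with probability ``return_prob`` each
    segment revisits the state two segments back, so three-state regions
    are dominated by pairwise alternation with excursions to the third
    level rather than a memoryless walk.  Starts/ends neutral when the
    set includes the neutral state, keeping region edges silent.
    """
    has_neutral = NEUTRAL_COPIES in states
    seq: list[int] = []
    if has_neutral:
        seq.append(NEUTRAL_COPIES)
    else:
        seq.append(int(rng.choice(states)))
    while len(seq) < n_segments:
        remaining = n_segments - len(seq)
        choices = [s for s in states if s != seq[-1]]
        if has_neutral and remaining == 1:
            # close on neutral when the walk allows it, so region edges are silent
            nxt = NEUTRAL_COPIES if seq[-1] != NEUTRAL_COPIES else int(rng.choice(choices))
        elif has_neutral and remaining == 2 and seq[-1] == NEUTRAL_COPIES:
            nxt = int(rng.choice([s for s in choices if s != NEUTRAL_COPIES]))
        elif len(seq) >= 2 and seq[-2] != seq[-1] and rng.random() < return_prob:
            nxt = seq[-2]
        else:
            nxt = int(rng.choice(choices))
        seq.append(nxt)
    return seq


def plant_chromothripsis(
    genome: GenomeModel,
    chromosome: str,
    n_breaks: int,
    n_states: int = 2,
    seed: int = 0,
    *,
    states: tuple[int, ...] | None = None,
    seg_len_range: tuple[int, int] = (250_000, 600_000),
    min_len_bp: int = 100_000,
    truth: GroundTruth | None = None,
    sigma_probe: float = 0.2,
    contamination: float = 0.0,
) -> GroundTruth:
    """Tile a sub-region of ``chromosome`` with oscillating copy states.

    ``n_breaks`` is the number of state changes among the oscillating
    segments (``n_breaks + 1`` segments are planted).  When the state set
    includes the neutral state the walk starts and ends neutral where the
    alternation parity allows, so region edges add no extra breaks;
    otherwise the region's two edges against the diploid background add
    two further true breakpoints.
    """
    if n_breaks < 8:
        raise ValueError(f"n_breaks must be >= 8 for a chromothripsis pattern, got {n_breaks}")
    if n_states not in (2, 3):
        raise ValueError(f"n_states must be 2 or 3, got {n_states}")
    if chromosome not in genome:
        raise KeyError(f"chromosome {chromosome} not in genome")
    rng = np.random.default_rng(seed)
    if states is None:
        pool = STATE_SETS_2 if n_states == 2 else STATE_SETS_3
        states = tuple(pool[int(rng.integers(len(pool)))])
    if len(set(states)) != n_states:
        raise ValueError(f"states {states} must contain {n_states} distinct values")
    if seg_len_range[0] < min_len_bp:
        raise ValueError(
            f"segment length range {seg_len_range} falls below the minimum "
            f"aberration length {min_len_bp} bp"
        )
    if truth is None:
        truth = GroundTruth(
            genome, sigma_probe=sigma_probe, contamination=contamination, min_len_bp=min_len_bp
        )
    n_segments = n_breaks + 1
    lengths = rng.integers(seg_len_range[0], seg_len_range[1] + 1, size=n_segments)
    total = int(lengths.sum())
    chrom_len = genome.length(chromosome)
    if total > 0.9 * chrom_len:
        raise ValueError(
            f"{n_segments} segments of {seg_len_range} bp need {total} bp, "
            f"exceeding 90% of {chromosome} ({chrom_len} bp)"
        )
    seq = _oscillation_sequence(rng, states, n_segments)
    placed = _place_interval(rng, truth, total, margin=500_000, chrom=chromosome)
    if placed is None:
        raise ValueError(f"no room for a {total} bp chromothripsis region on {chromosome}")
    _, region_start = placed
    pos = region_start
    for c, seg_len in zip(seq, lengths):
        if c != NEUTRAL_COPIES:
            truth.add_event(chromosome, pos, pos + int(seg_len), c)
        pos += int(seg_len)
    truth.chromothripsis.add(chromosome)
    return truth


def render_profile(
    grid: dict[str, tuple[np.ndarray, np.ndarray]],
    truth: GroundTruth,
    seed: int = 0,
    sample: str = "sim",
    floor: float = LOG2_FLOOR,
) -> ProbeTrack:
    """Probe-level log2 ratios for the planted truth on a probe grid."""
    rng = np.random.default_rng(seed)
    p = truth.contamination
    track = ProbeTrack(sample=sample)
    for chrom, (start, end) in grid.items():
        mid = (start + end) // 2
        copies = np.full(len(mid), NEUTRAL_COPIES, dtype=float)
        for s, e, c in truth.events.get(chrom, []):
            copies[(mid >= s) & (mid < e)] = c
        mix = p * 2.0 + (1.0 - p) * copies
        with np.errstate(divide="ignore"):
            log2 = np.where(mix > 0, np.log2(np.maximum(mix, 1e-300) / 2.0), floor)
        clamped = int((log2 < floor).sum())
        if clamped:
            logger.info("%s %s: %d probes clamped at log2 floor %.1f", sample, chrom, clamped, floor)
        log2 = np.maximum(log2, floor)
        if truth.sigma_probe > 0:
            log2 = log2 + rng.normal(0.0, truth.sigma_probe, size=len(log2))
        track.add_chromosome(chrom, start, end, log2, validate=False)
    return track


@dataclass(frozen=True)
class SubtypeSpec:
    """Per-subtype simulation profile for cohort generation."""

    events_range: tuple[int, int] = (10, 40)
    chromothripsis_prob: float = 0.0
    ct_breaks_range: tuple[int, int] = (12, 16)
    ct_states_choices: tuple[int, ...] = (2, 3)
    nested_prob: float = 0.15
    contamination: float = 0.0
    sigma_probe: float = 0.2
    ploidy_weights: dict[str, float] = dc_field(
        default_factory=lambda: {"A": 1.0}
    )


# Cohort defaults mirror the study setting: flow-sorted (near-pure) tumor
# fractions, subtype-dependent event burden, and chromothripsis prevalence
# of roughly one half in ER+/HER2+ and one quarter in TNBC.
DEFAULT_COHORT_SPECS: dict[str, SubtypeSpec] = {
    "ER+": SubtypeSpec(
        events_range=(10, 35),
        chromothripsis_prob=0.50,
        ploidy_weights={"A": 0.5, "D/T": 0.5},
    ),
    "HER2+": SubtypeSpec(
        events_range=(15, 50),
        chromothripsis_prob=0.556,
        ploidy_weights={"A": 1.0},
    ),
    "TNBC": SubtypeSpec(
        events_range=(12, 45),
        chromothripsis_prob=0.25,
        ploidy_weights={"A": 8.0, "D": 2.0, "T": 2.0},
    ),
}


def simulate_cohort(
    n_per_subtype: int | dict[str, int],
    specs: dict[str, SubtypeSpec] | None = None,
    seed: int = 0,
    genome: GenomeModel | None = None,
    mean_spacing_bp: float = 12_700.0,
) -> list[tuple[ProbeTrack, SampleMeta, GroundTruth]]:
    """Simulate a reproducible cohort of (profile, metadata, truth) triples."""
    from .genome import hg19

    specs = specs if specs is not None else DEFAULT_COHORT_SPECS
    if isinstance(n_per_subtype, int):
        n_per_subtype = {subtype: n_per_subtype for subtype in specs}
    genome = genome or hg19()
    rng = np.random.default_rng(seed)
    grid = make_probe_grid(genome, mean_spacing_bp, seed=int(rng.integers(2**31)))
    cohort = []
    for subtype, n in n_per_subtype.items():
        spec = specs[subtype]
        tag = subtype.replace("+", "pos").replace("/", "")
        for i in range(n):
            s_ct, s_step, s_noise = (int(rng.integers(2**31)) for _ in range(3))
            sample_id = f"{tag}_{i + 1:03d}"
            truth = GroundTruth(
                genome,
                sigma_probe=spec.sigma_probe,
                contamination=spec.contamination,
            )
            if rng.random() < spec.chromothripsis_prob:
                n_breaks = int(rng.integers(spec.ct_breaks_range[0], spec.ct_breaks_range[1] + 1))
                n_states = int(rng.choice(spec.ct_states_choices))
                # prefer chromosomes big enough for the oscillating region
                need = (n_breaks + 1) * 500_000 / 0.8
                eligible = [c for c in genome.chromosomes if genome.length(c) > need]
                if eligible:
                    chrom = eligible[int(rng.integers(len(eligible)))]
                    plant_chromothripsis(
                        genome, chrom, n_breaks, n_states, seed=s_ct, truth=truth
                    )
            n_events = int(rng.integers(spec.events_range[0], spec.events_range[1] + 1))
            plant_stepwise_cna(
                genome, n_events, seed=s_step, nested_prob=spec.nested_prob, truth=truth
            )
            track = render_profile(grid, truth, seed=s_noise, sample=sample_id)
            ploidies = list(spec.ploidy_weights)
            w = np.array([spec.ploidy_weights[p] for p in ploidies], dtype=float)
            ploidy = ploidies[int(rng.choice(len(ploidies), p=w / w.sum()))]
            meta = SampleMeta(sample=sample_id, subtype=subtype, ploidy=ploidy)
            cohort.append((track, meta, truth))
    return cohort
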