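"""Operational chromothripsis signature on copy-number evidence.

Chromothripsis leaves many breakpoints confined to one or two chromosomes
(sometimes a small part of one), with segments oscillating among a
limited number (two, sometimes three) of copy-number states.  The
detector formalizes that visual signature: per chromosome it clusters the
mean log2 ratios of the segments spanning the aberrant region into
states, counts oscillations (returns to a previously visited aberrant
state), and calls the chromosome when

* filtered breakpoints  >= ``min_breaks``       (default 10),
* aberrant copy states  <= ``max_states``       (default 3, counting the
  fewest states covering >= ``min_state_cover`` of aberrant bases), and
* oscillations          >= ``min_oscillations`` (default 4).

LOH is deliberately not an input: two-color aCGH cannot assess it.  A
sample called on more than ``max_chroms`` chromosomes is flagged as
globally unstable for review instead of being called, since the signature
is by definition confined.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .breakpoints import Breakpoint
from .containers import SampleMeta
from .segmentation import Segment

__all__ = [
    "ChromothripsisCall",
    "ChromothripsisParams",
    "cluster_states",
    "oscillation_count",
    "detect_chromothripsis",
    "tabulate_calls",
    "chromosome_prevalence",
    "TickTable",
]


@dataclass(frozen=True)
class ChromothripsisParams:
    min_breaks: int = 10
    max_states: int = 3
    min_state_cover: float = 0.8
    min_oscillations: int = 4
    max_chroms: int = 2
    state_gap: float = 0.25


@dataclass(frozen=True)
class ChromothripsisCall:
    """Per (sample, chromosome) decision with the evidence behind it."""

    sample: str
    chrom: str
    n_breakpoints: int
    n_states: int
    oscillation_count: int
    affected_span_bp: int
    confinement_fraction: float
    decision: bool
    params: ChromothripsisParams
    global_instability: bool = False  # set when the sample exceeded max_chroms


def cluster_states(means: np.ndarray | list[float], gap: float = 0.25) -> np.ndarray:
    """1-D agglomeration of segment means into copy-number states.

    Sorted means start a new state whenever the gap to the previous mean
    exceeds ``gap``.  Returns an integer label per input mean; labels are
    ordered by increasing mean.
    """
    means = np.asarray(means, dtype=np.float64)
    if len(means) == 0:
        return np.empty(0, dtype=np.int64)
    order = np.argsort(means, kind="stable")
    labels = np.empty(len(means), dtype=np.int64)
    state = 0
    labels[order[0]] = 0
    for prev, cur in zip(order[:-1], order[1:]):
        if means[cur] - means[prev] > gap:
            state += 1
        labels[cur] = state
    return labels


def oscillation_count(labels: np.ndarray | list[int], ignore: set[int] | None = None) -> int:
    """Returns to a previously visited state in the segment sequence.

    A return is counted when a segment revisits the state seen two
    segments back (``s[i] == s[i-2]`` with ``s[i] != s[i-1]``) — the
    interdigitated alternation that defines a copy-number oscillation.
    Revisits across longer distances are not oscillations: isolated
    aberrations separated by long neutral runs revisit the baseline
    without ever alternating.  ``ignore`` additionally drops returns
    *into* the listed states (the detector ignores returns to the neutral
    baseline, which any pair of isolated aberrations produces).
    """
    ignore = ignore or set()
    labs = [int(l) for l in labels]
    return sum(
        1
        for i in range(2, len(labs))
        if labs[i] != labs[i - 1] and labs[i] == labs[i - 2] and labs[i] not in ignore
    )


def _chromosome_evidence(
    tiles: list[Segment], params: ChromothripsisParams
) -> tuple[int, int, int] | None:
    """(n_states, oscillations, span_bp) over the chromosome's aberrant span."""
    aberrant = [s for s in tiles if s.is_aberrant]
    if not aberrant:
        return None
    span_lo = min(s.start for s in aberrant)
    span_hi = max(s.end for s in aberrant)
    in_span = [s for s in tiles if s.end > span_lo and s.start < span_hi]
    in_span.sort(key=lambda s: s.start)
    labels = cluster_states([s.mean_log2 for s in in_span], gap=params.state_gap)
    # states whose segments are all neutral count as baseline, not aberrant states
    aberrant_states = {int(l) for l, s in zip(labels, in_span) if s.is_aberrant}
    neutral_states = {int(l) for l in labels} - aberrant_states
    # fewest aberrant states covering >= min_state_cover of aberrant bases
    bp_per_state: dict[int, int] = {}
    for l, s in zip(labels, in_span):
        if s.is_aberrant:
            bp_per_state[int(l)] = bp_per_state.get(int(l), 0) + s.length_bp
    total_aberrant_bp = sum(bp_per_state.values())
    covered = 0
    n_states = 0
    for _, bp in sorted(bp_per_state.items(), key=lambda kv: -kv[1]):
        covered += bp
        n_states += 1
        if covered >= params.min_state_cover * total_aberrant_bp:
            break
    osc = oscillation_count(labels, ignore=neutral_states)
    return n_states, osc, span_hi - span_lo


def detect_chromothripsis(
    sample: str,
    segments: dict[str, list[Segment]],
    breakpoints: list[Breakpoint],
    params: ChromothripsisParams | None = None,
) -> list[ChromothripsisCall]:
    """Evaluate the signature on every chromosome carrying aberrations.

    Returns one call per chromosome with at least one aberrant segment.
    If more than ``params.max_chroms`` chromosomes meet the thresholds the
    sample is flagged ``global_instability`` and all decisions are
    withdrawn (confinement is part of the signature).
    """
    params = params or ChromothripsisParams()
    breaks_per_chrom: dict[str, int] = {}
    for bp in breakpoints:
        breaks_per_chrom[bp.chrom] = breaks_per_chrom.get(bp.chrom, 0) + 1
    total_breaks = sum(breaks_per_chrom.values())
    calls: list[ChromothripsisCall] = []
    for chrom, tiles in segments.items():
        evidence = _chromosome_evidence(tiles, params)
        if evidence is None:
            continue
        n_states, osc, span = evidence
        n_breaks = breaks_per_chrom.get(chrom, 0)
        decision = (
            n_breaks >= params.min_breaks
            and n_states <= params.max_states
            and osc >= params.min_oscillations
        )
        calls.append(
            ChromothripsisCall(
                sample=sample,
                chrom=chrom,
                n_breakpoints=n_breaks,
                n_states=n_states,
                oscillation_count=osc,
                affected_span_bp=span,
                confinement_fraction=(n_breaks / total_breaks) if total_breaks else 0.0,
                decision=decision,
                params=params,
            )
        )
    n_called = sum(c.decision for c in calls)
    if n_called > params.max_chroms:
        calls = [
            replace(c, decision=False, global_instability=True) if c.decision else c
            for c in calls
        ]
    return calls


@dataclass
class TickTable:
    """Tumor x chromosome chromothripsis tick matrix with marginals."""

    matrix: pd.DataFrame              # bool, samples x chromosomes
    per_chromosome: pd.Series         # tick totals per chromosome
    per_tumor: pd.Series              # tick totals per tumor
    prevalence_overall: float         # % of tumors with >= 1 tick
    prevalence_by_subtype: pd.Series  # % per clinical subtype


def _round_half_up(x: float, ndigits: int = 1) -> float:
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def tabulate_calls(
    calls: dict[str, list[ChromothripsisCall]] | pd.DataFrame,
    roster: list[SampleMeta],
) -> TickTable:
    """Aggregate per-sample calls into the tick matrix and its marginals.

    ``calls`` is either per-sample call lists or an existing boolean
    tumor x chromosome matrix.  ``roster`` supplies the full cohort
    (samples without calls count in the denominators).
    """
    subtype_of = {m.sample: m.subtype for m in roster}
    samples = [m.sample for m in roster]
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids in roster")
    if isinstance(calls, pd.DataFrame):
        matrix = calls.astype(bool).reindex(index=samples, fill_value=False)
    else:
        chroms = sorted(
            {c.chrom for per_sample in calls.values() for c in per_sample if c.decision}
        )
        matrix = pd.DataFrame(False, index=samples, columns=chroms)
        for sample_id, per_sample in calls.items():
            if sample_id not in subtype_of:
                raise KeyError(f"sample {sample_id} not in roster")
            for c in per_sample:
                if c.decision:
                    matrix.loc[sample_id, c.chrom] = True
    per_chromosome = matrix.sum(axis=0)
    per_tumor = matrix.sum(axis=1)
    affected = per_tumor > 0
    prevalence_overall = _round_half_up(100.0 * affected.sum() / len(samples))
    subtypes = pd.Series({s: subtype_of[s] for s in samples})
    prevalence_by_subtype = pd.Series(
        {
            st: _round_half_up(100.0 * affected[subtypes == st].sum() / (subtypes == st).sum())
            for st in sorted(subtypes.unique())
        }
    )
    return TickTable(
        matrix=matrix,
        per_chromosome=per_chromosome,
        per_tumor=per_tumor,
        prevalence_overall=prevalence_overall,
        prevalence_by_subtype=prevalence_by_subtype,
    )


def chromosome_prevalence(
    ticks: TickTable, roster: list[SampleMeta], chrom: str, subtype: str | None = None
) -> float:
    """% of (subtype) tumors ticked on ``chrom`` (round-half-up, 1 decimal)."""
    samples = [m.sample for m in roster if subtype is None or m.subtype == subtype]
    if not samples:
        raise ValueError(f"no samples in stratum {subtype!r}")
    if chrom not in ticks.matrix.columns:
        return 0.0
    hits = int(ticks.matrix.loc[samples, chrom].sum())
    return _round_half_up(100.0 * hits / len(samples))
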