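"""Cohort-level aggregation of instability statistics.

Produces the break-density heat-map matrix (samples x chromosomes, breaks
per 100 Mb, ordered from least to most aberrant genome), chromosome
rankings by total breaks, the BPI–PGA correlation, and the
sample-disposition accounting of a flow-sorting workflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .breakpoints import InstabilityStats
from .containers import SampleMeta
from .genome import GenomeModel

__all__ = [
    "CohortSummary",
    "density_matrix",
    "rank_chromosomes",
    "correlate_bpi_pga",
    "disposition_summary",
    "build_cohort_summary",
]


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    """Per-sample statistics plus the cohort-level aggregates."""

    stats: dict[str, InstabilityStats]
    meta: dict[str, SampleMeta]
    density: pd.DataFrame
    ranking: pd.DataFrame
    bpi_pga_r: float | None


def density_matrix(
    stats: list[InstabilityStats], genome: GenomeModel
) -> pd.DataFrame:
    """Samples x chromosomes matrix of breaks per 100 Mb.

    Rows are ordered by ascending BPI — least aberrant genome first — the
    conventional heat-map layout for break-density panels.
    """
    if not stats:
        raise ValueError("no samples")
    ordered = sorted(stats, key=lambda s: (s.bpi, s.sample))
    data = {
        s.sample: [s.density_per_100mb[c] for c in genome.chromosomes] for s in ordered
    }
    return pd.DataFrame(data, index=list(genome.chromosomes)).T


def rank_chromosomes(
    stats: list[InstabilityStats],
    genome: GenomeModel,
    meta: dict[str, SampleMeta] | None = None,
    subtype: str | None = None,
) -> pd.DataFrame:
    """Chromosomes ordered from most to least broken in a stratum.

    Sorted by total break count descending; ties broken by density (breaks
    per 100 Mb of chromosome) then by name.  ``subtype`` restricts the
    stratum (requires ``meta``).
    """
    stratum = stats
    if subtype is not None:
        if meta is None:
            raise ValueError("subtype stratification requires sample metadata")
        stratum = [s for s in stats if meta[s.sample].subtype == subtype]
    if not stratum:
        raise ValueError(f"empty stratum: {subtype!r}")
    totals = {c: 0 for c in genome.chromosomes}
    for s in stratum:
        for c in genome.chromosomes:
            totals[c] += s.breaks_per_chromosome.get(c, 0)
    rows = [
        {
            "chromosome": c,
            "total_breaks": totals[c],
            "density_per_100mb": totals[c] * 1e8 / genome.length(c),
        }
        for c in genome.chromosomes
    ]
    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["total_breaks", "density_per_100mb", "chromosome"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    return df


def correlate_bpi_pga(stats: list[InstabilityStats]) -> float:
    """Pearson correlation between per-sample BPI and PGA."""
    if len(stats) < 3:
        raise ValueError("need >= 3 samples for a correlation")
    bpi = np.array([s.bpi for s in stats], dtype=float)
    pga = np.array([s.pga for s in stats], dtype=float)
    if np.ptp(bpi) == 0 or np.ptp(pga) == 0:
        raise ValueError("zero variance in BPI or PGA; correlation undefined")
    r, _ = _stats.pearsonr(bpi, pga)
    return float(r)


def disposition_summary(roster: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages per flow-profile disposition category.

    ``roster`` needs one row per specimen with columns ``profile`` (e.g.
    aneuploid/diploid FACS profile), ``category`` (free-text disposition)
    and boolean ``included``.  Returns per-(profile, category) counts with
    an overall total row; percentages are of the grand total, reported to
    one decimal (round-half-up).
    """
    required = {"profile", "category", "included"}
    if roster.empty:
        raise ValueError("empty roster")
    if not required.issubset(roster.columns):
        raise ValueError(f"roster must have columns {sorted(required)}")
    if roster[["profile", "category"]].isna().any().any():
        raise ValueError("unlabeled sample in roster")
    total = len(roster)
    rows = []
    for (profile, category), grp in roster.groupby(["profile", "category"], sort=False):
        inc = int(grp["included"].sum())
        exc = int((~grp["included"].astype(bool)).sum())
        rows.append(
            {
                "profile": profile,
                "category": category,
                "included": inc,
                "excluded": exc,
                "pct_of_total": _round_half_up(100.0 * len(grp) / total),
            }
        )
    df = pd.DataFrame(rows)
    totals = {
        "profile": "Total",
        "category": "",
        "included": int(df["included"].sum()),
        "excluded": int(df["excluded"].sum()),
        "pct_of_total": 100.0,
    }
    out = pd.concat([df, pd.DataFrame([totals])], ignore_index=True)
    out.attrs["total"] = total
    out.attrs["pct_included"] = _round_half_up(100.0 * totals["included"] / total)
    out.attrs["pct_excluded"] = _round_half_up(100.0 * totals["excluded"] / total)
    return out


def profile_fractions(roster: pd.DataFrame) -> dict[str, float]:
    """% of specimens per FACS profile (round-half-up, 1 decimal)."""
    if roster.empty:
        raise ValueError("empty roster")
    total = len(roster)
    return {
        profile: _round_half_up(100.0 * n / total)
        for profile, n in roster["profile"].value_counts().items()
    }


def build_cohort_summary(
    stats: list[InstabilityStats],
    meta: list[SampleMeta],
    genome: GenomeModel,
) -> CohortSummary:
    meta_by_sample = {m.sample: m for m in meta}
    missing = [s.sample for s in stats if s.sample not in meta_by_sample]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    r: float | None
    try:
        r = correlate_bpi_pga(stats)
    except ValueError:
        r = None
    return CohortSummary(
        stats={s.sample: s for s in stats},
        meta=meta_by_sample,
        density=density_matrix(stats, genome),
        ranking=rank_chromosomes(stats, genome),
        bpi_pga_r=r,
    )
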