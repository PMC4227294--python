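"""Packaged reference tables for a 29-tumor flow-sorted breast-cancer cohort.

Three small TSVs ship with the package:

* ``cohort_roster.tsv`` — 29 analyzed tumors (8 ER+, 9 HER2+, 12 TNBC)
  with flow-sorting ploidy class, BPI, and chromothripsis status;
* ``chromothripsis_ticks.tsv`` — the tumor x chromosome chromothripsis
  tick matrix for the 12 affected tumors;
* ``flow_disposition.tsv`` — disposition of all 48 flow-sorted specimens
  (27 aneuploid-profile, 21 diploid-profile; 29 included, 19 excluded).

These drive the worked examples and the exact integer-ratio prevalence
computations of the cohort report.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .containers import SampleMeta

__all__ = [
    "load_cohort_roster",
    "load_chromothripsis_ticks",
    "load_flow_disposition",
    "roster_meta",
    "expand_disposition",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("breakscape.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_cohort_roster() -> pd.DataFrame:
    """Columns: sample, subtype, ploidy, bpi, chromothripsis (0/1)."""
    return _read("cohort_roster.tsv")


def load_chromothripsis_ticks() -> pd.DataFrame:
    """Boolean tumor x chromosome matrix (index: tumor) plus bpi/subtype."""
    df = _read("chromothripsis_ticks.tsv").set_index("tumor")
    chrom_cols = [c for c in df.columns if c.startswith("chr")]
    df[chrom_cols] = df[chrom_cols].astype(bool)
    return df


def load_flow_disposition() -> pd.DataFrame:
    """Per-(profile, category) included/excluded specimen counts."""
    return _read("flow_disposition.tsv")


def roster_meta() -> list[SampleMeta]:
    """The roster as :class:`~breakscape.containers.SampleMeta` records."""
    df = load_cohort_roster()
    return [
        SampleMeta(sample=row.sample, subtype=row.subtype, ploidy=row.ploidy)
        for row in df.itertuples(index=False)
    ]


def expand_disposition() -> pd.DataFrame:
    """Disposition counts expanded to one row per specimen.

    Excluded specimens have no published identifiers, so rows carry
    synthetic ids (F01..F48); columns match
    :func:`breakscape.cohort.disposition_summary` expectations.
    """
    counts = load_flow_disposition()
    rows = []
    for rec in counts.itertuples(index=False):
        for _ in range(int(rec.included)):
            rows.append({"profile": rec.profile, "category": rec.category, "included": True})
        for _ in range(int(rec.excluded)):
            rows.append({"profile": rec.profile, "category": rec.category, "included": False})
    df = pd.DataFrame(rows)
    df.insert(0, "specimen", [f"F{i + 1:02d}" for i in range(len(df))])
    return df
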