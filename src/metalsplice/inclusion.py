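"""Exon inclusion levels: PSI / EST aggregation, candidate selection and
validation bookkeeping.

PSI (percent spliced in) is on the 0-100 scale throughout; EST-derived
inclusion levels (inclLevel, constitLevel, usage3Level, usage5Level) are
treated identically once scaled to percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CATEGORIES = ("PSI", "inclLevel", "constitLevel", "usage3Level", "usage5Level")


@dataclass(frozen=True)
class InclusionRecord:
    exon_id: str
    tissue: str
    value: float  # percent, 0-100
    source: str = "psi_table"  # psi_table | est_table
    category: str = "PSI"

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 100.0):
            raise ValueError(
                f"inclusion value {self.value} for {self.exon_id}/{self.tissue} "
                "outside [0, 100]"
            )
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.source == "psi_table" and self.category != "PSI":
            raise ValueError("psi_table records must carry category PSI")
        if self.source == "est_table" and self.category == "PSI":
            raise ValueError("est_table records carry EST-level categories")


@dataclass(frozen=True)
class ValidationOutcome:
    """RT-PCR validation outcome of one exon in one transcriptome context."""

    exon_id: str
    transcriptome: str  # one of 4 declared contexts
    skipped: bool


def mean_inclusion(
    records: Sequence[InclusionRecord],
    by: str = "exon",
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """n / mean / SEM of inclusion values per stratum.

    ``by`` is one of 'exon', 'exon_tissue' or 'group' (the latter needs a
    ``groups`` mapping exon_id -> group label).  Missing tissues are simply
    absent; nothing is imputed.
    """
    if not records:
        raise ValueError("no inclusion records")
    df = pd.DataFrame(
        {
            "exon_id": [r.exon_id for r in records],
            "tissue": [r.tissue for r in records],
            "value": [r.value for r in records],
        }
    )
    if by == "exon":
        keys = ["exon_id"]
    elif by == "exon_tissue":
        keys = ["exon_id", "tissue"]
    elif by == "group":
        if groups is None:
            raise ValueError("by='group' requires a groups mapping")
        df["group"] = df["exon_id"].map(groups)
        if df["group"].isna().any():
            missing = sorted(df.loc[df["group"].isna(), "exon_id"].unique())
            raise ValueError(f"exons without a group label: {missing[:5]}")
        keys = ["group"]
    else:
        raise ValueError(f"unknown stratification {by!r}")
    agg = df.groupby(keys)["value"].agg(
        n="count", mean="mean", sem=lambda v: v.sem(ddof=1)
    )
    return agg.reset_index()


def exclude_small_exons(
    records: Iterable[InclusionRecord],
    lengths: Mapping[str, int],
    min_len: int = 28,
) -> tuple[list[InclusionRecord], int]:
    """Drop records for exons shorter than ``min_len`` nt (microexons are
    generally less efficiently included, biasing PSI comparisons)."""
    kept, dropped = [], 0
    for r in records:
        try:
            length = lengths[r.exon_id]
        except KeyError:
            raise KeyError(f"no length for exon {r.exon_id}") from None
        if length < min_len:
            dropped += 1
        else:
            kept.append(r)
    return kept, dropped


def select_candidates(
    records: Sequence[InclusionRecord],
    threshold: float = 90.0,
    tissue_set: Sequence[str] = ("neural", "muscle", "testis", "esc"),
) -> list[str]:
    """Exons whose mean PSI drops below ``threshold`` in at least one of
    the given tissues (candidates for regulated splicing)."""
    if not tissue_set:
        raise ValueError("tissue_set must be non-empty")
    tissues = set(tissue_set)
    per = mean_inclusion(
        [r for r in records if r.tissue in tissues], by="exon_tissue"
    ) if any(r.tissue in tissues for r in records) else pd.DataFrame(
        columns=["exon_id", "tissue", "n", "mean", "sem"]
    )
    hits = per.loc[per["mean"] < threshold, "exon_id"].unique()
    return sorted(hits)


def validation_summary(
    outcomes: Sequence[ValidationOutcome],
    tested_exons: Sequence[str],
    n_contexts: int = 4,
) -> dict:
    """Counts of exons skipping in >= 1 and in all transcriptome contexts.

    ``percent`` is 100 * n_skipping_any / n_tested, rounded to the nearest
    integer (the granularity at which such screens are reported).
    """
    tested = set(tested_exons)
    if not tested:
        raise ValueError("empty tested set")
    seen: dict[tuple[str, str], bool] = {}
    for o in outcomes:
        if o.exon_id not in tested:
            raise ValueError(f"outcome for untested exon {o.exon_id}")
        key = (o.exon_id, o.transcriptome)
        if key in seen:
            raise ValueError(f"duplicate outcome for {key}")
        seen[key] = o.skipped
    skip_counts: dict[str, int] = {}
    for (exon_id, _), skipped in seen.items():
        if skipped:
            skip_counts[exon_id] = skip_counts.get(exon_id, 0) + 1
    n_any = sum(1 for v in skip_counts.values() if v >= 1)
    n_all = sum(1 for v in skip_counts.values() if v >= n_contexts)
    n_tested = len(tested)
    return {
        "n_tested": n_tested,
        "n_skipping_any": n_any,
        "percent": int(round(100.0 * n_any / n_tested)),
        "n_skipping_all": n_all,
    }
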