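"""Exon-level ESE/ESS profiling and group comparisons.

Maps metal-coordinating residue annotations onto exons, applies the
dataset filters (stringent vs homology-extended, metal-site validation
status), trims the first and last 3 exonic nucleotides (which shape the
splice-site consensus rather than the auxiliary code), and computes the
mean ln(ESEseq/ESSseq) over all remaining overlapping hexamers per exon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from metalsplice.hexamers import HexamerScoreTable, normalize_nt
from metalsplice import stattests

EXON_GROUPS = ("ZF", "ZnT", "ZIP", "MT", "S100", "EF", "control")
CMM_STATUSES = ("plausible", "problematic", "not_validated", "unassessed")


@dataclass(frozen=True)
class CoordinatingResidue:
    """One metal-coordinating residue with its exon/codon bookkeeping."""

    protein_id: str
    residue_pos: int  # 1-based in the protein
    residue: str  # 1-letter amino acid
    metal: str  # e.g. Zn, Ca
    cmm_status: str = "unassessed"
    homology_extended: bool = False
    codon_start_in_exon: int | None = None  # 0-based, None if unmapped
    near_junction: bool = False  # codon within 3 nt of an exon-intron junction

    def __post_init__(self) -> None:
        if self.residue_pos < 1:
            raise ValueError("residue_pos is 1-based, must be >= 1")
        if self.cmm_status not in CMM_STATUSES:
            raise ValueError(f"unknown cmm_status {self.cmm_status!r}")


@dataclass
class ExonRecord:
    """An exon with its flanking intron sequence, sense strand.

    ``upstream_intron`` is the 3' end of the preceding intron (acceptor
    side), ``downstream_intron`` the 5' end of the following intron.
    """

    exon_id: str
    gene: str
    seq: str
    upstream_intron: str = ""
    downstream_intron: str = ""
    group: str = "control"
    coords: tuple[int, int] | None = None  # 0-based half-open
    strand: str = "+"

    def __post_init__(self) -> None:
        self.seq = normalize_nt(self.seq)
        self.upstream_intron = normalize_nt(self.upstream_intron)
        self.downstream_intron = normalize_nt(self.downstream_intron)
        if not self.seq:
            raise ValueError(f"exon {self.exon_id}: empty sequence")
        if self.strand not in "+-":
            raise ValueError(f"exon {self.exon_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class ExonProfile:
    exon_id: str
    n_hexamers: int  # non-neutral hexamer windows in the trimmed core
    mean_ln_ratio: float | None
    trimmed_len: int


def apply_dataset_filters(
    residues: Iterable[CoordinatingResidue],
    mode: str = "extended",
    cmm_filter: bool = False,
) -> tuple[list[CoordinatingResidue], dict[str, int]]:
    """Filter residue annotations like the stringent/extended dataset variants.

    ``mode='stringent'`` drops residues inferred only through homology in
    multiple alignments; ``cmm_filter`` additionally drops residues whose
    structural metal-site assignment could not be validated.  Returns the
    filtered list plus a count report (n_codons, n_proteins).
    """
    if mode not in ("stringent", "extended"):
        raise ValueError(f"unknown mode {mode!r}; use 'stringent' or 'extended'")
    kept = []
    for r in residues:
        if mode == "stringent" and r.homology_extended:
            continue
        if cmm_filter and r.cmm_status == "not_validated":
            continue
        kept.append(r)
    report = {
        "n_codons": len(kept),
        "n_proteins": len({r.protein_id for r in kept}),
    }
    return kept, report


def trim_exon(seq: str) -> str:
    """Drop the first and last 3 nt of an exon (splice-site consensus)."""
    seq = normalize_nt(seq)
    if len(seq) <= 6:
        return ""
    return seq[3 : len(seq) - 3]


def exon_profile(table: HexamerScoreTable, exon: ExonRecord) -> ExonProfile:
    """Mean ln(ESEseq/ESSseq) over all hexamers of the trimmed exon core.

    Each overlapping hexamer of the core contributes its own ln(ese/ess);
    neutral hexamers are skipped.  Cores shorter than 6 nt (exons of
    <= 11 nt) yield an undefined mean.  Intron flanks never enter the mean.
    """
    core = trim_exon(exon.seq)
    ratios = []
    for start in range(0, max(0, len(core) - 5)):
        r = table.ln_ratio(core[start : start + 6])
        if r is not None:
            ratios.append(r)
    if not ratios:
        return ExonProfile(exon.exon_id, 0, None, len(core))
    return ExonProfile(
        exon.exon_id, len(ratios), float(np.mean(ratios)), len(core)
    )


def filter_exons_for_comparison(
    exons: Iterable[ExonRecord], max_len: int = 350
) -> tuple[list[ExonRecord], int]:
    """Drop exons longer than ``max_len`` nt (terminal/large-exon bias)."""
    if max_len <= 0:
        raise ValueError("max_len must be positive")
    exons = list(exons)
    kept = [e for e in exons if len(e.seq) <= max_len]
    return kept, len(exons) - len(kept)


def pool_groups(
    exons: Iterable[ExonRecord], pooling: Mapping[str, str]
) -> list[ExonRecord]:
    """Relabel exon groups via a pooling map (e.g. ZnT/ZIP/MT/S100 -> other_ZnBP)."""
    out = []
    for e in exons:
        if e.group in pooling:
            e = ExonRecord(
                e.exon_id, e.gene, e.seq, e.upstream_intron,
                e.downstream_intron, pooling[e.group], e.coords, e.strand,
            )
        out.append(e)
    return out


def compare_exon_groups(
    profiles_by_group: Mapping[str, Sequence[ExonProfile]],
) -> dict:
    """Group comparison of exon mean ln(ESE/ESS): summaries, ANOVA with
    Tukey-Kramer post-hoc verdicts, and Kruskal-Wallis.

    Profiles with undefined means are dropped per group (reported as
    ``n_undefined``); every remaining group needs >= 2 defined profiles.
    """
    groups: dict[str, np.ndarray] = {}
    summaries: dict[str, dict] = {}
    for label, profiles in profiles_by_group.items():
        values = [p.mean_ln_ratio for p in profiles if p.mean_ln_ratio is not None]
        if not values:
            raise ValueError(f"group {label!r} has no defined exon profiles")
        arr = np.asarray(values, dtype=float)
        groups[label] = arr
        summaries[label] = {
            "n": int(arr.size),
            "n_undefined": len(profiles) - arr.size,
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / math.sqrt(arr.size))
            if arr.size >= 2
            else None,
        }
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    for label, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {label!r} needs >= 2 defined profiles")
    labels = sorted(groups)
    samples = [groups[g] for g in labels]
    anova = stattests.one_way_anova(samples)
    tukey = stattests.tukey_kramer(samples, labels)
    kw = stattests.kruskal_wallis(samples)
    return {
        "groups": summaries,
        "anova": anova,
        "tukey_kramer": tukey,
        "kruskal_wallis": kw,
    }
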