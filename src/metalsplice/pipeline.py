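"""End-to-end orchestration: codon scoring -> exon profiling -> splice
signals -> inclusion -> disorder -> statistics, from a validated config.

Runs either on files produced by the I/O layer or on a synthetic cohort
generated in-process; identical config + seed gives identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from metalsplice import io as msio
from metalsplice import simulate, stattests
from metalsplice.disorder import aa_level_lnratio, correlate_scale
from metalsplice.exons import (
    apply_dataset_filters,
    compare_exon_groups,
    exon_profile,
    filter_exons_for_comparison,
)
from metalsplice.hexamers import (
    codon_frequency_profile,
    load_score_table,
    load_hexamer_sets,
    score_codon,
)
from metalsplice.inclusion import mean_inclusion, select_candidates
from metalsplice.splice_signals import acceptor_architecture, minus3_association

log = logging.getLogger("metalsplice")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated run configuration; defaults are the study conditions."""

    out_dir: str = "metalsplice_run"
    seed: int = 0
    synthetic: bool = True
    n_exons_per_group: int = 200
    delta: float = 0.3
    # file inputs (used when synthetic=False)
    score_table_path: str | None = None
    hexamer_sets_path: str | None = None
    exon_fasta_path: str | None = None
    residue_tsv_path: str | None = None
    psi_tsv_path: str | None = None
    # thresholds
    dataset_mode: str = "extended"  # stringent | extended
    cmm_filter: bool = False
    max_exon_len: int = 350
    psi_threshold: float = 90.0
    microexon_min_len: int = 28
    smoothing_alpha: float = 0.5
    bp_window: tuple[int, int] = (-60, -13)
    disorder_target_r: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.dataset_mode not in ("stringent", "extended"):
            raise ValueError(f"bad dataset_mode {self.dataset_mode!r}")
        if not (0 < self.psi_threshold <= 100):
            raise ValueError("psi_threshold must be in (0, 100]")
        if self.max_exon_len <= 0 or self.microexon_min_len < 0:
            raise ValueError("length thresholds must be positive")
        if self.smoothing_alpha < 0:
            raise ValueError("smoothing_alpha must be >= 0")
        lo, hi = self.bp_window
        if not (-100 <= lo <= hi <= -1):
            raise ValueError("bp_window must be a negative range")
        if not self.synthetic:
            for attr in ("score_table_path", "hexamer_sets_path",
                         "exon_fasta_path", "residue_tsv_path", "psi_tsv_path"):
                p = getattr(self, attr)
                if p is None or not Path(p).exists():
                    raise ValueError(f"{attr} missing or does not exist: {p}")

    @property
    def bp_window_tuple(self) -> tuple[int, int]:
        return tuple(self.bp_window)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write TSV tables + a JSON summary + a log.

    Returns the summary dict.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    summary: dict = {"config": {k: v for k, v in asdict(config).items()}}
    t0 = time.time()
    try:
        # --- inputs -------------------------------------------------------
        stage = "inputs"
        if config.synthetic:
            spec = simulate.CohortSpec(
                seed=config.seed,
                n_exons_per_group=config.n_exons_per_group,
                delta=config.delta,
            )
            table, sets = simulate.gen_score_table(seed=config.seed)
            exons, residues = simulate.gen_exon_cohort(spec, table)
            psi = simulate.gen_psi_table(
                [e.exon_id for e in exons], seed=config.seed
            )
        else:
            table = load_score_table(config.score_table_path)
            sets = load_hexamer_sets(config.hexamer_sets_path)
            exons = msio.read_exon_fasta(config.exon_fasta_path)
            residues = msio.read_residue_tsv(config.residue_tsv_path)
            psi = msio.read_psi_tsv(config.psi_tsv_path)
        log.info("inputs: %d exons, %d residues, %d PSI records, table n=%d",
                 len(exons), len(residues), len(psi), len(table))

        # --- codon scoring ------------------------------------------------
        stage = "codon_scoring"
        exon_by_gene = {e.gene: e for e in exons}
        filtered, filter_report = apply_dataset_filters(
            residues, mode=config.dataset_mode, cmm_filter=config.cmm_filter
        )
        codon_rows = []
        for r in filtered:
            exon = exon_by_gene.get(r.protein_id)
            if exon is None or r.codon_start_in_exon is None:
                continue
            try:
                cs = score_codon(table, exon.seq, r.codon_start_in_exon)
            except (KeyError, ValueError) as exc:
                raise PipelineError(stage, f"{exon.exon_id}: {exc}") from exc
            if cs.status == "ok":
                codon_rows.append(
                    {"exon_id": exon.exon_id, "group": exon.group,
                     "codon": cs.codon, "ln_ratio": cs.ln_ratio}
                )
        profile = codon_frequency_profile(sets, alpha=config.smoothing_alpha)
        msio.write_codon_profile(profile, out / "codon_frequency_profile.tsv")
        summary["codon_scoring"] = {
            "dataset_filter": filter_report,
            "n_codons_scored": len(codon_rows),
            "per_group_mean_ln_ratio": _group_means(codon_rows),
        }
        log.info("codon_scoring: %d codons scored", len(codon_rows))

        # --- exon profiling -----------------------------------------------
        stage = "exon_profiling"
        kept, n_dropped = filter_exons_for_comparison(exons, config.max_exon_len)
        profiles_by_group: dict[str, list] = {}
        for e in kept:
            profiles_by_group.setdefault(e.group, []).append(exon_profile(table, e))
        comparison = compare_exon_groups(profiles_by_group)
        summary["exon_profiling"] = {
            "n_dropped_long": n_dropped,
            "groups": comparison["groups"],
            "anova": comparison["anova"].to_dict(),
            "kruskal_wallis": comparison["kruskal_wallis"].to_dict(),
            "tukey_kramer": comparison["tukey_kramer"],
        }
        _write_tsv(
            out / "exon_profiles.tsv",
            ["exon_id", "group", "n_hexamers", "mean_ln_ratio"],
            [
                [p.exon_id, g, p.n_hexamers,
                 "" if p.mean_ln_ratio is None else repr(p.mean_ln_ratio)]
                for g, ps in profiles_by_group.items() for p in ps
            ],
        )
        log.info("exon_profiling: ANOVA F=%.3f", comparison["anova"].statistic)

        # --- splice signals -----------------------------------------------
        stage = "splice_signals"
        arch_rows = []
        assoc_records = []
        for e in kept:
            if len(e.upstream_intron) < 20:
                continue
            arch = acceptor_architecture(e.exon_id, e.upstream_intron)
            arch_rows.append(
                {"intron_id": arch.intron_id, "group": e.group,
                 "terminal_nag": arch.terminal_nag, "minus3": arch.minus3,
                 "bp_pos": arch.bp.pos if arch.bp else "",
                 "agez_len": arch.agez_len if arch.agez_len is not None else "",
                 "ppt_score": arch.ppt_score,
                 "pyrimidine_fraction": arch.pyrimidine_fraction,
                 "u4_count": arch.u4_count, "c4_count": arch.c4_count,
                 "intron_type": arch.intron_type}
            )
            if arch.minus3 in "CT" and len(e.seq) >= 6:
                assoc_records.append((arch.minus3, e.seq[:6]))
        _write_tsv(
            out / "acceptor_architecture.tsv",
            list(arch_rows[0].keys()) if arch_rows else [],
            [list(r.values()) for r in arch_rows],
        )
        by_group_ppt = {}
        for row in arch_rows:
            by_group_ppt.setdefault(row["group"], []).append(row["ppt_score"])
        ppt_tests = {}
        labels = sorted(by_group_ppt)
        if len(labels) == 2:
            a, b = (by_group_ppt[g] for g in labels)
            ppt_tests = {
                "mann_whitney": stattests.mann_whitney_u(a, b).to_dict(),
                "median_test": stattests.median_test(a, b).to_dict(),
            }
        nag_tab = _nag_table(arch_rows, labels)
        assoc = minus3_association(assoc_records) if len(assoc_records) > 3 else None
        summary["splice_signals"] = {
            "n_introns": len(arch_rows),
            "ppt_score_by_group": {
                g: float(np.mean(v)) for g, v in by_group_ppt.items()
            },
            "ppt_tests": ppt_tests,
            "nag_counts": nag_tab,
            "minus3_most_associated": (
                assoc["most_associated"] if assoc else None
            ),
        }
        log.info("splice_signals: %d introns", len(arch_rows))

        # --- inclusion ----------------------------------------------------
        stage = "inclusion"
        lengths = {e.exon_id: len(e.seq) for e in exons}
        groups_map = {e.exon_id: e.group for e in exons}
        from metalsplice.inclusion import exclude_small_exons

        psi_kept, n_micro = exclude_small_exons(
            psi, lengths, config.microexon_min_len
        )
        by_group = mean_inclusion(psi_kept, by="group", groups=groups_map)
        candidates = select_candidates(psi_kept, threshold=config.psi_threshold)
        _write_tsv(out / "psi_candidates.tsv", ["exon_id"],
                   [[c] for c in candidates])
        summary["inclusion"] = {
            "n_microexon_records_dropped": n_micro,
            "mean_psi_by_group": {
                str(row.group): {"n": int(row.n), "mean": float(row.mean)}
                for row in by_group.itertuples()
            },
            "n_candidates_low_psi": len(candidates),
        }

        # --- disorder -----------------------------------------------------
        stage = "disorder"
        aa_vals = aa_level_lnratio(profile)
        scale = simulate.gen_disorder_scale(
            aa_vals, config.disorder_target_r, seed=config.seed
        )
        r, p = correlate_scale(aa_vals, scale)
        summary["disorder"] = {
            "scale": scale.name, "pearson_r": r, "p_value": p, "n": 20,
        }

        summary["elapsed_s"] = round(time.time() - t0, 3)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True, default=_jsonable)
        log.info("done in %.1fs", summary["elapsed_s"])
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc
    finally:
        log.removeHandler(handler)
        handler.close()


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, set)):
        return list(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def _group_means(rows):
    out: dict[str, list[float]] = {}
    for r in rows:
        out.setdefault(r["group"], []).append(r["ln_ratio"])
    return {g: {"n": len(v), "mean": float(np.mean(v))} for g, v in out.items()}


def _nag_table(arch_rows, labels):
    classes = ("CAG", "TAG", "AAG", "GAG", "other")
    return {
        g: {
            c: sum(1 for r in arch_rows
                   if r["group"] == g and r["terminal_nag"] == c)
            for c in classes
        }
        for g in labels
    }


def _write_tsv(path, header, rows):
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        if header:
            w.writerow(header)
        w.writerows(rows)
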