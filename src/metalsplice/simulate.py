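"""Synthetic cohorts with planted, recoverable structure.

Generates every input the pipeline consumes — hexamer score tables,
exon cohorts with metal-coordinating codons and flanking introns, PSI
tables, -3/first-six-exon-base association records and disorder scales —
so that each planted parameter (group score difference, PPT uridine
content, branchpoint position, -3 allele association pattern, PSI
distribution, target correlation) can be recovered by the corresponding
analysis stage.  Everything is bit-reproducible given the spec and its
root seed, which is split hierarchically per component.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from metalsplice.hexamers import (
    ALL_CODONS,
    HexamerScoreTable,
    HexamerSets,
    NUCLEOTIDES,
)
from metalsplice.exons import CoordinatingResidue, ExonRecord
from metalsplice.inclusion import InclusionRecord
from metalsplice.disorder import AMINO_ACIDS, CODON_TO_AA, DisorderScale

# Coordination chemistry of the two metals: Zn2+ is bound chiefly by Cys
# and His, Ca2+ by the acidic residues Asp and Glu.
ZN_CODON_POOL = ("TGC", "TGT", "CAC", "CAT")
CA_CODON_POOL = ("GAC", "GAT", "GAA", "GAG")

ASSOCIATED_FIRST6 = "GAATTA"  # bases enriched at exon +1..+6 under a -3T allele


@dataclass
class ScoreTableSpec:
    """Class counts and log-normal score distributions for a synthetic
    hexamer score table (reference high-confidence set sizes 1182/1090)."""

    n_e: int = 1182
    n_s: int = 1090
    n_n: int = 1824
    mu_strong: float = 0.6  # log-mean of the dominant score of E/S hexamers
    mu_weak: float = -0.6
    sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.n_e + self.n_s + self.n_n > 4096:
            raise ValueError(
                f"class counts sum to {self.n_e + self.n_s + self.n_n} > 4096"
            )
        if min(self.n_e, self.n_s) < 1:
            raise ValueError("need at least one E and one S hexamer")


@dataclass
class GroupParams:
    """Per-group intron/exon parameters."""

    metal: str = "Zn"
    codon_pool: tuple[str, ...] = ZN_CODON_POOL
    ppt_u_content: float = 0.75
    minus3_probs: dict = field(
        default_factory=lambda: {"C": 0.55, "T": 0.40, "A": 0.03, "G": 0.02}
    )
    atac_prob: float = 0.002  # U12-type (AT-AC) intron fraction
    psi_alpha: float = 50.0
    psi_beta: float = 1.0


def default_groups() -> dict[str, GroupParams]:
    """Study-condition defaults: a Zn-like (ZF) and a Ca-like (EF) cohort.

    Ca exons carry an excess of CAG over TAG acceptors, a lower PPT
    uridine content and a higher U12-type intron fraction (0.2% for Zn
    vs 3.5% for Ca cohorts).
    """
    return {
        "ZF": GroupParams(
            metal="Zn", codon_pool=ZN_CODON_POOL, ppt_u_content=0.75,
            minus3_probs={"C": 0.55, "T": 0.40, "A": 0.03, "G": 0.02},
            atac_prob=0.002, psi_alpha=50.0, psi_beta=1.0,
        ),
        "EF": GroupParams(
            metal="Ca", codon_pool=CA_CODON_POOL, ppt_u_content=0.55,
            minus3_probs={"C": 0.75, "T": 0.20, "A": 0.03, "G": 0.02},
            atac_prob=0.035, psi_alpha=50.0, psi_beta=1.0,
        ),
    }


@dataclass
class CohortSpec:
    """All knobs of a synthetic cohort, with the study-condition defaults."""

    seed: int = 0
    n_exons_per_group: int = 200
    exon_len_range: tuple[int, int] = (60, 240)  # nt, rounded to codons, <= 350
    coord_fraction: float = 0.2
    delta: float = 0.3  # planted Zn-vs-Ca difference in mean exon ln(ESE/ESS)
    homology_extended_rate: float = 0.135
    not_validated_rate: float = 0.115
    bp_range: tuple[int, int] = (-45, -18)
    agez_jitter: int = 8
    assoc_strength: float = 0.55  # P(planted base | -3T) at exon +1..+6
    tissues: tuple[str, ...] = ("neural", "muscle", "testis", "esc")
    score_table: ScoreTableSpec = field(default_factory=ScoreTableSpec)
    groups: dict[str, GroupParams] = field(default_factory=default_groups)

    def __post_init__(self) -> None:
        lo, hi = self.exon_len_range
        if not (6 <= lo <= hi <= 350):
            raise ValueError("exon length range must lie within [6, 350]")
        for p in (self.coord_fraction, self.homology_extended_rate,
                  self.not_validated_rate, self.assoc_strength):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not (-60 <= self.bp_range[0] <= self.bp_range[1] <= -13):
            raise ValueError("bp_range must lie within [-60, -13]")

    def rng_for(self, component: str) -> np.random.Generator:
        key = zlib.crc32(component.encode())  # stable across processes
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


# ---------------------------------------------------------------------------
# score table


def gen_score_table(
    spec: ScoreTableSpec | None = None, seed: int = 0
) -> tuple[HexamerScoreTable, HexamerSets]:
    """Synthetic hexamer score table + high-confidence sets.

    Class counts match the spec exactly; scores are log-normal and
    strictly positive, with E-class ESE > ESS (and vice versa for S) in
    expectation.  Deterministic given (spec, seed).
    """
    spec = spec or ScoreTableSpec()
    rng = np.random.default_rng(seed)
    all_hex = np.array(
        ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=6)]
    )
    order = rng.permutation(len(all_hex))
    n_e, n_s, n_n = spec.n_e, spec.n_s, spec.n_n
    picks = all_hex[order[: n_e + n_s + n_n]]
    entries: dict[str, tuple[float, float, str]] = {}
    for i, hexamer in enumerate(picks):
        if i < n_e:
            ese = math.exp(rng.normal(spec.mu_strong, spec.sigma))
            ess = math.exp(rng.normal(spec.mu_weak, spec.sigma))
            cls = "E"
        elif i < n_e + n_s:
            ese = math.exp(rng.normal(spec.mu_weak, spec.sigma))
            ess = math.exp(rng.normal(spec.mu_strong, spec.sigma))
            cls = "S"
        else:
            ese = math.exp(rng.normal(0.0, spec.sigma))
            ess = math.exp(rng.normal(0.0, spec.sigma))
            cls = "N"
        entries[str(hexamer)] = (ese, ess, cls)
    table = HexamerScoreTable(entries)
    sets = HexamerSets(
        frozenset(str(h) for h in picks[:n_e]),
        frozenset(str(h) for h in picks[n_e : n_e + n_s]),
    )
    return table, sets


# ---------------------------------------------------------------------------
# introns


def gen_intron(
    spec: CohortSpec, group: str, rng: np.random.Generator
) -> tuple[str, int]:
    """One intron with planted branchpoint, AGEZ, PPT and terminal NAG.

    Returns (sequence, planted branchpoint position).  The branch A sits
    in a TACTAAC box (guarded so the built-in scorer recovers it
    uniquely); the region between the branchpoint and the 3'ss AG is kept
    free of AG dinucleotides; PPT bases are T with probability
    ppt_u_content, the remainder mostly C; the nearest upstream AG bounds
    the AG-exclusion zone just 5' of the scanned branchpoint window.
    """
    gp = spec.groups[group]
    bp = int(rng.integers(spec.bp_range[0], spec.bp_range[1] + 1))
    is_atac = rng.random() < gp.atac_prob
    jitter = int(rng.integers(0, spec.agez_jitter + 1))
    stretch_start = min(-60, bp - 7) - jitter

    bases: dict[int, str] = {}
    if is_atac:
        bases[-2], bases[-1] = "A", "C"
        minus3 = "T" if rng.random() < 0.5 else "C"
    else:
        bases[-2], bases[-1] = "A", "G"
        m3p = gp.minus3_probs
        minus3 = str(rng.choice(list(m3p), p=np.array(list(m3p.values()))))
    bases[-3] = minus3
    # branchpoint box with a purine guard so no shifted A outscores it
    motif = "TACTAAC"  # branch A at the 6th position
    for k, b in enumerate(motif):
        bases[bp - 5 + k] = b
    bases[bp - 6] = "G"
    bases[bp - 7] = "C" if rng.random() < 0.5 else "T"
    # PPT between the box and the acceptor
    for pos in range(bp + 2, -3):
        if pos in bases:
            continue
        if rng.random() < gp.ppt_u_content:
            bases[pos] = "T"
        elif pos >= -12 and not (pos == -4 and minus3 == "G"):
            bases[pos] = "C" if rng.random() < 0.8 else "A"
        else:
            bases[pos] = "C"
    # pyrimidine run covering the rest of the branchpoint scan window
    for pos in range(stretch_start, bp - 7):
        if pos not in bases:
            bases[pos] = "T" if rng.random() < 0.6 else "C"
    bases[stretch_start - 2], bases[stretch_start - 1] = "A", "G"  # AGEZ bound
    core = "".join(bases[p] for p in range(stretch_start - 2, 0))
    filler = "".join(rng.choice(list(NUCLEOTIDES), size=int(rng.integers(8, 21))))
    donor = "AT" if is_atac else "GT"
    return donor + filler + core, bp


def gen_donor_flank(rng: np.random.Generator, atac: bool = False) -> str:
    """5' end of the downstream intron (donor side)."""
    head = "ATATCCTT" if atac else "GTAAGT"
    tail = "".join(rng.choice(list(NUCLEOTIDES), size=24))
    return head + tail


# ---------------------------------------------------------------------------
# exon cohorts


def _hexamer_lnratio_lookup(table: HexamerScoreTable) -> dict[str, float | None]:
    return {h: table.ln_ratio(h) for h in table.entries}


def gen_exon_cohort(
    spec: CohortSpec,
    table: HexamerScoreTable,
) -> tuple[list[ExonRecord], list[CoordinatingResidue]]:
    """Exon cohort with a planted between-group ESE/ESS difference.

    Zn-group exons draw coordinating codons from the Cys/His pool and
    Ca-group exons from the Asp/Glu pool at ``coord_fraction``; background
    codons are chosen greedily toward group targets placed delta apart
    around the table's central hexamer ln(ESE/ESS), so the realized group
    means of the exon profiles differ by ~delta.  Raises when delta is
    not achievable under the supplied table.
    """
    lookup = _hexamer_lnratio_lookup(table)
    ratios = np.array([v for v in lookup.values() if v is not None])
    if ratios.size == 0:
        raise ValueError("score table has no non-neutral hexamers")
    center = float(np.mean(ratios))
    lo, hi = np.percentile(ratios, [10, 90])
    metals = {g: spec.groups[g].metal for g in spec.groups}
    targets = {
        g: center + (spec.delta / 2 if metals[g] == "Ca" else -spec.delta / 2)
        for g in spec.groups
    }
    for g, t in targets.items():
        if not (lo <= t <= hi):
            raise ValueError(
                f"planted delta {spec.delta} unachievable: target {t:.3f} for "
                f"group {g} outside the table's central ln-ratio band "
                f"[{lo:.3f}, {hi:.3f}]"
            )
    rng = spec.rng_for("exons")
    exons: list[ExonRecord] = []
    residues: list[CoordinatingResidue] = []
    codon_list = list(ALL_CODONS)
    for group, gp in spec.groups.items():
        for i in range(spec.n_exons_per_group):
            length = int(rng.integers(spec.exon_len_range[0] // 3,
                                      spec.exon_len_range[1] // 3 + 1)) * 3
            n_codons = max(2, length // 3)
            upstream, _ = gen_intron(spec, group, rng)
            minus3 = upstream[-3]
            # first six exon bases: planted -3T association pattern
            first6 = []
            for k in range(6):
                if minus3 == "T" and rng.random() < spec.assoc_strength:
                    first6.append(ASSOCIATED_FIRST6[k])
                else:
                    first6.append(str(rng.choice(list(NUCLEOTIDES))))
            seq = "".join(first6)
            # running mean of non-neutral hexamer ln ratios, updated greedily
            total = 0.0
            n_win = 0
            for s in range(len(seq) - 5):
                r = lookup.get(seq[s : s + 6])
                if r is not None:
                    total += r
                    n_win += 1
            coord_positions: list[int] = []
            target = targets[group]
            for ci in range(2, n_codons):
                if rng.random() < spec.coord_fraction:
                    codon = str(rng.choice(gp.codon_pool))
                    coord_positions.append(ci)
                    seq, total, n_win = _append_codon(
                        seq, codon, lookup, total, n_win
                    )
                    continue
                cand_idx = rng.integers(0, 64, size=6)
                best = None
                for j in cand_idx:
                    codon = codon_list[int(j)]
                    _, t2, n2 = _append_codon(seq, codon, lookup, total, n_win)
                    mean = t2 / n2 if n2 else target
                    err = abs(mean - target)
                    if best is None or err < best[0]:
                        best = (err, codon)
                seq, total, n_win = _append_codon(seq, best[1], lookup, total, n_win)
            exon_id = f"{group}_ex{i:04d}"
            gene = f"{group}_gene{i:04d}"
            exons.append(
                ExonRecord(
                    exon_id=exon_id,
                    gene=gene,
                    seq=seq,
                    upstream_intron=upstream,
                    downstream_intron=gen_donor_flank(rng),
                    group=group,
                )
            )
            for ci in coord_positions:
                codon = seq[3 * ci : 3 * ci + 3]
                residues.append(
                    CoordinatingResidue(
                        protein_id=gene,
                        residue_pos=ci + 1,
                        residue=CODON_TO_AA[codon],
                        metal=gp.metal,
                        cmm_status=(
                            "not_validated"
                            if rng.random() < spec.not_validated_rate
                            else "plausible"
                        ),
                        homology_extended=bool(
                            rng.random() < spec.homology_extended_rate
                        ),
                        codon_start_in_exon=3 * ci,
                        near_junction=3 * ci < 3 or 3 * ci + 3 > len(seq) - 3,
                    )
                )
    return exons, residues


def _append_codon(seq, codon, lookup, total, n_win):
    new = seq + codon
    for s in range(max(0, len(seq) - 5), len(new) - 5):
        r = lookup.get(new[s : s + 6])
        if r is not None:
            total += r
            n_win += 1
    return new, total, n_win


def gen_residue_fixture(
    n_total: int = 4465,
    n_extended: int = 603,
    n_not_validated: int = 514,
    seed: int = 0,
) -> list[CoordinatingResidue]:
    """Residue annotations with exact dataset-variant counts planted.

    Defaults reproduce the reference dataset sizes: 4465 total codons,
    3862 after dropping homology-extended entries (stringent), 3951 after
    the metal-site validation filter alone, and 3348 under both.  The
    not-validated records are all placed among the non-extended entries.
    """
    if n_extended + n_not_validated > n_total:
        raise ValueError("flag counts exceed n_total")
    rng = np.random.default_rng(seed)
    residues = []
    for i in range(n_total):
        extended = i < n_extended
        not_validated = n_extended <= i < n_extended + n_not_validated
        residues.append(
            CoordinatingResidue(
                protein_id=f"P{i % 482:04d}",
                residue_pos=int(rng.integers(1, 500)),
                residue=str(rng.choice(["C", "H", "D", "E"])),
                metal="Zn",
                cmm_status="not_validated" if not_validated else "plausible",
                homology_extended=extended,
            )
        )
    return residues


# ---------------------------------------------------------------------------
# association records, PSI tables, disorder scales


def gen_minus3_cohort(
    n: int = 2000,
    p_t: float = 0.4,
    assoc_strength: float = 0.55,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """(minus3, first-six-exon-bases) records with the planted pattern
    +1G +2A +3A +4T +5T +6A enriched under the -3T allele."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        minus3 = "T" if rng.random() < p_t else "C"
        first6 = []
        for k in range(6):
            if minus3 == "T" and rng.random() < assoc_strength:
                first6.append(ASSOCIATED_FIRST6[k])
            else:
                first6.append(str(rng.choice(list(NUCLEOTIDES))))
        out.append((minus3, "".join(first6)))
    return out


def gen_psi_table(
    exon_ids,
    tissues=("neural", "muscle", "testis", "esc"),
    alpha: float = 50.0,
    beta: float = 1.0,
    seed: int = 0,
) -> list[InclusionRecord]:
    """PSI = 100 * Beta(alpha, beta) per exon x tissue (VastDB-style)."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta parameters must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for exon_id in exon_ids:
        for tissue in tissues:
            psi = 100.0 * float(rng.beta(alpha, beta))
            records.append(InclusionRecord(exon_id, tissue, psi))
    return records


def gen_disorder_scale(
    aa_values: dict[str, float],
    target_r: float,
    seed: int = 0,
    name: str = "synthetic_scale",
) -> DisorderScale:
    """A disorder scale correlated with ``aa_values`` at ``target_r`` in
    expectation (Gaussian construction: r * z(x) + sqrt(1-r^2) * noise)."""
    if not -1.0 <= target_r <= 1.0:
        raise ValueError("|target_r| must be <= 1")
    rng = np.random.default_rng(seed)
    x = np.array([aa_values[aa] for aa in AMINO_ACIDS])
    zx = (x - x.mean()) / x.std()
    noise = rng.standard_normal(len(AMINO_ACIDS))
    y = target_r * zx + math.sqrt(max(0.0, 1.0 - target_r**2)) * noise
    return DisorderScale(name, dict(zip(AMINO_ACIDS, map(float, y))))
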