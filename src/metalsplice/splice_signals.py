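"""Traditional splicing signals of the 3' splice-site neighbourhood.

Quantifies, per intron: splice-site strength under a position weight
model (or externally supplied maximum-entropy score tables), the
terminal NAG class of the acceptor (CAG/TAG/AAG/GAG, with the -3 base
contacted by U2AF35), lariat branchpoint calls restricted to the
canonical -13..-60 nt window, the AG-dinucleotide exclusion zone
(AGEZ), polypyrimidine-tract (PPT) composition and motif content, and
the allelic association between the -3 pyrimidine and the first six
exon positions.

Position convention throughout: -1 is the last intron nucleotide (the
G of the 3'ss AG); exon position +1 is the first exon nucleotide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from metalsplice.hexamers import NUCLEOTIDES, normalize_nt
from metalsplice import stattests

BP_WINDOW = (-60, -13)  # canonical human branchpoint range relative to 3'ss

_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

# PPT scoring weights: uridines are the optimal U2AF65 platform, cytidines
# are tolerated, purines interrupt the tract.
PPT_WEIGHTS = {"T": 1.0, "C": 0.5, "A": -2.0, "G": -2.0}


@dataclass
class SpliceSiteModel:
    """Donor/acceptor strength model.

    ``pwm`` kind scores a window as the sum of per-position log2 odds
    against a uniform background.  ``maxent_tables`` kind looks the window
    up in an externally supplied score table (window -> score).
    Window geometry: donor = 3 exonic + 6 intronic nt (9-mer); acceptor =
    20 intronic + 3 exonic nt (23-mer).
    """

    kind: str  # pwm | maxent_tables
    site: str  # donor | acceptor
    probs: np.ndarray | None = None  # (window_len, 4) for pwm kind
    table: Mapping[str, float] | None = None  # for maxent_tables kind

    WINDOW_LEN = {"donor": 9, "acceptor": 23}

    def __post_init__(self) -> None:
        if self.site not in self.WINDOW_LEN:
            raise ValueError(f"unknown site {self.site!r}")
        if self.kind == "pwm":
            p = np.asarray(self.probs, dtype=float)
            if p.shape != (self.WINDOW_LEN[self.site], 4):
                raise ValueError(
                    f"pwm shape {p.shape} != ({self.WINDOW_LEN[self.site]}, 4)"
                )
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("pwm rows must each sum to 1")
            self.probs = p
        elif self.kind == "maxent_tables":
            if self.table is None:
                raise ValueError("maxent_tables kind needs a score table")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def window_len(self) -> int:
        return self.WINDOW_LEN[self.site]


@dataclass(frozen=True)
class BranchpointCall:
    """A branch-adenine call; pos is negative, -1 = last intron nt."""

    pos: int
    score: float
    method: str  # builtin_pwm | imported


@dataclass
class AcceptorArchitecture:
    """Bundle of 3'ss-neighbourhood metrics for one intron."""

    intron_id: str
    terminal_nag: str  # CAG | TAG | AAG | GAG | other
    minus3: str
    bp: BranchpointCall | None
    agez_len: int | None
    agez_censored: bool
    ppt_u_profile: list[int] | None  # positions -4..-18
    ppt_score: float | None
    pyrimidine_fraction: float | None
    u4_count: int
    c4_count: int
    bp_to_3ss_len: int | None
    intron_type: str  # GT-AG | AT-AC | other


def _uniform_pwm(n: int) -> np.ndarray:
    return np.full((n, 4), 0.25)


def default_donor_model() -> SpliceSiteModel:
    """Rough human 5'ss consensus pwm (MAG | GTRAGT): 3 exonic + 6 intronic."""
    rows = [
        # exon -3..-1
        {"A": 0.33, "C": 0.36, "G": 0.18, "T": 0.13},
        {"A": 0.60, "C": 0.13, "G": 0.14, "T": 0.13},
        {"A": 0.09, "C": 0.05, "G": 0.79, "T": 0.07},
        # intron +1..+6
        {"A": 0.004, "C": 0.004, "G": 0.988, "T": 0.004},
        {"A": 0.004, "C": 0.004, "G": 0.004, "T": 0.988},
        {"A": 0.53, "C": 0.03, "G": 0.42, "T": 0.02},
        {"A": 0.71, "C": 0.08, "G": 0.12, "T": 0.09},
        {"A": 0.07, "C": 0.06, "G": 0.81, "T": 0.06},
        {"A": 0.16, "C": 0.15, "G": 0.21, "T": 0.48},
    ]
    return SpliceSiteModel("pwm", "donor", probs=_rows_to_probs(rows))


def default_acceptor_model() -> SpliceSiteModel:
    """Rough human 3'ss consensus pwm: 20 intronic (-20..-1) + 3 exonic nt."""
    ppt = {"A": 0.09, "C": 0.31, "G": 0.07, "T": 0.53}
    rows = [dict(ppt) for _ in range(15)]  # -20..-6
    rows += [
        {"A": 0.07, "C": 0.37, "G": 0.06, "T": 0.50},  # -5
        {"A": 0.24, "C": 0.30, "G": 0.21, "T": 0.25},  # -4
        {"A": 0.04, "C": 0.64, "G": 0.01, "T": 0.31},  # -3 (YAG)
        {"A": 0.988, "C": 0.004, "G": 0.004, "T": 0.004},  # -2 A
        {"A": 0.004, "C": 0.004, "G": 0.988, "T": 0.004},  # -1 G
        {"A": 0.25, "C": 0.19, "G": 0.49, "T": 0.07},  # +1
        {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},  # +2
        {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},  # +3
    ]
    return SpliceSiteModel("pwm", "acceptor", probs=_rows_to_probs(rows))


def _rows_to_probs(rows: Sequence[Mapping[str, float]]) -> np.ndarray:
    probs = np.array([[row[b] for b in NUCLEOTIDES] for row in rows], dtype=float)
    return probs / probs.sum(axis=1, keepdims=True)


def score_site(model: SpliceSiteModel, window: str) -> float:
    """Score a splice-site window; higher = stronger site.

    pwm kind: sum over positions of log2(P(base) / 0.25).
    """
    window = normalize_nt(window)
    if len(window) != model.window_len:
        raise ValueError(
            f"window length {len(window)} != {model.window_len} for {model.site}"
        )
    if any(b not in NUCLEOTIDES for b in window):
        raise ValueError(f"invalid base in window {window!r}")
    if model.kind == "maxent_tables":
        try:
            return float(model.table[window])
        except KeyError:
            raise KeyError(f"window {window!r} absent from maxent table") from None
    total = 0.0
    for i, b in enumerate(window):
        p = model.probs[i, _BASE_INDEX[b]]
        if p <= 0:
            return float("-inf")
        total += math.log2(p / 0.25)
    return total


def classify_terminal_nag(intron: str) -> tuple[str, str]:
    """Class of the last 3 intron nt (NAG by first base) and the -3 base."""
    intron = normalize_nt(intron)
    if len(intron) < 3:
        raise ValueError("intron shorter than 3 nt")
    last3 = intron[-3:]
    if last3.endswith("AG"):
        return last3, last3[0]
    return "other", last3[0]


# Branchpoint weight model: 7-mer with the branch adenine at index 5,
# covering a CU-rich yUnAy-style consensus (cf. the yeast TACTAAC box,
# whose branch A sits at the same offset).
_BP_ROWS = [
    {"A": 0.20, "C": 0.30, "G": 0.20, "T": 0.30},
    {"A": 0.20, "C": 0.30, "G": 0.20, "T": 0.30},
    {"A": 0.10, "C": 0.40, "G": 0.10, "T": 0.40},  # y
    {"A": 0.10, "C": 0.15, "G": 0.05, "T": 0.70},  # U
    {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},  # n
    {"A": 0.97, "C": 0.01, "G": 0.01, "T": 0.01},  # branch A
    {"A": 0.10, "C": 0.45, "G": 0.10, "T": 0.35},  # y
]
BP_PWM = _rows_to_probs(_BP_ROWS)
BP_BRANCH_OFFSET = 5  # index of the branch A within the 7-mer


def _bp_score(window7: str) -> float:
    total = 0.0
    for i, b in enumerate(window7):
        total += math.log(BP_PWM[i, _BASE_INDEX[b]] / 0.25)
    return total


def call_branchpoint(
    intron: str,
    window: tuple[int, int] = BP_WINDOW,
    mode: str = "builtin_pwm",
    imported_calls: Sequence[BranchpointCall] | None = None,
) -> BranchpointCall | None:
    """Best branch-adenine call within the canonical window.

    builtin_pwm mode scans every adenine at positions window[0]..window[1]
    (counted with -1 = last intron nt) and scores the 7-mer placing that
    adenine at the branch offset; ties go to the 3'-most position.
    imported mode filters externally computed calls (e.g. from dedicated
    branchpoint predictors) to the window and returns the highest-scoring
    one, same tie rule.  Returns None when no adenine (or no imported
    call) lies in the window.
    """
    lo, hi = min(window), max(window)
    if mode == "imported":
        if imported_calls is None:
            raise ValueError("imported mode requires imported_calls")
        in_window = [c for c in imported_calls if lo <= c.pos <= hi]
        if not in_window:
            return None
        best = max(in_window, key=lambda c: (c.score, c.pos))
        return BranchpointCall(best.pos, best.score, "imported")
    if mode != "builtin_pwm":
        raise ValueError(f"unknown mode {mode!r}")
    intron = normalize_nt(intron)
    n = len(intron)
    if n < 20:
        raise ValueError("intron too short for branchpoint calling (< 20 nt)")
    best_pos: int | None = None
    best_score = -math.inf
    for pos in range(max(lo, -n), hi + 1):  # 5'->3'; later pos wins ties
        idx = n + pos
        if intron[idx] != "A":
            continue
        start = idx - BP_BRANCH_OFFSET
        end = start + 7
        if start < 0 or end > n:
            continue
        s = _bp_score(intron[start:end])
        if s >= best_score:
            best_score = s
            best_pos = pos
    if best_pos is None:
        return None
    return BranchpointCall(best_pos, best_score, "builtin_pwm")


def agez_length(intron: str) -> tuple[int, bool]:
    """Length of the AG-dinucleotide exclusion zone upstream of the 3'ss AG.

    Counts nucleotides strictly between the nearest upstream AG and the
    terminal AG.  When the provided sequence contains no upstream AG the
    zone is censored: returns the available scan length with censored=True.
    """
    intron = normalize_nt(intron)
    if not intron.endswith("AG"):
        raise ValueError("AGEZ is defined only for introns ending in AG")
    scan_end = len(intron) - 2  # exclude the terminal AG itself
    hit = intron.rfind("AG", 0, scan_end)
    if hit == -1:
        return scan_end, True
    return scan_end - (hit + 2), False


def _ppt_region(intron: str, bp: BranchpointCall | None) -> str:
    """Sequence strictly between the branch A and the 3'ss AG."""
    n = len(intron)
    start = n + bp.pos + 1 if bp is not None else max(0, n - 60)
    return intron[start : n - 2]


def ppt_metrics(
    intron: str, bp: BranchpointCall | None = None
) -> tuple[list[int] | None, float, float]:
    """Uridine profile, PPT score and pyrimidine fraction.

    * ppt_u_profile[k] = 1 if the base at position -(k+4) is T (k = 0..14,
      i.e. positions -4..-18); None when the intron is shorter than 18 nt.
    * ppt_score: maximum-sum contiguous segment between the branchpoint
      (exclusive) and the 3'ss AG (exclusive) under weights T=+1.0, C=+0.5,
      A=G=-2.0; the empty segment scores 0, so the score is never negative.
    * pyrimidine fraction over the same region (0 for an empty region).
    """
    intron = normalize_nt(intron)
    n = len(intron)
    profile: list[int] | None = None
    if n >= 18:
        profile = [1 if intron[n - k] == "T" else 0 for k in range(4, 19)]
    region = _ppt_region(intron, bp)
    best = run = 0.0
    for base in region:
        run = max(0.0, run + PPT_WEIGHTS[base])
        best = max(best, run)
    pyr = sum(1 for b in region if b in "CT") / len(region) if region else 0.0
    return profile, best, pyr


def motif_counts(
    intron: str,
    bp: BranchpointCall,
    motifs: Sequence[str],
) -> dict[str, tuple[int, bool]]:
    """Overlapping occurrence counts of each motif strictly between the
    branch adenine and the 3'ss AG."""
    intron = normalize_nt(intron)
    if bp is None:
        raise ValueError("motif_counts requires a branchpoint call")
    region = _ppt_region(intron, bp)
    out: dict[str, tuple[int, bool]] = {}
    for motif in motifs:
        m = normalize_nt(motif)
        if not m or any(b not in NUCLEOTIDES for b in m):
            raise ValueError(f"invalid motif {motif!r}")
        count = sum(
            1 for i in range(len(region) - len(m) + 1) if region[i : i + len(m)] == m
        )
        out[motif] = (count, count > 0)
    return out


def intron_type(intron: str) -> str:
    """GT-AG / AT-AC / other, from the first and last 2 intron nt."""
    intron = normalize_nt(intron)
    if len(intron) < 4:
        raise ValueError("intron shorter than 4 nt")
    first2, last2 = intron[:2], intron[-2:]
    if first2 == "GT" and last2 == "AG":
        return "GT-AG"
    if first2 == "AT" and last2 == "AC":
        return "AT-AC"
    return "other"


def acceptor_architecture(
    intron_id: str,
    intron: str,
    bp_mode: str = "builtin_pwm",
    imported_calls: Sequence[BranchpointCall] | None = None,
    motifs: Sequence[str] = ("TTTT", "CCCC"),
) -> AcceptorArchitecture:
    """Compute the full acceptor-side architecture for one intron."""
    intron = normalize_nt(intron)
    nag, minus3 = classify_terminal_nag(intron)
    itype = intron_type(intron)
    bp = (
        call_branchpoint(intron, mode=bp_mode, imported_calls=imported_calls)
        if len(intron) >= 20
        else None
    )
    if intron.endswith("AG"):
        agez, censored = agez_length(intron)
    else:
        agez, censored = None, True
    profile, ppt_score, pyr = ppt_metrics(intron, bp)
    if bp is not None:
        counts = motif_counts(intron, bp, motifs)
        u4 = counts.get("TTTT", (0, False))[0]
        c4 = counts.get("CCCC", (0, False))[0]
        bp_len = -bp.pos - 2  # nt strictly between branch A and terminal AG
    else:
        u4 = c4 = 0
        bp_len = None
    return AcceptorArchitecture(
        intron_id=intron_id,
        terminal_nag=nag,
        minus3=minus3,
        bp=bp,
        agez_len=agez,
        agez_censored=censored,
        ppt_u_profile=profile,
        ppt_score=ppt_score,
        pyrimidine_fraction=pyr,
        u4_count=u4,
        c4_count=c4,
        bp_to_3ss_len=bp_len,
        intron_type=itype,
    )


def minus3_association(
    records: Iterable[tuple[str, str]],
) -> dict:
    """Allelic association between the -3 pyrimidine and exon positions 1-6.

    ``records`` are (minus3, first6) pairs with minus3 in {C, T}.  For
    every (position, base) cell a 2x2 table of -3 class x base presence is
    built; odds ratios are -3T vs -3C for base presence, with a Haldane
    +0.5 correction only when a cell is zero; chi-square has 1 df and no
    continuity correction.  Returns the per-cell table (list of dicts) and,
    per position, the base most associated with -3T (max odds ratio).
    """
    recs = []
    for minus3, first6 in records:
        minus3 = normalize_nt(minus3)
        first6 = normalize_nt(first6)
        if minus3 not in ("C", "T"):
            raise ValueError(f"minus3 must be C or T, got {minus3!r}")
        if len(first6) != 6 or any(b not in NUCLEOTIDES for b in first6):
            raise ValueError(f"first6 must be a 6-mer over ACGT, got {first6!r}")
        recs.append((minus3, first6))
    n_t = sum(1 for m, _ in recs if m == "T")
    n_c = len(recs) - n_t
    if n_t < 2 or n_c < 2:
        raise ValueError("need >= 2 records of each -3 class")
    rows = []
    most: dict[int, str] = {}
    for pos in range(1, 7):
        best_or = -math.inf
        for base in NUCLEOTIDES:
            a = sum(1 for m, f in recs if m == "T" and f[pos - 1] == base)
            c = sum(1 for m, f in recs if m == "C" and f[pos - 1] == base)
            b = n_t - a
            d = n_c - c
            if 0 in (a, b, c, d):
                oratio = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            else:
                oratio = (a * d) / (b * c)
            if (a + c) == 0 or (b + d) == 0:
                chi2, p = 0.0, 1.0
            else:
                res = stattests.chi2_contingency([[a, b], [c, d]])
                chi2, p = res.statistic, res.p_value
            rows.append(
                {
                    "position": pos,
                    "base": base,
                    "n_T_with": a,
                    "n_T_without": b,
                    "n_C_with": c,
                    "n_C_without": d,
                    "odds_ratio": oratio,
                    "chi2": chi2,
                    "p_value": p,
                }
            )
            if oratio > best_or:
                best_or = oratio
                most[pos] = base
    return {"table": rows, "most_associated": most}
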