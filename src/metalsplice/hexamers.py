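"""Hexamer score tables and codon-level splicing-propensity scores.

Exonic splicing enhancers (ESEs) and silencers (ESSs) were mapped
experimentally for all 4096 hexamers, yielding per-hexamer ESEseq and
ESSseq activity scores plus a three-way class label: E (enhancer),
S (silencer) or N (splicing-neutral).  This module models such score
tables and derives two codon-level summaries from them:

* the mean ESEseq/ESSseq score of the (at most four) overlapping
  hexamers that fully contain a codon of interest, reported as
  ln(mean ESE / mean ESS), with neutral hexamers ignored; and
* codon frequency profiles over the high-confidence ESE and ESS
  hexamer sets (each hexamer contributes its four complete in-frame
  triplet tokens), reported as ln(ESEf/ESSf).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

NUCLEOTIDES = "ACGT"
ALL_CODONS = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)
_CODON_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}

VALID_CLASSES = frozenset("ESN")


def normalize_nt(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def _check_kmer(kmer: str, k: int, what: str = "k-mer") -> str:
    kmer = normalize_nt(kmer)
    if len(kmer) != k or any(b not in NUCLEOTIDES for b in kmer):
        raise ValueError(f"invalid {what}: {kmer!r} (need {k}-mer over ACGT)")
    return kmer


@dataclass
class HexamerScoreTable:
    """Per-hexamer ESEseq/ESSseq scores with E/S/N class labels."""

    entries: dict[str, tuple[float, float, str]]
    score_offset: float = 0.0

    def __post_init__(self) -> None:
        if len(self.entries) > 4096:
            raise ValueError("more than 4096 hexamer entries")
        for hexamer, (ese, ess, cls) in self.entries.items():
            _check_kmer(hexamer, 6, "hexamer")
            if cls not in VALID_CLASSES:
                raise ValueError(f"invalid class {cls!r} for {hexamer}")
            if not (math.isfinite(ese) and math.isfinite(ess)):
                raise ValueError(f"non-finite score for {hexamer}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, hexamer: str) -> bool:
        return hexamer in self.entries

    def lookup(self, hexamer: str) -> tuple[float, float, str]:
        try:
            return self.entries[hexamer]
        except KeyError:
            raise KeyError(
                f"hexamer {hexamer!r} absent from score table; tables must be "
                "complete over every hexamer occurring in the input"
            ) from None

    def ln_ratio(self, hexamer: str) -> float | None:
        """ln(ese/ess) for one hexamer after the table's offset; None if
        the hexamer is neutral or either offset score is non-positive."""
        ese, ess, cls = self.lookup(hexamer)
        if cls == "N":
            return None
        ese += self.score_offset
        ess += self.score_offset
        if ese <= 0 or ess <= 0:
            return None
        return math.log(ese / ess)


@dataclass
class HexamerSets:
    """High-confidence ESE and ESS hexamer sets (reference sizes 1182/1090)."""

    ese_set: frozenset[str]
    ess_set: frozenset[str]

    def __post_init__(self) -> None:
        self.ese_set = frozenset(_check_kmer(h, 6, "hexamer") for h in self.ese_set)
        self.ess_set = frozenset(_check_kmer(h, 6, "hexamer") for h in self.ess_set)
        if self.ese_set & self.ess_set:
            overlap = sorted(self.ese_set & self.ess_set)[:5]
            raise ValueError(f"ESE and ESS sets overlap, e.g. {overlap}")


@dataclass(frozen=True)
class CodonScore:
    """Mean hexamer ESE/ESS scores over the windows covering one codon."""

    codon: str
    mean_ese: float | None
    mean_ess: float | None
    ln_ratio: float | None
    n_windows_used: int
    status: str  # ok | undefined_all_neutral | undefined_no_context


@dataclass
class CodonFrequencyProfile:
    """Per-codon token frequencies over ESE and ESS hexamer sets.

    Frequencies are additively smoothed: f(c) = (count + alpha) /
    (total + 64*alpha), so each of the two columns sums to one.
    """

    ese_count: np.ndarray  # (64,) ints, alphabetical codon order
    ess_count: np.ndarray
    ese_f: np.ndarray
    ess_f: np.ndarray
    ln_f_ratio: np.ndarray
    smoothing_alpha: float
    codons: tuple[str, ...] = field(default=ALL_CODONS)

    def value(self, codon: str) -> float:
        return float(self.ln_f_ratio[_CODON_INDEX[_check_kmer(codon, 3, "codon")]])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "codon": list(self.codons),
                "ese_count": self.ese_count,
                "ess_count": self.ess_count,
                "ese_f": self.ese_f,
                "ess_f": self.ess_f,
                "ln_f_ratio": self.ln_f_ratio,
            }
        )


def load_score_table(path: str | Path, score_offset: float = 0.0) -> HexamerScoreTable:
    """Read a hexamer score table from TSV.

    Expected header columns: ``hexamer``, ``ese_score``, ``ess_score`` and
    optionally ``class``.  When the class column is absent, hexamers are
    classified by the sign rule declared in a ``#classify:`` header line
    of the form ``#classify: neutral_band=<x>`` (|ese−ess| ≤ x → N, else
    E if ese>ess, else S).
    """
    path = Path(path)
    entries: dict[str, tuple[float, float, str]] = {}
    neutral_band: float | None = None
    header: list[str] | None = None
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                if line.lower().startswith("#classify:"):
                    for token in line.split(":", 1)[1].split():
                        key, _, val = token.partition("=")
                        if key == "neutral_band":
                            neutral_band = float(val)
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                for col in ("hexamer", "ese_score", "ess_score"):
                    if col not in header:
                        raise ValueError(
                            f"{path}:{lineno}: missing required column {col!r}"
                        )
                continue
            row = dict(zip(header, fields))
            try:
                hexamer = _check_kmer(row["hexamer"], 6, "hexamer")
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if hexamer in entries:
                raise ValueError(f"{path}:{lineno}: duplicate hexamer {hexamer}")
            try:
                ese = float(row["ese_score"])
                ess = float(row["ess_score"])
            except (KeyError, ValueError):
                raise ValueError(f"{path}:{lineno}: malformed score fields") from None
            if "class" in row and row["class"].strip():
                cls = row["class"].strip().upper()
                if cls not in VALID_CLASSES:
                    raise ValueError(f"{path}:{lineno}: invalid class {cls!r}")
            else:
                if neutral_band is None:
                    raise ValueError(
                        f"{path}:{lineno}: no class column and no '#classify: "
                        "neutral_band=<x>' header to derive one"
                    )
                diff = ese - ess
                cls = "N" if abs(diff) <= neutral_band else ("E" if diff > 0 else "S")
            entries[hexamer] = (ese, ess, cls)
    if not entries:
        raise ValueError(f"{path}: no data rows")
    return HexamerScoreTable(entries, score_offset=score_offset)


def load_hexamer_sets(path: str | Path) -> HexamerSets:
    """Read high-confidence hexamer sets from TSV (columns hexamer, set)."""
    path = Path(path)
    ese: set[str] = set()
    ess: set[str] = set()
    with path.open() as fh:
        header = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                continue
            row = dict(zip(header, fields))
            hexamer = _check_kmer(row["hexamer"], 6, "hexamer")
            which = row["set"].strip().upper()
            if which in ("ESE", "E"):
                ese.add(hexamer)
            elif which in ("ESS", "S"):
                ess.add(hexamer)
            else:
                raise ValueError(f"{path}:{lineno}: unknown set label {which!r}")
    return HexamerSets(frozenset(ese), frozenset(ess))


def codon_windows(seq: str, codon_start: int) -> list[str]:
    """The ≤4 hexamers fully containing the codon at ``codon_start``.

    Window starts run codon_start−3 .. codon_start (5'→3'); windows
    extending past either end of ``seq`` are dropped.
    """
    seq = normalize_nt(seq)
    if codon_start < 0 or codon_start + 3 > len(seq):
        raise ValueError(
            f"codon at {codon_start} not fully inside sequence of length {len(seq)}"
        )
    windows = []
    for start in range(codon_start - 3, codon_start + 1):
        if start >= 0 and start + 6 <= len(seq):
            windows.append(seq[start : start + 6])
    return windows


def score_codon(
    table: HexamerScoreTable,
    seq: str,
    codon_start: int,
    require_full_context: bool = True,
) -> CodonScore:
    """Average ESEseq/ESSseq scores of the hexamer windows covering a codon.

    Neutral (class N) hexamers are ignored.  With ``require_full_context``
    (the default) a codon lacking any of its four windows — i.e. sitting
    within 3 nt of a sequence end — is reported as ``undefined_no_context``
    rather than scored from partial context.
    """
    seq = normalize_nt(seq)
    windows = codon_windows(seq, codon_start)
    codon = seq[codon_start : codon_start + 3]
    if require_full_context and len(windows) < 4:
        return CodonScore(codon, None, None, None, 0, "undefined_no_context")
    ese_scores = []
    ess_scores = []
    for w in windows:
        ese, ess, cls = table.lookup(w)
        if cls == "N":
            continue
        ese_scores.append(ese + table.score_offset)
        ess_scores.append(ess + table.score_offset)
    if not ese_scores:
        return CodonScore(codon, None, None, None, 0, "undefined_all_neutral")
    mean_ese = sum(ese_scores) / len(ese_scores)
    mean_ess = sum(ess_scores) / len(ess_scores)
    ln_ratio = (
        math.log(mean_ese / mean_ess) if mean_ese > 0 and mean_ess > 0 else None
    )
    if ln_ratio is None:
        raise ValueError(
            "non-positive mean hexamer score; declare a score_offset on the "
            "table so that ln(mean_ese/mean_ess) is defined"
        )
    return CodonScore(codon, mean_ese, mean_ess, ln_ratio, len(ese_scores), "ok")


def codon_tokens(hexamer: str) -> list[str]:
    """The 4 complete in-frame triplet tokens of a hexamer (offsets 0–3)."""
    hexamer = _check_kmer(hexamer, 6, "hexamer")
    return [hexamer[i : i + 3] for i in range(4)]


def _token_counts(hexamers: Iterable[str]) -> np.ndarray:
    counts = np.zeros(64, dtype=np.int64)
    for h in hexamers:
        for token in codon_tokens(h):
            counts[_CODON_INDEX[token]] += 1
    return counts


def codon_frequency_profile(
    sets: HexamerSets, alpha: float = 0.5
) -> CodonFrequencyProfile:
    """Codon token frequencies over ESE vs ESS hexamer sets, ln(ESEf/ESSf).

    Each hexamer contributes 4 triplet tokens, so total token counts are
    exactly 4x the set sizes.  ``alpha`` is the additive smoothing constant
    per codon type; alpha=0 is allowed only when no codon count is zero.
    """
    if not sets.ese_set or not sets.ess_set:
        raise ValueError("both hexamer sets must be non-empty")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    ese_count = _token_counts(sets.ese_set)
    ess_count = _token_counts(sets.ess_set)
    if alpha == 0 and (np.any(ese_count == 0) or np.any(ess_count == 0)):
        raise ValueError(
            "zero codon counts present; set alpha > 0 to keep ln(ESEf/ESSf) finite"
        )
    ese_f = (ese_count + alpha) / (ese_count.sum() + 64 * alpha)
    ess_f = (ess_count + alpha) / (ess_count.sum() + 64 * alpha)
    return CodonFrequencyProfile(
        ese_count=ese_count,
        ess_count=ess_count,
        ese_f=ese_f,
        ess_f=ess_f,
        ln_f_ratio=np.log(ese_f / ess_f),
        smoothing_alpha=alpha,
    )


def aggregate_codon_scores(
    scores: Sequence[CodonScore],
    groups: Mapping[int, str] | Sequence[str],
) -> dict[str, dict[str, float | int | None]]:
    """Per-group n / mean / SEM / median / IQR of codon ln(ESE/ESS) ratios.

    ``groups`` assigns a group label to each score (by position).  Only
    scores with status ``ok`` are accepted.  Groups with n < 2 report SEM
    as None.
    """
    if isinstance(groups, Mapping):
        labels = [groups[i] for i in range(len(scores))]
    else:
        labels = list(groups)
    if len(labels) != len(scores):
        raise ValueError("groups must label every score")
    if not scores:
        raise ValueError("empty score collection")
    by_group: dict[str, list[float]] = {}
    for score, label in zip(scores, labels):
        if score.status != "ok":
            raise ValueError(
                f"score for codon {score.codon} has status {score.status}; "
                "drop undefined scores before aggregation"
            )
        by_group.setdefault(label, []).append(score.ln_ratio)
    out: dict[str, dict[str, float | int | None]] = {}
    for label, values in by_group.items():
        arr = np.asarray(values, dtype=float)
        n = arr.size
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        out[label] = {
            "n": int(n),
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / math.sqrt(n)) if n >= 2 else None,
            "median": float(med),
            "iqr": float(q3 - q1),
        }
    return out
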