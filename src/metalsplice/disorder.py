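"""Amino-acid-level splicing propensity vs intrinsic-disorder scales.

Collapses codon-level ln(ESEf/ESSf) values to the 20 standard amino
acids — either under equal codon usage or weighted by a codon-usage
table (e.g. usage typical of dividing vs differentiated cells) — and
correlates the result with published per-residue disorder propensity
scales (Top-IDP, B-value, FoldUnfold, DisProt and the like).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats
from Bio.Data.CodonTable import standard_dna_table

from metalsplice.hexamers import ALL_CODONS, CodonFrequencyProfile

AMINO_ACIDS = tuple(sorted(set(standard_dna_table.forward_table.values())))
# codon -> amino acid, sense codons only (stop codons excluded)
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
AA_TO_CODONS: dict[str, tuple[str, ...]] = {
    aa: tuple(c for c in ALL_CODONS if CODON_TO_AA.get(c) == aa)
    for aa in AMINO_ACIDS
}


@dataclass
class DisorderScale:
    """A per-amino-acid disorder propensity scale."""

    name: str
    values: Mapping[str, float]

    def __post_init__(self) -> None:
        got = set(self.values)
        if got != set(AMINO_ACIDS):
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues; mismatch: {sorted(got ^ set(AMINO_ACIDS))}"
            )


@dataclass
class CodonUsage:
    """Nonnegative weights over the 61 sense codons."""

    context: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        for codon, w in self.weights.items():
            if codon not in CODON_TO_AA:
                raise ValueError(f"{codon!r} is not a sense codon")
            if w < 0:
                raise ValueError(f"negative weight for {codon}")
        for aa, codons in AA_TO_CODONS.items():
            if sum(self.weights.get(c, 0.0) for c in codons) <= 0:
                raise ValueError(f"zero total usage weight for amino acid {aa}")

    @classmethod
    def equal(cls) -> "CodonUsage":
        return cls("equal", {c: 1.0 for c in CODON_TO_AA})


def aa_level_lnratio(
    profile: CodonFrequencyProfile, usage: CodonUsage | None = None
) -> dict[str, float]:
    """Usage-weighted mean ln(ESEf/ESSf) per amino acid.

    Equal usage (the default) averages uniformly over each residue's
    synonymous codons; stop codons never contribute.
    """
    if usage is None:
        usage = CodonUsage.equal()
    out: dict[str, float] = {}
    for aa, codons in AA_TO_CODONS.items():
        weights = np.array([usage.weights.get(c, 0.0) for c in codons])
        values = np.array([profile.value(c) for c in codons])
        out[aa] = float(np.average(values, weights=weights))
    return out


def correlate_scale(
    aa_values: Mapping[str, float], scale: DisorderScale
) -> tuple[float, float]:
    """Pearson r between amino-acid splicing values and a disorder scale,
    with the two-sided p-value from the t-transform on n-2 = 18 df."""
    if set(aa_values) != set(AMINO_ACIDS):
        raise ValueError("aa_values must cover exactly the 20 standard residues")
    x = np.array([aa_values[aa] for aa in AMINO_ACIDS])
    y = np.array([scale.values[aa] for aa in AMINO_ACIDS])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
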