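"""Splice-site scoring, branchpoints, AGEZ, PPT metrics and -3 association."""

import itertools
import math

import numpy as np
import pytest

from metalsplice import simulate
from metalsplice.splice_signals import (
    BranchpointCall,
    PPT_WEIGHTS,
    SpliceSiteModel,
    agez_length,
    call_branchpoint,
    classify_terminal_nag,
    default_acceptor_model,
    default_donor_model,
    intron_type,
    minus3_association,
    motif_counts,
    ppt_metrics,
    score_site,
)
from conftest import random_seq


# -- site scoring -------------------------------------------------------------


def test_uniform_pwm_scores_zero():
    model = SpliceSiteModel("pwm", "donor", probs=np.full((9, 4), 0.25))
    assert score_site(model, "ACGTACGTA") == pytest.approx(0.0)


def test_minus3_pyrimidine_log_odds_difference():
    probs = np.full((23, 4), 0.25)
    probs[20 - 3] = [0.0, 0.8, 0.0, 0.2]  # acceptor -3: C=0.8, T=0.2
    model = SpliceSiteModel(
        "pwm", "acceptor", probs=probs / probs.sum(axis=1, keepdims=True)
    )
    base = "A" * 17 + "{}AG" + "AAA"
    diff = score_site(model, base.format("C")) - score_site(model, base.format("T"))
    assert diff == pytest.approx(math.log2(0.8 / 0.2))


def test_consensus_window_maximizes_toy_pwm():
    probs = np.array(
        [[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1],
         [0.1, 0.1, 0.7, 0.1], [0.1, 0.1, 0.1, 0.7]]
    )

    class Toy(SpliceSiteModel):
        WINDOW_LEN = {"donor": 4, "acceptor": 23}

    model = Toy("pwm", "donor", probs=probs)
    scores = {
        "".join(w): score_site(model, "".join(w))
        for w in itertools.product("ACGT", repeat=4)
    }
    assert max(scores, key=scores.get) == "ACGT"


def test_score_site_matches_per_position_oracle(rng):
    model = default_acceptor_model()
    for _ in range(50):
        window = random_seq(rng, 23)
        expected = sum(
            math.log2(model.probs[i, "ACGT".index(b)] / 0.25)
            for i, b in enumerate(window)
        )
        assert score_site(model, window) == pytest.approx(expected)


def test_score_site_validates_input():
    model = default_donor_model()
    with pytest.raises(ValueError):
        score_site(model, "ACGT")
    with pytest.raises(ValueError):
        score_site(model, "ACGTACGTX")


# -- terminal NAG -------------------------------------------------------------


@pytest.mark.parametrize(
    "intron,nag,minus3",
    [
        ("GTAAGTTTTTCAG", "CAG", "C"),
        ("GTAAGTTTTTTAG", "TAG", "T"),
        ("ATAAGTTTTTAAC", "other", "A"),
        ("GTAAGTTTTTAAG", "AAG", "A"),
        ("GTAAGTTTTTGAG", "GAG", "G"),
    ],
)
def test_classify_terminal_nag(intron, nag, minus3):
    assert classify_terminal_nag(intron) == (nag, minus3)


# -- branchpoints --------------------------------------------------------------


def _intron_with_motif_at(pos, length=90):
    """Intron whose only window adenines come from a TACTAAC box with its
    branch A at `pos`; everything else in the scan window is pyrimidine."""
    bases = {p: "T" if p % 2 else "C" for p in range(-length + 2, 0)}
    for k, b in enumerate("TACTAAC"):
        bases[pos - 5 + k] = b
    bases[pos - 6] = "G"
    bases[-2], bases[-1] = "A", "G"
    return "GT" + "".join(bases[p] for p in range(-length + 2, 0))


def test_planted_branchpoint_recovered_at_minus25():
    call = call_branchpoint(_intron_with_motif_at(-25))
    assert call is not None
    assert call.pos == -25
    assert call.method == "builtin_pwm"


def test_adenine_outside_window_ignored():
    intron = _intron_with_motif_at(-70)
    assert call_branchpoint(intron) is None


def test_tie_breaks_to_three_prime_most():
    intron = _intron_with_motif_at(-30)
    # plant an identical box at -20 as well: identical context, equal score
    bases = list(intron)
    n = len(intron)
    for k, b in enumerate("TACTAAC"):
        bases[n - 20 - 5 + k] = b
    bases[n - 20 - 6] = "G"
    call = call_branchpoint("".join(bases))
    assert call.pos == -20


def test_calls_always_inside_window(rng):
    for _ in range(50):
        intron = random_seq(rng, int(rng.integers(30, 120)))
        call = call_branchpoint(intron)
        if call is not None:
            assert -60 <= call.pos <= -13


def test_imported_calls_filtered_and_maxed():
    calls = [
        BranchpointCall(-70, 9.0, "svm"),
        BranchpointCall(-30, 2.0, "svm"),
        BranchpointCall(-22, 5.0, "svm"),
    ]
    best = call_branchpoint("G" * 40, mode="imported", imported_calls=calls)
    assert best.pos == -22
    with pytest.raises(ValueError):
        call_branchpoint("G" * 40, mode="imported")


# -- AGEZ ----------------------------------------------------------------------


@pytest.mark.parametrize(
    "intron,length,censored",
    [
        ("AGTTTTTTTTTTCAG", 11, False),
        ("TTTTTTTTTTTTTAG", 13, True),
        ("AGAG", 0, False),
    ],
)
def test_agez_examples(intron, length, censored):
    assert agez_length(intron) == (length, censored)


def test_agez_requires_ag_terminus():
    with pytest.raises(ValueError):
        agez_length("TTTTTTAC")


def test_agez_region_contains_no_ag(rng):
    """Rescan: the zone strictly between the bounding AGs is AG-free."""
    spec = simulate.CohortSpec(seed=13)
    r = spec.rng_for("agez-test")
    for _ in range(100):
        intron, _ = simulate.gen_intron(spec, "ZF", r)
        if not intron.endswith("AG"):
            continue
        length, censored = agez_length(intron)
        zone = intron[len(intron) - 2 - length : len(intron) - 2]
        assert "AG" not in zone


# -- PPT -----------------------------------------------------------------------


def _score_region(region):
    best = 0.0
    for i in range(len(region)):
        for j in range(i, len(region) + 1):
            best = max(best, sum(PPT_WEIGHTS[b] for b in region[i:j]))
    return best


@pytest.mark.parametrize(
    "region,expected",
    [
        ("TTTTCTTTT", 8.5),
        ("TTTTATTTT", 6.0),
        ("GGAAGG", 0.0),
    ],
)
def test_ppt_score_examples(region, expected):
    bp = BranchpointCall(-(len(region) + 3), 1.0, "builtin_pwm")
    intron = "GT" + "C" * 20 + "A" + region + "AG"
    _, score, _ = ppt_metrics(intron, BranchpointCall(-(len(region) + 3), 1.0,
                                                      "builtin_pwm"))
    assert score == pytest.approx(expected)


def test_ppt_score_matches_exhaustive_oracle(rng):
    for _ in range(100):
        region = random_seq(rng, int(rng.integers(1, 30)))
        intron = "GT" + "C" * 10 + "A" + region + "AG"
        bp = BranchpointCall(-(len(region) + 3), 1.0, "builtin_pwm")
        _, score, _ = ppt_metrics(intron, bp)
        assert score == pytest.approx(_score_region(region))


def test_ppt_score_monotone_in_purine_to_t(rng):
    for _ in range(30):
        region = list(random_seq(rng, 20))
        purines = [i for i, b in enumerate(region) if b in "AG"]
        if not purines:
            continue
        intron = "GT" + "C" * 10 + "A" + "".join(region) + "AG"
        bp = BranchpointCall(-23, 1.0, "builtin_pwm")
        _, before, _ = ppt_metrics(intron, bp)
        region[purines[0]] = "T"
        intron2 = "GT" + "C" * 10 + "A" + "".join(region) + "AG"
        _, after, _ = ppt_metrics(intron2, bp)
        assert after >= before


def test_ppt_u_profile_positions():
    # positions -4..-18 relative to the 3' end; -1 is the last nt
    intron = "G" * 30 + "T" * 15 + "CAG"  # Ts occupy -4..-18 exactly
    profile, _, _ = ppt_metrics(intron, None)
    assert profile == [1] * 15
    intron2 = "G" * 30 + "T" * 14 + "ACAG"  # -4 is A now
    profile2, _, _ = ppt_metrics(intron2, None)
    assert profile2[0] == 0 and profile2[1:] == [1] * 14


# -- motifs, intron type -------------------------------------------------------


def test_motif_counts_overlapping():
    bp = BranchpointCall(-8, 1.0, "builtin_pwm")
    intron = "GT" + "C" * 20 + "A" + "TTTTT" + "AG"
    counts = motif_counts(intron, bp, ["TTTT", "CCCC"])
    assert counts["TTTT"] == (2, True)
    assert counts["CCCC"] == (0, False)


def test_motif_counts_match_bruteforce(rng):
    for _ in range(50):
        region = random_seq(rng, 30)
        intron = "GT" + "C" * 5 + "A" + region + "AG"
        bp = BranchpointCall(-(len(region) + 3), 1.0, "builtin_pwm")
        counts = motif_counts(intron, bp, ["TTTT"])
        expected = sum(
            1 for i in range(len(region) - 3) if region[i : i + 4] == "TTTT"
        )
        assert counts["TTTT"][0] == expected


@pytest.mark.parametrize(
    "intron,expected",
    [
        ("GTAAGTTTCAG", "GT-AG"),
        ("ATATCCTTTAC", "AT-AC"),
        ("ATATCCTTTAA", "other"),
    ],
)
def test_intron_type(intron, expected):
    assert intron_type(intron) == expected


# -- minus3 association --------------------------------------------------------


def test_minus3_association_hand_2x2():
    records = (
        [("T", "GAAAAA")] * 80 + [("T", "CAAAAA")] * 20
        + [("C", "GAAAAA")] * 40 + [("C", "CAAAAA")] * 60
    )
    res = minus3_association(records)
    row = next(
        r for r in res["table"] if r["position"] == 1 and r["base"] == "G"
    )
    assert row["odds_ratio"] == pytest.approx(6.0)
    assert row["chi2"] == pytest.approx(33.333, abs=0.01)
    assert res["most_associated"][1] == "G"


def test_minus3_association_null_is_flat():
    records = [("T", "ACGTAC")] * 10 + [("C", "ACGTAC")] * 10
    res = minus3_association(records)
    for row in res["table"]:
        assert row["chi2"] == pytest.approx(0.0)


def test_minus3_association_reciprocal_under_class_swap():
    rng = np.random.default_rng(5)
    records = [
        (("T", "C")[int(rng.integers(2))],
         "".join(rng.choice(list("ACGT"), size=6)))
        for _ in range(300)
    ]
    res = minus3_association(records)
    swapped = minus3_association(
        [("C" if m == "T" else "T", f) for m, f in records]
    )
    for r1, r2 in zip(res["table"], swapped["table"]):
        assert r1["odds_ratio"] == pytest.approx(1.0 / r2["odds_ratio"])


def test_minus3_association_planted_pattern_recovered():
    records = simulate.gen_minus3_cohort(n=2000, seed=42)
    res = minus3_association(records)
    assert [res["most_associated"][p] for p in range(1, 7)] == list("GAATTA")


def test_minus3_association_needs_both_classes():
    with pytest.raises(ValueError):
        minus3_association([("T", "AAAAAA")] * 5)
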