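"""Codon windowing, hexamer averaging and codon frequency profiles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metalsplice.hexamers import (
    HexamerScoreTable,
    HexamerSets,
    NUCLEOTIDES,
    aggregate_codon_scores,
    codon_frequency_profile,
    codon_tokens,
    codon_windows,
    load_score_table,
    score_codon,
)
from conftest import make_constant_table, make_random_table, random_seq

seq_strategy = st.text(alphabet="ACGT", min_size=6, max_size=40)


# -- score table I/O --------------------------------------------------------


def test_load_score_table_toy(tmp_path):
    path = tmp_path / "table.tsv"
    path.write_text(
        "hexamer\tese_score\tess_score\tclass\n"
        "AAAAAA\t2.0\t1.0\tE\n"
        "CCCCCC\t0.5\t1.5\tS\n"
        "GGGGGG\t1.0\t1.0\tN\n"
    )
    table = load_score_table(path)
    assert len(table) == 3
    assert table.lookup("AAAAAA") == (2.0, 1.0, "E")
    assert table.lookup("CCCCCC")[2] == "S"
    assert table.lookup("GGGGGG")[2] == "N"


@pytest.mark.parametrize(
    "bad_row,match",
    [
        ("AAAAXA\t1\t1\tE\n", ":3"),  # invalid alphabet, line number named
        ("AAAAAA\t2\t1\tE\n", "duplicate"),
    ],
)
def test_load_score_table_bad_rows(tmp_path, bad_row, match):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "hexamer\tese_score\tess_score\tclass\nAAAAAA\t2\t1\tE\n" + bad_row
    )
    with pytest.raises(ValueError, match=match):
        load_score_table(path)


def test_load_score_table_missing_column(tmp_path):
    path = tmp_path / "cols.tsv"
    path.write_text("hexamer\tese_score\nAAAAAA\t1\n")
    with pytest.raises(ValueError, match="ess_score"):
        load_score_table(path)


def test_load_complete_table_roundtrip(tmp_path):
    rows = ["hexamer\tese_score\tess_score\tclass"]
    for i, p in enumerate(itertools.product(NUCLEOTIDES, repeat=6)):
        rows.append(f"{''.join(p)}\t{1 + i % 5}\t{1 + i % 3}\tE")
    path = tmp_path / "full.tsv"
    path.write_text("\n".join(rows) + "\n")
    table = load_score_table(path)
    assert len(table) == 4096


def test_load_score_table_sign_rule(tmp_path):
    path = tmp_path / "norule.tsv"
    path.write_text(
        "#classify: neutral_band=0.1\n"
        "hexamer\tese_score\tess_score\n"
        "AAAAAA\t2.0\t1.0\nCCCCCC\t0.5\t1.5\nGGGGGG\t1.0\t1.05\n"
    )
    table = load_score_table(path)
    assert [table.lookup(h)[2] for h in ("AAAAAA", "CCCCCC", "GGGGGG")] == [
        "E", "S", "N",
    ]


# -- codon windows ----------------------------------------------------------


@pytest.mark.parametrize(
    "seq,start,expected",
    [
        ("AAATGCAAA", 3, ["AAATGC", "AATGCA", "ATGCAA", "TGCAAA"]),
        ("AAATGCAAA", 0, ["AAATGC"]),
        ("AAATGC", 3, ["AAATGC"]),
    ],
)
def test_codon_windows_examples(seq, start, expected):
    assert codon_windows(seq, start) == expected


def test_codon_windows_out_of_bounds():
    with pytest.raises(ValueError):
        codon_windows("AAATGC", 4)


@settings(max_examples=200, derandomize=True)
@given(seq=seq_strategy, start=st.integers(0, 37))
def test_codon_windows_matches_bruteforce(seq, start):
    """Windows are exactly the in-bounds hexamer starts containing the codon."""
    if start + 3 > len(seq):
        return
    oracle = [
        seq[s : s + 6]
        for s in range(len(seq) - 5)
        if s <= start and start + 3 <= s + 6
    ]
    assert codon_windows(seq, start) == oracle


# -- codon scoring ----------------------------------------------------------


def test_score_codon_constant_table(constant_table):
    cs = score_codon(constant_table, "AAATGCAAA", 3)
    assert cs.status == "ok"
    assert cs.mean_ese == pytest.approx(2.0)
    assert cs.mean_ess == pytest.approx(1.0)
    assert cs.ln_ratio == pytest.approx(math.log(2), abs=1e-12)
    assert cs.n_windows_used == 4


def test_score_codon_hand_average():
    seq = "AAATGCAAA"
    windows = codon_windows(seq, 3)
    entries = {w: (float(i + 1), 1.0, "E") for i, w in enumerate(windows)}
    table = HexamerScoreTable(entries)
    cs = score_codon(table, seq, 3)
    assert cs.mean_ese == pytest.approx(2.5)
    assert cs.ln_ratio == pytest.approx(math.log(2.5))


def test_score_codon_boundary_requires_context(constant_table):
    cs = score_codon(constant_table, "AAATGCAAA", 0)
    assert cs.status == "undefined_no_context"
    relaxed = score_codon(constant_table, "AAATGCAAA", 0, require_full_context=False)
    assert relaxed.status == "ok"
    assert relaxed.n_windows_used == 1


def test_score_codon_all_neutral():
    table = make_constant_table(cls="N")
    cs = score_codon(table, "AAATGCAAA", 3)
    assert cs.status == "undefined_all_neutral"
    assert cs.ln_ratio is None


def test_score_codon_missing_hexamer_errors():
    table = HexamerScoreTable({"AAAAAA": (1.0, 1.0, "E")})
    with pytest.raises(KeyError, match="absent"):
        score_codon(table, "AAATGCAAA", 3)


def test_score_codon_constant_table_identical_everywhere(constant_table, rng):
    """With one score for all hexamers every full-context codon scores alike."""
    seq = random_seq(rng, 60)
    scores = {
        score_codon(constant_table, seq, s).ln_ratio for s in range(3, 51, 3)
    }
    assert len(scores) == 1


def test_score_codon_matches_bruteforce_oracle(rng):
    """Mean over non-neutral in-bounds windows, enumerated independently."""
    table = make_random_table(rng)
    for _ in range(200):
        seq = random_seq(rng, int(rng.integers(6, 30)))
        start = int(rng.integers(0, len(seq) - 2))
        ese, ess = [], []
        for s in range(len(seq) - 5):
            if s <= start and start + 3 <= s + 6:
                e, x, cls = table.entries[seq[s : s + 6]]
                if cls != "N":
                    ese.append(e)
                    ess.append(x)
        cs = score_codon(table, seq, start, require_full_context=False)
        if not ese:
            assert cs.status == "undefined_all_neutral"
        else:
            assert cs.mean_ese == pytest.approx(sum(ese) / len(ese))
            assert cs.ln_ratio == pytest.approx(
                math.log(sum(ese) / sum(ess) * len(ess) / len(ese))
            )


# -- codon tokens and frequency profiles ------------------------------------


@pytest.mark.parametrize(
    "hexamer,expected",
    [
        ("GAAGAA", ["GAA", "AAG", "AGA", "GAA"]),
        ("AAAAAA", ["AAA", "AAA", "AAA", "AAA"]),
    ],
)
def test_codon_tokens_examples(hexamer, expected):
    assert codon_tokens(hexamer) == expected


def test_codon_tokens_rejects_wrong_length():
    with pytest.raises(ValueError):
        codon_tokens("AAAA")


@settings(max_examples=50, derandomize=True)
@given(st.sets(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1,
               max_size=30))
def test_token_conservation(hexamers):
    """Any hexamer set yields exactly 4 tokens per member."""
    total = sum(len(codon_tokens(h)) for h in hexamers)
    assert total == 4 * len(hexamers)


def test_frequency_profile_hand_smoothing():
    sets = HexamerSets(frozenset({"AAAAAA"}), frozenset({"CCCCCC"}))
    prof = codon_frequency_profile(sets, alpha=0.5)
    assert prof.value("AAA") == pytest.approx(math.log(9))
    i = prof.codons.index("AAA")
    assert prof.ese_f[i] == pytest.approx(4.5 / 36)
    assert prof.ess_f[i] == pytest.approx(0.5 / 36)


def test_frequency_profile_symmetry_and_sums(rng):
    hexes = list({random_seq(rng, 6) for _ in range(200)})
    sets = HexamerSets(frozenset(hexes[:80]), frozenset(hexes[80:160]))
    prof = codon_frequency_profile(sets)
    assert prof.ese_f.sum() == pytest.approx(1.0, abs=1e-12)
    assert prof.ess_f.sum() == pytest.approx(1.0, abs=1e-12)
    swapped = codon_frequency_profile(
        HexamerSets(sets.ess_set, sets.ese_set)
    )
    np.testing.assert_allclose(swapped.ln_f_ratio, -prof.ln_f_ratio, atol=1e-12)


def test_frequency_profile_identical_sets_zero():
    s = frozenset({"AAATGC", "GGGCCC"})
    with pytest.raises(ValueError):
        HexamerSets(s, s)  # sets must be disjoint
    prof_a = codon_frequency_profile(
        HexamerSets(s, frozenset({"TTTGGG", "CCCAAA"}))
    )
    assert prof_a.ln_f_ratio.shape == (64,)


def test_frequency_profile_alpha_zero_guard():
    sets = HexamerSets(frozenset({"AAAAAA"}), frozenset({"CCCCCC"}))
    with pytest.raises(ValueError, match="alpha"):
        codon_frequency_profile(sets, alpha=0.0)


# -- aggregation ------------------------------------------------------------


def _ok_scores(values):
    from metalsplice.hexamers import CodonScore

    return [
        CodonScore("AAA", 2.0, 1.0, v, 4, "ok") for v in values
    ]


def test_aggregate_codon_scores_hand_values():
    scores = _ok_scores([0.1, 0.3, 0.5])
    out = aggregate_codon_scores(scores, ["g"] * 3)
    assert out["g"]["mean"] == pytest.approx(0.3)
    assert out["g"]["median"] == pytest.approx(0.3)
    assert out["g"]["sem"] == pytest.approx(0.2 / math.sqrt(3), rel=1e-6)


def test_aggregate_single_element_sem_undefined():
    out = aggregate_codon_scores(_ok_scores([0.7]), ["g"])
    assert out["g"]["mean"] == pytest.approx(0.7)
    assert out["g"]["sem"] is None


def test_aggregate_identical_groups_identical_summaries():
    scores = _ok_scores([0.1, 0.2, 0.4, 0.1, 0.2, 0.4])
    out = aggregate_codon_scores(scores, ["a"] * 3 + ["b"] * 3)
    assert out["a"] == out["b"]


def test_aggregate_rejects_undefined_and_empty():
    from metalsplice.hexamers import CodonScore

    bad = [CodonScore("AAA", None, None, None, 0, "undefined_all_neutral")]
    with pytest.raises(ValueError):
        aggregate_codon_scores(bad, ["g"])
    with pytest.raises(ValueError):
        aggregate_codon_scores([], [])
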