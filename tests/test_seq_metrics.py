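"""Dinucleotide statistics: worked values, oracle equivalence, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captss import seq_metrics as sm
from captss.sequence import revcomp

SEQ = st.text(alphabet="ACGTN", min_size=0, max_size=300)


def naive_dinuc_counts(seq):
    """Position-by-position oracle for overlapping dinucleotide counting."""
    counts = {d: 0 for d in sm.DINUCLEOTIDES}
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if "N" not in pair:
            counts[pair] += 1
    return counts


def naive_score(seq, xy):
    counts = naive_dinuc_counts(seq)
    x = sum(1 for b in seq if b == xy[0])
    y = sum(1 for b in seq if b == xy[1])
    if x == 0 or y == 0:
        return None
    return counts[xy] * len(seq) / (x * y)


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("CGCGCG", {"CG": 3, "GC": 2}),
        ("ACGT", {"AC": 1, "CG": 1, "GT": 1}),
        ("AANAA", {"AA": 2}),
        ("", {}),
        ("A", {}),
    ],
)
def test_count_dinucleotides_worked_examples(seq, expected):
    counts = sm.count_dinucleotides(seq)
    assert {k: v for k, v in counts.items() if v} == expected
    assert set(counts) == set(sm.DINUCLEOTIDES)


@pytest.mark.parametrize(
    "seq,expected",
    [("ACGCGT", 3.0), ("CGCGCG", 2.0), ("ATATAT", None)],
)
def test_cpg_score_worked_examples(seq, expected):
    assert sm.cpg_score(seq) == expected


def test_content_worked_examples():
    assert sm.cpg_content("ACGCGT") == pytest.approx(0.4)
    assert sm.gc_content("ACGCGT") == pytest.approx(2 / 3)
    assert sm.cpg_content("AAAA") == 0.0
    assert sm.dinuc_score("TGTG", "TG") == pytest.approx(2.0)


def test_random_sequence_oracle_equivalence(rng):
    """count_dinucleotides and scores match the naive scan on random input."""
    for _ in range(300):
        n = int(rng.integers(2, 2000))
        seq = "".join(rng.choice(list("ACGTN"), n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        assert sm.count_dinucleotides(seq) == naive_dinuc_counts(seq)
        xy = "".join(rng.choice(list("ACGT"), 2))
        got = sm.dinuc_score(seq, xy)
        want = naive_score(seq, xy)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)


@given(SEQ)
@settings(max_examples=200, deadline=None)
def test_dinuc_score_cg_equals_cpg_score(seq):
    assert sm.dinuc_score(seq, "CG") == sm.cpg_score(seq)


@given(SEQ)
@settings(max_examples=200, deadline=None)
def test_reverse_complement_symmetry(seq):
    """CpG is its own reverse complement; TG maps to CA under revcomp."""
    assert sm.cpg_score(revcomp(seq)) == sm.cpg_score(seq)
    tg, ca = sm.dinuc_score(seq, "TG"), sm.dinuc_score(revcomp(seq), "CA")
    if tg is None:
        assert ca is None
    else:
        assert ca == pytest.approx(tg)


def test_iid_sequence_scores_near_one(rng):
    """On i.i.d. sequence the expected CpG score is 1; check within 3 SE."""
    n = 100_000
    seq = "".join(rng.choice(list("ACGT"), n, p=[0.3, 0.2, 0.2, 0.3]))
    score = sm.cpg_score(seq)
    # SE of the score ~ 1/sqrt(expected CpG count)
    se = 1 / np.sqrt(n * 0.2 * 0.2)
    assert abs(score - 1.0) < 3 * se
    assert sm.cpg_content(seq) == pytest.approx(0.2 * 0.2, abs=3 * se / 16)


def test_sliding_window_scan_counts_and_truncation():
    genome = {"c": "ACGT" * 750}  # 3000 nt
    wins = list(sm.sliding_window_scan(genome, 1000, 1000))
    assert len(wins) == 3
    assert all(w.end - w.start == 1000 for w in wins)
    assert sum(w.counts[d] for d in sm.DINUCLEOTIDES for w in wins[:1]) == 999
    assert list(sm.sliding_window_scan({"c": "A" * 999}, 1000)) == []


def test_sliding_window_uniform_cg_repeat():
    wins = list(sm.sliding_window_scan({"c": "CG" * 500}, 1000))
    assert len(wins) == 1
    assert wins[0].cpg_score == pytest.approx(2.0)  # 500*1000/(500*500)


def test_window_flagging_on_ambiguous_bases():
    genome = {"c": "ACGT" * 100 + "N" * 10 + "ACGT" * 100}
    wins = list(sm.sliding_window_scan(genome, 200, 200, max_ambiguous_frac=0.0))
    assert any(w.flagged for w in wins)
    assert all(w.flagged == (w.ambiguous_frac > 0) for w in wins)


def test_island_calls():
    assert sm.is_cpg_island("CG" * 100).is_island is True
    assert sm.is_cpg_island("AT" * 100).is_island is False
    short = sm.is_cpg_island("A" * 199)
    assert short.is_island is False and short.reason == "too short"


def test_island_reports_best_window_and_runs():
    seq = "AT" * 200 + "CG" * 150 + "AT" * 200
    call = sm.is_cpg_island(seq)
    assert call.is_island
    assert call.best_score >= 0.6 and call.best_gc >= 0.5
    # the merged qualifying run must cover the CpG-rich block at [400, 700)
    run = call.qualifying_runs[0]
    assert run[0] <= 400 and run[1] >= 700


def test_classify_promoter_cpg_thresholds(rng):
    # constructed windows on either side of the published 0.5/0.6 split
    assert sm.classify_promoter_cpg("AT" * 100) == "unclassifiable"  # no G
    rich = sm.classify_promoter_cpg("CG" * 100)
    assert rich == "rich"
    poor_seq = "".join(rng.choice(list("ACGT"), 200, p=[0.3, 0.2, 0.2, 0.3]))
    poor_seq = poor_seq.replace("CG", "TG")  # strip CpG -> score ~0
    assert sm.classify_promoter_cpg(poor_seq) == "poor"
    with pytest.raises(ValueError):
        sm.classify_promoter_cpg("ACGT")


def test_classify_boundary_scores_are_intermediate():
    # strict inequalities: scores exactly at 0.5 / 0.6 are intermediate.
    # score = CpG*200/(C*G); A spacers prevent accidental CpG at junctions.
    at_half = "CG" + "C" * 19 + "A" + "G" * 19 + "A" * 159  # 1*200/(20*20)
    assert sm.cpg_score(at_half) == pytest.approx(0.5)
    assert sm.classify_promoter_cpg(at_half) == "intermediate"
    at_sixty = "CGCGCG" + "C" * 22 + "A" + "G" * 37 + "A" * 134  # 3*200/(25*40)
    assert sm.cpg_score(at_sixty) == pytest.approx(0.6)
    assert sm.classify_promoter_cpg(at_sixty) == "intermediate"
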