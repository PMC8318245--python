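"""Q accuracy, SOV, boundary/internal accuracy and misclassification rates.

The three frameshift actual/predicted pairs — an all-alpha, an
alpha-beta mixed, and an alpha-beta segregated pseudo-structure, each
differing from its reference only by a two-residue frameshift — pin
the SOV variant: the 1999 revision must reproduce their printed
Q3/SOV3 values exactly.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sse_pssm as sp
from sse_pssm.errors import DataError, LengthMismatchError
from sse_pssm.metrics import segments

ALL_ALPHA = ("CHHHHCHHHHCHHHHCHHHHCHHHH", "HHCHHHHCHHHHCHHHHCHHHHCHH")
AB_MIXED = ("CHHHHCEEEECHHHHCEEEECHHHH", "HHCHHHHCEEEECHHHHCEEEECHH")
AB_SEGREGATED = ("CHHHHCHHHHCHHHHCEEEECEEEE", "EECHHHHCHHHHCHHHHCEEEECEE")

q3_strings = st.text(alphabet="HEC", min_size=1, max_size=40)


@pytest.mark.parametrize(
    "pair,q3,sov3",
    [
        (ALL_ALPHA, 0.600, 0.441),
        (AB_MIXED, 0.440, 0.526),
        (AB_SEGREGATED, 0.520, 0.462),
    ],
)
def test_frameshift_worked_examples(pair, q3, sov3):
    actual, predicted = pair
    assert round(sp.q_accuracy(actual, predicted), 3) == q3
    assert round(sp.sov(actual, predicted), 3) == sov3


def test_q_accuracy_basics():
    assert sp.q_accuracy("HEC", "HEC") == 1.0
    with pytest.raises(LengthMismatchError):
        sp.q_accuracy("HE", "H")


def test_macro_micro_averaging_worked_example():
    macro, micro = sp.average_q([(50, 0.90), (350, 0.50)])
    assert macro == pytest.approx(0.70)
    assert micro == pytest.approx(0.55)
    # 220 of 400 residues correct
    assert round(50 * 0.90) + round(350 * 0.50) == 220


def test_average_q_single_query():
    macro, micro = sp.average_q([(30, 0.8)])
    assert macro == micro == pytest.approx(0.8)
    with pytest.raises(DataError):
        sp.average_q([])


def test_sov_perfect_prediction():
    assert sp.sov("CHHHHEEC", "CHHHHEEC") == pytest.approx(1.0)


def test_boundary_internal_partition():
    actual = "CCHHHHCC"
    # segments CC|HHHH|CC -> boundary residues (1-based) {1,2,3,6,7,8}
    predicted = "ACHHHHCC".replace("A", "H")  # wrong only at position 1
    boundary, internal = sp.boundary_internal_q(actual, predicted)
    assert boundary == pytest.approx(5 / 6)
    assert internal == pytest.approx(1.0)


def test_boundary_single_segment():
    # "HHHH": boundary {1, 4}, internal {2, 3}
    boundary, internal = sp.boundary_internal_q("HHHH", "HHEE")
    assert boundary == pytest.approx(1 / 2)
    assert internal == pytest.approx(1 / 2)
    b, i = sp.boundary_internal_q("HE", "HE")
    assert b == 1.0 and math.isnan(i)  # no internal residues


def test_misclassification_complete_swap():
    rates = sp.misclassification_rates("HHEE", "EEHH")
    assert rates == {"H<->E": 1.0, "H<->C": 0.0, "E<->C": 0.0}
    assert sp.misclassification_rates("HEC", "HEC") == {
        "H<->E": 0.0,
        "H<->C": 0.0,
        "E<->C": 0.0,
    }


def test_misclassification_matches_confusion_recount():
    rng = np.random.default_rng(0)
    actual = "".join(rng.choice(list("HEC"), size=30))
    predicted = "".join(rng.choice(list("HEC"), size=30))
    rates = sp.misclassification_rates(actual, predicted)
    counts = {"H<->E": 0, "H<->C": 0, "E<->C": 0}
    for a, p in zip(actual, predicted):
        if a != p:
            counts["<->".join(sorted((a, p), key="HEC".index))] += 1
    assert rates == {k: v / 30 for k, v in counts.items()}


@settings(max_examples=60, derandomize=True)
@given(q3_strings, q3_strings)
def test_rates_plus_q3_sum_to_one(a, p):
    n = min(len(a), len(p))
    a, p = a[:n], p[:n]
    if n == 0:
        return
    rates = sp.misclassification_rates(a, p)
    assert sum(rates.values()) + sp.q_accuracy(a, p) == pytest.approx(1.0)


@settings(max_examples=40, derandomize=True)
@given(q3_strings, q3_strings)
def test_sov_invariant_under_state_relabeling(a, p):
    n = min(len(a), len(p))
    a, p = a[:n], p[:n]
    if n == 0:
        return
    relabel = str.maketrans("HEC", "ECH")
    assert sp.sov(a, p) == pytest.approx(sp.sov(a.translate(relabel), p.translate(relabel)))


def test_macro_equals_micro_for_equal_lengths():
    per_query = [(40, 0.5), (40, 0.9), (40, 0.7)]
    macro, micro = sp.average_q(per_query)
    assert macro == pytest.approx(micro)


def test_segments_helper():
    assert segments("CCHHC") == [("C", 0, 1), ("H", 2, 3), ("C", 4, 4)]


def test_evaluate_queries_pools_counts():
    pairs = [("a", *ALL_ALPHA), ("b", *AB_MIXED)]
    report = sp.evaluate_queries(pairs, sp.Q3)
    assert report.micro_q == pytest.approx((15 + 11) / 50)
    assert report.macro_q == pytest.approx((0.6 + 0.44) / 2)
    assert len(report.queries) == 2
    assert report.queries[0].confusion.sum() == 25
    total_mis = sum(report.misclassification.values())
    assert total_mis + report.micro_q == pytest.approx(1.0)


def test_evaluate_queries_8state_inputs():
    pairs = [("a", "GGHHEETTSS", "HHGGBBTTCC")]
    report = sp.evaluate_queries(pairs, sp.DSSP8)
    # rates are computed after 8->3 reduction automatically
    assert sum(report.misclassification.values()) <= 1.0
    assert report.queries[0].n_residues == 10
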