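"""Profile construction: transformation, occurrences, PPM/PSSM, BLOSUM-style
substitution matrices — each against naive loop oracles."""

import math

import numpy as np
import pytest

import sse_pssm as sp
from sse_pssm.errors import DataError, LengthMismatchError, ParameterError
from sse_pssm.pssm import (
    SCORE_FLOOR,
    TransformedAlignment,
    apply_pseudocounts,
)


def test_transform_alignment_threads_codes_through_gaps():
    t = sp.transform_alignment("ILAGWKKL", "IL-GW--L", "CHHEE", 1.0, hit_sequence="ILGWL")
    assert t.hit_sse_aligned == "CH-HE--E"


def test_transform_alignment_all_gaps():
    t = sp.transform_alignment("ILAGW", "-----", "CHHEE", 1.0, hit_sequence="ILGWL")
    assert t.hit_sse_aligned == "-----"


def test_transform_alignment_length_mismatch():
    with pytest.raises(LengthMismatchError):
        sp.transform_alignment("ILAGWKKL", "IL-GW--L", "CHHE", 1.0, hit_sequence="ILGWL")


def _query(seq="MKVIL"):
    return sp.SequenceRecord("q", seq)


def test_occurrences_single_hit():
    t = TransformedAlignment("MKVIL", "HH-EC", 1.0)
    occ = sp.compute_occurrences(_query(), [t], sp.Q3)
    assert occ.values[0, sp.Q3.index("H")] == 1.0
    assert occ.values[2].sum() == 0.0  # gap contributes nothing


def test_occurrences_are_weight_linear():
    hits = [
        TransformedAlignment("MKVIL", "CCCCC", 0.8),
        TransformedAlignment("MKVIL", "CCCCC", 0.4),
    ]
    occ = sp.compute_occurrences(_query(), hits, sp.Q3)
    assert occ.values[0, sp.Q3.index("C")] == pytest.approx(1.2)


def _naive_occurrences(query_len, transformed, alphabet):
    values = np.zeros((query_len, len(alphabet)))
    for t in transformed:
        p = t.query_start
        for qc, sc in zip(t.query_aligned, t.hit_sse_aligned):
            if qc != "-":
                if sc != "-":
                    values[p, alphabet.codes.index(sc)] += t.weight
                p += 1
    return values


@pytest.mark.parametrize("seed", range(8))
def test_occurrence_matrix_equals_naive_loop(seed):
    """Random instances (<=10 residues, <=5 hits, gapped) recounted naively."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 11))
    query = _query("A" * n)
    transformed = []
    for _ in range(rng.integers(1, 6)):
        start = int(rng.integers(0, n))
        span = int(rng.integers(1, n - start + 1))
        qcols, scols = [], []
        for _ in range(span):
            qcols.append("A")
            scols.append(rng.choice(["H", "E", "C", "-"]))
        transformed.append(
            TransformedAlignment(
                "".join(qcols), "".join(scols), float(rng.uniform(0.1, 1.0)),
                query_start=start,
            )
        )
    occ = sp.compute_occurrences(query, transformed, sp.Q3)
    assert np.allclose(occ.values, _naive_occurrences(n, transformed, sp.Q3))
    # conservation: column mass equals summed weights of covering hits
    for p in range(n):
        covering = sum(
            t.weight
            for t in transformed
            if t.query_start <= p < t.query_start + len(t.query_aligned)
            and t.hit_sse_aligned[p - t.query_start] != "-"
        )
        assert occ.values[p].sum() == pytest.approx(covering)


BG = sp.BackgroundFrequencies({"H": 0.4, "E": 0.25, "C": 0.35})


def test_ppm_normalization():
    occ = sp.OccurrenceMatrix(np.array([[3.0, 1.0, 0.0]]), sp.Q3)
    ppm, fallback = sp.ppm_from_occurrences(occ)
    assert np.allclose(ppm[0], [0.75, 0.25, 0.0])
    assert fallback == frozenset()


def test_ppm_zero_column_falls_back_to_background():
    occ = sp.OccurrenceMatrix(np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]]), sp.Q3)
    ppm, fallback = sp.ppm_from_occurrences(occ, BG)
    assert fallback == frozenset({1})
    assert np.allclose(ppm[1], BG.vector(sp.Q3))
    assert np.allclose(ppm.sum(axis=1), 1.0)


def _toy_subst():
    pairs = [("HHEEC", "HHECC"), ("HECC", "HECC")]
    return sp.build_substitution_matrix(pairs, sp.Q3)


def test_pseudocounts_tau_zero_is_identity():
    col = np.array([2.0, 1.0, 1.0])
    out = apply_pseudocounts(col, BG, _toy_subst(), 0.0, sp.Q3)
    assert np.allclose(out, col / col.sum())


def test_pseudocounts_empty_column_is_background():
    out = apply_pseudocounts(np.zeros(3), BG, _toy_subst(), 1.0, sp.Q3)
    assert np.allclose(out, BG.vector(sp.Q3))


def test_pseudocounts_match_hand_formula():
    subst = _toy_subst()
    col = np.array([2.0, 0.0, 0.0])
    tau = 1.0
    out = apply_pseudocounts(col, BG, subst, tau, sp.Q3)
    # hand computation of f' = (N f + tau g) / (N + tau)
    T = subst.conditional_probabilities()
    f = col / col.sum()
    g = T @ f
    g = g / g.sum()
    expected = (col.sum() * f + tau * g) / (col.sum() + tau)
    expected = expected / expected.sum()
    assert np.allclose(out, expected)
    assert out.sum() == pytest.approx(1.0)
    assert np.all(out > 0)


def test_pseudocounts_negative_tau_rejected():
    with pytest.raises(ParameterError):
        apply_pseudocounts(np.ones(3), BG, None, -0.1, sp.Q3)


def test_pssm_log_odds_values():
    bg = sp.BackgroundFrequencies({"H": 0.25, "E": 0.25, "C": 0.5})
    ppm = np.array([[0.5, 0.25, 0.25]])
    pssm = sp.pssm_from_ppm(ppm, bg, sp.Q3)
    assert pssm[0, 0] == pytest.approx(1.0)  # log2(0.5/0.25)
    assert pssm[0, 1] == pytest.approx(0.0)
    ppm_bg = np.tile(bg.vector(sp.Q3), (4, 1))
    assert np.allclose(sp.pssm_from_ppm(ppm_bg, bg, sp.Q3), 0.0)


def test_pssm_floor_for_zero_cells():
    pssm = sp.pssm_from_ppm(np.array([[1.0, 0.0, 0.0]]), BG, sp.Q3)
    assert pssm[0, 1] == SCORE_FLOOR
    with pytest.raises(ParameterError):
        sp.pssm_from_ppm(
            np.array([[1.0, 0.0, 0.0]]),
            sp.BackgroundFrequencies({"H": 1.0, "E": 0.0, "C": 0.0}),
            sp.Q3,
        )


def test_build_profile_single_perfect_hit_is_one_hot():
    query = _query("MKVIL")
    hit = sp.HitAlignment("q", "h", "MKVIL", "MKVIL", 1.0, query_start=0, hit_start=0)
    profile = sp.build_profile(query, [hit], {"h": "CHHEE"}, sp.Q3, BG, tau=0.0)
    expected = np.zeros((5, 3))
    for p, code in enumerate("CHHEE"):
        expected[p, sp.Q3.index(code)] = 1.0
    assert np.allclose(profile.ppm, expected)
    assert profile.pseudocount_positions == frozenset()


def test_build_profile_zero_hits_is_background():
    query = _query("MKVIL")
    profile = sp.build_profile(query, [], {}, sp.Q3, BG, tau=0.5)
    assert profile.pseudocount_positions == frozenset(range(5))
    assert np.allclose(profile.ppm, np.tile(BG.vector(sp.Q3), (5, 1)))
    assert np.allclose(profile.pssm, 0.0)


def test_build_profile_invariant_to_hit_order(small_family):
    fam = small_family
    lib = {r.id: r.sse for r in fam.target_sse}
    bg = sp.compute_background(fam.target_sse, sp.Q3)
    a = sp.build_profile(fam.query, fam.alignments, lib, sp.Q3, bg, tau=0.5)
    b = sp.build_profile(fam.query, list(reversed(fam.alignments)), lib, sp.Q3, bg, tau=0.5)
    assert np.allclose(a.ppm, b.ppm)
    assert np.allclose(a.pssm, b.pssm)


def test_profile_reduction_equivalence(small_family):
    """Summing 8-state PPM mass through the 8->3 mapping equals building the
    profile directly from pre-reduced strings (tau = 0, covered positions)."""
    fam = small_family
    # lift the q3 family onto dssp8 codes (H->H, E->E, C->C are valid dssp8)
    lib8 = {r.id: r.sse for r in fam.target_sse}
    bg8 = sp.compute_background(
        [sp.SSERecord(r.id, r.sse) for r in fam.target_sse], sp.DSSP8
    )
    prof8 = sp.build_profile(fam.query, fam.alignments, lib8, sp.DSSP8, bg8, tau=0.0)
    lib3 = {k: sp.reduce_sse_string(v, sp.DSSP8_TO_Q3) for k, v in lib8.items()}
    bg3 = sp.compute_background(lib3, sp.Q3)
    prof3 = sp.build_profile(fam.query, fam.alignments, lib3, sp.Q3, bg3, tau=0.0)
    reduced = np.zeros_like(prof3.ppm)
    for i8, code8 in enumerate(sp.DSSP8.codes):
        reduced[:, sp.Q3.index(sp.DSSP8_TO_Q3.mapping[code8])] += prof8.ppm[:, i8]
    covered = sorted(set(range(len(fam.query.sequence))) - prof8.pseudocount_positions)
    assert np.allclose(reduced[covered], prof3.ppm[covered])


def test_compute_background_counts_and_smoothing():
    bg = sp.compute_background({"a": "HHEE"}, sp.Q3)
    # C absent -> add-one smoothing over (2+1, 2+1, 0+1)
    assert bg.freq["H"] == pytest.approx(3 / 7)
    assert bg.freq["C"] == pytest.approx(1 / 7)
    assert sum(bg.freq.values()) == pytest.approx(1.0)
    assert all(v > 0 for v in bg.freq.values())
    with pytest.raises(DataError):
        sp.compute_background({}, sp.Q3)


def test_background_matches_per_string_recount():
    strings = {"a": "HHECC", "b": "EEEC", "c": "HCH"}
    bg = sp.compute_background(strings, sp.Q3)
    counts = {"H": 0, "E": 0, "C": 0}
    for s in strings.values():
        for ch in s:
            counts[ch] += 1
    total = sum(counts.values())
    for c in "HEC":
        assert bg.freq[c] == pytest.approx(counts[c] / total)


def test_substitution_matrix_symmetry_and_floor():
    m = sp.build_substitution_matrix([("HHH", "HHH"), ("EEE", "EEE"), ("CC", "CC")], sp.Q3)
    assert np.allclose(m.scores, m.scores.T)
    off = ~np.eye(3, dtype=bool)
    assert np.all(m.scores[off] == SCORE_FLOOR)
    rng = np.random.default_rng(0)
    pairs = [
        (
            "".join(rng.choice(list("HEC"), size=12)),
            "".join(rng.choice(list("HEC"), size=12)),
        )
        for _ in range(4)
    ]
    m2 = sp.build_substitution_matrix(pairs, sp.Q3)
    assert np.allclose(m2.scores, m2.scores.T)


def test_substitution_matrix_equals_hand_pair_count():
    """2-pair toy corpus of 4 columns, checked against the stated formulas."""
    pairs = [("HE", "HH"), ("CC", "EC")]
    m = sp.build_substitution_matrix(pairs, sp.Q3)
    # columns: (H,H), (E,H), (C,E), (C,C) -> q over 4 columns
    q = {("H", "H"): 0.25, ("E", "H"): 0.25, ("C", "E"): 0.25, ("C", "C"): 0.25}
    p = {"H": 0.25 + 0.125, "E": 0.125 + 0.125, "C": 0.25 + 0.125}
    for (a, b), qv in q.items():
        e = p[a] ** 2 if a == b else 2 * p[a] * p[b]
        i, j = sp.Q3.index(a), sp.Q3.index(b)
        assert m.scores[i, j] == pytest.approx(math.log2(qv / e))
    with pytest.raises(DataError):
        sp.build_substitution_matrix([("-", "H")], sp.Q3)
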