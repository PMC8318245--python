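"""Feature engineering: windows, amino-acid-type encoding, merging, imports."""

import numpy as np
import pytest

import sse_pssm as sp
from sse_pssm.errors import DataError, InvalidCodeError, ParameterError
from sse_pssm.features import (
    AA_CLASSES,
    ABUNDANCE,
    KYTE_DOOLITTLE,
    FeatureMatrix,
    aa_type_features,
)


def _matrix(values, prefix="f", source=""):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(values, [f"{prefix}{i}" for i in range(values.shape[1])], source=source)


def test_window_one_is_identity():
    m = _matrix(np.arange(12).reshape(4, 3))
    out = sp.window_features(m, sp.WindowParams(window_size=1))
    assert np.array_equal(out.values, m.values)


def test_window_feature_arithmetic():
    m = _matrix(np.arange(24).reshape(3, 8))
    out = sp.window_features(m, sp.WindowParams(window_size=5))
    assert out.values.shape == (3, 40)
    # residue 1 (row 0) has positions -2 and -1 out of range: 16 padded cells
    assert np.count_nonzero(out.values[0, :16] == 0.0) == 16


def test_window_rows_equal_slice_oracle():
    rng = np.random.default_rng(0)
    m = _matrix(rng.normal(size=(7, 4)))
    out = sp.window_features(m, sp.WindowParams(window_size=3))
    for p in range(1, 6):  # interior rows
        expected = np.concatenate([m.values[p - 1], m.values[p], m.values[p + 1]])
        assert np.allclose(out.values[p], expected)


def test_window_even_size_rejected():
    with pytest.raises(ParameterError):
        sp.WindowParams(window_size=4)


def test_encoding_is_a_bijection_onto_1_20():
    codes = [sp.encode_amino_acid(a) for a in "ACDEFGHIKLMNPQRSTVWY"]
    assert sorted(codes) == list(range(1, 21))
    assert sp.encode_amino_acid("X") == 0
    with pytest.raises(InvalidCodeError):
        sp.encode_amino_acid("Z")


def test_encoding_class_blocks_follow_shipped_tables():
    """Residues of one class occupy a consecutive integer block, classes
    ordered by mean hydropathy (high to low), residues by abundance."""
    class_mean = {
        name: sum(KYTE_DOOLITTLE[a] for a in members) / len(members)
        for name, members in AA_CLASSES.items()
    }
    expected_order = sorted(AA_CLASSES, key=lambda n: -class_mean[n])
    k = 1
    for name in expected_order:
        members = sorted(AA_CLASSES[name], key=lambda a: ABUNDANCE[a])
        for aa in members:
            assert sp.encode_amino_acid(aa) == k
            k += 1


def test_merge_feature_arithmetic():
    sse = _matrix(np.zeros((6, 40)), "s", source="sse-pssm")
    aa = _matrix(np.zeros((6, 100)), "a", source="aa-pssm")
    typ = _matrix(np.zeros((6, 1)), "t", source="aa_type")
    merged = sp.merge_features([sse, aa, typ])
    assert merged.values.shape == (6, 141)
    assert merged.feature_names[0].startswith("sse-pssm:")
    assert merged.feature_names[-1] == "aa_type:t0"


def test_merge_single_source_is_identity():
    m = _matrix(np.arange(6).reshape(2, 3))
    merged = sp.merge_features([m])
    assert np.array_equal(merged.values, m.values)


def test_merge_rejects_row_mismatch():
    with pytest.raises(DataError):
        sp.merge_features([_matrix(np.zeros((3, 2))), _matrix(np.zeros((4, 2)))])


def test_window_and_merge_commute_up_to_column_order():
    rng = np.random.default_rng(1)
    a = _matrix(rng.normal(size=(5, 2)), "a", source="A")
    b = _matrix(rng.normal(size=(5, 3)), "b", source="B")
    w = sp.WindowParams(window_size=3)
    merged_then_windowed = sp.window_features(sp.merge_features([a, b]), w)
    windowed_then_merged = sp.merge_features(
        [sp.window_features(a, w), sp.window_features(b, w)]
    )
    # same multiset of named columns, values equal after aligning names
    assert sorted(windowed_then_merged.feature_names) == sorted(
        merged_then_windowed.feature_names
    )
    perm = [
        merged_then_windowed.feature_names.index(n)
        for n in windowed_then_merged.feature_names
    ]
    assert np.allclose(
        windowed_then_merged.values, merged_then_windowed.values[:, perm]
    )


def test_import_external_labels_one_hot():
    m = sp.import_external_prediction("HEC", sp.Q3)
    assert np.array_equal(m.values, np.eye(3))
    assert m.feature_names == ["p(H)", "p(E)", "p(C)"]


def test_import_external_probability_rows():
    rows = np.array([[0.5, 0.3, 0.2], [0.3334, 0.3333, 0.3333]])
    m = sp.import_external_prediction(rows, sp.Q3)
    assert np.allclose(m.values.sum(axis=1), 1.0)
    with pytest.raises(DataError, match="malformed"):
        sp.import_external_prediction(np.array([[0.5, 0.2, 0.2]]), sp.Q3)


def test_aa_type_features_column():
    m = aa_type_features("MKX")
    assert m.values.shape == (3, 1)
    assert m.values[2, 0] == 0.0
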