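"""Per-residue machine-learning features from profiles.

Three feature sources are supported and freely merged: the SSE-PSSM,
the classic amino-acid PSSM (both windowed over a centered sliding
window, default 5 residues), and a single-integer amino-acid-type
encoding.  Output probability tables of external predictors can also
be imported as features, so an existing predictor's output can be
combined with the SSE-PSSM through a second-level model.

Amino-acid-type encoding
------------------------
The 20 standard residues are mapped onto the integers 1..20 by
(1) grouping them into five side-chain classes (nonpolar aliphatic,
aromatic, polar uncharged, negatively charged, positively charged),
(2) ordering the classes by mean Kyte-Doolittle hydropathy, high to
low, and (3) ordering residues within a class by natural abundance,
low to high.  Physiochemically similar residues thus receive nearby
integers.  The unknown residue 'X' maps to the sentinel 0.  The class,
hydropathy and abundance tables ship as data below and the encoding is
recomputed from them at import, so the construction — not a frozen
table — is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabets import SSEAlphabet
from .errors import DataError, InvalidCodeError, ParameterError

#: Side-chain classes (conventional five-way scheme).
AA_CLASSES: dict[str, tuple[str, ...]] = {
    "nonpolar_aliphatic": ("G", "A", "P", "V", "L", "I", "M"),
    "aromatic": ("F", "Y", "W"),
    "polar_uncharged": ("S", "T", "C", "N", "Q"),
    "negatively_charged": ("D", "E"),
    "positively_charged": ("K", "R", "H"),
}

#: Kyte-Doolittle hydropathy index per residue.
KYTE_DOOLITTLE: dict[str, float] = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

#: Natural abundance (%) of residues in well-curated sequence databases.
ABUNDANCE: dict[str, float] = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38, "Q": 3.93,
    "E": 6.72, "G": 7.07, "H": 2.27, "I": 5.91, "L": 9.65, "K": 5.80,
    "M": 2.41, "F": 3.86, "P": 4.74, "S": 6.63, "T": 5.35, "W": 1.10,
    "Y": 2.92, "V": 6.86,
}


def _build_encoding() -> dict[str, int]:
    class_mean = {
        name: sum(KYTE_DOOLITTLE[a] for a in members) / len(members)
        for name, members in AA_CLASSES.items()
    }
    ordered_classes = sorted(AA_CLASSES, key=lambda n: -class_mean[n])
    encoding: dict[str, int] = {"X": 0}
    k = 1
    for name in ordered_classes:
        for aa in sorted(AA_CLASSES[name], key=lambda a: ABUNDANCE[a]):
            encoding[aa] = k
            k += 1
    return encoding


AA_ENCODING: dict[str, int] = _build_encoding()


def encode_amino_acid(aa: str) -> int:
    """Integer code of one residue letter; 'X' -> 0."""
    try:
        return AA_ENCODING[aa]
    except KeyError:
        raise InvalidCodeError(f"invalid residue {aa!r}") from None


@dataclass
class FeatureMatrix:
    """n_residues x n_features numeric matrix with unique column names."""

    values: np.ndarray
    feature_names: list[str]
    query_id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("feature values must be a 2-D matrix")
        if self.values.shape[1] != len(self.feature_names):
            raise DataError("feature_names length must match the column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataError("feature names must be unique")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WindowParams:
    """A centered window of ``window_size`` residues (odd), padded with
    ``pad_value`` outside the sequence.  Zero padding means "background"
    for log-odds features and the 'X' sentinel for the type encoding."""

    window_size: int = 5
    pad_value: float = 0.0

    def __post_init__(self) -> None:
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ParameterError("window_size must be an odd integer >= 1")


def window_features(matrix: FeatureMatrix, params: WindowParams) -> FeatureMatrix:
    """Concatenate each row with its k neighbours on both sides.

    Row p of the output is the concatenation of input rows
    p-k .. p+k (k = (window_size - 1) / 2), out-of-range rows replaced
    by ``pad_value``.  Column names carry the offset, e.g. ``H@-2``.
    """
    if matrix.n_residues == 0:
        raise DataError("empty feature matrix")
    k = (params.window_size - 1) // 2
    n, m = matrix.values.shape
    padded = np.full((n + 2 * k, m), params.pad_value, dtype=float)
    padded[k : k + n] = matrix.values
    blocks = [padded[i : i + n] for i in range(2 * k + 1)]
    names = [
        f"{name}@{off:+d}"
        for off in range(-k, k + 1)
        for name in matrix.feature_names
    ]
    return FeatureMatrix(
        values=np.hstack(blocks),
        feature_names=names,
        query_id=matrix.query_id,
        source=matrix.source,
    )


def profile_features(profile, matrix: str = "pssm") -> FeatureMatrix:
    """Per-position features straight from a profile's PSSM (or PPM)."""
    values = getattr(profile, matrix)
    if values is None:
        raise DataError(f"profile carries no {matrix} matrix")
    return FeatureMatrix(
        values=np.asarray(values, dtype=float),
        feature_names=list(profile.alphabet.codes),
        query_id=profile.query_id,
        source=f"{profile.alphabet.name}-{matrix}",
    )


def aa_type_features(sequence: str, query_id: str = "") -> FeatureMatrix:
    """The single-column amino-acid-type feature for a sequence."""
    values = np.array([[encode_amino_acid(a)] for a in sequence], dtype=float)
    return FeatureMatrix(values, ["aa_type"], query_id=query_id, source="aa_type")


def merge_features(sources: list[FeatureMatrix]) -> FeatureMatrix:
    """Column-wise concatenation; names are prefixed by their source label."""
    if not sources:
        raise DataError("no feature matrices to merge")
    n = sources[0].n_residues
    for s in sources[1:]:
        if s.n_residues != n:
            raise DataError(
                f"feature matrices disagree on residue count ({s.n_residues} vs {n})"
            )
    names = []
    for i, s in enumerate(sources):
        prefix = s.source or f"src{i}"
        names.extend(f"{prefix}:{name}" for name in s.feature_names)
    return FeatureMatrix(
        values=np.hstack([s.values for s in sources]),
        feature_names=names,
        query_id=sources[0].query_id,
        source="merged",
    )


def import_external_prediction(per_residue, alphabet: SSEAlphabet, query_id: str = "") -> FeatureMatrix:
    """Turn an external predictor's output into probability features.

    A string (or list) of predicted labels becomes one-hot rows (the
    predicted code gets probability 1, the rest 0).  Numeric rows of
    width |alphabet| are accepted as probabilities and renormalized
    when their sum is within 1e-3 of 1; anything further off is
    rejected as malformed.
    """
    names = [f"p({c})" for c in alphabet.codes]
    if isinstance(per_residue, str) or (
        len(per_residue) > 0 and isinstance(per_residue[0], str)
    ):
        rows = np.zeros((len(per_residue), len(alphabet)))
        for i, label in enumerate(per_residue):
            rows[i, alphabet.index(label)] = 1.0
        return FeatureMatrix(rows, names, query_id=query_id, source="external")
    rows = np.asarray(per_residue, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != len(alphabet):
        raise DataError(
            f"probability rows must have width {len(alphabet)} (alphabet {alphabet.name!r})"
        )
    sums = rows.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-3)[0]
    if bad.size:
        raise DataError(
            f"malformed probabilities: row {bad[0] + 1} sums to {sums[bad[0]]:.4f}"
        )
    return FeatureMatrix(rows / sums[:, None], names, query_id=query_id, source="external")


def write_features_tsv(matrix: FeatureMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("pos\t" + "\t".join(matrix.feature_names) + "\n")
        for p in range(matrix.n_residues):
            fh.write(str(p + 1) + "\t" + "\t".join(f"{v:.4f}" for v in matrix.values[p]) + "\n")


def read_features_tsv(path, query_id: str = "") -> FeatureMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "pos":
            raise DataError(f"{path}: bad feature header")
        names = header[1:]
        rows = []
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(names) + 1:
                raise DataError(f"{path}: ragged feature row")
            rows.append([float(v) for v in parts[1:]])
    values = np.asarray(rows) if rows else np.zeros((0, len(names)))
    return FeatureMatrix(values, names, query_id=query_id)
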