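"""Bootstrap-ensemble per-residue classifier.

A simplified version of a bagged classification system: each of
``n_members`` minor models is trained on a seeded bootstrap sample of
the residues and a seeded random subset of the features, and the
ensemble's class probabilities are the fractions of member votes each
code receives.  Members are decision trees, small multilayer
perceptrons, or an even mix (a tree collection of this kind is a
random forest).  Defaults are desk-scale (20 trees); a 50-tree +
50-network layout is reachable through :class:`EnsembleParams`.

Three- and eight-state predictions use separately trained models;
reducing an eight-state model's output to three states is supported
but is not a substitute for a native three-state model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .alphabets import SSEAlphabet
from .errors import DataError, DegenerateTrainingError, ParameterError
from .features import FeatureMatrix


@dataclass(frozen=True)
class EnsembleParams:
    """Hyperparameters of the bootstrap ensemble."""

    alphabet: SSEAlphabet
    n_members: int = 20
    member_kind: str = "tree"  # tree | mlp | mixed
    bootstrap_fraction: float = 0.8
    feature_fraction: float = 0.7
    seed: int = 0
    max_depth: int | None = None
    hidden_units: int = 16

    def __post_init__(self) -> None:
        if self.n_members < 1:
            raise ParameterError("n_members must be >= 1")
        if not 0 < self.bootstrap_fraction <= 1 or not 0 < self.feature_fraction <= 1:
            raise ParameterError("fractions must be in (0, 1]")
        if self.member_kind not in ("tree", "mlp", "mixed"):
            raise ParameterError("member_kind must be 'tree', 'mlp' or 'mixed'")


@dataclass
class EnsembleModel:
    """Fitted minor models plus their feature subsets and metadata."""

    params: EnsembleParams
    members: list = field(default_factory=list)
    feature_subsets: list[np.ndarray] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise DataError(f"{path} does not contain an EnsembleModel")
        return model


def _member_seed(master: int, index: int) -> int:
    # distinct, reproducible per-member streams below 2**31
    return (master * 69069 + index * 1013904223 + 12345) % (2**31 - 1)


def _make_member(kind: str, index: int, params: EnsembleParams, seed: int):
    if kind == "mixed":
        kind = "tree" if index % 2 == 0 else "mlp"
    if kind == "tree":
        return DecisionTreeClassifier(max_depth=params.max_depth, random_state=seed)
    return MLPClassifier(
        hidden_layer_sizes=(params.hidden_units,),
        max_iter=300,
        random_state=seed,
    )


def fit(features: FeatureMatrix, labels: str, params: EnsembleParams) -> EnsembleModel:
    """Train the ensemble on stacked per-residue features and SSE labels.

    Deterministic given ``params.seed``: member b draws its bootstrap
    rows and feature subset from a stream seeded by (seed, b).
    """
    x = features.values
    y = np.array(list(labels))
    if x.shape[0] != y.shape[0]:
        raise DataError(f"{x.shape[0]} feature rows but {y.shape[0]} labels")
    if x.shape[0] == 0:
        raise DataError("no training rows")
    params.alphabet.validate(labels, "training labels")
    if len(set(labels)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    n, m = x.shape
    n_rows = max(2, round(params.bootstrap_fraction * n))
    n_cols = max(1, round(params.feature_fraction * m))
    members = []
    subsets = []
    for b in range(params.n_members):
        rng = np.random.default_rng(_member_seed(params.seed, b))
        if params.bootstrap_fraction == 1.0:
            # degenerate limit: every row exactly once, no resampling
            rows = np.arange(n)
        else:
            # resample until the bootstrap carries >= 2 classes
            for _ in range(100):
                rows = rng.integers(0, n, size=n_rows)
                if len(set(y[rows])) >= 2:
                    break
            else:
                raise DegenerateTrainingError("could not draw a multi-class bootstrap sample")
        cols = np.sort(rng.choice(m, size=n_cols, replace=False))
        member = _make_member(params.member_kind, b, params, _member_seed(params.seed, b))
        member.fit(x[rows][:, cols], y[rows])
        members.append(member)
        subsets.append(cols)
    return EnsembleModel(
        params=params,
        members=members,
        feature_subsets=subsets,
        feature_names=list(features.feature_names),
    )


def predict_proba(model: EnsembleModel, features: FeatureMatrix) -> np.ndarray:
    """Vote-fraction probabilities, one row per residue, columns in
    alphabet order.  Every entry is a multiple of 1/n_members."""
    if list(features.feature_names) != model.feature_names:
        raise DataError("feature names do not match the training features")
    x = features.values
    alphabet = model.params.alphabet
    votes = np.zeros((x.shape[0], len(alphabet)))
    code_index = {c: i for i, c in enumerate(alphabet.codes)}
    if x.shape[0] == 0:
        return votes
    for member, cols in zip(model.members, model.feature_subsets):
        pred = member.predict(x[:, cols])
        for r, code in enumerate(pred):
            votes[r, code_index[code]] += 1
    return votes / len(model.members)


def predict_sse(model: EnsembleModel, features: FeatureMatrix) -> str:
    """Argmax of the vote fractions; ties break by alphabet order."""
    proba = predict_proba(model, features)
    if proba.shape[0] == 0:
        return ""
    codes = model.params.alphabet.codes
    return "".join(codes[i] for i in np.argmax(proba, axis=1))
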