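"""End-to-end workflows built from the module pieces.

Wires together homolog search, SSE assignment, profile construction,
feature engineering and the ensemble classifier, so that a complete
train-and-evaluate experiment on a synthetic benchmark is a couple of
calls.  Nothing here adds behaviour; it only composes the modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabets import AA20, SSEAlphabet
from .assignment import SSELibrary
from .errors import DataError
from .features import (
    FeatureMatrix,
    WindowParams,
    aa_type_features,
    merge_features,
    profile_features,
    window_features,
)
from .fixtures import Benchmark
from .metrics import EvaluationReport, evaluate_queries
from .predictor import EnsembleParams, fit, predict_sse
from .pssm import (
    BackgroundFrequencies,
    SSEProfile,
    SubstitutionMatrix,
    build_profile,
    compute_background,
)
from .search import SearchParams, search
from .seqio import SSERecord, SequenceRecord


def build_query_profile(
    query: SequenceRecord,
    targets: list[SequenceRecord],
    library: SSELibrary,
    background: BackgroundFrequencies,
    *,
    search_params: SearchParams | None = None,
    subst: SubstitutionMatrix | None = None,
    tau: float = 0.5,
    transform: bool = True,
) -> SSEProfile:
    """Search the query against the targets and build its profile.

    ``transform=True`` gives the SSE-PSSM over ``library.alphabet``;
    ``transform=False`` gives the classic AA-PSSM over the amino-acid
    alphabet (``background`` must then be over amino acids).
    """
    hits = search(query, targets, search_params)
    if transform:
        sse_by_id = {}
        for hit in hits:
            if hit.hit_id not in library:
                raise DataError(
                    f"hit {hit.hit_id!r} has no SSE annotation; synthesize one "
                    "with sse_pssm.assignment.get_sse first"
                )
            sse_by_id[hit.hit_id] = library[hit.hit_id]
        alphabet = library.alphabet
    else:
        sse_by_id = {}
        alphabet = AA20
    return build_profile(
        query,
        hits.hits,
        sse_by_id,
        alphabet,
        background,
        subst=subst,
        tau=tau,
        transform=transform,
    )


def featurize_profile(
    profile: SSEProfile,
    window: WindowParams | None = None,
    *,
    include_aa_type: bool = True,
) -> FeatureMatrix:
    """Windowed PSSM features, optionally merged with the aa-type column."""
    if window is None:
        window = WindowParams()
    feats = [window_features(profile_features(profile), window)]
    if include_aa_type:
        feats.append(aa_type_features(profile.query_seq, profile.query_id))
    return merge_features(feats) if len(feats) > 1 else feats[0]


def stack_features(matrices: list[FeatureMatrix]) -> FeatureMatrix:
    """Row-stack per-query feature matrices (identical columns required)."""
    if not matrices:
        raise DataError("nothing to stack")
    names = matrices[0].feature_names
    for m in matrices[1:]:
        if m.feature_names != names:
            raise DataError("feature matrices disagree on columns")
    return FeatureMatrix(
        values=np.vstack([m.values for m in matrices]),
        feature_names=list(names),
        query_id="stacked",
    )


@dataclass
class BenchmarkResult:
    """Outcome of one train/test experiment on a synthetic benchmark."""

    feature_kind: str
    report: EvaluationReport
    predictions: dict[str, str]

    @property
    def micro_q(self) -> float:
        return self.report.micro_q


def run_benchmark(
    bench: Benchmark,
    feature_kind: str = "sse",
    *,
    window: WindowParams | None = None,
    include_aa_type: bool = True,
    ensemble: EnsembleParams | None = None,
    search_params: SearchParams | None = None,
    subst: SubstitutionMatrix | None = None,
    tau: float = 0.5,
    seed: int = 0,
) -> BenchmarkResult:
    """Train on the benchmark's training queries, evaluate on its test set.

    ``feature_kind`` selects the profile: ``"sse"`` (SSE-PSSM) or
    ``"aa"`` (classic AA-PSSM); both run through the identical feature
    and classifier machinery so results are directly comparable.
    """
    if feature_kind not in ("sse", "aa"):
        raise DataError("feature_kind must be 'sse' or 'aa'")
    alphabet: SSEAlphabet = bench.params.alphabet
    targets = bench.target_records
    library = SSELibrary.from_records(bench.target_sse_records, alphabet)
    if feature_kind == "sse":
        background = compute_background(bench.target_sse_records, alphabet)
        transform = True
    else:
        aa_records = [SSERecord(t.id, t.sequence) for t in targets]
        background = compute_background(aa_records, AA20)
        transform = False

    def features_for(family) -> FeatureMatrix:
        profile = build_query_profile(
            family.query,
            targets,
            library,
            background,
            search_params=search_params,
            subst=subst,
            tau=tau,
            transform=transform,
        )
        return featurize_profile(profile, window, include_aa_type=include_aa_type)

    train_feats = [features_for(f) for f in bench.train]
    train_labels = "".join(f.query_sse.sse for f in bench.train)
    stacked = stack_features(train_feats)
    if ensemble is None:
        ensemble = EnsembleParams(alphabet=alphabet, seed=seed)
    model = fit(stacked, train_labels, ensemble)
    predictions = {}
    pairs = []
    for fam in bench.test:
        predicted = predict_sse(model, features_for(fam))
        predictions[fam.query.id] = predicted
        pairs.append((fam.query.id, fam.query_sse.sse, predicted))
    report = evaluate_queries(pairs, alphabet)
    return BenchmarkResult(feature_kind=feature_kind, report=report, predictions=predictions)
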