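"""Evaluation suite for secondary structure predictions.

Measures
--------
* Q accuracy: the fraction of residues whose state is predicted
  correctly (Q3 over three states, Q8 over eight), with two ways of
  averaging over a query set — the macro average (mean of per-query
  accuracies, weighting proteins equally) and the micro average
  (pooled correct residues over pooled residues, weighting residues
  equally).
* SOV, the segment overlap measure (1999 revision): per state, each
  reference segment is compared with the predicted segments it
  overlaps, scoring (minov + delta) / maxov weighted by the reference
  segment length, with the allowance
  delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2);
  reference segments with no overlapping partner contribute only to
  the normalization.  Rewards getting the segment pattern right over
  exact per-residue placement.
* Boundary vs internal accuracy: accuracy restricted to residues that
  are the first or last residue of a maximal same-code segment of the
  reference string, vs all other residues.
* Pairwise misclassification rates after reduction to three states:
  rate(X<->Y) counts residues confused between states X and Y in
  either direction, so the three rates plus Q3 sum to exactly 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabets import AlphabetReduction, SSEAlphabet, reduce_sse_string
from .errors import DataError, LengthMismatchError


def _check_pair(actual: str, predicted: str) -> None:
    if len(actual) != len(predicted):
        raise LengthMismatchError(
            f"actual/predicted lengths differ ({len(actual)} vs {len(predicted)})"
        )
    if not actual:
        raise DataError("empty strings")


def q_accuracy(actual: str, predicted: str) -> float:
    """Fraction of positions predicted correctly."""
    _check_pair(actual, predicted)
    return sum(a == p for a, p in zip(actual, predicted)) / len(actual)


def average_q(per_query: list[tuple[int, float]]) -> tuple[float, float]:
    """(macro, micro) averages from (n_residues, q_value) pairs.

    The macro average is the arithmetic mean of the per-query values;
    the micro average divides pooled correct-residue counts (each
    n * q rounded to the nearest integer) by pooled residues.
    """
    if not per_query:
        raise DataError("no queries to average")
    for n, _ in per_query:
        if n < 1:
            raise DataError("every query must have >= 1 residue")
    macro = sum(q for _, q in per_query) / len(per_query)
    correct = sum(round(n * q) for n, q in per_query)
    total = sum(n for n, _ in per_query)
    return macro, correct / total


def segments(s: str) -> list[tuple[str, int, int]]:
    """Maximal same-code runs as (code, start, end) with 0-based inclusive ends."""
    out = []
    start = 0
    for i in range(1, len(s) + 1):
        if i == len(s) or s[i] != s[start]:
            out.append((s[start], start, i - 1))
            start = i
    return out


def _sov_accumulate(actual: str, predicted: str) -> tuple[float, int]:
    """(numerator, normalization) of the 1999 segment overlap score."""
    by_state_pred: dict[str, list[tuple[int, int]]] = {}
    for code, a, b in segments(predicted):
        by_state_pred.setdefault(code, []).append((a, b))
    num = 0.0
    norm = 0
    for code, a1, b1 in segments(actual):
        len1 = b1 - a1 + 1
        overlaps = [
            (a2, b2)
            for a2, b2 in by_state_pred.get(code, [])
            if a2 <= b1 and b2 >= a1
        ]
        if not overlaps:
            norm += len1
            continue
        for a2, b2 in overlaps:
            len2 = b2 - a2 + 1
            minov = min(b1, b2) - max(a1, a2) + 1
            maxov = max(b1, b2) - min(a1, a2) + 1
            delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
            num += (minov + delta) / maxov * len1
            norm += len1
    return num, norm


def sov(actual: str, predicted: str, alphabet: SSEAlphabet | None = None) -> float:
    """Segment overlap score (1999 revision), all states pooled.

    The same code path serves SOV3 and SOV8; the optional alphabet is
    used only to validate the inputs.
    """
    _check_pair(actual, predicted)
    if alphabet is not None:
        alphabet.validate(actual, "actual")
        alphabet.validate(predicted, "predicted")
    num, norm = _sov_accumulate(actual, predicted)
    return num / norm if norm else float("nan")


def boundary_internal_q(actual: str, predicted: str) -> tuple[float, float]:
    """(boundary accuracy, internal accuracy), partitioned on the actual string.

    A residue is a boundary residue iff it is the first or last residue
    of a maximal same-code segment of the actual string.  An empty
    partition yields NaN for that fraction.
    """
    _check_pair(actual, predicted)
    boundary = set()
    for _, a, b in segments(actual):
        boundary.add(a)
        boundary.add(b)
    b_total = b_ok = i_total = i_ok = 0
    for p, (a, pr) in enumerate(zip(actual, predicted)):
        if p in boundary:
            b_total += 1
            b_ok += a == pr
        else:
            i_total += 1
            i_ok += a == pr
    return (
        b_ok / b_total if b_total else math.nan,
        i_ok / i_total if i_total else math.nan,
    )


def misclassification_rates(
    actual: str, predicted: str, reduction: AlphabetReduction | None = None
) -> dict[str, float]:
    """Pairwise 3-state confusion rates {"H<->E", "H<->C", "E<->C"}.

    Inputs already over three states need no reduction.  The three
    rates plus the 3-state Q accuracy sum to exactly 1.
    """
    _check_pair(actual, predicted)
    if reduction is not None:
        actual = reduce_sse_string(actual, reduction)
        predicted = reduce_sse_string(predicted, reduction)
    n = len(actual)
    rates = {"H<->E": 0, "H<->C": 0, "E<->C": 0}
    for a, p in zip(actual, predicted):
        if a == p:
            continue
        key = "<->".join(sorted((a, p), key="HEC".index))
        rates[key] += 1
    return {k: v / n for k, v in rates.items()}


def confusion_matrix(actual: str, predicted: str, alphabet: SSEAlphabet) -> np.ndarray:
    """Counts indexed [actual, predicted] in alphabet order."""
    _check_pair(actual, predicted)
    m = np.zeros((len(alphabet), len(alphabet)), dtype=int)
    for a, p in zip(actual, predicted):
        m[alphabet.index(a), alphabet.index(p)] += 1
    return m


@dataclass
class QueryEvaluation:
    """All per-query measures for one actual/predicted pair."""

    query_id: str
    n_residues: int
    n_correct: int
    q_value: float
    sov_value: float
    boundary_q: float
    internal_q: float
    confusion: np.ndarray
    sov_numerator: float = 0.0
    sov_normalization: int = 0


@dataclass
class EvaluationReport:
    """Per-query evaluations plus pooled summary values.

    Pooled SOV and boundary/internal accuracies aggregate numerators
    and normalizations over queries (residue-weighted), matching the
    micro-average philosophy; macro_q / micro_q are the two Q averages.
    """

    queries: list[QueryEvaluation]
    macro_q: float
    micro_q: float
    pooled_sov: float
    pooled_boundary_q: float
    pooled_internal_q: float
    misclassification: dict[str, float] = field(default_factory=dict)


def evaluate_queries(
    pairs: list[tuple[str, str, str]],
    alphabet: SSEAlphabet,
    reduction_for_rates: AlphabetReduction | None = None,
) -> EvaluationReport:
    """Evaluate (query_id, actual, predicted) triples and pool the results.

    ``reduction_for_rates`` maps onto three states before computing the
    pairwise misclassification rates; pass None for inputs already over
    {H, E, C}.
    """
    if not pairs:
        raise DataError("no query pairs to evaluate")
    if reduction_for_rates is None and alphabet.name == "dssp8":
        from .alphabets import DSSP8_TO_Q3

        reduction_for_rates = DSSP8_TO_Q3
    evals = []
    sov_num = 0.0
    sov_norm = 0
    b_ok = b_tot = i_ok = i_tot = 0
    mis_counts = {"H<->E": 0.0, "H<->C": 0.0, "E<->C": 0.0}
    total = 0
    for qid, actual, predicted in pairs:
        _check_pair(actual, predicted)
        n = len(actual)
        correct = sum(a == p for a, p in zip(actual, predicted))
        num, norm = _sov_accumulate(actual, predicted)
        boundary = set()
        for _, a, b in segments(actual):
            boundary.update((a, b))
        qb_ok = sum(actual[p] == predicted[p] for p in boundary)
        qi_tot = n - len(boundary)
        qi_ok = correct - qb_ok
        rates = misclassification_rates(actual, predicted, reduction_for_rates)
        for k, v in rates.items():
            mis_counts[k] += v * n
        evals.append(
            QueryEvaluation(
                query_id=qid,
                n_residues=n,
                n_correct=correct,
                q_value=correct / n,
                sov_value=num / norm if norm else math.nan,
                boundary_q=qb_ok / len(boundary) if boundary else math.nan,
                internal_q=qi_ok / qi_tot if qi_tot else math.nan,
                confusion=confusion_matrix(actual, predicted, alphabet),
                sov_numerator=num,
                sov_normalization=norm,
            )
        )
        sov_num += num
        sov_norm += norm
        b_ok += qb_ok
        b_tot += len(boundary)
        i_ok += qi_ok
        i_tot += qi_tot
        total += n
    return EvaluationReport(
        queries=evals,
        macro_q=sum(e.q_value for e in evals) / len(evals),
        micro_q=sum(e.n_correct for e in evals) / total,
        pooled_sov=sov_num / sov_norm if sov_norm else math.nan,
        pooled_boundary_q=b_ok / b_tot if b_tot else math.nan,
        pooled_internal_q=i_ok / i_tot if i_tot else math.nan,
        misclassification={k: v / total for k, v in mis_counts.items()},
    )
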