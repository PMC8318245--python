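"""SSE strings for hits: direct lookup or representative-by-vote synthesis.

When a hit's structure annotation exists in the library its SSE string
is returned verbatim.  Otherwise the hit sequence is searched (a
second round) against a reference set of annotated structures; for each
residue of the hit, the SSE codes of all reference residues aligned
with it are collected and the representative code is chosen by
weighted vote, weights being the second-round alignment identities
(the same weight the profile stage uses, keeping both rounds
consistent).  Ties are broken by a configured code order — by default
the codes sorted by descending background frequency in the reference
library (prefer the a-priori likelier conformation), then
alphabetically.  Residues covered by no homolog receive the
"uncovered" code, by default coil.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .alphabets import GAP, SSEAlphabet
from .errors import DataError, MissingAnnotationError, ParameterError
from .search import SearchParams, hit_weight, search
from .seqio import SSERecord, SequenceRecord


@dataclass
class SSELibrary:
    """Known SSE annotations: protein id -> SSE string, over one alphabet."""

    records: dict[str, str]
    alphabet: SSEAlphabet

    def __post_init__(self) -> None:
        for pid, sse in self.records.items():
            self.alphabet.validate(sse, where=f"library record {pid!r}")

    @classmethod
    def from_records(cls, records: list[SSERecord], alphabet: SSEAlphabet) -> "SSELibrary":
        return cls({r.id: r.sse for r in records}, alphabet)

    def __contains__(self, pid: str) -> bool:
        return pid in self.records

    def __getitem__(self, pid: str) -> str:
        return self.records[pid]


def default_tie_break_order(library: SSELibrary) -> tuple[str, ...]:
    """Codes by descending frequency in the library, ties alphabetical."""
    counts = Counter()
    for sse in library.records.values():
        counts.update(sse)
    return tuple(sorted(library.alphabet.codes, key=lambda c: (-counts[c], c)))


@dataclass
class VoteParams:
    """Controls for representative-by-vote SSE synthesis."""

    tie_break_order: tuple[str, ...]
    uncovered_code: str = "C"
    search_params: SearchParams = field(default_factory=SearchParams)
    weighted: bool = True

    def validate(self, alphabet: SSEAlphabet) -> None:
        if sorted(self.tie_break_order) != sorted(alphabet.codes):
            raise ParameterError("tie_break_order must be a permutation of the alphabet")
        if self.uncovered_code not in alphabet:
            raise ParameterError("uncovered_code must belong to the alphabet")

    @classmethod
    def for_library(cls, library: SSELibrary, **kwargs) -> "VoteParams":
        return cls(tie_break_order=default_tie_break_order(library), **kwargs)


def vote_column(codes: list[str], weights: list[float], params: VoteParams) -> str:
    """Weighted-argmax over a column of SSE codes; empty -> uncovered code."""
    if len(codes) != len(weights):
        raise DataError("codes and weights differ in length")
    if any(w < 0 for w in weights):
        raise ParameterError("vote weights must be >= 0")
    if not codes:
        return params.uncovered_code
    totals: dict[str, float] = {}
    for c, w in zip(codes, weights):
        totals[c] = totals.get(c, 0.0) + (w if params.weighted else 1.0)
    rank = {c: i for i, c in enumerate(params.tie_break_order)}
    return max(totals, key=lambda c: (totals[c], -rank[c]))


def get_sse(
    hit_id: str,
    hit_sequence: str,
    library: SSELibrary,
    reference_targets: list[SequenceRecord],
    params: VoteParams,
) -> str:
    """SSE string of a hit: library lookup, else position-specific voting.

    All ``reference_targets`` must carry annotations in ``library``.
    The output always has the length of ``hit_sequence``.
    """
    if not hit_sequence:
        raise DataError("empty hit sequence")
    params.validate(library.alphabet)
    if hit_id in library:
        sse = library[hit_id]
        if len(sse) != len(hit_sequence):
            raise DataError(
                f"library SSE for {hit_id!r} has length {len(sse)}, "
                f"sequence has {len(hit_sequence)}"
            )
        return sse
    for ref in reference_targets:
        if ref.id not in library:
            raise MissingAnnotationError(
                f"reference target {ref.id!r} has no SSE annotation in the library"
            )
    hit_record = SequenceRecord(hit_id, hit_sequence)
    homologs = search(hit_record, reference_targets, params.search_params)
    n = len(hit_sequence)
    col_codes: list[list[str]] = [[] for _ in range(n)]
    col_weights: list[list[float]] = [[] for _ in range(n)]
    for hom in homologs:
        ref_sse = library[hom.hit_id]
        w = hit_weight(hom)
        p = hom.query_start or 0
        k = hom.hit_start or 0
        for qc, hc in zip(hom.query_aligned, hom.hit_aligned):
            if qc != GAP and hc != GAP:
                col_codes[p].append(ref_sse[k])
                col_weights[p].append(w)
            if qc != GAP:
                p += 1
            if hc != GAP:
                k += 1
    return "".join(
        vote_column(col_codes[p], col_weights[p], params) for p in range(n)
    )
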