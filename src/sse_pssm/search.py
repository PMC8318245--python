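"""Local sequence similarity search: retrieve a hit list for a query.

A self-contained affine-gap local aligner (Smith-Waterman scoring via
Biopython's :class:`Bio.Align.PairwiseAligner`) plays the role an
external search tool (PSI-BLAST, HHBlits) plays in a production
pipeline: given a query and a target set it returns the best local
alignment against each target, filtered and sorted into a hit list.
Precomputed alignments in the package's TSV dialect bypass this module
entirely, so real search-tool output converted upstream can be injected.

The per-hit weight used by profile construction is the alignment
identity fraction — the simplest reading of "sequence similarity"
between query and hit, and the quantity dataset non-redundancy
thresholds are phrased in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align

from .alphabets import GAP
from .errors import DataError, ParameterError
from .seqio import HitAlignment, SequenceRecord


@dataclass(frozen=True)
class SearchParams:
    """Scoring and filtering parameters for the local aligner.

    A gap of length k scores ``gap_open + k * gap_extend`` (both are
    ≤ 0).  Defaults mimic BLAST-like behaviour at toy scale.
    """

    match_score: float = 2.0
    mismatch_score: float = -1.0
    gap_open: float = -11.0
    gap_extend: float = -1.0
    min_identity: float = 0.0
    min_aligned_length: int = 10
    max_hits: int = 500

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ParameterError("min_identity must be in [0, 1]")
        if self.max_hits < 1:
            raise ParameterError("max_hits must be >= 1")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ParameterError("gap penalties must be <= 0")


@dataclass
class HitList:
    """Hits for one query, sorted by score descending then hit id ascending."""

    query_id: str
    hits: list[HitAlignment] = field(default_factory=list)

    def __iter__(self):
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)


def _make_aligner(params: SearchParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = params.match_score
    aligner.mismatch_score = params.mismatch_score
    # Biopython charges open_gap_score for the first gap column and
    # extend_gap_score for each further one; our convention charges
    # gap_open once plus gap_extend per column.
    aligner.open_gap_score = params.gap_open + params.gap_extend
    aligner.extend_gap_score = params.gap_extend
    return aligner


def alignment_identity(query_aligned: str, hit_aligned: str) -> float:
    """Matched columns over non-gap aligned columns."""
    matched = 0
    columns = 0
    for a, b in zip(query_aligned, hit_aligned):
        if a == GAP or b == GAP:
            continue
        columns += 1
        if a == b:
            matched += 1
    return matched / columns if columns else 0.0


def score_alignment(query_aligned: str, hit_aligned: str, params: SearchParams) -> float:
    """Recompute the affine-gap score of a gapped alignment pair."""
    score = 0.0
    in_gap = False
    for a, b in zip(query_aligned, hit_aligned):
        if a == GAP or b == GAP:
            if not in_gap:
                score += params.gap_open
                in_gap = True
            score += params.gap_extend
        else:
            in_gap = False
            score += params.match_score if a == b else params.mismatch_score
    return score


def align_pair(
    query: SequenceRecord, target: SequenceRecord, params: SearchParams
) -> HitAlignment | None:
    """Best local alignment of query vs target, or None if none scores > 0."""
    aligner = _make_aligner(params)
    alignments = aligner.align(query.sequence, target.sequence)
    try:
        if len(alignments) == 0:
            return None
    except OverflowError:
        pass  # astronomically many co-optimal alignments; take the first
    aln = alignments[0]
    if aln.score <= 0:
        return None
    query_aligned = str(aln[0])
    hit_aligned = str(aln[1])
    return HitAlignment(
        query_id=query.id,
        hit_id=target.id,
        query_aligned=query_aligned,
        hit_aligned=hit_aligned,
        identity=alignment_identity(query_aligned, hit_aligned),
        score=float(aln.score),
        query_start=int(aln.coordinates[0][0]),
        hit_start=int(aln.coordinates[1][0]),
    )


def search(
    query: SequenceRecord, targets: list[SequenceRecord], params: SearchParams | None = None
) -> HitList:
    """Align the query against every target and return the filtered hit list.

    Deterministic: no randomness, and the result is invariant to the
    order of ``targets`` up to the documented tie-break (score
    descending, then hit id ascending).
    """
    if params is None:
        params = SearchParams()
    if not targets:
        raise DataError("empty target set")
    if not query.sequence:
        raise DataError("empty query sequence")
    hits = []
    for target in targets:
        hit = align_pair(query, target, params)
        if hit is None:
            continue
        if hit.identity < params.min_identity:
            continue
        if len(hit.query_aligned) < params.min_aligned_length:
            continue
        hits.append(hit)
    hits.sort(key=lambda h: (-h.score, h.hit_id))
    return HitList(query_id=query.id, hits=hits[: params.max_hits])


def hit_weight(hit: HitAlignment) -> float:
    """Profile weight W(h) of a hit: its alignment identity fraction."""
    return hit.identity
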