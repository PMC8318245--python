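"""Profile construction: the SSE-PSSM and its amino-acid analogue.

Given a query and the pairwise alignments of its hits, each hit's
amino-acid string is replaced, residue by residue and preserving gaps,
with that hit's secondary-structure codes ("SSE transformation").  From
the transformed alignments, per-position weighted code occurrences are
accumulated,

    Occ(c, p) = sum over hits h of  1[Code(h, p) = c] * W(h),

with W(h) the hit's alignment identity.  Normalizing each position
gives a position propensity matrix (PPM); log-odds against background
code frequencies give the position-specific scoring matrix,

    PSSM(s, p) = log2( PPM(s, p) / B(s) ).

Running the identical machinery over the 20-letter amino-acid alphabet
(hit strings left untransformed) yields the classic AA-PSSM, so both
feature sets share one code path.

Sparse or empty columns are smoothed with a substitution-matrix-driven
pseudocount mixture (parameter ``tau``); columns with no aligned hit
residue at all fall back to the background distribution, because the
query's own structure is unknown and cannot seed a substitution-row
prior.  A BLOSUM-style constructor estimates the required SSE
substitution matrix from any corpus of aligned SSE string pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabets import GAP, SSEAlphabet
from .errors import DataError, LengthMismatchError, ParameterError
from .search import hit_weight
from .seqio import HitAlignment, SSERecord, SequenceRecord

#: Log-odds score assigned to zero-probability cells (tau = 0) so that
#: matrices stay finite and serializable.
SCORE_FLOOR = -10.0


@dataclass
class TransformedAlignment:
    """One hit alignment with the hit side rewritten in SSE codes."""

    query_aligned: str
    hit_sse_aligned: str
    weight: float
    hit_id: str = ""
    query_start: int = 0

    def __post_init__(self) -> None:
        if len(self.query_aligned) != len(self.hit_sse_aligned):
            raise LengthMismatchError(
                f"transformed alignment {self.hit_id!r}: strings differ in length"
            )


@dataclass
class OccurrenceMatrix:
    """Weighted code occurrences, one row per query residue."""

    values: np.ndarray  # (n_residues, n_codes), all >= 0
    alphabet: SSEAlphabet
    query_id: str = ""


@dataclass(frozen=True)
class BackgroundFrequencies:
    """Corpus-wide code frequencies B(s); all strictly positive, sum 1."""

    freq: dict[str, float]
    source: str = ""

    def vector(self, alphabet: SSEAlphabet) -> np.ndarray:
        try:
            return np.array([self.freq[c] for c in alphabet.codes])
        except KeyError as exc:
            raise ParameterError(f"background lacks code {exc}") from None


@dataclass
class SSEProfile:
    """Occurrence / PPM / PSSM matrices for one query.

    ``pseudocount_positions`` records the 0-based positions where no
    hit residue aligned and the background fallback was applied.
    Profiles read back from a PSSM TSV carry only ``pssm``.
    """

    query_id: str
    query_seq: str
    alphabet: SSEAlphabet
    occ: OccurrenceMatrix | None
    ppm: np.ndarray | None
    pssm: np.ndarray
    background: BackgroundFrequencies | None
    pseudocount_positions: frozenset[int] = field(default_factory=frozenset)


@dataclass
class SubstitutionMatrix:
    """Symmetric log-odds matrix (bits) over an SSE alphabet."""

    alphabet: SSEAlphabet
    scores: np.ndarray
    background: BackgroundFrequencies

    def conditional_probabilities(self) -> np.ndarray:
        """T[a, b] = P(code a | code b), derived from scores and background.

        Inverts the log-odds construction: expected pair frequencies
        e(a,b) times 2**score recover target pair frequencies, halved
        off-diagonal to give a symmetric joint, then each column is
        normalized.
        """
        p = self.background.vector(self.alphabet)
        e = 2.0 * np.outer(p, p)
        np.fill_diagonal(e, p**2)
        q = e * np.power(2.0, self.scores)
        # off-diagonal q counts both orders; split evenly for the joint
        joint = np.where(np.eye(len(p), dtype=bool), q, q / 2.0)
        col = joint.sum(axis=0)
        if np.any(col <= 0):
            raise ParameterError("substitution matrix yields a zero marginal")
        return joint / col


def transform_alignment(
    query_aligned: str,
    hit_aligned: str,
    hit_sse_unaligned: str,
    weight: float,
    *,
    hit_id: str = "",
    hit_sequence: str | None = None,
    hit_start: int | None = None,
    query_start: int = 0,
) -> TransformedAlignment:
    """Thread a hit's SSE codes into the gap structure of its alignment.

    ``hit_sse_unaligned`` is the hit's full (ungapped) SSE string; the
    de-gapped ``hit_aligned`` must be a contiguous region of the hit
    sequence starting at ``hit_start`` (located with ``str.find`` on
    ``hit_sequence`` when not given; 0 when neither is given).
    """
    if len(query_aligned) != len(hit_aligned):
        raise LengthMismatchError("aligned strings differ in length")
    degapped = hit_aligned.replace(GAP, "")
    if hit_sequence is not None and len(hit_sequence) != len(hit_sse_unaligned):
        raise LengthMismatchError(
            f"hit {hit_id!r}: SSE string length {len(hit_sse_unaligned)} != "
            f"sequence length {len(hit_sequence)}"
        )
    if hit_start is None:
        hit_start = hit_sequence.find(degapped) if hit_sequence is not None else 0
        if hit_start < 0:
            raise DataError(f"hit {hit_id!r}: aligned region not found in hit sequence")
    if hit_start + len(degapped) > len(hit_sse_unaligned):
        raise LengthMismatchError(
            f"hit {hit_id!r}: SSE string too short for the aligned region"
        )
    out = []
    k = hit_start
    for ch in hit_aligned:
        if ch == GAP:
            out.append(GAP)
        else:
            out.append(hit_sse_unaligned[k])
            k += 1
    return TransformedAlignment(
        query_aligned=query_aligned,
        hit_sse_aligned="".join(out),
        weight=weight,
        hit_id=hit_id,
        query_start=query_start,
    )


def transform_hits(
    query: SequenceRecord,
    hits: list[HitAlignment],
    sse_by_id: dict[str, str],
    *,
    transform: bool = True,
) -> list[TransformedAlignment]:
    """SSE-transform a hit list using each hit's full SSE string.

    With ``transform=False`` the hit amino-acid strings are kept as-is
    (the AA-PSSM code path); ``sse_by_id`` is then unused.
    """
    out = []
    for hit in hits:
        qstart = hit.query_start
        if qstart is None:
            qstart = query.sequence.find(hit.query_aligned.replace(GAP, ""))
            if qstart < 0:
                raise DataError(
                    f"hit {hit.hit_id!r}: aligned query region not found in query"
                )
        if transform:
            try:
                sse = sse_by_id[hit.hit_id]
            except KeyError:
                raise DataError(f"no SSE string for hit {hit.hit_id!r}") from None
            out.append(
                transform_alignment(
                    hit.query_aligned,
                    hit.hit_aligned,
                    sse,
                    hit_weight(hit),
                    hit_id=hit.hit_id,
                    hit_start=hit.hit_start,
                    query_start=qstart,
                )
            )
        else:
            out.append(
                TransformedAlignment(
                    query_aligned=hit.query_aligned,
                    hit_sse_aligned=hit.hit_aligned,
                    weight=hit_weight(hit),
                    hit_id=hit.hit_id,
                    query_start=qstart,
                )
            )
    return out


def compute_occurrences(
    query: SequenceRecord,
    transformed: list[TransformedAlignment],
    alphabet: SSEAlphabet,
) -> OccurrenceMatrix:
    """Accumulate Occ(c, p): weighted counts of each code aligned at each
    query position.  Gap on either side of a column contributes nothing."""
    n = len(query.sequence)
    values = np.zeros((n, len(alphabet)))
    index = {c: i for i, c in enumerate(alphabet.codes)}
    for t in transformed:
        p = t.query_start
        for qc, sc in zip(t.query_aligned, t.hit_sse_aligned):
            if qc == GAP:
                continue
            if p >= n:
                raise DataError(
                    f"hit {t.hit_id!r}: alignment extends past query length {n}"
                )
            if sc != GAP:
                try:
                    values[p, index[sc]] += t.weight
                except KeyError:
                    raise DataError(
                        f"hit {t.hit_id!r}: code {sc!r} not in alphabet {alphabet.name!r}"
                    ) from None
            p += 1
    return OccurrenceMatrix(values=values, alphabet=alphabet, query_id=query.id)


def apply_pseudocounts(
    occ_column: np.ndarray,
    background: BackgroundFrequencies,
    subst: SubstitutionMatrix | None,
    tau: float,
    alphabet: SSEAlphabet,
) -> np.ndarray:
    """Smooth one occurrence column into a frequency column.

    f'(c) = (N f(c) + tau g(c)) / (N + tau) with N the column's total
    weighted count, f the observed frequencies and g the
    substitution-matrix prior g(c) = sum over c' of f(c') T(c | c').
    When N = 0 the observed frequencies carry no information and f' is
    the background distribution.  Output sums to 1 and is strictly
    positive whenever tau > 0 (or N = 0, since backgrounds are
    strictly positive).
    """
    if tau < 0:
        raise ParameterError("tau must be >= 0")
    occ_column = np.asarray(occ_column, dtype=float)
    total = occ_column.sum()
    if total <= 0:
        return background.vector(alphabet).copy()
    f = occ_column / total
    if tau == 0:
        return f
    if subst is None:
        g = background.vector(alphabet)
    else:
        g = subst.conditional_probabilities() @ f
        g = g / g.sum()
    out = (total * f + tau * g) / (total + tau)
    return out / out.sum()


def ppm_from_occurrences(
    occ: OccurrenceMatrix,
    background: BackgroundFrequencies | None = None,
    subst: SubstitutionMatrix | None = None,
    tau: float = 0.0,
) -> tuple[np.ndarray, frozenset[int]]:
    """Normalize occurrences into a PPM, column fallback where empty.

    Returns the PPM plus the set of 0-based positions where no hit
    residue aligned (filled with background; requires ``background``
    when such positions exist).
    """
    n, _ = occ.values.shape
    ppm = np.zeros_like(occ.values)
    fallback: set[int] = set()
    for p in range(n):
        total = occ.values[p].sum()
        if total <= 0:
            fallback.add(p)
            if background is None:
                raise ParameterError(
                    f"position {p + 1} has no aligned residues and no background was given"
                )
        if tau > 0 or total <= 0:
            ppm[p] = apply_pseudocounts(occ.values[p], background, subst, tau, occ.alphabet)
        else:
            ppm[p] = occ.values[p] / total
    return ppm, frozenset(fallback)


def pssm_from_ppm(ppm: np.ndarray, background: BackgroundFrequencies, alphabet: SSEAlphabet) -> np.ndarray:
    """Elementwise log2(PPM / B); zero cells map to the documented floor."""
    b = background.vector(alphabet)
    if np.any(b <= 0):
        raise ParameterError("background frequencies must be strictly positive")
    with np.errstate(divide="ignore"):
        pssm = np.log2(np.asarray(ppm, dtype=float) / b)
    pssm[np.isneginf(pssm)] = SCORE_FLOOR
    return pssm


def build_profile(
    query: SequenceRecord,
    hits: list[HitAlignment],
    sse_by_id: dict[str, str],
    alphabet: SSEAlphabet,
    background: BackgroundFrequencies,
    subst: SubstitutionMatrix | None = None,
    tau: float = 0.5,
    *,
    transform: bool = True,
) -> SSEProfile:
    """Compose transform -> occurrences -> pseudocounted PPM -> PSSM.

    With ``transform=False`` and an amino-acid alphabet this builds the
    classic AA-PSSM from the same alignments.  The result is invariant
    to the order of ``hits``.
    """
    transformed = transform_hits(query, hits, sse_by_id, transform=transform)
    occ = compute_occurrences(query, transformed, alphabet)
    ppm, fallback = ppm_from_occurrences(occ, background, subst, tau)
    pssm = pssm_from_ppm(ppm, background, alphabet)
    return SSEProfile(
        query_id=query.id,
        query_seq=query.sequence,
        alphabet=alphabet,
        occ=occ,
        ppm=ppm,
        pssm=pssm,
        background=background,
        pseudocount_positions=fallback,
    )


def compute_background(
    records: list[SSERecord] | dict[str, str], alphabet: SSEAlphabet, source: str = ""
) -> BackgroundFrequencies:
    """Pool code counts over a reference library; add-one smooth only when
    some code never occurs, so every frequency is strictly positive."""
    strings = records.values() if isinstance(records, dict) else [r.sse for r in records]
    strings = list(strings)
    if not strings:
        raise DataError("empty SSE library")
    counts = np.zeros(len(alphabet))
    index = {c: i for i, c in enumerate(alphabet.codes)}
    for s in strings:
        for ch in s:
            if ch == GAP:
                continue
            try:
                counts[index[ch]] += 1
            except KeyError:
                raise DataError(f"code {ch!r} not in alphabet {alphabet.name!r}") from None
    if counts.sum() == 0:
        raise DataError("SSE library contains no residues")
    if np.any(counts == 0):
        counts = counts + 1.0
    freq = counts / counts.sum()
    return BackgroundFrequencies(
        freq={c: float(freq[i]) for i, c in enumerate(alphabet.codes)},
        source=source or f"{len(strings)} library strings",
    )


def build_substitution_matrix(
    aligned_pairs: list[tuple[str, str]],
    alphabet: SSEAlphabet,
    floor: float = SCORE_FLOOR,
) -> SubstitutionMatrix:
    """BLOSUM-style log-odds matrix from aligned SSE string pairs.

    Columns containing a gap on either side are skipped.  Observed
    unordered-pair frequencies q(a,b) (both orders pooled) are compared
    with the expectation e(a,a) = p(a)^2, e(a,b) = 2 p(a) p(b) for
    a != b, where p are the marginals; score(a,b) = log2(q/e), with
    never-observed pairs floored.  Symmetric by construction.
    """
    n = len(alphabet)
    index = {c: i for i, c in enumerate(alphabet.codes)}
    pair_counts = np.zeros((n, n))
    for s1, s2 in aligned_pairs:
        if len(s1) != len(s2):
            raise LengthMismatchError("aligned pair strings differ in length")
        for a, b in zip(s1, s2):
            if a == GAP or b == GAP:
                continue
            try:
                i, j = index[a], index[b]
            except KeyError as exc:
                raise DataError(f"code {exc} not in alphabet {alphabet.name!r}") from None
            if i <= j:
                pair_counts[i, j] += 1
            else:
                pair_counts[j, i] += 1
    total = pair_counts.sum()
    if total == 0:
        raise DataError("no usable (gap-free) aligned columns")
    q = (pair_counts + pair_counts.T - np.diag(np.diag(pair_counts))) / total
    marginals = np.diag(q) + (q.sum(axis=1) - np.diag(q)) / 2.0
    expected = 2.0 * np.outer(marginals, marginals)
    np.fill_diagonal(expected, marginals**2)
    scores = np.full((n, n), float(floor))
    mask = (q > 0) & (expected > 0)
    scores[mask] = np.log2(q[mask] / expected[mask])
    # a code absent from the corpus leaves marginal 0; smooth for background
    if np.any(marginals == 0):
        marginals = marginals + 1.0 / total
        marginals = marginals / marginals.sum()
    bg = BackgroundFrequencies(
        freq={c: float(marginals[i]) for i, c in enumerate(alphabet.codes)},
        source=f"marginals of {len(aligned_pairs)} aligned pairs",
    )
    return SubstitutionMatrix(alphabet=alphabet, scores=scores, background=bg)
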