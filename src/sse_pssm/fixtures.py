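"""Seeded synthetic protein families with known secondary structure.

The generator emulates the structural premise the SSE-PSSM method
rests on: homologous proteins conserve their secondary structure far
better than their sequence.  A query protein is built by sampling a
segment grammar (helix / strand / coil runs with class-specific length
ranges) and then drawing amino acids from per-class emission tables
that carry only a *mild* sequence signal (e.g. A/L/E enriched in
helices, V/I/Y in strands).  Each homolog is a mutated copy: random
substitutions bring it down to a requested sequence identity while the
SSE string is preserved except for segment-end jitter (boundaries
shifted by up to two residues), mimicking how real homolog structures
drift at segment termini but keep the segment architecture.

Everything is deterministic given the seed.  What this emulates — and
what it does not (real PDB statistics, chain breaks, indels, domain
architecture) — is discussed in the package's methods notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .alphabets import AMINO_ACIDS, Q3, SSEAlphabet
from .errors import GenerationError, ParameterError
from .seqio import HitAlignment, SSERecord, SequenceRecord

#: Default segment-type grammar: "start" gives initial segment-class
#: weights, the other entries give transition weights between classes.
DEFAULT_GRAMMAR: dict[str, dict[str, float]] = {
    "start": {"C": 0.6, "H": 0.25, "E": 0.15},
    "H": {"C": 0.8, "E": 0.2},
    "E": {"C": 0.8, "H": 0.2},
    "C": {"H": 0.5, "E": 0.5},
}

DEFAULT_SEGMENT_LENGTHS: dict[str, tuple[int, int]] = {
    "H": (4, 12),
    "E": (3, 8),
    "C": (2, 6),
}

#: Residues mildly enriched per structural class; the factor keeps the
#: sequence signal weak so that profiles, not raw residues, carry the
#: structural information.
_ENRICHED = {"H": "ALMEQK", "E": "VIYFWT", "C": "GPSND"}
_ENRICHMENT_FACTOR = 4.0


def default_emission_tables() -> dict[str, np.ndarray]:
    tables = {}
    for code, enriched in _ENRICHED.items():
        w = np.ones(len(AMINO_ACIDS))
        for aa in enriched:
            w[AMINO_ACIDS.index(aa)] *= _ENRICHMENT_FACTOR
        tables[code] = w / w.sum()
    return tables


@dataclass(frozen=True)
class FamilyParams:
    """Generation settings for synthetic protein families."""

    alphabet: SSEAlphabet = Q3
    n_queries: int = 1
    n_targets_per_query: int = 8
    protein_length_range: tuple[int, int] = (80, 160)
    segment_length_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_LENGTHS)
    )
    sse_grammar: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_GRAMMAR.items()}
    )
    emission_tables: dict[str, np.ndarray] = field(default_factory=default_emission_tables)
    homolog_identity_range: tuple[float, float] = (0.30, 0.50)
    sse_jitter_prob: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein_length_range
        if lo < 10 or hi < lo:
            raise ParameterError("protein_length_range must satisfy 10 <= lo <= hi")
        ilo, ihi = self.homolog_identity_range
        if not (0.0 <= ilo <= ihi <= 1.0):
            raise ParameterError("homolog_identity_range must be within [0, 1]")
        for code, (slo, shi) in self.segment_length_ranges.items():
            if slo < 1 or shi < slo:
                raise ParameterError(f"bad segment length range for {code!r}")
            if code not in self.alphabet:
                raise ParameterError(f"segment class {code!r} not in alphabet")
        for code, table in self.emission_tables.items():
            if abs(float(np.sum(table)) - 1.0) > 1e-9:
                raise ParameterError(f"emission table for {code!r} does not sum to 1")


@dataclass
class Family:
    """One query with its homologous targets and the true alignments."""

    query: SequenceRecord
    query_sse: SSERecord
    targets: list[SequenceRecord]
    target_sse: list[SSERecord]
    alignments: list[HitAlignment]


def _sample_sse(params: FamilyParams, rng: np.random.Generator) -> str:
    length = int(rng.integers(params.protein_length_range[0], params.protein_length_range[1] + 1))
    grammar = params.sse_grammar
    def draw(weights: dict[str, float]) -> str:
        codes = sorted(weights)
        w = np.array([weights[c] for c in codes], dtype=float)
        return codes[rng.choice(len(codes), p=w / w.sum())]

    out: list[str] = []
    state = draw(grammar["start"])
    while len(out) < length:
        lo, hi = params.segment_length_ranges[state]
        seg_len = int(rng.integers(lo, hi + 1))
        out.extend(state * seg_len)
        state = draw(grammar[state])
    return "".join(out[:length])


def _emit_sequence(sse: str, params: FamilyParams, rng: np.random.Generator) -> str:
    return "".join(
        AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=params.emission_tables[c])]
        for c in sse
    )


def _jitter_segments(sse: str, prob: float, rng: np.random.Generator) -> str:
    """Shift internal segment boundaries by up to two residues."""
    chars = list(sse)
    boundaries = [i for i in range(1, len(chars)) if chars[i] != chars[i - 1]]
    for b in boundaries:
        if rng.random() >= prob:
            continue
        shift = int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
        if shift > 0:  # grow the left segment rightwards
            for j in range(b, min(b + shift, len(chars) - 1)):
                chars[j] = chars[b - 1]
        else:  # grow the right segment leftwards
            for j in range(max(b + shift, 1), b):
                chars[j] = chars[b]
    return "".join(chars)


def _mutate(
    query_seq: str, query_sse: str, params: FamilyParams, rng: np.random.Generator
) -> tuple[str, str, float]:
    n = len(query_seq)
    ilo, ihi = params.homolog_identity_range
    identity = float(rng.uniform(ilo, ihi))
    k = int(round((1.0 - identity) * n))
    positions = rng.choice(n, size=k, replace=False)
    seq = list(query_seq)
    for p in positions:
        table = params.emission_tables[query_sse[p]].copy()
        table[AMINO_ACIDS.index(seq[p])] = 0.0
        table = table / table.sum()
        seq[p] = AMINO_ACIDS[rng.choice(len(AMINO_ACIDS), p=table)]
    sse = _jitter_segments(query_sse, params.sse_jitter_prob, rng)
    return "".join(seq), sse, 1.0 - k / n


def generate_family(
    params: FamilyParams, query_id: str = "q0", rng: np.random.Generator | None = None
) -> Family:
    """Generate one query plus its mutated homologs and true alignments.

    The true alignments are gapless full-length pairings (homologs are
    substitution-only copies); their identities equal the realized
    substitution fractions exactly.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    sse = _sample_sse(params, rng)
    seq = _emit_sequence(sse, params, rng)
    targets, target_sse, alignments = [], [], []
    for i in range(params.n_targets_per_query):
        tid = f"{query_id}_t{i}"
        tseq, tsse, identity = _mutate(seq, sse, params, rng)
        targets.append(SequenceRecord(tid, tseq))
        target_sse.append(SSERecord(tid, tsse))
        alignments.append(
            HitAlignment(
                query_id=query_id,
                hit_id=tid,
                query_aligned=seq,
                hit_aligned=tseq,
                identity=identity,
                query_start=0,
                hit_start=0,
            )
        )
    return Family(
        query=SequenceRecord(query_id, seq),
        query_sse=SSERecord(query_id, sse),
        targets=targets,
        target_sse=target_sse,
        alignments=alignments,
    )


@dataclass
class Benchmark:
    """Disjoint training/test query families over a shared target library."""

    train: list[Family]
    test: list[Family]
    params: FamilyParams

    @property
    def target_records(self) -> list[SequenceRecord]:
        return [t for fam in self.train + self.test for t in fam.targets]

    @property
    def target_sse_records(self) -> list[SSERecord]:
        return [t for fam in self.train + self.test for t in fam.target_sse]


def cross_identity(a: str, b: str) -> float:
    """Identity of the best gapless overlap, relative to the shorter
    sequence — the scale dataset non-redundancy ceilings are phrased in.

    Local-alignment per-column identity is useless here: unrelated
    short proteins trivially share tiny perfect-match regions.
    """
    best = 0
    la, lb = len(a), len(b)
    for off in range(-(lb - 1), la):
        matches = sum(
            1
            for i in range(max(0, off), min(la, lb + off))
            if a[i] == b[i - off]
        )
        best = max(best, matches)
    return best / min(la, lb)


def generate_benchmark(
    params: FamilyParams,
    split: tuple[float, float] = (2 / 3, 1 / 3),
    identity_ceiling: float = 1.0,
    max_attempts: int = 20,
) -> Benchmark:
    """Generate train/test query families sharing one target library.

    ``split`` gives (train, test) fractions of ``params.n_queries``
    (must sum to 1).  No test query may exceed ``identity_ceiling``
    (cross-sequence identity per :func:`cross_identity`) against any
    training query; offending test families are regenerated up to
    ``max_attempts`` times before a :class:`GenerationError`.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ParameterError("split fractions must sum to 1")
    n_train = int(round(split[0] * params.n_queries))
    n_test = params.n_queries - n_train
    if n_train < 1 or n_test < 1:
        raise ParameterError("both splits must receive at least one query")
    rng = np.random.default_rng(params.seed)
    train = [generate_family(params, f"train{i}", rng) for i in range(n_train)]
    test = []
    for i in range(n_test):
        for _ in range(max_attempts):
            fam = generate_family(params, f"test{i}", rng)
            worst = max(
                cross_identity(fam.query.sequence, tr.query.sequence) for tr in train
            )
            if worst <= identity_ceiling:
                test.append(fam)
                break
        else:
            raise GenerationError(
                f"could not generate test query {i} under the identity "
                f"ceiling {identity_ceiling} in {max_attempts} attempts"
            )
    return Benchmark(train=train, test=test, params=params)


def small_preset(seed: int = 0) -> FamilyParams:
    """A tiny, fast family: one query, few short homologs."""
    return FamilyParams(
        n_queries=1,
        n_targets_per_query=5,
        protein_length_range=(60, 90),
        seed=seed,
    )


def benchmark_preset(seed: int = 0) -> FamilyParams:
    """A small train/test benchmark for end-to-end runs."""
    return FamilyParams(
        n_queries=18,
        n_targets_per_query=8,
        protein_length_range=(80, 140),
        seed=seed,
    )


def with_seed(params: FamilyParams, seed: int) -> FamilyParams:
    return replace(params, seed=seed)
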