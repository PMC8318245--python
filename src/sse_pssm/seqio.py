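"""Readers and writers for every on-disk format the pipeline touches.

Formats
-------
* FASTA for amino-acid sequences and for same-length SSE strings
  (the latter stand in for DSSP output on known structures).
* A 5-column alignment TSV, one query-hit pairwise alignment per row —
  the injection point for alignments produced by external search tools.
* A per-position PSSM TSV (``pos  res  <code scores...>``), 4 decimal
  places, 1-based positions.
* A labeled square substitution-matrix text file, 2 decimal places.

All round trips are lossless up to the stated decimal precision, and
readers never reorder records.  User-facing coordinates are 1-based;
everything in memory is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabets import SSEAlphabet, get_alphabet
from .errors import FormatError, InvalidCodeError

ALIGNMENT_HEADER = ("query_id", "hit_id", "query_aln", "hit_aln", "identity")


@dataclass(frozen=True)
class SequenceRecord:
    """One amino-acid sequence (20 standard codes plus 'X')."""

    id: str
    sequence: str


@dataclass(frozen=True)
class SSERecord:
    """One per-residue secondary-structure string over a declared alphabet."""

    id: str
    sse: str


@dataclass
class HitAlignment:
    """One query-hit pairwise alignment.

    ``query_aligned``/``hit_aligned`` are equal-length gapped strings
    covering the locally aligned region only.  ``identity`` is a
    fraction in [0, 1]: matched columns over non-gap aligned columns.
    ``query_start``/``hit_start`` are 0-based offsets of the aligned
    region within the full sequences; they are convenience metadata not
    serialized to TSV (readers recover them with ``str.find``).
    """

    query_id: str
    hit_id: str
    query_aligned: str
    hit_aligned: str
    identity: float
    score: float | None = field(default=None, compare=False)
    query_start: int | None = field(default=None, compare=False)
    hit_start: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if len(self.query_aligned) != len(self.hit_aligned):
            raise FormatError(
                f"alignment {self.query_id}/{self.hit_id}: aligned strings differ "
                f"in length ({len(self.query_aligned)} vs {len(self.hit_aligned)})"
            )


def _clean_sequence(raw: str, rec_id: str) -> str:
    s = str(raw).strip().rstrip("*")
    if s != s.upper():
        warnings.warn(f"record {rec_id!r}: sequence upper-cased on read", stacklevel=3)
    return s.upper()


def read_fasta(path) -> list[SequenceRecord]:
    """Read amino-acid FASTA records in file order, upper-cased, '*' stripped."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _clean_sequence(str(rec.seq), rec.id)
        if not seq:
            raise FormatError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    return records


def read_sse_fasta(path, alphabet: SSEAlphabet) -> list[SSERecord]:
    """Read SSE strings from FASTA; every code must belong to ``alphabet``."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        sse = _clean_sequence(str(rec.seq), rec.id)
        try:
            alphabet.validate(sse, where=f"record {rec.id!r}")
        except InvalidCodeError as exc:
            raise InvalidCodeError(f"{path}: {exc}") from None
        records.append(SSERecord(rec.id, sse))
    return records


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = rec.sequence if isinstance(rec, SequenceRecord) else rec.sse
            fh.write(f">{rec.id}\n{seq}\n")


def read_alignment_tsv(path) -> list[HitAlignment]:
    """Read the 5-column alignment TSV dialect (header required)."""
    rows: list[HitAlignment] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if tuple(header.split("\t")) != ALIGNMENT_HEADER:
            raise FormatError(f"{path}: bad header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns, got {len(parts)}")
            qid, hid, qaln, haln, ident = parts
            if len(qaln) != len(haln):
                raise FormatError(
                    f"{path}:{lineno}: aligned strings differ in length "
                    f"({len(qaln)} vs {len(haln)})"
                )
            try:
                identity = float(ident)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: bad identity {ident!r}") from None
            rows.append(HitAlignment(qid, hid, qaln.upper(), haln.upper(), identity))
    return rows


def write_alignment_tsv(table, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(ALIGNMENT_HEADER) + "\n")
        for row in table:
            fh.write(
                f"{row.query_id}\t{row.hit_id}\t{row.query_aligned}\t"
                f"{row.hit_aligned}\t{row.identity:g}\n"
            )


def write_pssm_tsv(profile, path) -> None:
    """Serialize a profile's PSSM: ``pos  res  <one score per code>``, 4 dp."""
    codes = profile.alphabet.codes
    with open(path, "w") as fh:
        fh.write("pos\tres\t" + "\t".join(codes) + "\n")
        for p in range(len(profile.query_seq)):
            scores = "\t".join(f"{v:.4f}" for v in profile.pssm[p])
            fh.write(f"{p + 1}\t{profile.query_seq[p]}\t{scores}\n")


def read_pssm_tsv(path, alphabet: SSEAlphabet | str = None, query_id: str = ""):
    """Read a PSSM TSV back into an :class:`~sse_pssm.pssm.SSEProfile`.

    Only the PSSM matrix is serialized, so the returned profile carries
    ``occ is None`` and ``ppm is None``.  If ``alphabet`` is given the
    header codes must match it; otherwise the header defines an ad-hoc
    alphabet looked up by its code string among the registered ones.
    """
    from .pssm import SSEProfile  # local import: pssm does not import seqio

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3 or header[:2] != ["pos", "res"]:
            raise FormatError(f"{path}: bad PSSM header")
        codes = tuple(header[2:])
        if alphabet is not None:
            if isinstance(alphabet, str):
                alphabet = get_alphabet(alphabet)
            if codes != alphabet.codes:
                raise FormatError(
                    f"{path}: header codes {''.join(codes)!r} do not match "
                    f"alphabet {alphabet.name!r}"
                )
        else:
            alphabet = SSEAlphabet("file", codes)
        residues: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2 + len(codes):
                raise FormatError(
                    f"{path}:{lineno}: expected {2 + len(codes)} columns, got {len(parts)}"
                )
            if int(parts[0]) != len(residues) + 1:
                raise FormatError(f"{path}:{lineno}: positions must be 1..N in order")
            residues.append(parts[1])
            rows.append([float(v) for v in parts[2:]])
    pssm = np.asarray(rows, dtype=float) if rows else np.zeros((0, len(codes)))
    return SSEProfile(
        query_id=query_id or Path(str(path)).stem,
        query_seq="".join(residues),
        alphabet=alphabet,
        occ=None,
        ppm=None,
        pssm=pssm,
        background=None,
        pseudocount_positions=frozenset(),
    )


def write_substitution_matrix(matrix, path) -> None:
    """Labeled square matrix text format, 2 decimal places.

    Layout mirrors the classic substitution-matrix files: a comment
    header naming the alphabet, a row of column labels, then one
    labeled row per code.
    """
    codes = matrix.alphabet.codes
    with open(path, "w") as fh:
        fh.write(f"# alphabet: {matrix.alphabet.name}\n")
        fh.write("  " + " ".join(f"{c:>7s}" for c in codes) + "\n")
        for i, a in enumerate(codes):
            fh.write(a + " " + " ".join(f"{matrix.scores[i, j]:7.2f}" for j in range(len(codes))) + "\n")


def read_substitution_matrix(path):
    """Read the labeled square matrix format written by
    :func:`write_substitution_matrix`."""
    from .pssm import BackgroundFrequencies, SubstitutionMatrix

    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines or not lines[0].startswith("# alphabet:"):
        raise FormatError(f"{path}: missing '# alphabet:' header")
    name = lines[0].split(":", 1)[1].strip()
    codes = tuple(lines[1].split())
    try:
        alphabet = get_alphabet(name)
        if alphabet.codes != codes:
            raise FormatError(f"{path}: column labels do not match alphabet {name!r}")
    except Exception:
        alphabet = SSEAlphabet(name, codes)
    n = len(codes)
    scores = np.zeros((n, n))
    if len(lines) != 2 + n:
        raise FormatError(f"{path}: expected {n} matrix rows, got {len(lines) - 2}")
    for i, line in enumerate(lines[2:]):
        parts = line.split()
        if len(parts) != n + 1 or parts[0] != codes[i]:
            raise FormatError(f"{path}: bad matrix row {i + 1}")
        scores[i] = [float(v) for v in parts[1:]]
    # background is not serialized; reconstruct a flat one
    bg = BackgroundFrequencies({c: 1.0 / n for c in codes}, source=f"uniform (read from {path})")
    return SubstitutionMatrix(alphabet=alphabet, scores=scores, background=bg)
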