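"""Sequence and matrix I/O: peptide FASTA dialect, AAindex-format substitution
matrices, square matrix tables, and assembly of merged peptide fragment sets.

Peptides travel as :class:`PeptideRecord` / :class:`PeptideSet`.  Substitution
matrices are 20x20 integer tables over the standard amino-acid alphabet,
clamped to ``[-19, 19]``; they may become asymmetric during training, in which
case rows index the query residue and columns the dataset (target) residue.

The FASTA header dialect is ``>protein_id|start-end|label`` where the span and
label fields are optional.  Spans are 0-based half-open intervals in the
source protein.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Tuple

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

# Canonical residue order used for all internal score tables.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Index of the wildcard residue (B/Z/X/U and friends map here, scored 0).
X_INDEX = 20

SCORE_MIN, SCORE_MAX = -19, 19

_AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
for _nonstd in "BZXUJO":
    _AA_TO_INDEX[_nonstd] = X_INDEX

VALID_LABELS = ("functional", "control", "unknown")


class FormatError(ValueError):
    """Raised when an input file does not parse under its declared format."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Map an amino-acid string to integer indices into the extended alphabet.

    Nonstandard residues (B, Z, X, U, J, O) all map to the wildcard index and
    score 0 against everything.  Any other letter is an error.
    """
    try:
        return np.array([_AA_TO_INDEX[c] for c in sequence.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence {sequence!r}") from None


@dataclass(frozen=True)
class SubstitutionMatrix:
    """A 20x20 integer substitution score table.

    ``scores[i][j]`` is the score for aligning query residue ``ALPHABET[i]``
    against target residue ``ALPHABET[j]``.  All entries lie in [-19, 19].
    """

    scores: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.shape != (20, 20):
            raise ValueError(f"expected a 20x20 score grid, got {scores.shape}")
        if scores.min() < SCORE_MIN or scores.max() > SCORE_MAX:
            raise ValueError(f"matrix entries must lie in [{SCORE_MIN}, {SCORE_MAX}]")
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)

    @property
    def symmetric(self) -> bool:
        return bool(np.array_equal(self.scores, self.scores.T))

    def extended(self) -> np.ndarray:
        """21x21 table with a zero-scoring wildcard row/column appended."""
        ext = np.zeros((21, 21), dtype=np.int64)
        ext[:20, :20] = self.scores
        return ext

    def score(self, query_residue: str, target_residue: str) -> int:
        qi = _AA_TO_INDEX[query_residue.upper()]
        ti = _AA_TO_INDEX[target_residue.upper()]
        return int(self.extended()[qi, ti])

    def with_scores(self, scores: np.ndarray, id: Optional[str] = None) -> "SubstitutionMatrix":
        return SubstitutionMatrix(scores=scores, id=self.id if id is None else id)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SubstitutionMatrix):
            return NotImplemented
        return self.id == other.id and np.array_equal(self.scores, other.scores)


def identity_matrix(match: int = 4, mismatch: int = 0, id: str = "identity") -> SubstitutionMatrix:
    """Diagonal matrix scoring ``match`` for identical residues, ``mismatch`` otherwise."""
    scores = np.full((20, 20), mismatch, dtype=np.int64)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix(scores=scores, id=id)


def matrix_from_pairs(pairs: dict, default: int = 0, id: str = "") -> SubstitutionMatrix:
    """Build a matrix from a ``{(query_aa, target_aa): score}`` mapping (symmetrised)."""
    scores = np.full((20, 20), default, dtype=np.int64)
    for (a, b), v in pairs.items():
        i, j = _AA_TO_INDEX[a], _AA_TO_INDEX[b]
        scores[i, j] = v
        scores[j, i] = v
    return SubstitutionMatrix(scores=scores, id=id)


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide: sequence, source protein, optional span, functional label."""

    sequence: str
    protein_id: str
    span: Optional[Tuple[int, int]] = None
    label: str = "unknown"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty peptide sequence")
        encode_sequence(seq)  # validates the alphabet
        object.__setattr__(self, "sequence", seq)
        if self.span is not None:
            start, end = self.span
            if end - start != len(seq):
                raise ValueError(
                    f"span {self.span} length {end - start} != sequence length {len(seq)}"
                )
            object.__setattr__(self, "span", (int(start), int(end)))
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")

    @property
    def key(self) -> Tuple[str, str, Optional[Tuple[int, int]]]:
        return (self.sequence, self.protein_id, self.span)

    def encoded(self) -> np.ndarray:
        return encode_sequence(self.sequence)


@dataclass
class PeptideSet:
    """An ordered collection of peptide records; the unit of TSS computation."""

    records: list = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.records = list(self.records)
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise ValueError(
                    f"duplicate record (sequence={rec.sequence!r}, protein={rec.protein_id!r}, "
                    f"span={rec.span}) in set {self.name!r}"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PeptideRecord:
        return self.records[i]

    @property
    def sequences(self) -> list:
        return [r.sequence for r in self.records]

    @property
    def protein_ids(self) -> list:
        return [r.protein_id for r in self.records]

    def exclude_protein(self, protein_id: str, name: Optional[str] = None) -> "PeptideSet":
        """All records whose source protein differs from ``protein_id``."""
        kept = [r for r in self.records if r.protein_id != protein_id]
        return PeptideSet(kept, name=name if name is not None else self.name)

    def relabel(self, label: str) -> "PeptideSet":
        return PeptideSet([replace(r, label=label) for r in self.records], name=self.name)


# ---------------------------------------------------------------------------
# FASTA dialect
# ---------------------------------------------------------------------------

_SPAN_RE = re.compile(r"^(\d+)-(\d+)$")


def _parse_header(header: str) -> Tuple[str, Optional[Tuple[int, int]], str]:
    parts = header.strip().split("|")
    protein_id = parts[0].strip()
    if not protein_id:
        raise FormatError(f"FASTA header has no protein id: >{header!r}")
    span: Optional[Tuple[int, int]] = None
    label = "unknown"
    rest = [p.strip() for p in parts[1:] if p.strip()]
    for tok in rest:
        m = _SPAN_RE.match(tok)
        if m:
            if span is not None:
                raise FormatError(f"FASTA header has two span fields: >{header!r}")
            span = (int(m.group(1)), int(m.group(2)))
        elif tok in VALID_LABELS:
            label = tok
        else:
            raise FormatError(
                f"unrecognised FASTA header field {tok!r} in >{header!r} "
                f"(expected start-end or one of {VALID_LABELS})"
            )
    return protein_id, span, label


def read_fasta(path, name: Optional[str] = None, default_label: str = "unknown") -> PeptideSet:
    """Read peptides from FASTA using the ``>id|start-end|label`` header dialect.

    Empty-sequence entries are dropped with a warning; duplicate
    (sequence, protein, span) triples raise.
    """
    records = []
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            seq = seq.strip().upper()
            if not seq:
                warnings.warn(f"skipping empty-sequence entry >{header} in {path}")
                continue
            protein_id, span, label = _parse_header(header)
            if label == "unknown":
                label = default_label
            records.append(PeptideRecord(seq, protein_id, span=span, label=label))
    return PeptideSet(records, name=name if name is not None else str(path))


def write_fasta(peptides: PeptideSet, path) -> None:
    """Write peptides in the package's FASTA header dialect."""
    with open(path, "w") as out:
        for rec in peptides:
            header = rec.protein_id
            if rec.span is not None:
                header += f"|{rec.span[0]}-{rec.span[1]}"
            if rec.label != "unknown":
                header += f"|{rec.label}"
            out.write(f">{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# AAindex-format matrices
# ---------------------------------------------------------------------------

_AAINDEX_ROWCOL_RE = re.compile(
    r"rows\s*=\s*([A-Z\-/]+)\s*,\s*cols\s*=\s*([A-Z\-/]+)", re.IGNORECASE
)


def _finish_aaindex_entry(accession: str, rows: str, cols: str, values: list):
    n = len(rows)
    if len(cols) != n:
        raise FormatError(f"{accession}: row alphabet ({rows}) != column alphabet ({cols})")
    if len(values) != n:
        raise FormatError(f"{accession}: expected {n} value rows, got {len(values)}")
    lower_triangular = all(len(values[i]) == i + 1 for i in range(n))
    square = all(len(v) == n for v in values)
    if not (lower_triangular or square):
        raise FormatError(f"{accession}: value block is neither lower-triangular nor square")
    grid = np.zeros((n, n), dtype=float)
    for i, row in enumerate(values):
        for j, v in enumerate(row):
            grid[i, j] = v
            if lower_triangular:
                grid[j, i] = v
    # Reorder into the canonical alphabet; AAindex files typically use
    # the ARNDCQEGHILKMFPSTWYV ordering.
    try:
        perm = [rows.index(aa) for aa in ALPHABET]
    except ValueError as exc:
        raise FormatError(f"{accession}: alphabet {rows!r} is not the 20 standard residues") from exc
    grid = grid[np.ix_(perm, perm)]
    scores = np.clip(np.rint(grid).astype(np.int64), SCORE_MIN, SCORE_MAX)
    return SubstitutionMatrix(scores=scores, id=accession)


def parse_aaindex(path) -> list:
    """Parse substitution matrices from an AAindex-format flat file.

    Lower-triangular value blocks are mirrored to full symmetric matrices.
    Real-valued entries are rounded to the nearest integer and clamped to
    [-19, 19]; missing values (``-``) are filled with 0 with a warning.
    """
    matrices = []
    accession = ""
    rows = cols = ""
    values: list = []
    in_block = False

    def flush():
        nonlocal accession, rows, cols, values, in_block
        if accession and values:
            matrices.append(_finish_aaindex_entry(accession, rows, cols, values))
        accession, rows, cols, values, in_block = "", "", "", [], False

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("//"):
                flush()
                continue
            if line.startswith("H "):
                accession = line[2:].strip()
                in_block = False
                continue
            if line.startswith("M "):
                m = _AAINDEX_ROWCOL_RE.search(line)
                if not m:
                    raise FormatError(f"line {lineno}: malformed M record: {line.strip()!r}")
                rows, cols = m.group(1), m.group(2)
                in_block = True
                continue
            if in_block and line.strip() and not line[0].isalpha():
                toks = line.split()
                parsed = []
                for tok in toks:
                    if tok in ("-", "NA"):
                        warnings.warn(
                            f"{accession}: missing value at line {lineno} filled with 0"
                        )
                        parsed.append(0.0)
                    else:
                        try:
                            parsed.append(float(tok))
                        except ValueError:
                            raise FormatError(
                                f"line {lineno}: non-numeric value {tok!r} in matrix block"
                            ) from None
                values.append(parsed)
            elif in_block and line[0].isalpha():
                in_block = False
    flush()
    if not matrices:
        raise FormatError(f"{path}: no matrix entries found")
    return matrices


def _write_aaindex(matrix: SubstitutionMatrix, out) -> None:
    if not matrix.symmetric:
        raise ValueError(
            "the AAindex dialect is lower-triangular and cannot represent an "
            "asymmetric matrix; use the square dialect"
        )
    out.write(f"H {matrix.id or 'UNNAMED'}\n")
    out.write("D Substitution matrix exported by pepmat\n")
    out.write(f"M rows = {ALPHABET}, cols = {ALPHABET}\n")
    for i in range(20):
        out.write(" ".join(f"{int(matrix.scores[i, j]):>4d}" for j in range(i + 1)) + "\n")
    out.write("//\n")


def _write_square(matrix: SubstitutionMatrix, out) -> None:
    out.write("# " + (matrix.id or "UNNAMED") + "\n")
    out.write("  " + " ".join(f"{aa:>4s}" for aa in ALPHABET) + "\n")
    for i, aa in enumerate(ALPHABET):
        out.write(aa + " " + " ".join(f"{int(v):>4d}" for v in matrix.scores[i]) + "\n")


def write_matrix(matrix: SubstitutionMatrix, path, dialect: str = "square") -> None:
    """Write a matrix in the ``aaindex`` (symmetric only) or ``square`` dialect."""
    writers = {"aaindex": _write_aaindex, "square": _write_square}
    if dialect not in writers:
        raise ValueError(f"unknown matrix dialect {dialect!r}; expected one of {sorted(writers)}")
    with open(path, "w") as out:
        writers[dialect](matrix, out)


def parse_square_matrix(path) -> SubstitutionMatrix:
    """Read a whitespace-delimited square matrix table with residue headers."""
    matrix_id = ""
    header: Optional[list] = None
    rows = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip()
            if not line:
                continue
            if line.startswith("#"):
                if not matrix_id:
                    matrix_id = line[1:].strip()
                continue
            toks = line.split()
            if header is None:
                header = toks
                if sorted(header) != sorted(ALPHABET):
                    raise FormatError(
                        f"line {lineno}: column header is not the 20 standard residues"
                    )
                continue
            if len(toks) != 21:
                raise FormatError(f"line {lineno}: expected residue + 20 values, got {len(toks)}")
            rows[toks[0]] = [int(round(float(t))) for t in toks[1:]]
    if header is None or sorted(rows) != sorted(ALPHABET):
        raise FormatError(f"{path}: expected 20 rows over the standard residues")
    scores = np.zeros((20, 20), dtype=np.int64)
    col_perm = [header.index(aa) for aa in ALPHABET]
    for i, aa in enumerate(ALPHABET):
        scores[i] = np.array(rows[aa], dtype=np.int64)[col_perm]
    scores = np.clip(scores, SCORE_MIN, SCORE_MAX)
    return SubstitutionMatrix(scores=scores, id=matrix_id)


def read_matrix(path) -> SubstitutionMatrix:
    """Read a matrix file, sniffing between the AAindex and square dialects."""
    with open(path) as handle:
        for line in handle:
            if line.strip():
                first = line
                break
        else:
            raise FormatError(f"{path}: empty matrix file")
    if first.startswith("H "):
        return parse_aaindex(path)[0]
    return parse_square_matrix(path)


# ---------------------------------------------------------------------------
# Fragment-set assembly
# ---------------------------------------------------------------------------

def build_fragment_set(raw_peptides: PeptideSet, name: str = "fragments") -> PeptideSet:
    """Merge raw observed peptides into a non-redundant fragment set.

    Exact-duplicate sequences are removed, then records from the same protein
    whose spans overlap or abut are merged into a single record covering the
    union span.  Overlapping records whose shared residues disagree raise a
    consistency error.  Idempotent: re-applying is a no-op.
    """
    for rec in raw_peptides:
        if rec.span is None:
            raise ValueError(
                f"record {rec.sequence!r} ({rec.protein_id}) has no span; "
                "fragment merging requires source coordinates"
            )
    seen_sequences = set()
    by_protein: dict = {}
    protein_order = []
    for rec in raw_peptides:
        if rec.sequence in seen_sequences:
            continue
        seen_sequences.add(rec.sequence)
        if rec.protein_id not in by_protein:
            by_protein[rec.protein_id] = []
            protein_order.append(rec.protein_id)
        by_protein[rec.protein_id].append(rec)

    merged = []
    for pid in protein_order:
        residues: dict = {}
        labels = set()
        for rec in by_protein[pid]:
            start = rec.span[0]
            labels.add(rec.label)
            for offset, aa in enumerate(rec.sequence):
                pos = start + offset
                if pos in residues and residues[pos] != aa:
                    raise ValueError(
                        f"inconsistent overlap in protein {pid} at position {pos}: "
                        f"{residues[pos]!r} vs {aa!r}"
                    )
                residues[pos] = aa
        label = labels.pop() if len(labels) == 1 else "unknown"
        positions = sorted(residues)
        run_start = positions[0]
        prev = positions[0]
        for pos in positions[1:] + [None]:
            if pos is None or pos != prev + 1:
                seq = "".join(residues[p] for p in range(run_start, prev + 1))
                merged.append(PeptideRecord(seq, pid, span=(run_start, prev + 1), label=label))
                if pos is not None:
                    run_start = pos
            prev = pos if pos is not None else prev
    return PeptideSet(merged, name=name)
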