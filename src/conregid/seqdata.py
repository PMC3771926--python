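"""Core sequence/alignment data types and file I/O.

Conventions used throughout the package:

* Residues are upper-case letters over the 20-letter amino-acid alphabet plus
  ``X`` for unknowns; any non-standard letter (B, Z, U, J, O, ...) is mapped to
  ``X`` on input.
* Internal coordinates are 0-based half-open; every file read or written uses
  1-based inclusive positions.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: Canonical residue order used for every count/frequency vector in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Index of the unknown-residue symbol in encoded arrays.
X_INDEX = 20
#: Index of the gap symbol in encoded arrays (alignments only).
GAP_INDEX = 21
#: Full symbol alphabet for encoded alignment columns.
ALPHABET = AMINO_ACIDS + "X-"

_STANDARD = set(AMINO_ACIDS)
_RESIDUE_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_RESIDUE_INDEX["X"] = X_INDEX
_GAP_CHARS = set("-.")


def sanitize_residues(raw: str) -> str:
    """Upper-case ``raw`` and map non-standard letters to ``X``.

    Gap characters are rejected: plain sequences must be ungapped.
    """
    out = []
    for ch in raw.upper():
        if ch in _STANDARD:
            out.append(ch)
        elif ch in _GAP_CHARS:
            raise ValueError("sequence residues may not contain gap characters")
        elif ch.isalpha() or ch == "*":
            out.append("X")
        else:
            raise ValueError(f"invalid residue character {ch!r}")
    return "".join(out)


@dataclass(frozen=True)
class Sequence:
    """An identified, ungapped amino-acid sequence."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        object.__setattr__(self, "residues", sanitize_residues(self.residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class RegionAnnotation:
    """A labelled region on a sequence, 1-based inclusive coordinates."""

    seq_id: str
    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid annotation interval [{self.start}, {self.end}]")

    def positions(self) -> set[int]:
        return set(range(self.start, self.end + 1))


class SubstitutionMatrix:
    """A symmetric residue substitution score lookup (20 residues + X)."""

    _BUNDLED = ("BLOSUM50", "BLOSUM62", "BLOSUM80", "PAM250")

    def __init__(self, name: str, array) -> None:
        self.name = name
        self._array = array  # Bio.Align.substitution_matrices.Array

    @classmethod
    def load(cls, name: str) -> "SubstitutionMatrix":
        key = name.upper()
        if key not in cls._BUNDLED:
            raise ValueError(
                f"unknown substitution matrix {name!r}; available: {', '.join(cls._BUNDLED)}"
            )
        return cls(key, substitution_matrices.load(key))

    def score(self, a: str, b: str) -> float:
        a = a if a in self._array.alphabet else "X"
        b = b if b in self._array.alphabet else "X"
        return float(self._array[a, b])

    @property
    def biopython(self):
        """The underlying Biopython scoring array (for PairwiseAligner)."""
        return self._array

    def to_numpy(self) -> np.ndarray:
        """Scores as a 21x21 array in :data:`AMINO_ACIDS` + X order."""
        symbols = AMINO_ACIDS + "X"
        out = np.empty((21, 21), dtype=np.float64)
        for i, a in enumerate(symbols):
            for j, b in enumerate(symbols):
                out[i, j] = self.score(a, b)
        return out


def load_matrix(name: str) -> SubstitutionMatrix:
    """Load a bundled substitution matrix by name (e.g. ``"BLOSUM62"``)."""
    return SubstitutionMatrix.load(name)


@dataclass
class Alignment:
    """A multiple alignment: ordered rows of equal-length gapped strings."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if self.rows:
            n = len(self.rows[0])
            for sid, row in zip(self.ids, self.rows):
                if len(row) != n:
                    raise ValueError(f"ragged alignment row for {sid!r}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self) -> list[Sequence]:
        return [
            Sequence(sid, row.replace("-", "").replace(".", ""))
            for sid, row in zip(self.ids, self.rows)
        ]

    def encoded(self) -> np.ndarray:
        """Rows encoded as int8 indices into :data:`ALPHABET`."""
        lut = np.full(128, -1, dtype=np.int8)
        for aa, i in _RESIDUE_INDEX.items():
            lut[ord(aa)] = i
        lut[ord("-")] = GAP_INDEX
        lut[ord(".")] = GAP_INDEX
        arr = np.frombuffer("".join(self.rows).encode("ascii"), dtype=np.uint8)
        enc = lut[arr].reshape(self.n_rows, self.n_columns)
        if (enc < 0).any():
            raise ValueError("alignment contains invalid characters")
        return enc


class SimilarityMap:
    """Sparse symmetric map from unordered sequence-id pairs to best e-values."""

    def __init__(self) -> None:
        self._entries: dict[tuple[str, str], float] = {}

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, evalue: float) -> None:
        """Record an e-value; self-pairs are ignored, directions collapse to the minimum."""
        if a == b:
            return
        if evalue < 0:
            raise ValueError("e-values must be non-negative")
        key = self._key(a, b)
        prev = self._entries.get(key)
        if prev is None or evalue < prev:
            self._entries[key] = evalue

    def get(self, a: str, b: str, default: float | None = None) -> float | None:
        return self._entries.get(self._key(a, b), default)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(sorted(self._entries.items()))

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self._key(*pair) in self._entries


# ---------------------------------------------------------------------------
# File I/O


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file; ids are the first whitespace-delimited header token.

    Raises ``ValueError`` on duplicate ids.
    """
    seqs: list[Sequence] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise ValueError(f"duplicate sequence id {record.id!r} in {path}")
            seen.add(record.id)
            seqs.append(Sequence(record.id, str(record.seq)))
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 60) -> None:
    with _open_text(path, "wt") as handle:
        for seq in seqs:
            handle.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                handle.write(seq.residues[i : i + width] + "\n")


def length_filter(
    seqs: list[Sequence], min_len: int = 100, max_len: int = 10000
) -> list[Sequence]:
    """Drop outlier sequences outside ``[min_len, max_len]`` (inclusive)."""
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    kept = [s for s in seqs if min_len <= len(s) <= max_len]
    removed = len(seqs) - len(kept)
    if removed:
        logger.info("length_filter removed %d of %d sequences", removed, len(seqs))
    return kept


def read_similarity_table(path: str | Path) -> SimilarityMap:
    """Read a pairwise similarity table into a :class:`SimilarityMap`.

    Accepts either the 3-column dialect (query, subject, e-value) or the
    standard 12-column tabular alignment-report dialect (e-value in column 11).
    Per unordered pair the minimum e-value is kept; self-pairs are ignored.
    """
    sim = SimilarityMap()
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                q, s, ev = fields[0], fields[1], fields[2]
            elif len(fields) >= 12:
                q, s, ev = fields[0], fields[1], fields[10]
            else:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or >=12 tab-separated columns, got {len(fields)}"
                )
            try:
                evalue = float(ev)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric e-value {ev!r}") from exc
            sim.add(q, s, evalue)
    return sim


def write_similarity_table(sim: SimilarityMap, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for (a, b), ev in sim.items():
            handle.write(f"{a}\t{b}\t{ev:.6g}\n")


def read_alignment(path: str | Path, fmt: str | None = None) -> Alignment:
    """Read an aligned-FASTA or Clustal alignment.

    ``fmt`` may be ``"fasta"`` or ``"clustal"``; when omitted it is guessed
    from the first line.
    """
    path = Path(path)
    if fmt is None:
        with _open_text(path) as handle:
            first = handle.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    with _open_text(path) as handle:
        try:
            msa = AlignIO.read(handle, fmt)
        except ValueError as exc:
            raise ValueError(f"cannot parse alignment {path}: {exc}") from exc
    ids = [rec.id for rec in msa]
    rows = [str(rec.seq).upper() for rec in msa]
    return Alignment(ids, rows)


def write_alignment(al: Alignment, path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for sid, row in zip(al.ids, al.rows):
            handle.write(f">{sid}\n{row}\n")


def read_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read a TSV of (seq_id, start, end, label), 1-based inclusive."""
    out: list[RegionAnnotation] = []
    with _open_text(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            out.append(RegionAnnotation(fields[0], start, end, fields[3]))
    return out


def write_annotations(annos: Iterable[RegionAnnotation], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for a in annos:
            handle.write(f"{a.seq_id}\t{a.start}\t{a.end}\t{a.label}\n")
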