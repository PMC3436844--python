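"""FASTA input and the concatenated-text database representation.

A protein set is stored as a single string ``txt`` over the amino-acid
alphabet with a sentinel character appended after every protein, plus an
offset array ``start`` such that protein *i* is ``txt[start[i]:start[i+1]-1]``.
The sentinel sorts below every residue letter, which makes the lexicographic
order of all suffixes of ``txt`` strict and well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

#: Separator appended after every protein; ASCII '$' sorts below 'A'..'Z'.
SENTINEL = "$"

#: The 20 standard residues plus the IUPAC ambiguity/rare letters kept as-is.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYBZXUO")

#: Letters outside the kept set are mapped to 'X'; '*' and '-' are dropped.
_CLEAN = {}
for _c in map(chr, range(ord("A"), ord("Z") + 1)):
    _CLEAN[ord(_c)] = _c if _c in VALID_RESIDUES else "X"
# Rare residues indexed as 'X' so lexicographic comparison stays total.
for _c in "UO":
    _CLEAN[ord(_c)] = "X"
for _c in "*-.":
    _CLEAN[ord(_c)] = None


@dataclass
class SequenceDB:
    """Concatenated protein text with per-protein offsets and identifiers.

    Attributes
    ----------
    txt:
        Residue string; one sentinel follows every protein, including the last.
    start:
        ``int64`` array of length ``n_proteins + 1``; ``start[i]`` is the text
        offset of protein *i*'s first residue and ``start[n_proteins]``
        equals ``len(txt)`` (one past the final sentinel).
    ids:
        Protein identifiers (first whitespace-delimited header token).
    """

    txt: str
    start: np.ndarray
    ids: list[str]
    skipped: list[str] = field(default_factory=list, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=np.int64)

    @property
    def n_proteins(self) -> int:
        return len(self.ids)

    @property
    def n_residues(self) -> int:
        """Total residue count, sentinels excluded."""
        return len(self.txt) - self.n_proteins

    def sequence(self, i: int) -> str:
        """Residues of protein ``i`` (no sentinel)."""
        return self.txt[self.start[i] : self.start[i + 1] - 1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceDB):
            return NotImplemented
        return (
            self.txt == other.txt
            and np.array_equal(self.start, other.start)
            and self.ids == other.ids
        )


def clean_sequence(raw: str) -> str:
    """Uppercase, map non-IUPAC letters to 'X' and drop '*', '-', '.'."""
    return raw.upper().translate(_CLEAN)


def db_from_records(records: list[tuple[str, str]]) -> SequenceDB:
    """Build a :class:`SequenceDB` from (id, cleaned residue string) pairs."""
    txt = "".join(seq + SENTINEL for _, seq in records)
    start = np.zeros(len(records) + 1, dtype=np.int64)
    np.cumsum([len(seq) + 1 for _, seq in records], out=start[1:])
    return SequenceDB(txt=txt, start=start, ids=[name for name, _ in records])


def load_fasta(path: str | Path, strip_annotation: bool = True) -> SequenceDB:
    """Read a FASTA file into a :class:`SequenceDB`.

    Residues are uppercased; letters outside the 25-letter IUPAC amino-acid
    set become 'X'; '*' and '-' are removed.  Records that are empty after
    cleaning are skipped with a warning and listed in ``db.skipped``.

    Raises
    ------
    ValueError
        If the file contains no usable sequence records.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    skipped: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id if strip_annotation else rec.description
        seq = clean_sequence(str(rec.seq))
        if not seq:
            warnings.warn(f"record {rec.id!r} empty after cleaning; skipped")
            skipped.append(rec.id)
            continue
        records.append((name, seq))
    if not records:
        raise ValueError(f"no sequences in {path}")
    db = db_from_records(records)
    db.skipped = skipped
    return db


def protein_of_position(db: SequenceDB, s: int) -> int:
    """Protein index owning text offset ``s``.

    A protein owns its residues and its trailing sentinel, so the map is
    total over ``0 <= s < len(txt)``.  Binary search over ``start``.
    """
    if not 0 <= s < len(db.txt):
        raise IndexError(f"position {s} outside text of length {len(db.txt)}")
    # protein i owns the half-open slab [start[i], start[i+1]): its residues
    # plus its trailing sentinel at start[i+1]-1.
    return int(np.searchsorted(db.start, s, side="right")) - 1


def proteins_of_positions(db: SequenceDB, s: np.ndarray) -> np.ndarray:
    """Vectorised :func:`protein_of_position` over an offset array."""
    return np.searchsorted(db.start, s, side="right") - 1


def save_db(db: SequenceDB, directory: str | Path) -> None:
    """Persist a database: txt at one byte per character plus sidecars."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "txt").write_bytes(db.txt.encode("ascii"))
    db.start.astype(np.int64).tofile(directory / "start")
    (directory / "ids").write_text("\n".join(db.ids) + "\n")


def load_db(directory: str | Path) -> SequenceDB:
    """Load a database persisted by :func:`save_db`.

    Raises
    ------
    ValueError
        On missing, truncated or mutually inconsistent artifact files.
    """
    directory = Path(directory)
    for name in ("txt", "start", "ids"):
        if not (directory / name).exists():
            raise ValueError(f"missing index file: {directory / name}")
    txt = (directory / "txt").read_bytes().decode("ascii")
    start = np.fromfile(directory / "start", dtype=np.int64)
    ids = (directory / "ids").read_text().splitlines()
    if len(start) != len(ids) + 1:
        raise ValueError(f"corrupted artifact: {directory / 'start'} inconsistent with ids")
    if len(txt) == 0 or len(start) == 0 or start[-1] != len(txt):
        raise ValueError(f"corrupted artifact: {directory / 'txt'} truncated")
    return SequenceDB(txt=txt, start=start, ids=ids)
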