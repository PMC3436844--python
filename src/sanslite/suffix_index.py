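"""Suffix array, inverse suffix array, suffix-to-protein map, query merge.

The database text (proteins concatenated with sentinels) is indexed once:

* ``sa``  — text offsets of all suffixes in lexicographic order,
* ``isa`` — rank of the suffix starting at each offset (inverse of ``sa``),
* ``sap`` — protein label of each rank's suffix.

Query suffixes are then located in the database order by a single merge
pass over the two sorted suffix arrays, giving ``isa_mapped[s_Q]`` = the
largest database rank whose suffix sorts <= the query suffix at ``s_Q``
(−1 if the query suffix precedes every database suffix).  Because each
protein ends in a sentinel that sorts below all residues, suffix order is
strict and the merge is a plain two-pointer scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from sanslite.sequence_io import SequenceDB, proteins_of_positions

__all__ = [
    "SuffixIndex",
    "QueryMapping",
    "build_suffix_array",
    "build_isa",
    "build_sap",
    "build_index",
    "map_query_suffixes",
    "save_index",
    "load_index",
]


@dataclass
class SuffixIndex:
    """Lexicographic suffix order of a database text plus derived arrays."""

    sa: np.ndarray
    isa: np.ndarray
    sap: np.ndarray
    n: int


@dataclass
class QueryMapping:
    """Insertion ranks of query suffixes into a database suffix order.

    ``isa_mapped[s_Q]`` is the largest database rank ``l`` with
    ``db_suffix(sa[l]) <= query_suffix(s_Q)``; −1 when the query suffix
    precedes all database suffixes.
    """

    isa_mapped: np.ndarray
    m: int


def build_suffix_array(txt: str, stats: dict | None = None) -> np.ndarray:
    """Suffix array of ``txt`` by prefix doubling on integer rank pairs.

    Each round sorts suffixes by their current rank and the rank ``k``
    positions ahead, doubling ``k`` until all ranks are distinct.  All
    suffixes of the concatenated text are distinct (distinct lengths ending
    at the final sentinel), so the resulting order is strict.  With a
    ``stats`` dict, ``steps`` counts elements processed over all rounds
    (the work measure; rounds grow with the longest repeated prefix, not
    with text length).
    """
    if not txt:
        raise ValueError("empty text")
    n = len(txt)
    arr = np.frombuffer(txt.encode("ascii"), dtype=np.uint8)
    # initial ranks from single characters
    rank = np.unique(arr, return_inverse=True)[1].astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    if stats is not None:
        stats["steps"] = stats.get("steps", 0) + n
        stats["rounds"] = 0
    k = 1
    while rank[sa[-1]] < n - 1:
        if stats is not None:
            stats["steps"] += n
            stats["rounds"] += 1
        key2 = np.full(n, -1, dtype=np.int64)
        key2[:-k] = rank[k:]
        sa = np.lexsort((key2, rank))
        # re-rank: increment where either key differs from the predecessor
        new = np.ones(n, dtype=np.int64)
        new[0] = 0
        same = (rank[sa[1:]] == rank[sa[:-1]]) & (key2[sa[1:]] == key2[sa[:-1]])
        new[1:][same] = 0
        out = np.empty(n, dtype=np.int64)
        out[sa] = np.cumsum(new)
        rank = out
        k *= 2
    return sa


def build_isa(sa: np.ndarray) -> np.ndarray:
    """Inverse permutation: ``isa[sa[l]] = l``."""
    sa = np.asarray(sa)
    n = len(sa)
    if n == 0 or sa.min() != 0 or sa.max() != n - 1 or len(np.unique(sa)) != n:
        raise ValueError("sa is not a permutation of 0..n-1")
    isa = np.empty(n, dtype=np.int64)
    isa[sa] = np.arange(n, dtype=np.int64)
    return isa


def build_sap(sa: np.ndarray, db: SequenceDB) -> np.ndarray:
    """Protein label per lexicographic rank: ``sap[l]`` owns suffix ``sa[l]``.

    Sentinel-initial suffixes are labelled with the preceding protein, the
    owner of the sentinel, so the map is total.
    """
    if len(sa) != len(db.txt):
        raise ValueError("suffix array length does not match database text")
    return proteins_of_positions(db, np.asarray(sa)).astype(np.int32)


def build_index(db: SequenceDB) -> SuffixIndex:
    """Build the full index (sa, isa, sap) for a database."""
    sa = build_suffix_array(db.txt)
    return SuffixIndex(sa=sa, isa=build_isa(sa), sap=build_sap(sa, db), n=len(db.txt))


def _suffix_less(a: str, i: int, b: str, j: int, chunk: int = 32) -> bool:
    """True iff suffix ``a[i:]`` < suffix ``b[j:]``, compared in chunks.

    Chunked comparison avoids slicing out whole suffixes; typical calls
    resolve within the first chunk because common prefixes are short.
    """
    la, lb = len(a), len(b)
    while i < la and j < lb:
        ca = a[i : i + chunk]
        cb = b[j : j + chunk]
        if ca != cb:
            return ca < cb
        i += chunk
        j += chunk
    # one suffix exhausted: the shorter (a prefix of the other) sorts first
    return (la - i) < (lb - j)


def map_query_suffixes(
    db_index: SuffixIndex,
    db: SequenceDB,
    qdb: SequenceDB,
    q_sa: np.ndarray | None = None,
) -> QueryMapping:
    """Merge the query suffix order into the database suffix order.

    A two-pointer pass over the two sorted arrays assigns every query
    suffix its insertion rank.  A query suffix equal (as a string) to a
    database suffix receives that suffix's rank — exact matches sit at the
    left edge of the neighborhood window.
    """
    if q_sa is None:
        q_sa = build_suffix_array(qdb.txt)
    sa = db_index.sa
    n = len(sa)
    m = len(qdb.txt)
    isa_mapped = np.empty(m, dtype=np.int64)
    txt, qtxt = db.txt, qdb.txt
    a = 0  # database rank pointer
    for b in range(m):
        sq = int(q_sa[b])
        # advance while the database suffix sorts <= the query suffix
        while a < n and not _suffix_less(qtxt, sq, txt, int(sa[a])):
            a += 1
        isa_mapped[sq] = a - 1
    return QueryMapping(isa_mapped=isa_mapped, m=m)


def save_index(index: SuffixIndex, mapping: QueryMapping | None, directory: str | Path) -> None:
    """Persist index arrays: sap at 4 bytes/entry, isa_mapped at 8 bytes/entry."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index.sa.astype(np.int64).tofile(directory / "sa")
    index.sap.astype(np.int32).tofile(directory / "sap")
    if mapping is not None:
        mapping.isa_mapped.astype(np.int64).tofile(directory / "isa_mapped")


def load_index(directory: str | Path) -> tuple[SuffixIndex, QueryMapping | None]:
    """Load arrays persisted by :func:`save_index`; isa is rebuilt from sa."""
    directory = Path(directory)
    for name in ("sa", "sap"):
        if not (directory / name).exists():
            raise ValueError(f"missing index file: {directory / name}")
    sa = np.fromfile(directory / "sa", dtype=np.int64)
    sap = np.fromfile(directory / "sap", dtype=np.int32)
    if len(sap) != len(sa):
        raise ValueError(f"corrupted index: {directory / 'sap'} length mismatch")
    index = SuffixIndex(sa=sa, isa=build_isa(sa), sap=sap, n=len(sa))
    mapping = None
    if (directory / "isa_mapped").exists():
        isa_mapped = np.fromfile(directory / "isa_mapped", dtype=np.int64)
        mapping = QueryMapping(isa_mapped=isa_mapped, m=len(isa_mapped))
    return index, mapping
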