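"""The SANS score: suffix-array neighborhood co-occurrence counting.

For every unmasked suffix of a query protein, a window of ``W`` ranks on
each side of the suffix's insertion point in the database suffix order is
inspected, and every database protein labelling a rank in that window
earns one point.  Summed over all query suffixes this gives the SANS
score::

    score(qprot, sprot) = sum_{s_Q in qprot} sum_{j in window(s_Q)} id(sap[j], sprot)

with ``id(a, b) = 1`` if ``a == b`` else ``0``.  Proteins with long common
prefixes to many query suffixes accumulate high scores; the window size is
constant, so the per-query work is independent of database size.

Low-complexity query suffixes whose first residues look like a short
tandem repeat (identical characters at suffix positions 1,2,3 or 1,3,5)
are masked and contribute nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from sanslite.sequence_io import SequenceDB, db_from_records
from sanslite.suffix_index import QueryMapping, SuffixIndex, build_index, build_suffix_array, map_query_suffixes

__all__ = [
    "SearchParams",
    "Hit",
    "mask_query_suffixes",
    "sans_scores",
    "select_hits",
    "search",
]


@dataclass
class SearchParams:
    """Search knobs.

    W: window half-width (ranks inspected on each side of the insertion
    point; 2W per suffix). H: number of hits reported per query. By default
    W = H. T: optional score threshold replacing top-H selection.
    memory_limit: bytes of database text per section (sectioned search).
    """

    H: int = 100
    W: int | None = None
    T: int | None = None
    memory_limit: int | None = None

    def __post_init__(self) -> None:
        if self.W is None:
            self.W = self.H
        if self.W < 1 or self.H < 1:
            raise ValueError("W and H must be >= 1")


@dataclass
class Hit:
    """One ranked database match for a query protein."""

    query_id: str
    target_id: str
    rank: int
    score: int
    target_index: int = -1
    greedy_score: int | None = None


def mask_query_suffixes(qdb: SequenceDB) -> np.ndarray:
    """Boolean mask over query text offsets; ``True`` = suffix is ignored.

    A suffix is masked when its first residues form a short tandem repeat:
    the same character at suffix positions (1,2,3) or at (1,3,5), counted
    1-based from the suffix start.  Positions are only read within the
    suffix's own protein; a pattern applies when every position of it that
    exists carries the same character, so suffixes with fewer than three
    in-protein residues are degenerate (the 1,3,5 pattern is vacuous) and
    always masked.  Sentinel offsets are masked outright.
    """
    txt = np.frombuffer(qdb.txt.encode("ascii"), dtype=np.uint8)
    n = len(txt)
    # end[s] = offset one past the last residue of the protein owning s
    end = np.empty(n, dtype=np.int64)
    for i in range(qdb.n_proteins):
        end[qdb.start[i] : qdb.start[i + 1]] = qdb.start[i + 1] - 1
    avail = end - np.arange(n)  # residues from s to protein end; <=0 at sentinel

    def char(k: int) -> np.ndarray:
        c = np.zeros(n, dtype=np.uint8)
        if k < n:
            c[: n - k] = txt[k:]
        return c

    c0, c1, c2, c4 = txt, char(1), char(2), char(4)
    pat123 = ((avail < 2) | (c1 == c0)) & ((avail < 3) | (c2 == c0))
    pat135 = ((avail < 3) | (c2 == c0)) & ((avail < 5) | (c4 == c0))
    return (avail <= 0) | pat123 | pat135


def _window_counts(
    db_index: SuffixIndex,
    isa_mapped: np.ndarray,
    offsets: np.ndarray,
    W: int,
    n_proteins: int,
) -> np.ndarray:
    """Accumulate window label counts for the given query suffix offsets."""
    scores = np.zeros(n_proteins, dtype=np.int64)
    if len(offsets) == 0:
        return scores
    ell = isa_mapped[offsets]
    n = db_index.n
    # window ranks: l-W+1..l on the left, l+1..l+W on the right
    deltas = np.arange(-W + 1, W + 1, dtype=np.int64)
    ranks = ell[:, None] + deltas[None, :]
    ranks = ranks[(ranks >= 0) & (ranks < n)]
    np.add.at(scores, db_index.sap[ranks], 1)
    return scores


def sans_scores(
    db_index: SuffixIndex,
    mapping: QueryMapping,
    qdb: SequenceDB,
    qprot: int,
    params: SearchParams,
    mask: np.ndarray | None = None,
    n_proteins: int | None = None,
) -> np.ndarray:
    """SANS score of one query protein against every database protein.

    Returns an ``int64`` array indexed by database protein.  Out-of-range
    window ranks are discarded (windows shrink at the ends of the suffix
    order); sentinel-initial database suffixes inside a window credit the
    protein owning the sentinel.
    """
    if not 0 <= qprot < qdb.n_proteins:
        raise IndexError(f"query protein {qprot} out of range")
    if mask is None:
        mask = mask_query_suffixes(qdb)
    if n_proteins is None:
        n_proteins = int(db_index.sap.max()) + 1
    offsets = np.arange(qdb.start[qprot], qdb.start[qprot + 1] - 1, dtype=np.int64)
    offsets = offsets[~mask[offsets]]
    return _window_counts(db_index, mapping.isa_mapped, offsets, params.W, n_proteins)


def select_hits(
    scores: np.ndarray,
    params: SearchParams,
    db_ids: list[str],
    query_id: str,
) -> list[Hit]:
    """Top-H (or score >= T) selection, scores descending.

    Ties break toward the lower database protein index; zero-score proteins
    are never reported.
    """
    scores = np.asarray(scores)
    if params.T is not None:
        keep = np.flatnonzero(scores >= max(params.T, 1))
    else:
        keep = np.flatnonzero(scores > 0)
    order = keep[np.lexsort((keep, -scores[keep]))]
    if params.T is None:
        order = order[: params.H]
    return [
        Hit(query_id=query_id, target_id=db_ids[i], rank=r + 1, score=int(scores[i]), target_index=int(i))
        for r, i in enumerate(order)
    ]


def _sections(db: SequenceDB, memory_limit: int | None) -> list[tuple[int, int]]:
    """Split the database into runs of whole proteins fitting memory_limit."""
    if memory_limit is None:
        return [(0, db.n_proteins)]
    lengths = np.diff(db.start)
    if int(lengths.max()) > memory_limit:
        raise ValueError("memory_limit smaller than the largest single protein")
    sections = []
    lo = 0
    size = 0
    for i, ln in enumerate(lengths):
        if size + int(ln) > memory_limit and size > 0:
            sections.append((lo, i))
            lo, size = i, 0
        size += int(ln)
    sections.append((lo, db.n_proteins))
    return sections


def search(
    db: SequenceDB,
    qdb: SequenceDB,
    params: SearchParams,
) -> dict[str, list[Hit]]:
    """Full SANS search of a query set against a database.

    The database is processed in contiguous sections whose concatenated
    text fits ``params.memory_limit`` (one section when unset); each
    section gets its own suffix index and query mapping, window counts are
    accumulated into global per-protein scores, and top-H selection runs on
    the combined scores.  Windows never span section boundaries.
    """
    mask = mask_query_suffixes(qdb)
    q_sa = build_suffix_array(qdb.txt)
    totals = np.zeros((qdb.n_proteins, db.n_proteins), dtype=np.int64)
    for lo, hi in _sections(db, params.memory_limit):
        sec = db_from_records([(db.ids[i], db.sequence(i)) for i in range(lo, hi)])
        index = build_index(sec)
        mapping = map_query_suffixes(index, sec, qdb, q_sa=q_sa)
        for qprot in range(qdb.n_proteins):
            totals[qprot, lo:hi] += sans_scores(
                index, mapping, qdb, qprot, params, mask=mask, n_proteins=hi - lo
            )
    return {
        qdb.ids[qprot]: select_hits(totals[qprot], params, db.ids, qdb.ids[qprot])
        for qprot in range(qdb.n_proteins)
    }
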