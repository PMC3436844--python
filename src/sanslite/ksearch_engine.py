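"""KSEARCH: the fixed-word-length k-mer baseline.

A protein is summarised by its feature vector of k-mer occurrence counts;
two proteins are scored by the dot product of those vectors.  The word
length ``k`` trades selectivity against sensitivity (k = 6 is the default
sweet spot for protein-scale databases).  Implemented with an inverted
k-mer table over the database: per-query cost grows with the number of
database k-mer instances matched, unlike the constant-window SANS scan.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np

from sanslite.sequence_io import SequenceDB
from sanslite.sans_engine import Hit, SearchParams, mask_query_suffixes, select_hits

__all__ = ["kmer_vector", "ksearch_score", "ksearch_search", "DEFAULT_K"]

DEFAULT_K = 6


def kmer_vector(seq: str, k: int) -> dict[str, int]:
    """Occurrence counts of every length-``k`` substring of ``seq``.

    ``seq`` is a single protein (no sentinels).  A sequence shorter than
    ``k`` yields an empty vector.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return dict(Counter(seq[i : i + k] for i in range(len(seq) - k + 1)))


def ksearch_score(qvec: dict[str, int], dvec: dict[str, int], k: int | None = None) -> int:
    """Dot product of two k-mer count vectors over their shared support."""
    if qvec and dvec:
        ka = len(next(iter(qvec)))
        kb = len(next(iter(dvec)))
        if ka != kb:
            raise ValueError(f"mismatched word lengths: {ka} != {kb}")
    if len(qvec) > len(dvec):
        qvec, dvec = dvec, qvec
    return sum(c * dvec[m] for m, c in qvec.items() if m in dvec)


def _masked_kmer_counts(qdb: SequenceDB, qprot: int, k: int, mask: np.ndarray) -> Counter:
    """Query-side k-mer counts, skipping k-mers at masked suffix offsets."""
    lo, hi = int(qdb.start[qprot]), int(qdb.start[qprot + 1]) - 1
    counts: Counter = Counter()
    for s in range(lo, hi - k + 1):
        if not mask[s]:
            counts[qdb.txt[s : s + k]] += 1
    return counts


def ksearch_search(
    db: SequenceDB,
    qdb: SequenceDB,
    k: int = DEFAULT_K,
    params: SearchParams | None = None,
) -> dict[str, list[Hit]]:
    """Rank database proteins by k-mer dot product for every query protein.

    The tandem-repeat mask from the SANS engine is applied on the query
    side: a masked suffix suppresses exactly the k-mer starting at its
    offset.  Database vectors are unmasked.  Selection semantics (top-H,
    threshold, tie-breaks) match the SANS engine.
    """
    if params is None:
        params = SearchParams()
    # inverted table: k-mer -> {protein: count}
    table: dict[str, dict[int, int]] = defaultdict(dict)
    for i in range(db.n_proteins):
        for mer, c in kmer_vector(db.sequence(i), k).items():
            table[mer][i] = c
    mask = mask_query_suffixes(qdb)
    out: dict[str, list[Hit]] = {}
    for qprot in range(qdb.n_proteins):
        scores = np.zeros(db.n_proteins, dtype=np.int64)
        for mer, qc in _masked_kmer_counts(qdb, qprot, k, mask).items():
            for i, dc in table.get(mer, {}).items():
                scores[i] += qc * dc
        out[qdb.ids[qprot]] = select_hits(scores, params, db.ids, qdb.ids[qprot])
    return out
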