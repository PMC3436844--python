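"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — sort all suffix strings, count
windows by scanning, enumerate dense k-mer spaces, dynamic programming
over explicit HSP subchains — so the fast implementations are checked
against code that shares none of their machinery.
"""

from __future__ import annotations

import bisect

import numpy as np

from sanslite.sequence_io import SequenceDB, protein_of_position
from sanslite.sans_engine import mask_query_suffixes


def naive_suffix_array(txt: str) -> list[int]:
    """Sort all suffixes as plain strings."""
    return sorted(range(len(txt)), key=lambda i: txt[i:])


def bisect_isa_mapped(db: SequenceDB, qdb: SequenceDB) -> list[int]:
    """Per-suffix binary search of each query suffix into the sorted db suffixes."""
    suffixes = sorted(db.txt[i:] for i in range(len(db.txt)))
    return [bisect.bisect_right(suffixes, qdb.txt[s:]) - 1 for s in range(len(qdb.txt))]


def literal_mask(suffix_in_protein: str) -> bool:
    """Tandem-repeat mask applied literally to one within-protein suffix."""

    def pattern(positions: list[int]) -> bool:
        chars = [suffix_in_protein[i] for i in positions if i < len(suffix_in_protein)]
        return len(set(chars)) <= 1  # vacuously satisfied by short suffixes

    return len(suffix_in_protein) == 0 or pattern([0, 1, 2]) or pattern([0, 2, 4])


def brute_sans_scores(db: SequenceDB, qdb: SequenceDB, W: int) -> np.ndarray:
    """Window-counting oracle: sort suffixes, bisect each query suffix, count labels."""
    order = naive_suffix_array(db.txt)
    strings = [db.txt[i:] for i in order]
    mask = mask_query_suffixes(qdb)
    scores = np.zeros((qdb.n_proteins, db.n_proteins), dtype=np.int64)
    for qprot in range(qdb.n_proteins):
        for s in range(qdb.start[qprot], qdb.start[qprot + 1] - 1):
            if mask[s]:
                continue
            ell = bisect.bisect_right(strings, qdb.txt[s:]) - 1
            for j in range(ell - W + 1, ell + W + 1):
                if 0 <= j < len(order):
                    scores[qprot, protein_of_position(db, order[j])] += 1
    return scores


def dense_kmer_dot(a: str, b: str, k: int, alphabet: str) -> int:
    """Dot product over the full |alphabet|^k dense k-mer space."""
    import itertools

    def counts(seq: str) -> dict[str, int]:
        out: dict[str, int] = {}
        for i in range(len(seq) - k + 1):
            out[seq[i : i + k]] = out.get(seq[i : i + k], 0) + 1
        return out

    ca, cb = counts(a), counts(b)
    return sum(
        ca.get(m, 0) * cb.get(m, 0) for m in ("".join(t) for t in itertools.product(alphabet, repeat=k))
    )


def best_segment_on_diagonal(q: str, s: str, d: int, matrix: np.ndarray) -> tuple[int, int, int]:
    """Maximum-scoring contiguous segment on one diagonal (exhaustive).

    Returns (q_start, q_end, score) of the best half-open segment.
    """
    lo = max(0, d)
    hi = min(len(q), len(s) + d)
    best = (lo, lo, 0)
    for a in range(lo, hi):
        total = 0
        for b in range(a, hi):
            total += int(matrix[ord(q[b]), ord(s[b - d])])
            if total > best[2]:
                best = (a, b + 1, total)
    return best


def optimal_chain_score(hsps) -> int:
    """Optimal colinear non-overlapping chain score by dynamic programming.

    Any pairwise-compatible HSP set is totally ordered by the strictly-before
    relation, so the optimum is a maximum-weight path in that partial order.
    """
    hs = sorted(hsps, key=lambda h: (h.q_start, h.s_start))
    best = [0] * len(hs)
    for i, h in enumerate(hs):
        prior = 0
        for j in range(i):
            g = hs[j]
            if g.q_end <= h.q_start and g.s_end <= h.s_start:
                prior = max(prior, best[j])
        best[i] = prior + h.score
    return max(best, default=0)


def average_precision(ranked: list[str], true_set: set[str]) -> float:
    """Flat recomputation of average precision for a ranked target list."""
    tp = 0
    total = 0.0
    for p, t in enumerate(ranked, start=1):
        if t in true_set:
            tp += 1
            total += tp / p
    return total / len(true_set)


def random_db(rng, n_max: int = 8, len_max: int = 30, alphabet: str = "ACDE") -> SequenceDB:
    """Small random database for property tests."""
    from sanslite.sequence_io import db_from_records

    n = rng.randint(1, n_max)
    return db_from_records(
        [
            (f"p{i}", "".join(rng.choice(alphabet) for _ in range(rng.randint(1, len_max))))
            for i in range(n)
        ]
    )
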