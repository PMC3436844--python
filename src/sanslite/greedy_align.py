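"""Greedy ungapped alignment for rescoring retrieval hit lists.

The procedure mirrors the first stage of seeded alignment heuristics: scan
the query for diagonals carrying two nearby exact 3-mer matches (start
distance 3..40), extend each two-hit seed without gaps in both directions
under an x-drop stopping rule, score segments with BLOSUM62, and finally
pick a compatible (colinear, non-overlapping) subset of the HSPs in
descending score order.  The sum of the selected HSP scores — no gap
penalties — is the greedy alignment score used to rerank hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

from sanslite.sans_engine import Hit
from sanslite.sequence_io import SequenceDB

__all__ = [
    "HSP",
    "Seed",
    "GreedyAlignment",
    "load_matrix",
    "find_two_hit_seeds",
    "extend_hsp",
    "chain_hsps",
    "scan_hsps",
    "greedy_align_pair",
    "rescore_hits",
]

SEED_LEN = 3
MAX_SEED_DIST = 40  # start-to-start distance limit for the two 3-mer hits
DEFAULT_XDROP = 20  # raw BLOSUM62 score units


@dataclass(frozen=True)
class Seed:
    """A two-hit seed: query span covering both 3-mer matches on one diagonal."""

    diagonal: int
    q_start: int
    q_end: int


@dataclass
class HSP:
    """Ungapped high-scoring segment pair (half-open coordinates)."""

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: int

    @property
    def diagonal(self) -> int:
        return self.q_start - self.s_start


@dataclass
class GreedyAlignment:
    """A colinear, non-overlapping HSP chain; score = plain sum of members."""

    hsps: list[HSP] = field(default_factory=list)

    @property
    def total_score(self) -> int:
        return sum(h.score for h in self.hsps)


_MATRIX_CACHE: dict[str, np.ndarray] = {}


def _as_lookup(m) -> np.ndarray:
    """Dense 128x128 int lookup table from a Biopython substitution matrix."""
    table = np.zeros((128, 128), dtype=np.int64)
    letters = [c for c in m.alphabet if ord(c) < 128]
    for a in letters:
        for b in letters:
            table[ord(a), ord(b)] = int(m[a, b])
    return table


def load_matrix(path: str | Path | None = None) -> np.ndarray:
    """BLOSUM62 by default, or any NCBI-format matrix file, as a lookup table."""
    if path is None:
        if "BLOSUM62" not in _MATRIX_CACHE:
            _MATRIX_CACHE["BLOSUM62"] = _as_lookup(substitution_matrices.load("BLOSUM62"))
        return _MATRIX_CACHE["BLOSUM62"]
    return _as_lookup(substitution_matrices.read(str(path)))


def _kmer_positions(s: str, k: int = SEED_LEN) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for j in range(len(s) - k + 1):
        pos.setdefault(s[j : j + k], []).append(j)
    return pos


def find_two_hit_seeds(q: str, s: str, max_dist: int = MAX_SEED_DIST) -> list[Seed]:
    """All two-hit seeds between ``q`` and ``s``.

    Scanning the query left to right, the last 3-mer hit on each diagonal
    is remembered; a new hit at start distance in [3, max_dist] from it
    emits a seed.  Hits closer than 3 overlap the previous hit and are
    treated as the same hit; hits farther than max_dist restart the
    diagonal.
    """
    spos = _kmer_positions(s)
    last: dict[int, int] = {}
    seeds: list[Seed] = []
    for i in range(len(q) - SEED_LEN + 1):
        for j in spos.get(q[i : i + SEED_LEN], ()):
            d = i - j
            prev = last.get(d)
            if prev is None:
                last[d] = i
            elif i - prev < SEED_LEN:
                continue  # overlapping: counts as one hit
            elif i - prev <= max_dist:
                seeds.append(Seed(diagonal=d, q_start=prev, q_end=i + SEED_LEN))
                last[d] = i
            else:
                last[d] = i
    return seeds


def _segment_score(q: str, s: str, qa: int, qb: int, d: int, matrix: np.ndarray) -> int:
    total = 0
    for i in range(qa, qb):
        total += int(matrix[ord(q[i]), ord(s[i - d])])
    return total


def extend_hsp(
    q: str,
    s: str,
    seed: Seed,
    matrix: np.ndarray | None = None,
    xdrop: int = DEFAULT_XDROP,
    stats: dict | None = None,
) -> HSP:
    """Ungapped x-drop extension of a seed, trimmed to the best extent.

    In each direction the running score is accumulated one diagonal step at
    a time; extension stops once it falls more than ``xdrop`` below its
    running maximum, and the segment end is placed at that maximum.  When
    ``stats`` is given, the counter ``stats['ext_steps']`` accumulates the
    number of extension iterations performed (work, not final extent).
    """
    if matrix is None:
        matrix = load_matrix()
    d = seed.diagonal
    steps = seed.q_end - seed.q_start
    score = _segment_score(q, s, seed.q_start, seed.q_end, d, matrix)
    # right extension
    run = 0
    best = 0
    qb = seed.q_end
    i = seed.q_end
    while i < len(q) and i - d < len(s):
        steps += 1
        run += int(matrix[ord(q[i]), ord(s[i - d])])
        if run > best:
            best, qb = run, i + 1
        elif run < best - xdrop:
            break
        i += 1
    score += best
    # left extension
    run = 0
    bestl = 0
    qa = seed.q_start
    i = seed.q_start - 1
    while i >= 0 and i - d >= 0:
        steps += 1
        run += int(matrix[ord(q[i]), ord(s[i - d])])
        if run > bestl:
            bestl, qa = run, i
        elif run < bestl - xdrop:
            break
        i -= 1
    score += bestl
    if stats is not None:
        stats["ext_steps"] = stats.get("ext_steps", 0) + steps
        stats["extend_calls"] = stats.get("extend_calls", 0) + 1
    return HSP(q_start=qa, q_end=qb, s_start=qa - d, s_end=qb - d, score=score)


def _compatible(a: HSP, b: HSP) -> bool:
    before = a.q_end <= b.q_start and a.s_end <= b.s_start
    after = a.q_start >= b.q_end and a.s_start >= b.s_end
    return before or after


def chain_hsps(hsps: list[HSP]) -> GreedyAlignment:
    """Greedy compatible-set selection in descending score order.

    An HSP joins the chain only if it lies strictly before or strictly
    after every already-selected HSP in both query and subject coordinates
    (a sequential, non-overlapping alignment).  Non-positive HSPs are
    dropped first.
    """
    chosen: list[HSP] = []
    for h in sorted((h for h in hsps if h.score > 0), key=lambda h: (-h.score, h.q_start, h.s_start)):
        if all(_compatible(h, t) for t in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.q_start)
    return GreedyAlignment(hsps=chosen)


def scan_hsps(
    q: str,
    s: str,
    matrix: np.ndarray | None = None,
    xdrop: int = DEFAULT_XDROP,
    max_dist: int = MAX_SEED_DIST,
    stats: dict | None = None,
) -> list[HSP]:
    """Collect HSPs by scanning the query for two-hit seeds left to right.

    Each accepted HSP makes the scan jump past its end, so 3-mers inside an
    HSP are never retested.  With a ``stats`` dict, ``scan_steps`` and
    ``ext_steps`` count the query positions visited and the extension
    iterations spent — a wall-clock proxy showing that near-identical pairs
    (one long HSP, one jump) cost less than distant ones (many scan
    positions and restarted extensions).
    """
    if matrix is None:
        matrix = load_matrix()
    spos = _kmer_positions(s)
    last: dict[int, int] = {}
    hsps: list[HSP] = []
    i = 0
    limit = len(q) - SEED_LEN + 1
    while i < limit:
        if stats is not None:
            stats["scan_steps"] = stats.get("scan_steps", 0) + 1
        hsp = None
        for j in spos.get(q[i : i + SEED_LEN], ()):
            d = i - j
            prev = last.get(d)
            if prev is None or i - prev > max_dist:
                last[d] = i
                continue
            if i - prev < SEED_LEN:
                continue
            last[d] = i
            cand = extend_hsp(q, s, Seed(d, prev, i + SEED_LEN), matrix, xdrop, stats=stats)
            if cand.score > 0:
                hsp = cand
                break
        if hsp is not None:
            hsps.append(hsp)
            i = hsp.q_end  # jump past the accepted HSP
        else:
            i += 1
    return hsps


def greedy_align_pair(
    q: str,
    s: str,
    matrix: np.ndarray | None = None,
    xdrop: int = DEFAULT_XDROP,
    max_dist: int = MAX_SEED_DIST,
    stats: dict | None = None,
) -> GreedyAlignment:
    """Greedy approximate alignment: scan for HSPs, then chain them."""
    return chain_hsps(scan_hsps(q, s, matrix, xdrop, max_dist, stats))


def rescore_hits(
    hits: dict[str, list[Hit]],
    db: SequenceDB,
    qdb: SequenceDB,
    keep: int,
    matrix: np.ndarray | None = None,
    xdrop: int = DEFAULT_XDROP,
) -> dict[str, list[Hit]]:
    """Rerank each query's hit list by greedy alignment score.

    Hits with no seeds score 0 and sink below every aligned hit; ties fall
    back to the original retrieval score, then the database index.  The
    reranked list is truncated to ``keep`` entries.
    """
    if matrix is None:
        matrix = load_matrix()
    qindex = {qid: i for i, qid in enumerate(qdb.ids)}
    out: dict[str, list[Hit]] = {}
    for qid, hitlist in hits.items():
        qseq = qdb.sequence(qindex[qid])
        rescored = []
        for h in hitlist:
            g = greedy_align_pair(qseq, db.sequence(h.target_index), matrix, xdrop).total_score
            rescored.append(
                Hit(
                    query_id=qid,
                    target_id=h.target_id,
                    rank=0,
                    score=h.score,
                    target_index=h.target_index,
                    greedy_score=g,
                )
            )
        rescored.sort(key=lambda h: (-(h.greedy_score or 0), -h.score, h.target_index))
        out[qid] = [
            Hit(h.query_id, h.target_id, r + 1, h.score, h.target_index, h.greedy_score)
            for r, h in enumerate(rescored[: max(keep, 0)])
        ]
    return out
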