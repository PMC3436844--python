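"""Retrieval evaluation: precision, recall, per-query AUC, binned sensitivity.

Given a ranked hit list for a query and a truth set of acceptable targets,
precision = TP/P and recall = TP/T where P is the number of hits
considered, TP the true hits among them and T the truth-set size.  The
area under the per-query precision-recall curve is computed as average
precision (a step function gaining area at each newly recovered true hit),
so a ranking that lists exactly the truth set first scores 1 and a ranking
with no true hit scores 0.  Method comparison uses the mean AUC over
queries and, at a fixed reporting depth, sensitivity ratios within bins of
pairwise sequence identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["TruthSet", "PRCurve", "load_truth", "pr_curve", "mean_auc", "binned_sensitivity"]


@dataclass
class TruthSet:
    """True target sets per query, with optional per-pair identity percent."""

    targets: dict[str, set[str]]
    identity: dict[tuple[str, str], float] = field(default_factory=dict)

    def __contains__(self, query: str) -> bool:
        return query in self.targets


@dataclass
class PRCurve:
    """Precision-recall points at each rank plus the average-precision AUC."""

    points: list[tuple[int, int, float, float]]  # (P, TP, precision, recall)
    auc: float


def load_truth(path: str | Path) -> TruthSet:
    """Read a tab-separated truth file: query_id, target_id[, identity%]."""
    targets: dict[str, set[str]] = {}
    identity: dict[tuple[str, str], float] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        q, t = parts[0], parts[1]
        targets.setdefault(q, set()).add(t)
        if len(parts) > 2 and parts[2]:
            identity[(q, t)] = float(parts[2])
    return TruthSet(targets=targets, identity=identity)


def pr_curve(ranked_targets: list[str], truth: TruthSet, query: str) -> PRCurve | None:
    """Precision-recall curve and AUC for one query's ranked target list.

    AUC is average precision: the sum over each new true positive of the
    precision at its rank, divided by the truth-set size.  Queries absent
    from the truth are skipped (returns ``None`` with a warning).
    """
    if query not in truth:
        warnings.warn(f"query {query!r} absent from truth; skipped")
        return None
    true_set = truth.targets[query]
    t_true = len(true_set)
    points = []
    tp = 0
    ap = 0.0
    for p, target in enumerate(ranked_targets, start=1):
        if target in true_set:
            tp += 1
            ap += tp / p
        points.append((p, tp, tp / p, tp / t_true))
    auc = min(max(ap / t_true, 0.0), 1.0)
    return PRCurve(points=points, auc=auc)


def mean_auc(curves: list[PRCurve | float]) -> float:
    """Arithmetic mean of per-query AUC values."""
    if not curves:
        raise ValueError("no curves to average")
    vals = [c.auc if isinstance(c, PRCurve) else float(c) for c in curves]
    return sum(vals) / len(vals)


def _bin_label(identity: float, edges: list[float]) -> int:
    """Bin index for an identity percentage given interior edges."""
    for b, e in enumerate(edges):
        if identity < e:
            return b
    return len(edges)


def bin_name(b: int, edges: list[float]) -> str:
    if b == 0:
        return f"<{edges[0]:g}"
    if b == len(edges):
        return f">={edges[-1]:g}"
    return f"{edges[b - 1]:g}-{edges[b]:g}"


def binned_sensitivity(
    method_hits: dict[str, list[str]],
    reference_hits: dict[str, list[str]],
    truth: TruthSet,
    edges: list[float] = (30.0, 50.0, 70.0, 90.0),
) -> dict[str, float | None]:
    """Per-identity-bin sensitivity of a method relative to a reference.

    Both hit dictionaries map query id to the targets it reported (already
    cut to the same depth).  For each bin of pairwise identity, sensitivity
    is the fraction of true pairs in the bin that were recovered; the
    returned value is method sensitivity divided by reference sensitivity.
    Bins with no true pairs, or where the reference recovers nothing, are
    reported as ``None``.
    """
    edges = list(edges)
    method_hits = {q: set(v) for q, v in method_hits.items()}
    reference_hits = {q: set(v) for q, v in reference_hits.items()}
    n_bins = len(edges) + 1
    total = [0] * n_bins
    got_m = [0] * n_bins
    got_r = [0] * n_bins
    for (q, t), ident in truth.identity.items():
        if t not in truth.targets.get(q, ()):  # identity rows must be true pairs
            continue
        b = _bin_label(ident, edges)
        total[b] += 1
        if t in method_hits.get(q, ()):
            got_m[b] += 1
        if t in reference_hits.get(q, ()):
            got_r[b] += 1
    out: dict[str, float | None] = {}
    for b in range(n_bins):
        name = bin_name(b, edges)
        if total[b] == 0 or got_r[b] == 0:
            out[name] = None
        else:
            out[name] = (got_m[b] / total[b]) / (got_r[b] / total[b])
    return out
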