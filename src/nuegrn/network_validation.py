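"""Validation of a ranked edge list against gold-standard edges.

Given experimentally validated TF->target edges over a defined assayed
universe (by default, the assayed TFs crossed with every target of the
predicted network), the ranked predictions restricted to that universe
yield a precision/recall curve; its step-function area (AUPR) is
compared against a label-permutation null; a precision target picks the
deepest curve point still meeting it, whose weight becomes the pruning
threshold applied to the *whole* network (assayed and unassayed TFs
alike).  Set-level precision/recall/F-score compare arbitrary predicted
and reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError
from .grn_inference import EdgeList

__all__ = [
    "GoldStandard",
    "PRCurve",
    "PruneResult",
    "precision_recall_curve",
    "aupr",
    "permutation_test_aupr",
    "select_threshold",
    "prune_network",
    "prf_scores",
]


@dataclass
class GoldStandard:
    """Validated TF->target edges over the (tf, target) pairs that were testable."""

    validated_edges: set[tuple[str, str]]
    assayed_tfs: set[str]
    assayed_universe: set[tuple[str, str]] | None = None
    dataset_labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.assayed_tfs:
            raise DataError("assayed_tfs must be nonempty")
        if self.assayed_universe is not None:
            extra = self.validated_edges - self.assayed_universe
            if extra:
                raise DataError(
                    f"validated edges outside assayed universe: {sorted(extra)[:3]}"
                )

    def universe_for(self, edges: EdgeList) -> set[tuple[str, str]]:
        """The assayed universe, defaulting to assayed_tfs x predicted targets."""
        if self.assayed_universe is not None:
            return self.assayed_universe
        targets = set(edges.edges["target"])
        return {
            (tf, t) for tf in self.assayed_tfs for t in targets if t != tf
        }


@dataclass
class PRCurve:
    """Cumulative precision/recall along the ranked assayed edges."""

    points: pd.DataFrame  # columns: rank, weight, tp, precision, recall
    n_validated: int


def precision_recall_curve(edges: EdgeList, gold: GoldStandard) -> PRCurve:
    """Precision and recall at every rank of the assayed predictions.

    Predictions are first restricted to the assayed universe; at rank k,
    precision = tp_k / k and recall = tp_k / |validated|.
    """
    universe = gold.universe_for(edges)
    validated = gold.validated_edges & universe
    if not validated:
        raise DataError("no validated edges within the assayed universe")
    df = edges.edges
    mask = [
        (r, t) in universe for r, t in zip(df["regulator"], df["target"])
    ]
    sub = df.loc[mask].reset_index(drop=True)
    if sub.empty:
        raise DataError("no predicted edge lies in the assayed universe")
    hits = np.array(
        [(r, t) in validated for r, t in zip(sub["regulator"], sub["target"])],
        dtype=bool,
    )
    tp = np.cumsum(hits)
    rank = np.arange(1, len(sub) + 1)
    points = pd.DataFrame(
        {
            "rank": rank,
            "weight": sub["weight"].to_numpy(),
            "tp": tp,
            "precision": tp / rank,
            "recall": tp / len(validated),
        }
    )
    return PRCurve(points=points, n_validated=len(validated))


def aupr(curve: PRCurve) -> float:
    """Step-function area under precision as a function of recall.

    Sums precision_k * delta(recall) over the ranks where recall
    increases (i.e. over true positives); equals the average precision
    of the validated edges found.
    """
    pts = curve.points
    if pts.empty:
        raise DataError("empty precision/recall curve")
    d_recall = np.diff(pts["recall"].to_numpy(), prepend=0.0)
    return float(np.sum(pts["precision"].to_numpy() * d_recall))


def _aupr_from_labels(labels: np.ndarray, n_validated: int) -> float:
    tp = np.cumsum(labels)
    rank = np.arange(1, len(labels) + 1)
    precision = tp / rank
    d_recall = np.diff(tp / n_validated, prepend=0.0)
    return float(np.sum(precision * d_recall))


def permutation_test_aupr(
    edges: EdgeList,
    gold: GoldStandard,
    n_perm: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Permutation p-value for the observed AUPR.

    Validated labels are reassigned uniformly at random over the
    assayed-universe predictions (preserving their count) and the AUPR
    recomputed; p uses the add-one estimator.  Returns
    ``(p, min_permuted_aupr, max_permuted_aupr)``.
    """
    if n_perm < 1:
        raise DataError("n_perm must be >= 1")
    curve = precision_recall_curve(edges, gold)
    observed = aupr(curve)
    hits = curve.points["tp"].to_numpy()
    labels = np.diff(hits, prepend=0).astype(bool)
    n_val = int(labels.sum())
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_perm)
    m = len(labels)
    for i in range(n_perm):
        perm = np.zeros(m, dtype=bool)
        perm[rng.choice(m, size=n_val, replace=False)] = True
        permuted[i] = _aupr_from_labels(perm, curve.n_validated)
    p = (1 + int((permuted >= observed).sum())) / (1 + n_perm)
    return float(p), float(permuted.min()), float(permuted.max())


def select_threshold(curve: PRCurve, precision_target: float) -> float:
    """Weight at the deepest rank whose precision still meets the target.

    Scanning ranks in increasing order, the largest rank k* with
    precision_{k*} >= precision_target is found; the weight at k* is the
    pruning threshold.  Raises (reporting the maximum achievable
    precision) when no rank qualifies.
    """
    if not 0 < precision_target <= 1:
        raise DataError("precision_target must be in (0, 1]")
    pts = curve.points
    ok = pts["precision"] >= precision_target
    if not ok.any():
        raise DataError(
            "precision target "
            f"{precision_target} unattainable; maximum precision is "
            f"{pts['precision'].max():.4f}"
        )
    k_star = int(pts.index[ok][-1])
    return float(pts.loc[k_star, "weight"])


@dataclass
class PruneResult:
    """The network surviving a weight threshold, with its summary counts."""

    precision_target: float | None
    weight_threshold: float
    pruned_edges: EdgeList
    n_edges: int
    n_tfs: int
    n_targets: int

    def targets_of(self, tf: str) -> set[str]:
        df = self.pruned_edges.edges
        return set(df.loc[df["regulator"] == tf, "target"])

    def tfs(self) -> list[str]:
        return sorted(set(self.pruned_edges.edges["regulator"]))


def prune_network(
    all_edges: EdgeList,
    weight_threshold: float,
    precision_target: float | None = None,
) -> PruneResult:
    """Keep every edge (all TFs, validated or not) with weight >= threshold."""
    if weight_threshold < 0:
        raise DataError("weight_threshold must be >= 0")
    df = all_edges.edges
    kept = df.loc[df["weight"] >= weight_threshold].reset_index(drop=True)
    return PruneResult(
        precision_target=precision_target,
        weight_threshold=float(weight_threshold),
        pruned_edges=EdgeList(kept),
        n_edges=len(kept),
        n_tfs=kept["regulator"].nunique(),
        n_targets=kept["target"].nunique(),
    )


def prf_scores(predicted, reference) -> tuple[float, float, float]:
    """Set-level precision, recall and F-score of predicted vs reference.

    Empty predictions yield (0, 0, 0); an empty reference is an error.
    """
    P, R = set(predicted), set(reference)
    if not R:
        raise DataError("reference set must be nonempty")
    if not P:
        return (0.0, 0.0, 0.0)
    tp = len(P & R)
    precision = tp / len(P)
    recall = tp / len(R)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return (precision, recall, f)
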