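"""Tree-ensemble gene regulatory network inference (GENIE3-style).

For every target gene, an ensemble of regression trees predicts the
target's standardized expression from the standardized expression of the
candidate regulators (the TF list, minus the target itself when the
target is a TF).  The weight of the edge TF -> target is the total
variance-reduction importance of that TF accumulated over all trees,
divided by the number of trees.  Concatenating all targets and sorting
by weight yields a globally ranked edge list with no self-edges.

The default ensemble is extremely randomized trees with sqrt candidate
regulators per split, matching the randomized-tree family the original
method ships; bagged random forests are available via
``tree_method="RF"``.  Per-gene standardization makes importances
comparable across targets.  Results are deterministic for a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor, ExtraTreeRegressor

from ._errors import ConfigurationError, DataError
from .expression import ExpressionMatrix

__all__ = ["InferenceConfig", "EdgeList", "infer_grn", "expected_edge_count"]


@dataclass
class InferenceConfig:
    """Parameters of the tree-ensemble inference."""

    n_trees: int = 1000
    candidate_regulators_per_split: str | int = "sqrt"  # "sqrt", "all", or fixed k
    tree_method: str = "ET"  # "ET" (extra-trees) or "RF" (random forest)
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")
        if self.tree_method not in ("ET", "RF"):
            raise ConfigurationError("tree_method must be 'ET' or 'RF'")
        k = self.candidate_regulators_per_split
        if not (k in ("sqrt", "all") or (isinstance(k, int) and k >= 1)):
            raise ConfigurationError(
                "candidate_regulators_per_split must be 'sqrt', 'all' or a"
                " positive integer"
            )


@dataclass
class EdgeList:
    """Globally ranked TF->target edges.

    ``edges`` has columns ``regulator, target, weight`` and is sorted by
    decreasing weight with ties broken by (regulator, target) id order,
    so the ranking is total and reproducible.
    """

    edges: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["regulator", "target", "weight"]
        if list(self.edges.columns[:3]) != required:
            raise DataError(f"edge list must have columns {required}")
        if (self.edges["regulator"] == self.edges["target"]).any():
            raise DataError("self-edges are not allowed")
        if (self.edges["weight"] < 0).any():
            raise DataError("edge weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.edges)

    @staticmethod
    def from_records(records) -> "EdgeList":
        df = pd.DataFrame(records, columns=["regulator", "target", "weight"])
        return EdgeList(_sort_edges(df))


def _sort_edges(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["weight", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)


def expected_edge_count(tf_list, target_list) -> int:
    """Number of TF->target edges excluding self-regulation.

    ``|TFs| * |targets| - |TFs intersect targets|``; e.g. 90 TFs that are
    all among 10,815 targets give 90*10815 - 90 = 973,260 edges.
    """
    tfs, targets = set(tf_list), set(target_list)
    return len(tfs) * len(targets) - len(tfs & targets)


def _max_features(k, n_features: int):
    if k == "sqrt":
        return max(1, int(np.sqrt(n_features)))
    if k == "all":
        return n_features
    return min(int(k), n_features)


def infer_grn(
    expr: ExpressionMatrix,
    tf_list,
    target_list,
    config: InferenceConfig | None = None,
) -> EdgeList:
    """Infer a ranked TF->target edge list from expression data.

    Both gene lists must be rows of ``expr``; at least two TFs are
    required so every target (including TF targets, which exclude only
    themselves) has candidate regulators.  Zero-variance targets are
    skipped with a warning.
    """
    config = config or InferenceConfig()
    config.validate()
    tfs = sorted(set(tf_list))
    targets = sorted(set(target_list))
    if len(tfs) < 2:
        raise DataError("need at least 2 TFs (no split candidates otherwise)")
    missing = (set(tfs) | set(targets)) - set(expr.gene_ids)
    if missing:
        raise DataError(f"genes absent from expression matrix: {sorted(missing)[:5]}")

    x = np.asarray(expr.values.loc[tfs], dtype=float).T  # samples x TFs
    y_all = np.asarray(expr.values.loc[targets], dtype=float)  # targets x samples
    sd_x = x.std(axis=0)
    if np.any(sd_x == 0):
        bad = tfs[int(np.flatnonzero(sd_x == 0)[0])]
        raise DataError(f"zero-variance TF: {bad}")
    # float32 regressors: the tree backend's native dtype, fitted with
    # input checks off since standardization already produced clean arrays
    xs = np.ascontiguousarray((x - x.mean(axis=0)) / sd_x, dtype=np.float32)

    tf_index = {tf: i for i, tf in enumerate(tfs)}
    n_samples = xs.shape[0]
    records = []
    for t_idx, target in enumerate(targets):
        y = y_all[t_idx]
        sd = y.std()
        if sd == 0:
            warnings.warn(f"target {target} has zero variance; skipped")
            continue
        ys = np.ascontiguousarray((y - y.mean()) / sd, dtype=np.float64)
        if target in tf_index:
            cols = [i for i, tf in enumerate(tfs) if tf != target]
        else:
            cols = list(range(len(tfs)))
        xt = np.ascontiguousarray(xs[:, cols])
        k = _max_features(config.candidate_regulators_per_split, len(cols))
        rs = np.random.RandomState((config.seed * 1_000_003 + t_idx) % (2**31 - 1))
        imp = np.zeros(len(cols))
        for _ in range(config.n_trees):
            if config.tree_method == "ET":
                tree = ExtraTreeRegressor(max_features=k, random_state=rs)
                tree.fit(xt, ys, check_input=False)
            else:  # bagged random forest
                idx = rs.randint(n_samples, size=n_samples)
                tree = DecisionTreeRegressor(max_features=k, random_state=rs)
                tree.fit(
                    np.ascontiguousarray(xt[idx]), ys[idx], check_input=False
                )
            # Total variance-reduction importance (unnormalized, unlike
            # sklearn's feature_importances_), averaged over trees below.
            imp += tree.tree_.compute_feature_importances(normalize=False)
        imp /= config.n_trees
        for c, w in zip(cols, imp):
            records.append((tfs[c], target, float(w)))
    return EdgeList.from_records(records)
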