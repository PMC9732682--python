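"""Weighted co-expression module detection and trait correlation.

The workflow mirrors the classical weighted gene co-expression analysis:
replicate averaging, soft-threshold adjacency ``|cor|^beta`` chosen for
approximate scale-free topology, topological overlap (TOM) similarity,
average-linkage hierarchical module detection, module eigengenes (first
principal component of each module), eigengene-based module merging at a
dissimilarity threshold (default 0.5), module--trait correlation with
Student-t p-values, per-gene Gene Significance (GS, gene--trait
correlation) and Module Membership (MM, gene--eigengene correlation),
and the above-average ``|GS| and |MM|`` hub-gene filter.

The network is unsigned (absolute correlations) and Pearson correlation
is used throughout.  Branch cutting is a static height cut with a
minimum module size; small clusters are assigned the reserved label
``grey``.  Module labels are deterministic, ordered by decreasing size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._errors import DataError
from .expression import ExpressionMatrix

__all__ = [
    "ModuleSet",
    "CorrelationStats",
    "average_replicates",
    "pick_soft_power",
    "adjacency",
    "tom_similarity",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "gene_trait_stats",
    "filter_hub_genes",
]

GREY = "grey"


@dataclass
class ModuleSet:
    """Gene->module assignment plus eigengenes and the merge history."""

    labels: dict[str, str]
    eigengenes: pd.DataFrame | None = None  # samples x modules
    merge_log: list[tuple[str, str, float]] = field(default_factory=list)

    def modules(self) -> list[str]:
        """Non-grey module names, by decreasing size then name."""
        sizes: dict[str, int] = {}
        for g, m in self.labels.items():
            if m != GREY:
                sizes[m] = sizes.get(m, 0) + 1
        return sorted(sizes, key=lambda m: (-sizes[m], m))

    def genes_of(self, module: str) -> list[str]:
        return [g for g, m in self.labels.items() if m == module]


@dataclass
class CorrelationStats:
    """Module--trait and gene-level correlation statistics."""

    module_trait_cor: pd.DataFrame | None = None  # modules x traits
    module_trait_p: pd.DataFrame | None = None
    gs: pd.DataFrame | None = None  # genes x traits (signed)
    mm: pd.DataFrame | None = None  # genes x modules (signed)


def average_replicates(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicate columns into one column per variety x condition.

    The output sample ids are ``<variety>_<COND>`` (e.g. ``V01_HWHN``);
    with 19 varieties and 4 conditions this yields the 76-column matrix
    the module analysis operates on.
    """
    if expr.metadata is None:
        raise DataError("average_replicates requires sample metadata")
    meta = expr.metadata
    wlab = meta["w_level"].map({"high": "HW", "low": "LW"})
    nlab = meta["n_level"].map({"high": "HN", "low": "LN"})
    cell = meta["variety"].astype(str) + "_" + wlab + nlab
    averaged = expr.values.T.groupby(cell.values, sort=False).mean().T
    new_meta = pd.DataFrame(
        {
            "variety": meta.groupby(cell.values, sort=False)["variety"].first(),
            "n_level": meta.groupby(cell.values, sort=False)["n_level"].first(),
            "w_level": meta.groupby(cell.values, sort=False)["w_level"].first(),
            "replicate": 0,
        }
    )
    new_meta.index.name = "sample_id"
    return ExpressionMatrix(averaged, new_meta.loc[averaged.columns])


def _correlation_matrix(values: np.ndarray) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DataError(f"zero-variance gene at row {bad}; remove constant genes")
    c = np.corrcoef(values)
    return np.clip(c, -1.0, 1.0)


def adjacency(expr: ExpressionMatrix, power: int) -> pd.DataFrame:
    """Unsigned soft-threshold adjacency ``a_ij = |cor(x_i, x_j)|^power``."""
    if power < 1:
        raise DataError("power must be >= 1")
    values = np.asarray(expr.values, dtype=float)
    sd = values.std(axis=1)
    if np.any(sd == 0):
        gene = expr.gene_ids[int(np.flatnonzero(sd == 0)[0])]
        raise DataError(f"zero-variance gene: {gene}")
    a = np.abs(_correlation_matrix(values)) ** power
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=expr.values.index, columns=expr.values.index)


def pick_soft_power(
    expr: ExpressionMatrix,
    candidate_powers=tuple(range(1, 13)),
    r2_target: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    For each candidate power, gene connectivities ``k_i = sum_j |cor|^beta``
    are binned, and log10(frequency) is regressed on log10(mean k per
    bin); the signed R^2 (negated when the slope is positive) measures
    scale-free fit.  Returns the smallest power whose signed R^2 reaches
    ``r2_target`` together with the per-power fit table; if none
    qualifies, the power with the best signed R^2 is returned with a
    warning.
    """
    candidate_powers = list(candidate_powers)
    if not candidate_powers or any(p < 1 for p in candidate_powers):
        raise DataError("candidate_powers must be nonempty positive integers")
    values = np.asarray(expr.values, dtype=float)
    abs_cor = np.abs(_correlation_matrix(values))
    rows = []
    for beta in candidate_powers:
        a = abs_cor**beta
        k = a.sum(axis=1) - 1.0  # exclude self
        if np.ptp(k) <= 1e-10 * max(1.0, float(np.abs(k).max())):
            raise DataError(
                f"degenerate connectivity at power {beta}: all genes identical"
            )
        counts, edges = np.histogram(k, bins=n_bins)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ok = counts > 0
        if ok.sum() < 3:
            raise DataError("fewer than 3 usable connectivity bins")
        x = np.log10(centers[ok])
        y = np.log10(counts[ok])
        fit = stats.linregress(x, y)
        signed_r2 = -np.sign(fit.slope) * fit.rvalue**2
        rows.append((beta, signed_r2, fit.slope, float(k.mean())))
    table = pd.DataFrame(
        rows, columns=["power", "signed_r2", "slope", "mean_connectivity"]
    )
    hits = table[table["signed_r2"] >= r2_target]
    if len(hits):
        return int(hits.iloc[0]["power"]), table
    best = int(table.loc[table["signed_r2"].idxmax(), "power"])
    warnings.warn(
        f"no candidate power reached signed R^2 {r2_target}; "
        f"falling back to power {best}",
        stacklevel=2,
    )
    return best, table


def tom_similarity(adj: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap similarity of an adjacency matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity excluding the diagonal; TOM_ii = 1.
    """
    a = np.asarray(adj, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise DataError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise DataError("adjacency entries must lie in [0, 1]")
    k = a.sum(axis=1) - np.diag(a)
    # L_ij = sum_u a_iu a_uj; remove the u == i and u == j terms (diag = 1).
    shared = a @ a - 2.0 * a  # subtracts a_ii*a_ij + a_ij*a_jj off-diagonal
    num = shared + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = num / den
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return pd.DataFrame(tom, index=adj.index, columns=adj.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    cut_height: float = 0.9,
) -> ModuleSet:
    """Detect modules by average-linkage clustering of TOM dissimilarity.

    ``cut_height`` is a fraction in (0, 1) of the maximum merge height of
    the dendrogram (a static height cut).  Clusters smaller than
    ``min_module_size`` are assigned the reserved ``grey`` label, and
    surviving modules are named ``module_1, module_2, ...`` by
    decreasing size (ties broken by first gene position).
    """
    if not 0 < cut_height < 1:
        raise DataError("cut_height must be in (0, 1)")
    genes = list(tom.index)
    diss = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(diss, 0.0)
    condensed = squareform(diss, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    height = cut_height * link[:, 2].max() if len(link) else 0.0
    raw = hierarchy.fcluster(link, t=height, criterion="distance")
    labels: dict[str, str] = {}
    clusters: dict[int, list[int]] = {}
    for i, c in enumerate(raw):
        clusters.setdefault(int(c), []).append(i)
    kept = [
        (c, idxs)
        for c, idxs in clusters.items()
        if len(idxs) >= min_module_size
    ]
    kept.sort(key=lambda item: (-len(item[1]), item[1][0]))
    for rank, (_, idxs) in enumerate(kept, start=1):
        for i in idxs:
            labels[genes[i]] = f"module_{rank}"
    for g in genes:
        labels.setdefault(g, GREY)
    if not kept:
        warnings.warn("all genes assigned grey (no cluster met min_module_size)")
    return ModuleSet(labels=labels)


def module_eigengenes(expr: ExpressionMatrix, labels: dict[str, str]) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    Each gene is centered and scaled to unit variance; the eigengene is
    the leading left singular vector over samples, rescaled to unit
    variance.  The sign is fixed so the mean correlation between the
    eigengene and the module's genes is >= 0, with ties broken toward
    positive correlation with the module's first gene.
    """
    module_set = ModuleSet(labels=labels)
    samples = expr.sample_ids
    me = {}
    for module in module_set.modules():
        genes = [g for g in expr.gene_ids if labels.get(g) == module]
        if len(genes) < 2:
            raise DataError(f"module {module} has fewer than 2 genes")
        x = np.asarray(expr.values.loc[genes], dtype=float)
        sd = x.std(axis=1, ddof=1)
        if np.any(sd == 0):
            raise DataError(f"constant gene in module {module}")
        xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
        # Leading PC over samples of the genes x samples standardized block.
        u, s, vt = np.linalg.svd(xs, full_matrices=False)
        pc = vt[0]
        pc_sd = pc.std(ddof=1)
        if pc_sd == 0:
            raise DataError(f"degenerate eigengene for module {module}")
        pc = pc / pc_sd
        cors = np.array([np.corrcoef(pc, row)[0, 1] for row in xs])
        mean_cor = cors.mean()
        if mean_cor < 0 or (mean_cor == 0 and cors[0] < 0):
            pc = -pc
        me[module] = pc
    return pd.DataFrame(me, index=samples)


def merge_modules(
    expr: ExpressionMatrix,
    module_set: ModuleSet,
    me_diss_thres: float = 0.5,
) -> ModuleSet:
    """Merge modules whose eigengene dissimilarity ``1 - cor`` is below threshold.

    Iteratively merges the closest pair (the smaller module is absorbed
    into the larger; ties broken by label order) and recomputes
    eigengenes until no pair is closer than ``me_diss_thres``.  Every
    merge is recorded in ``merge_log``.
    """
    labels = dict(module_set.labels)
    log: list[tuple[str, str, float]] = list(module_set.merge_log)
    while True:
        ms = ModuleSet(labels=labels)
        mods = ms.modules()
        if len(mods) < 2:
            break
        me = module_eigengenes(expr, labels)
        cor = np.corrcoef(np.asarray(me[mods], dtype=float).T)
        diss = 1.0 - cor
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= me_diss_thres:
            break
        a, b = mods[i], mods[j]
        size = {m: len(ms.genes_of(m)) for m in (a, b)}
        if size[a] > size[b] or (size[a] == size[b] and a < b):
            survivor, absorbed = a, b
        else:
            survivor, absorbed = b, a
        for g, m in labels.items():
            if m == absorbed:
                labels[g] = survivor
        log.append((absorbed, survivor, float(diss[i, j])))
    final = ModuleSet(labels=labels, merge_log=log)
    if final.modules():
        final.eigengenes = module_eigengenes(expr, labels)
    return final


def _cor_p_student(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value for a Pearson correlation via the Student-t approximation."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def module_trait_correlation(
    me: pd.DataFrame, traits: pd.DataFrame
) -> CorrelationStats:
    """Pearson correlation (and Student-t p) of each eigengene with each trait."""
    if len(me) != len(traits):
        raise DataError("eigengene and trait tables must share sample ordering")
    n = len(me)
    if n < 3:
        raise DataError("need at least 3 samples for correlation p-values")
    me_arr = np.asarray(me, dtype=float)
    tr_arr = np.asarray(traits, dtype=float)
    cor = _pairwise_cor(me_arr, tr_arr)
    p = _cor_p_student(cor, n)
    return CorrelationStats(
        module_trait_cor=pd.DataFrame(cor, index=me.columns, columns=traits.columns),
        module_trait_p=pd.DataFrame(p, index=me.columns, columns=traits.columns),
    )


def _pairwise_cor(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations between two sample x feature blocks."""
    az = a - a.mean(axis=0)
    bz = b - b.mean(axis=0)
    asd = az.std(axis=0)
    bsd = bz.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (az.T @ bz) / len(a) / np.outer(asd, bsd)
    return np.clip(c, -1.0, 1.0)


def gene_trait_stats(
    expr: ExpressionMatrix,
    me: pd.DataFrame,
    labels: dict[str, str],
    traits: pd.DataFrame,
) -> CorrelationStats:
    """Per-gene Gene Significance and Module Membership correlations.

    GS[g, t] is the signed correlation of gene g with trait t; MM[g, m]
    the signed correlation of gene g with module m's eigengene.
    Constant genes or traits yield NaN entries (flagged, excluded from
    downstream averages).
    """
    x = np.asarray(expr.values, dtype=float).T  # samples x genes
    if len(x) != len(me) or len(x) != len(traits):
        raise DataError("expression, eigengenes and traits must share samples")
    gs = _pairwise_cor(x, np.asarray(traits, dtype=float))
    mm = _pairwise_cor(x, np.asarray(me, dtype=float))
    return CorrelationStats(
        gs=pd.DataFrame(gs, index=expr.gene_ids, columns=traits.columns),
        mm=pd.DataFrame(mm, index=expr.gene_ids, columns=me.columns),
    )


def filter_hub_genes(
    labels: dict[str, str],
    stats_: CorrelationStats,
    module: str,
    trait: str,
) -> set[str]:
    """Above-average ``|GS|`` and ``|MM|`` genes of one module for one trait.

    Thresholds are the module means of ``|GS[., trait]|`` and
    ``|MM[., module]|``; genes meeting both (inclusively) are returned.
    """
    genes = [g for g, m in labels.items() if m == module]
    if not genes:
        raise DataError(f"module {module!r} is empty")
    gs = stats_.gs.loc[genes, trait].abs()
    mm = stats_.mm.loc[genes, module].abs()
    gs_ok = gs.dropna()
    mm_ok = mm.dropna()
    gs_cut = gs_ok.mean()
    mm_cut = mm_ok.mean()
    # inclusive boundary, robust to summation round-off in the mean
    gs_tol = 1e-12 * max(1.0, abs(gs_cut))
    mm_tol = 1e-12 * max(1.0, abs(mm_cut))
    return {
        g
        for g in genes
        if g in gs_ok.index
        and g in mm_ok.index
        and gs_ok[g] >= gs_cut - gs_tol
        and mm_ok[g] >= mm_cut - mm_tol
    }
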