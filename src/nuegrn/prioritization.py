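"""Prioritization of master TFs and subnetwork extraction.

TFs in the pruned network are ranked by the significance (hypergeometric
Z-score) of the overlap between their target sets and a
trait-correlated gene set within a stated universe; TFs passing
``z >= z_min`` and ``p <= p_max`` (defaults 10 and 0.001) are the
prioritized candidates.  Secondary TFs (TF2s) are overlapping targets
that are themselves TFs.  Local GO-style enrichment uses a flat
term->gene annotation with hypergeometric upper-tail p-values and
Benjamini-Hochberg FDR.  Finally, the subnetwork of prioritized TFs
restricted to targets annotated with selected terms can be extracted
for visualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._errors import DataError
from .network_validation import PruneResult
from .set_stats import overlap_zscore

__all__ = [
    "TFPriorityRecord",
    "EnrichmentResult",
    "prioritize_tfs",
    "count_tf2",
    "go_enrichment",
    "extract_subnetwork",
]


@dataclass
class TFPriorityRecord:
    tf: str
    n_pruned_targets: int
    overlap_genes: set[str]
    overlap_count: int
    tf2_count: int
    z: float
    p: float
    rank: int = 0


@dataclass
class EnrichmentResult:
    term: str
    name: str
    annotated_in_set: int
    annotated_in_universe: int
    p: float
    fdr: float


def count_tf2(overlap_genes, tf_list) -> int:
    """Number of overlapping target genes that are themselves TFs."""
    return len(set(overlap_genes) & set(tf_list))


def prioritize_tfs(
    pruned: PruneResult,
    trait_gene_set,
    universe,
    z_min: float = 10.0,
    p_max: float = 0.001,
    tf_list=None,
) -> list[TFPriorityRecord]:
    """Rank pruned-network TFs by target-set overlap with a trait gene set.

    For each TF, the overlap of its pruned targets (restricted to the
    universe) with ``trait_gene_set`` is scored by the analytic
    hypergeometric Z-score; TFs with ``z >= z_min`` and ``p <= p_max``
    are kept, ranked by decreasing z (ties by TF id).  ``tf_list``
    (default: the pruned network's own regulators) defines which
    overlapping targets count as secondary TFs.
    """
    trait_set = set(trait_gene_set)
    uni = set(universe)
    if not trait_set <= uni:
        raise DataError("trait_gene_set must be contained in the universe")
    tfs = pruned.tfs()
    if not tfs:
        warnings.warn("empty pruned network; no TFs to prioritize")
        return []
    tf_universe = set(tf_list) if tf_list is not None else set(tfs)
    records = []
    for tf in tfs:
        targets = pruned.targets_of(tf) & uni
        if not targets:
            continue
        res = overlap_zscore(targets, trait_set, uni, method="analytic")
        overlap = targets & trait_set
        records.append(
            TFPriorityRecord(
                tf=tf,
                n_pruned_targets=len(targets),
                overlap_genes=overlap,
                overlap_count=len(overlap),
                tf2_count=count_tf2(overlap, tf_universe),
                z=res.z,
                p=res.p,
            )
        )
    kept = [r for r in records if r.z >= z_min and r.p <= p_max]
    kept.sort(key=lambda r: (-r.z, r.tf))
    for i, r in enumerate(kept, start=1):
        r.rank = i
    return kept


def go_enrichment(
    gene_set,
    annotation: dict,
    universe,
    alpha: float = 0.05,
    term_names: dict | None = None,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment with Benjamini-Hochberg FDR.

    ``annotation`` maps term id -> set of annotated genes (taken as
    already propagated).  Annotated genes outside the universe are
    dropped with a warning.  Terms with ``fdr <= alpha`` are returned,
    sorted by (fdr, term id).
    """
    if not annotation:
        raise DataError("empty annotation")
    uni = set(universe)
    genes = set(gene_set) & uni
    if set(gene_set) - uni:
        warnings.warn("gene_set entries outside the universe were dropped")
    term_names = term_names or {}
    terms, pvals, in_set, in_uni = [], [], [], []
    for term in sorted(annotation):
        ann = set(annotation[term]) & uni
        if len(ann) < len(set(annotation[term])):
            warnings.warn(f"annotation for {term} has genes outside the universe")
        if not ann:
            continue
        x = len(genes & ann)
        # Upper tail P(X >= x) for drawing |genes| from universe with |ann| marked.
        p = float(stats.hypergeom.sf(x - 1, len(uni), len(ann), len(genes)))
        terms.append(term)
        pvals.append(p)
        in_set.append(x)
        in_uni.append(len(ann))
    if not terms:
        return []
    _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            term=t,
            name=term_names.get(t, t),
            annotated_in_set=s,
            annotated_in_universe=u,
            p=p,
            fdr=float(q),
        )
        for t, s, u, p, q in zip(terms, in_set, in_uni, pvals, fdr)
    ]
    results = [r for r in results if r.fdr <= alpha]
    results.sort(key=lambda r: (r.fdr, r.term))
    return results


@dataclass
class Subnetwork:
    """A term-filtered slice of the pruned network."""

    edges: pd.DataFrame  # columns: regulator, target, weight
    node_terms: dict[str, list[str]] = field(default_factory=dict)


def extract_subnetwork(
    pruned: PruneResult,
    prioritized: list[TFPriorityRecord],
    term_gene_map: dict,
    terms_of_interest,
) -> Subnetwork:
    """Subnetwork of prioritized TFs over targets annotated to selected terms.

    Keeps targets annotated to any term of interest that are regulated
    by a prioritized TF, the prioritized TFs with at least one edge to
    them, and TF->TF edges among the kept nodes.  Nodes are annotated
    with their matched terms; output ordering is deterministic.
    """
    terms_of_interest = sorted(set(terms_of_interest))
    missing = set(terms_of_interest) - set(term_gene_map)
    if missing:
        raise DataError(f"unknown terms: {sorted(missing)}")
    annotated = {}
    for term in terms_of_interest:
        for g in term_gene_map[term]:
            annotated.setdefault(g, []).append(term)
    tf_ids = {r.tf for r in prioritized}
    df = pruned.pruned_edges.edges
    df = df[df["regulator"].isin(tf_ids)]
    kept_targets = {
        t for t in df["target"] if t in annotated
    }
    core = df[df["target"].isin(kept_targets)]
    kept_tfs = set(core["regulator"])
    kept_nodes = kept_tfs | kept_targets
    tf_tf = df[df["regulator"].isin(kept_tfs) & df["target"].isin(kept_tfs)]
    out = (
        pd.concat([core, tf_tf])
        .drop_duplicates(subset=["regulator", "target"])
        .sort_values(["regulator", "target"])
        .reset_index(drop=True)
    )
    if out.empty:
        warnings.warn("no surviving nodes in the term-filtered subnetwork")
    node_terms = {
        n: sorted(annotated.get(n, [])) for n in sorted(kept_nodes)
    }
    return Subnetwork(edges=out, node_terms=node_terms)
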