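# Methods

`nuegrn` implements a gene-to-phenotype network pipeline for
nitrogen-use-efficiency (NUE) analysis in multi-variety field designs:
derived NUE phenotype metrics, weighted co-expression module detection
with trait correlation, tree-ensemble gene regulatory network (GRN)
inference, precision/recall validation and pruning against gold-standard
TF→target edges, and overlap-significance prioritization of master TFs.
This note records the models, the defaults and why, the numerical
choices, and what the synthetic benchmark does and does not show.

## Study design and the synthetic generator

The pipeline targets a field design of `n_varieties` varieties (default
19) grown in a 2×2 nitrogen-by-water (N-by-W) treatment matrix with
`n_replicates` replicates (default 3; 228 samples, collapsing to 76
variety×condition cells after replicate averaging).

The generator (`nuegrn.synthetic_data`) plants the statistical structure
each downstream stage assumes:

* **Module activities.** Each of `n_modules` co-expression modules has a
  per-sample latent activity
  `a_m = μ + β_N·[N=high] + β_W·[W=high] + β_NW·[both high] +
  variety_effect + N(0, noise_sd)`, with variety effects drawn once per
  variety×module from `N(0, variety_sd²)` (default sd 0.5) so eigengenes
  vary across the 76-cell design. Default effect sizes cycle through the
  three mutually orthogonal condition contrasts of the 2×2 design — an
  N main effect (1.5, 0, 0), a W main effect (0, 1.5, 0) and the
  interaction contrast (−1.5, −1.5, 3) — plus a condition-silent
  (variety-driven) module. Orthogonality matters: a bare β_NW pattern
  carries main-effect components that correlate ≈ 0.5 with the N and W
  modules, which the eigengene-merging step at threshold 0.5 would —
  correctly — absorb; and a 2×2 design has no room for a fourth
  orthogonal condition pattern, hence the condition-silent module.
* **Gene expression.** Member genes follow their module's activity
  through a loading drawn once per gene from U(0.5, 1.5), plus
  `N(0, noise_sd)` measurement noise (default 0.1, in latent activity
  units, i.e. roughly 10:1 signal-to-noise). Genes outside any module
  get independent unit-variance noise.
* **Regulatory edges.** `n_tfs` genes (default 20) sit inside modules,
  round-robin. Each TF carries an additional independent per-sample
  activity component `N(0, tf_activity_sd²)` (default 1.0): without it,
  co-members of a module are nearly collinear and no inference method
  could attribute a target to its specific TF at the stated noise
  levels. Each TF drives `tf_out_degree` targets (default 10) drawn
  uniformly over the other genes; a target adds
  `edge_strength · f(TF expression)` with `f` linear (default) or
  quadratic and `edge_strength = 0.8`. Edge contributions are applied in
  one pass from pre-edge TF expression; there is no multi-hop
  propagation when a TF targets another TF. With all noise terms and
  `tf_activity_sd` zero and a single module, every target is an exact
  affine function of its TF (tested to machine tolerance).
* **Phenotypes.** Per variety×condition cell, each trait is a linear
  combination of the cell-mean module activities (defaults: a NUEg-like
  trait loading +1 on module 1 and −0.5 on module 2, a WUE-like trait
  loading +1 on module 2) plus `N(0, phenotype_noise_sd)` (default 0.1).
* **Gold standard.** Validation data for a set of assayed TFs is
  simulated by dropping true edges with probability `gold_fn_rate` and
  adding non-edges with probability `gold_fp_rate` (defaults 0.1),
  over the assayed-TFs × candidate-targets universe (self-pairs
  excluded, since the predicted network has none).
* **Response classes.** Each gene's N/W/N:W differential-expression
  labels are read off its driving module's design contrasts: the gene is
  N-responsive when the module's N main effect β_N + β_NW/2 is nonzero
  (likewise for W), and N:W-responsive when β_NW is nonzero — matching
  what differential-expression analysis of the balanced 2×2 design would
  report.

One seed drives everything, split into per-component substreams with
`numpy.random.SeedSequence(seed, spawn_key=...)`, so identical
configurations are bitwise-reproducible.

What the generator does **not** emulate: count overdispersion,
library-size effects, missing data, correlated measurement noise, or
multi-layer regulatory cascades. Passing the benchmark therefore shows
the pipeline recovers the planted linear-Gaussian structure at realistic
sizes and noise; it does not certify performance on raw sequencing
counts, which enter the real pipeline only after normalization.

## Phenotype metrics

N uptake (g/m²) = (Kjeldahl N% / 100 × shoot dry weight g/plant) ×
plants/m². The Kjeldahl value is interpreted as a percentage; the
division by 100 gives unit consistency (g N per g tissue). NUEg and NUEb
divide grain yield and biomass (g/m²) by N uptake; records with
non-positive uptake are flagged, not dropped, and excluded from index
computation. The potential index per condition j is
I_PO = (Y_ij − Ȳ_j)/Ȳ_j, which sums to zero over varieties within a
condition by construction (tested to 1e−12); the metrics work per record
and any averaging over plots is the caller's choice.

## Co-expression modules

Unsigned weighted-correlation analysis: adjacency `|cor(x_i,x_j)|^β`
(Pearson throughout; missing values are disallowed after preprocessing
rather than treated pairwise-complete), topological overlap
TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij),
average-linkage clustering of 1 − TOM, and a **static height cut** at
`cut_height` (fraction of the maximum merge height) with clusters below
`min_module_size` (default 30) sent to the reserved `grey` label. The
static cut is a deliberate simplification of hybrid dynamic tree
cutting: it is deterministic and directly testable. Its default is 0.9:
on block-structured data the within-module merges finish below ~0.3 of
the maximum height while the final inter-module merges cluster in the
top decile, so a cut in the 0.9 neighbourhood sits in the valley
between them (a cut at 0.99 would absorb inter-module merges whose
heights tie within 1% of the maximum, collapsing distinct modules).
Module labels are deterministic size-ordered names (`module_1`, ...);
color names used by other implementations are arbitrary and can be
supplied as a user mapping.

The soft power can be chosen by the scale-free topology criterion:
connectivities are binned (10 bins), log10 frequency is regressed on
log10 mean connectivity, and the smallest power with signed R² ≥ 0.8 is
taken, else the best power with a warning. Two caveats are documented
rather than hidden: synthetic block data is not scale-free, so the
selector typically falls back (the benchmark fixes β = 6, the
conventional unsigned default); and at large powers the connectivity of
pure noise collapses toward zero, whose histogram mimics
scale-freeness — consult the reported mean connectivity before trusting
a large selected power.

Module eigengenes are the first principal component of the module's
gene-standardized expression, rescaled to unit variance (ddof = 1), with
sign fixed so the mean eigengene–gene correlation is ≥ 0 (ties broken
toward positive correlation with the module's first gene). Modules are
merged greedily while any eigengene pair has dissimilarity
1 − cor < `me_diss_thres` (default 0.5): the closest pair merges first,
the smaller module is absorbed into the larger (label order on ties),
eigengenes are recomputed, and every merge is logged. The loop
terminates because the module count strictly decreases.

Module–trait p-values use the Student approximation
t = r√(n−2)/√(1−r²) with n−2 df, two-sided, and no multiplicity
correction at this stage (per-cell significance marks). Gene
Significance (GS) is the signed gene–trait correlation, Module
Membership (MM) the signed gene–eigengene correlation. The hub filter
for one module and one trait keeps genes whose |GS| and |MM| are both at
or above the module means (inclusive, with a 1e−12 relative tolerance so
exact-tie boundaries are not lost to round-off).

## Overlap significance

The overlap x of gene sets A and B in an explicit universe (never
implicit — the Z-score depends strongly on it) is scored against the
hypergeometric null: E[X] = nK/N, Var[X] = nK(N−K)(N−n)/(N²(N−1)),
z = (x − E)/sd, p = exact upper tail P(X ≥ x). A permutation null
(resampling A only; B held fixed) provides the fidelity check, with the
add-one estimator p = (1 + #{X* ≥ x})/(1 + n_perm) so p is never 0. The
two methods agree in z to within 0.2 at n_perm = 10,000 for
moderate-sized sets (tested).

## GRN inference

For each target, an ensemble of `n_trees` (default 1000) regression
trees predicts the target's standardized expression from the
standardized TF expressions (TF targets exclude only themselves). The
edge weight is the TF's total variance-reduction importance summed over
trees and divided by `n_trees` — unnormalized, so weights are comparable
across targets because of the per-gene standardization. The default
estimator is extremely randomized trees with √|TFs| candidate regulators
per split; both randomized-tree variants (extra-trees and bagged random
forests, `tree_method="ET"/"RF"`) carry identical importance semantics,
and extra-trees was chosen as the default for its substantially lower
fitting cost at indistinguishable ranking skill on the benchmark. The
global ranking sorts by weight with lexicographic (regulator, target)
tie-breaks so precision/recall downstream is total and reproducible;
per-target seeds derive deterministically from the configured seed. Edge
count is |TFs|·|targets| − |TFs ∩ targets| (self-edges excluded).

## Validation and pruning

Predictions are restricted to the assayed universe (default: assayed
TFs × all predicted targets — the negative set is explicit and
configurable, since validation data rarely states it). Precision and
recall are cumulative along the ranking; AUPR is the rectangular
(step-function) area — conservative, standard for PR curves, and exactly
reproducible, which trapezoidal interpolation is not. Significance comes
from permuting the validated labels over the assayed predictions
(preserving their count), with add-one p and the min/max permuted AUPR
reported as the random envelope. The pruning threshold is the weight at
the deepest rank whose precision still meets `precision_target`
(default 0.31); automating "the highest precision before the curve
flattens" is a visual judgement deliberately replaced by an explicit
parameter. The threshold is then applied to the whole network, assayed
and unassayed TFs alike. Multiple gold-standard datasets are unioned by
default ("validated in any dataset"). Set-level precision/recall/F-score
use |P∩R|/|P|, |P∩R|/|R| and their harmonic mean, with empty predictions
reported as zero.

Because the pruning weight threshold depends on the tree count, the
estimator and the expression data, thresholds are not portable across
configurations; only the precision target is.

## Prioritization

Each pruned-network TF's target set is scored against the
trait-correlated gene set with the analytic overlap Z-score over an
explicit universe (default: the DE-gene universe used for inference);
TFs with z ≥ 10 and p ≤ 0.001 are kept, ranked by decreasing z, ties by
id. Secondary TFs (TF₂) are overlapping targets that are themselves TFs;
pooled counts across prioritized TFs are unions, not column sums.
Enrichment uses a local flat term→gene annotation (taken as already
propagated; no ontology-graph closure), hypergeometric upper-tail
p-values and Benjamini–Hochberg FDR at α = 0.05. The subnetwork export
keeps targets annotated to the selected terms, the prioritized TFs with
at least one edge to them, and TF→TF edges among kept nodes, in
deterministic order, as SIF plus node/edge tables.

## Benchmark problem sizes

The shipped benchmark uses module-recovery datasets of 400 genes
(4×100-gene modules, noise 0.1, 10 seeds; recovery measured by adjusted
Rand index against the planted labels), an inference problem of 20 TFs ×
500 targets × 1000 trees on 228 samples with a sample-shuffled negative
control, pruning calibration against an fp = fn = 0.1 gold standard at
precision target 0.31, and a master-TF recovery design in which a TF
driving 40 hub-filtered trait-correlated targets must pass the
(z ≥ 10, p ≤ 0.001) gate while a decoy TF driving 40 uniform targets
must not, across 10 seeds. These sizes keep the full benchmark within
tens of minutes on a single CPU while preserving the statistical regime
(per-module gene counts, sample layout, signal-to-noise) of the emulated
study.

## Known limitations

* Static-height module detection can split or fuse modules whose
  separation varies along the dendrogram; hybrid dynamic cutting and
  blockwise (memory-tiled) detection are out of scope.
* Gaussian expression is a stand-in: the variance structure of real
  normalized counts is not modelled.
* The permutation null resamples one set (the TF target set), not both.
* Weight thresholds from one inference configuration must not be reused
  in another; re-derive them from the precision target.
* No ontology-graph propagation, ortholog mapping, or live annotation
  queries; annotation files are versioned external inputs.
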