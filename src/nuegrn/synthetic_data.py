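"""Seeded synthetic datasets with the structure the pipeline stages assume.

The generator emulates a field-trial design: ``n_varieties`` rice-like
varieties grown under a 2x2 nitrogen-by-water treatment matrix with
``n_replicates`` replicates per cell.  Expression is built from planted
co-expression modules: each module has a latent activity per sample,

    a_m = mu + beta_N * [N=high] + beta_W * [W=high] + beta_NW * [both high]
          + variety_effect + Normal(0, noise_sd),

member genes follow the activity through a positive loading drawn once
per gene from [0.5, 1.5], phenotypes are linear in the per-cell mean
module activities, and a subset of genes act as transcription factors
(TFs) whose expression additionally feeds planted TF->target edges.
Each TF also carries an independent per-sample activity component
(``tf_activity_sd``) so that its targets are statistically attributable
to it rather than to the shared module activity; set it to 0 to recover
a purely module-driven matrix.

Everything is driven by one seed, split deterministically per component,
so identical configurations produce bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, DataError
from .expression import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "GoldStandardSpec",
    "simulate_dataset",
    "simulate_gold_standard",
    "condition_label",
]

#: (n_level, w_level) cells of the 2x2 treatment matrix.
DEFAULT_CONDITIONS = (
    ("high", "high"),
    ("low", "high"),
    ("high", "low"),
    ("low", "low"),
)

DE_CLASSES = ("N", "W", "N:W")


def condition_label(n_level: str, w_level: str) -> str:
    """Condition name in the HW/LW x HN/LN convention (e.g. ``HWHN``)."""
    return f"{'H' if w_level == 'high' else 'L'}W{'H' if n_level == 'high' else 'L'}N"


def _default_effects(n_modules: int) -> list[tuple[float, float, float]]:
    # Cycle through N-, W-, NxW-responsive and condition-silent
    # (variety-driven) modules.  A 2x2 design supports only three
    # condition contrasts, so a fourth condition-responsive pattern would
    # necessarily correlate with the others and defeat eigengene merging.
    # The NxW module uses the orthogonal interaction contrast
    # (beta_N = beta_W = -beta_NW/2), not a bare beta_NW, whose cell
    # pattern would carry main-effect components correlating ~0.5 with
    # the N and W modules.
    base = [(1.5, 0.0, 0.0), (0.0, 1.5, 0.0), (-1.5, -1.5, 3.0), (0.0, 0.0, 0.0)]
    return [base[m % len(base)] for m in range(n_modules)]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic field-study generator.

    Defaults mirror the emulated study design: 19 varieties, a 2x2
    nitrogen-by-water matrix, 3 replicates (228 samples), 4 planted
    modules and 20 TFs with 10 planted targets each.
    """

    n_varieties: int = 19
    conditions: tuple = DEFAULT_CONDITIONS
    n_replicates: int = 3
    n_genes: int = 600
    n_tfs: int = 20
    n_modules: int = 4
    module_sizes: list[int] | None = None
    latent_mean: float = 0.0
    latent_effect_sizes: list[tuple[float, float, float]] | None = None
    variety_sd: float = 0.5
    tf_out_degree: int = 10
    edge_function: str = "linear"
    edge_strength: float = 0.8
    tf_activity_sd: float = 1.0
    noise_sd: float = 0.1
    phenotype_loadings: dict[str, list[float]] | None = None
    phenotype_noise_sd: float = 0.1
    gold_fp_rate: float = 0.1
    gold_fn_rate: float = 0.1
    seed: int = 0

    def resolved_module_sizes(self) -> list[int]:
        if self.module_sizes is not None:
            return list(self.module_sizes)
        base = self.n_genes // self.n_modules
        sizes = [base] * self.n_modules
        sizes[0] += self.n_genes - base * self.n_modules
        return sizes

    def resolved_effects(self) -> list[tuple[float, float, float]]:
        if self.latent_effect_sizes is not None:
            return [tuple(e) for e in self.latent_effect_sizes]
        return _default_effects(self.n_modules)

    def resolved_phenotype_loadings(self) -> dict[str, list[float]]:
        if self.phenotype_loadings is not None:
            return {t: list(v) for t, v in self.phenotype_loadings.items()}
        # Two traits in the spirit of NUEg and WUE: each driven mainly by
        # one module, with a weak opposite-sign loading on another.
        nueg = [0.0] * self.n_modules
        wue = [0.0] * self.n_modules
        nueg[0] = 1.0
        if self.n_modules > 1:
            nueg[1] = -0.5
            wue[1] = 1.0
        else:
            wue[0] = 0.5
        return {"nueg": nueg, "wue": wue}

    def validate(self) -> None:
        if self.n_varieties < 1:
            raise ConfigurationError("n_varieties must be >= 1")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if not self.conditions:
            raise ConfigurationError("conditions must be nonempty")
        sizes = self.resolved_module_sizes()
        if len(sizes) != self.n_modules:
            raise ConfigurationError("module_sizes length must equal n_modules")
        if any(s < 1 for s in sizes):
            raise ConfigurationError("module_sizes entries must be >= 1")
        if sum(sizes) > self.n_genes:
            raise ConfigurationError("module_sizes must sum to <= n_genes")
        if not 0 <= self.n_tfs <= self.n_genes:
            raise ConfigurationError("n_tfs must be in [0, n_genes]")
        if self.tf_out_degree < 0 or self.tf_out_degree > self.n_genes - 1:
            raise ConfigurationError("tf_out_degree must be in [0, n_genes-1]")
        if self.edge_function not in ("linear", "quadratic"):
            raise ConfigurationError("edge_function must be 'linear' or 'quadratic'")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.phenotype_noise_sd < 0:
            raise ConfigurationError("phenotype_noise_sd must be >= 0")
        if self.variety_sd < 0:
            raise ConfigurationError("variety_sd must be >= 0")
        if self.tf_activity_sd < 0:
            raise ConfigurationError("tf_activity_sd must be >= 0")
        for name in ("gold_fp_rate", "gold_fn_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if len(self.resolved_effects()) != self.n_modules:
            raise ConfigurationError("latent_effect_sizes length must equal n_modules")
        for trait, load in self.resolved_phenotype_loadings().items():
            if len(load) != self.n_modules:
                raise ConfigurationError(
                    f"phenotype_loadings[{trait!r}] length must equal n_modules"
                )


@dataclass
class SyntheticDataset:
    """A generated dataset together with its planted ground truth."""

    expression: ExpressionMatrix
    phenotypes: pd.DataFrame  # rows: variety x condition; columns: traits
    true_module_labels: dict[str, str]
    true_edges: set[tuple[str, str]]
    true_de_classes: dict[str, frozenset]
    tf_list: list[str]
    latent_activities: pd.DataFrame | None = None  # samples x modules (diagnostic)
    config: SimulationConfig | None = None


@dataclass
class GoldStandardSpec:
    """Noisy experimentally-validated edge set over an assayed universe."""

    validated_edges: set[tuple[str, str]]
    assayed_tfs: set[str]
    assayed_universe: set[tuple[str, str]]


def _rng(seed: int, key: int) -> np.random.Generator:
    """Deterministic per-component stream split from one dataset seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a :class:`SyntheticDataset` according to ``config``.

    See the module docstring for the generative model.  The same config
    (including seed) always yields an identical dataset.
    """
    config.validate()
    sizes = config.resolved_module_sizes()
    effects = config.resolved_effects()
    loadings_map = config.resolved_phenotype_loadings()

    varieties = [f"V{i + 1:02d}" for i in range(config.n_varieties)]
    cells = [
        (v, n, w) for v in varieties for (n, w) in config.conditions
    ]
    samples = []
    for v, n, w in cells:
        for r in range(1, config.n_replicates + 1):
            samples.append((f"{v}_{condition_label(n, w)}_R{r}", v, n, w, r))
    sample_ids = [s[0] for s in samples]
    metadata = pd.DataFrame(
        [(v, n, w, r) for _, v, n, w, r in samples],
        index=pd.Index(sample_ids, name="sample_id"),
        columns=["variety", "n_level", "w_level", "replicate"],
    )
    n_samples = len(samples)

    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    module_names = [f"module_{m + 1}" for m in range(config.n_modules)]

    # Gene -> module assignment: contiguous blocks, leftovers unassigned.
    labels: dict[str, str] = {}
    pos = 0
    members: dict[str, list[str]] = {}
    for m, size in enumerate(sizes):
        members[module_names[m]] = gene_ids[pos : pos + size]
        for g in gene_ids[pos : pos + size]:
            labels[g] = module_names[m]
        pos += size
    for g in gene_ids[pos:]:
        labels[g] = "grey"

    # TFs sit inside modules, round-robin across them.
    tf_list: list[str] = []
    counters = [0] * config.n_modules
    m = 0
    while len(tf_list) < config.n_tfs:
        mod = module_names[m % config.n_modules]
        idx = counters[m % config.n_modules]
        if idx < len(members[mod]):
            tf_list.append(members[mod][idx])
            counters[m % config.n_modules] += 1
        m += 1
        if m > config.n_genes * config.n_modules:  # all modules exhausted
            raise ConfigurationError("n_tfs exceeds genes available inside modules")

    # --- latent module activities -------------------------------------
    rng_variety = _rng(config.seed, 0)
    rng_latent = _rng(config.seed, 1)
    variety_eff = rng_variety.normal(
        0.0, config.variety_sd, size=(config.n_varieties, config.n_modules)
    )
    v_index = {v: i for i, v in enumerate(varieties)}
    activities = np.empty((n_samples, config.n_modules))
    for j, (b_n, b_w, b_nw) in enumerate(effects):
        for i, (_, v, n, w, _) in enumerate(samples):
            mean = (
                config.latent_mean
                + b_n * (n == "high")
                + b_w * (w == "high")
                + b_nw * (n == "high" and w == "high")
                + variety_eff[v_index[v], j]
            )
            activities[i, j] = mean
    activities += rng_latent.normal(0.0, config.noise_sd, size=activities.shape)

    # --- gene expression ----------------------------------------------
    rng_load = _rng(config.seed, 2)
    rng_noise = _rng(config.seed, 3)
    rng_bg = _rng(config.seed, 4)
    gene_loading = rng_load.uniform(0.5, 1.5, size=config.n_genes)
    expr = np.empty((config.n_genes, n_samples))
    mod_index = {name: j for j, name in enumerate(module_names)}
    for i, g in enumerate(gene_ids):
        if labels[g] == "grey":
            # Background genes: independent unit-variance variation.
            expr[i] = rng_bg.normal(0.0, 1.0, size=n_samples)
        else:
            expr[i] = gene_loading[i] * activities[:, mod_index[labels[g]]]
    expr += rng_noise.normal(0.0, config.noise_sd, size=expr.shape)

    # TF-intrinsic activity, added before planted edges are applied.
    rng_tfact = _rng(config.seed, 5)
    g_index = {g: i for i, g in enumerate(gene_ids)}
    if config.tf_activity_sd > 0:
        for tf in tf_list:
            expr[g_index[tf]] += rng_tfact.normal(
                0.0, config.tf_activity_sd, size=n_samples
            )

    # --- planted TF->target edges (single-layer propagation) ----------
    rng_edges = _rng(config.seed, 6)
    true_edges: set[tuple[str, str]] = set()
    tf_expr_snapshot = {tf: expr[g_index[tf]].copy() for tf in tf_list}
    for tf in tf_list:
        candidates = [g for g in gene_ids if g != tf]
        targets = rng_edges.choice(
            len(candidates), size=config.tf_out_degree, replace=False
        )
        for t in targets:
            target = candidates[t]
            true_edges.add((tf, target))
            x = tf_expr_snapshot[tf]
            fx = x if config.edge_function == "linear" else x**2
            expr[g_index[target]] += config.edge_strength * fx

    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        metadata,
    )

    # --- phenotypes per variety x condition ---------------------------
    rng_pheno = _rng(config.seed, 7)
    cell_key = [f"{v}|{condition_label(n, w)}" for (v, n, w) in cells]
    cell_of_sample = np.array(
        [cell_key.index(f"{v}|{condition_label(n, w)}") for (_, v, n, w, _) in samples]
    )
    mean_act = np.zeros((len(cells), config.n_modules))
    for c in range(len(cells)):
        mean_act[c] = activities[cell_of_sample == c].mean(axis=0)
    traits = sorted(loadings_map)
    pheno = np.zeros((len(cells), len(traits)))
    for t, trait in enumerate(traits):
        load = np.asarray(loadings_map[trait], dtype=float)
        pheno[:, t] = mean_act @ load
    pheno += rng_pheno.normal(0.0, config.phenotype_noise_sd, size=pheno.shape)
    phenotypes = pd.DataFrame(pheno, columns=traits)
    phenotypes.insert(0, "variety", [v for (v, _, _) in cells])
    phenotypes.insert(1, "condition", [condition_label(n, w) for (_, n, w) in cells])

    # --- DE classes from the driving module's design contrasts --------
    # A gene responds to N if its module has a nonzero N main effect
    # (beta_N + beta_NW/2 in the balanced 2x2 design), and likewise for
    # W; the interaction class follows beta_NW directly.
    de_classes: dict[str, frozenset] = {}
    for g in gene_ids:
        if labels[g] == "grey":
            de_classes[g] = frozenset()
        else:
            b_n, b_w, b_nw = effects[mod_index[labels[g]]]
            cls = set()
            if abs(b_n + b_nw / 2) > 1e-12:
                cls.add("N")
            if abs(b_w + b_nw / 2) > 1e-12:
                cls.add("W")
            if abs(b_nw) > 1e-12:
                cls.add("N:W")
            de_classes[g] = frozenset(cls)

    latent = pd.DataFrame(activities, index=sample_ids, columns=module_names)
    return SyntheticDataset(
        expression=expression,
        phenotypes=phenotypes,
        true_module_labels=labels,
        true_edges=true_edges,
        true_de_classes=de_classes,
        tf_list=tf_list,
        latent_activities=latent,
        config=replace(config),
    )


def simulate_gold_standard(
    true_edges: set[tuple[str, str]],
    assayed_tfs,
    fp_rate: float,
    fn_rate: float,
    candidate_targets,
    seed: int,
) -> GoldStandardSpec:
    """Corrupt the planted edges of ``assayed_tfs`` into a noisy gold standard.

    True edges are dropped with probability ``fn_rate``; non-edges within
    ``assayed_tfs x candidate_targets`` are added with probability
    ``fp_rate``.  Emulates validation data that covers only a few assayed
    TFs and is itself imperfect.
    """
    assayed_tfs = sorted(set(assayed_tfs))
    if not assayed_tfs:
        raise DataError("assayed_tfs must be nonempty")
    for rate, name in ((fp_rate, "fp_rate"), (fn_rate, "fn_rate")):
        if not 0.0 <= rate <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1]")
    candidate_targets = sorted(set(candidate_targets))
    rng = np.random.default_rng(seed)
    validated: set[tuple[str, str]] = set()
    universe: set[tuple[str, str]] = set()
    for tf in assayed_tfs:
        for target in candidate_targets:
            if target == tf:
                continue
            pair = (tf, target)
            universe.add(pair)
            if pair in true_edges:
                if rng.random() >= fn_rate:
                    validated.add(pair)
            else:
                if rng.random() < fp_rate:
                    validated.add(pair)
    return GoldStandardSpec(
        validated_edges=validated,
        assayed_tfs=set(assayed_tfs),
        assayed_universe=universe,
    )
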