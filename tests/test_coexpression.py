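"""Module detection, eigengenes, trait statistics and hub filtering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from nuegrn import (
    DataError,
    ExpressionMatrix,
    adjacency,
    average_replicates,
    detect_modules,
    filter_hub_genes,
    gene_trait_stats,
    merge_modules,
    module_eigengenes,
    module_trait_correlation,
    pick_soft_power,
    tom_similarity,
)
from nuegrn.coexpression import CorrelationStats, ModuleSet

from conftest import make_expression


class TestAverageReplicates:
    def test_identical_replicates_are_idempotent(self, four_module_dataset):
        expr = four_module_dataset.expression
        averaged = average_replicates(expr)
        # replace all replicates of the first cell by the first column
        vals = expr.values.copy()
        meta = expr.metadata
        first = meta.iloc[0]
        cell = meta[
            (meta["variety"] == first["variety"])
            & (meta["n_level"] == first["n_level"])
            & (meta["w_level"] == first["w_level"])
        ].index
        for s in cell:
            vals[s] = vals[cell[0]]
        dup = average_replicates(ExpressionMatrix(vals, meta))
        np.testing.assert_allclose(
            dup.values.iloc[:, 0], vals[cell[0]], rtol=0, atol=1e-12
        )

    def test_mean_of_two_replicates(self):
        values = pd.DataFrame(
            {"s1": [1.0], "s2": [3.0]}, index=["G1"]
        )
        meta = pd.DataFrame(
            {
                "variety": ["V1", "V1"],
                "n_level": ["high", "high"],
                "w_level": ["low", "low"],
                "replicate": [1, 2],
            },
            index=["s1", "s2"],
        )
        out = average_replicates(ExpressionMatrix(values, meta))
        assert out.values.iloc[0, 0] == 2.0

    def test_full_design_collapses_to_76_columns(self, four_module_dataset):
        out = average_replicates(four_module_dataset.expression)
        assert out.values.shape[1] == 76

    def test_requires_metadata(self):
        expr = make_expression(np.random.default_rng(0).normal(size=(4, 6)))
        with pytest.raises(DataError):
            average_replicates(expr)


class TestSoftPower:
    def test_iid_noise_falls_back_with_warning(self):
        """Noise has no scale-free topology at moderate powers: the
        selector must warn and fall back to the best-fitting power.
        (Very high powers can mimic scale-freeness on noise as the
        connectivity collapses toward zero, so they are excluded here.)"""
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(60, 30)))
        with pytest.warns(UserWarning, match="falling back"):
            power, table = pick_soft_power(expr, range(1, 5), r2_target=0.8)
        assert (table["signed_r2"] < 0.8).all()
        assert power in range(1, 5)

    def test_single_module_matrix_is_degenerate(self):
        rng = np.random.default_rng(1)
        profile = rng.normal(size=20)
        expr = make_expression(np.outer(np.linspace(1, 2, 10), profile))
        with pytest.raises(DataError, match="degenerate|bins"):
            pick_soft_power(expr, [2])

    def test_selected_power_fit_is_reproducible(self, four_module_dataset):
        expr = average_replicates(four_module_dataset.expression)
        with pytest.warns(UserWarning):
            power, table = pick_soft_power(expr, range(1, 13), r2_target=0.95)
        with pytest.warns(UserWarning):
            _, table2 = pick_soft_power(expr, [power], r2_target=0.95)
        row = table.loc[table["power"] == power, "signed_r2"].iloc[0]
        assert table2["signed_r2"].iloc[0] == pytest.approx(row, abs=1e-12)


class TestAdjacency:
    def test_perfectly_correlated_pair_is_one(self):
        x = np.arange(10.0)
        expr = make_expression(np.vstack([x, 2 * x + 1]))
        for power in (1, 6):
            assert adjacency(expr, power).iloc[0, 1] == pytest.approx(1.0)

    def test_half_correlation_power_six(self):
        # construct two genes with exact correlation 0.5
        u = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        v = np.array([1.0, 1.0, -1.0, -1.0] * 2)
        y = 0.5 * u + np.sqrt(0.75) * v
        expr = make_expression(np.vstack([u, y]))
        assert adjacency(expr, 6).iloc[0, 1] == pytest.approx(0.5**6, abs=1e-12)

    def test_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        expr = make_expression(rng.normal(size=(20, 10)))
        a = adjacency(expr, 6).values
        assert np.allclose(a, a.T)
        np.testing.assert_allclose(np.diag(a), 1.0)
        c = np.corrcoef(expr.values.values)
        np.testing.assert_allclose(a, np.abs(c) ** 6, atol=1e-12)

    def test_zero_variance_gene_named(self):
        vals = np.vstack([np.ones(8), np.arange(8.0)])
        expr = make_expression(vals)
        with pytest.raises(DataError, match="G001"):
            adjacency(expr, 2)


def tom_bruteforce(a: np.ndarray) -> np.ndarray:
    """Independent double-loop evaluation of the topological overlap formula."""
    n = len(a)
    k = a.sum(axis=1) - np.diag(a)
    out = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestTOM:
    def test_two_gene_closed_form(self):
        for c in (0.2, 0.7):
            a = pd.DataFrame([[1.0, c], [c, 1.0]], index=["a", "b"], columns=["a", "b"])
            assert tom_similarity(a).iloc[0, 1] == pytest.approx(c)

    def test_identity_adjacency_gives_zero_overlap(self):
        a = pd.DataFrame(np.eye(5))
        t = tom_similarity(a).values
        assert np.all(t[~np.eye(5, dtype=bool)] == 0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        raw = rng.uniform(0, 1, size=(6, 6))
        a = (raw + raw.T) / 2
        np.fill_diagonal(a, 1.0)
        t = tom_similarity(pd.DataFrame(a)).values
        np.testing.assert_allclose(t, tom_bruteforce(a), atol=1e-12)

    def test_rejects_asymmetric_input(self):
        a = pd.DataFrame([[1.0, 0.2], [0.8, 1.0]])
        with pytest.raises(DataError, match="symmetric"):
            tom_similarity(a)


class TestDetectModules:
    def _two_block_tom(self):
        t = np.full((100, 100), 0.02)
        t[:50, :50] = 0.95
        t[50:, 50:] = 0.95
        np.fill_diagonal(t, 1.0)
        rng = np.random.default_rng(0)
        jitter = rng.uniform(0, 0.01, size=(100, 100))
        t = np.clip(t + (jitter + jitter.T) / 2, 0, 1)
        np.fill_diagonal(t, 1.0)
        return pd.DataFrame(
            t, index=[f"G{i}" for i in range(100)], columns=[f"G{i}" for i in range(100)]
        )

    def test_two_planted_blocks_recovered(self):
        ms = detect_modules(self._two_block_tom(), min_module_size=30)
        mods = ms.modules()
        assert len(mods) == 2
        first = {f"G{i}" for i in range(50)}
        assert {g for g in first} in (
            set(ms.genes_of(mods[0])),
            set(ms.genes_of(mods[1])),
        )

    def test_min_size_larger_than_n_genes_gives_all_grey(self):
        with pytest.warns(UserWarning, match="grey"):
            ms = detect_modules(self._two_block_tom(), min_module_size=1000)
        assert set(ms.labels.values()) == {"grey"}

    def test_recovers_planted_modules_with_high_ari(self, four_module_dataset):
        ds = four_module_dataset
        expr = average_replicates(ds.expression)
        tom = tom_similarity(adjacency(expr, 6))
        ms = merge_modules(expr, detect_modules(tom, min_module_size=20))
        genes = expr.gene_ids
        ari = adjusted_rand_score(
            [ds.true_module_labels[g] for g in genes], [ms.labels[g] for g in genes]
        )
        assert ari >= 0.8


class TestEigengenes:
    def test_identical_genes_module(self):
        profile = np.random.default_rng(1).normal(size=12)
        expr = make_expression(np.vstack([profile] * 4))
        labels = {g: "module_1" for g in expr.gene_ids}
        me = module_eigengenes(expr, labels)
        std = (profile - profile.mean()) / profile.std(ddof=1)
        np.testing.assert_allclose(me["module_1"].values, std, atol=1e-10)

    def test_sign_tie_break_toward_first_gene(self):
        profile = np.random.default_rng(2).normal(size=10)
        expr = make_expression(np.vstack([profile, -profile]))
        labels = {g: "module_1" for g in expr.gene_ids}
        me = module_eigengenes(expr, labels)["module_1"].values
        assert np.corrcoef(me, profile)[0, 1] > 0

    def test_matches_leading_eigenvector_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 15))
        expr = make_expression(x)
        labels = {g: "module_1" for g in expr.gene_ids}
        me = module_eigengenes(expr, labels)["module_1"].values
        xs = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, ddof=1, keepdims=True)
        w, v = np.linalg.eigh(xs @ xs.T)
        lead = xs.T @ v[:, -1]  # sample-space projection of top eigenvector
        r = np.corrcoef(me, lead)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10

    def test_constant_gene_errors(self):
        expr = make_expression(np.vstack([np.ones(8), np.arange(8.0)]))
        with pytest.raises(DataError, match="constant"):
            module_eigengenes(expr, {g: "module_1" for g in expr.gene_ids})


def _correlated_profiles(rho: float, n: int = 40, seed: int = 0):
    rng = np.random.default_rng(seed)
    u = rng.normal(size=n)
    w = rng.normal(size=n)
    u = (u - u.mean()) / u.std()
    w = w - w.mean() - u * (u @ (w - w.mean())) / (u @ u)
    w /= w.std()
    return u, rho * u + np.sqrt(1 - rho**2) * w


class TestMergeModules:
    def _expr_for(self, profiles, genes_per=3, jitter=1e-3):
        rng = np.random.default_rng(9)
        rows, labels = [], {}
        for m, p in enumerate(profiles, start=1):
            for i in range(genes_per):
                g = f"M{m}_{i}"
                rows.append((g, p + rng.normal(0, jitter, size=len(p))))
                labels[g] = f"module_{m}"
        values = pd.DataFrame(
            {g: r for g, r in rows}
        ).T
        values.columns = [f"S{j}" for j in range(values.shape[1])]
        return ExpressionMatrix(values), labels

    def test_close_pair_is_merged(self):
        u, v = _correlated_profiles(0.9)
        expr, labels = self._expr_for([u, v])
        merged = merge_modules(expr, ModuleSet(labels=labels), 0.5)
        assert len(merged.modules()) == 1
        assert len(merged.merge_log) == 1

    def test_distant_pair_is_kept(self):
        u, v = _correlated_profiles(0.2)
        expr, labels = self._expr_for([u, v])
        merged = merge_modules(expr, ModuleSet(labels=labels), 0.5)
        assert len(merged.modules()) == 2
        assert merged.merge_log == []

    def test_three_module_merge_order_matches_hand_trace(self):
        """A-B (cor .8) merge first; the merged eigengene stays far from C."""
        rng = np.random.default_rng(4)
        u = rng.normal(size=60)
        u = (u - u.mean()) / u.std()
        _, b = _correlated_profiles(0.8, seed=5)
        # reuse u as profile A; construct B at cor .8 to A, C near-orthogonal
        w = rng.normal(size=60)
        w = w - w.mean() - u * (u @ (w - w.mean())) / (u @ u)
        w /= w.std()
        a_prof = u
        b_prof = 0.8 * u + 0.6 * w
        q = rng.normal(size=60)
        for base in (u, w):
            q = q - base * (base @ q) / (base @ base)
        c_prof = q / q.std() - 0.1 * u
        expr, labels = self._expr_for([a_prof, b_prof, c_prof], genes_per=4)
        # module_1 larger so module_2 is absorbed into it
        extra = {}
        vals = expr.values.copy()
        vals.loc["M1_extra"] = a_prof + 1e-3
        expr = ExpressionMatrix(vals)
        labels["M1_extra"] = "module_1"
        merged = merge_modules(expr, ModuleSet(labels=labels), 0.5)
        assert len(merged.merge_log) == 1
        absorbed, survivor, diss = merged.merge_log[0]
        assert (absorbed, survivor) == ("module_2", "module_1")
        assert diss == pytest.approx(0.2, abs=0.05)
        assert set(merged.modules()) == {"module_1", "module_3"}


class TestTraitCorrelation:
    def test_trait_equal_to_eigengene(self):
        rng = np.random.default_rng(5)
        me = pd.DataFrame({"module_1": rng.normal(size=20)})
        traits = pd.DataFrame({"t": me["module_1"].values})
        st_ = module_trait_correlation(me, traits)
        assert st_.module_trait_cor.iloc[0, 0] == pytest.approx(1.0)
        assert st_.module_trait_p.iloc[0, 0] < 1e-12

    def test_zero_correlation_gives_p_one(self):
        me = pd.DataFrame({"m": [1.0, -1.0, 1.0, -1.0]})
        traits = pd.DataFrame({"t": [1.0, 1.0, -1.0, -1.0]})
        st_ = module_trait_correlation(me, traits)
        assert st_.module_trait_cor.iloc[0, 0] == pytest.approx(0.0, abs=1e-15)
        assert st_.module_trait_p.iloc[0, 0] == pytest.approx(1.0)

    def test_p_matches_t_distribution_oracle(self):
        """r = 0.73 over 76 samples: the printed module-trait correlation scale."""
        r, n = 0.73, 76
        u, v = _correlated_profiles(r, n=n, seed=8)
        # force exact correlation by orthogonal construction
        me = pd.DataFrame({"m": u})
        traits = pd.DataFrame({"t": v})
        st_ = module_trait_correlation(me, traits)
        r_obs = st_.module_trait_cor.iloc[0, 0]
        t = r_obs * np.sqrt(n - 2) / np.sqrt(1 - r_obs**2)
        expected = 2 * stats.t.sf(abs(t), df=n - 2)
        assert st_.module_trait_p.iloc[0, 0] == pytest.approx(expected, rel=1e-10)
        assert r_obs == pytest.approx(0.73, abs=1e-9)

    def test_too_few_samples(self):
        me = pd.DataFrame({"m": [1.0, 2.0]})
        with pytest.raises(DataError):
            module_trait_correlation(me, pd.DataFrame({"t": [1.0, 2.0]}))


class TestGeneTraitStats:
    def test_gene_equal_to_trait_has_gs_one(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(3, 15))
        expr = make_expression(x)
        labels = {g: "module_1" for g in expr.gene_ids}
        me = module_eigengenes(expr, labels)
        traits = pd.DataFrame({"t": x[0]}, index=expr.sample_ids)
        st_ = gene_trait_stats(expr, me, labels, traits)
        assert st_.gs.iloc[0, 0] == pytest.approx(1.0)

    def test_orthogonal_gene_has_mm_zero(self):
        me_prof = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        ortho = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0])
        expr = make_expression(np.vstack([me_prof, me_prof, ortho]))
        labels = {"G001": "module_1", "G002": "module_1", "G003": "grey"}
        me = module_eigengenes(expr, labels)
        st_ = gene_trait_stats(
            expr, me, labels, pd.DataFrame({"t": me_prof}, index=expr.sample_ids)
        )
        assert st_.mm.loc["G003", "module_1"] == pytest.approx(0.0, abs=1e-12)

    def test_driving_module_genes_have_higher_gs_than_grey(self):
        from nuegrn import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(
            n_genes=150,
            n_modules=2,
            module_sizes=[50, 50],  # 50 grey genes left over
            phenotype_loadings={"t": [1.0, 0.0]},
            n_tfs=0,
            tf_out_degree=0,
            seed=9,
        )
        ds = simulate_dataset(cfg)
        expr = average_replicates(ds.expression)
        labels = ds.true_module_labels
        me = module_eigengenes(expr, labels)
        key = ds.phenotypes["variety"] + "_" + ds.phenotypes["condition"]
        traits = pd.DataFrame({"t": ds.phenotypes["t"].values}, index=key)
        traits = traits.loc[expr.sample_ids]
        st_ = gene_trait_stats(expr, me, labels, traits)
        m1 = [g for g, m in labels.items() if m == "module_1"]
        grey = [g for g, m in labels.items() if m == "grey"]
        assert st_.gs.loc[m1, "t"].abs().mean() > st_.gs.loc[grey, "t"].abs().mean()

    def test_agreement_with_direct_correlation(self, four_module_dataset):
        ds = four_module_dataset
        expr = average_replicates(ds.expression)
        labels = ds.true_module_labels
        me = module_eigengenes(expr, labels)
        rng = np.random.default_rng(10)
        traits = pd.DataFrame(
            {"t": rng.normal(size=expr.n_samples)}, index=expr.sample_ids
        )
        st_ = gene_trait_stats(expr, me, labels, traits)
        for g in expr.gene_ids[:5]:
            direct = np.corrcoef(expr.values.loc[g], traits["t"])[0, 1]
            assert st_.gs.loc[g, "t"] == pytest.approx(direct, abs=1e-10)


class TestHubFilter:
    def _stats(self, gs_vals, mm_vals, genes):
        gs = pd.DataFrame({"t": gs_vals}, index=genes)
        mm = pd.DataFrame({"module_1": mm_vals}, index=genes)
        return CorrelationStats(gs=gs, mm=mm)

    def test_identical_scores_all_pass(self):
        genes = ["a", "b", "c"]
        labels = {g: "module_1" for g in genes}
        st_ = self._stats([0.5, 0.5, 0.5], [0.4, 0.4, 0.4], genes)
        assert filter_hub_genes(labels, st_, "module_1", "t") == set(genes)

    def test_direct_evaluation(self):
        genes = ["a", "b"]
        labels = {g: "module_1" for g in genes}
        st_ = self._stats([0.9, 0.1], [0.9, 0.1], genes)
        assert filter_hub_genes(labels, st_, "module_1", "t") == {"a"}

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(11)
        genes = [f"g{i}" for i in range(100)]
        labels = {g: "module_1" for g in genes}
        gs_vals = rng.uniform(-1, 1, size=100)
        mm_vals = rng.uniform(-1, 1, size=100)
        st_ = self._stats(gs_vals, mm_vals, genes)
        got = filter_hub_genes(labels, st_, "module_1", "t")
        gs_cut = np.abs(gs_vals).mean()
        mm_cut = np.abs(mm_vals).mean()
        expected = {
            g
            for g, gv, mv in zip(genes, gs_vals, mm_vals)
            if abs(gv) >= gs_cut and abs(mv) >= mm_cut
        }
        assert got == expected
        assert got <= set(genes)
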