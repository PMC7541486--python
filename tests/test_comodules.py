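"""Consensus co-expression networks: TOM algebra against the hand formula,
scale-free power selection, planted-block module recovery, kIM-driven
refinement, the filter cascade and the VIF-corrected rank-sum test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from episcope.comodules import (
    GeneModule,
    TOMStack,
    _overlap_stage,
    consensus_tom,
    detect_modules,
    filter_modules,
    injury_signature_p,
    kim_matrix,
    modules_from_labels,
    module_expression,
    pick_soft_threshold,
    refine_modules,
    scale_free_fit_r2,
    select_genes,
    signed_hybrid_adjacency,
    tom_from_adjacency,
    vif_ranksum_enrichment,
)
from episcope.core import ValidationError

from conftest import make_annotated


def block_tom(sizes, within, between=0.01, background=0, bg_level=0.02, seed=0):
    """Synthetic consensus TOM with planted blocks."""
    rng = np.random.default_rng(seed)
    n = sum(sizes) + background
    T = np.full((n, n), between)
    start = 0
    for size in sizes:
        T[start:start + size, start:start + size] = within
        start += size
    T[start:, :] = bg_level
    T[:, start:] = bg_level
    T += rng.uniform(0, 1e-3, size=(n, n))
    T = (T + T.T) / 2
    np.fill_diagonal(T, 1.0)
    genes = pd.Index([f"g{i:03d}" for i in range(n)])
    return TOMStack(pd.DataFrame(T, index=genes, columns=genes), 6, 1, 1.0, 0.5)


class TestSelectGenes:
    def _cohort(self, n_cells=40, n_genes=30):
        rng = np.random.default_rng(0)
        counts = rng.poisson(3, size=(n_cells, n_genes))
        counts[:, 0] = 0
        counts[:19, 0] = 1  # gene present in 19 cells -> excluded
        return make_annotated(
            counts, ["s1"] * (n_cells // 2) + ["s2"] * (n_cells - n_cells // 2),
            ["control"] * (n_cells // 2) + ["case"] * (n_cells - n_cells // 2),
            ["A"] * n_cells,
        )

    def test_rare_gene_excluded(self):
        data = self._cohort()
        genes = select_genes(data, "fam", min_cells=20, n_pcs=5, top_n=50)
        assert "g0" not in genes

    def test_dominant_gene_ranks_first(self):
        # g3 carries the dominant shared signal; a few genes echo it weakly,
        # so PC1 aligns with g3 and it attains the largest absolute loading
        rng = np.random.default_rng(1)
        counts = rng.poisson(2, size=(60, 20)).astype(float)
        signal = np.repeat([0, 40], 30)
        counts[:, 3] = signal
        for j in (4, 5, 6, 7):
            counts[:, j] = rng.poisson(2, size=60) + 0.15 * signal
        data = make_annotated(
            counts, ["s1"] * 30 + ["s2"] * 30,
            ["control"] * 30 + ["case"] * 30, ["A"] * 60,
        )
        genes = select_genes(data, "fam", min_cells=5, n_pcs=1, top_n=1)
        assert list(genes) == ["g3"]

    def test_top_n_capped_with_warning(self):
        data = self._cohort()
        with pytest.warns(UserWarning, match="returning all"):
            genes = select_genes(data, "fam", min_cells=5, n_pcs=5, top_n=10_000)
        assert len(genes) <= 30

    def test_small_cluster_rejected(self):
        data = self._cohort(n_cells=10)
        with pytest.raises(ValidationError, match="cells"):
            select_genes(data, "fam", min_cells=20)


class TestTOM:
    def test_hand_formula_on_four_genes(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 0.8, size=(4, 4))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        tom = tom_from_adjacency(a)
        k = a.sum(axis=1)
        for i in range(4):
            for j in range(4):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                num = sum(a[i, u] * a[u, j] for u in range(4)) + a[i, j]
                den = min(k[i], k[j]) + 1 - a[i, j]
                assert tom[i, j] == pytest.approx(num / den, rel=1e-12)

    def test_isolated_perfect_pair_has_tom_one(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 1.0
        assert tom_from_adjacency(a)[0, 1] == pytest.approx(1.0)

    def test_signed_hybrid_zeroes_negative_correlations(self):
        corr = np.array([[1.0, -0.5], [-0.5, 1.0]])
        a = signed_hybrid_adjacency(corr, 3)
        assert a[0, 1] == 0.0 and a[0, 0] == 0.0

    def test_consensus_of_duplicated_gene_high(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(90, 8))
        X[:, 1] = X[:, 0]  # exact duplicate
        expr = pd.DataFrame(X, columns=[f"g{j}" for j in range(8)])
        tom = consensus_tom(expr, beta=12, n_resamples=5, seed=0)
        assert tom.consensus.loc["g0", "g1"] > 0.95

    def test_independent_genes_consensus_near_zero(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(500, 30)))
        tom = consensus_tom(expr, beta=6, n_resamples=5, seed=0)
        off = tom.consensus.values[np.triu_indices(30, k=1)]
        assert np.median(off) < 0.05

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(60, 12)))
        tom = consensus_tom(expr, beta=4, n_resamples=3, seed=1)
        C = tom.consensus.values
        np.testing.assert_allclose(C, C.T)
        np.testing.assert_allclose(np.diag(C), 1.0)

    def test_too_few_cells_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 5)))
        with pytest.raises(ValidationError, match="30"):
            consensus_tom(expr, beta=6)


class TestSoftThreshold:
    def test_r2_matches_direct_loglog_regression(self):
        rng = np.random.default_rng(0)
        k = rng.pareto(2.0, size=400) + 0.1
        edges = np.linspace(k.min(), k.max() * (1 + 1e-9), 11)
        which = np.digitize(k, edges) - 1
        freq, centers = [], []
        for b in range(10):
            sel = which == b
            if sel.sum():
                freq.append(sel.mean())
                centers.append(k[sel].mean())
        slope, intercept, r, *_ = stats.linregress(np.log10(centers), np.log10(freq))
        assert scale_free_fit_r2(k) == pytest.approx(r**2, rel=1e-10)

    @pytest.fixture(scope="class")
    def scale_free_expr(self):
        # preferential-attachment co-expression: each gene mixes its graph
        # neighbors' latent factors, yielding a power-law degree distribution
        import networkx as nx

        rng = np.random.default_rng(1)
        n_genes, n_cells = 250, 2000
        G = nx.barabasi_albert_graph(n_genes, 2, seed=1)
        F = rng.normal(size=(n_cells, n_genes))
        X = np.zeros((n_cells, n_genes))
        for i in range(n_genes):
            nbrs = list(G.neighbors(i))
            X[:, i] = F[:, i] + 1.2 * F[:, nbrs].sum(axis=1) / np.sqrt(len(nbrs))
            X[:, i] += 0.3 * rng.normal(size=n_cells)
        return pd.DataFrame(X)

    def test_scale_free_network_reaches_target(self, scale_free_expr):
        beta = pick_soft_threshold(scale_free_expr)
        corr = np.corrcoef(scale_free_expr.to_numpy(), rowvar=False)
        k = signed_hybrid_adjacency(corr, beta).sum(axis=1)
        assert scale_free_fit_r2(k) >= 0.93

    def test_fallback_returns_argmax_r2(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(120, 60)))  # no scale-free structure
        beta = pick_soft_threshold(expr, powers=range(1, 8), r2_target=0.999)
        corr = np.nan_to_num(np.corrcoef(expr.to_numpy(), rowvar=False))
        rows = []
        for b in range(1, 8):
            k = signed_hybrid_adjacency(corr, b).sum(axis=1)
            rows.append((b, k.mean(), scale_free_fit_r2(k)))
        df = pd.DataFrame(rows, columns=["beta", "mean_k", "r2"])
        surv = df[(df["mean_k"] < np.percentile(df["mean_k"], 95)) & (df["mean_k"] >= 0.05)]
        if surv.empty:
            surv = df[df["mean_k"] < np.percentile(df["mean_k"], 95)]
        assert beta == int(surv.loc[surv["r2"].idxmax(), "beta"])


class TestDetect:
    def test_planted_blocks_recovered_exactly(self):
        tom = block_tom([20, 20], within=0.5, background=40)
        labels = detect_modules(tom, min_size=15)
        assert set(labels.iloc[:20]) == {labels.iloc[0]} and labels.iloc[0] > 0
        assert set(labels.iloc[20:40]) == {labels.iloc[20]} and labels.iloc[20] > 0
        assert labels.iloc[0] != labels.iloc[20]
        assert (labels.iloc[40:] == 0).all()

    def test_block_below_min_size_rejected(self):
        tom = block_tom([14], within=0.5, background=40)
        labels = detect_modules(tom, min_size=15)
        assert (labels == 0).all()

    def test_gene_order_invariance(self):
        from sklearn.metrics import adjusted_rand_score

        tom = block_tom([18, 22], within=0.4, background=30, seed=3)
        labels = detect_modules(tom)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(tom.genes))
        shuffled = TOMStack(
            tom.consensus.iloc[perm, perm], tom.beta, 1, 1.0, 0.5
        )
        labels2 = detect_modules(shuffled)
        joined = pd.concat([labels.rename("a"), labels2.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0


class TestRefine:
    def test_split_module_merged(self):
        tom = block_tom([30], within=0.5, background=40)
        labels = pd.Series(0, index=tom.genes)
        labels.iloc[:15] = 1
        labels.iloc[15:30] = 2  # the same block split in two
        refined, _ = refine_modules(labels, tom)
        mods = set(refined.iloc[:30])
        assert len(mods) == 1 and 0 not in mods

    def test_misassigned_gene_reassigned(self):
        tom = block_tom([20, 20], within=0.5, background=20)
        labels = pd.Series(0, index=tom.genes)
        labels.iloc[:20] = 1
        labels.iloc[20:40] = 2
        labels.iloc[25] = 1  # block-2 gene mislabeled into module 1
        refined, _ = refine_modules(labels, tom)
        assert refined.iloc[25] == refined.iloc[20]

    def test_planted_partition_is_fixed_point(self):
        tom = block_tom([20, 20], within=0.5, background=40)
        labels = detect_modules(tom)
        refined, _ = refine_modules(labels, tom)
        pd.testing.assert_series_equal(labels, refined)

    def test_kim_excludes_self(self):
        tom = block_tom([20], within=0.5, background=10)
        labels = pd.Series(0, index=tom.genes)
        labels.iloc[:20] = 1
        kim = kim_matrix(labels, tom)
        g = tom.genes[0]
        manual = tom.consensus.loc[g, tom.genes[:20]].sum() - 1.0
        assert kim.loc[g, 1] == pytest.approx(manual)


class TestFilterCascade:
    def test_contained_smaller_module_removed(self):
        tom = block_tom([30], within=0.5, background=30)
        labels = pd.Series(0, index=tom.genes)
        labels.iloc[:30] = 1
        kim = kim_matrix(labels, tom)
        large = GeneModule("L", list(tom.genes[:30]), kim[1])
        # smaller module: 16 of its 20 genes (80%) inside the larger one
        small_genes = list(tom.genes[:16]) + list(tom.genes[30:34])
        small = GeneModule("S", small_genes, kim[1] * 0.9)
        _overlap_stage([large, small], overlap_frac=0.75, overlap_cor=0.75)
        assert small.flags.get("overlap_removed") and not large.flags.get("overlap_removed")

    def test_disjoint_modules_kept(self):
        tom = block_tom([20, 20], within=0.5, background=0)
        labels = detect_modules(tom)
        kim = kim_matrix(labels, tom)
        mods = modules_from_labels(labels, kim)
        _overlap_stage(mods, 0.75, 0.75)
        assert not any(m.flags.get("overlap_removed") for m in mods)

    def test_injury_signature_detected(self):
        tom = block_tom([20], within=0.5, background=40)
        labels = pd.Series(0, index=tom.genes)
        labels.iloc[:20] = 1
        kim = kim_matrix(labels, tom)
        mod = GeneModule("M", list(tom.genes[:20]), kim[1])
        neglog = pd.Series(0.1, index=tom.genes)
        neglog.iloc[:20] = 5.0  # member genes carry the injury signature
        assert injury_signature_p(mod, neglog, n_perm=2000, seed=0) < 0.05

    def test_injury_null_rate_near_alpha(self):
        tom = block_tom([20], within=0.5, background=40)
        labels = pd.Series(0, index=tom.genes)
        labels.iloc[:20] = 1
        kim = kim_matrix(labels, tom)
        mod = GeneModule("M", list(tom.genes[:20]), kim[1])
        rng = np.random.default_rng(1)
        hits = 0
        n_runs = 200
        for i in range(n_runs):
            neglog = pd.Series(-np.log10(rng.uniform(size=len(tom.genes))), index=tom.genes)
            hits += injury_signature_p(mod, neglog, n_perm=400, seed=i) < 0.05
        assert 0.01 <= hits / n_runs <= 0.12

    def _expression_fixture(self, couple_to, seed=0):
        """Cells × genes expression with the module factor coupled either to
        condition or to one sample."""
        rng = np.random.default_rng(seed)
        n_cells, n_genes = 240, 60
        samples = pd.Series(
            np.repeat([f"s{i}" for i in range(8)], n_cells // 8),
            index=[f"c{i}" for i in range(n_cells)],
        )
        condition = samples.map(lambda s: "case" if int(s[1:]) >= 4 else "control")
        X = rng.normal(size=(n_cells, n_genes))
        factor = rng.normal(size=n_cells)
        if couple_to == "condition":
            factor += 2.0 * (condition == "case").to_numpy()
        else:
            factor += 2.0 * (samples == "s2").to_numpy()
        X[:, :15] += factor[:, None] * 0.9
        expr = pd.DataFrame(X, index=samples.index, columns=[f"g{j}" for j in range(n_genes)])
        return expr, samples, condition

    def _module_for(self, expr):
        genes = list(expr.columns)
        kim = pd.Series(0.05, index=genes)
        kim.iloc[:15] = 1.0
        return GeneModule("M", genes[:15], kim)

    def test_condition_coupled_module_survives(self):
        expr, samples, condition = self._expression_fixture("condition")
        mod = self._module_for(expr)
        injury = pd.Series(0.1, index=expr.columns)
        surviving = filter_modules([mod], injury, expr, samples, condition, n_perm=500)
        assert [m.name for m in surviving] == ["M"]
        assert mod.condition_p < 0.05 and mod.condition_coef > 0
        assert mod.condition_ci[0] < mod.condition_coef < mod.condition_ci[1]

    def test_sample_coupled_module_fails_confounding_stage(self):
        expr, samples, condition = self._expression_fixture("sample")
        mod = self._module_for(expr)
        injury = pd.Series(0.1, index=expr.columns)
        surviving = filter_modules([mod], injury, expr, samples, condition, n_perm=500)
        assert surviving == [] and mod.flags.get("sample_confounded")

    def test_module_expression_is_weighted_zscore_sum(self):
        expr, *_ = self._expression_fixture("condition")
        mod = self._module_for(expr)
        me = module_expression(mod, expr)
        sub = expr[mod.genes]
        z = (sub - sub.mean()) / sub.std(ddof=0)
        manual = z @ mod.weights.reindex(mod.genes)
        np.testing.assert_allclose(me, manual, rtol=1e-10)


class TestVifRankSum:
    def _module_and_kim(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n)]
        kim = pd.Series(rng.uniform(0.1, 1.0, n), index=genes)
        members = list(kim.sort_values(ascending=False).index[:20])
        return GeneModule("M", members, kim)

    def test_matches_classical_ranksum_when_uncorrelated(self):
        mod = self._module_and_kim()
        curated = list(mod.kim.sort_values(ascending=False).index[:6])
        # curated genes absent from the expression frame -> VIF = 1
        expr = pd.DataFrame(
            np.random.default_rng(1).normal(size=(50, 3)), columns=["x1", "x2", "x3"]
        )
        z, p = vif_ranksum_enrichment(mod, curated, expr)
        others = [g for g in mod.kim.index if g not in curated]
        oracle = stats.mannwhitneyu(
            mod.kim[curated], mod.kim[others], alternative="greater",
            method="asymptotic", use_continuity=False,
        ).pvalue
        assert p == pytest.approx(float(oracle), rel=1e-9)

    def test_perfect_correlation_shrinks_z_by_sqrt_m(self):
        mod = self._module_and_kim()
        curated = [g for g in mod.genes][:5]
        rng = np.random.default_rng(2)
        base = rng.normal(size=80)
        dup = pd.DataFrame({g: base for g in curated})  # rho = 1 exactly
        z_vif, _ = vif_ranksum_enrichment(mod, curated, dup)
        empty = pd.DataFrame(index=range(80))
        z0, _ = vif_ranksum_enrichment(mod, curated, empty)
        assert z_vif == pytest.approx(z0 / np.sqrt(len(curated)), rel=1e-9)

    def test_random_curated_pvalues_uniform(self):
        mod = self._module_and_kim(n=80)
        expr = pd.DataFrame(index=range(10))  # no expression info -> VIF = 1
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            curated = list(rng.choice(mod.kim.index, size=8, replace=False))
            ps.append(vif_ranksum_enrichment(mod, curated, expr)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_curated_genes_rejected(self):
        mod = self._module_and_kim()
        with pytest.raises(ValidationError, match="curated"):
            vif_ranksum_enrichment(mod, ["nope"], pd.DataFrame())
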