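import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cleavecat.network import (Network, cluster_and_cut, detect_modules,
                               enrichment, hub_edges, kme, merge_modules,
                               module_eigengene, module_trait_correlation,
                               refine_by_kme, scale_free_fit,
                               signed_adjacency, tom_similarity)


def expr_df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(len(arr))],
                        columns=[f"S{j}" for j in range(arr.shape[1])])


class TestAdjacency:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        net = signed_adjacency(expr_df([x, 2 * x + 1]))
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        net = signed_adjacency(expr_df([x, -x]))
        assert net.adjacency[0, 1] == pytest.approx(0.0)

    def test_zero_correlation_value(self):
        # r = 0  =>  a = 0.5^6 = 0.015625
        assert ((1 + 0.0) / 2) ** 6 == 0.015625
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        net = signed_adjacency(expr_df([x, y]))
        assert net.adjacency[0, 1] == pytest.approx(0.015625, abs=5e-3)

    def test_zero_variance_genes_removed(self):
        net = signed_adjacency(expr_df([[1, 1, 1, 1],
                                        [1, 2, 3, 4],
                                        [2, 1, 4, 3]]))
        assert net.gene_ids == ["g1", "g2"]

    def test_unsigned_option(self):
        x = np.arange(10.0)
        net = signed_adjacency(expr_df([x, -x]), signed=False)
        assert net.adjacency[0, 1] == pytest.approx(1.0)  # (-1)^6


class TestScaleFree:
    def test_exact_power_law_fits_well(self):
        # bin counts constructed to follow n(k) ~ k^-2 exactly
        centers = np.linspace(1, 30, 10)
        counts = np.round(2000 * centers ** -2.0).astype(int)
        k = np.repeat(centers, counts)
        fit = scale_free_fit(k)
        assert fit >= 0.9
        # direct regression oracle on the binned representation
        from scipy import stats as sps
        slope, _, r, _, _ = sps.linregress(np.log10(centers),
                                           np.log10(counts / counts.sum()))
        assert fit == pytest.approx(-np.sign(slope) * r ** 2, abs=0.05)

    def test_narrow_band_fits_poorly(self, rng):
        k = rng.uniform(10, 11, size=1000)
        assert scale_free_fit(k) < 0.5

    def test_constant_k_errors(self):
        with pytest.raises(ValueError):
            scale_free_fit(np.ones(100))


class TestTom:
    def test_isolated_nodes(self):
        a = np.eye(4)
        tom = tom_similarity(Network(list("abcd"), a.copy(), a.copy()))
        assert np.allclose(tom, np.eye(4))

    def test_complete_graph(self):
        a = np.ones((5, 5))
        tom = tom_similarity(Network(list("abcde"), a.copy(), a.copy()))
        assert np.allclose(tom, 1.0)

    def test_three_node_half_adjacency_exact(self):
        a = np.full((3, 3), 0.5)
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(Network(list("abc"), a.copy(), a))
        # (0.25 + 0.5) / (min(1,1) + 1 - 0.5) = 0.5
        assert tom[0, 1] == pytest.approx(0.5)

    def test_symmetric_unit_interval(self, rng):
        r = rng.uniform(-1, 1, size=(20, 20))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        a = ((1 + r) / 2) ** 6
        np.fill_diagonal(a, 1.0)
        tom = tom_similarity(Network(list(map(str, range(20))), r, a))
        assert np.allclose(tom, tom.T)
        assert tom.min() >= 0 and tom.max() <= 1 + 1e-12


def _block_expr(rng, sizes, n_samples=24, cor=0.85, n_noise=0):
    rows, labels = [], []
    for m, size in enumerate(sizes, start=1):
        latent = rng.standard_normal(n_samples)
        for _ in range(size):
            rows.append(np.sqrt(cor) * latent
                        + np.sqrt(1 - cor) * rng.standard_normal(n_samples))
            labels.append(m)
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        labels.append(0)
    return expr_df(rows), np.array(labels)


class TestClusterAndCut:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        expr, planted = _block_expr(rng, [40, 40])
        net = signed_adjacency(expr)
        tom = tom_similarity(net)
        _, labels = cluster_and_cut(tom, net.gene_ids)
        assert adjusted_rand_score(planted, labels.values) == 1.0
        assert len(set(labels.values) - {0}) == 2

    def test_identical_profiles_single_module(self, rng):
        base = rng.standard_normal(24)
        expr = expr_df([base + rng.normal(0, 1e-6, 24) for _ in range(40)])
        net = signed_adjacency(expr)
        tom = tom_similarity(net)
        _, labels = cluster_and_cut(tom, net.gene_ids)
        assert (labels.values == 1).all()

    def test_iid_noise_mostly_unassigned(self):
        rng = np.random.default_rng(42)
        expr, _ = _block_expr(rng, [], n_noise=200)
        net = signed_adjacency(expr)
        tom = tom_similarity(net)
        _, labels = cluster_and_cut(tom, net.gene_ids)
        assert (labels.values == 0).mean() >= 0.9

    def test_fewer_genes_than_min_size(self, rng):
        expr, _ = _block_expr(rng, [5])
        net = signed_adjacency(expr)
        tom = tom_similarity(net)
        _, labels = cluster_and_cut(tom, net.gene_ids, min_module_size=30)
        assert (labels.values == 0).all()


class TestEigengene:
    def test_identical_profile_module(self, rng):
        base = rng.standard_normal(10)
        expr = expr_df([2 * base + 3, base - 1, 5 * base])
        labels = pd.Series([1, 1, 1], index=expr.index)
        mes = module_eigengene(expr, labels)
        z = (base - base.mean()) / base.std()
        e = mes.loc["ME1"].to_numpy()
        assert np.allclose(np.abs(np.corrcoef(e, z)[0, 1]), 1.0)
        r, _ = kme(expr, mes)
        assert np.allclose(r["ME1"], 1.0)

    def test_first_pc_optimality_eigendecomposition_oracle(self, rng):
        expr = expr_df(rng.standard_normal((8, 12)))
        labels = pd.Series(1, index=expr.index)
        mes = module_eigengene(expr, labels)
        X = expr.to_numpy()
        Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        w, v = np.linalg.eigh(Z.T @ Z)
        top = v[:, -1]
        e = mes.loc["ME1"].to_numpy()
        assert np.allclose(np.abs(e @ top), 1.0, atol=1e-8)
        # explains at least as much variance as any single member direction
        var_e = ((Z @ e) ** 2).sum()
        for i in range(8):
            d = Z[i] / np.linalg.norm(Z[i])
            assert var_e >= ((Z @ d) ** 2).sum() - 1e-9

    def test_sign_flip_symmetry(self, rng):
        expr = expr_df(rng.standard_normal((6, 10)) + 5)
        labels = pd.Series(1, index=expr.index)
        e1 = module_eigengene(expr, labels).loc["ME1"]
        e2 = module_eigengene(-expr, labels).loc["ME1"]
        assert np.allclose(e1.to_numpy(), -e2.to_numpy())

    def test_constant_module_errors(self):
        expr = expr_df(np.ones((3, 5)))
        with pytest.raises(ValueError):
            module_eigengene(expr, pd.Series(1, index=expr.index))


class TestMergeModules:
    def _labelled(self, rng, latents, size=10, cor=0.95):
        rows, labels = [], []
        for m, z in enumerate(latents, start=1):
            for _ in range(size):
                rows.append(np.sqrt(cor) * z
                            + np.sqrt(1 - cor) * rng.standard_normal(len(z)))
                labels.append(m)
        expr = expr_df(rows)
        return expr, pd.Series(labels, index=expr.index)

    def test_highly_correlated_pair_merged(self, rng):
        z = rng.standard_normal(24)
        z2 = 0.97 * z + 0.1 * rng.standard_normal(24)
        expr, labels = self._labelled(rng, [z, z2])
        merged, mes = merge_modules(expr, labels)
        assert merged.nunique() == 1

    def test_uncorrelated_unchanged(self, rng):
        z1, z2 = rng.standard_normal(24), rng.standard_normal(24)
        expr, labels = self._labelled(rng, [z1, z2])
        merged, _ = merge_modules(expr, labels)
        assert merged.nunique() == 2

    def test_idempotent(self, rng):
        z = rng.standard_normal(24)
        latents = [z, 0.98 * z + 0.05 * rng.standard_normal(24),
                   rng.standard_normal(24)]
        expr, labels = self._labelled(rng, latents)
        m1, _ = merge_modules(expr, labels)
        m2, _ = merge_modules(expr, m1)
        assert m1.equals(m2)

    def test_four_module_exhaustive_merge_order_oracle(self, rng):
        # known correlation structure: A~B strongly, C~D strongly, A!~C
        zA = rng.standard_normal(24)
        zB = 0.97 * zA + 0.1 * rng.standard_normal(24)
        zC = rng.standard_normal(24)
        zD = 0.97 * zC + 0.1 * rng.standard_normal(24)
        expr, labels = self._labelled(rng, [zA, zB, zC, zD])
        merged, _ = merge_modules(expr, labels)
        # exhaustive check: the only partitions reachable by greedy merging
        # at cut 0.75 are {A,B} and {C,D}
        part = {}
        for g, m in merged.items():
            part.setdefault(m, set()).add(labels[g])
        groups = sorted(tuple(sorted(v)) for v in part.values())
        assert groups == [(1, 2), (3, 4)]


class TestKme:
    def test_ten_gene_direct_oracle(self, rng):
        expr = expr_df(rng.standard_normal((10, 14)))
        labels = pd.Series([1] * 5 + [2] * 5, index=expr.index)
        mes = module_eigengene(expr, labels)
        r, p = kme(expr, mes)
        for g in expr.index:
            for me in mes.index:
                expect = np.corrcoef(expr.loc[g], mes.loc[me])[0, 1]
                assert r.loc[g, me] == pytest.approx(expect, abs=1e-10)
        assert ((p >= 0) & (p <= 1)).all().all()

    def test_orthogonal_profile_near_zero(self, rng):
        base = np.array([1.0, -1, 1, -1] * 6)
        orth = np.array([1.0, 1, -1, -1] * 6)
        expr = expr_df([base, base, orth])
        labels = pd.Series([1, 1, 0], index=expr.index)
        mes = module_eigengene(expr, labels)
        r, _ = kme(expr, mes)
        assert abs(r.loc["g2", "ME1"]) < 1e-9


class TestModuleTrait:
    def test_one_hot_eigengene_perfect_correlation(self):
        e = np.array([1.0, 1, 0, 0, 0, 0])
        mes = pd.DataFrame([e], index=["ME1"],
                           columns=[f"S{i}" for i in range(6)])
        traits = pd.DataFrame({"stageA": e, "const": np.ones(6)},
                              index=mes.columns)
        r, p, flags = module_trait_correlation(mes, traits)
        assert r.loc["ME1", "stageA"] == pytest.approx(1.0)
        assert np.isnan(r.loc["ME1", "const"])
        assert not flags.loc["ME1", "const"]

    def test_sample_permutation_invariance(self, rng):
        mes = pd.DataFrame(rng.standard_normal((2, 12)),
                           index=["ME1", "ME2"],
                           columns=[f"S{i}" for i in range(12)])
        traits = pd.DataFrame({"t": rng.standard_normal(12)},
                              index=mes.columns)
        perm = rng.permutation(12)
        r1, _, _ = module_trait_correlation(mes, traits)
        r2, _, _ = module_trait_correlation(
            mes.iloc[:, perm], traits.iloc[perm])
        assert np.allclose(r1.values.astype(float),
                           r2.values.astype(float))


class TestHubEdges:
    def test_small_module_edge_bound(self, rng):
        expr = expr_df(rng.standard_normal((6, 10)))
        net = signed_adjacency(expr)
        tom_similarity(net)
        labels = pd.Series([1, 1, 1, 2, 2, 2], index=expr.index)
        edges = hub_edges(net, labels, module=1, top_k=100)
        assert len(edges) == 3  # C(3,2)

    def test_ranking_full_sort_oracle(self, rng):
        expr = expr_df(rng.standard_normal((20, 15)))
        net = signed_adjacency(expr)
        tom = tom_similarity(net)
        labels = pd.Series(1, index=expr.index)
        edges = hub_edges(net, labels, module=1, top_k=10)
        pos = {g: i for i, g in enumerate(net.gene_ids)}
        all_w = sorted((tom[pos[a], pos[b]]
                        for i, a in enumerate(net.gene_ids)
                        for b in net.gene_ids[i + 1:]), reverse=True)
        assert list(edges["weight"]) == pytest.approx(all_w[:10])
        assert (np.diff(edges["weight"]) <= 1e-12).all()


class TestEnrichment:
    def test_module_equals_universe(self):
        uni = [f"g{i}" for i in range(50)]
        df = enrichment(uni, {"setA": uni[:20]}, uni)
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_two_by_two_exact_tail_sum(self):
        uni = [f"g{i}" for i in range(100)]
        module = uni[:10]
        gene_set = uni[2:22]          # 20 genes, overlap with module = 8
        df = enrichment(module, {"s": gene_set}, uni)
        expect = sum(comb(20, k) * comb(80, 10 - k) for k in range(8, 11)) \
            / comb(100, 10)
        assert df["p"].iloc[0] == pytest.approx(expect)

    def test_bh_monotone_and_order_preserving(self, rng):
        uni = [f"g{i}" for i in range(200)]
        sets = {f"s{j}": list(rng.choice(uni, size=30, replace=False))
                for j in range(8)}
        module = list(rng.choice(uni, size=40, replace=False))
        df = enrichment(module, sets, uni)
        assert (df["p_adjusted"] >= df["p"] - 1e-15).all()
        # adjusted p is a monotone non-decreasing function of raw p
        by_p = df.sort_values("p")
        assert (np.diff(by_p["p_adjusted"]) >= -1e-15).all()

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            enrichment(["a"], {"s": ["a"]}, [])
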