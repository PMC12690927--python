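import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mirnomics import netmod
from mirnomics.netmod import (
    NetworkParams,
    call_hubs,
    detect_modules,
    fit_network,
    module_summaries,
    pick_soft_threshold,
    signed_adjacency,
    topological_overlap,
)


def brute_tom(a):
    """O(n^3) triple-loop topological overlap oracle."""
    n = a.shape[0]
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    k = a0.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a0[i, u] * a0[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a0[i, j]) / (min(k[i], k[j]) + 1 - a0[i, j])
    return tom


def random_adjacency(rng, n):
    m = rng.uniform(0, 1, size=(n, n))
    a = (m + m.T) / 2
    np.fill_diagonal(a, 1.0)
    return a


class TestSignedAdjacency:
    def test_cor_one_gives_one(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(c, 12)[0, 1] == 1.0

    def test_cor_minus_one_gives_zero(self):
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert signed_adjacency(c, 12)[0, 1] == 0.0

    def test_cor_zero_closed_form(self):
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(c, 12)[0, 1] == 0.5 ** 12 == 0.000244140625

    def test_monotone_in_correlation(self):
        cors = np.linspace(-1, 1, 41)
        c = np.eye(2)
        vals = []
        for r in cors:
            c[0, 1] = c[1, 0] = r
            vals.append(signed_adjacency(c, 7)[0, 1])
        assert (np.diff(vals) >= 0).all()

    def test_out_of_range_rejected(self):
        c = np.array([[1.0, 1.5], [1.5, 1.0]])
        with pytest.raises(ValueError):
            signed_adjacency(c, 12)

    def test_dataframe_labels_preserved(self):
        c = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        adj = signed_adjacency(c, 12)
        assert list(adj.index) == ["a", "b"]


class TestTopologicalOverlap:
    def test_two_nodes_full_edge(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert topological_overlap(a)[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair(self):
        a = np.eye(4)
        assert topological_overlap(a)[0, 1] == 0.0

    def test_matches_brute_force_small(self, rng):
        for n in range(3, 13):
            a = random_adjacency(rng, n)
            assert np.allclose(topological_overlap(a), brute_tom(a), atol=1e-12)

    def test_symmetric_unit_interval(self, rng):
        a = random_adjacency(rng, 15)
        tom = topological_overlap(a)
        assert np.allclose(tom, tom.T, atol=1e-12)
        assert tom.min() >= 0 and tom.max() <= 1

    def test_asymmetric_rejected(self):
        a = np.array([[1.0, 0.2], [0.4, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            topological_overlap(a)


def _block_expression(rng, block_sizes, within_cor, n_samples=30):
    rows, ids = [], []
    for b, size in enumerate(block_sizes):
        factor = rng.standard_normal(n_samples)
        lam = np.sqrt(within_cor)
        for i in range(size):
            rows.append(lam * factor + np.sqrt(1 - within_cor) * rng.standard_normal(n_samples))
            ids.append(f"b{b}_f{i}")
    return pd.DataFrame(rows, index=ids,
                        columns=[f"s{j}" for j in range(n_samples)])


class TestDetectModules:
    def test_two_planted_blocks_recovered(self, rng):
        expr = _block_expression(rng, [15, 15], within_cor=0.9)
        model = fit_network(expr, NetworkParams(beta=6))
        assert model.modules.nunique() == 2
        truth = [i.split("_")[0] for i in model.modules.index]
        assert adjusted_rand_score(truth, model.modules) == 1.0

    def test_identical_profiles_single_module(self):
        profile = np.sin(np.arange(10))
        expr = pd.DataFrame([profile] * 6, index=[f"f{i}" for i in range(6)],
                            columns=[f"s{j}" for j in range(10)])
        tom = topological_overlap(signed_adjacency(np.corrcoef(expr), 6))
        modules = detect_modules(pd.DataFrame(tom, index=expr.index, columns=expr.index),
                                 NetworkParams(min_module_size=2))
        assert modules.nunique() == 1

    def test_fewer_features_than_min_size_flagged(self, caplog):
        tom = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
        with caplog.at_level("WARNING"):
            modules = detect_modules(tom, NetworkParams(min_module_size=10))
        assert modules.nunique() == 1
        assert "min_module_size" in caplog.text

    def test_labels_ordered_by_size(self, rng):
        expr = _block_expression(rng, [20, 12], within_cor=0.9)
        model = fit_network(expr, NetworkParams(beta=6, min_module_size=5))
        sizes = model.modules.value_counts()
        assert list(sizes.index) == sorted(sizes.index)
        assert sizes.loc[1] >= sizes.loc[2]


class TestModuleSummaries:
    def test_identical_features_mm_one(self):
        profile = np.array([1.0, 2.0, 0.5, 3.0, 1.5, 2.5])
        expr = pd.DataFrame([profile, profile, profile],
                            index=["a", "b", "c"], columns=[f"s{j}" for j in range(6)])
        modules = pd.Series(1, index=expr.index)
        adjacency = pd.DataFrame(np.ones((3, 3)), index=expr.index, columns=expr.index)
        _, mm, _ = module_summaries(expr, modules, adjacency)
        assert np.allclose(mm, 1.0)

    def test_orthogonal_feature_mm_zero(self):
        s = np.array([1.0, -1.0, 1.0, -1.0])
        t = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to s
        expr = pd.DataFrame([s, s, t], index=["a", "b", "c"],
                            columns=[f"s{j}" for j in range(4)])
        modules = pd.Series(1, index=expr.index)
        adjacency = pd.DataFrame(np.eye(3), index=expr.index, columns=expr.index)
        eig, mm, _ = module_summaries(expr, modules, adjacency)
        assert abs(mm["c"]) == pytest.approx(0.0, abs=1e-10)

    def test_k_within_equal_adjacency(self):
        ids = ["a", "b", "c"]
        adjacency = pd.DataFrame(0.5, index=ids, columns=ids)
        np.fill_diagonal(adjacency.values, 1.0)
        expr = pd.DataFrame(np.random.default_rng(0).standard_normal((3, 8)),
                            index=ids, columns=[f"s{j}" for j in range(8)])
        modules = pd.Series(1, index=ids)
        _, _, k_within = module_summaries(expr, modules, adjacency)
        assert np.allclose(k_within, 1.0)

    def test_singleton_module_eigengene_is_profile(self):
        profile = np.array([2.0, 4.0, 6.0, 8.0])
        expr = pd.DataFrame([profile], index=["solo"], columns=list("wxyz"))
        modules = pd.Series(1, index=["solo"])
        adjacency = pd.DataFrame([[1.0]], index=["solo"], columns=["solo"])
        eig, mm, _ = module_summaries(expr, modules, adjacency)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(eig[1].to_numpy(), z)
        assert mm["solo"] == pytest.approx(1.0)


class TestCallHubs:
    def _params(self):
        return NetworkParams()

    def test_mm_gate_dominates(self):
        ids = [f"f{i}" for i in range(8)]
        modules = pd.Series(1, index=ids)
        mm = pd.Series([0.9, 0.8, 0.76, 0.5, 0.5, 0.5, 0.5, 0.5], index=ids)
        kw = pd.Series(np.arange(8, 0, -1, dtype=float), index=ids)
        hubs = call_hubs(mm, kw, modules, self._params())
        assert hubs[1] == ["f0", "f1", "f2"]

    def test_top_five_rule(self):
        ids = [f"f{i}" for i in range(6)]
        modules = pd.Series(1, index=ids)
        mm = pd.Series(1.0, index=ids)
        kw = pd.Series([6.0, 5.0, 4.0, 3.0, 2.0, 1.0], index=ids)
        hubs = call_hubs(mm, kw, modules, self._params())
        assert len(hubs[1]) == 5
        assert "f5" not in hubs[1]

    def test_mm_exactly_threshold_excluded(self):
        ids = ["a", "b", "c"]
        modules = pd.Series(1, index=ids)
        mm = pd.Series([0.75, 0.8, 0.9], index=ids)
        kw = pd.Series([3.0, 2.0, 1.0], index=ids)
        hubs = call_hubs(mm, kw, modules, self._params())
        assert "a" not in hubs[1]
        assert hubs[1] == ["b", "c"]


class TestPickSoftThreshold:
    def test_single_candidate_returned(self, rng):
        expr = _block_expression(rng, [30], within_cor=0.5)
        beta, table = pick_soft_threshold(expr, candidate_betas=(12,))
        assert beta == 12
        assert len(table) == 1

    def test_scale_free_generative_data_fits(self):
        # hub-structured loadings produce an approximately scale-free
        # connectivity distribution at some soft power
        rng = np.random.default_rng(42)
        n_feat, n_samp = 200, 30
        u = rng.uniform(0.2, 1.0, n_feat)
        f = rng.standard_normal(n_samp)
        x = u[:, None] * f[None, :] + np.sqrt(1 - u ** 2)[:, None] * \
            rng.standard_normal((n_feat, n_samp))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(n_feat)],
                            columns=[f"s{j}" for j in range(n_samp)])
        beta, table = pick_soft_threshold(expr)
        assert table["fit"].max() >= 0.8
        assert table.loc[table["beta"] == beta, "fit"].iloc[0] >= 0.8

    def test_noise_data_falls_back_to_argmax(self, rng, caplog):
        x = rng.standard_normal((40, 12))
        expr = pd.DataFrame(x, index=[f"g{i}" for i in range(40)],
                            columns=[f"s{j}" for j in range(12)])
        with caplog.at_level("WARNING"):
            beta, table = pick_soft_threshold(expr, candidate_betas=(1, 2),
                                              fit_cut=0.999)
        assert beta in (1, 2)
        assert "falling back" in caplog.text

    def test_too_few_features_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((10, 12)))
        with pytest.raises(ValueError, match="20 features"):
            pick_soft_threshold(expr)

    def test_too_few_samples_rejected(self, rng):
        expr = pd.DataFrame(rng.standard_normal((30, 5)))
        with pytest.raises(ValueError, match="8 samples"):
            pick_soft_threshold(expr)


class TestPlantedRecovery:
    """Stochastic recovery of the generator's planted modules and hubs."""

    def test_module_recovery_ari(self, module_cohorts):
        ok = 0
        for bundle in module_cohorts[:10]:
            logv = np.log2(bundle.mirna_counts.subset_class("mature").values + 1)
            model = fit_network(logv, NetworkParams())
            truth = pd.Series(bundle.truth["modules"])
            ari = adjusted_rand_score(truth[model.modules.index], model.modules)
            ok += ari >= 0.8
        assert ok >= 8

    def test_hub_recovery(self, module_cohorts):
        got = tot = 0
        for bundle in module_cohorts[:10]:
            logv = np.log2(bundle.mirna_counts.subset_class("mature").values + 1)
            model = fit_network(logv, NetworkParams())
            hubs_all = {h for hs in model.hubs.values() for h in hs}
            planted = set(bundle.truth["module_hubs"].values())
            got += sum(1 for h in planted if h in hubs_all)
            tot += len(planted)
        assert got / tot >= 0.8
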