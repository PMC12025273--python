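"""Co-expression network construction and module detection."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dims.simulate import SimulationConfig, simulate_expression
from dims.wgcna import (
    ModuleAssignment,
    build_network,
    detect_modules,
    pick_soft_threshold,
    tom_similarity,
)
from oracles import bf_tom


def _scale_free_expr(n_genes: int = 400, n_samples: int = 300,
                     gamma: float = 2.5, seed: int = 2) -> pd.DataFrame:
    """Expression whose soft-thresholded connectivity is power-law: genes
    load a single factor with Pareto-distributed loadings v, so that
    k_i ~ v_i^beta stays heavy-tailed at every power."""
    rng = np.random.default_rng(seed)
    lo, hi, a = 0.1, 0.95, 1.0 - gamma
    v = (lo**a + rng.uniform(size=n_genes) * (hi**a - lo**a)) ** (1 / a)
    f = rng.standard_normal(n_samples)
    x = v[:, None] * f + np.sqrt(1 - v**2)[:, None] * rng.standard_normal(
        (n_genes, n_samples)
    )
    return pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)])


class TestTOM:
    def test_perfectly_correlated_pair_has_unit_overlap(self):
        # two genes, a_12 = 1: TOM = (0 + 1) / (0 + 1 - 1 + 1) = 1
        adj = np.array([[1.0, 1.0], [1.0, 1.0]])
        tom = tom_similarity(adj)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_matches_bruteforce_on_handwritten_adjacency(self):
        adj = np.array(
            [
                [1.0, 0.8, 0.3, 0.1],
                [0.8, 1.0, 0.5, 0.2],
                [0.3, 0.5, 1.0, 0.6],
                [0.1, 0.2, 0.6, 1.0],
            ]
        )
        np.testing.assert_allclose(tom_similarity(adj), bf_tom(adj), atol=1e-12)

    def test_bounded_and_symmetric(self):
        rng = np.random.default_rng(5)
        cor = np.corrcoef(rng.standard_normal((15, 40)))
        adj = np.abs(cor) ** 6
        np.fill_diagonal(adj, 1.0)
        tom = tom_similarity(adj)
        assert np.all(tom >= 0) and np.all(tom <= 1 + 1e-12)
        assert np.abs(tom - tom.T).max() < 1e-12

    def test_raising_beta_never_increases_adjacency(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.standard_normal((12, 30)),
                            index=[f"g{i}" for i in range(12)])
        off = ~np.eye(12, dtype=bool)
        a_lo = build_network(expr, beta=4).adjacency[off]
        a_hi = build_network(expr, beta=8).adjacency[off]
        assert np.all(a_hi <= a_lo + 1e-15)

    def test_zero_variance_gene_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0], [0.1, 0.4, 0.2, 0.9]], index=["flat", "ok"]
        )
        with pytest.raises(ValueError, match="zero-variance"):
            build_network(expr, beta=6)


class TestSoftThreshold:
    def test_independent_noise_never_fits_scale_free(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((1000, 30)),
                            index=[f"g{i}" for i in range(1000)])
        with pytest.warns(UserWarning, match="no power reached"):
            res = pick_soft_threshold(expr, powers=range(1, 7))
        assert res.table.sft_r2.max() < 0.5
        assert not res.criterion_met

    def test_chosen_beta_is_smallest_power_meeting_target(self):
        expr = _scale_free_expr(seed=2)
        res = pick_soft_threshold(expr, powers=range(1, 13), target_r2=0.8)
        meeting = res.table[res.table.sft_r2 >= 0.8]
        assert len(meeting), "fixture should reach the fit target"
        assert res.criterion_met
        assert res.chosen_beta == int(meeting.beta.iloc[0])

    @pytest.mark.parametrize("beta", [10, 16, 20])
    def test_published_betas_accepted_as_overrides(self, beta, intact_study):
        # explicit powers bypass selection entirely
        _, mats, _ = intact_study
        net = build_network(mats["sham"].iloc[:50], beta=beta)
        assert net.beta == beta
        assert net.adjacency.shape == (50, 50)


class TestModuleDetection:
    def test_recovers_planted_modules(self):
        cfg = SimulationConfig(
            n_genes=200, n_samples_per_group=50, module_sizes=(30,) * 5,
            module_corr=0.9, disruption_map={}, deg_map={}, seed=0,
        )
        mats, truth = simulate_expression(cfg)
        net = build_network(mats["sham"], beta=6)
        mod = detect_modules(net, min_size=3)
        assert len(mod.module_ids) == 5
        planted = [truth.module_of[g] for g in mod.genes]
        assert adjusted_rand_score(planted, mod.labels) >= 0.8

    def test_pure_noise_is_mostly_unassigned(self):
        cfg = SimulationConfig(
            n_genes=200, module_sizes=(), module_corr=(),
            disruption_map={}, deg_map={}, seed=3,
        )
        mats, _ = simulate_expression(cfg)
        mod = detect_modules(build_network(mats["sham"], beta=6), min_size=3)
        assert (mod.labels == 0).mean() >= 0.5

    def test_min_size_honoured_and_labels_sorted_by_size(self, intact_study):
        _, mats, _ = intact_study
        mod = detect_modules(build_network(mats["sham"], beta=6), min_size=3)
        sizes = [len(mod.module_genes(k)) for k in mod.module_ids]
        assert all(s >= 3 for s in sizes)
        assert sizes == sorted(sizes, reverse=True)

    def test_gene_order_does_not_change_partition(self, intact_study):
        _, mats, _ = intact_study
        expr = mats["sham"]
        rng = np.random.default_rng(9)
        perm = rng.permutation(len(expr))
        mod1 = detect_modules(build_network(expr, beta=6))
        mod2 = detect_modules(build_network(expr.iloc[perm], beta=6))
        d1, d2 = mod1.as_dict(), mod2.as_dict()
        labels1 = [d1[g] for g in expr.index]
        labels2 = [d2[g] for g in expr.index]
        assert adjusted_rand_score(labels1, labels2) == pytest.approx(1.0)

    def test_fewer_genes_than_min_size_all_grey(self):
        expr = pd.DataFrame(
            np.random.default_rng(0).standard_normal((2, 10)), index=["a", "b"]
        )
        net = build_network(expr, beta=2)
        with pytest.warns(UserWarning):
            mod = detect_modules(net, min_size=3)
        assert set(mod.labels) == {0}

    def test_module_names_and_colors(self):
        mod = ModuleAssignment(["a", "b", "c"], [1, 1, 0], prefix="combo-Mod")
        assert mod.module_name(1) == "combo-Mod-1"
        assert mod.color(0) == "grey"
        frame = mod.as_frame()
        assert list(frame.columns) == ["gene", "module_label", "module", "color"]
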