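"""Variance-component mapping and trial data generation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from swcrt import (
    CorrelationParams,
    TrialConfig,
    TrialDataset,
    correlations_from_components,
    simulate_trial,
    variance_components,
)
from swcrt.datagen import replicate_seed


class TestVarianceComponents:
    def test_no_clustering(self):
        assert variance_components(0.0, 0.7, 1.0) == (0.0, 0.0)

    def test_exchangeable_inversion(self):
        # rho1 = sigma_C2 / (sigma_C2 + 1) solved at rho1 = 0.05
        sC2, sCP2 = variance_components(0.05, 1.0, 1.0)
        assert sC2 == pytest.approx(0.05 / 0.95, rel=1e-12)
        assert sCP2 == 0.0

    def test_block_inversion(self):
        sC2, sCP2 = variance_components(0.1, 0.8, 1.0)
        assert sC2 == pytest.approx(0.8 * 0.1 / 0.9, rel=1e-12)
        assert sCP2 == pytest.approx(0.2 * 0.1 / 0.9, rel=1e-12)

    def test_degenerate_rho_rejected(self):
        with pytest.raises(ValueError):
            variance_components(1.0, 0.8, 1.0)

    @settings(deadline=None, max_examples=60)
    @given(
        rho1=st.floats(0.001, 0.95),
        cac=st.floats(0.05, 1.0),
        se2=st.floats(0.1, 10.0),
    )
    def test_round_trip(self, rho1, cac, se2):
        sC2, sCP2 = variance_components(rho1, cac, se2)
        r1, r = correlations_from_components(sC2, sCP2, se2)
        assert r1 == pytest.approx(rho1, rel=1e-10)
        assert r == pytest.approx(cac, rel=1e-10)

    def test_between_period_correlation_identity(self):
        p = CorrelationParams(rho1=0.1, cac=0.8)
        assert p.rho2 == pytest.approx(0.08)
        assert p.rho2 <= p.rho1
        assert CorrelationParams(rho1=0.1, cac=1.0).rho2 == pytest.approx(0.1)


class TestSimulateTrial:
    def test_shape_and_balance(self):
        cfg = TrialConfig(S=2, T=5, m=10, rho1=0.05, cac=0.8)
        data = simulate_trial(cfg, seed=1)
        assert data.n_obs == 8 * 5 * 10
        counts = data.frame.groupby(["cluster", "period"])["y"].count()
        assert (counts == 10).all()
        # treatment column mirrors the design matrix
        treat = (
            data.frame.groupby(["cluster", "period"])["treatment"]
            .first()
            .unstack()
            .to_numpy()
        )
        np.testing.assert_array_equal(treat, data.design.X)

    def test_determinism(self):
        cfg = TrialConfig(S=1, T=5, m=10, rho1=0.1, cac=0.8)
        a = simulate_trial(cfg, seed=42)
        b = simulate_trial(cfg, seed=42)
        np.testing.assert_array_equal(a.frame["y"], b.frame["y"])
        c = simulate_trial(cfg, seed=43)
        assert not np.array_equal(a.frame["y"], c.frame["y"])

    def test_iid_case_moments(self):
        """With rho1 = 0 outcomes are iid N(beta_j, sigma_e2) in period j."""
        cfg = TrialConfig(S=5, T=5, m=200, rho1=0.0, cac=0.8)
        data = simulate_trial(cfg, seed=3)
        y = data.y_array()  # (N, T, m)
        beta = np.arange(1, 6) / 5
        means = y.mean(axis=(0, 2))
        assert np.abs(means - beta).max() < 4 / np.sqrt(20 * 200)
        resid = y - beta[None, :, None]
        assert resid.std() == pytest.approx(1.0, abs=0.02)
        # no intracluster correlation: cluster means of residuals are tight
        assert resid.mean(axis=(1, 2)).std() < 3 / np.sqrt(5 * 200)

    def test_empirical_intracluster_correlations(self):
        """Pooled cross-moments recover rho1 and rho2 = rho1 * r."""
        cfg = TrialConfig(S=5, T=5, m=20, rho1=0.1, cac=0.8)
        beta = np.arange(1, 6) / 5
        within, between, var = [], [], []
        for rep in range(200):
            data = simulate_trial(cfg, seed=rep)
            r = data.y_array() - beta[None, :, None]  # theta = 0
            cell_sum = r.sum(axis=2)
            sq = (r**2).sum()
            m = cfg.m
            # mean cross product within a cell: rho1 * total variance
            within.append(
                ((cell_sum**2).sum() - sq) / (data.design.N * 5 * m * (m - 1))
            )
            cl_sum = cell_sum.sum(axis=1)
            between.append(
                ((cl_sum**2 - (cell_sum**2).sum(axis=1)).sum())
                / (data.design.N * 5 * 4 * m * m)
            )
            var.append(np.mean(r**2))  # true mean is 0: unbiased
        total_var = np.mean(var)
        rho1_emp = np.mean(within) / total_var
        rho2_emp = np.mean(between) / total_var
        assert total_var == pytest.approx(1.0 / 0.9, abs=0.01)
        assert rho1_emp == pytest.approx(0.1, abs=0.01)
        assert rho2_emp == pytest.approx(0.08, abs=0.01)

    def test_exchangeable_has_no_cluster_period_component(self):
        """With r = 1, cell means within a cluster co-vary only through the
        cluster effect: the covariance between different periods equals the
        variance attributable to the cluster level."""
        cfg = TrialConfig(S=5, T=5, m=10, rho1=0.2, cac=1.0)
        covs = []
        for rep in range(300):
            data = simulate_trial(cfg, seed=rep)
            cm = data.cell_means() - (np.arange(1, 6) / 5)[None, :]
            c = np.cov(cm.T)
            covs.append(c[np.triu_indices(5, 1)].mean())
        sigma_C2 = 0.2 / 0.8
        assert np.mean(covs) == pytest.approx(sigma_C2, abs=0.02)

    def test_mismatched_design_rejected(self):
        from swcrt import build_standard_sw

        cfg = TrialConfig(S=2, T=5, m=10, rho1=0.05, cac=0.8)
        with pytest.raises(ValueError):
            simulate_trial(cfg, design=build_standard_sw(1, 5), seed=0)

    def test_csv_round_trip(self, tmp_path):
        cfg = TrialConfig(S=1, T=3, m=4, rho1=0.05, cac=1.0)
        data = simulate_trial(cfg, seed=9)
        path = tmp_path / "trial.csv"
        data.to_csv(path)
        back = TrialDataset.from_csv(path)
        np.testing.assert_allclose(back.frame["y"], data.frame["y"])
        assert back.truth == data.truth
        assert back.m == data.m


class TestReplicateSeeds:
    def test_streams_unique_and_reproducible(self):
        seen = set()
        for cfg_idx in range(3):
            for rep in range(5):
                s1 = replicate_seed(7, cfg_idx, rep)
                s2 = replicate_seed(7, cfg_idx, rep)
                key = s1.spawn_key
                assert key == s2.spawn_key and s1.entropy == s2.entropy
                assert (s1.entropy, key) not in seen
                seen.add((s1.entropy, key))
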