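"""REML estimation: exactness, oracle equivalence, boundary behavior."""

import numpy as np
import pandas as pd
import pytest

from swcrt import TrialConfig, fit_reml, simulate_trial
from swcrt.model import SteppedWedgeLMM


def _noise_free_frame(S=2, T=5, m=3, theta=0.7):
    from swcrt import build_standard_sw

    d = build_standard_sw(S, T)
    rows = []
    for i in range(d.N):
        for j in range(T):
            for k in range(m):
                rows.append(
                    {
                        "cluster": i + 1,
                        "period": j + 1,
                        "subject": k + 1,
                        "treatment": d.X[i, j],
                        "y": (j + 1) / T + d.X[i, j] * theta,
                    }
                )
    return pd.DataFrame(rows)


class TestFitREML:
    def test_noise_free_data_recovered_exactly(self):
        """Zero-residual data: theta exact, variance estimates zero."""
        frame = _noise_free_frame(theta=0.7)
        model = SteppedWedgeLMM.from_dataframe(frame, "block_exchangeable")
        fit = model.fit()
        assert fit.theta_hat == pytest.approx(0.7, abs=1e-10)
        np.testing.assert_allclose(
            fit.beta_hat, np.arange(1, 6) / 5, atol=1e-10
        )
        assert fit.sigma_C2 < 1e-12
        assert fit.sigma_CP2 < 1e-12
        assert fit.sigma_e2 < 1e-12

    def test_dataframe_and_dataset_paths_agree(self, small_block_dataset):
        a = SteppedWedgeLMM.from_dataset(small_block_dataset).fit()
        b = SteppedWedgeLMM.from_dataframe(
            small_block_dataset.frame, "block_exchangeable"
        ).fit()
        assert a.theta_hat == pytest.approx(b.theta_hat, rel=1e-6)
        assert a.sigma_C2 == pytest.approx(b.sigma_C2, rel=1e-4, abs=1e-10)
        assert a.llf == pytest.approx(b.llf, rel=1e-10)

    def test_row_order_invariance(self, small_block_dataset):
        """Fitting is a function of the sufficient statistics only."""
        shuffled = small_block_dataset.frame.sample(frac=1.0, random_state=0)
        a = SteppedWedgeLMM.from_dataframe(shuffled, "block_exchangeable").fit()
        b = fit_reml(small_block_dataset)
        assert a.llf == pytest.approx(b.llf, rel=1e-10)
        np.testing.assert_allclose(a.params, b.params, rtol=1e-6)

    def test_restricted_loglik_matches_dense_oracle(
        self, small_block_dataset, oracles
    ):
        """Structured likelihood equals the explicit-matrix evaluation."""
        fit = fit_reml(small_block_dataset)
        ll_dense = oracles["restricted_loglik"](
            small_block_dataset, fit.sigma_C2, fit.sigma_CP2, fit.sigma_e2
        )
        assert fit.llf == pytest.approx(ll_dense, abs=1e-8)

    @pytest.mark.parametrize("structure,cac", [("block_exchangeable", 0.8),
                                               ("exchangeable", 1.0)])
    def test_grid_oracle_equivalence(self, oracles, structure, cac):
        """REML optimum matches brute-force grid maximization (4 s.f.)."""
        for seed in range(5):
            cfg = TrialConfig(S=1, T=3, m=2, rho1=0.1, cac=cac)
            data = simulate_trial(cfg, seed=seed)
            fit = fit_reml(data)
            ref = oracles["reml_grid_max"](data, structure)
            assert fit.llf >= ref["llf"] - 1e-6
            assert fit.llf == pytest.approx(ref["llf"], rel=1e-4, abs=1e-4)
            assert fit.sigma_e2 == pytest.approx(
                ref["sigma_e2"], rel=5e-4, abs=1e-6
            )

    def test_statsmodels_cross_check_exchangeable(self, small_exch_dataset):
        """Estimates agree with an independent mixed-model fitter."""
        import statsmodels.formula.api as smf

        fit = fit_reml(small_exch_dataset)
        df = small_exch_dataset.frame.copy()
        df["period"] = df["period"].astype("category")
        mf = smf.mixedlm(
            "y ~ 0 + period + treatment", df, groups="cluster"
        ).fit(reml=True)
        assert fit.theta_hat == pytest.approx(mf.params["treatment"], abs=1e-5)
        assert fit.sigma_C2 == pytest.approx(float(mf.cov_re.iloc[0, 0]), abs=1e-5)
        assert fit.sigma_e2 == pytest.approx(float(mf.scale), rel=1e-4)

    def test_boundary_fit_flags_undefined_cac(self):
        """A replicate with both cluster-level variances at zero has an
        undefined cluster autocorrelation and is flagged."""
        found = False
        cfg = TrialConfig(S=1, T=4, m=2, rho1=0.01, cac=0.8)
        for seed in range(60):
            fit = fit_reml(simulate_trial(cfg, seed=seed))
            if fit.sigma_C2 == 0.0 and fit.sigma_CP2 == 0.0:
                assert not fit.cac_defined
                assert fit.cac_hat is None
                assert set(fit.boundary) == {"sigma_C2", "sigma_CP2"}
                found = True
                break
        assert found, "no boundary replicate found in 60 seeds"

    def test_partial_boundary_keeps_cac_defined(self):
        """sigma_C2 = 0 with sigma_CP2 > 0 gives the extreme estimate r = 0,
        which is still defined (and retained in performance summaries)."""
        cfg = TrialConfig(S=1, T=4, m=3, rho1=0.05, cac=0.1)
        found = False
        for seed in range(80):
            fit = fit_reml(simulate_trial(cfg, seed=seed))
            if fit.sigma_C2 == 0.0 and fit.sigma_CP2 > 0.0:
                assert fit.cac_defined and fit.cac_hat == 0.0
                found = True
                break
        assert found, "no partial-boundary replicate found"

    def test_rank_deficient_design_rejected(self):
        """S=1, T=2: treatment coincides with the period-2 indicator."""
        cfg = TrialConfig(S=1, T=2, m=5, rho1=0.05, cac=1.0)
        data = simulate_trial(cfg, seed=0)
        with pytest.raises(np.linalg.LinAlgError):
            fit_reml(data)

    def test_unbalanced_data_rejected(self, small_block_dataset):
        frame = small_block_dataset.frame.iloc[:-1]
        with pytest.raises(ValueError):
            SteppedWedgeLMM.from_dataframe(frame)

    def test_summary_renders(self, small_block_dataset):
        text = fit_reml(small_block_dataset).summary()
        assert "theta" in text and "rho1_hat" in text


class TestParameterRecovery:
    def test_estimates_unbiased_at_large_design(self):
        """Across replicates of the largest design, the treatment effect and
        rho1 estimators are unbiased to within Monte Carlo error."""
        from swcrt import bias
        from swcrt.datagen import replicate_seed

        cfg = TrialConfig(S=5, T=9, m=100, rho1=0.1, cac=0.8, base_seed=11)
        thetas, rhos = [], []
        for rep in range(120):
            seed = replicate_seed(cfg.base_seed, 0, rep)
            data = simulate_trial(cfg, seed=seed.spawn(2)[0])
            fit = fit_reml(data)
            thetas.append(fit.theta_hat)
            rhos.append(fit.rho1_hat)
        b, mcse = bias(thetas, 0.0)
        assert abs(b) < 3 * mcse
        assert abs(np.mean(rhos) - 0.1) < 0.01
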