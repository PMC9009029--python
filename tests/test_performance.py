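"""Performance measures, MCSEs and replicate-exclusion rules."""

import numpy as np
import pandas as pd
import pytest

from swcrt import apply_exclusions, bias, coverage, modse_and_empse, mse
from swcrt.performance import interval_width, performance_table


class TestBias:
    def test_hand_computed_example(self):
        b, mcse = bias([0.1, -0.1], 0.0)
        assert b == pytest.approx(0.0)
        assert mcse == pytest.approx(0.1)

    def test_exact_estimates(self):
        b, mcse = bias([0.3, 0.3, 0.3], 0.3)
        assert b == 0.0 and mcse == 0.0

    def test_constant_offset(self):
        b, mcse = bias([0.4] * 5, 0.0)
        assert b == pytest.approx(0.4) and mcse == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bias([], 0.0)


class TestMSE:
    def test_hand_computed_example(self):
        m, mcse = mse([1.0, -1.0], 0.0)
        assert m == pytest.approx(1.0) and mcse == pytest.approx(0.0)

    def test_zero_at_truth(self):
        m, mcse = mse([0.2, 0.2], 0.2)
        assert m == 0.0 and mcse == 0.0

    def test_identity_with_bias_and_empse(self):
        """MSE = bias^2 + EmpSE^2 * (n-1)/n to machine precision."""
        rng = np.random.default_rng(5)
        est = rng.normal(0.3, 0.7, size=257)
        m, _ = mse(est, 0.0)
        b, _ = bias(est, 0.0)
        empse = np.std(est, ddof=1)
        n = est.size
        assert m == pytest.approx(b**2 + empse**2 * (n - 1) / n, rel=1e-12)


class TestCoverage:
    def test_all_contain(self):
        cov, mcse = coverage([-1, -1], [1, 1], 0.0)
        assert cov == 1.0 and mcse == 0.0

    def test_nominal_mcse_at_n1000(self):
        """95% coverage at n_sim = 1000 has MCSE 0.0069 (0.7 points)."""
        lows = np.full(1000, -1.0)
        upps = np.where(np.arange(1000) < 950, 1.0, -0.5)
        cov, mcse = coverage(lows, upps, 0.0)
        assert cov == pytest.approx(0.95)
        assert mcse == pytest.approx(np.sqrt(0.95 * 0.05 / 1000))
        assert round(mcse * 100, 1) == 0.7

    def test_binomial_formula(self):
        lows = np.full(100, -1.0)
        upps = np.where(np.arange(100) < 50, 1.0, -0.5)
        cov, mcse = coverage(lows, upps, 0.0)
        assert cov == 0.5 and mcse == pytest.approx(0.05)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            coverage([0.0], [1.0, 2.0], 0.5)


class TestModSEEmpSE:
    def test_zero_relative_error_when_matched(self):
        est = [0.0, 2.0, 1.0, 3.0]
        empse2 = np.var(est, ddof=1)
        out = modse_and_empse([empse2] * 4, est)
        assert out["rel_error_pct"] == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_example(self):
        out = modse_and_empse([1.0, 1.0], [0.0, 2.0])
        assert out["empse"] == pytest.approx(np.sqrt(2))
        assert out["modse"] == pytest.approx(1.0)
        assert out["rel_error_pct"] == pytest.approx(
            100 * (1 / np.sqrt(2) - 1), abs=1e-9
        )

    def test_empse_mcse_formula(self):
        rng = np.random.default_rng(2)
        est = rng.normal(size=1000)
        out = modse_and_empse(np.ones(1000), est)
        assert out["empse_mcse"] == pytest.approx(
            out["empse"] / np.sqrt(2 * 999)
        )

    def test_degenerate_empse_flagged(self):
        out = modse_and_empse([1.0, 1.0], [0.5, 0.5])
        assert not out["rel_error_defined"]
        assert np.isnan(out["rel_error_pct"])

    def test_interval_width_summary(self):
        out = interval_width([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        assert out["width_mean"] == pytest.approx(2.0)
        assert out["width_median"] == pytest.approx(2.0)


def _records():
    rows = []

    def add(rep, method, parameter, est, valid=True, cac_def=True):
        rows.append(
            {
                "config": 0,
                "replicate": rep,
                "method": method,
                "parameter": parameter,
                "estimate": est,
                "ci_low": est - 1,
                "ci_upp": est + 1,
                "model_variance": 0.25,
                "bayes_valid": valid if method == "bayes" else np.nan,
                "cac_defined": cac_def,
            }
        )

    for rep in range(4):
        add(rep, "reml", "theta", 0.1 * rep, cac_def=rep != 2)
        add(rep, "reml", "rho1", 0.05, cac_def=rep != 2)
        add(rep, "reml", "cac", np.nan if rep == 2 else 0.8, cac_def=rep != 2)
        add(rep, "bayes", "theta", 0.1 * rep, valid=rep != 1)
        add(rep, "bayes", "rho1", 0.07, valid=rep != 1)
        add(rep, "bayes", "cac", 0.75, valid=rep != 1)
    return pd.DataFrame(rows)


class TestExclusions:
    def test_bayes_invalid_dropped_everywhere(self):
        retained, ledger = apply_exclusions(_records())
        bayes = retained[retained["method"] == "bayes"]
        assert set(bayes["replicate"]) == {0, 2, 3}
        assert len(bayes) == 9  # 3 replicates x 3 parameters

    def test_reml_undefined_cac_dropped_only_from_cac(self):
        retained, _ = apply_exclusions(_records())
        reml = retained[retained["method"] == "reml"]
        assert set(reml[reml["parameter"] == "theta"]["replicate"]) == {0, 1, 2, 3}
        assert set(reml[reml["parameter"] == "rho1"]["replicate"]) == {0, 1, 2, 3}
        assert set(reml[reml["parameter"] == "cac"]["replicate"]) == {0, 1, 3}

    def test_ledger_percentages(self):
        _, ledger = apply_exclusions(_records())
        led = ledger.set_index("method")["pct_valid"]
        assert led["bayes"] == pytest.approx(75.0)
        assert led["reml"] == pytest.approx(75.0)

    def test_order_invariance(self):
        rec = _records()
        shuffled = rec.sample(frac=1.0, random_state=3)
        t1 = performance_table(rec, {0: {"theta": 0.0, "rho1": 0.05, "cac": 0.8}})
        t2 = performance_table(
            shuffled, {0: {"theta": 0.0, "rho1": 0.05, "cac": 0.8}}
        )
        a = t1.table.sort_values(["method", "parameter"]).reset_index(drop=True)
        b = t2.table.sort_values(["method", "parameter"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_mcse_uses_retained_count(self):
        table = performance_table(
            _records(), {0: {"theta": 0.0, "rho1": 0.05, "cac": 0.8}}
        )
        cell = table.cell(0, "bayes", "theta")
        assert cell["n_retained"] == 3
        est = [0.0, 0.2, 0.3]
        assert cell["bias_mcse"] == pytest.approx(
            np.std(est, ddof=1) / np.sqrt(3)
        )
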