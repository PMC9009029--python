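"""Simulation performance measures with Monte Carlo standard errors.

Implements the standard repeated-sampling measures for an estimator
``theta_hat`` of a true value ``theta`` over ``n_sim`` replicates — bias,
MSE, 95% interval coverage, average model-based standard error (ModSE),
empirical standard error (EmpSE) and the relative percent error in ModSE —
each with its Monte Carlo standard error (MCSE), following Morris, White &
Crowther's simulation-study guidance.  Replicate-validity exclusion rules:

- a Bayesian replicate that yielded any post-warmup divergent transition or
  failed the R-hat/ESS diagnostics is excluded from *all* measures;
- a REML replicate that estimated both the cluster and the cluster-period
  variances as zero has an undefined cluster autocorrelation and is
  excluded from the cluster-autocorrelation measures *only* — it is
  retained for the treatment effect and rho1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "bias",
    "mse",
    "coverage",
    "modse_and_empse",
    "interval_width",
    "apply_exclusions",
    "performance_table",
    "PerformanceTable",
]


def _as_array(values, name):
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def bias(estimates, truth: float) -> tuple[float, float]:
    """Mean estimate minus truth, and its MCSE (SD of estimates / sqrt(n))."""
    est = _as_array(estimates, "estimates")
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 replicates")
    b = est.mean() - truth
    mcse = np.sqrt(((est - est.mean()) ** 2).sum() / (n * (n - 1)))
    return float(b), float(mcse)


def mse(estimates, truth: float) -> tuple[float, float]:
    """Mean squared error about the truth, and its MCSE."""
    est = _as_array(estimates, "estimates")
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 replicates")
    sq = (est - truth) ** 2
    m = sq.mean()
    mcse = np.sqrt(((sq - m) ** 2).sum() / (n * (n - 1)))
    return float(m), float(mcse)


def coverage(ci_lows, ci_upps, truth: float) -> tuple[float, float]:
    """Proportion of intervals containing the truth, with binomial MCSE."""
    lows = _as_array(ci_lows, "ci_lows")
    upps = _as_array(ci_upps, "ci_upps")
    if lows.shape != upps.shape:
        raise ValueError("ci_lows and ci_upps must have equal length")
    n = lows.size
    cov = float(np.mean((lows <= truth) & (truth <= upps)))
    mcse = float(np.sqrt(cov * (1.0 - cov) / n))
    return cov, mcse


def modse_and_empse(model_variances, estimates) -> dict:
    """Average model-based SE, empirical SE, and relative % error in ModSE.

    ``model_variances`` are the squared model-based standard errors
    ``Var_hat(theta_hat_i)`` per replicate.  Returns a dict with keys
    ``modse``, ``modse_mcse``, ``empse``, ``empse_mcse``, ``rel_error_pct``,
    ``rel_error_pct_mcse`` (the latter two are NaN, flagged via
    ``rel_error_defined``, when EmpSE is zero).
    """
    mv = _as_array(model_variances, "model_variances")
    est = _as_array(estimates, "estimates")
    if mv.size != est.size:
        raise ValueError("model_variances and estimates must have equal length")
    if (mv < 0).any():
        raise ValueError("model variances must be non-negative")
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 replicates")
    modse = float(np.sqrt(mv.mean()))
    empse = float(np.std(est, ddof=1))
    var_of_var = float(((mv - mv.mean()) ** 2).sum() / (n - 1))
    modse_mcse = (
        float(np.sqrt(var_of_var / (4.0 * n * modse**2))) if modse > 0 else 0.0
    )
    empse_mcse = empse / np.sqrt(2.0 * (n - 1))
    if empse > 0:
        rel = 100.0 * (modse / empse - 1.0)
        rel_mcse = (
            100.0
            * (modse / empse)
            * np.sqrt(
                var_of_var / (4.0 * n * modse**4) + 1.0 / (2.0 * (n - 1))
            )
            if modse > 0
            else np.nan
        )
        defined = True
    else:
        rel, rel_mcse, defined = np.nan, np.nan, False
    return {
        "modse": modse,
        "modse_mcse": modse_mcse,
        "empse": empse,
        "empse_mcse": float(empse_mcse),
        "rel_error_pct": rel,
        "rel_error_pct_mcse": rel_mcse,
        "rel_error_defined": defined,
    }


def interval_width(ci_lows, ci_upps) -> dict:
    """Mean and quartiles of interval widths (upp - low)."""
    lows = _as_array(ci_lows, "ci_lows")
    upps = _as_array(ci_upps, "ci_upps")
    widths = upps - lows
    q1, q2, q3 = np.quantile(widths, [0.25, 0.5, 0.75])
    return {
        "width_mean": float(widths.mean()),
        "width_q1": float(q1),
        "width_median": float(q2),
        "width_q3": float(q3),
    }


# ---------------------------------------------------------------------- #
# replicate records and exclusion rules

#: required columns of a per-replicate record frame
RECORD_COLUMNS = [
    "config",
    "replicate",
    "method",  # "reml", "reml_kr", "reml_satt", "bayes"
    "parameter",  # "theta", "rho1", "cac"
    "estimate",
    "ci_low",
    "ci_upp",
    "model_variance",
    "bayes_valid",  # bool; NaN/True for REML rows
    "cac_defined",  # bool; False when sigma_C2 = sigma_CP2 = 0 under REML
]


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply replicate-validity rules to a long-format record frame.

    Returns ``(retained, ledger)``: Bayesian replicates failing any
    diagnostic are removed from every measure; REML replicates with an
    undefined cluster autocorrelation are removed from the ``cac`` rows
    only.  The ledger reports, per (config, method), the percentage of
    replicates retained (for REML the percentage refers to the
    cluster-autocorrelation calculations, the only place REML replicates
    can be invalid).
    """
    rec = records.copy()
    is_bayes = rec["method"] == "bayes"
    bayes_ok = rec["bayes_valid"].astype("boolean").fillna(True).astype(bool)
    cac_ok = rec["cac_defined"].astype("boolean").fillna(True).astype(bool)
    drop = (is_bayes & ~bayes_ok) | (
        ~is_bayes & (rec["parameter"] == "cac") & ~cac_ok
    )
    retained = rec[~drop].copy()

    rows = []
    for (config, method), grp in rec.groupby(["config", "method"], sort=False):
        n_rep = grp["replicate"].nunique()
        if method == "bayes":
            ok = (
                grp.groupby("replicate")["bayes_valid"]
                .first()
                .astype("boolean")
                .fillna(True)
            )
            pct = 100.0 * float(ok.astype(bool).mean())
        else:
            has_cac = grp[grp["parameter"] == "cac"]
            if len(has_cac):
                ok = (
                    has_cac.groupby("replicate")["cac_defined"]
                    .first()
                    .astype("boolean")
                    .fillna(True)
                )
                pct = 100.0 * float(ok.astype(bool).mean())
            else:
                pct = 100.0  # exchangeable: cac not estimated, nothing to drop
        rows.append(
            {
                "config": config,
                "method": method,
                "n_replicates": n_rep,
                "pct_valid": pct,
            }
        )
    return retained, pd.DataFrame(rows)


_TRUTH_KEYS = {"theta": "theta", "rho1": "rho1", "cac": "cac"}


def performance_table(
    records: pd.DataFrame, truths: dict | pd.DataFrame
) -> "PerformanceTable":
    """Compute all measures per (config, method, parameter) cell.

    Parameters
    ----------
    records : DataFrame
        Long-format per-replicate records with :data:`RECORD_COLUMNS`.
    truths : dict or DataFrame
        Per config: the true values, e.g. ``{config: {"theta": 0.0,
        "rho1": 0.05, "cac": 0.8}}``.

    Notes
    -----
    The MCSE denominators use the retained replicate count of each cell.
    Relative % error in ModSE and coverage are only computed for cells with
    interval / model-variance information (the treatment effect).
    """
    retained, ledger = apply_exclusions(records)
    if isinstance(truths, pd.DataFrame):
        truths = truths.set_index("config").to_dict("index")
    rows = []
    for (config, method, parameter), grp in retained.groupby(
        ["config", "method", "parameter"], sort=False
    ):
        truth = truths[config][_TRUTH_KEYS[parameter]]
        est = grp["estimate"].to_numpy(dtype=float)
        n = est.size
        if n < 2:
            continue
        b, b_mcse = bias(est, truth)
        m, m_mcse = mse(est, truth)
        row = {
            "config": config,
            "method": method,
            "parameter": parameter,
            "n_retained": n,
            "truth": truth,
            "bias": b,
            "bias_mcse": b_mcse,
            "mse": m,
            "mse_mcse": m_mcse,
        }
        if grp["ci_low"].notna().all() and grp["ci_upp"].notna().all():
            lows = grp["ci_low"].to_numpy(dtype=float)
            upps = grp["ci_upp"].to_numpy(dtype=float)
            cov, cov_mcse = coverage(lows, upps, truth)
            row.update({"coverage": cov, "coverage_mcse": cov_mcse})
            row.update(interval_width(lows, upps))
        if parameter == "theta" and grp["model_variance"].notna().all():
            row.update(
                modse_and_empse(grp["model_variance"].to_numpy(float), est)
            )
        rows.append(row)
    return PerformanceTable(table=pd.DataFrame(rows), ledger=ledger)


@dataclass
class PerformanceTable:
    """Tidy per-(config, method, parameter) performance measures.

    ``table`` carries the estimates and MCSEs; ``ledger`` the percentage of
    valid replicates per (config, method).
    """

    table: pd.DataFrame
    ledger: pd.DataFrame = field(default=None)

    def to_csv(self, path, ledger_path=None) -> None:
        self.table.to_csv(path, index=False)
        if ledger_path is not None and self.ledger is not None:
            self.ledger.to_csv(ledger_path, index=False)

    def cell(self, config, method: str, parameter: str) -> pd.Series:
        t = self.table
        sel = t[
            (t["config"] == config)
            & (t["method"] == method)
            & (t["parameter"] == parameter)
        ]
        if len(sel) != 1:
            raise KeyError((config, method, parameter))
        return sel.iloc[0]
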