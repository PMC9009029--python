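"""The stepped wedge linear mixed model as a fittable model object.

:class:`SteppedWedgeLMM` plays the role of a statsmodels-style model class:
it is constructed from data (a :class:`~swcrt.datagen.TrialDataset` or a
long-format DataFrame), holds the design information and sufficient
statistics, and exposes ``fit()`` (REML, returning
:class:`~swcrt.reml.REMLResults`) and ``fit_bayes()`` (MCMC, returning
:class:`~swcrt.bayes.BayesResults`).

Balanced-design sufficiency
---------------------------
With equal cluster-period sizes ``m`` the likelihood depends on the data
only through the cluster-period means and the pooled within-cell sum of
squares.  Writing ``x_i = sqrt(m) * ybar_i`` for the scaled cell-mean
vector of cluster ``i``, its covariance is

    A = D1 * (I - P) + DT * P,     P = 11'/T,
    D1 = sigma_e2 + m * sigma_CP2,
    DT = sigma_e2 + m * sigma_CP2 + T * m * sigma_C2,

i.e. the within-cluster between-period contrast space has eigenvalue ``D1``
(multiplicity ``T - 1``) and the cluster-mean direction has eigenvalue
``DT``; the remaining ``N * T * (m - 1)`` within-cell dimensions have
variance ``sigma_e2``.  All (restricted) likelihood, GLS and information
computations reduce to scalar weights on these three eigenspaces, which is
what makes per-replicate fitting cheap at every design size used here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datagen import TrialDataset

__all__ = ["SteppedWedgeLMM", "CellStats"]

_STRUCTURES = ("block_exchangeable", "exchangeable", "none")


@dataclass(frozen=True)
class CellStats:
    """Sufficient statistics of a balanced stepped wedge dataset."""

    ybar: np.ndarray  # (N, T) cluster-period means
    ssw: float  # pooled within-cell sum of squares
    m: int  # subjects per cluster-period
    x: np.ndarray  # (N, T) treatment indicators (float)

    @property
    def N(self) -> int:
        return self.ybar.shape[0]

    @property
    def T(self) -> int:
        return self.ybar.shape[1]

    @property
    def n_obs(self) -> int:
        return self.N * self.T * self.m


class SteppedWedgeLMM:
    """Linear mixed model for a cross-sectional stepped wedge trial.

    The mean model has one categorical effect per period plus the treatment
    effect theta (``p = T + 1`` fixed effects); the covariance structure is
    selected by ``structure``:

    - ``"block_exchangeable"``: cluster and cluster-period random effects
      (two intracluster correlation parameters, rho1 and the cluster
      autocorrelation r);
    - ``"exchangeable"``: cluster random effect only (r fixed at 1);
    - ``"none"``: independent errors (no random effects) — mainly useful to
      verify that small-sample corrections collapse to exact OLS t-inference.

    Parameters
    ----------
    stats : CellStats
        Sufficient statistics (cell means, within-cell SS, m, treatment).
    structure : str
        One of the structures above.
    """

    def __init__(self, stats: CellStats, structure: str = "block_exchangeable"):
        if structure not in _STRUCTURES:
            raise ValueError(f"structure must be one of {_STRUCTURES}")
        self.stats = stats
        self.structure = structure
        self._precompute()

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_dataset(
        cls, data: TrialDataset, structure: str | None = None
    ) -> "SteppedWedgeLMM":
        """Build the model from a simulated dataset.

        When ``structure`` is omitted it is taken from the generating
        configuration (correctly specified analysis).
        """
        if structure is None:
            structure = (
                data.truth.structure if data.truth is not None else "block_exchangeable"
            )
        y = data.y_array()
        ybar = y.mean(axis=2)
        ssw = float(((y - ybar[:, :, None]) ** 2).sum())
        stats = CellStats(
            ybar=ybar, ssw=ssw, m=data.m, x=data.design.X.astype(float)
        )
        return cls(stats, structure)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, structure: str = "block_exchangeable"
    ) -> "SteppedWedgeLMM":
        """Build the model from a long-format DataFrame.

        ``frame`` needs columns ``cluster``, ``period``, ``treatment`` and
        ``y``; the design must be balanced (equal cluster-period sizes) and
        treatment must be constant within each cluster-period.
        """
        grouped = frame.groupby(["cluster", "period"])
        counts = grouped["y"].count()
        if counts.nunique() != 1:
            raise ValueError("unbalanced data: cluster-period sizes differ")
        m = int(counts.iloc[0])
        ybar = grouped["y"].mean().unstack()
        treat = grouped["treatment"].agg(["min", "max"])
        if (treat["min"] != treat["max"]).any():
            raise ValueError("treatment varies within a cluster-period cell")
        x = treat["min"].unstack().to_numpy(dtype=float)
        ssw = float(
            ((frame["y"] - grouped["y"].transform("mean")) ** 2).sum()
        )
        stats = CellStats(ybar=ybar.to_numpy(dtype=float), ssw=ssw, m=m, x=x)
        return cls(stats, structure)

    # ------------------------------------------------------------------ #
    # basic dimensions

    @property
    def N(self) -> int:
        return self.stats.N

    @property
    def T(self) -> int:
        return self.stats.T

    @property
    def m(self) -> int:
        return self.stats.m

    @property
    def n_obs(self) -> int:
        return self.stats.n_obs

    @property
    def k_fe(self) -> int:
        """Number of fixed effects (T period effects + treatment)."""
        return self.T + 1

    @property
    def resid_df(self) -> int:
        return self.n_obs - self.k_fe

    # ------------------------------------------------------------------ #
    # eigenspace-weighted cross products

    def _precompute(self) -> None:
        s = self.stats
        x, ybar = s.x, s.ybar
        self._xb = x.mean(axis=1)  # (N,) cluster means of treatment
        self._yb = ybar.mean(axis=1)
        self._Sx = x.sum(axis=0)  # (T,)
        self._Sy = ybar.sum(axis=0)
        self._Sxb = float(self._xb.sum())
        self._Syb = float(self._yb.sum())
        self._Sxx = float((x * x).sum())
        self._Sxx_b = float((self._xb**2).sum())
        self._Sxy = float((x * ybar).sum())
        self._Sxy_b = float((self._xb * self._yb).sum())
        self._Syy = float((ybar * ybar).sum())
        self._Syy_b = float((self._yb**2).sum())

    def _cross_products(self, w1: float, wT: float):
        """Weighted fixed-effect cross products on the cell-mean space.

        Returns ``(A, b, c)`` with ``A = X' W X``, ``b = X' W y`` and
        ``c = y' W y`` where ``W`` applies weight ``w1`` on the
        within-cluster contrast space and ``wT`` on the cluster-mean
        direction of each cluster (both already include the factor ``m``
        from averaging cells of size m).  Fixed-effect order: period
        effects beta_1..beta_T, then theta.
        """
        s, T, N, m = self.stats, self.T, self.N, self.m
        P_like = np.full((T, T), 1.0 / T)
        I_T = np.eye(T)
        A = np.empty((T + 1, T + 1))
        A[:T, :T] = m * N * (w1 * (I_T - P_like) + wT * P_like)
        a_pt = m * (
            w1 * (self._Sx - self._Sxb * np.ones(T))
            + wT * self._Sxb * np.ones(T)
        )
        A[:T, T] = a_pt
        A[T, :T] = a_pt
        A[T, T] = m * (
            w1 * (self._Sxx - T * self._Sxx_b) + wT * T * self._Sxx_b
        )
        b = np.empty(T + 1)
        b[:T] = m * (
            w1 * (self._Sy - self._Syb * np.ones(T))
            + wT * self._Syb * np.ones(T)
        )
        b[T] = m * (
            w1 * (self._Sxy - T * self._Sxy_b) + wT * T * self._Sxy_b
        )
        c = m * (w1 * (self._Syy - T * self._Syy_b) + wT * T * self._Syy_b)
        return A, b, c

    def eigenvalues(self, sigma_C2: float, sigma_CP2: float, sigma_e2: float):
        """Covariance eigenvalues ``(D1, DT)`` of the scaled cell-mean space."""
        D1 = sigma_e2 + self.m * sigma_CP2
        DT = D1 + self.T * self.m * sigma_C2
        return D1, DT

    # ------------------------------------------------------------------ #
    # restricted likelihood

    def loglike_restricted(
        self, sigma_C2: float, sigma_CP2: float, sigma_e2: float
    ) -> float:
        """Exact restricted log-likelihood at the given variance components."""
        if min(sigma_C2, sigma_CP2) < 0 or sigma_e2 <= 0:
            return -np.inf
        N, T, m = self.N, self.T, self.m
        D1, DT = self.eigenvalues(sigma_C2, sigma_CP2, sigma_e2)
        A, b, c = self._cross_products(1.0 / D1, 1.0 / DT)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
        beta = np.linalg.solve(A, b)
        quad = self.stats.ssw / sigma_e2 + (c - b @ beta)
        logdet_V = N * (
            T * (m - 1) * np.log(sigma_e2) + (T - 1) * np.log(D1) + np.log(DT)
        )
        n_p = self.resid_df
        return -0.5 * (n_p * np.log(2 * np.pi) + logdet_V + logdet_A + quad)

    def profiled_criterion(self, gamma_C: float, gamma_CP: float):
        """-2 restricted log-likelihood with sigma_e2 profiled out.

        ``gamma_C = sigma_C2 / sigma_e2`` and ``gamma_CP = sigma_CP2 /
        sigma_e2`` are the variance ratios.  Returns ``(criterion,
        sigma_e2_hat, beta_hat, A)`` where ``A`` is the weighted normal
        matrix in sigma_e2 units (so ``cov(beta) = sigma_e2 * inv(A)``).
        """
        N, T, m = self.N, self.T, self.m
        d1 = 1.0 + m * gamma_CP
        dT = d1 + T * m * gamma_C
        A, b, c = self._cross_products(1.0 / d1, 1.0 / dT)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            raise np.linalg.LinAlgError("rank-deficient fixed-effect design")
        beta = np.linalg.solve(A, b)
        quad0 = self.stats.ssw + (c - b @ beta)
        n_p = self.resid_df
        sigma_e2_hat = max(quad0 / n_p, 1e-300)
        logdet_V0 = N * ((T - 1) * np.log(d1) + np.log(dT))
        crit = (
            n_p * (np.log(2 * np.pi) + 1.0 + np.log(sigma_e2_hat))
            + logdet_V0
            + logdet_A
        )
        return crit, sigma_e2_hat, beta, A

    def fe_covariance(
        self, sigma_C2: float, sigma_CP2: float, sigma_e2: float
    ) -> np.ndarray:
        """Model-based covariance of the GLS fixed effects, ``inv(X'V^-1 X)``."""
        D1, DT = self.eigenvalues(sigma_C2, sigma_CP2, sigma_e2)
        A, _, _ = self._cross_products(1.0 / D1, 1.0 / DT)
        return np.linalg.inv(A)

    # ------------------------------------------------------------------ #
    # fitting front-ends (implementations live in reml.py / bayes.py)

    def fit(self, **kwargs):
        """REML fit; see :func:`swcrt.reml.fit_reml_model`."""
        from .reml import fit_reml_model

        return fit_reml_model(self, **kwargs)

    def fit_bayes(self, **kwargs):
        """Bayesian MCMC fit; see :func:`swcrt.bayes.fit_bayes_model`."""
        from .bayes import fit_bayes_model

        return fit_bayes_model(self, **kwargs)
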