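"""REML estimation with Kenward-Roger / Satterthwaite small-sample inference.

The restricted likelihood is maximized over the variance ratios
``gamma_C = sigma_C2/sigma_e2`` and ``gamma_CP = sigma_CP2/sigma_e2`` on the
log scale with ``sigma_e2`` and the fixed effects profiled out analytically;
boundary solutions (a component estimated as exactly zero) are handled by
comparing against explicit reduced-model fits.  Small-sample corrections for
the treatment effect use the first-order Kenward-Roger adjusted covariance
with the expected (REML) information for the variance parameters.  Because
the marginal covariance is *linear* in the variance components here, the
Kenward-Roger second-derivative terms vanish identically, and for the
one-dimensional treatment contrast the Kenward-Roger degrees of freedom
coincide with the Satterthwaite degrees of freedom computed from the same
expected information — the two methods then differ only in whether the
adjusted or the unadjusted standard error is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .datagen import TrialDataset, correlations_from_components
from .model import SteppedWedgeLMM

__all__ = [
    "REMLResults",
    "SmallSampleResult",
    "fit_reml",
    "fit_reml_model",
    "kr_adjust",
    "satterthwaite_ddf",
    "wald_interval",
]

#: a variance ratio below this is declared to lie on the zero boundary
BOUNDARY_TOL = 1e-8

_LOG_GAMMA_LO, _LOG_GAMMA_HI = -34.5, 8.0  # ~ [1e-15, 3e3] on the ratio scale


def wald_interval(
    theta_hat: float, se: float, ddf: float, level: float = 0.95
) -> tuple[float, float]:
    """t-based interval ``theta_hat +/- t_{1-(1-level)/2, ddf} * se``.

    Infinite ``ddf`` gives the normal quantile.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if not (ddf > 0):
        raise ValueError("ddf must be positive (or infinite)")
    q = 1.0 - (1.0 - level) / 2.0
    crit = stats.norm.ppf(q) if np.isinf(ddf) else stats.t.ppf(q, ddf)
    return theta_hat - crit * se, theta_hat + crit * se


@dataclass
class SmallSampleResult:
    """Adjusted inference for the treatment effect from one fit."""

    se_adj: float
    ddf: float
    method_used: str  # "kr", "satterthwaite" or "none"
    ci_low: float
    ci_upp: float
    level: float = 0.95
    flags: tuple[str, ...] = ()


@dataclass
class REMLResults:
    """Results of a REML fit of :class:`~swcrt.model.SteppedWedgeLMM`.

    ``params`` holds the GLS fixed effects in the order beta_1..beta_T,
    theta; ``cov_params`` is the model-based (unadjusted) covariance
    ``inv(X' V^-1 X)`` at the REML variance estimates.
    """

    model: SteppedWedgeLMM
    params: np.ndarray
    cov_params: np.ndarray = field(repr=False)
    sigma_C2: float = 0.0
    sigma_CP2: float = 0.0
    sigma_e2: float = 1.0
    llf: float = np.nan  # restricted log-likelihood at the optimum
    converged: bool = True
    boundary: tuple[str, ...] = ()
    n_restarts_used: int = 0

    # -------------------------------------------------------------- #
    @property
    def theta_hat(self) -> float:
        """Treatment effect estimate."""
        return float(self.params[-1])

    @property
    def beta_hat(self) -> np.ndarray:
        """Period effect estimates."""
        return self.params[:-1]

    @property
    def se_theta(self) -> float:
        """Unadjusted model-based standard error of the treatment effect."""
        return float(np.sqrt(self.cov_params[-1, -1]))

    @property
    def rho1_hat(self) -> float:
        return correlations_from_components(
            self.sigma_C2, self.sigma_CP2, self.sigma_e2
        )[0]

    @property
    def cac_hat(self) -> float | None:
        """Cluster autocorrelation estimate; None when undefined.

        Undefined when both the cluster and cluster-period variances are
        estimated as zero (the corresponding replicate is excluded from
        cluster-autocorrelation performance summaries).
        """
        if self.model.structure != "block_exchangeable":
            return None
        return correlations_from_components(
            self.sigma_C2, self.sigma_CP2, self.sigma_e2
        )[1]

    @property
    def cac_defined(self) -> bool:
        return self.cac_hat is not None

    # -------------------------------------------------------------- #
    def small_sample(
        self, method: str = "kr", level: float = 0.95
    ) -> SmallSampleResult:
        """Small-sample-corrected interval for the treatment effect.

        ``method="kr"`` uses the Kenward-Roger adjusted SE and degrees of
        freedom; ``"satterthwaite"`` keeps the unadjusted SE with the
        Satterthwaite degrees of freedom (the fallback used for very large
        fits); ``"none"`` is the unadjusted z-interval.
        """
        if method == "kr":
            return kr_adjust(self, level=level)
        if method == "satterthwaite":
            ddf, flags = satterthwaite_ddf(self)
            se = self.se_theta
            lo, up = wald_interval(self.theta_hat, se, ddf, level)
            return SmallSampleResult(
                se_adj=se, ddf=ddf, method_used="satterthwaite",
                ci_low=lo, ci_upp=up, level=level, flags=flags,
            )
        if method == "none":
            lo, up = wald_interval(self.theta_hat, self.se_theta, np.inf, level)
            return SmallSampleResult(
                se_adj=self.se_theta, ddf=np.inf, method_used="none",
                ci_low=lo, ci_upp=up, level=level,
            )
        raise ValueError("method must be 'kr', 'satterthwaite' or 'none'")

    def conf_int(self, method: str = "kr", level: float = 0.95):
        res = self.small_sample(method, level)
        return res.ci_low, res.ci_upp

    def summary(self) -> str:
        T = self.model.T
        lines = [
            "Stepped wedge LMM (REML)",
            "=" * 60,
            f"structure: {self.model.structure}   clusters: {self.model.N}"
            f"   periods: {T}   m: {self.model.m}",
            f"restricted log-likelihood: {self.llf:.4f}"
            f"   converged: {self.converged}   boundary: {self.boundary or '-'}",
            "-" * 60,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        for j in range(T):
            se_j = np.sqrt(self.cov_params[j, j])
            lines.append(f"{f'beta_{j + 1}':<14}{self.params[j]:>12.4f}{se_j:>12.4f}")
        lines.append(
            f"{'theta':<14}{self.theta_hat:>12.4f}{self.se_theta:>12.4f}"
        )
        lines += [
            "-" * 60,
            f"sigma_C2  = {self.sigma_C2:.6g}",
            f"sigma_CP2 = {self.sigma_CP2:.6g}",
            f"sigma_e2  = {self.sigma_e2:.6g}",
            f"rho1_hat  = {self.rho1_hat:.6g}",
            f"cac_hat   = {self.cac_hat if self.cac_defined else 'undefined'}",
        ]
        return "\n".join(lines)


# ------------------------------------------------------------------ #
# fitting

_NM_STARTS = [(-3.0, -3.0), (-1.5, -5.5), (-5.5, -1.5)]


def _finish(model, gamma_C, gamma_CP, converged, n_restarts):
    crit, sigma_e2, beta, A = model.profiled_criterion(gamma_C, gamma_CP)
    sigma_C2 = gamma_C * sigma_e2
    sigma_CP2 = gamma_CP * sigma_e2
    boundary = []
    if model.structure != "none" and gamma_C == 0.0:
        boundary.append("sigma_C2")
    if model.structure == "block_exchangeable" and gamma_CP == 0.0:
        boundary.append("sigma_CP2")
    cov = sigma_e2 * np.linalg.inv(A)
    return REMLResults(
        model=model,
        params=beta,
        cov_params=cov,
        sigma_C2=sigma_C2,
        sigma_CP2=sigma_CP2,
        sigma_e2=sigma_e2,
        llf=-0.5 * crit,
        converged=converged,
        boundary=tuple(boundary),
        n_restarts_used=n_restarts,
    )


def _minimize_1d(fun) -> tuple[float, float, bool]:
    res = optimize.minimize_scalar(
        fun, bounds=(_LOG_GAMMA_LO, _LOG_GAMMA_HI), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x), float(res.fun), bool(res.success)


def fit_reml_model(model: SteppedWedgeLMM, max_restarts: int = 3) -> REMLResults:
    """Maximize the restricted likelihood of ``model``.

    The two variance ratios are optimized on the log scale (Nelder-Mead,
    with up to ``max_restarts`` dispersed starting simplexes), and the
    interior solution is compared against the boundary candidates in which
    one or both components are fixed at zero; the best restricted
    likelihood wins.  A ratio below ``BOUNDARY_TOL`` is declared zero.
    """
    structure = model.structure
    if structure == "none":
        return _finish(model, 0.0, 0.0, True, 0)

    crit_of = lambda gC, gCP: model.profiled_criterion(gC, gCP)[0]

    candidates: list[tuple[float, float, float, bool]] = []  # crit, gC, gCP, ok
    # both components at the zero boundary (iid errors)
    candidates.append((crit_of(0.0, 0.0), 0.0, 0.0, True))

    # cluster component only (always relevant; it's the whole model when
    # the structure is exchangeable, and a boundary candidate otherwise)
    xg, fg, ok = _minimize_1d(lambda lg: crit_of(np.exp(lg), 0.0))
    gC = np.exp(xg)
    candidates.append((fg, 0.0 if gC < BOUNDARY_TOL else gC, 0.0, ok))

    n_used = 0
    if structure == "block_exchangeable":
        # cluster-period component only
        xg, fg, ok = _minimize_1d(lambda lg: crit_of(0.0, np.exp(lg)))
        gCP = np.exp(xg)
        candidates.append((fg, 0.0, 0.0 if gCP < BOUNDARY_TOL else gCP, ok))
        # interior 2-d search with restarts
        best = None
        for n_used, start in enumerate(_NM_STARTS[:max_restarts], start=1):
            res = optimize.minimize(
                lambda lg: crit_of(np.exp(lg[0]), np.exp(lg[1])),
                x0=np.asarray(start),
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 600},
            )
            if best is None or res.fun < best.fun - 1e-9:
                best = res
            if res.success and n_used >= 1 and best.fun <= res.fun + 1e-7:
                break
        gC, gCP = np.exp(best.x)
        gC = 0.0 if gC < BOUNDARY_TOL else gC
        gCP = 0.0 if gCP < BOUNDARY_TOL else gCP
        candidates.append((float(best.fun), gC, gCP, bool(best.success)))

    # re-evaluate candidates after boundary snapping and keep the best
    rescored = [
        (crit_of(gC, gCP), gC, gCP, ok) for _, gC, gCP, ok in candidates
    ]
    crit, gC, gCP, ok = min(rescored, key=lambda t: t[0])
    return _finish(model, gC, gCP, ok, n_used)


def fit_reml(data: TrialDataset, structure: str | None = None) -> REMLResults:
    """REML fit of the stepped wedge LMM to a simulated dataset."""
    return SteppedWedgeLMM.from_dataset(data, structure).fit()


# ------------------------------------------------------------------ #
# Kenward-Roger / Satterthwaite machinery

def _variance_param_names(structure: str) -> list[str]:
    return {
        "block_exchangeable": ["sigma_C2", "sigma_CP2", "sigma_e2"],
        "exchangeable": ["sigma_C2", "sigma_e2"],
        "none": ["sigma_e2"],
    }[structure]


def _kr_core(fit: REMLResults):
    """Shared Kenward-Roger ingredients at the REML estimates.

    Uses the eigenspace decomposition: the derivative of V with respect to
    each variance component acts on the within-cluster contrast space, the
    cluster-mean direction and the within-cell space with scalar
    coefficients, so every trace reduces to weighted cross products.
    Returns (Phi, Phi_adj, W, a) where ``a[r] = c' Phi B_r Phi c / c'Phi c``
    for the treatment contrast and ``W`` is the inverse expected (REML)
    information of the variance parameters.
    """
    model = fit.model
    N, T, m = model.N, model.T, model.m
    se2 = fit.sigma_e2
    D1, DT = model.eigenvalues(fit.sigma_C2, fit.sigma_CP2, se2)
    names = _variance_param_names(model.structure)
    # eigen-coefficients of dV/dsigma_r on (contrast, mean-line, within-cell)
    lam = {
        "sigma_C2": (0.0, T * m, 0.0),
        "sigma_CP2": (float(m), float(m), 0.0),
        "sigma_e2": (1.0, 1.0, 1.0),
    }
    k = len(names)
    A_phi, _, _ = model._cross_products(1.0 / D1, 1.0 / DT)
    Phi = np.linalg.inv(A_phi)

    def XtX(coef1, coefT):
        return model._cross_products(coef1, coefT)[0]

    B = []
    for r in names:
        l1, lT, _ = lam[r]
        B.append(XtX(l1 / D1**2, lT / DT**2))
    C = {}
    for i, r in enumerate(names):
        for j, s in enumerate(names[: i + 1]):
            l1r, lTr, _ = lam[r]
            l1s, lTs, _ = lam[s]
            C[(i, j)] = XtX(l1r * l1s / D1**3, lTr * lTs / DT**3)
            C[(j, i)] = C[(i, j)]

    info = np.empty((k, k))
    flags: list[str] = []
    for i, r in enumerate(names):
        l1r, lTr, lwr = lam[r]
        for j, s in enumerate(names[: i + 1]):
            l1s, lTs, lws = lam[s]
            tr_full = N * (
                (T - 1) * l1r * l1s / D1**2 + lTr * lTs / DT**2
            ) + N * T * (m - 1) * lwr * lws / se2**2
            val = 0.5 * (
                tr_full
                - 2.0 * np.trace(Phi @ C[(i, j)])
                + np.trace(Phi @ B[i] @ Phi @ B[j])
            )
            info[i, j] = info[j, i] = val
    try:
        W = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(info)
        flags.append("singular_information")

    correction = np.zeros_like(Phi)
    for i in range(k):
        for j in range(k):
            correction += W[i, j] * (C[(i, j)] - B[i] @ Phi @ B[j])
    Phi_adj = Phi + 2.0 * Phi @ correction @ Phi

    c = np.zeros(model.k_fe)
    c[-1] = 1.0  # the treatment contrast
    cPhic = float(c @ Phi @ c)
    a = np.array([float(c @ Phi @ Bi @ Phi @ c) / cPhic for Bi in B])
    return Phi, Phi_adj, W, a, tuple(flags)


def _ddf_from(W: np.ndarray, a: np.ndarray) -> float:
    denom = float(a @ W @ a)
    if denom <= 0:
        return np.inf  # zero gradient: the interval reduces to a z-interval
    return 2.0 / denom


def kr_adjust(fit: REMLResults, level: float = 0.95) -> SmallSampleResult:
    """First-order Kenward-Roger inference for the treatment effect.

    The adjusted covariance accounts for the uncertainty in the variance
    parameter estimates; the degrees of freedom come from the
    Satterthwaite-type moment matching of the scaled Wald statistic (for a
    one-dimensional contrast the Kenward-Roger scale factor is exactly 1).
    When variance components sit on the zero boundary, derivatives are
    evaluated at the boundary point and the result is flagged.
    """
    Phi, Phi_adj, W, a, flags = _kr_core(fit)
    var_adj = float(Phi_adj[-1, -1])
    if fit.boundary:
        flags = flags + ("boundary",)
    if var_adj <= 0 or "singular_information" in flags:
        # degenerate adjustment: fall back to Satterthwaite with the
        # unadjusted standard error
        ddf = _ddf_from(W, a)
        se = fit.se_theta
        lo, up = wald_interval(fit.theta_hat, se, ddf, level)
        return SmallSampleResult(
            se_adj=se, ddf=ddf, method_used="satterthwaite",
            ci_low=lo, ci_upp=up, level=level, flags=flags + ("kr_fallback",),
        )
    se_adj = float(np.sqrt(var_adj))
    ddf = _ddf_from(W, a)
    lo, up = wald_interval(fit.theta_hat, se_adj, ddf, level)
    return SmallSampleResult(
        se_adj=se_adj, ddf=ddf, method_used="kr",
        ci_low=lo, ci_upp=up, level=level, flags=flags,
    )


def satterthwaite_ddf(fit: REMLResults) -> tuple[float, tuple[str, ...]]:
    """Satterthwaite denominator degrees of freedom for the treatment effect.

    Moment-matching of the estimated contrast variance using the
    delta-method variance built from the expected (REML) information of the
    variance parameters.
    """
    _, _, W, a, flags = _kr_core(fit)
    return _ddf_from(W, a), flags
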