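"""Bayesian estimation of the stepped wedge LMM.

The model is parameterized directly by the within-period intracluster
correlation ``rho1``, the cluster autocorrelation ``r`` and the subject
error variance ``sigma_e2`` (the variance components are derived inside the
model through the same inversion formulas as the data generator), with
weakly informative priors:

- theta and the period effects beta_j: Normal(0, 10^4),
- sigma_e2: half-Cauchy(0, 1),
- rho1: Beta(1.5, 10.5) (mode 0.05, right-skewed, little mass above 0.2),
- r: Beta(5, 2) (mode 0.8), estimated only under the block-exchangeable
  structure; under the exchangeable structure r is fixed at 1 and removed
  from sampling.

Sampling uses the in-package NUTS implementation (see ``swcrt._nuts``) with
a target average acceptance statistic of 0.95; default settings run four
chains of 1000 warmup + 5000 retained iterations.  A replicate is *valid*
when there are no post-warmup divergent transitions, every monitored
parameter has rank-normalized split R-hat below 1.01, and bulk and tail
effective sample sizes of at least 400.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datagen import TrialDataset, variance_components
from .model import SteppedWedgeLMM
from ._nuts import logpost_and_grad, sample_nuts

__all__ = [
    "PriorSpec",
    "SamplerSettings",
    "BayesResults",
    "fit_bayes",
    "fit_bayes_model",
    "sample_prior",
    "summarize_posterior",
    "check_validity",
]

RHAT_LIMIT = 1.01
ESS_LIMIT = 400.0


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters for the Bayesian fit."""

    fe_sd: float = 100.0  # Normal(0, fe_sd^2) on theta and each beta_j
    sigma_e2_scale: float = 1.0  # half-Cauchy scale on sigma_e2
    rho1_beta: tuple[float, float] = (1.5, 10.5)
    cac_beta: tuple[float, float] = (5.0, 2.0)

    def __post_init__(self) -> None:
        if min(
            self.fe_sd, self.sigma_e2_scale, *self.rho1_beta, *self.cac_beta
        ) <= 0:
            raise ValueError("all prior hyperparameters must be positive")

    @staticmethod
    def beta_mode(a: float, b: float) -> float:
        """Mode of a Beta(a, b) distribution, (a-1)/(a+b-2)."""
        if a <= 1 or a + b <= 2:
            raise ValueError("mode requires a > 1 and a + b > 2")
        return (a - 1.0) / (a + b - 2.0)


@dataclass(frozen=True)
class SamplerSettings:
    """NUTS settings; defaults follow the simulation study."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 5000
    target_accept: float = 0.95
    max_treedepth: int = 10
    init_jitter: float = 2.0  # uniform(-j, j) initialization, unconstrained

    def __post_init__(self) -> None:
        if self.chains < 1 or self.warmup < 10 or self.draws < 10:
            raise ValueError("need chains >= 1, warmup >= 10, draws >= 10")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must lie in (0, 1)")


@dataclass
class BayesResults:
    """Posterior draws, diagnostics and validity for one MCMC fit.

    ``draws`` maps parameter names (``theta``, ``beta_1`` .., ``sigma_e2``,
    ``rho1``, ``cac``, ``sigma_C2``, ``sigma_CP2``, ``lp``) to arrays of
    shape ``(chains, draws)`` on the natural scale.
    """

    draws: dict[str, np.ndarray] = field(repr=False)
    n_divergent: int = 0
    diagnostics: pd.DataFrame = field(default=None, repr=False)
    structure: str = "block_exchangeable"
    settings: SamplerSettings = None
    priors: PriorSpec = None
    seed: int | None = None
    sampler_stats: list = field(default_factory=list, repr=False)

    @property
    def parameters(self) -> list[str]:
        return list(self.draws)

    @property
    def valid(self) -> bool:
        return check_validity(self)[0]

    @property
    def reasons(self) -> tuple[str, ...]:
        return check_validity(self)[1]

    def pooled(self, parameter: str) -> np.ndarray:
        """Post-warmup draws pooled across chains."""
        if parameter not in self.draws:
            raise KeyError(parameter)
        return self.draws[parameter].reshape(-1)

    def posterior_median(self, parameter: str) -> float:
        return float(np.median(self.pooled(parameter)))

    def credible_interval(
        self, parameter: str, level: float = 0.95
    ) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        q = np.quantile(self.pooled(parameter), [lo, 1.0 - lo])
        return float(q[0]), float(q[1])

    def to_inference_data(self):
        """Draws as an arviz InferenceData object."""
        import arviz as az

        return az.from_dict(posterior={k: v for k, v in self.draws.items()})

    def summary(self) -> str:
        valid, reasons = check_validity(self)
        lines = [
            "Stepped wedge LMM (Bayesian MCMC, NUTS)",
            "=" * 72,
            f"structure: {self.structure}   chains: {self.settings.chains}"
            f"   warmup: {self.settings.warmup}   draws: {self.settings.draws}",
            f"divergent transitions (post-warmup): {self.n_divergent}"
            f"   valid: {valid}{'' if valid else '  reasons: ' + ','.join(reasons)}",
            "-" * 72,
            f"{'parameter':<12}{'median':>10}{'q2.5':>10}{'q97.5':>10}"
            f"{'rhat':>8}{'ess_b':>8}{'ess_t':>8}",
        ]
        diag = self.diagnostics.set_index("parameter")
        for name in self.draws:
            if name == "lp" or name.startswith("sigma_C"):
                continue
            med = self.posterior_median(name)
            lo, up = self.credible_interval(name)
            if name in diag.index:
                d = diag.loc[name]
                extra = f"{d['rhat']:>8.3f}{d['ess_bulk']:>8.0f}{d['ess_tail']:>8.0f}"
            else:
                extra = ""
            lines.append(f"{name:<12}{med:>10.4f}{lo:>10.4f}{up:>10.4f}{extra}")
        return "\n".join(lines)


def summarize_posterior(
    result: BayesResults, parameter: str
) -> tuple[float, float, float]:
    """Posterior median and 2.5th/97.5th percentiles of pooled draws."""
    pooled = result.pooled(parameter)
    if pooled.size == 0:
        raise ValueError("no draws to summarize")
    med = float(np.median(pooled))
    lo, up = np.quantile(pooled, [0.025, 0.975])
    return med, float(lo), float(up)


def check_validity(result: BayesResults) -> tuple[bool, tuple[str, ...]]:
    """Replicate-validity flag with reason codes.

    A fit is valid iff it has zero post-warmup divergent transitions, all
    monitored parameters have split R-hat < 1.01, and bulk and tail ESS of
    at least 400.
    """
    reasons = []
    if result.n_divergent > 0:
        reasons.append("divergences")
    diag = result.diagnostics
    if diag is None or len(diag) == 0:
        reasons.append("missing_diagnostics")
    else:
        if (diag["rhat"] >= RHAT_LIMIT).any() or diag["rhat"].isna().any():
            reasons.append("rhat")
        if (diag["ess_bulk"] < ESS_LIMIT).any() or (
            diag["ess_tail"] < ESS_LIMIT
        ).any():
            reasons.append("ESS")
    return (len(reasons) == 0, tuple(reasons))


# ---------------------------------------------------------------------- #
# fitting


def _compute_diagnostics(monitored: dict[str, np.ndarray]) -> pd.DataFrame:
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: v for k, v in monitored.items()})
        rhat = az.rhat(ds, method="rank")
        ess_bulk = az.ess(ds, method="bulk")
        ess_tail = az.ess(ds, method="tail")
    rows = [
        {
            "parameter": name,
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess_bulk[name].values),
            "ess_tail": float(ess_tail[name].values),
        }
        for name in monitored
    ]
    return pd.DataFrame(rows)


def fit_bayes_model(
    model: SteppedWedgeLMM,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
    likelihood: bool = True,
    max_init_retries: int = 5,
) -> BayesResults:
    """Sample the marginal posterior of a :class:`SteppedWedgeLMM`.

    Parameters
    ----------
    model : SteppedWedgeLMM
        The model; its ``structure`` decides whether the cluster
        autocorrelation is estimated (block-exchangeable) or fixed at 1
        (exchangeable).
    priors, settings :
        Hyperparameters and sampler settings; defaults follow the
        simulation study.
    seed : int or SeedSequence
        Reproducibility: identical (model, priors, settings, seed) give
        identical draws.
    likelihood : bool
        When False the sampler targets the prior only (useful for
        prior-predictive checks of the implied variance components).
    """
    if model.structure == "none":
        raise ValueError("Bayesian fit requires a random-effects structure")
    priors = priors or PriorSpec()
    settings = settings or SamplerSettings()
    estimate_r = model.structure == "block_exchangeable"
    T = model.T
    dim = T + 3 + (1 if estimate_r else 0)

    stats = model.stats
    ybar = np.ascontiguousarray(stats.ybar, dtype=np.float64)
    x = np.ascontiguousarray(stats.x, dtype=np.float64)
    args = (
        ybar,
        x,
        float(stats.ssw),
        stats.m,
        estimate_r,
        bool(likelihood),
        priors.fe_sd,
        priors.sigma_e2_scale,
        priors.rho1_beta[0],
        priors.rho1_beta[1],
        priors.cac_beta[0],
        priors.cac_beta[1],
    )

    def logp_grad(q):
        return logpost_and_grad(q, *args)

    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    chain_seeds = ss.spawn(settings.chains)
    chain_draws, chain_lps, chain_div = [], [], []
    sampler_stats = []
    for cs in chain_seeds:
        rng = np.random.default_rng(cs)
        draws = None
        for _ in range(max_init_retries):
            q0 = rng.uniform(-settings.init_jitter, settings.init_jitter, dim)
            try:
                draws, lps, div, st = sample_nuts(
                    logp_grad,
                    q0,
                    settings.warmup,
                    settings.draws,
                    rng,
                    target_accept=settings.target_accept,
                    max_treedepth=settings.max_treedepth,
                )
                break
            except FloatingPointError:
                continue
        if draws is None:
            raise RuntimeError(
                "sampler initialization failed after retries"
            )
        chain_draws.append(draws)
        chain_lps.append(lps)
        chain_div.append(div)
        sampler_stats.append(st)

    raw = np.stack(chain_draws)  # (chains, draws, dim)
    lp = np.stack(chain_lps)
    divergent = np.stack(chain_div)

    beta = raw[:, :, :T]
    theta = raw[:, :, T]
    sigma_e2 = np.exp(raw[:, :, T + 1])
    rho1 = 1.0 / (1.0 + np.exp(-raw[:, :, T + 2]))
    out: dict[str, np.ndarray] = {"theta": theta}
    for j in range(T):
        out[f"beta_{j + 1}"] = beta[:, :, j]
    out["sigma_e2"] = sigma_e2
    out["rho1"] = rho1
    if estimate_r:
        cac = 1.0 / (1.0 + np.exp(-raw[:, :, T + 3]))
        out["cac"] = cac
    else:
        cac = np.ones_like(rho1)
    # derived variance components, same inversion as the data generator
    total_cluster = rho1 * sigma_e2 / (1.0 - rho1)
    out["sigma_C2"] = cac * total_cluster
    out["sigma_CP2"] = (1.0 - cac) * total_cluster
    out["lp"] = lp

    monitored = {
        k: v
        for k, v in out.items()
        if k not in ("sigma_C2", "sigma_CP2")
    }
    diagnostics = _compute_diagnostics(monitored)

    return BayesResults(
        draws=out,
        n_divergent=int(divergent.sum()),
        diagnostics=diagnostics,
        structure=model.structure,
        settings=settings,
        priors=priors,
        seed=seed if isinstance(seed, (int, type(None))) else None,
        sampler_stats=sampler_stats,
    )


def fit_bayes(
    data: TrialDataset,
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int | np.random.SeedSequence | None = None,
    structure: str | None = None,
) -> BayesResults:
    """Bayesian fit of the stepped wedge LMM to a simulated dataset."""
    model = SteppedWedgeLMM.from_dataset(data, structure)
    return fit_bayes_model(model, priors=priors, settings=settings, seed=seed)


def sample_prior(
    T: int = 5,
    structure: str = "block_exchangeable",
    priors: PriorSpec | None = None,
    settings: SamplerSettings | None = None,
    seed: int | None = None,
) -> BayesResults:
    """Prior-only run: sample the model with the likelihood disabled.

    The marginal draws of (rho1, r, sigma_e2) — and hence of the implied
    variance components sigma_C2, sigma_CP2 — should reproduce direct Monte
    Carlo draws from the priors.
    """
    from .model import CellStats

    dummy = CellStats(
        ybar=np.zeros((2, T)), ssw=0.0, m=2, x=np.zeros((2, T))
    )
    model = SteppedWedgeLMM(dummy, structure)
    return fit_bayes_model(
        model, priors=priors, settings=settings, seed=seed, likelihood=False
    )
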