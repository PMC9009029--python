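"""Synthetic trial data under the stepped wedge linear mixed model.

Outcomes are generated from

    Y_ijk = beta_j + X_ij * theta + C_i + CP_ij + e_ijk

with cluster effects ``C_i ~ N(0, sigma_C2)``, cluster-period effects
``CP_ij ~ N(0, sigma_CP2)`` and subject errors ``e_ijk ~ N(0, sigma_e2)``,
all mutually independent; each subject is measured once (cross-sectional
sampling).  The model is parameterized by the within-period intracluster
correlation ``rho1 = (sigma_C2 + sigma_CP2) / (sigma_C2 + sigma_CP2 +
sigma_e2)`` and the cluster autocorrelation ``r = sigma_C2 / (sigma_C2 +
sigma_CP2)``; the between-period correlation is ``rho2 = rho1 * r``.  When
``r = 1`` the cluster-period term vanishes and the model reduces to the
exchangeable structure.

The generating period effects are linear, ``beta_j = j / T``; the analysis
model fits categorical period effects and so remains correctly specified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import SWDesign, TrialConfig, build_standard_sw

__all__ = [
    "CorrelationParams",
    "TrialDataset",
    "variance_components",
    "correlations_from_components",
    "simulate_trial",
    "replicate_seed",
]


def variance_components(
    rho1: float, cac: float, sigma_e2: float
) -> tuple[float, float]:
    """Invert the correlation definitions to variance components.

    Solving ``rho1 = (sigma_C2 + sigma_CP2) / (sigma_C2 + sigma_CP2 +
    sigma_e2)`` and ``r = sigma_C2 / (sigma_C2 + sigma_CP2)`` gives

        sigma_C2  = r * rho1 * sigma_e2 / (1 - rho1)
        sigma_CP2 = (1 - r) * rho1 * sigma_e2 / (1 - rho1)

    Parameters
    ----------
    rho1 : float
        Within-period intracluster correlation, in ``[0, 1)``.
    cac : float
        Cluster autocorrelation ``r``, in ``(0, 1]``.
    sigma_e2 : float
        Subject-level error variance (> 0).

    Returns
    -------
    (sigma_C2, sigma_CP2) : tuple of float
    """
    if not 0.0 <= rho1 < 1.0:
        raise ValueError("rho1 must lie in [0, 1); rho1 = 1 implies infinite variance")
    if not 0.0 < cac <= 1.0:
        raise ValueError("cac must lie in (0, 1]")
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    total_cluster = rho1 * sigma_e2 / (1.0 - rho1)  # sigma_C2 + sigma_CP2
    return cac * total_cluster, (1.0 - cac) * total_cluster


def correlations_from_components(
    sigma_C2: float, sigma_CP2: float, sigma_e2: float
) -> tuple[float, float | None]:
    """Map variance components back to ``(rho1, r)``.

    ``r`` is ``None`` (undefined) when both cluster-level components are
    zero, mirroring the invalid-replicate rule for REML estimates.
    """
    total = sigma_C2 + sigma_CP2
    rho1 = total / (total + sigma_e2)
    cac = sigma_C2 / total if total > 0 else None
    return rho1, cac


@dataclass(frozen=True)
class CorrelationParams:
    """Correlation parameterization of the block-exchangeable LMM."""

    rho1: float
    cac: float
    sigma_e2: float = 1.0

    @property
    def rho2(self) -> float:
        """Between-period intracluster correlation, ``rho1 * r``."""
        return self.rho1 * self.cac

    @property
    def sigma_C2(self) -> float:
        return variance_components(self.rho1, self.cac, self.sigma_e2)[0]

    @property
    def sigma_CP2(self) -> float:
        return variance_components(self.rho1, self.cac, self.sigma_e2)[1]

    @property
    def total_variance(self) -> float:
        return self.sigma_C2 + self.sigma_CP2 + self.sigma_e2


@dataclass
class TrialDataset:
    """Simulated individual-level outcomes for one trial replicate.

    ``frame`` is long-format with columns ``cluster`` (1-based), ``period``
    (1-based), ``subject`` (1-based within cluster-period; the index has no
    meaning across periods), ``treatment`` and ``y``.
    """

    design: SWDesign
    m: int
    frame: pd.DataFrame = field(repr=False)
    truth: TrialConfig | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        expected = self.design.N * self.design.T * self.m
        if len(self.frame) != expected:
            raise ValueError(
                f"expected {expected} outcomes, found {len(self.frame)}"
            )

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def y_array(self) -> np.ndarray:
        """Outcomes as an (N, T, m) array (cluster, period, subject order)."""
        df = self.frame.sort_values(["cluster", "period", "subject"])
        return df["y"].to_numpy().reshape(self.design.N, self.design.T, self.m)

    def cell_means(self) -> np.ndarray:
        """Cluster-period means, shape (N, T)."""
        return self.y_array().mean(axis=2)

    def to_csv(self, path) -> None:
        """Write long-format CSV plus a JSON metadata sidecar."""
        path = Path(path)
        self.frame.to_csv(path, index=False)
        meta = {
            "S": self.design.S,
            "T": self.design.T,
            "m": self.m,
            "seed": self.seed,
            "truth": None
            if self.truth is None
            else {
                "S": self.truth.S,
                "T": self.truth.T,
                "m": self.truth.m,
                "rho1": self.truth.rho1,
                "cac": self.truth.cac,
                "theta": self.truth.theta,
                "sigma_e2": self.truth.sigma_e2,
                "n_sim": self.truth.n_sim,
                "base_seed": self.truth.base_seed,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_csv(cls, path) -> "TrialDataset":
        path = Path(path)
        frame = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        design = build_standard_sw(meta["S"], meta["T"])
        truth = None
        if meta.get("truth") is not None:
            truth = TrialConfig(**meta["truth"])
        return cls(
            design=design, m=meta["m"], frame=frame, truth=truth,
            seed=meta.get("seed"),
        )


def replicate_seed(base_seed: int, config_index: int, replicate: int) -> np.random.SeedSequence:
    """Independent, reproducible seed stream for one replicate.

    Spawn-key composition guarantees non-overlapping streams across all
    (config, replicate) pairs regardless of batching, so a study can be run
    in parallel batches and still be reproducible replicate-by-replicate.
    """
    return np.random.SeedSequence(
        entropy=base_seed, spawn_key=(config_index, replicate)
    )


def simulate_trial(
    config: TrialConfig,
    design: SWDesign | None = None,
    seed: int | np.random.SeedSequence | None = None,
) -> TrialDataset:
    """Simulate one trial dataset under the generating model.

    Parameters
    ----------
    config : TrialConfig
        Trial configuration; supplies (S, T, m), the correlation parameters
        and the fixed effects (``beta_j = j / T``, treatment effect
        ``config.theta``).
    design : SWDesign, optional
        Must match ``config``'s S and T; built on the fly if omitted.
    seed : int or numpy SeedSequence, optional
        Seed for the replicate's generator; identical (config, seed) pairs
        produce identical datasets.

    Returns
    -------
    TrialDataset
    """
    if design is None:
        design = build_standard_sw(config.S, config.T)
    if (design.S, design.T) != (config.S, config.T):
        raise ValueError("design does not match config's (S, T)")
    sigma_C2, sigma_CP2 = variance_components(
        config.rho1, config.cac, config.sigma_e2
    )
    rng = np.random.default_rng(seed)
    N, T, m = design.N, design.T, config.m

    beta = np.arange(1, T + 1) / T  # linear generating period effects
    mu = beta[None, :] + design.X * config.theta  # (N, T)
    cluster_eff = rng.normal(0.0, np.sqrt(sigma_C2), size=N)
    # model (2): with r = 1 the cluster-period effect is identically zero
    if sigma_CP2 > 0:
        cp_eff = rng.normal(0.0, np.sqrt(sigma_CP2), size=(N, T))
    else:
        cp_eff = np.zeros((N, T))
    errors = rng.normal(0.0, np.sqrt(config.sigma_e2), size=(N, T, m))
    y = mu[:, :, None] + cluster_eff[:, None, None] + cp_eff[:, :, None] + errors

    clusters = np.repeat(np.arange(1, N + 1), T * m)
    periods = np.tile(np.repeat(np.arange(1, T + 1), m), N)
    subjects = np.tile(np.arange(1, m + 1), N * T)
    frame = pd.DataFrame(
        {
            "cluster": clusters,
            "period": periods,
            "subject": subjects,
            "treatment": design.X[clusters - 1, periods - 1],
            "y": y.ravel(),
        }
    )
    seed_int = None
    if isinstance(seed, (int, np.integer)):
        seed_int = int(seed)
    return TrialDataset(design=design, m=m, frame=frame, truth=config, seed=seed_int)
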