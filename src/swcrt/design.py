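"""Standard stepped wedge designs and the simulation configuration grid.

A *standard* stepped wedge (SW) design with ``T`` periods has ``T - 1``
unique treatment sequences: sequence ``q`` crosses from control to
intervention at period ``q + 1``, so the first period is all-control and the
last period is all-intervention.  With ``S`` clusters per sequence the trial
has ``N = S * (T - 1)`` clusters.  Clusters are assigned to sequences in
blocks (clusters ``1..S`` on sequence 1, and so on); any ordering is
statistically equivalent under the exchangeable models used here, but a
fixed one keeps outputs reproducible.  Clusters and periods are 1-based.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SWDesign",
    "TrialConfig",
    "build_standard_sw",
    "enumerate_configs",
    "TABLE1_GRID",
]

#: Default parameter values varied in the simulation study: number of
#: clusters per sequence S, periods T, subjects per cluster-period m,
#: within-period intracluster correlation rho1 and cluster autocorrelation r.
TABLE1_GRID: dict[str, tuple] = {
    "S": (1, 2, 5),
    "T": (5, 9),
    "m": (10, 100),
    "rho1": (0.05, 0.1),
    "cac": (0.8, 1.0),
}


@dataclass(frozen=True)
class SWDesign:
    """A standard stepped wedge treatment layout.

    Attributes
    ----------
    S : int
        Clusters per treatment sequence.
    T : int
        Number of periods.
    N : int
        Total number of clusters, ``S * (T - 1)``.
    X : ndarray of shape (N, T)
        Binary treatment indicator; ``X[i, j] = 1`` when cluster ``i + 1``
        is in the intervention condition during period ``j + 1``.
    sequence_of_cluster : ndarray of shape (N,)
        1-based sequence index of each cluster; sequence ``q`` switches to
        intervention at period ``q + 1``.
    """

    S: int
    T: int
    N: int
    X: np.ndarray = field(repr=False)
    sequence_of_cluster: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.N != self.S * (self.T - 1):
            raise ValueError("N must equal S * (T - 1)")
        X = np.asarray(self.X)
        if X.shape != (self.N, self.T):
            raise ValueError("X must have shape (N, T)")

    def to_frame(self) -> pd.DataFrame:
        """Treatment matrix as a DataFrame (rows=clusters, columns=periods)."""
        return pd.DataFrame(
            self.X,
            index=pd.Index(np.arange(1, self.N + 1), name="cluster"),
            columns=pd.Index(np.arange(1, self.T + 1), name="period"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass(frozen=True)
class TrialConfig:
    """One cell of the simulation grid.

    Parameters
    ----------
    S, T, m : int
        Clusters per sequence, periods, and subjects per cluster-period.
    rho1 : float
        Within-period intracluster correlation, in ``[0, 1)``.
    cac : float
        Cluster autocorrelation ``r``, in ``(0, 1]``.  ``cac == 1`` selects
        the exchangeable model (no cluster-period random effect).
    theta : float
        True treatment effect (outcome units).
    sigma_e2 : float
        Subject-level error variance.
    n_sim : int
        Number of simulation replicates.
    base_seed : int
        Base entropy for the replicate seed streams.
    """

    S: int
    T: int
    m: int
    rho1: float
    cac: float
    theta: float = 0.0
    sigma_e2: float = 1.0
    n_sim: int = 1000
    base_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.S, self.T, self.m, self.n_sim) < 1:
            raise ValueError("S, T, m and n_sim must be >= 1")
        if not 0.0 <= self.rho1 < 1.0:
            raise ValueError("rho1 must lie in [0, 1)")
        if not 0.0 < self.cac <= 1.0:
            raise ValueError("cac must lie in (0, 1]")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be positive")

    @property
    def N(self) -> int:
        return self.S * (self.T - 1)

    @property
    def structure(self) -> str:
        """Correlation structure of the generating (and analysis) model."""
        return "exchangeable" if self.cac == 1.0 else "block_exchangeable"

    @property
    def label(self) -> str:
        return (
            f"S{self.S}_T{self.T}_m{self.m}_rho{self.rho1:g}_r{self.cac:g}"
        )


def build_standard_sw(S: int, T: int) -> SWDesign:
    """Construct a standard stepped wedge design.

    Parameters
    ----------
    S : int
        Clusters per treatment sequence (>= 1).
    T : int
        Number of periods (>= 2).

    Returns
    -------
    SWDesign
        Design with ``N = S * (T - 1)`` clusters ordered by sequence; the
        cluster on sequence ``q`` has ``X[i, j] = 1`` iff ``j + 1 >= q + 1``.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if T < 2:
        raise ValueError("T must be >= 2: a stepped wedge needs room for a step")
    N = S * (T - 1)
    sequences = np.repeat(np.arange(1, T), S)  # block assignment, 1-based
    periods = np.arange(1, T + 1)
    X = (periods[None, :] >= sequences[:, None] + 1).astype(np.int8)
    return SWDesign(S=S, T=T, N=N, X=X, sequence_of_cluster=sequences)


def enumerate_configs(
    grid: dict | None = None,
    *,
    theta: float = 0.0,
    sigma_e2: float = 1.0,
    n_sim: int = 1000,
    base_seed: int = 0,
) -> list[TrialConfig]:
    """Enumerate the full cross product of a configuration grid.

    With the default grid this yields the full set of 48 trial configurations:
    S in {1, 2, 5}, T in {5, 9}, m in {10, 100}, rho1 in {0.05, 0.1} and
    cluster autocorrelation in {0.8, 1}.

    Parameters
    ----------
    grid : dict, optional
        Mapping with keys ``S``, ``T``, ``m``, ``rho1``, ``cac``, each a
        non-empty iterable of values.  Defaults to :data:`TABLE1_GRID`.
    theta, sigma_e2, n_sim, base_seed :
        Attached to every configuration.
    """
    grid = dict(TABLE1_GRID if grid is None else grid)
    missing = set(TABLE1_GRID) - set(grid)
    if missing:
        raise ValueError(f"grid missing keys: {sorted(missing)}")
    for key, values in grid.items():
        if not len(tuple(values)):
            raise ValueError(f"grid value list for {key!r} is empty")
    combos = itertools.product(
        grid["S"], grid["T"], grid["m"], grid["rho1"], grid["cac"]
    )
    return [
        TrialConfig(
            S=S, T=T, m=m, rho1=rho1, cac=cac,
            theta=theta, sigma_e2=sigma_e2, n_sim=n_sim, base_seed=base_seed,
        )
        for S, T, m, rho1, cac in combos
    ]


def configs_to_frame(configs: list[TrialConfig]) -> pd.DataFrame:
    """Configuration grid as a DataFrame, one row per configuration."""
    rows = []
    for k, cfg in enumerate(configs):
        rows.append(
            {
                "config": k,
                "label": cfg.label,
                "S": cfg.S,
                "T": cfg.T,
                "m": cfg.m,
                "N": cfg.N,
                "rho1": cfg.rho1,
                "cac": cfg.cac,
                "theta": cfg.theta,
                "sigma_e2": cfg.sigma_e2,
                "n_sim": cfg.n_sim,
                "base_seed": cfg.base_seed,
                "structure": cfg.structure,
            }
        )
    return pd.DataFrame(rows)
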