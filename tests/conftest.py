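"""Shared fixtures: small simulated datasets and independent dense-matrix
oracles (restricted likelihood and Kenward-Roger built from explicit n x n
covariance matrices, no structure exploitation) used to validate the
package's structured implementations."""

import numpy as np
import pytest

from swcrt import TrialConfig, simulate_trial, variance_components


@pytest.fixture(scope="session")
def tiny_block_dataset():
    """Very small block-exchangeable dataset (N=2 clusters, n=12)."""
    cfg = TrialConfig(S=1, T=3, m=2, rho1=0.1, cac=0.8)
    return simulate_trial(cfg, seed=77)


@pytest.fixture(scope="session")
def small_block_dataset():
    cfg = TrialConfig(S=2, T=5, m=10, rho1=0.1, cac=0.8)
    return simulate_trial(cfg, seed=123)


@pytest.fixture(scope="session")
def small_exch_dataset():
    cfg = TrialConfig(S=2, T=5, m=10, rho1=0.1, cac=1.0)
    return simulate_trial(cfg, seed=45)


def _design_matrices(data):
    """Individual-level fixed-effect design and grouping index vectors."""
    T = data.design.T
    df = data.frame.sort_values(["cluster", "period", "subject"])
    n = len(df)
    X = np.zeros((n, T + 1))
    per = df["period"].to_numpy()
    X[np.arange(n), per - 1] = 1.0
    X[:, T] = df["treatment"].to_numpy()
    cl = df["cluster"].to_numpy()
    cp = (cl - 1) * T + (per - 1)
    y = df["y"].to_numpy()
    return y, X, cl, cp


def dense_restricted_loglik(data, sigma_C2, sigma_CP2, sigma_e2):
    """Restricted log-likelihood from explicit dense matrices."""
    y, X, cl, cp = _design_matrices(data)
    n, p = X.shape
    V = (
        sigma_e2 * np.eye(n)
        + sigma_C2 * (cl[:, None] == cl[None, :])
        + sigma_CP2 * (cp[:, None] == cp[None, :])
    )
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    beta = np.linalg.solve(A, X.T @ Vi @ y)
    r = y - X @ beta
    _, ldV = np.linalg.slogdet(V)
    _, ldA = np.linalg.slogdet(A)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ldV + ldA + r @ Vi @ r)


def dense_reml_grid_max(data, structure="block_exchangeable", n_grid=35):
    """Brute-force restricted-likelihood maximization on a dense grid.

    Profiles sigma_e2 analytically (for V = sigma_e2 * V0 the REML estimate
    is the GLS residual quadratic form over n - p) and sweeps the variance
    ratios on a log grid with a zoom refinement — all with generic dense
    linear algebra, independent of the package's structured computations.
    """
    y, X, cl, cp = _design_matrices(data)
    n, p = X.shape
    same_cl = (cl[:, None] == cl[None, :]).astype(float)
    same_cp = (cp[:, None] == cp[None, :]).astype(float)

    def profiled(gC, gCP):
        V0 = np.eye(n) + gC * same_cl + gCP * same_cp
        Vi = np.linalg.inv(V0)
        A = X.T @ Vi @ X
        beta = np.linalg.solve(A, X.T @ Vi @ y)
        r = y - X @ beta
        q0 = r @ Vi @ r
        se2 = q0 / (n - p)
        _, ldV = np.linalg.slogdet(V0)
        _, ldA = np.linalg.slogdet(A)
        ll = -0.5 * (
            (n - p) * (np.log(2 * np.pi) + 1 + np.log(se2)) + ldV + ldA
        )
        return ll, se2

    grid = np.concatenate([[0.0], np.exp(np.linspace(-9.0, 2.0, n_grid))])
    gCP_values = grid if structure == "block_exchangeable" else np.array([0.0])

    best = (-np.inf, 0.0, 0.0, 1.0)
    for gC in grid:
        for gCP in gCP_values:
            ll, se2 = profiled(gC, gCP)
            if ll > best[0]:
                best = (ll, gC, gCP, se2)
    # zoom refinement around the coarse optimum with shrinking spans
    _, gC0, gCP0, _ = best
    for span in (3.0, 1.5, 1.12, 1.03):
        gC_lo = gC0 / span if gC0 > 0 else 0.0
        gC_hi = max(gC0 * span, 1e-6)
        gCs = np.concatenate([[0.0], np.linspace(gC_lo, gC_hi, n_grid)])
        if structure == "block_exchangeable":
            gCP_lo = gCP0 / span if gCP0 > 0 else 0.0
            gCP_hi = max(gCP0 * span, 1e-6)
            gCPs = np.concatenate([[0.0], np.linspace(gCP_lo, gCP_hi, n_grid)])
        else:
            gCPs = np.array([0.0])
        for gC in gCs:
            for gCP in gCPs:
                ll, se2 = profiled(gC, gCP)
                if ll > best[0]:
                    best = (ll, gC, gCP, se2)
        _, gC0, gCP0, _ = best
    ll, gC, gCP, se2 = best
    return {
        "llf": ll,
        "sigma_C2": gC * se2,
        "sigma_CP2": gCP * se2,
        "sigma_e2": se2,
    }


def dense_kr(data, fit, structure):
    """Kenward-Roger adjusted SE and ddf from explicit dense matrices."""
    y, X, cl, cp = _design_matrices(data)
    n, p = X.shape
    Vc = (cl[:, None] == cl[None, :]).astype(float)
    Vcp = (cp[:, None] == cp[None, :]).astype(float)
    Ve = np.eye(n)
    V = fit.sigma_e2 * Ve + fit.sigma_C2 * Vc + fit.sigma_CP2 * Vcp
    Vi = np.linalg.inv(V)
    Phi = np.linalg.inv(X.T @ Vi @ X)
    P_reml = Vi - Vi @ X @ Phi @ X.T @ Vi
    derivs = {
        "block_exchangeable": [Vc, Vcp, Ve],
        "exchangeable": [Vc, Ve],
        "none": [Ve],
    }[structure]
    k = len(derivs)
    B = [X.T @ Vi @ Vr @ Vi @ X for Vr in derivs]
    C = {}
    info = np.empty((k, k))
    for r, Vr in enumerate(derivs):
        for s, Vs in enumerate(derivs):
            C[(r, s)] = X.T @ Vi @ Vr @ Vi @ Vs @ Vi @ X
            info[r, s] = 0.5 * np.trace(P_reml @ Vr @ P_reml @ Vs)
    W = np.linalg.inv(info)
    corr = sum(
        W[r, s] * (C[(r, s)] - B[r] @ Phi @ B[s])
        for r in range(k)
        for s in range(k)
    )
    Phi_A = Phi + 2 * Phi @ corr @ Phi
    c = np.zeros(p)
    c[-1] = 1.0
    a = np.array([c @ Phi @ B[r] @ Phi @ c for r in range(k)]) / (c @ Phi @ c)
    ddf = 2.0 / float(a @ W @ a)
    return float(np.sqrt(Phi_A[-1, -1])), ddf


@pytest.fixture(scope="session")
def oracles():
    """Bundle of dense-matrix oracle functions."""
    return {
        "restricted_loglik": dense_restricted_loglik,
        "reml_grid_max": dense_reml_grid_max,
        "kr": dense_kr,
        "design_matrices": _design_matrices,
    }
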