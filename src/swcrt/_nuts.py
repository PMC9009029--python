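"""No-U-Turn sampler with a numba-compiled log posterior gradient.

The sampler targets the *marginal* posterior of the stepped wedge LMM —
cluster and cluster-period random effects are integrated out analytically
(the balanced block-exchangeable covariance has a two-eigenvalue structure
on the cell-mean space), so the unconstrained parameter vector is

    q = [beta_1 .. beta_T, theta, log sigma_e2, logit rho1, (logit r)]

with the last coordinate present only when the cluster autocorrelation is
estimated.  Sampling the marginal removes the funnel geometry that latent
effect parameterizations (centered or non-centered) can create, which is
what divergent transitions diagnose; divergences are still tracked with the
usual energy-error criterion so that pathological fits are flagged.

The kernel is multinomial NUTS with biased progressive sampling, dual
averaging of the step size toward a target acceptance statistic, and a
diagonal mass matrix estimated during an adaptation window — the standard
warmup recipe of modern HMC implementations.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["logpost_and_grad", "sample_nuts"]

_ENERGY_ERROR_LIMIT = 1000.0  # energy error above this flags a divergence


@njit(cache=True, error_model="numpy")
def logpost_and_grad(
    q,
    ybar,
    x,
    ssw,
    m,
    estimate_r,
    like_on,
    fe_sd,
    hc_scale,
    a_rho,
    b_rho,
    a_cac,
    b_cac,
):
    """Log posterior density and gradient on the unconstrained scale.

    Beta priors on rho1 and r and the log/logit transform Jacobians are
    folded together (a Beta(a,b) density plus the logit Jacobian gives
    ``a*log(p) + b*log(1-p)`` up to a constant).  The half-Cauchy prior is
    placed on the error *variance* sigma_e2.
    """
    N, T = ybar.shape
    p = T + 1
    dim = q.shape[0]
    grad = np.zeros(dim)
    lp = 0.0

    beta = q[:T]
    theta = q[T]
    u = q[T + 1]
    a = q[T + 2]
    se2 = np.exp(u)

    # stable sigmoid / log-sigmoid for logit(rho1)
    if a >= 0.0:
        rho1 = 1.0 / (1.0 + np.exp(-a))
        log_rho1 = -np.log1p(np.exp(-a))
        log_1m_rho1 = -a - np.log1p(np.exp(-a))
    else:
        ea = np.exp(a)
        rho1 = ea / (1.0 + ea)
        log_rho1 = a - np.log1p(ea)
        log_1m_rho1 = -np.log1p(ea)

    if estimate_r:
        b = q[T + 3]
        if b >= 0.0:
            cac = 1.0 / (1.0 + np.exp(-b))
            log_cac = -np.log1p(np.exp(-b))
            log_1m_cac = -b - np.log1p(np.exp(-b))
        else:
            eb = np.exp(b)
            cac = eb / (1.0 + eb)
            log_cac = b - np.log1p(eb)
            log_1m_cac = -np.log1p(eb)
    else:
        cac = 1.0
        log_cac = 0.0
        log_1m_cac = 0.0

    # rho1 numerically at 1 means infinite cluster-level variance: reject
    # the point outright (treated as an off-support divergence)
    if rho1 >= 1.0 - 1e-14 or not np.isfinite(se2):
        return -np.inf, grad

    if like_on:
        g = rho1 / (1.0 - rho1)
        D1 = se2 * (1.0 + m * (1.0 - cac) * g)
        DT = se2 * (1.0 + m * (1.0 - cac) * g + T * m * cac * g)
        sqm = np.sqrt(m)
        n_within = N * T * (m - 1)

        SS_tot = 0.0
        SS_rbar = 0.0
        dbeta = np.zeros(T)
        dtheta = 0.0
        # first pass: residuals and row means
        R = np.empty((N, T))
        rbar = np.empty(N)
        for i in range(N):
            acc = 0.0
            for j in range(T):
                rij = sqm * (ybar[i, j] - beta[j] - theta * x[i, j])
                R[i, j] = rij
                acc += rij
            rbar[i] = acc / T
            SS_rbar += rbar[i] * rbar[i]
            for j in range(T):
                SS_tot += R[i, j] * R[i, j]
        SSc = SS_tot - T * SS_rbar
        SSm = T * SS_rbar

        lp += -0.5 * (
            n_within * (np.log(2.0 * np.pi) + u)
            + ssw / se2
            + N * T * np.log(2.0 * np.pi)
            + N * (T - 1) * np.log(D1)
            + N * np.log(DT)
            + SSc / D1
            + SSm / DT
        )

        for i in range(N):
            for j in range(T):
                w = (R[i, j] - rbar[i]) / D1 + rbar[i] / DT
                dbeta[j] += sqm * w
                dtheta += sqm * w * x[i, j]
        for j in range(T):
            grad[j] += dbeta[j]
        grad[T] += dtheta

        dL_dD1 = -0.5 * (N * (T - 1) / D1 - SSc / (D1 * D1))
        dL_dDT = -0.5 * (N / DT - SSm / (DT * DT))
        dL_dse2 = -0.5 * (n_within / se2 - ssw / (se2 * se2))
        # chain rules through D1, DT
        dD1_dse2 = D1 / se2
        dDT_dse2 = DT / se2
        dD1_dg = se2 * m * (1.0 - cac)
        dDT_dg = se2 * m * ((1.0 - cac) + T * cac)
        dg_drho1 = 1.0 / ((1.0 - rho1) * (1.0 - rho1))

        grad[T + 1] += (dL_dse2 + dL_dD1 * dD1_dse2 + dL_dDT * dDT_dse2) * se2
        grad[T + 2] += (
            (dL_dD1 * dD1_dg + dL_dDT * dDT_dg)
            * dg_drho1
            * rho1
            * (1.0 - rho1)
        )
        if estimate_r:
            dD1_dcac = -se2 * m * g
            dDT_dcac = se2 * m * g * (T - 1)
            grad[T + 3] += (
                (dL_dD1 * dD1_dcac + dL_dDT * dDT_dcac) * cac * (1.0 - cac)
            )

    # priors ------------------------------------------------------------
    fe_var = fe_sd * fe_sd
    for j in range(p):
        lp += -0.5 * q[j] * q[j] / fe_var
        grad[j] += -q[j] / fe_var
    # half-Cauchy(0, hc_scale) on sigma_e2, plus log-transform Jacobian
    ratio = se2 / hc_scale
    lp += -np.log1p(ratio * ratio) + u
    grad[T + 1] += -2.0 * se2 * se2 / (hc_scale * hc_scale + se2 * se2) + 1.0
    # Beta priors with logit Jacobians folded in
    lp += a_rho * log_rho1 + b_rho * log_1m_rho1
    grad[T + 2] += a_rho - (a_rho + b_rho) * rho1
    if estimate_r:
        lp += a_cac * log_cac + b_cac * log_1m_cac
        grad[T + 3] += a_cac - (a_cac + b_cac) * cac

    return lp, grad


# ---------------------------------------------------------------------- #
# NUTS kernel


def _kinetic(p, inv_mass):
    return 0.5 * float(np.dot(p * inv_mass, p))


def _leapfrog(logp_grad, q, p, grad, eps, inv_mass):
    p_half = p + 0.5 * eps * grad
    q_new = q + eps * inv_mass * p_half
    lp_new, grad_new = logp_grad(q_new)
    p_new = p_half + 0.5 * eps * grad_new
    return q_new, p_new, lp_new, grad_new


def _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass):
    dq = q_plus - q_minus
    return (
        float(np.dot(dq, inv_mass * p_minus)) < 0.0
        or float(np.dot(dq, inv_mass * p_plus)) < 0.0
    )


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus",
        "q_plus", "p_plus", "g_plus",
        "q_prop", "lp_prop", "g_prop",
        "logw", "stop", "diverged", "astat_sum", "n_leap",
    )


def _build_tree(logp_grad, depth, q, p, grad, direction, eps, H0, inv_mass, rng):
    t = _Tree()
    if depth == 0:
        q1, p1, lp1, g1 = _leapfrog(logp_grad, q, p, grad, direction * eps, inv_mass)
        if np.isfinite(lp1):
            H1 = lp1 - _kinetic(p1, inv_mass)
            dH = H1 - H0
        else:
            dH = -np.inf
        diverged = not np.isfinite(dH) or dH < -_ENERGY_ERROR_LIMIT
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = t.g_prop = g1
        t.lp_prop = lp1
        t.logw = -np.inf if diverged else dH
        t.stop = diverged
        t.diverged = diverged
        t.astat_sum = min(1.0, np.exp(min(dH, 0.0))) if np.isfinite(dH) else 0.0
        t.n_leap = 1
        return t

    first = _build_tree(logp_grad, depth - 1, q, p, grad, direction, eps, H0, inv_mass, rng)
    if first.stop:
        return first
    if direction == 1:
        second = _build_tree(
            logp_grad, depth - 1, first.q_plus, first.p_plus, first.g_plus,
            direction, eps, H0, inv_mass, rng,
        )
        first.q_plus, first.p_plus, first.g_plus = (
            second.q_plus, second.p_plus, second.g_plus,
        )
    else:
        second = _build_tree(
            logp_grad, depth - 1, first.q_minus, first.p_minus, first.g_minus,
            direction, eps, H0, inv_mass, rng,
        )
        first.q_minus, first.p_minus, first.g_minus = (
            second.q_minus, second.p_minus, second.g_minus,
        )
    first.astat_sum += second.astat_sum
    first.n_leap += second.n_leap
    first.diverged = first.diverged or second.diverged
    if second.stop:
        first.stop = True
        return first
    total = np.logaddexp(first.logw, second.logw)
    if np.log(rng.random()) < second.logw - total:  # multinomial within tree
        first.q_prop, first.lp_prop, first.g_prop = (
            second.q_prop, second.lp_prop, second.g_prop,
        )
    first.logw = total
    first.stop = _uturn(
        first.q_minus, first.q_plus, first.p_minus, first.p_plus, inv_mass
    )
    return first


def _find_reasonable_epsilon(logp_grad, q, grad, lp, inv_mass, rng):
    eps = 1.0
    p = rng.standard_normal(q.shape[0]) / np.sqrt(inv_mass)
    H0 = lp - _kinetic(p, inv_mass)
    _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
    H1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
    direction = 1.0 if (H1 - H0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        _, p1, lp1, _ = _leapfrog(logp_grad, q, p, grad, eps, inv_mass)
        H1 = lp1 - _kinetic(p1, inv_mass) if np.isfinite(lp1) else -np.inf
        if direction * (H1 - H0) < direction * np.log(0.5):
            break
    return eps


def sample_nuts(
    logp_grad,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.95,
    max_treedepth: int = 10,
):
    """Run one NUTS chain.

    Returns ``(draws, lps, divergent, stats)`` where ``draws`` has shape
    ``(n_draws, dim)``, ``divergent`` flags post-warmup iterations whose
    trajectory contained an energy-error divergence, and ``stats`` records
    the adapted step size and inverse mass.
    """
    dim = q0.shape[0]
    q = q0.astype(float).copy()
    lp, grad = logp_grad(q)
    if not np.isfinite(lp):
        raise FloatingPointError("non-finite log posterior at the initial point")
    inv_mass = np.ones(dim)

    # dual-averaging state
    eps = _find_reasonable_epsilon(logp_grad, q, grad, lp, inv_mass, rng)
    mu = np.log(10.0 * eps)
    log_eps_bar, H_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    # windowed mass adaptation: fast / slow (Welford) / fast
    fast1 = max(1, int(0.15 * n_warmup))
    term = max(1, int(0.10 * n_warmup))
    slow_end = n_warmup - term
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    draws = np.empty((n_draws, dim))
    lps = np.empty(n_draws)
    divergent = np.zeros(n_draws, dtype=bool)
    n_div_warm = 0

    total = n_warmup + n_draws
    for it in range(total):
        p = rng.standard_normal(dim) / np.sqrt(inv_mass)
        H0 = lp - _kinetic(p, inv_mass)
        q_minus = q_plus = q
        p_minus = p_plus = p
        g_minus = g_plus = grad
        prop_q, prop_lp, prop_g = q, lp, grad
        logw_tot = 0.0
        astat_sum, n_leap = 0.0, 0
        diverged = False
        for depth in range(max_treedepth):
            direction = 1 if rng.random() < 0.5 else -1
            if direction == 1:
                tree = _build_tree(
                    logp_grad, depth, q_plus, p_plus, g_plus, 1, eps, H0,
                    inv_mass, rng,
                )
                q_plus, p_plus, g_plus = tree.q_plus, tree.p_plus, tree.g_plus
            else:
                tree = _build_tree(
                    logp_grad, depth, q_minus, p_minus, g_minus, -1, eps, H0,
                    inv_mass, rng,
                )
                q_minus, p_minus, g_minus = (
                    tree.q_minus, tree.p_minus, tree.g_minus,
                )
            astat_sum += tree.astat_sum
            n_leap += tree.n_leap
            diverged = diverged or tree.diverged
            if tree.stop:
                break
            # biased progressive sampling across doublings
            if np.log(rng.random()) < tree.logw - logw_tot:
                prop_q, prop_lp, prop_g = tree.q_prop, tree.lp_prop, tree.g_prop
            logw_tot = np.logaddexp(logw_tot, tree.logw)
            if _uturn(q_minus, q_plus, p_minus, p_plus, inv_mass):
                break
        q, lp, grad = prop_q, prop_lp, prop_g
        accept_stat = astat_sum / max(n_leap, 1)

        if it < n_warmup:
            if diverged:
                n_div_warm += 1
            # dual averaging
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            H_bar = (1.0 - frac) * H_bar + frac * (target_accept - accept_stat)
            log_eps = mu - np.sqrt(adapt_count) / gamma * H_bar
            w = adapt_count ** (-kappa)
            log_eps_bar = w * log_eps + (1.0 - w) * log_eps_bar
            eps = np.exp(log_eps)
            if fast1 <= it < slow_end:
                welford_n += 1
                delta = q - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (q - welford_mean)
            if it == slow_end - 1 and welford_n > 1:
                var = welford_m2 / (welford_n - 1)
                inv_mass = var * (welford_n / (welford_n + 5.0)) + 1e-3 * (
                    5.0 / (welford_n + 5.0)
                )
                # restart step-size adaptation at the new metric
                eps = _find_reasonable_epsilon(logp_grad, q, grad, lp, inv_mass, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, H_bar, adapt_count = 0.0, 0.0, 0
            if it == n_warmup - 1:
                eps = np.exp(log_eps_bar)
        else:
            k = it - n_warmup
            draws[k] = q
            lps[k] = lp
            divergent[k] = diverged

    stats = {
        "step_size": eps,
        "inv_mass": inv_mass,
        "n_divergent_warmup": n_div_warm,
    }
    return draws, lps, divergent, stats
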