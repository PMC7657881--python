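"""MCMC samplers: multinomial NUTS and a random-walk Metropolis fallback.

The primary sampler is a dynamic Hamiltonian Monte Carlo sampler (No-U-Turn
termination with multinomial state selection), with dual-averaging
step-size adaptation toward a target acceptance statistic and diagonal
mass-matrix estimation during warmup.  Trajectories are capped at a
configurable tree depth; energy errors above 1000 nats mark a divergence.

The fallback is an adaptive Gaussian random-walk Metropolis sampler: it
needs only log-density evaluations, mixes far more slowly, and exists so
every model remains estimable (and cross-checkable in distribution)
without gradient code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_MAX_ENERGY_ERROR = 1000.0


@dataclass
class SamplerStats:
    divergences: int = 0
    mean_accept: float = float("nan")
    step_size: float = float("nan")
    n_gradient_evals: int = 0
    max_depth_hits: int = 0


class _DualAveraging:
    """Nesterov dual averaging of the log step size (standard constants)."""

    def __init__(self, eps0: float, target: float):
        self.target = target
        self.gamma, self.t0, self.kappa = 0.05, 10.0, 0.75
        self.restart(eps0)

    def update(self, accept_stat: float) -> float:
        self.count += 1
        m = self.count
        eta = 1.0 / (m + self.t0)
        self.h_bar = (1.0 - eta) * self.h_bar + eta * (self.target - accept_stat)
        self.log_eps = self.mu - np.sqrt(m) / self.gamma * self.h_bar
        w = m ** (-self.kappa)
        self.log_eps_bar = w * self.log_eps + (1.0 - w) * self.log_eps_bar
        return float(np.exp(self.log_eps))

    def restart(self, eps: float) -> None:
        self.mu = np.log(10.0 * eps)
        self.log_eps = np.log(eps)
        self.log_eps_bar = np.log(eps)
        self.h_bar = 0.0
        self.count = 0


class _Tree:
    __slots__ = (
        "theta_minus", "p_minus", "g_minus",
        "theta_plus", "p_plus", "g_plus",
        "theta_prop", "g_prop", "logp_prop",
        "log_weight", "divergent", "turning", "accept_sum", "n_states",
    )


def _find_initial_step(logp_grad, theta, rng, m_inv):
    logp0, g0 = logp_grad(theta)
    p = rng.standard_normal(len(theta)) / np.sqrt(m_inv)
    h0 = logp0 - 0.5 * float(p * m_inv @ p)

    def joint(eps):
        p1 = p + 0.5 * eps * g0
        th1 = theta + eps * m_inv * p1
        lp1, g1 = logp_grad(th1)
        p1 = p1 + 0.5 * eps * g1
        h = lp1 - 0.5 * float(p1 * m_inv @ p1)
        return h if np.isfinite(h) else -np.inf

    eps = 1.0
    direction = 1.0 if (joint(eps) - h0) > np.log(0.5) else -1.0
    for _ in range(50):
        eps = eps * 2.0**direction
        if direction * (joint(eps) - h0) < direction * np.log(0.5):
            break
    return min(eps, 10.0)


def nuts(
    logp_grad,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    target_accept: float = 0.9,
    max_depth: int = 10,
):
    """Sample with dynamic HMC; returns (draws, logp trace, stats)."""
    theta = np.asarray(theta0, dtype=float).copy()
    dim = len(theta)
    m_inv = np.ones(dim)
    stats = SamplerStats()
    n_evals = 0

    def lg(th):
        nonlocal n_evals
        n_evals += 1
        return logp_grad(th)

    logp, grad = lg(theta)
    eps = _find_initial_step(lg, theta, rng, m_inv)
    da = _DualAveraging(eps, target_accept)

    # warmup schedule: step-size-only phase, then expanding covariance
    # windows (mass-matrix updates), then a final step-size-only phase
    w_init = max(int(0.15 * n_warmup), 1)
    w_term = n_warmup - max(int(0.1 * n_warmup), 1)
    window_ends: list[int] = []
    nxt, size = w_init, 25
    while nxt < w_term:
        nxt = min(nxt + size, w_term)
        # absorb a too-small trailing window into the last one
        if w_term - nxt < 25:
            nxt = w_term
        window_ends.append(nxt)
        size *= 2
    window: list[np.ndarray] = []

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accepts = []

    def leapfrog(th, p, g, direction):
        p1 = p + 0.5 * direction * eps * g
        th1 = th + direction * eps * m_inv * p1
        lp1, g1 = lg(th1)
        p1 = p1 + 0.5 * direction * eps * g1
        return th1, p1, g1, lp1

    def uturn(th_plus, th_minus, p_plus, p_minus):
        dtheta = th_plus - th_minus
        return (
            float(dtheta @ (m_inv * p_minus)) < 0
            or float(dtheta @ (m_inv * p_plus)) < 0
        )

    def build(th, p, g, h0, direction, depth):
        tree = _Tree()
        if depth == 0:
            th1, p1, g1, lp1 = leapfrog(th, p, g, direction)
            h1 = lp1 - 0.5 * float(p1 * m_inv @ p1)
            log_w = h1 - h0
            if not np.isfinite(log_w):
                log_w = -np.inf
            tree.divergent = log_w < -_MAX_ENERGY_ERROR
            tree.turning = False
            tree.theta_minus = tree.theta_plus = tree.theta_prop = th1
            tree.p_minus = tree.p_plus = p1
            tree.g_minus = tree.g_plus = tree.g_prop = g1
            tree.logp_prop = lp1
            tree.log_weight = log_w
            tree.accept_sum = min(1.0, float(np.exp(min(log_w, 0.0))))
            tree.n_states = 1
            return tree
        first = build(th, p, g, h0, direction, depth - 1)
        if first.divergent or first.turning:
            return first
        if direction > 0:
            second = build(first.theta_plus, first.p_plus, first.g_plus, h0, direction, depth - 1)
            first.theta_plus, first.p_plus, first.g_plus = (
                second.theta_plus, second.p_plus, second.g_plus,
            )
        else:
            second = build(first.theta_minus, first.p_minus, first.g_minus, h0, direction, depth - 1)
            first.theta_minus, first.p_minus, first.g_minus = (
                second.theta_minus, second.p_minus, second.g_minus,
            )
        first.accept_sum += second.accept_sum
        first.n_states += second.n_states
        first.divergent = second.divergent
        first.turning = second.turning
        if first.divergent or first.turning:
            return first
        total = np.logaddexp(first.log_weight, second.log_weight)
        if np.isfinite(second.log_weight) and np.log(rng.random()) < second.log_weight - total:
            first.theta_prop = second.theta_prop
            first.g_prop = second.g_prop
            first.logp_prop = second.logp_prop
        first.log_weight = total
        first.turning = uturn(first.theta_plus, first.theta_minus, first.p_plus, first.p_minus)
        return first

    total_iters = n_warmup + n_draws
    for it in range(total_iters):
        p0 = rng.standard_normal(dim) / np.sqrt(m_inv)
        h0 = logp - 0.5 * float(p0 * m_inv @ p0)
        th_minus = th_plus = theta
        p_minus = p_plus = p0
        g_minus = g_plus = grad
        theta_prop, g_prop, logp_prop = theta, grad, logp
        log_weight = 0.0
        accept_sum, n_states = 0.0, 0
        divergent = False
        depth = 0
        while True:
            direction = 1.0 if rng.random() < 0.5 else -1.0
            if direction > 0:
                sub = build(th_plus, p_plus, g_plus, h0, direction, depth)
            else:
                sub = build(th_minus, p_minus, g_minus, h0, direction, depth)
            accept_sum += sub.accept_sum
            n_states += sub.n_states
            if sub.divergent:
                divergent = True
                break
            if direction > 0:
                th_plus, p_plus, g_plus = sub.theta_plus, sub.p_plus, sub.g_plus
            else:
                th_minus, p_minus, g_minus = sub.theta_minus, sub.p_minus, sub.g_minus
            if sub.turning:
                break
            total = np.logaddexp(log_weight, sub.log_weight)
            if np.isfinite(sub.log_weight) and np.log(rng.random()) < sub.log_weight - total:
                theta_prop, g_prop, logp_prop = sub.theta_prop, sub.g_prop, sub.logp_prop
            log_weight = total
            if uturn(th_plus, th_minus, p_plus, p_minus):
                break
            depth += 1
            if depth >= max_depth:
                stats.max_depth_hits += 1
                break

        theta, grad, logp = theta_prop, g_prop, logp_prop
        accept_stat = accept_sum / max(n_states, 1)

        if it < n_warmup:
            eps = da.update(accept_stat)
            if w_init <= it < w_term:
                window.append(theta.copy())
            if it + 1 in window_ends and len(window) >= 10:
                var = np.var(np.asarray(window), axis=0, ddof=1)
                n = len(window)
                m_inv = (n / (n + 5.0)) * var + 1e-3 * (5.0 / (n + 5.0))
                m_inv = np.maximum(m_inv, 1e-10)
                da.restart(float(np.exp(da.log_eps)))
                window = []
            if it + 1 == n_warmup:
                eps = float(np.exp(da.log_eps_bar))
        else:
            if divergent:
                stats.divergences += 1
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = logp
            accepts.append(accept_stat)

    stats.mean_accept = float(np.mean(accepts)) if accepts else float("nan")
    stats.step_size = float(eps)
    stats.n_gradient_evals = n_evals
    return draws, logps, stats


def random_walk_metropolis(
    logp,
    theta0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    blocks: list[np.ndarray] | None = None,
):
    """Adaptive Gaussian random-walk Metropolis (within Gibbs over blocks)."""
    theta = np.asarray(theta0, dtype=float).copy()
    dim = len(theta)
    if blocks is None:
        blocks = [np.arange(dim)]
    scales = [2.38 / np.sqrt(len(b)) * 0.1 for b in blocks]
    lp = logp(theta)
    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    acc = np.zeros(len(blocks))
    stats = SamplerStats()
    for it in range(n_warmup + n_draws):
        for bi, b in enumerate(blocks):
            prop = theta.copy()
            prop[b] = prop[b] + scales[bi] * rng.standard_normal(len(b))
            lp_prop = logp(prop)
            accepted = float(np.log(rng.random()) < lp_prop - lp)
            if accepted:
                theta, lp = prop, lp_prop
            if it < n_warmup:
                # Robbins-Monro toward the multivariate-optimal 0.234 rate
                scales[bi] *= float(np.exp((accepted - 0.234) / np.sqrt(1.0 + it)))
            else:
                acc[bi] += accepted
        if it >= n_warmup:
            draws[it - n_warmup] = theta
            logps[it - n_warmup] = lp
    stats.mean_accept = float(np.mean(acc / max(n_draws, 1)))
    stats.step_size = float(np.mean(scales))
    return draws, logps, stats
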