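"""Pareto-smoothed importance-sampling leave-one-out cross-validation.

Out-of-sample predictive accuracy (elpd) is estimated per trial by
self-normalized importance sampling, with the largest importance ratios
replaced by expected order statistics of a generalized Pareto distribution
fitted to the tail.  The tail shape estimate k doubles as a reliability
diagnostic: values above 0.7 flag trials whose leave-one-out estimate
cannot be trusted.  LOOIC is -2 x elpd on the deviance scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .fitting import PosteriorFit
from .models import bernoulli_probit_loglik, design_arrays

#: tail-shape value above which a pointwise estimate is flagged unreliable
K_WARN = 0.7


@dataclass
class LooResult:
    elpd_loo: float
    se_elpd: float
    looic: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray
    label: str | None = None

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > K_WARN))

    @property
    def flagged_trials(self) -> np.ndarray:
        return np.flatnonzero(self.pareto_k > K_WARN)


def gpd_fit(excesses: np.ndarray, method: str = "profile") -> tuple[float, float]:
    """Fit a generalized Pareto (shape k, scale sigma) to tail excesses.

    ``profile`` is the quantile/profile-likelihood estimator with a weak
    prior pulling k toward 1/2; ``moments`` is a method-of-moments
    fallback (valid for k < 1/2).
    """
    x = np.sort(np.asarray(excesses, dtype=float))
    n = len(x)
    if n < 5 or x[-1] <= 0:
        raise ValueError("need at least 5 positive excesses")
    if method == "moments":
        m1, s2 = x.mean(), x.var(ddof=1)
        k = 0.5 * (1.0 - m1 * m1 / s2)
        sigma = m1 * (1.0 - k)
        return float(k), float(sigma)
    m = 30 + int(np.sqrt(n))
    j = np.arange(1, m + 1)
    xq = x[int(n / 4.0 + 0.5) - 1]
    # candidate values of b = -k/sigma; profile likelihood over the grid
    b = 1.0 / x[-1] + (1.0 - np.sqrt(m / (j - 0.5))) / (3.0 * xq)
    k_b = np.mean(np.log1p(-b[:, None] * x[None, :]), axis=1)
    profile = n * (np.log(-b / k_b) - k_b - 1.0)
    weights = 1.0 / np.exp(profile - profile[:, None]).sum(axis=1)
    b_post = float(np.sum(b * weights) / np.sum(weights))
    k = float(np.mean(np.log1p(-b_post * x)))
    sigma = float(-k / b_post)
    # weak prior regularization toward k = 1/2 (stabilizes small tails)
    k = k * n / (n + 10.0) + 0.5 * 10.0 / (n + 10.0)
    return k, sigma


def _gpd_quantile(p: np.ndarray, k: float, sigma: float) -> np.ndarray:
    if abs(k) < 1e-12:
        return -sigma * np.log1p(-p)
    return sigma / k * (np.power(1.0 - p, -k) - 1.0)


def psis_smooth(log_ratios: np.ndarray, tail_fraction: float = 0.2):
    """Smooth one trial's importance ratios; returns (log weights, k).

    The tail is the smaller of ``tail_fraction * S`` and ``3 * sqrt(S)``
    largest ratios; tail values are replaced by expected order statistics
    of the fitted generalized Pareto, weights are capped at the largest
    raw ratio, and the returned log weights are normalized to sum to one.
    Constant ratios carry no information about the tail: they are returned
    uniform with the sentinel k = -inf.
    """
    lr = np.asarray(log_ratios, dtype=float)
    s = len(lr)
    if s < 100:
        raise ValueError("need at least 100 draws for PSIS")
    lr = lr - lr.max()
    if np.ptp(lr) < 1e-14:
        return np.full(s, -np.log(s)), -np.inf
    m = int(min(np.ceil(tail_fraction * s), np.ceil(3.0 * np.sqrt(s))))
    order = np.argsort(lr)
    tail_idx = order[s - m :]
    cutoff = np.exp(lr[order[s - m - 1]])
    excess = np.exp(lr[tail_idx]) - cutoff
    smoothed = lr.copy()
    if np.ptp(excess) > 0 and m >= 5:
        try:
            k, sigma = gpd_fit(excess)
        except ValueError:
            k, sigma = np.inf, np.nan
        if np.isfinite(k) and sigma > 0:
            p = (np.arange(1, m + 1) - 0.5) / m
            quantiles = cutoff + _gpd_quantile(p, k, sigma)
            smoothed[tail_idx] = np.log(quantiles)
    else:
        k = -np.inf
    smoothed = np.minimum(smoothed, 0.0)  # cap at the largest raw ratio
    smoothed = smoothed - logsumexp(smoothed)
    return smoothed, float(k)


def pointwise_loglik(
    fit: PosteriorFit, trials: pd.DataFrame, chunk: int = 200
) -> np.ndarray:
    """S x N matrix of per-draw, per-trial log-likelihoods."""
    x, y, pidx, sidx, participants, stimuli = design_arrays(fit.model, trials)
    if not np.array_equal(participants, fit.participants) or not np.array_equal(
        stimuli, fit.stimuli
    ):
        raise ValueError("trials do not match the units the model was fitted on")
    beta = fit.stacked("beta")  # (S, K)
    s_total = beta.shape[0]
    out = np.empty((s_total, len(y)))
    has_re = "participant_effects" in fit.draws
    if has_re:
        effects = fit.stacked("participant_effects")  # (S, P, K)
        stim = fit.stacked("stimulus_intercepts")  # (S, n_stim)
    for start in range(0, s_total, chunk):
        sl = slice(start, min(start + chunk, s_total))
        eta = beta[sl] @ x.T
        if has_re:
            eta = eta + np.einsum("nk,cnk->cn", x, effects[sl][:, pidx, :])
            eta = eta + stim[sl][:, sidx]
        out[sl] = bernoulli_probit_loglik(eta, y[None, :])
    return out


def loo(loglik: np.ndarray, label: str | None = None) -> LooResult:
    """PSIS-LOO from an S x N log-likelihood matrix."""
    loglik = np.asarray(loglik, dtype=float)
    if not np.all(np.isfinite(loglik)):
        raise ValueError("log-likelihood matrix must be finite")
    s, n = loglik.shape
    pointwise = np.empty(n)
    ks = np.empty(n)
    for i in range(n):
        logw, k = psis_smooth(-loglik[:, i])
        pointwise[i] = logsumexp(logw + loglik[:, i])
        ks[i] = k
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * np.var(pointwise))) if n > 1 else 0.0
    return LooResult(
        elpd_loo=elpd,
        se_elpd=se,
        looic=-2.0 * elpd,
        pointwise_elpd=pointwise,
        pareto_k=ks,
        label=label,
    )


def exact_loo_elpd(loglik_without, loglik_at) -> float:
    """Exact leave-one-out elpd for one trial from a refitted posterior.

    Given draws from p(theta | y_{-i}) this is log E[p(y_i | theta)]; used
    as the refit oracle that PSIS approximates.
    """
    ll = np.asarray(loglik_at, dtype=float)
    return float(logsumexp(ll) - np.log(len(ll)))


def compare(results: dict | list) -> pd.DataFrame:
    """Rank models by LOOIC with pairwise difference standard errors.

    Accepts a dict label -> LooResult or a list of labelled results.
    Differences in elpd (to the best model) use the pointwise pairing, so
    any additive constant shared across models cancels.
    """
    if isinstance(results, dict):
        items = [(str(k), v) for k, v in results.items()]
    else:
        items = [(r.label or str(i), r) for i, r in enumerate(results)]
    if len(items) < 2:
        raise ValueError("need at least two models to compare")
    n = len(items[0][1].pointwise_elpd)
    for _, r in items:
        if len(r.pointwise_elpd) != n:
            raise ValueError("models were evaluated on different numbers of trials")
    best_label, best = max(items, key=lambda kv: kv[1].elpd_loo)
    rows = []
    for label, r in items:
        diff = best.pointwise_elpd - r.pointwise_elpd
        rows.append(
            {
                "model": label,
                "looic": r.looic,
                "elpd_loo": r.elpd_loo,
                "se_elpd": r.se_elpd,
                "elpd_diff": float(diff.sum()),
                "se_diff": float(np.sqrt(n * np.var(diff))) if label != best_label else 0.0,
                "n_high_k": r.n_high_k,
            }
        )
    table = pd.DataFrame(rows).sort_values("looic", ignore_index=True)
    return table


def write_comparison(table: pd.DataFrame, path) -> None:
    table[["model", "looic", "elpd_diff", "se_diff", "n_high_k"]].to_csv(
        path, index=False
    )
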