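"""Posterior sampling of the multilevel probit models, with diagnostics.

``fit`` runs the in-package NUTS sampler (or the random-walk Metropolis
fallback) on the unconstrained posterior, transforms the chains back to
the constrained scale, and attaches a diagnostics report: divergence
counts, split-Rhat and effective sample sizes (via arviz), and a
prior-vs-posterior learning check comparing interquartile ranges.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .models import DataError, FitConfig, ModelSpec, PriorSpec
from .posterior import ProbitPosterior
from .samplers import SamplerStats, nuts, random_walk_metropolis
from .coding import term_columns


@dataclass
class DiagnosticsReport:
    n_divergences: int
    rhat: dict[str, float]
    effective_samples: dict[str, float]
    prior_posterior_overlap: dict[str, dict[str, float]]
    sampler: list[SamplerStats] = field(default_factory=list)

    RHAT_BOUNDS = (0.99, 1.01)
    MIN_ESS = 200

    def flags(self) -> dict[str, bool]:
        lo, hi = self.RHAT_BOUNDS
        finite_rhat = {k: v for k, v in self.rhat.items() if np.isfinite(v)}
        return {
            "no_divergences": self.n_divergences == 0,
            "rhat_ok": all(lo <= v <= hi for v in finite_rhat.values()),
            "ess_ok": all(
                v > self.MIN_ESS for v in self.effective_samples.values() if np.isfinite(v)
            ),
            "learned_from_data": all(
                d["posterior_iqr"] < d["prior_iqr"]
                for d in self.prior_posterior_overlap.values()
            ),
        }

    def passed(self) -> bool:
        return all(self.flags().values())

    def to_dict(self) -> dict:
        return {
            "n_divergences": self.n_divergences,
            "rhat": self.rhat,
            "effective_samples": self.effective_samples,
            "prior_posterior_overlap": self.prior_posterior_overlap,
            "flags": self.flags(),
        }


@dataclass
class PosteriorFit:
    """Named posterior draws for one model, plus sampler diagnostics.

    Draw arrays are keyed ``beta`` (chains, draws, K), ``sd_participant``
    (chains, draws, K), ``corr_participant`` (chains, draws, K, K),
    ``participant_effects`` (chains, draws, P, K), ``sd_stimulus`` and
    ``stimulus_intercepts``; scalar views use the naming convention
    ``b_<term>``, ``sd_participant__<term>``,
    ``cor_participant__<term1>__<term2>`` and ``sd_stimulus__intercept``.
    """

    model: ModelSpec
    draws: dict[str, np.ndarray]
    diagnostics: DiagnosticsReport
    participants: np.ndarray
    stimuli: np.ndarray
    priors: PriorSpec
    config: FitConfig

    @property
    def n_chains(self) -> int:
        return self.draws["beta"].shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws["beta"].shape[1]

    def stacked(self, key: str) -> np.ndarray:
        """Draw array with chains flattened into one leading axis."""
        a = self.draws[key]
        return a.reshape(-1, *a.shape[2:])

    def scalar_draws(self) -> dict[str, np.ndarray]:
        """Flat named scalar parameters, chains stacked."""
        terms = self.model.fixed_terms
        out: dict[str, np.ndarray] = {}
        beta = self.stacked("beta")
        for i, t in enumerate(terms):
            out[f"b_{t}"] = beta[:, i]
        if "sd_participant" in self.draws:
            sd = self.stacked("sd_participant")
            for i, t in enumerate(terms):
                out[f"sd_participant__{t}"] = sd[:, i]
            corr = self.stacked("corr_participant")
            for i in range(1, len(terms)):
                for j in range(i):
                    out[f"cor_participant__{terms[j]}__{terms[i]}"] = corr[:, i, j]
            out["sd_stimulus__intercept"] = self.stacked("sd_stimulus")
        return out

    def beta_draws(self, term: str) -> np.ndarray:
        return self.stacked("beta")[:, self.model.fixed_terms.index(term)]

    def to_inference_data(self):
        import arviz as az

        c, d = self.n_chains, self.n_draws
        flat = self.scalar_draws()
        return az.from_dict({k: v.reshape(c, d) for k, v in flat.items()})

    def save(self, directory) -> None:
        """Draws table as CSV plus a JSON diagnostics sidecar."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        flat = self.scalar_draws()
        c, d = self.n_chains, self.n_draws
        table = pd.DataFrame(flat)
        table.insert(0, "chain", np.repeat(np.arange(c), d))
        table.insert(1, "draw", np.tile(np.arange(d), c))
        table.to_csv(directory / "draws.csv", index=False)
        with open(directory / "diagnostics.json", "w") as fh:
            json.dump(self.diagnostics.to_dict(), fh, indent=2)


def _constrained_chains(post: ProbitPosterior, chains: list[np.ndarray]) -> dict[str, np.ndarray]:
    c = len(chains)
    d, _ = chains[0].shape
    k, p, s = post.k, post.n_participants, post.n_stimuli
    out = {"beta": np.empty((c, d, k))}
    if post.random_effects:
        out.update(
            sd_participant=np.empty((c, d, k)),
            corr_participant=np.empty((c, d, k, k)),
            participant_effects=np.empty((c, d, p, k)),
            sd_stimulus=np.empty((c, d)),
            stimulus_intercepts=np.empty((c, d, s)),
        )
    for ci, chain in enumerate(chains):
        for di in range(d):
            u = post.unpack(chain[di])
            out["beta"][ci, di] = u["beta"]
            if post.random_effects:
                out["sd_participant"][ci, di] = u["sd_participant"]
                out["corr_participant"][ci, di] = u["corr"]
                out["participant_effects"][ci, di] = u["participant_effects"]
                out["sd_stimulus"][ci, di] = u["sd_stimulus"]
                out["stimulus_intercepts"][ci, di] = u["stimulus_intercepts"]
    return out


def _diagnose(
    draws: dict[str, np.ndarray],
    stats: list[SamplerStats],
    model: ModelSpec,
    priors: PriorSpec,
) -> DiagnosticsReport:
    import arviz as az

    terms = model.fixed_terms
    scalars = {f"b_{t}": draws["beta"][:, :, i] for i, t in enumerate(terms)}
    if "sd_participant" in draws:
        for i, t in enumerate(terms):
            scalars[f"sd_participant__{t}"] = draws["sd_participant"][:, :, i]
        scalars["sd_stimulus__intercept"] = draws["sd_stimulus"]
    idata = az.from_dict(scalars)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat_ds = az.rhat(idata)
        ess_ds = az.ess(idata)
    rhat = {k: float(rhat_ds[k].values) for k in scalars}
    ess = {k: float(ess_ds[k].values) for k in scalars}

    overlap = {}
    scales = priors.beta_scales(terms)
    prior_iqr = 2.0 * 0.6744897501960817 * scales  # IQR of a centred normal
    for i, t in enumerate(terms):
        q75, q25 = np.percentile(draws["beta"][:, :, i], [75, 25])
        overlap[f"b_{t}"] = {
            "prior_iqr": float(prior_iqr[i]),
            "posterior_iqr": float(q75 - q25),
            "shrinkage": float(1.0 - (q75 - q25) / prior_iqr[i]),
        }
    return DiagnosticsReport(
        n_divergences=int(sum(s.divergences for s in stats)),
        rhat=rhat,
        effective_samples=ess,
        prior_posterior_overlap=overlap,
        sampler=stats,
    )


def fit(
    model: ModelSpec,
    trials: pd.DataFrame,
    priors: PriorSpec | None = None,
    config: FitConfig | None = None,
    random_effects: bool = True,
) -> PosteriorFit:
    """Sample the posterior of one model on a trial table.

    ``random_effects=False`` fits the complete-pooling variant (fixed
    effects only), the regime in which Model 1's familiarity coefficient is
    the classical equal-variance d' = z(hit) - z(false alarm).
    """
    priors = priors or PriorSpec()
    config = config or FitConfig()
    post = ProbitPosterior(model, trials, priors, random_effects=random_effects)
    n_warmup = config.n_warmup
    n_keep = config.n_iterations - n_warmup
    if n_keep < 1:
        raise ValueError("no post-warmup iterations")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains, stats = [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        theta0 = post.initial(rng)
        if config.sampler == "nuts":
            draws, _, st = nuts(
                post.logp_grad,
                theta0,
                n_warmup,
                n_keep,
                rng,
                target_accept=config.target_accept,
                max_depth=config.max_trajectory_depth,
            )
        else:
            draws, _, st = random_walk_metropolis(
                post.logp, theta0, n_warmup, n_keep, rng
            )
        chains.append(draws)
        stats.append(st)

    draw_arrays = _constrained_chains(post, chains)
    report = _diagnose(draw_arrays, stats, model, priors)
    if report.n_divergences > 0:
        warnings.warn(
            f"{report.n_divergences} divergent transitions; "
            "inspect diagnostics before trusting the posterior",
            RuntimeWarning,
            stacklevel=2,
        )
    return PosteriorFit(
        model=model,
        draws=draw_arrays,
        diagnostics=report,
        participants=post.participants,
        stimuli=post.stimuli,
        priors=priors,
        config=config,
    )


def check_diagnostics(fit_result: PosteriorFit) -> dict:
    """Apply the four quality criteria; always returns a report, never raises."""
    rep = fit_result.diagnostics
    return {"flags": rep.flags(), "passed": rep.passed(), "report": rep.to_dict()}


@dataclass
class PriorPredictiveSummary:
    """Distribution of the simulated overall "friends" rate per prior scale."""

    rates: dict[float, np.ndarray]
    extreme_bounds: tuple[float, float]

    @property
    def p_extreme(self) -> dict[float, float]:
        lo, hi = self.extreme_bounds
        return {
            sd: float(np.mean((r < lo) | (r > hi))) for sd, r in self.rates.items()
        }

    def as_frame(self) -> pd.DataFrame:
        pe = self.p_extreme
        return pd.DataFrame(
            {
                "prior_sd": list(self.rates),
                "rate_mean": [float(np.mean(r)) for r in self.rates.values()],
                "rate_sd": [float(np.std(r)) for r in self.rates.values()],
                "p_extreme": [pe[sd] for sd in self.rates],
            }
        )


def prior_predictive(
    model: ModelSpec,
    priors: PriorSpec,
    design: pd.DataFrame,
    n_draws: int = 2000,
    sd_grid: tuple[float, ...] = (1.0, 0.5, 0.3, 0.1),
    extreme_bounds: tuple[float, float] = (0.05, 0.95),
    include_random_effects: bool = False,
    seed: int = 0,
) -> PriorPredictiveSummary:
    """Prior-predictive screening of candidate fixed-effect prior scales.

    For each scale in the grid, the whole fixed-effect vector is drawn from
    a zero-mean normal at that scale and responses are simulated over the
    design; the summary records the distribution of the overall "friends"
    rate and the probability it falls outside ``extreme_bounds``.  With
    ``include_random_effects`` the half-normal scale priors contribute
    marginalized unit-level variance via the probit-normal identity
    Phi(eta / sqrt(1 + v)).
    """
    if len(sd_grid) == 0:
        raise ValueError("empty prior-scale grid")
    if n_draws < 100:
        raise ValueError("need at least 100 prior draws")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    x = term_columns(design, model.fixed_terms)
    cells, counts = np.unique(x, axis=0, return_counts=True)
    n_total = counts.sum()
    k = model.n_terms
    rates: dict[float, np.ndarray] = {}
    for sd in sd_grid:
        betas = sd * rng.standard_normal((n_draws, k))
        eta = betas @ cells.T
        if include_random_effects:
            tau = priors.re_sd_scale
            sd_p = np.abs(tau * rng.standard_normal((n_draws, k)))
            sd_s = np.abs(tau * rng.standard_normal((n_draws, 1)))
            v = (cells[None, :, :] ** 2 * sd_p[:, None, :] ** 2).sum(-1) + sd_s**2
            eta = eta / np.sqrt(1.0 + v)
        p = ndtr(eta)
        successes = rng.binomial(counts[None, :], p)
        rates[sd] = successes.sum(axis=1) / n_total
    return PriorPredictiveSummary(rates=rates, extreme_bounds=extreme_bounds)
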