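"""Model specifications, priors and the Bernoulli-probit likelihood.

Five nested multilevel probit models are considered:

* Model 0 — intercept (criterion) only;
* Model 1 — adds familiarity (sensitivity / d');
* Model 2 — adds talk (colaughter vs cospeech) and familiarity:talk;
* Model 3 — intercept, familiarity, speed, familiarity:speed (no talk terms);
* Model 4 — all 8 terms including the three-way interaction.

Every fixed term also varies by participant (correlated random slopes) and
the intercept varies by stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import log_ndtr

from .coding import TERMS, term_columns

_MODEL_TERMS = {
    0: ("intercept",),
    1: ("intercept", "familiarity"),
    2: ("intercept", "familiarity", "talk", "familiarity:talk"),
    3: ("intercept", "familiarity", "speed", "familiarity:speed"),
    4: TERMS,
}


class DataError(ValueError):
    """Raised for trial data unusable by a model (bad coding, degenerate)."""


@dataclass(frozen=True)
class ModelSpec:
    level: int
    fixed_terms: tuple[str, ...]
    participant_varying: tuple[str, ...]
    stimulus_varying: tuple[str, ...] = ("intercept",)

    @property
    def n_terms(self) -> int:
        return len(self.fixed_terms)


def make_model(level: int) -> ModelSpec:
    """Model spec for one of the five nested levels (0-4)."""
    if level not in _MODEL_TERMS:
        raise ValueError(f"unknown model level {level!r}; expected 0-4")
    terms = tuple(_MODEL_TERMS[level])
    return ModelSpec(level=level, fixed_terms=terms, participant_varying=terms)


@dataclass
class PriorSpec:
    """Weakly regularizing priors.

    ``fixed_effect_sd`` is the zero-mean normal prior scale on manipulation
    effects (0.3 after prior-predictive screening over {1, 0.5, 0.3, 0.1});
    the intercept gets its own, wider scale.  Random-effect sds are
    half-normal(``re_sd_scale``); the participant correlation matrix has an
    LKJ prior with the given concentration.
    """

    fixed_effect_sd: float = 0.3
    intercept_sd: float = 1.0
    re_sd_scale: float = 0.3
    corr_concentration: float = 2.0

    def __post_init__(self) -> None:
        for name in ("fixed_effect_sd", "intercept_sd", "re_sd_scale", "corr_concentration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def beta_scales(self, terms) -> np.ndarray:
        return np.array(
            [self.intercept_sd if t == "intercept" else self.fixed_effect_sd for t in terms]
        )


@dataclass
class FitConfig:
    """Sampler configuration; defaults mirror the original analysis."""

    n_chains: int = 2
    n_iterations: int = 3000
    target_accept: float = 0.99
    max_trajectory_depth: int = 20
    seed: int = 0
    warmup_fraction: float = 0.5
    sampler: str = "nuts"  # "nuts" or "rwm" fallback

    def __post_init__(self) -> None:
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")
        if not 0 < self.warmup_fraction < 1:
            raise ValueError("warmup_fraction must be in (0, 1)")
        if self.sampler not in ("nuts", "rwm"):
            raise ValueError("sampler must be 'nuts' or 'rwm'")

    @property
    def n_warmup(self) -> int:
        return int(round(self.n_iterations * self.warmup_fraction))


#: reduced-scale profile used for fast end-to-end runs and simulation studies
REDUCED_FIT = dict(n_chains=2, n_iterations=600, target_accept=0.9, max_trajectory_depth=10)


def design_arrays(model: ModelSpec, trials: pd.DataFrame):
    """(X, y, participant_index, stimulus_index, participants, stimuli)."""
    y = trials["response"].to_numpy()
    if not np.isin(y, (0, 1)).all():
        raise DataError("response must be coded 0/1")
    x = term_columns(trials, model.fixed_terms)
    participants = np.unique(trials["participant_id"].to_numpy())
    stimuli = np.unique(trials["stimulus_id"].to_numpy())
    pidx = pd.Categorical(trials["participant_id"], categories=participants).codes
    sidx = pd.Categorical(trials["stimulus_id"], categories=stimuli).codes
    return x, y.astype(float), np.asarray(pidx), np.asarray(sidx), participants, stimuli


def bernoulli_probit_loglik(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-trial log-likelihood y*log Phi(eta) + (1-y)*log Phi(-eta).

    Uses the stable normal log-CDF, finite for |eta| well beyond 30.
    """
    return y * log_ndtr(eta) + (1.0 - y) * log_ndtr(-eta)


def log_likelihood(model: ModelSpec, point: dict, trials: pd.DataFrame) -> np.ndarray:
    """Per-trial log-likelihood at one parameter point.

    ``point`` maps ``beta`` (length n_terms) and optionally
    ``participant_effects`` (P x n_terms) and ``stimulus_intercepts`` (S,)
    to values; omitted unit effects are zero.
    """
    x, y, pidx, sidx, participants, stimuli = design_arrays(model, trials)
    beta = np.asarray(point["beta"], dtype=float)
    if beta.shape != (model.n_terms,):
        raise DataError(
            f"beta has shape {beta.shape}, model needs ({model.n_terms},)"
        )
    eta = x @ beta
    u = point.get("participant_effects")
    if u is not None:
        u = np.asarray(u, dtype=float)
        if u.shape != (len(participants), model.n_terms):
            raise DataError("participant_effects must be P x n_terms")
        eta = eta + np.einsum("nk,nk->n", x, u[pidx])
    s = point.get("stimulus_intercepts")
    if s is not None:
        s = np.asarray(s, dtype=float)
        if s.shape != (len(stimuli),):
            raise DataError("stimulus_intercepts must have one entry per stimulus")
        eta = eta + s[sidx]
    return bernoulli_probit_loglik(eta, y)
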