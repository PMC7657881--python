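"""Generative probit simulator for trial-level affiliation judgements.

Responses are drawn from the same multilevel probit model the analysis
fits: a trial's linear predictor is the fixed-effect vector plus the
participant's (correlated, multivariate-normal) deviation vector, dotted
with the trial's design codes, plus a normal per-stimulus intercept; the
response is Bernoulli with probability Phi(eta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .coding import TERMS, term_columns
from .design import validate_trials
from .study import betas_from_condition_z


class ParameterError(ValueError):
    """Raised for invalid generative parameters."""


def _default_beta() -> np.ndarray:
    return betas_from_condition_z()


def _default_participant_sd() -> np.ndarray:
    # main effects vary more across listeners than higher-order interactions
    return np.array([0.3, 0.3, 0.15, 0.15, 0.1, 0.1, 0.1, 0.1])


@dataclass
class GenerativeParams:
    """Ground-truth parameters of the simulator.

    ``beta`` is ordered as :data:`vocalsdt.coding.TERMS`.  The participant
    deviation vectors are multivariate normal with covariance
    ``diag(participant_sd) @ participant_corr @ diag(participant_sd)``;
    stimulus intercepts are normal with sd ``stimulus_sd`` and are shared
    between the two speed versions of a clip (stimulus = clip).
    """

    beta: np.ndarray = field(default_factory=_default_beta)
    participant_sd: np.ndarray = field(default_factory=_default_participant_sd)
    participant_corr: np.ndarray | None = None
    stimulus_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.participant_sd = np.asarray(self.participant_sd, dtype=float)
        k = len(self.beta)
        if self.participant_sd.shape != (k,):
            raise ParameterError("participant_sd must match beta length")
        if (self.participant_sd < 0).any() or self.stimulus_sd < 0:
            raise ParameterError("standard deviations must be non-negative")
        if self.participant_corr is None:
            self.participant_corr = np.eye(k)
        self.participant_corr = np.asarray(self.participant_corr, dtype=float)
        c = self.participant_corr
        if c.shape != (k, k):
            raise ParameterError("participant_corr must be k x k")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ParameterError("participant_corr must be symmetric with unit diagonal")
        eig = np.linalg.eigvalsh(c)
        if eig.min() < -1e-10:
            raise ParameterError("participant_corr must be positive semi-definite")

    @property
    def covariance(self) -> np.ndarray:
        d = np.diag(self.participant_sd)
        return d @ self.participant_corr @ d

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "participant_sd": self.participant_sd.tolist(),
            "participant_corr": self.participant_corr.tolist(),
            "stimulus_sd": float(self.stimulus_sd),
            "seed": int(self.seed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerativeParams":
        d = dict(d)
        if d.get("participant_corr") is not None:
            d["participant_corr"] = np.asarray(d["participant_corr"])
        return cls(
            beta=np.asarray(d["beta"]),
            participant_sd=np.asarray(d["participant_sd"]),
            participant_corr=d.get("participant_corr"),
            stimulus_sd=d.get("stimulus_sd", 0.0),
            seed=d.get("seed", 0),
        )


def linear_predictor(
    trials: pd.DataFrame,
    params: GenerativeParams,
    participant_effects: np.ndarray,
    stimulus_intercepts: np.ndarray,
    participant_index: np.ndarray,
    stimulus_index: np.ndarray,
) -> np.ndarray:
    x = term_columns(trials, TERMS[: len(params.beta)])
    eta = x @ params.beta
    eta += np.einsum("nk,nk->n", x, participant_effects[participant_index])
    eta += stimulus_intercepts[stimulus_index]
    return eta


def simulate_responses(
    design: pd.DataFrame,
    params: GenerativeParams,
    liking: bool = False,
) -> pd.DataFrame:
    """Attach simulated binary responses (and optional liking ratings).

    Reproducible: the same design, parameters and seed give a byte-identical
    table.  Liking ratings, when requested, are a monotone map of Phi(eta)
    plus noise onto the 1-7 scale; they exist for I/O testing only and are
    never modelled.
    """
    validate_trials(design)
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))

    participants = np.unique(design["participant_id"].to_numpy())
    stimuli = np.unique(design["stimulus_id"].to_numpy())
    pidx = pd.Categorical(design["participant_id"], categories=participants).codes
    sidx = pd.Categorical(design["stimulus_id"], categories=stimuli).codes

    k = len(params.beta)
    chol = np.linalg.cholesky(
        params.covariance + 1e-12 * np.eye(k)
    )
    u = rng.standard_normal((len(participants), k)) @ chol.T
    s = params.stimulus_sd * rng.standard_normal(len(stimuli))

    eta = linear_predictor(design, params, u, s, pidx, sidx)
    p = ndtr(eta)
    out = design.copy()
    out["response"] = (rng.random(len(out)) < p).astype(int)
    if liking:
        noisy = np.clip(p + 0.15 * rng.standard_normal(len(out)), 0.0, 1.0)
        out["liking"] = 1 + np.floor(noisy * 6.999).astype(int)
    return out
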