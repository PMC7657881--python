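"""Signal-detection summaries of posterior draws.

Under the probit model, each mode x speed condition has a criterion (the
z-scale propensity to answer "friends" when the dyad is strangers — the
cell's intercept) and a sensitivity (d', the additional z-scale shift when
the dyad really is friends — the cell's familiarity effect).  Both are
linear combinations of the full model's fixed effects, so posterior draws
of any cell quantity or contrast between cells are exact by-products of
the fixed-effect draws.

Percent-scale views: criterion maps to the "friends" rate for stranger
stimuli, 100 * Phi(c); sensitivity maps to the percentage-point gain for
friend stimuli, 100 * (Phi(c + d) - Phi(c)).  Table-style reports apply
the transform at the posterior mean z (transform-of-mean); mean-of-
transform is also available and agrees within a point for moderate |z|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .coding import TERMS, cell_codes
from .fitting import PosteriorFit

CELLS = (
    ("cospeech", "original"),
    ("cospeech", "sped-up"),
    ("colaughter", "original"),
    ("colaughter", "sped-up"),
)


def cell_combination(mode: str, speed: str, quantity: str) -> np.ndarray:
    """Weight vector over the 8 fixed-effect terms for one cell quantity.

    ``criterion`` is the cell's linear predictor for stranger stimuli;
    ``sensitivity`` is the friends-minus-strangers difference, i.e. the
    familiarity terms active in the cell.
    """
    if (mode, speed) not in CELLS:
        raise ValueError(f"unknown cell ({mode!r}, {speed!r})")
    if quantity not in ("criterion", "sensitivity"):
        raise ValueError(f"unknown quantity {quantity!r}")
    strangers = cell_codes(mode, speed, "strangers")
    if quantity == "criterion":
        return strangers
    return cell_codes(mode, speed, "friends") - strangers


def z_to_percent(z: float) -> float:
    """Percent "friends" responses implied by a z-scale criterion: 100*Phi(z)."""
    return 100.0 * float(ndtr(z))


def sensitivity_to_percent(criterion_z: float, sensitivity_z: float) -> float:
    """Percentage-point response difference friends - strangers."""
    return 100.0 * float(ndtr(criterion_z + sensitivity_z) - ndtr(criterion_z))


@dataclass
class DrawSummary:
    mean: float
    ci_low: float
    ci_high: float
    credibility: float  # % of draws sharing the sign of the mean

    def round(self, nd: int = 2) -> tuple[float, float, float]:
        return (round(self.mean, nd), round(self.ci_low, nd), round(self.ci_high, nd))


def summarize_draws(draws: np.ndarray, interval: float = 0.95) -> DrawSummary:
    """Posterior mean, central credibility interval and credibility of sign.

    Credibility is the share of draws on the same side of zero as the mean
    (100 when every draw agrees in sign, following the convention of
    reporting "100% credibility").
    """
    draws = np.asarray(draws, dtype=float)
    if draws.size < 100:
        raise ValueError("need at least 100 draws to summarize")
    mean = float(draws.mean())
    alpha = (1.0 - interval) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    side = draws > 0 if mean > 0 else draws < 0
    return DrawSummary(
        mean=mean,
        ci_low=float(lo),
        ci_high=float(hi),
        credibility=100.0 * float(side.mean()),
    )


def _beta_matrix(fit: PosteriorFit) -> np.ndarray:
    """Fixed-effect draws embedded in the full 8-term space (absent terms 0)."""
    beta = fit.stacked("beta")
    full = np.zeros((beta.shape[0], len(TERMS)))
    for i, t in enumerate(fit.model.fixed_terms):
        full[:, TERMS.index(t)] = beta[:, i]
    return full


def cell_draws(fit: PosteriorFit, mode: str, speed: str, quantity: str) -> np.ndarray:
    """Per-draw values of one cell's criterion or sensitivity."""
    return _beta_matrix(fit) @ cell_combination(mode, speed, quantity)


def contrast(fit: PosteriorFit, weights: dict[tuple[str, str, str], float]) -> DrawSummary:
    """Posterior summary of a weighted combination of cell quantities.

    ``weights`` maps (mode, speed, quantity) to a coefficient, e.g.
    ``{("colaughter", "original", "sensitivity"): 1,
    ("cospeech", "original", "sensitivity"): -1}`` for the original-speed
    sensitivity difference between modes.
    """
    if not weights or all(w == 0 for w in weights.values()):
        raise ValueError("contrast weights are all zero")
    total = None
    for (mode, speed, quantity), w in weights.items():
        d = w * cell_draws(fit, mode, speed, quantity)
        total = d if total is None else total + d
    return summarize_draws(total)


@dataclass
class SDTSummary:
    mode: str
    speed: str
    criterion: DrawSummary
    sensitivity: DrawSummary

    @property
    def criterion_pct(self) -> float:
        return z_to_percent(self.criterion.mean)

    @property
    def sensitivity_pct(self) -> float:
        return sensitivity_to_percent(self.criterion.mean, self.sensitivity.mean)


def condition_summaries(fit: PosteriorFit) -> list[SDTSummary]:
    """Criterion and sensitivity summaries for all four conditions."""
    out = []
    for mode, speed in CELLS:
        out.append(
            SDTSummary(
                mode=mode,
                speed=speed,
                criterion=summarize_draws(cell_draws(fit, mode, speed, "criterion")),
                sensitivity=summarize_draws(cell_draws(fit, mode, speed, "sensitivity")),
            )
        )
    return out


def summary_table(
    fit: PosteriorFit, auc: dict[tuple[str, str], DrawSummary] | None = None
) -> pd.DataFrame:
    """Condition-level report: percent and z scales with 95% intervals.

    Mirrors the conventional SDT report layout: percent criterion and
    sensitivity are transform-of-posterior-mean values rounded for display
    elsewhere; unrounded values are kept here.
    """
    rows = []
    for s in condition_summaries(fit):
        row = {
            "condition": f"{s.mode} ({s.speed})",
            "criterion_pct": s.criterion_pct,
            "criterion_z": s.criterion.mean,
            "criterion_ci_low": s.criterion.ci_low,
            "criterion_ci_high": s.criterion.ci_high,
            "sensitivity_pct": s.sensitivity_pct,
            "sensitivity_z": s.sensitivity.mean,
            "sensitivity_ci_low": s.sensitivity.ci_low,
            "sensitivity_ci_high": s.sensitivity.ci_high,
        }
        if auc is not None and (s.mode, s.speed) in auc:
            a = auc[(s.mode, s.speed)]
            row.update(auc=a.mean, auc_ci_low=a.ci_low, auc_ci_high=a.ci_high)
        rows.append(row)
    return pd.DataFrame(rows)


def mean_of_transform_percent(fit: PosteriorFit, mode: str, speed: str) -> tuple[float, float]:
    """Alternative percent summaries: posterior mean of the transformed draws."""
    c = cell_draws(fit, mode, speed, "criterion")
    d = cell_draws(fit, mode, speed, "sensitivity")
    return (
        100.0 * float(ndtr(c).mean()),
        100.0 * float((ndtr(c + d) - ndtr(c)).mean()),
    )
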