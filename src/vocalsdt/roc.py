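"""ROC curves and AUC from posterior model predictions.

A trial's score is the model-implied probability that the clip came from
friends.  Sweeping a classification threshold over [0, 1] and computing,
at each threshold, the proportion of friend stimuli correctly called
"friends" (sensitivity) and stranger stimuli correctly called "strangers"
(specificity) traces the ROC; the area under it equals the probability
that a randomly chosen friend trial outscores a randomly chosen stranger
trial (ties count half), computed exactly by the rank-statistic identity.

Curves are conventionally plotted as TPR against FPR = 1 - specificity;
a specificity x-axis (strangers correctly identified) is offered as a
writer option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import rankdata

from .fitting import PosteriorFit
from .models import design_arrays


class SingleClassError(ValueError):
    pass


@dataclass
class ScoredTrials:
    scores: np.ndarray  # P(friends) per trial, in [0, 1]
    is_friend: np.ndarray  # true familiarity label
    mode: np.ndarray
    speed: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.is_friend = np.asarray(self.is_friend, dtype=bool)
        if self.scores.min() < 0 or self.scores.max() > 1:
            raise ValueError("scores must be probabilities in [0, 1]")

    def subset(self, mode: str | None = None, speed: str | None = None) -> "ScoredTrials":
        keep = np.ones(len(self.scores), dtype=bool)
        if mode is not None:
            keep &= self.mode == mode
        if speed is not None:
            keep &= self.speed == speed
        return ScoredTrials(
            self.scores[keep], self.is_friend[keep], self.mode[keep], self.speed[keep]
        )


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    auc_interval: tuple[float, float] | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.tpr,
                "specificity": 1.0 - self.fpr,
            }
        )


def _predict_eta(fit: PosteriorFit, trials: pd.DataFrame, marginalize: bool, chunk: int = 200):
    """Per-draw linear predictors (S, N); new units error unless marginalized."""
    x, _, pidx, sidx, participants, stimuli = design_arrays(fit.model, trials)
    units_match = np.array_equal(participants, fit.participants) and np.array_equal(
        stimuli, fit.stimuli
    )
    if not units_match and not marginalize:
        raise ValueError(
            "trials contain participants or stimuli the model was not fitted on; "
            "pass marginalize=True to integrate over new units"
        )
    beta = fit.stacked("beta")
    s_total = beta.shape[0]
    eta = np.empty((s_total, len(x)))
    has_re = "participant_effects" in fit.draws
    for start in range(0, s_total, chunk):
        sl = slice(start, min(start + chunk, s_total))
        e = beta[sl] @ x.T
        if has_re and units_match:
            effects = fit.stacked("participant_effects")[sl]
            e = e + np.einsum("nk,cnk->cn", x, effects[:, pidx, :])
            e = e + fit.stacked("stimulus_intercepts")[sl][:, sidx]
        eta[sl] = e
    if has_re and not units_match:
        # probit-normal marginalization over unseen participants/stimuli
        sd_p = fit.stacked("sd_participant")
        sd_s = fit.stacked("sd_stimulus")
        var = (x[None, :, :] ** 2 * sd_p[:, None, :] ** 2).sum(-1) + sd_s[:, None] ** 2
        eta = eta / np.sqrt(1.0 + var)
    return eta


def predict_probabilities(
    fit: PosteriorFit,
    trials: pd.DataFrame,
    mode: str = "posterior_mean",
    marginalize: bool = False,
):
    """Score trials with P(respond "friends").

    ``posterior_mean`` returns one :class:`ScoredTrials` (mean over draws
    of Phi(eta)); ``per_draw`` returns the (S, N) score matrix along with
    the labels, for draw-wise AUC intervals.
    """
    if mode not in ("posterior_mean", "per_draw"):
        raise ValueError("mode must be 'posterior_mean' or 'per_draw'")
    eta = _predict_eta(fit, trials, marginalize)
    p = ndtr(eta)
    labels = trials["familiarity"].to_numpy() == "friends"
    modes = trials["mode"].to_numpy()
    speeds = trials["speed"].to_numpy()
    if mode == "posterior_mean":
        return ScoredTrials(p.mean(axis=0), labels, modes, speeds)
    return p, labels, modes, speeds


def _check_two_classes(is_friend: np.ndarray) -> None:
    if is_friend.all():
        raise SingleClassError("no stranger trials in the subset")
    if not is_friend.any():
        raise SingleClassError("no friend trials in the subset")


def roc_points(scored: ScoredTrials, thresholds: np.ndarray | None = None) -> ROCCurve:
    """ROC by threshold sweep (score >= t classified as "friends")."""
    _check_two_classes(scored.is_friend)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 1001)
    thresholds = np.sort(np.asarray(thresholds, dtype=float))[::-1]
    pos = scored.scores[scored.is_friend]
    neg = scored.scores[~scored.is_friend]
    tpr = (pos[None, :] >= thresholds[:, None]).mean(axis=1)
    fpr = (neg[None, :] >= thresholds[:, None]).mean(axis=1)
    # force the curve endpoints
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    thresholds = np.concatenate([[np.inf], thresholds, [-np.inf]])
    area = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=area)


def auc_rank(scored: ScoredTrials) -> float:
    """AUC via the rank (Mann-Whitney) identity, ties counted half."""
    _check_two_classes(scored.is_friend)
    n_pos = int(scored.is_friend.sum())
    n_neg = len(scored.is_friend) - n_pos
    ranks = rankdata(scored.scores)
    r_pos = ranks[scored.is_friend].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_posterior(
    fit: PosteriorFit,
    trials: pd.DataFrame,
    mode: str | None = None,
    speed: str | None = None,
    marginalize: bool = False,
):
    """Draw-wise AUC within one condition cell: mean and 95% interval."""
    from .sdt import DrawSummary, summarize_draws

    p, labels, modes, speeds = predict_probabilities(
        fit, trials, mode="per_draw", marginalize=marginalize
    )
    keep = np.ones(len(labels), dtype=bool)
    if mode is not None:
        keep &= modes == mode
    if speed is not None:
        keep &= speeds == speed
    labels = labels[keep]
    _check_two_classes(labels)
    p = p[:, keep]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    aucs = np.empty(p.shape[0])
    for i in range(p.shape[0]):
        ranks = rankdata(p[i])
        aucs[i] = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return summarize_draws(aucs)


def write_roc(curve: ROCCurve, path, specificity_axis: bool = False) -> None:
    """CSV of (threshold, sensitivity, specificity).

    ``specificity_axis`` additionally orders rows for plotting with the
    proportion of stranger stimuli correctly identified on x.
    """
    frame = curve.as_frame()
    if specificity_axis:
        frame = frame.sort_values("specificity", ignore_index=True)
    frame.to_csv(path, index=False)


def plot_roc(curves: dict[str, ROCCurve], path=None, specificity_axis: bool = False):
    """Basic ROC figure; returns the matplotlib axes."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, c in curves.items():
        x = 1.0 - c.fpr if specificity_axis else c.fpr
        ax.plot(x, c.tpr, label=f"{label} (AUC {c.auc:.2f})")
    guide = [1, 0] if specificity_axis else [0, 1]
    ax.plot(guide, [0, 1], "k:", lw=0.8)
    ax.set_xlabel(
        "strangers correctly identified" if specificity_axis else "false positive rate"
    )
    ax.set_ylabel("friends correctly identified")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
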