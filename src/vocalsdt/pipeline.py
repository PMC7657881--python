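"""End-to-end orchestration: simulate -> fit -> compare -> summarize -> ROC.

Every stage derives its randomness from one master seed, and each run
writes a machine-readable manifest (seeds, a hash of the configuration,
package versions) sufficient to re-execute the deterministic stages
bit-compatibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coding import TERMS
from .design import DesignSpec, build_design, condition_rates, validate_trials, write_trials
from .fitting import PosteriorFit, check_diagnostics, fit
from .loo import compare, loo, pointwise_loglik, write_comparison
from .models import REDUCED_FIT, FitConfig, PriorSpec, make_model
from .roc import auc_posterior, predict_probabilities, roc_points, write_roc
from .sdt import CELLS, summary_table
from .simulate import GenerativeParams, simulate_responses

log = logging.getLogger("vocalsdt")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    design: DesignSpec = field(default_factory=DesignSpec)
    params: GenerativeParams | None = None
    models: tuple[int, ...] = (0, 1, 2, 3, 4)
    priors: PriorSpec = field(default_factory=PriorSpec)
    fit: FitConfig = field(default_factory=FitConfig)
    output_dir: str = "runs"
    seed: int = 0
    profile: str = "full"  # "full" (study-scale defaults) or "reduced"

    def __post_init__(self) -> None:
        if self.profile not in ("full", "reduced"):
            raise ValueError("profile must be 'full' or 'reduced'")
        if self.profile == "reduced":
            for key, value in REDUCED_FIT.items():
                setattr(self.fit, key, value)

    def to_dict(self) -> dict:
        return {
            "design": self.design.to_dict(),
            "params": self.params.to_dict() if self.params else None,
            "models": list(self.models),
            "priors": vars(self.priors).copy(),
            "fit": vars(self.fit).copy(),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "profile": self.profile,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            design=DesignSpec.from_dict(d.get("design", {})),
            params=GenerativeParams.from_dict(d["params"]) if d.get("params") else None,
            models=tuple(d.get("models", (0, 1, 2, 3, 4))),
            priors=PriorSpec(**d.get("priors", {})),
            fit=FitConfig(**d.get("fit", {})),
            output_dir=d.get("output_dir", "runs"),
            seed=d.get("seed", 0),
            profile=d.get("profile", "full"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def stage_seed(self, stage: str, extra: int = 0) -> int:
        """Deterministic per-stage seed below 2**31 derived from the master."""
        h = hashlib.sha256(f"{self.seed}:{stage}:{extra}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def simulate_trials(config: RunConfig) -> pd.DataFrame:
    """Simulation stage: build the design and draw responses."""
    design = DesignSpec(**{**config.design.to_dict(), "seed": config.stage_seed("design")})
    table = build_design(design)
    params = config.params or GenerativeParams()
    params = GenerativeParams.from_dict(
        {**params.to_dict(), "seed": config.stage_seed("responses")}
    )
    return simulate_responses(table, params)


def run_analysis(config: RunConfig, trials: pd.DataFrame) -> dict:
    """Fit the requested models and write the full output bundle.

    Writes: per-model draws + diagnostics, a LOOIC comparison table, the
    condition-level SDT summary (criterion/sensitivity on percent and z
    scales, AUC with intervals) for the best model, per-condition ROC
    curves, raw condition response rates, and a run manifest.  Diagnostic
    failures are reported in the bundle but do not abort the run.
    """
    validate_trials(trials, require_response=True)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    fits: dict[int, PosteriorFit] = {}
    loos = {}
    diagnostics = {}
    for level in config.models:
        t0 = time.perf_counter()
        cfg = FitConfig(**{**vars(config.fit), "seed": config.stage_seed("fit", level)})
        model = make_model(level)
        log.info("fitting Model %d (%d trials)", level, len(trials))
        f = fit(model, trials, config.priors, cfg)
        fits[level] = f
        f.save(out / f"model{level}")
        diagnostics[level] = check_diagnostics(f)
        if not diagnostics[level]["passed"]:
            log.warning("Model %d diagnostics flagged: %s", level, diagnostics[level]["flags"])
        loos[f"model{level}"] = loo(pointwise_loglik(f, trials), label=f"model{level}")
        timings[f"fit_model{level}"] = time.perf_counter() - t0

    comparison = None
    if len(loos) >= 2:
        comparison = compare(loos)
        write_comparison(comparison, out / "comparison.csv")
        best_label = comparison.loc[0, "model"]
        best_level = int(best_label.removeprefix("model"))
    else:
        best_level = next(iter(fits))
    best = fits[best_level]

    auc = {}
    for mode, speed in CELLS:
        try:
            auc[(mode, speed)] = auc_posterior(best, trials, mode=mode, speed=speed)
        except ValueError as exc:
            log.warning("AUC skipped for %s/%s: %s", mode, speed, exc)
    table = summary_table(best, auc=auc)
    table.to_csv(out / "sdt_summary.csv", index=False)

    scored = predict_probabilities(best, trials)
    for mode, speed in CELLS:
        curve = roc_points(scored.subset(mode=mode, speed=speed))
        write_roc(curve, out / f"roc_{mode}_{speed.replace('-', '')}.csv")

    condition_rates(trials).to_csv(out / "condition_rates.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "master_seed": config.seed,
        "stage_seeds": {
            "design": config.stage_seed("design"),
            "responses": config.stage_seed("responses"),
            **{f"fit_model{lv}": config.stage_seed("fit", lv) for lv in config.models},
        },
        "n_trials": int(len(trials)),
        "models": list(config.models),
        "best_model": best_level,
        "diagnostics": {str(k): v["flags"] for k, v in diagnostics.items()},
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "versions": _versions(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return {
        "fits": fits,
        "comparison": comparison,
        "summary": table,
        "auc": auc,
        "diagnostics": diagnostics,
        "manifest": manifest,
    }


def _versions() -> dict:
    import arviz
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "arviz": arviz.__version__,
    }


def run_recovery(config: RunConfig, n_replicates: int, model_level: int = 4) -> pd.DataFrame:
    """Parameter-recovery study: repeated simulate -> fit cycles.

    Reports, per fixed effect and variance component, the bias and RMSE of
    posterior means and the coverage of 95% credibility intervals across
    replicates.
    """
    if n_replicates < 2:
        raise ValueError("need at least 2 replicates")
    params = config.params or GenerativeParams()
    model = make_model(model_level)
    terms = model.fixed_terms
    records = []
    for rep in range(n_replicates):
        rc = RunConfig.from_dict({**config.to_dict(), "seed": config.stage_seed("recovery", rep)})
        trials = simulate_trials(rc)
        cfg = FitConfig(**{**vars(config.fit), "seed": rc.stage_seed("fit", model_level)})
        f = fit(model, trials, config.priors, cfg)
        beta = f.stacked("beta")
        sd_p = f.stacked("sd_participant")
        sd_s = f.stacked("sd_stimulus")
        for i, t in enumerate(terms):
            full_i = TERMS.index(t)
            records.append(
                _recovery_record(rep, f"b_{t}", params.beta[full_i], beta[:, i])
            )
            records.append(
                _recovery_record(
                    rep,
                    f"sd_participant__{t}",
                    params.participant_sd[full_i],
                    sd_p[:, i],
                )
            )
        records.append(
            _recovery_record(rep, "sd_stimulus__intercept", params.stimulus_sd, sd_s)
        )
    raw = pd.DataFrame(records)
    report = (
        raw.groupby("parameter", sort=False)
        .agg(
            truth=("truth", "first"),
            bias=("error", "mean"),
            rmse=("error", lambda e: float(np.sqrt(np.mean(np.square(e))))),
            coverage=("covered", "mean"),
        )
        .reset_index()
    )
    return report


def _recovery_record(rep: int, name: str, truth: float, draws: np.ndarray) -> dict:
    lo, hi = np.percentile(draws, [2.5, 97.5])
    mean = float(draws.mean())
    return {
        "replicate": rep,
        "parameter": name,
        "truth": float(truth),
        "posterior_mean": mean,
        "error": mean - float(truth),
        "covered": bool(lo <= truth <= hi),
    }
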