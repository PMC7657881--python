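import numpy as np
import pytest

from vocalsdt.design import DesignSpec, build_design
from vocalsdt.fitting import PosteriorFit, fit
from vocalsdt.models import FitConfig, PriorSpec, make_model
from vocalsdt.simulate import GenerativeParams, simulate_responses


#: fast sampler settings for unit tests (distinct from the reduced profile)
QUICK_FIT = dict(n_chains=2, n_iterations=400, target_accept=0.9, max_trajectory_depth=10)


@pytest.fixture(scope="session")
def small_trials():
    """384-trial simulated dataset (12 participants x 32 stimuli)."""
    spec = DesignSpec(n_participants=12, n_conversations_per_familiarity=4, seed=101)
    params = GenerativeParams(seed=102)
    return simulate_responses(build_design(spec), params)


@pytest.fixture(scope="session")
def small_fit(small_trials):
    """Model 2 posterior on the small dataset, shared across test modules."""
    return fit(
        make_model(2),
        small_trials,
        PriorSpec(),
        FitConfig(seed=103, **QUICK_FIT),
    )


def make_fake_fit(beta_draws: np.ndarray, level: int, trials=None) -> PosteriorFit:
    """Fixed-effects-only PosteriorFit with prescribed draws (for unit tests)."""
    from vocalsdt.fitting import DiagnosticsReport

    model = make_model(level)
    beta_draws = np.asarray(beta_draws, dtype=float)
    if beta_draws.ndim == 2:
        beta_draws = beta_draws[None, :, :]
    if trials is not None:
        participants = np.unique(trials["participant_id"].to_numpy())
        stimuli = np.unique(trials["stimulus_id"].to_numpy())
    else:
        participants = np.array([])
        stimuli = np.array([])
    return PosteriorFit(
        model=model,
        draws={"beta": beta_draws},
        diagnostics=DiagnosticsReport(0, {}, {}, {}),
        participants=participants,
        stimuli=stimuli,
        priors=PriorSpec(),
        config=FitConfig(),
    )
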