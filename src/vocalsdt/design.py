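"""Trial design of the dyadic-vocalization affiliation-judgement experiment.

The experiment presents short audio clips of two people either laughing
together (colaughter) or talking over each other (cospeech), excised from
recorded conversations between established friends or newly acquainted
strangers.  Each conversation contributes its first and last qualifying
occurrence of each vocalization mode.  Every clip also exists in a
time-compressed ("sped-up") version; two counterbalanced stimulus lists
decide which half of the clips a given participant hears sped-up, so each
participant hears every clip exactly once, in exactly one speed version.

This module builds that design as a tidy trial table (one row per
participant x stimulus presentation) without responses; responses are
attached by :mod:`vocalsdt.simulate`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

FAMILIARITY_LEVELS = ("strangers", "friends")
MODE_LEVELS = ("cospeech", "colaughter")
SPEED_LEVELS = ("original", "sped-up")
OCCURRENCE_LEVELS = ("first", "last")

#: canonical trial-table columns; ``liking`` and ``response`` are optional
TRIAL_COLUMNS = (
    "participant_id",
    "list_id",
    "trial_index",
    "stimulus_id",
    "familiarity",
    "mode",
    "speed",
)


class DesignError(ValueError):
    """Raised when a design specification cannot be realized."""


class SchemaError(ValueError):
    """Raised when a trial table violates the expected schema."""


@dataclass
class DesignSpec:
    """Counts and factor structure of the judgement experiment.

    Defaults reproduce the original study design: 108 participants,
    24 conversations (12 friend dyads, 12 stranger dyads), first and last
    occurrence of each mode per conversation (96 stimuli), two
    counterbalanced speed lists.
    """

    n_participants: int = 108
    n_conversations_per_familiarity: int = 12
    clips_per_conversation_per_mode: int = 2
    modes: tuple[str, ...] = MODE_LEVELS
    speeds: tuple[str, ...] = SPEED_LEVELS
    n_lists: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.modes = tuple(self.modes)
        self.speeds = tuple(self.speeds)
        if self.n_participants < 1:
            raise DesignError("need at least one participant")
        if self.n_conversations_per_familiarity < 1:
            raise DesignError("need at least one conversation per familiarity")
        if self.clips_per_conversation_per_mode < 1:
            raise DesignError("need at least one clip per conversation and mode")
        if self.clips_per_conversation_per_mode > len(OCCURRENCE_LEVELS):
            raise DesignError(
                "at most %d occurrences (first/last) per conversation and mode"
                % len(OCCURRENCE_LEVELS)
            )
        if self.n_lists < 1:
            raise DesignError("need at least one list")
        cell = self.n_conversations_per_familiarity * self.clips_per_conversation_per_mode
        if cell % self.n_lists and self.n_lists > 1:
            raise DesignError(
                f"{self.n_lists} lists cannot evenly split the "
                f"{cell} stimuli of each familiarity x mode cell"
            )

    @property
    def n_stimuli(self) -> int:
        return (
            len(FAMILIARITY_LEVELS)
            * self.n_conversations_per_familiarity
            * self.clips_per_conversation_per_mode
            * len(self.modes)
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["modes"] = list(self.modes)
        d["speeds"] = list(self.speeds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSpec":
        return cls(**d)


def build_stimuli(spec: DesignSpec) -> pd.DataFrame:
    """Enumerate the stimulus set: one row per clip.

    ``(conversation_id, mode, occurrence)`` is unique and familiarity is
    constant within a conversation.
    """
    rows = []
    for fam in FAMILIARITY_LEVELS:
        for c in range(spec.n_conversations_per_familiarity):
            conv = f"{fam[0]}{c + 1:02d}"
            for mode in spec.modes:
                for occ in OCCURRENCE_LEVELS[: spec.clips_per_conversation_per_mode]:
                    rows.append(
                        {
                            "stimulus_id": f"{conv}_{mode}_{occ}",
                            "conversation_id": conv,
                            "familiarity": fam,
                            "mode": mode,
                            "occurrence": occ,
                        }
                    )
    return pd.DataFrame(rows)


def _speed_groups(stimuli: pd.DataFrame, spec: DesignSpec, rng: np.random.Generator) -> pd.Series:
    """Assign each stimulus to a counterbalancing group 0..n_lists-1.

    Within every familiarity x mode cell the groups are equal-sized, so each
    list hears 1/n_lists of that cell's clips in the manipulated (sped-up)
    version — with two lists, half of each mode's sped-up clips per list.
    """
    group = pd.Series(0, index=stimuli.index, dtype=int)
    for _, idx in stimuli.groupby(["familiarity", "mode"], sort=True).groups.items():
        idx = np.asarray(idx)
        if len(idx) % spec.n_lists and spec.n_lists > 1:
            raise DesignError(
                f"cell of size {len(idx)} not divisible by {spec.n_lists} lists"
            )
        perm = rng.permutation(len(idx))
        group.loc[idx[perm]] = np.repeat(
            np.arange(spec.n_lists), len(idx) // spec.n_lists
        )
    return group


def build_design(spec: DesignSpec) -> pd.DataFrame:
    """Build the full trial table (no responses yet).

    Participants alternate between the counterbalanced lists by index; each
    participant's presentation order is an independent seeded permutation.
    With default settings the table has 108 x 96 = 10 368 rows, and each
    participant contributes 12 trials to each familiarity x mode x speed cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    stimuli = build_stimuli(spec)
    group = _speed_groups(stimuli, spec, rng).to_numpy()

    n_stim = len(stimuli)
    n_part = spec.n_participants
    # one independent presentation-order permutation per participant
    orders = np.argsort(rng.random((n_part, n_stim)), axis=1)
    flat = orders.ravel()
    width = max(3, len(str(n_part)))
    pids = np.array([f"p{i + 1:0{width}d}" for i in range(n_part)])
    list_idx = np.arange(n_part) % spec.n_lists
    lists = np.array([f"L{i + 1}" for i in list_idx])
    if spec.n_lists == 1:
        # no counterbalancing possible: original versions only
        sped = np.zeros(n_part * n_stim, dtype=bool)
    else:
        sped = group[flat] == np.repeat(list_idx, n_stim)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(pids, n_stim),
            "list_id": np.repeat(lists, n_stim),
            "trial_index": np.tile(np.arange(n_stim), n_part),
            "stimulus_id": stimuli["stimulus_id"].to_numpy()[flat],
            "familiarity": stimuli["familiarity"].to_numpy()[flat],
            "mode": stimuli["mode"].to_numpy()[flat],
            "speed": np.where(sped, "sped-up", "original"),
        }
    )


def validate_trials(trials: pd.DataFrame, require_response: bool = False) -> None:
    """Check a trial table against the CSV schema; raise SchemaError with rows."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing columns: {missing}")
    for col, levels in (
        ("familiarity", FAMILIARITY_LEVELS),
        ("mode", MODE_LEVELS),
        ("speed", SPEED_LEVELS),
    ):
        bad = ~trials[col].isin(levels)
        if bad.any():
            rows = trials.index[bad][:10].tolist()
            raise SchemaError(
                f"column {col!r} has values outside {levels} at rows {rows}"
            )
    if require_response or "response" in trials.columns:
        if "response" not in trials.columns:
            raise SchemaError("missing column 'response'")
        resp = trials["response"]
        bad = ~resp.isin((0, 1))
        if bad.any():
            rows = trials.index[bad][:10].tolist()
            raise SchemaError(f"response must be 0/1; offending rows {rows}")
    dup = trials.duplicated(subset=["participant_id", "stimulus_id"])
    if dup.any():
        rows = trials.index[dup][:10].tolist()
        raise SchemaError(f"duplicate participant x stimulus rows: {rows}")


def condition_rates(trials: pd.DataFrame) -> pd.DataFrame:
    """Mean "friends"-response rate and trial count per design cell.

    Always returns all 8 familiarity x mode x speed cells; a cell absent from
    the data is reported explicitly with count 0 and missing mean rather than
    silently dropped.
    """
    if trials.empty:
        raise SchemaError("empty trial table")
    validate_trials(trials, require_response=True)
    g = trials.groupby(["familiarity", "mode", "speed"], sort=True)["response"].agg(
        ["mean", "count"]
    )
    full = pd.MultiIndex.from_tuples(
        list(itertools.product(FAMILIARITY_LEVELS, MODE_LEVELS, SPEED_LEVELS)),
        names=["familiarity", "mode", "speed"],
    )
    out = g.reindex(full)
    out["count"] = out["count"].fillna(0).astype(int)
    return out.rename(columns={"mean": "rate"}).reset_index()


def write_trials(trials: pd.DataFrame, path) -> None:
    validate_trials(trials)
    trials.to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    validate_trials(trials)
    return trials
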