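"""Design coding for the probit models.

All factors are 0/1 indicators with reference levels strangers, cospeech,
original speed: Familiarity = 1 for friend dyads, Talk = 1 for colaughter,
Speed = 1 for sped-up clips.  The full fixed-effect vector is ordered
(intercept, familiarity, talk, speed, familiarity:speed, familiarity:talk,
talk:speed, familiarity:talk:speed); every model's terms are a subset in
this order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TERMS = (
    "intercept",
    "familiarity",
    "talk",
    "speed",
    "familiarity:speed",
    "familiarity:talk",
    "talk:speed",
    "familiarity:talk:speed",
)

_BASE = {
    "intercept": None,
    "familiarity": ("familiarity", "friends"),
    "talk": ("mode", "colaughter"),
    "speed": ("speed", "sped-up"),
}


def term_columns(trials: pd.DataFrame, terms=TERMS) -> np.ndarray:
    """0/1 design matrix (n_trials x n_terms) for the requested terms."""
    cache: dict[str, np.ndarray] = {}

    def base(name: str) -> np.ndarray:
        if name not in cache:
            col, level = _BASE[name]
            cache[name] = (trials[col].to_numpy() == level).astype(float)
        return cache[name]

    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(trials)))
        else:
            x = np.ones(len(trials))
            for part in t.split(":"):
                x = x * base(part)
            cols.append(x)
    return np.column_stack(cols)


def cell_codes(mode: str, speed: str, familiarity: str) -> np.ndarray:
    """Design-code row for one condition cell, over the full 8 terms."""
    row = pd.DataFrame(
        {"familiarity": [familiarity], "mode": [mode], "speed": [speed]}
    )
    return term_columns(row)[0]
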