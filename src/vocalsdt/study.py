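"""Condition-level estimates from the original listening experiment.

The study that this package models reported, for each vocalization mode x
speed condition, a posterior-mean criterion (probit-scale bias toward
answering "friends" when the dyad is in fact strangers) and sensitivity
(probit-scale separation between friend and stranger stimuli, i.e. d'),
plus an AUC.  Those condition summaries pin down the full 8-term
fixed-effect vector under the package's reference coding, which makes them
the natural ground truth for the synthetic-data generator and for
round-trip checks of the criterion/sensitivity cell algebra.
"""

from __future__ import annotations

import numpy as np

from .coding import TERMS

#: (criterion_z, sensitivity_z) posterior means per (mode, speed) condition
REPORTED_CONDITION_Z: dict[tuple[str, str], tuple[float, float]] = {
    ("cospeech", "original"): (-0.22, 0.33),
    ("cospeech", "sped-up"): (-0.01, 0.22),
    ("colaughter", "original"): (-0.03, 0.70),
    ("colaughter", "sped-up"): (0.16, 0.69),
}

#: reported AUC point estimates per condition (0-1 scale)
REPORTED_AUC: dict[tuple[str, str], float] = {
    ("cospeech", "original"): 0.66,
    ("cospeech", "sped-up"): 0.68,
    ("colaughter", "original"): 0.75,
    ("colaughter", "sped-up"): 0.75,
}


def betas_from_condition_z(
    condition_z: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> np.ndarray:
    """Invert the cell map: condition (criterion, sensitivity) -> 8 betas.

    Under 0/1 coding with reference levels strangers/cospeech/original:

    ==============================  =========================================
    quantity                        linear combination
    ==============================  =========================================
    criterion(cospeech, original)   intercept
    criterion(colaughter, original) intercept + talk
    criterion(cospeech, sped-up)    intercept + speed
    criterion(colaughter, sped-up)  intercept + talk + speed + talk:speed
    sensitivity(cospeech, original) familiarity
    sensitivity(colaughter, orig.)  familiarity + familiarity:talk
    sensitivity(cospeech, sped-up)  familiarity + familiarity:speed
    sensitivity(colaughter, sped)   familiarity + fam:talk + fam:speed
                                    + fam:talk:speed
    ==============================  =========================================
    """
    z = condition_z or REPORTED_CONDITION_Z
    c_co_o, d_co_o = z[("cospeech", "original")]
    c_co_s, d_co_s = z[("cospeech", "sped-up")]
    c_cl_o, d_cl_o = z[("colaughter", "original")]
    c_cl_s, d_cl_s = z[("colaughter", "sped-up")]

    beta = {
        "intercept": c_co_o,
        "talk": c_cl_o - c_co_o,
        "speed": c_co_s - c_co_o,
        "familiarity": d_co_o,
        "familiarity:talk": d_cl_o - d_co_o,
        "familiarity:speed": d_co_s - d_co_o,
    }
    beta["talk:speed"] = c_cl_s - c_co_o - beta["talk"] - beta["speed"]
    beta["familiarity:talk:speed"] = (
        d_cl_s - d_co_o - beta["familiarity:talk"] - beta["familiarity:speed"]
    )
    return np.array([beta[t] for t in TERMS])
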