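"""Screen candidate fixed-effect prior scales by prior prediction.

Draw the whole fixed-effect vector from N(0, sd) for each candidate sd,
simulate the overall "friends" rate over the real design, and record how
often the rate is extreme (outside [0.05, 0.95]).  A weakly regularizing
prior should allow a broader spread than the data but make extreme rates
rare — the rationale for choosing sd = 0.3.
"""

from vocalsdt import DesignSpec, PriorSpec, build_design, make_model, prior_predictive

design = build_design(DesignSpec(seed=1))
summary = prior_predictive(
    make_model(4), PriorSpec(), design, n_draws=2000, sd_grid=(1.0, 0.5, 0.3, 0.1), seed=3
)
print(summary.as_frame().to_string(index=False))
print()
print("p_extreme shrinks monotonically with the prior scale; at sd = 0.3 the")
print("prior still spans a wide band of plausible rates while putting little")
print("mass on near-deterministic response patterns.")
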