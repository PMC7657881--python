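"""Build the listening-experiment design and simulate judgements.

108 participants each hear 96 clips (colaughter and cospeech from 12
friend and 12 stranger dyads, half sped-up according to the participant's
counterbalancing list) and judge "friends" (1) or "strangers" (0).
Responses come from the generative probit model whose fixed effects are
set to the condition-level estimates of the original experiment.
"""

from vocalsdt import DesignSpec, GenerativeParams, build_design, condition_rates, simulate_responses

design = build_design(DesignSpec(seed=1))
trials = simulate_responses(design, GenerativeParams(seed=2))

print(f"trials: {len(trials)} (expected 108 x 96 = 10 368)")
print(f"stimuli: {trials['stimulus_id'].nunique()}, participants: "
      f"{trials['participant_id'].nunique()}")
print()
print(condition_rates(trials).to_string(index=False))
print()
print("Each row is one familiarity x mode x speed cell; 'rate' is the share")
print("of 'friends' answers. Friend stimuli, colaughter and sped-up clips")
print("should all pull the rate upward, mirroring the generating model.")
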