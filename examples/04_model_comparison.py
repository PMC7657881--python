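"""Compare the intercept-only and full interaction models by PSIS-LOO.

Data are simulated from the full model, so the comparison should prefer
Model 4 (lower LOOIC = better estimated out-of-sample fit).  se_diff is
the standard error of the pointwise elpd difference to the best model;
a difference within ~2 se is not a credible preference.
"""

from vocalsdt import (
    DesignSpec,
    FitConfig,
    GenerativeParams,
    PriorSpec,
    build_design,
    compare,
    fit,
    loo,
    make_model,
    pointwise_loglik,
    simulate_responses,
)

design = build_design(DesignSpec(n_participants=16, n_conversations_per_familiarity=4, seed=7))
trials = simulate_responses(design, GenerativeParams(seed=8))

results = {}
for level in (0, 4):
    f = fit(
        make_model(level),
        trials,
        PriorSpec(),
        FitConfig(n_chains=2, n_iterations=500, target_accept=0.9,
                  max_trajectory_depth=10, seed=9 + level),
    )
    results[f"model{level}"] = loo(pointwise_loglik(f, trials), label=f"model{level}")

print(compare(results).round(2).to_string(index=False))
print()
print("model4 should rank first: the experimental conditions credibly affect")
print("the simulated judgements, and leave-one-out prediction rewards that.")
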