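"""Type A / Type B context effects and their link to stimulus weights.

Simulates a heterogeneous cohort in which each participant weights the
second stimulus more strongly than the first (w2 > w1), fits per-
participant psychometric functions, and correlates the proportional weight
difference (w1 - w2)/(w1 + w2) with the Type B effect.
"""

import numpy as np

from contextddm import (ExperimentDesign, IndividualParameters, ModelSpec,
                        correlate_weights_effects, effects_table,
                        proportional_weight_difference, simulate_experiment)

rng = np.random.default_rng(11)
design = ExperimentDesign(n_trials_per_level_per_order=40)  # 720 trials
spec = ModelSpec.from_number(6)

params = {}
for i in range(21):
    w1 = 0.0096 * np.exp(0.25 * rng.standard_normal())
    ratio = np.exp(rng.normal(np.log(1.8), 0.35))  # w2/w1, mostly > 1
    params[f"p{i:02d}"] = IndividualParameters(
        a=1.4736, tau=0.1456, z0=0.4411,
        v0=0.0437 + 0.05 * rng.standard_normal(),
        v1=float(w1), v2=float(-w1 * ratio), z1=0.0007)

ds = simulate_experiment(design, spec, params, rng=rng)
table = effects_table(ds).set_index("participant_id")
diffs = [proportional_weight_difference(params[p].v1, params[p].v2)
         for p in table.index]
r = correlate_weights_effects(diffs, table["type_b"].to_numpy())

print(table[["pse_sc", "pse_cs", "dl_sc", "dl_cs", "type_a", "type_b"]]
      .round(1).to_string())
print(f"\nmedian Type B effect: {table['type_b'].median():.1f} ms "
      "(negative = better discrimination when the standard comes first)")
print(f"correlation between (w1-w2)/(w1+w2) and Type B: r = {r:.2f}")
print("A larger second-stimulus weight flattens the comparison-first "
      "psychometric curve, producing the classical negative Type B effect; "
      "the correlation shows the weight asymmetry predicts its size.")
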