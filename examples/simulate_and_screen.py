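"""Simulate a duration-discrimination session and screen it for fast guesses.

Generates a two-participant experiment (500 ms standard, nine comparison
durations between 400 and 600 ms, both presentation orders intermixed) from
the separate-weight starting-point diffusion variant, contaminates one
participant with fast guesses, and runs the EWMA screening rules.
"""

import numpy as np
import pandas as pd

from contextddm import (ExperimentDesign, IndividualParameters, ModelSpec,
                        apply_exclusions, simulate_experiment)

design = ExperimentDesign(n_trials_per_level_per_order=20)  # 360 trials
spec = ModelSpec.from_number(6)
params = {
    "clean": IndividualParameters(a=1.47, tau=0.15, z0=0.44, v0=0.04,
                                  v1=0.0096, v2=-0.0198, z1=0.0007),
    "guesser": IndividualParameters(a=1.3, tau=0.12, z0=0.46, v0=0.0,
                                    v1=0.010, v2=-0.016, z1=0.0005),
}
ds = simulate_experiment(design, spec, params, rng=1)

# contaminate: replace 15% of the guesser's trials with sub-250 ms chance
# responses
rng = np.random.default_rng(2)
trials = ds.trials.copy()
rows = trials.index[trials["participant_id"] == "guesser"][:54]
trials.loc[rows, "rt_s"] = rng.uniform(0.1, 0.25, len(rows))
trials.loc[rows, "response"] = rng.choice(["first_longer", "second_longer"],
                                          len(rows))
from contextddm import Dataset  # noqa: E402

contaminated = Dataset(trials, design=design)

clean, report = apply_exclusions(contaminated)
pd.set_option("display.width", 120)
print(report.to_frame().to_string(index=False))
print(f"\nretained {clean.n_trials} of {contaminated.n_trials} trials; "
      f"excluded participants: {report.excluded_participants}")
print("Each row shows the participant's RT cutoff from the EWMA accuracy "
      "chart, the share of responses below it (fast guesses), and whether "
      "the 10% exclusion rule fired.")
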