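"""Fit the hierarchical diffusion model to a small synthetic cohort.

Simulates six participants from the separate-weight starting-point variant
at the published group modes, fits the same variant with the blocked MCMC
sampler at reduced settings, and prints group-level posterior summaries
next to the generating values.
"""

from contextddm import (ExperimentDesign, ModelSpec, fit, hdi,
                        posterior_mode, sample_individual_parameters,
                        simulate_experiment)

GROUP = {"a": 1.4736, "tau": 0.1456, "z0": 0.4411, "v0": 0.0437,
         "v1": 0.0096, "v2": -0.0198, "z1": 0.0007}
SDS = {"a": 0.15, "tau": 0.2, "z0": 0.15, "v0": 0.15,
       "v1": 0.002, "v2": 0.004, "z1": 0.0003}

spec = ModelSpec.from_number(6)
design = ExperimentDesign(n_trials_per_level_per_order=5)  # 90 trials each
params = sample_individual_parameters(GROUP, SDS, 6, rng=3)
ds = simulate_experiment(design, spec, params, rng=4)

draws = fit(spec, ds, n_chains=3, n_iter=1200, seed=5)
print(f"max split R-hat: {draws.rhat_table().max():.4f} "
      f"(converged: {draws.converged})\n")
print(f"{'parameter':>9} {'true':>8} {'mode':>8} {'95% HDI':>20}")
for name, true in GROUP.items():
    gm = draws.group_mean(name).ravel()
    lo, hi = hdi(gm, 0.95)
    print(f"{name:>9} {true:8.4f} {posterior_mode(gm):8.4f} "
          f"[{lo:8.4f}, {hi:8.4f}]")
print("\nEach group mean is the constrained transform of the Gaussian "
      "hyper-mean; with a correct model the true value should sit inside "
      "most of the 95% HDIs.")
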