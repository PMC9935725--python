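import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from contextddm.datasets import ExperimentDesign
from contextddm.models import IndividualParameters, ModelSpec, dataset_dynamics
from contextddm.wiener import (choice_probability_upper, loglik_participant,
                               simulate_choice_rt, simulate_experiment,
                               simulate_trials_batch, wfpt_log_density)


class TestDensity:
    @pytest.mark.parametrize("t,a,v,z,tau", [
        (0.8, 1.5, 1.2, 0.4, 0.1),
        (0.35, 0.8, -2.0, 0.6, 0.05),
        (2.5, 2.5, 0.0, 0.5, 0.0),
    ])
    def test_reflection_symmetry(self, t, a, v, z, tau):
        up = wfpt_log_density(t, "upper", a, v, z, tau)
        lo = wfpt_log_density(t, "lower", a, -v, 1 - z, tau)
        assert up == pytest.approx(lo, rel=1e-12)

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.2, 3.0), st.floats(0.5, 2.5), st.floats(-3, 3),
           st.floats(0.1, 0.9))
    def test_reflection_symmetry_property(self, t, a, v, z):
        up = wfpt_log_density(t, "upper", a, v, z, 0.0)
        lo = wfpt_log_density(t, "lower", a, -v, 1 - z, 0.0)
        assert np.isclose(up, lo, rtol=1e-10) or (up == lo == -np.inf)

    def test_at_or_before_nondecision_time(self):
        assert wfpt_log_density(0.1, "upper", 1.5, 1.0, 0.5, 0.1) == -np.inf
        assert wfpt_log_density(0.05, "lower", 1.5, 1.0, 0.5, 0.1) == -np.inf

    def test_invalid_domain_raises_rather_than_neg_inf(self):
        with pytest.raises(ValueError):
            wfpt_log_density(1.0, "upper", -1.0, 0.0, 0.5, 0.0)
        with pytest.raises(ValueError):
            wfpt_log_density(1.0, "upper", 1.0, 0.0, 1.5, 0.0)
        with pytest.raises(ValueError):
            wfpt_log_density(1.0, "sideways", 1.0, 0.0, 0.5, 0.0)

    def test_defective_densities_integrate_to_one(self):
        a, v, z, tau = 1.5, 1.0, 0.45, 0.15
        up, _ = quad(lambda t: np.exp(wfpt_log_density(t, "upper", a, v, z, tau)),
                     tau, 40, limit=200)
        lo, _ = quad(lambda t: np.exp(wfpt_log_density(t, "lower", a, v, z, tau)),
                     tau, 40, limit=200)
        assert up + lo == pytest.approx(1.0, abs=1e-4)
        assert up == pytest.approx(choice_probability_upper(a, v, z), abs=1e-4)


class TestChoiceProbability:
    def test_unbiased_driftless_walk(self):
        assert choice_probability_upper(1.5, 0.0, 0.5) == pytest.approx(0.5)

    def test_zero_drift_limit_equals_start_point(self):
        assert choice_probability_upper(1.5, 0.0, 0.3) == pytest.approx(0.3)
        # continuity across the v=0 stabilization
        assert choice_probability_upper(1.5, 1e-12, 0.3) == pytest.approx(
            0.3, abs=1e-6)

    def test_simulation_agreement(self):
        a, v, z = 1.5, 5.0, 0.5
        n = 10_000
        ch, _ = simulate_trials_batch(np.full(n, v), np.full(n, z), a, 0.0,
                                      rng=13)
        p = choice_probability_upper(a, v, z)
        se = np.sqrt(p * (1 - p) / n)
        assert abs((ch == 1).mean() - p) < 4 * se


class TestSimulation:
    def test_nondecision_time_offsets_all_rts(self):
        r = simulate_choice_rt(1.0, 0.0, 0.5, tau=0.2, rng=3)
        assert r.rt_s > 0.2

    def test_same_seed_identical_draw(self):
        a = simulate_choice_rt(1.0, 1.0, 0.5, 0.1, rng=42)
        b = simulate_choice_rt(1.0, 1.0, 0.5, 0.1, rng=42)
        assert (a.choice, a.rt_s) == (b.choice, b.rt_s)

    def test_non_absorption_is_censored(self):
        r = simulate_choice_rt(50.0, 0.0, 0.5, 0.0, rng=1, time_cap=0.01)
        assert r.censored and np.isnan(r.rt_s)

    def test_simulated_conditional_rts_match_density(self):
        """Defective-CDF KS distance at one parameter set, at the default
        step and at half the step (convergence of the Euler scheme)."""
        a, v, z, tau = 1.5, 1.0, 0.45, 0.1
        for dt in (1e-4, 5e-5):
            d = _defective_ks(a, v, z, tau, n=50_000, dt=dt, seed=29)
            assert d < 0.01, f"KS {d:.4f} at dt={dt}"


def _defective_ks(a, v, z, tau, n, dt, seed):
    ch, rt = simulate_trials_batch(np.full(n, v), np.full(n, z), a, tau,
                                   dt=dt, rng=seed)
    grid = np.linspace(tau + 1e-6, max(np.nanmax(rt) * 1.05, tau + 1.0), 4000)
    dmax = 0.0
    for lab, flag in (("upper", 1), ("lower", 0)):
        dens = np.exp([wfpt_log_density(t, lab, a, v, z, tau) for t in grid])
        cdf = np.concatenate([[0.0], np.cumsum(
            (dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        s = np.sort(rt[ch == flag])
        emp_hi = np.arange(1, s.size + 1) / n
        emp_lo = np.arange(0, s.size) / n
        F = np.interp(s, grid, cdf)
        dmax = max(dmax, np.abs(F - emp_hi).max(), np.abs(F - emp_lo).max())
    return dmax


class TestParticipantLikelihood:
    def test_label_symmetry_at_neutral_parameters(self):
        import pandas as pd

        spec = ModelSpec.from_number(1)
        p = IndividualParameters(a=1.5, tau=0.1, z0=0.5, v0=0.0, v1=0.0)
        rows = []
        for i, resp in enumerate(["first_longer", "second_longer"], start=1):
            rows.append(("s", i, 500.0, 500.0, "sc", resp, 0.6))
        trials = pd.DataFrame(rows, columns=["participant_id", "trial_index",
                                             "dur1_ms", "dur2_ms", "order",
                                             "response", "rt_s"])
        _, per = loglik_participant(spec, p, trials)
        assert per[0] == pytest.approx(per[1], rel=1e-12)

    def test_vector_sums_to_total(self, two_participant_dataset,
                                  single_params):
        spec, design, params, ds = two_participant_dataset
        trials = ds.participant_trials(ds.participants[0])
        total, per = loglik_participant(spec, single_params, trials)
        assert total == pytest.approx(per.sum())
        assert per.shape[0] == len(trials)

    def test_rt_below_nondecision_time_flagged_not_raised(self):
        import pandas as pd

        spec = ModelSpec.from_number(1)
        p = IndividualParameters(a=1.5, tau=0.5, z0=0.5, v0=0.0, v1=0.01)
        trials = pd.DataFrame(
            [("s", 1, 600.0, 500.0, "cs", "first_longer", 0.3)],
            columns=["participant_id", "trial_index", "dur1_ms", "dur2_ms",
                     "order", "response", "rt_s"])
        total, per = loglik_participant(spec, p, trials)
        assert per[0] == -np.inf and total == -np.inf

    def test_likelihood_peaks_near_generating_parameters(self):
        """Across replicate datasets the generating parameters beat a 50%
        boundary-separation perturbation on average (self-consistency)."""
        spec = ModelSpec.from_number(1)
        true = IndividualParameters(a=1.4, tau=0.15, z0=0.5, v0=0.0, v1=0.01)
        worse = IndividualParameters(a=2.1, tau=0.15, z0=0.5, v0=0.0, v1=0.01)
        design = ExperimentDesign(n_trials_per_level_per_order=12)  # 216 trials
        rng = np.random.default_rng(77)
        margins = []
        for _ in range(10):
            ds = simulate_experiment(design, spec, {"s": true}, rng=rng)
            trials = ds.participant_trials("s")
            margins.append(loglik_participant(spec, true, trials)[0]
                           - loglik_participant(spec, worse, trials)[0])
        assert np.mean(margins) > 0


class TestSimulateExperiment:
    def test_fixed_seed_reproduces_dataset(self, single_params):
        spec = ModelSpec.from_number(6)
        design = ExperimentDesign(n_trials_per_level_per_order=2)
        a = simulate_experiment(design, spec, {"p": single_params}, rng=5)
        b = simulate_experiment(design, spec, {"p": single_params}, rng=5)
        assert a.equals(b)

    def test_trial_order_irrelevant_without_state(self, single_params):
        """Model variants without reference updating assign each trial the
        same dynamics regardless of its position in the session."""
        spec = ModelSpec.from_number(6)
        design = ExperimentDesign(n_trials_per_level_per_order=2)
        from contextddm.datasets import generate_design_trials

        ds = generate_design_trials(design, seed=1)
        v1, z1, _ = dataset_dynamics(spec, single_params, ds.trials,
                                     as_arrays=True)
        shuffled = ds.trials.sample(frac=1.0, random_state=4).reset_index(drop=True)
        shuffled["trial_index"] = np.arange(1, len(shuffled) + 1)
        v2, z2, _ = dataset_dynamics(spec, single_params, shuffled,
                                     as_arrays=True)
        key1 = sorted(zip(ds.trials["dur1_ms"], ds.trials["dur2_ms"], v1, z1))
        key2 = sorted(zip(shuffled["dur1_ms"], shuffled["dur2_ms"], v2, z2))
        assert key1 == key2

    def test_psychometric_monotonicity(self, single_params):
        """P(comparison longer) rises with comparison duration, both in the
        analytic choice probabilities and in simulation."""
        spec = ModelSpec.from_number(6)
        levels = np.linspace(400, 600, 9)
        # analytic: cs-order trials, comparison presented first
        probs = []
        for lvl in levels:
            from contextddm.models import trial_dynamics

            dyn = trial_dynamics(spec, single_params,
                                 {"dur1_ms": lvl, "dur2_ms": 500.0})
            probs.append(choice_probability_upper(single_params.a, dyn.v_n,
                                                  dyn.z_n))
        assert np.all(np.diff(probs) > 0)
        design = ExperimentDesign(n_trials_per_level_per_order=150,
                                  order_scheme="blocked_cs")
        ds = simulate_experiment(design, spec, {"p": single_params}, rng=8)
        emp = (ds.trials.assign(longer=ds.trials["response"] == "first_longer")
               .groupby("dur1_ms")["longer"].mean())
        # coarse agreement: endpoints clearly ordered
        assert emp.iloc[-1] - emp.iloc[0] > 0.5
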