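"""Two-boundary Wiener diffusion: first-passage-time density, choice
probabilities, likelihoods, and stochastic simulation.

The diffusion coefficient is fixed at 1 throughout (the scale convention of
most probabilistic-programming Wiener implementations).  Note that a ``0.1``
convention also circulates in the diffusion-model literature; under that
convention boundary separation, drift rates and starting-point slopes are
rescaled by a factor of 10, so parameter values are not directly comparable
across conventions.

The density is evaluated with the classic dual-series representation of the
first-passage-time distribution of drifted Brownian motion between two
absorbing boundaries: a small-time (image-method) expansion and a large-time
(spectral) expansion, switching to whichever needs fewer terms for the
requested truncation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "ChoiceRT",
    "wfpt_log_density",
    "choice_probability_upper",
    "loglik_participant",
    "simulate_choice_rt",
    "simulate_experiment",
]

#: default truncation error for the series expansions, in density units
DEFAULT_ERR = 1e-7

#: default Euler-Maruyama step (seconds)
DEFAULT_DT = 1e-4

#: default simulation time cap (seconds); non-absorbed paths are censored
DEFAULT_TIME_CAP = 30.0


@dataclass(frozen=True)
class ChoiceRT:
    """Outcome of a single simulated diffusion trial.

    ``choice`` is ``"upper"`` or ``"lower"``; ``rt_s`` is decision time plus
    non-decision time in seconds.  ``censored`` marks paths that did not
    reach a boundary within the time cap; their ``rt_s`` is NaN.
    """

    choice: str
    rt_s: float
    censored: bool = False


# ---------------------------------------------------------------------------
# density kernels
# ---------------------------------------------------------------------------


@njit(cache=False)
def _fptd_standardized(u: float, w: float, eps: float) -> float:
    """FPT density at the lower boundary for a=1, v=0, start w, at time u.

    Switches between the small-time and large-time series following the
    standard term-count criterion for truncation error ``eps``.
    """
    if u <= 0.0:
        return 0.0
    # number of terms required by each expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    if math.pi * u * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * eps) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        half = (K - 1) // 2
        acc = 0.0
        for k in range(-half, K - half):
            term = w + 2.0 * k
            acc += term * math.exp(-term * term / (2.0 * u))
        return acc / math.sqrt(2.0 * math.pi * u * u * u)
    # large-time expansion
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return acc * math.pi


@njit(cache=False)
def _wfpt_logpdf(t: float, upper: bool, a: float, v: float, z_rel: float, tau: float, err: float) -> float:
    """Log defective FPT density at time ``t`` for the given boundary."""
    tdec = t - tau
    if tdec <= 0.0:
        return -np.inf
    if upper:
        vv = -v
        ww = 1.0 - z_rel
    else:
        vv = v
        ww = z_rel
    u = tdec / (a * a)
    # drift/scale factor on the log scale; the series error is requested in
    # final density units, so rescale eps by the (inverse) factor
    log_scale = -vv * a * ww - vv * vv * tdec / 2.0 - 2.0 * math.log(a)
    eps = err * math.exp(min(-log_scale, 50.0))
    if eps > 1e-5:
        eps = 1e-5
    if eps < 1e-15:
        eps = 1e-15
    f = _fptd_standardized(u, ww, eps)
    if f <= 0.0:
        # series round-off can produce tiny negatives in far tails
        return -np.inf
    return math.log(f) + log_scale


@njit(cache=False)
def _loglik_vector(rt: np.ndarray, upper: np.ndarray, a: float, tau: float,
                   v: np.ndarray, z: np.ndarray, err: float) -> np.ndarray:
    out = np.empty(rt.shape[0])
    for i in range(rt.shape[0]):
        zi = z[i]
        if zi <= 0.0 or zi >= 1.0:
            out[i] = -np.inf
        else:
            out[i] = _wfpt_logpdf(rt[i], bool(upper[i]), a, v[i], zi, tau, err)
    return out


@njit(cache=False)
def _block_loglik(x1: np.ndarray, x2: np.ndarray, rt: np.ndarray,
                  upper: np.ndarray, a: float, tau: float, z0: float,
                  z1: float, v0: float, v1: float, v2: float, g: float,
                  use_ref: bool, err: float) -> float:
    """Total log-likelihood of one participant block with the internal
    reference threaded inline (hot path of the hierarchical sampler)."""
    total = 0.0
    I = 0.0
    for n in range(rt.shape[0]):
        if use_ref:
            I = x1[0] if n == 0 else g * I + (1.0 - g) * x1[n]
            ref = I
        else:
            ref = x1[n]
        v = v0 + v1 * ref + v2 * x2[n]
        z = z0 + z1 * ref
        if z <= 0.0 or z >= 1.0:
            return -np.inf
        ll = _wfpt_logpdf(rt[n], bool(upper[n]), a, v, z, tau, err)
        total += ll
        if total == -np.inf:
            return total
    return total


@njit(cache=False)
def _cohort_loglik(x1, x2, rt, upper, offsets, a_arr, tau_arr, z0_arr,
                   z1_arr, v0_arr, v1_arr, v2_arr, g_arr, use_ref: bool,
                   err: float) -> float:
    """Summed log-likelihood over all participant blocks (offsets delimit
    each participant's trials in the concatenated arrays)."""
    tot = 0.0
    for p in range(offsets.shape[0] - 1):
        s = offsets[p]
        e = offsets[p + 1]
        b = _block_loglik(x1[s:e], x2[s:e], rt[s:e], upper[s:e],
                          a_arr[p], tau_arr[p], z0_arr[p], z1_arr[p],
                          v0_arr[p], v1_arr[p], v2_arr[p], g_arr[p],
                          use_ref, err)
        if b == -np.inf:
            return -np.inf
        tot += b
    return tot


#: constant of the Broadie-Glasserman-Kou continuity correction,
#: -zeta(1/2)/sqrt(2*pi)
_BGK_BETA = 0.5825971579390107


def _simulate_trials(v: np.ndarray, z: np.ndarray, a: float, tau: float,
                     dt: float, time_cap: float, rng: np.random.Generator):
    """Euler-Maruyama simulation of one diffusion trial per (v, z) pair.

    All paths advance in lockstep, with absorbed paths dropped from the
    active set so the per-step cost shrinks as trials finish.  Because the
    path is only observed on the grid, crossings between grid points are
    missed and the boundaries effectively widen by ~0.5826*sqrt(dt); the
    standard continuity correction (testing against boundaries shifted
    inward by that amount) removes this O(sqrt(dt)) bias, so the simulated
    process matches the analytic first-passage law at the nominal
    boundaries.  Returns (choice_upper int8 array, rt array); censored
    trials get choice -1 and NaN rt.
    """
    n = v.shape[0]
    choice = np.full(n, -1, dtype=np.int8)
    n_steps = np.zeros(n, dtype=np.int64)
    sqdt = np.float32(math.sqrt(dt))
    max_steps = int(round(time_cap / dt))
    active = np.arange(n)
    # float32 path state: per-step rounding (~1e-7 of the boundary scale)
    # is far below the Euler discretization error at any sensible dt
    x = (z * a).astype(np.float32)
    drift = (v * dt).astype(np.float32)
    shift = _BGK_BETA * math.sqrt(dt)
    hi = np.float32(a - shift)
    lo = np.float32(shift)
    step = 0
    while active.size and step < max_steps:
        step += 1
        x += drift
        x += sqdt * rng.standard_normal(active.size, dtype=np.float32)
        up = x >= hi
        done = up | (x <= lo)
        if done.any():
            hit = active[done]
            choice[hit] = up[done]
            n_steps[hit] = step
            keep = ~done
            active = active[keep]
            x = x[keep]
            drift = drift[keep]
    rt = np.where(choice >= 0, n_steps * dt + tau, np.nan)
    return choice, rt


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _check_params(a: float, z_rel: float, tau: float) -> None:
    if not a > 0:
        raise ValueError(f"boundary separation a must be > 0, got {a}")
    if not 0 < z_rel < 1:
        raise ValueError(f"relative starting point must lie in (0, 1), got {z_rel}")
    if tau < 0:
        raise ValueError(f"non-decision time must be >= 0, got {tau}")


def wfpt_log_density(t: float, choice: str, a: float, v: float, z_rel: float,
                     tau: float, err: float = DEFAULT_ERR) -> float:
    """Log of the defective first-passage-time density at time ``t``.

    Parameters
    ----------
    t : float
        Response time in seconds (decision time is ``t - tau``).
    choice : {"upper", "lower"}
        Which absorbing boundary was hit.
    a, v, z_rel, tau : float
        Boundary separation, drift rate (evidence/s), relative starting
        point in (0, 1), and non-decision time (s).  Diffusion coefficient 1.
    err : float
        Truncation error bound of the series evaluation, in density units.

    Returns ``-inf`` for ``t <= tau`` (a legal likelihood value, not an
    error).  Invalid parameter domains raise ``ValueError`` instead.
    """
    _check_params(a, z_rel, tau)
    if choice not in ("upper", "lower"):
        raise ValueError(f"choice must be 'upper' or 'lower', got {choice!r}")
    return float(_wfpt_logpdf(float(t), choice == "upper", a, v, z_rel, tau, err))


def choice_probability_upper(a: float, v: float, z_rel: float) -> float:
    """Probability that the diffusion is absorbed at the upper boundary.

    Closed form ``(1 - exp(-2 v a z)) / (1 - exp(-2 v a))`` for nonzero
    drift, with the ``z_rel`` limit at ``v = 0``; evaluated stably via
    ``expm1`` for small arguments.
    """
    _check_params(a, z_rel, 1.0)
    x = 2.0 * v * a
    if abs(x) < 1e-9:
        return z_rel
    # stabilized: for large positive x the ratio approaches 1
    num = -math.expm1(-x * z_rel)
    den = -math.expm1(-x)
    return num / den


def loglik_participant(spec, params, trials, standard_ms: float = 500.0,
                       err: float = DEFAULT_ERR):
    """Wiener log-likelihood of one participant's responded trials.

    Trial drift/starting point are computed by
    :func:`contextddm.models.dataset_dynamics` (internal-reference state
    threaded across trials in presentation order), and each trial's response
    enters the defective density with ``first_longer`` mapped to the upper
    boundary.

    Parameters
    ----------
    spec : contextddm.models.ModelSpec
    params : contextddm.models.IndividualParameters
    trials : pandas.DataFrame
        One participant's trials ordered by ``trial_index``, with
        ``dur1_ms``, ``dur2_ms``, ``response`` and ``rt_s`` present.
    standard_ms : float
        Duration used to center the stimulus regressors.

    Returns
    -------
    (total, per_trial) : tuple of float and ndarray
        Trials with ``rt <= tau`` (or out-of-range starting point)
        contribute ``-inf``; they are reported, never raised.
    """
    from .models import dataset_dynamics

    v_n, z_n, _ = dataset_dynamics(spec, params, trials, standard_ms=standard_ms,
                                   as_arrays=True)
    rt = np.ascontiguousarray(trials["rt_s"].to_numpy(dtype=float))
    upper = np.ascontiguousarray(
        (trials["response"].to_numpy() == "first_longer").astype(np.uint8))
    if np.isnan(rt).any():
        raise ValueError("loglik_participant requires responses/RTs on every trial")
    per_trial = _loglik_vector(rt, upper, params.a, params.tau,
                               np.ascontiguousarray(v_n),
                               np.ascontiguousarray(z_n), err)
    return float(per_trial.sum()), per_trial


def simulate_choice_rt(a: float, v: float, z_rel: float, tau: float,
                       dt: float = DEFAULT_DT, rng=None,
                       time_cap: float = DEFAULT_TIME_CAP) -> ChoiceRT:
    """Simulate one diffusion trial by the Euler-Maruyama scheme.

    The path starts at ``z_rel * a`` and steps by ``v dt + sqrt(dt) N(0,1)``
    until absorption; the reported RT is first-passage time plus ``tau``.
    Reproducible given a seeded ``numpy.random.Generator``.
    """
    _check_params(a, z_rel, tau)
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(rng)
    choice, rt = _simulate_trials(np.array([v]), np.array([z_rel]), a, tau,
                                  dt, time_cap, rng)
    if choice[0] < 0:
        return ChoiceRT("censored", float("nan"), censored=True)
    return ChoiceRT("upper" if choice[0] == 1 else "lower", float(rt[0]))


def simulate_trials_batch(v: np.ndarray, z: np.ndarray, a: float, tau: float,
                          dt: float = DEFAULT_DT, rng=None,
                          time_cap: float = DEFAULT_TIME_CAP):
    """Vectorized Euler-Maruyama simulation, one trial per (v, z) entry.

    Returns ``(choice_upper, rt)`` where censored trials carry choice -1
    and NaN rt.
    """
    rng = np.random.default_rng(rng)
    v = np.ascontiguousarray(v, dtype=float)
    z = np.ascontiguousarray(z, dtype=float)
    if np.any(z <= 0) or np.any(z >= 1):
        raise ValueError("all relative starting points must lie in (0, 1)")
    return _simulate_trials(v, z, a, tau, dt, time_cap, rng)


def simulate_experiment(design, spec, params_by_participant: dict,
                        rng=None, dt: float = DEFAULT_DT,
                        time_cap: float = DEFAULT_TIME_CAP):
    """Simulate a full experiment dataset from a model variant.

    For each participant the design's trial skeleton is generated (seeded
    from ``rng``), trial dynamics are threaded across the realized stimulus
    sequence, and each trial is simulated with the Euler scheme.  Simulated
    upper-boundary absorptions map back to ``first_longer`` responses.

    Censored (non-absorbed) trials are dropped with a count recorded in the
    dataset provenance.

    Parameters
    ----------
    design : contextddm.datasets.ExperimentDesign
    spec : contextddm.models.ModelSpec
    params_by_participant : dict
        Mapping participant id -> IndividualParameters.
    rng : seed or numpy.random.Generator

    Returns
    -------
    contextddm.datasets.Dataset
    """
    import pandas as pd

    from .datasets import Dataset, generate_design_trials
    from .models import dataset_dynamics

    rng = np.random.default_rng(rng)
    frames = []
    n_censored = 0
    for pid, params in params_by_participant.items():
        skeleton = generate_design_trials(
            design, participant_ids=[pid],
            seed=int(rng.integers(0, 2**31 - 1))).trials
        v_n, z_n, _ = dataset_dynamics(spec, params, skeleton,
                                       standard_ms=design.standard_ms,
                                       as_arrays=True)
        if np.any(z_n <= 0) or np.any(z_n >= 1):
            raise ValueError(
                f"participant {pid}: trial starting point outside (0, 1); "
                "cannot simulate")
        choice, rt = simulate_trials_batch(v_n, z_n, params.a, params.tau,
                                           dt=dt, rng=rng, time_cap=time_cap)
        frame = skeleton.copy()
        frame["response"] = np.where(choice == 1, "first_longer", "second_longer")
        frame["rt_s"] = rt
        keep = choice >= 0
        n_censored += int((~keep).sum())
        frames.append(frame.loc[keep])
    trials = pd.concat(frames, ignore_index=True)
    provenance = f"simulated spec={spec.model_number}"
    if n_censored:
        import warnings

        warnings.warn(f"{n_censored} simulated trials were censored at the "
                      f"{time_cap} s cap and dropped")
        provenance += f"; censored_trials={n_censored}"
    return Dataset(trials, design=design, provenance=provenance)
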