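"""Trial-level drift and starting-point rules for the seven diffusion-model
variants of two-interval duration discrimination.

All variants share the linear drift rule

    v_n = v0 + v1 * ref_n + v2 * X2_n,       ref_n = I_n or X1_n,

where X1, X2 are the stimulus durations centered on the standard (ms) and
I_n is the internal reference, a geometrically weighted average of first
stimuli updated every trial:

    I_n = g * I_{n-1} + (1 - g) * X1_n,      0 <= g <= 1.

With g = 0 the reference collapses to the current first stimulus and the
model reduces to a plain difference/sensation-weighting form.  When the two
stimuli share a single difference weight, v2 is tied to -v1.  Variants 5-7
additionally let the starting point vary with the first interval:

    z_n = z0 + z1 * ref_n.

The three structural switches (reference updating, separate weights,
starting-point regression) generate the model family; see
:data:`MODEL_NUMBERS` for the canonical numbering.

Stimulus slopes (v1, v2, z1) are per-millisecond; drift is evidence per
second under a unit diffusion coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "ModelSpec",
    "IndividualParameters",
    "TrialDynamics",
    "InvalidDynamicsError",
    "MODEL_NUMBERS",
    "TRANSFORMS",
    "constrain",
    "unconstrain",
    "update_internal_reference",
    "reference_trajectory",
    "trial_dynamics",
    "dataset_dynamics",
    "sample_individual_parameters",
]

#: unconstrained-scale transform per parameter: positive parameters are
#: sampled on the log scale, unit-interval parameters on the logit scale
TRANSFORMS = {"a": "log", "tau": "log", "z0": "logit", "g": "logit",
              "v0": "identity", "v1": "identity", "v2": "identity",
              "z1": "identity"}


def constrain(name: str, u):
    """Map an unconstrained value to the parameter's natural support."""
    t = TRANSFORMS[name]
    if t == "log":
        return np.exp(u)
    if t == "logit":
        return 1.0 / (1.0 + np.exp(-np.asarray(u, dtype=float)))
    return u


def unconstrain(name: str, x):
    """Inverse of :func:`constrain`."""
    t = TRANSFORMS[name]
    if t == "log":
        return np.log(x)
    if t == "logit":
        x = np.asarray(x, dtype=float)
        return np.log(x / (1.0 - x))
    return x

#: (use_internal_reference, separate_weights, start_point_regression) -> model number
MODEL_NUMBERS = {
    (False, False, False): 1,
    (True, False, False): 2,
    (False, True, False): 3,
    (True, True, False): 4,
    (True, False, True): 5,
    (False, True, True): 6,
    (True, True, True): 7,
}
_FLAGS_BY_NUMBER = {n: f for f, n in MODEL_NUMBERS.items()}


class InvalidDynamicsError(ValueError):
    """A trial's starting point left (0, 1).

    Fitting code treats this as log-likelihood -inf rather than an error;
    the exception exists for direct API use.
    """


@dataclass(frozen=True)
class ModelSpec:
    """Structural switches selecting one of the seven model variants."""

    use_internal_reference: bool = False
    separate_weights: bool = False
    start_point_regression: bool = False

    @classmethod
    def from_number(cls, number: int) -> "ModelSpec":
        if number not in _FLAGS_BY_NUMBER:
            raise ValueError(f"model number must be 1..7, got {number}")
        return cls(*_FLAGS_BY_NUMBER[number])

    @property
    def model_number(self) -> int:
        return MODEL_NUMBERS[(self.use_internal_reference,
                              self.separate_weights,
                              self.start_point_regression)]

    @property
    def n_free_parameters(self) -> int:
        """Free individual-level parameters: a, tau, z0, v0, v1 always;
        plus g, v2, z1 per switch."""
        return (5 + self.use_internal_reference + self.separate_weights
                + self.start_point_regression)

    @property
    def parameter_names(self) -> tuple:
        names = ["a", "tau", "z0", "v0", "v1"]
        if self.separate_weights:
            names.append("v2")
        if self.start_point_regression:
            names.append("z1")
        if self.use_internal_reference:
            names.append("g")
        return tuple(names)


@dataclass(frozen=True)
class IndividualParameters:
    """One participant's diffusion + comparison-rule parameters.

    ``v2`` and ``z1`` may be supplied for any spec; specs without separate
    weights ignore the stored v2 and use -v1, specs without the
    starting-point regression use z1 = 0, and g is ignored unless the
    internal reference is active.
    """

    a: float
    tau: float
    z0: float
    v0: float
    v1: float
    v2: float = 0.0
    z1: float = 0.0
    g: float = 0.0

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError(f"boundary separation a must be > 0, got {self.a}")
        if self.tau < 0:
            raise ValueError(f"non-decision time must be >= 0, got {self.tau}")
        if not 0 < self.z0 < 1:
            raise ValueError(f"z0 must lie in (0, 1), got {self.z0}")
        if not 0 <= self.g <= 1:
            raise ValueError(f"reference weight g must lie in [0, 1], got {self.g}")

    def effective(self, spec: ModelSpec) -> tuple:
        """(v2, z1, g) actually used under ``spec``."""
        v2 = self.v2 if spec.separate_weights else -self.v1
        z1 = self.z1 if spec.start_point_regression else 0.0
        g = self.g if spec.use_internal_reference else 0.0
        return v2, z1, g

    def as_dict(self, spec: ModelSpec) -> dict:
        v2, z1, g = self.effective(spec)
        full = {"a": self.a, "tau": self.tau, "z0": self.z0, "v0": self.v0,
                "v1": self.v1, "v2": v2, "z1": z1, "g": g}
        return {k: full[k] for k in spec.parameter_names}


@dataclass(frozen=True)
class TrialDynamics:
    """Per-trial drift, starting point, and internal-reference state."""

    v_n: float
    z_n: float
    I_n: float


def update_internal_reference(I_prev: float, X1: float, g: float) -> float:
    """One step of the geometric reference update g*I_prev + (1-g)*X1."""
    if not 0 <= g <= 1:
        raise ValueError(f"reference weight g must lie in [0, 1], got {g}")
    return g * I_prev + (1.0 - g) * X1


def reference_trajectory(X1_sequence, g: float) -> np.ndarray:
    """Internal-reference sequence over a session.

    The reference is initialized at the first trial's first stimulus
    (I_1 = X1_1), so trial 1 behaves identically with and without reference
    updating, and follows the geometric update thereafter.  Implemented as
    a first-order linear filter.
    """
    if not 0 <= g <= 1:
        raise ValueError(f"reference weight g must lie in [0, 1], got {g}")
    x = np.asarray(X1_sequence, dtype=float)
    if x.size == 0:
        raise ValueError("reference_trajectory requires a non-empty sequence")
    if g == 0:
        return x.copy()
    # y[n] = (1-g) x[n] + g y[n-1], with state preloaded so y[0] = x[0]
    y, _ = lfilter([1.0 - g], [1.0, -g], x, zi=[g * x[0]])
    return y


def sample_individual_parameters(group_means: dict, group_sds: dict,
                                 n: int, rng=None, prefix: str = "p") -> dict:
    """Draw a synthetic cohort around group-level parameter values.

    ``group_means`` are on the natural (constrained) scale; ``group_sds``
    are standard deviations on the unconstrained scale (log/logit for the
    bounded parameters), matching the Gaussian hyper-distribution used in
    hierarchical fitting.  Parameters missing from ``group_sds`` are held
    constant across the cohort.  Returns {participant_id:
    IndividualParameters}.
    """
    rng = np.random.default_rng(rng)
    out = {}
    for i in range(n):
        vals = {}
        for name, mean in group_means.items():
            u = float(unconstrain(name, mean))
            u += group_sds.get(name, 0.0) * rng.standard_normal()
            vals[name] = float(constrain(name, u))
        out[f"{prefix}{i + 1:02d}"] = IndividualParameters(**vals)
    return out


def _centered(trials, standard_ms: float):
    x1 = trials["dur1_ms"].to_numpy(dtype=float) - standard_ms
    x2 = trials["dur2_ms"].to_numpy(dtype=float) - standard_ms
    return x1, x2


def trial_dynamics(spec: ModelSpec, params: IndividualParameters, trial,
                   I_prev: float | None = None,
                   standard_ms: float = 500.0) -> TrialDynamics:
    """Drift and starting point of a single trial.

    ``trial`` is a mapping/row with ``dur1_ms`` and ``dur2_ms``.  ``I_prev``
    is the reference state carried in from the previous trial (centered ms);
    ``None`` marks the participant's first trial, where the reference is
    initialized at the current X1.

    Raises :class:`InvalidDynamicsError` if the computed starting point
    leaves (0, 1).
    """
    x1 = float(trial["dur1_ms"]) - standard_ms
    x2 = float(trial["dur2_ms"]) - standard_ms
    v2, z1, g = params.effective(spec)
    if spec.use_internal_reference:
        I_n = x1 if I_prev is None else update_internal_reference(I_prev, x1, g)
    else:
        I_n = x1
    ref = I_n
    v_n = params.v0 + params.v1 * ref + v2 * x2
    z_n = params.z0 + z1 * ref
    if not 0 < z_n < 1:
        raise InvalidDynamicsError(
            f"starting point {z_n:.4f} outside (0, 1) on trial with "
            f"dur1={trial['dur1_ms']}, dur2={trial['dur2_ms']}")
    return TrialDynamics(v_n=v_n, z_n=z_n, I_n=I_n)


def dataset_dynamics(spec: ModelSpec, params: IndividualParameters, trials,
                     standard_ms: float = 500.0, as_arrays: bool = False):
    """Dynamics of one participant's full session, reference state threaded
    across trials in presentation order.

    ``trials`` must be ordered by ``trial_index`` (ascending).  Returns a
    list of :class:`TrialDynamics`, or with ``as_arrays=True`` the tuple
    ``(v_n, z_n, I_n)`` of ndarrays (starting points NOT range-checked, so
    fitting code can map violations to -inf likelihood itself).
    """
    idx = trials["trial_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be ordered by ascending trial_index")
    x1, x2 = _centered(trials, standard_ms)
    v2, z1, g = params.effective(spec)
    if spec.use_internal_reference:
        I = reference_trajectory(x1, g)
    else:
        I = x1
    v_n = params.v0 + params.v1 * I + v2 * x2
    z_n = params.z0 + z1 * I
    if as_arrays:
        return v_n, z_n, I
    out = []
    for v, z, i_n, d1, d2 in zip(v_n, z_n, I, x1, x2):
        if not 0 < z < 1:
            raise InvalidDynamicsError(
                f"starting point {z:.4f} outside (0, 1) on trial with "
                f"dur1={d1 + standard_ms}, dur2={d2 + standard_ms}")
        out.append(TrialDynamics(v_n=float(v), z_n=float(z), I_n=float(i_n)))
    return out
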