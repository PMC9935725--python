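"""Per-participant psychometric functions and order-dependent context
effects.

For each participant a logistic regression predicts the probability of a
"comparison longer" response from the comparison duration (centered on the
standard), the presentation order, and their interaction.  From the
per-order curves follow:

* PSE (point of subjective equality): the duration at which both responses
  are equally likely, ``standard - b0/b`` for a per-order curve with
  intercept b0 and slope b (logit/ms).
* DL (difference limen): half the 25%-75% percentile distance of the
  psychometric function, analytically ``ln(3)/b``.
* Type A effect: ``pse_sc - pse_cs`` -- an order-dependent shift of the
  PSE (the time-order error).
* Type B effect: ``dl_sc - dl_cs`` -- an order-dependent change in
  discrimination sensitivity.  Negative values are the classical pattern:
  discrimination is better (smaller DL) when the standard precedes the
  comparison.

The sign conventions above are fixed package-wide.

In the drift-regression parametrization, stimulus weights map to drift
slopes as w1 = v1 and w2 = -v2 (the second stimulus is subtracted, and
fitted v2 is negative when both weights are positive); the proportional
weight difference (w1 - w2)/(w1 + w2) is the model-side predictor of the
Type B effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PsychometricFit",
    "ContextEffects",
    "fit_psychometric",
    "pse",
    "dl",
    "context_effects",
    "proportional_weight_difference",
    "correlate_weights_effects",
    "effects_table",
]


@dataclass(frozen=True)
class PsychometricFit:
    """Per-order logistic curves for one participant.

    ``beta0`` are intercepts (logit units at the standard duration) and
    ``beta`` slopes (logit per ms of comparison duration), keyed by order.
    """

    beta0: dict
    beta: dict
    standard_ms: float
    method: str
    converged: bool = True

    def predict(self, order: str, comparison_ms):
        x = np.asarray(comparison_ms, dtype=float) - self.standard_ms
        eta = self.beta0[order] + self.beta[order] * x
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class ContextEffects:
    pse_sc: float
    pse_cs: float
    dl_sc: float
    dl_cs: float
    type_a: float
    type_b: float
    prop_weight_diff: float | None = None


def _comparison_longer(trials: pd.DataFrame) -> np.ndarray:
    """1 when the response favored the comparison stimulus."""
    first_longer = trials["response"].to_numpy() == "first_longer"
    sc = trials["order"].to_numpy() == "sc"
    # on sc trials the comparison came second
    return np.where(sc, ~first_longer, first_longer).astype(float)


def _comparison_duration(trials: pd.DataFrame) -> np.ndarray:
    sc = trials["order"].to_numpy() == "sc"
    return np.where(sc, trials["dur2_ms"].to_numpy(float),
                    trials["dur1_ms"].to_numpy(float))


def fit_psychometric(trials: pd.DataFrame, standard_ms: float = 500.0,
                     method: str = "ml", prior_scale: float = 5.0) -> PsychometricFit:
    """Fit the order-by-duration logistic model for one participant.

    The linear predictor is ``b0 + b1*x + b2*cs + b3*x*cs`` with x the
    centered comparison duration and cs an indicator for comparison-first
    trials; per-order intercepts/slopes are recovered from the
    coefficients.  ``method="ml"`` is plain maximum likelihood;
    ``method="bayes"`` is a maximum a posteriori fit under weak zero-mean
    Gaussian priors (scale ``prior_scale`` on standardized coefficients),
    which also serves as the fallback under complete separation.  Both
    agree in the large-data limit.
    """
    resp = trials[trials["response"].notna()]
    y = _comparison_longer(resp)
    x = _comparison_duration(resp) - standard_ms
    cs = (resp["order"].to_numpy() == "cs").astype(float)
    for o in ("sc", "cs"):
        lv = np.unique(x[cs == (o == "cs")])
        if lv.size < 2:
            raise ValueError(f"order {o!r} needs >= 2 comparison levels")
    X = np.column_stack([np.ones_like(x), x, cs, x * cs])

    def _map_fit():
        from scipy.optimize import minimize

        scale = np.array([prior_scale, prior_scale / 100.0,
                          prior_scale, prior_scale / 100.0])

        def nlp(b):
            eta = X @ b
            nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
            return nll + 0.5 * np.sum((b / scale) ** 2)

        res = minimize(nlp, np.zeros(4), method="BFGS")
        return res.x, bool(res.success)

    converged = True
    if method == "bayes":
        coef, converged = _map_fit()
    elif method == "ml":
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(y, X, family=sm.families.Binomial())
                res = model.fit(maxiter=200)
            coef = res.params
            # slopes beyond ~0.3 logit/ms mean a difference limen under
            # 4 ms -- a separation artifact, not a credible psychometric
            if (not np.all(np.isfinite(coef))
                    or np.abs(coef[[1, 3]]).max() > 0.3
                    or np.abs(coef[[0, 2]]).max() > 30.0):
                raise RuntimeError("separation-like solution")
        except Exception:
            warnings.warn("maximum likelihood failed (separation?); "
                          "falling back to weakly regularized fit")
            coef, converged = _map_fit()
            method = "ml+fallback"
    else:
        raise ValueError(f"unknown method {method!r}")

    b0, b1, b2, b3 = (float(c) for c in coef)
    return PsychometricFit(
        beta0={"sc": b0, "cs": b0 + b2},
        beta={"sc": b1, "cs": b1 + b3},
        standard_ms=standard_ms, method=method, converged=converged)


def pse(fit: PsychometricFit, order: str) -> float:
    """Point of subjective equality: duration where the curve crosses 50%."""
    b = fit.beta[order]
    if b == 0.0:
        raise ZeroDivisionError("PSE undefined for a flat psychometric curve")
    return fit.standard_ms - fit.beta0[order] / b


def dl(fit: PsychometricFit, order: str) -> float:
    """Difference limen: (75th - 25th percentile)/2 = ln(3)/slope."""
    b = fit.beta[order]
    if b <= 0.0:
        raise ValueError("DL undefined for non-positive psychometric slope")
    return math.log(3.0) / b


def context_effects(fit: PsychometricFit, v1: float | None = None,
                    v2: float | None = None) -> ContextEffects:
    """Type A and Type B effects from per-order curves.

    ``type_a = pse_sc - pse_cs``; ``type_b = dl_sc - dl_cs`` (negative =
    classical pattern, better discrimination with the standard first).
    Optionally attaches the proportional weight difference when drift
    weights are supplied.
    """
    eff = ContextEffects(
        pse_sc=pse(fit, "sc"), pse_cs=pse(fit, "cs"),
        dl_sc=dl(fit, "sc"), dl_cs=dl(fit, "cs"),
        type_a=pse(fit, "sc") - pse(fit, "cs"),
        type_b=dl(fit, "sc") - dl(fit, "cs"),
        prop_weight_diff=(proportional_weight_difference(v1, v2)
                          if v1 is not None and v2 is not None else None))
    return eff


def proportional_weight_difference(v1: float, v2: float) -> float:
    """(w1 - w2)/(w1 + w2) with weight magnitudes w1 = v1, w2 = -v2.

    The drift regression subtracts the second stimulus, so a fitted v2 < 0
    corresponds to a positive weight magnitude w2 = -v2; the proportional
    difference is computed on magnitudes (raw coefficients would make the
    denominator near-degenerate).
    """
    w1, w2 = v1, -v2
    if w1 + w2 <= 0:
        raise ValueError("weight magnitudes must sum to a positive value")
    return (w1 - w2) / (w1 + w2)


def correlate_weights_effects(weight_diffs, effects) -> float:
    """Pearson correlation across participants, with listwise deletion."""
    x = np.asarray(weight_diffs, dtype=float)
    y = np.asarray(effects, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} participant(s) with missing values")
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need >= 3 complete participant pairs")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def effects_table(dataset, standard_ms: float | None = None,
                  method: str = "ml", weights: dict | None = None) -> pd.DataFrame:
    """Per-participant context-effects table.

    ``weights`` optionally maps participant id -> (v1, v2) drift weights
    (e.g. posterior means of an individual-level fit) to attach the
    proportional weight difference.
    """
    if standard_ms is None:
        standard_ms = dataset.design.standard_ms if dataset.design else 500.0
    rows = []
    for pid in dataset.participants:
        trials = dataset.participant_trials(pid)
        f = fit_psychometric(trials, standard_ms=standard_ms, method=method)
        v1 = v2 = None
        if weights and pid in weights:
            v1, v2 = weights[pid]
        e = context_effects(f, v1=v1, v2=v2)
        rows.append({"participant_id": pid, "pse_sc": e.pse_sc,
                     "pse_cs": e.pse_cs, "dl_sc": e.dl_sc, "dl_cs": e.dl_cs,
                     "type_a": e.type_a, "type_b": e.type_b,
                     "prop_weight_diff": e.prop_weight_diff})
    return pd.DataFrame(rows)
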