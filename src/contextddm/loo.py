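"""Approximate leave-one-out cross-validation by Pareto-smoothed
importance sampling (PSIS-LOO).

Models are compared on their expected log pointwise predictive density
(elpd): for each trial the leave-one-out predictive density is estimated
from the full-data posterior draws by importance sampling, with the raw
importance ratios stabilized by a generalized-Pareto fit to their largest
values (tail size min(0.2 S, 3 sqrt(S)), weights truncated at
S^(3/4) times the mean weight).  The Pareto shape diagnostic k flags trials
whose importance weights are too heavy-tailed to trust (k > 0.7).

The Pareto smoothing itself is delegated to ``arviz.psislw``; the pointwise
log-likelihood extraction, elpd arithmetic and paired model comparison are
implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datasets import Dataset
from .inference import PosteriorDraws
from .models import reference_trajectory
from .wiener import _loglik_vector, DEFAULT_ERR

__all__ = ["PointwiseLogLik", "LooResult", "pointwise_loglik", "psis_loo",
           "elpd_compare"]

PARETO_K_WARN = 0.7


@dataclass
class PointwiseLogLik:
    """Per-draw, per-trial log-likelihood matrix (S draws x N trials)."""

    values: np.ndarray
    trial_ids: list
    n_draws: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_draws = self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]


@dataclass
class LooResult:
    """PSIS-LOO estimate: total elpd, its SE, and per-trial diagnostics."""

    elpd: float
    se: float
    pointwise: np.ndarray
    pareto_k: np.ndarray
    trial_ids: list = field(default_factory=list)

    @property
    def n_high_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def pointwise_loglik(spec, draws: PosteriorDraws, dataset: Dataset,
                     err: float = DEFAULT_ERR,
                     standard_ms: float | None = None) -> PointwiseLogLik:
    """Log-likelihood of every clean trial under every posterior draw.

    The internal-reference state is recomputed per draw (the reference
    trajectory depends on g), so entry (s, n) is the exact per-trial log
    density under draw s's individual-level parameters.  Trials are ordered
    by (participant, trial_index); ids are (participant_id, trial_index)
    tuples.
    """
    if spec.model_number != draws.spec.model_number:
        raise ValueError("spec does not match the fitted draws")
    if standard_ms is None:
        standard_ms = draws.metadata.get("standard_ms",
                                         dataset.design.standard_ms
                                         if dataset.design else 500.0)
    missing = [p for p in dataset.participants if p not in draws.participants]
    if missing:
        raise ValueError(f"draws lack participants {missing}")

    blocks, trial_ids = [], []
    for pid in dataset.participants:
        t = dataset.participant_trials(pid)
        t = t[t["response"].notna() & t["rt_s"].notna()]
        blocks.append((pid, {
            "x1": np.ascontiguousarray(t["dur1_ms"].to_numpy(float) - standard_ms),
            "x2": np.ascontiguousarray(t["dur2_ms"].to_numpy(float) - standard_ms),
            "rt": np.ascontiguousarray(t["rt_s"].to_numpy(float)),
            "upper": np.ascontiguousarray(
                (t["response"].to_numpy() == "first_longer").astype(np.uint8)),
        }))
        trial_ids.extend((pid, int(i)) for i in t["trial_index"])

    S = draws.n_chains * draws.n_draws
    N = len(trial_ids)
    out = np.empty((S, N))
    for s, (c, t_idx) in enumerate(draws.draw_indices()):
        params = draws.individual_parameters(c, t_idx)
        col = 0
        for pid, d in blocks:
            q = params[pid]
            n = d["rt"].shape[0]
            if spec.use_internal_reference and q.g > 0.0:
                ref = reference_trajectory(d["x1"], q.g)
            else:
                ref = d["x1"]
            v2, z1, _ = q.effective(spec)
            v_n = q.v0 + q.v1 * ref + v2 * d["x2"]
            z_n = q.z0 + z1 * ref
            out[s, col:col + n] = _loglik_vector(
                d["rt"], d["upper"], q.a, q.tau,
                np.ascontiguousarray(v_n), np.ascontiguousarray(z_n), err)
            col += n
    return PointwiseLogLik(values=out, trial_ids=trial_ids)


def psis_loo(ll: PointwiseLogLik) -> LooResult:
    """PSIS approximate leave-one-out elpd from a pointwise matrix.

    Trials whose log-likelihood is -inf under every draw cannot be scored;
    they are excluded with a warning.  ``se = sqrt(n var(pointwise))``.
    """
    import arviz as az

    values = ll.values
    if values.shape[0] < 100:
        raise ValueError(f"psis_loo requires >= 100 draws, got {values.shape[0]}")
    dead = np.all(~np.isfinite(values), axis=0)
    ids = list(ll.trial_ids)
    if dead.any():
        warnings.warn(f"{int(dead.sum())} trials have -inf log-likelihood "
                      "under every draw; excluded from LOO")
        values = values[:, ~dead]
        ids = [i for i, d in zip(ids, dead) if not d]

    # importance ratios are 1/p(y_i | theta_s); psislw smooths along the
    # draw axis, which it expects last
    with np.errstate(invalid="ignore"):
        lw, k = az.psislw(-values.T, reff=1.0)
        pointwise = logsumexp(np.asarray(lw) + values.T, axis=1)
    pointwise = np.asarray(pointwise, dtype=float)
    k = np.asarray(k, dtype=float)
    # trials whose log-likelihood is constant across draws need no
    # reweighting: the Pareto fit is undefined there, not alarming
    degenerate = np.ptp(values, axis=0) < 1e-10
    if degenerate.any():
        S = values.shape[0]
        pointwise[degenerate] = logsumexp(values[:, degenerate],
                                          axis=0) - np.log(S)
        k[degenerate] = 0.0
    n = pointwise.shape[0]
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n * pointwise.var(ddof=0))) if n > 1 else 0.0
    if np.sum(k > PARETO_K_WARN):
        warnings.warn(f"{int(np.sum(k > PARETO_K_WARN))} trials have Pareto "
                      f"k > {PARETO_K_WARN}; their LOO contributions may be "
                      "unreliable")
    return LooResult(elpd=elpd, se=se, pointwise=pointwise, pareto_k=k,
                     trial_ids=ids)


def elpd_compare(results: dict) -> pd.DataFrame:
    """Rank models by elpd and difference each against the best.

    ``results`` maps model labels to :class:`LooResult` computed on the
    identical trial set.  Difference SEs come from the paired pointwise
    contributions, sqrt(n var(elpd_i^A - elpd_i^best)); the best model's
    difference and SE are 0 by construction.
    """
    labels = list(results)
    if len(labels) < 1:
        raise ValueError("nothing to compare")
    ref_ids = results[labels[0]].trial_ids
    for lab in labels[1:]:
        if results[lab].trial_ids != ref_ids:
            raise ValueError(f"model {lab!r} was scored on a different trial set")
    best = max(labels, key=lambda lab: results[lab].elpd)
    rows = []
    for lab in labels:
        r = results[lab]
        diff_pw = r.pointwise - results[best].pointwise
        n = diff_pw.shape[0]
        rows.append({
            "model": lab,
            "elpd": r.elpd,
            "se": r.se,
            "elpd_diff": float(diff_pw.sum()),
            "se_diff": float(np.sqrt(n * diff_pw.var(ddof=0))),
            "n_high_k": r.n_high_k,
        })
    table = pd.DataFrame(rows).sort_values("elpd", ascending=False)
    return table.reset_index(drop=True)
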