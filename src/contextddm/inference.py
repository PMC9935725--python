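"""Hierarchical Bayesian estimation of the diffusion-model variants.

Model structure
---------------
Each individual-level parameter is sampled on an unconstrained scale
(log for boundary separation and non-decision time, logit for the
starting-point intercept and the reference weight, identity otherwise).
For every parameter a Gaussian hyper-distribution is estimated:

    theta_ik ~ Normal(mu_k, sigma_k)        (unconstrained scale)
    mu_k     ~ Normal(m0_k, s0_k)
    sigma_k  ~ HalfNormal(s_hn_k)

and the Wiener likelihood of participant i's trials is evaluated at the
constrained transforms of theta_i.  Because the sampled variables are the
unconstrained ones, the transforms need no separate Jacobian terms in the
individual-level density; the half-normal hyper-sd is sampled on the log
scale with its Jacobian included.

Sampling
--------
The posterior factorizes over participants given the hyper-parameters, so a
blocked Metropolis-within-Gibbs scheme is used: each participant's
parameter block is updated by directional slice sampling with directions
drawn from a proposal covariance adapted during warm-up; hyper-means by
their exact conjugate Gaussian conditional and hyper-sds by univariate
slice sampling; and, because the centered parametrization mixes slowly
along the direction where a group mean and all its individual values move
together, interweaved (ancillarity-sufficiency) group shift/scale moves
re-update the hyper-parameters with the individual deviations held fixed.
Any sampler meeting the split R-hat < 1.01 convergence contract would do;
this one is chosen because the conditional independence structure makes the
per-sweep cost linear in participants and trials and it needs no gradients
of the Wiener density.

Defaults mirror common practice for this model class: 4 chains, 2000
iterations each, the first 50% discarded as warm-up, convergence declared
only when every parameter's split R-hat is below 1.01.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from .datasets import Dataset
from .models import (ModelSpec, IndividualParameters, TRANSFORMS, constrain,
                     unconstrain)
from .wiener import _block_loglik, _cohort_loglik, DEFAULT_ERR

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "fit",
    "fit_until_converged",
    "log_posterior",
    "rhat",
    "hdi",
    "posterior_mode",
    "load_draws",
]

_DEFAULT_HYPER_MEAN = {
    "a": (0.0, 1.0), "tau": (-1.5, 1.0), "z0": (0.0, 1.0), "g": (0.0, 1.0),
    "v0": (0.0, 2.0), "v1": (0.0, 0.1), "v2": (0.0, 0.1), "z1": (0.0, 0.1),
}
_DEFAULT_HYPER_SD_SCALE = {name: 0.5 for name in TRANSFORMS}


@dataclass(frozen=True)
class PriorSpec:
    """Hyper-priors per parameter, on the unconstrained scale.

    ``hyper_mean[name] = (location, scale)`` of the Gaussian prior on the
    group mean; ``hyper_sd_scale[name]`` the scale of the half-normal prior
    on the group standard deviation.  These are weakly informative defaults
    declared as configuration, not constants; every fit records the priors
    it used in the posterior metadata.
    """

    hyper_mean: dict = field(default_factory=lambda: dict(_DEFAULT_HYPER_MEAN))
    hyper_sd_scale: dict = field(default_factory=lambda: dict(_DEFAULT_HYPER_SD_SCALE))

    def describe(self) -> dict:
        return {"transforms": dict(TRANSFORMS),
                "hyper_mean": {k: list(v) for k, v in self.hyper_mean.items()},
                "hyper_sd_scale": dict(self.hyper_sd_scale)}


# ---------------------------------------------------------------------------
# model internals
# ---------------------------------------------------------------------------


class _HierarchicalModel:
    """Precomputed per-participant arrays and density pieces."""

    def __init__(self, spec: ModelSpec, priors: PriorSpec, dataset: Dataset,
                 standard_ms: float | None = None, err: float = DEFAULT_ERR):
        self.spec = spec
        self.priors = priors
        self.err = err
        if standard_ms is None:
            standard_ms = dataset.design.standard_ms if dataset.design else 500.0
        self.standard_ms = standard_ms
        self.names = list(spec.parameter_names)
        self.K = len(self.names)
        self.participants = dataset.participants
        self.P = len(self.participants)
        self.data = []
        for pid in self.participants:
            t = dataset.participant_trials(pid)
            t = t[t["response"].notna() & t["rt_s"].notna()]
            self.data.append({
                "x1": np.ascontiguousarray(t["dur1_ms"].to_numpy(float) - standard_ms),
                "x2": np.ascontiguousarray(t["dur2_ms"].to_numpy(float) - standard_ms),
                "rt": np.ascontiguousarray(t["rt_s"].to_numpy(float)),
                "upper": np.ascontiguousarray(
                    (t["response"].to_numpy() == "first_longer").astype(np.uint8)),
            })
        self.m0 = np.array([priors.hyper_mean[n][0] for n in self.names])
        self.s0 = np.array([priors.hyper_mean[n][1] for n in self.names])
        self.s_hn = np.array([priors.hyper_sd_scale[n] for n in self.names])
        self._i = {n: k for k, n in enumerate(self.names)}

    def constrained(self, theta_u: np.ndarray) -> dict:
        return {n: float(constrain(n, theta_u[self._i[n]])) for n in self.names}

    def _constrained_full(self, theta_u: np.ndarray) -> tuple:
        """(a, tau, z0, z1, v0, v1, v2, g) with structural defaults."""
        i = self._i
        a = math.exp(theta_u[i["a"]])
        tau = math.exp(theta_u[i["tau"]])
        z0 = 1.0 / (1.0 + math.exp(-theta_u[i["z0"]]))
        v0 = theta_u[i["v0"]]
        v1 = theta_u[i["v1"]]
        v2 = theta_u[i["v2"]] if "v2" in i else -v1
        z1 = theta_u[i["z1"]] if "z1" in i else 0.0
        g = 1.0 / (1.0 + math.exp(-theta_u[i["g"]])) if "g" in i else 0.0
        return a, tau, z0, z1, v0, v1, v2, g

    def loglik_block(self, p: int, theta_u: np.ndarray) -> float:
        """Wiener log-likelihood of participant block p at unconstrained theta."""
        a, tau, z0, z1, v0, v1, v2, g = self._constrained_full(theta_u)
        d = self.data[p]
        return float(_block_loglik(d["x1"], d["x2"], d["rt"], d["upper"],
                                   a, tau, z0, z1, v0, v1, v2, g,
                                   self.spec.use_internal_reference, self.err))

    def _concat(self):
        if not hasattr(self, "_cat"):
            off = np.zeros(self.P + 1, dtype=np.int64)
            for p, d in enumerate(self.data):
                off[p + 1] = off[p] + d["rt"].shape[0]
            self._cat = {key: np.concatenate([d[key] for d in self.data])
                         for key in ("x1", "x2", "rt", "upper")}
            self._cat["offsets"] = off
        return self._cat

    def cohort_loglik(self, theta_mat: np.ndarray) -> float:
        """Summed likelihood over all participants at a (P, K) theta matrix."""
        cat = self._concat()
        i = self._i
        a = np.exp(theta_mat[:, i["a"]])
        tau = np.exp(theta_mat[:, i["tau"]])
        z0 = 1.0 / (1.0 + np.exp(-theta_mat[:, i["z0"]]))
        v0 = theta_mat[:, i["v0"]].copy()
        v1 = theta_mat[:, i["v1"]].copy()
        v2 = theta_mat[:, i["v2"]].copy() if "v2" in i else -v1
        z1 = theta_mat[:, i["z1"]].copy() if "z1" in i else np.zeros(self.P)
        if "g" in i:
            g = 1.0 / (1.0 + np.exp(-theta_mat[:, i["g"]]))
        else:
            g = np.zeros(self.P)
        return float(_cohort_loglik(cat["x1"], cat["x2"], cat["rt"],
                                    cat["upper"], cat["offsets"],
                                    a, tau, z0, z1, v0, v1, v2, g,
                                    self.spec.use_internal_reference, self.err))

    # -- flat-vector density (public log_posterior contract) ---------------

    def flat_size(self) -> int:
        return self.K * (self.P + 2)

    def unpack(self, vec: np.ndarray):
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (self.flat_size(),):
            raise ValueError(
                f"expected vector of length {self.flat_size()} "
                f"(= {self.K} parameters x ({self.P} participants + 2 hyper "
                f"levels)), got shape {vec.shape}")
        mu = vec[:self.K]
        log_sigma = vec[self.K:2 * self.K]
        theta = vec[2 * self.K:].reshape(self.P, self.K)
        return mu, log_sigma, theta

    def log_posterior(self, vec: np.ndarray) -> float:
        mu, log_sigma, theta = self.unpack(vec)
        sigma = np.exp(log_sigma)
        lp = _normal_logpdf(mu, self.m0, self.s0).sum()
        # half-normal on sigma plus the log-scale Jacobian
        lp += np.sum(-0.5 * (sigma / self.s_hn) ** 2
                     - np.log(self.s_hn) + 0.5 * math.log(2.0 / math.pi)
                     + log_sigma)
        for p in range(self.P):
            lp += _normal_logpdf(theta[p], mu, sigma).sum()
            if not np.isfinite(lp):
                return -np.inf
            lp += self.loglik_block(p, theta[p])
            if not np.isfinite(lp):
                return -np.inf
        return float(lp)


def _normal_logpdf(x, loc, scale):
    z = (np.asarray(x) - loc) / scale
    return -0.5 * z * z - np.log(scale) - 0.5 * math.log(2.0 * math.pi)


def log_posterior(spec: ModelSpec, priors: PriorSpec | None, dataset: Dataset,
                  vec, standard_ms: float | None = None) -> float:
    """Unnormalized log posterior density at a flat unconstrained vector.

    Layout: ``[mu (K), log_sigma (K), theta (P x K, row-major)]`` with K the
    spec's parameter count and P the number of participants.  ``-inf``
    propagates cleanly from likelihood violations; a wrong vector length
    raises ``ValueError``.
    """
    priors = priors or PriorSpec()
    model = _HierarchicalModel(spec, priors, dataset, standard_ms=standard_ms)
    return model.log_posterior(np.asarray(vec, dtype=float))


# ---------------------------------------------------------------------------
# posterior draws container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Post-warm-up MCMC draws of a hierarchical (or individual) fit.

    Arrays are indexed ``(chain, draw, ...)`` on the unconstrained scale;
    use :meth:`group_mean` / :meth:`individual` for constrained-scale
    views.  For non-hierarchical fits ``mu``/``sigma`` are absent (None).
    """

    spec: ModelSpec
    param_names: list
    participants: list
    theta: np.ndarray                  # (C, T, P, K)
    mu: np.ndarray | None = None       # (C, T, K)
    sigma: np.ndarray | None = None    # (C, T, K)
    metadata: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def _k(self, name: str) -> int:
        return self.param_names.index(name)

    def group_mean(self, name: str) -> np.ndarray:
        """Constrained-scale group central parameter, shape (chain, draw).

        The Gaussian hyper-mean lives on the unconstrained scale; the
        constrained transform of mu is the group median of the implied
        individual distribution (e.g. exp(mu) for log-normal parameters).
        """
        if self.mu is None:
            raise ValueError("non-hierarchical fit has no group level")
        return constrain(name, self.mu[:, :, self._k(name)])

    def group_sd(self, name: str) -> np.ndarray:
        if self.sigma is None:
            raise ValueError("non-hierarchical fit has no group level")
        return self.sigma[:, :, self._k(name)]

    def individual(self, pid, name: str) -> np.ndarray:
        p = self.participants.index(pid)
        return constrain(name, self.theta[:, :, p, self._k(name)])

    def individual_parameters(self, chain: int, draw: int) -> dict:
        """Per-participant IndividualParameters at one posterior draw."""
        out = {}
        for p, pid in enumerate(self.participants):
            vals = {n: float(constrain(n, self.theta[chain, draw, p, k]))
                    for k, n in enumerate(self.param_names)}
            out[pid] = IndividualParameters(
                a=vals["a"], tau=vals["tau"], z0=vals["z0"], v0=vals["v0"],
                v1=vals["v1"], v2=vals.get("v2", -vals["v1"]),
                z1=vals.get("z1", 0.0), g=vals.get("g", 0.0))
        return out

    def draw_indices(self) -> list:
        return [(c, t) for c in range(self.n_chains) for t in range(self.n_draws)]

    def scalar_chains(self) -> dict:
        """Every scalar parameter as a (chain, draw) array, keyed by name."""
        out = {}
        if self.mu is not None:
            for k, n in enumerate(self.param_names):
                out[f"mu_{n}"] = self.mu[:, :, k]
                out[f"sigma_{n}"] = self.sigma[:, :, k]
        for p, pid in enumerate(self.participants):
            for k, n in enumerate(self.param_names):
                out[f"theta[{pid}]_{n}"] = self.theta[:, :, p, k]
        return out

    def rhat_table(self) -> pd.Series:
        return pd.Series({name: rhat(draws)
                          for name, draws in self.scalar_chains().items()})

    @property
    def converged(self) -> bool:
        return bool((self.rhat_table() < 1.01).all())

    # -- serialization ------------------------------------------------------

    def to_csv(self, path) -> None:
        """Chain-tagged long-format CSV plus a JSON metadata sidecar."""
        rows = []
        for name, draws in self.scalar_chains().items():
            for c in range(draws.shape[0]):
                for t in range(draws.shape[1]):
                    rows.append((c, t, name, draws[c, t]))
        pd.DataFrame(rows, columns=["chain", "iteration", "parameter", "value"]
                     ).to_csv(path, index=False)
        meta = dict(self.metadata)
        meta.update({"model_number": self.spec.model_number,
                     "param_names": self.param_names,
                     "participants": [str(p) for p in self.participants],
                     "hierarchical": self.mu is not None})
        with open(str(path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)


def load_draws(path) -> PosteriorDraws:
    """Load draws written by :meth:`PosteriorDraws.to_csv`."""
    with open(str(path) + ".meta.json") as fh:
        meta = json.load(fh)
    df = pd.read_csv(path)
    spec = ModelSpec.from_number(meta["model_number"])
    names = meta["param_names"]
    pids = meta["participants"]
    C = int(df["chain"].max()) + 1
    T = int(df["iteration"].max()) + 1
    by_param = {name: sub.sort_values(["chain", "iteration"])["value"]
                .to_numpy().reshape(C, T)
                for name, sub in df.groupby("parameter")}
    theta = np.stack([np.stack([by_param[f"theta[{pid}]_{n}"] for n in names],
                               axis=-1) for pid in pids], axis=2)
    mu = sigma = None
    if meta["hierarchical"]:
        mu = np.stack([by_param[f"mu_{n}"] for n in names], axis=-1)
        sigma = np.stack([by_param[f"sigma_{n}"] for n in names], axis=-1)
    return PosteriorDraws(spec=spec, param_names=names, participants=pids,
                          theta=theta, mu=mu, sigma=sigma, metadata=meta)


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def rhat(draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``draws`` has shape (chain, iteration).  Each chain is split in half
    before the classic between/within variance comparison.  Chains with
    zero total variance return 1.0 by convention.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("rhat requires draws shaped (>=2 chains, iterations)")
    n = draws.shape[1] // 2
    halves = np.concatenate([draws[:, :n], draws[:, n:2 * n]], axis=0)
    m, n = halves.shape
    chain_means = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * chain_means.var(ddof=1)
    if W <= 0.0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(math.sqrt(var_plus / W))


def hdi(samples, mass: float = 0.95) -> tuple:
    """Shortest contiguous interval containing ``mass`` of the samples."""
    if not 0 < mass < 1:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < 50:
        raise ValueError(f"hdi requires >= 50 samples, got {n}")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[:n - m + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m - 1])


def posterior_mode(samples) -> float:
    """Marginal posterior mode by Gaussian-kernel density estimation.

    Bandwidth follows the normal-reference (Scott) rule; the argmax is
    taken over a 512-point grid spanning the sample range.  On ties the
    lower value is returned.  Degenerate (zero-variance) samples return
    their constant.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 100:
        raise ValueError(f"posterior_mode requires >= 100 samples, got {x.size}")
    if np.ptp(x) == 0.0:
        return float(x[0])
    kde = gaussian_kde(x, bw_method="scott")
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    # ties (within floating noise of the maximum) break toward the lower value
    near_max = np.nonzero(dens >= dens.max() * (1.0 - 1e-9))[0]
    return float(grid[near_max[0]])


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _slice_sample(x0: float, logp, rng, w: float = 0.5, max_out: int = 30) -> float:
    """Univariate slice sampling with stepping-out and shrinkage."""
    y = logp(x0) + math.log(rng.uniform())
    lo = x0 - w * rng.uniform()
    hi = lo + w
    for _ in range(max_out):
        if logp(lo) <= y:
            break
        lo -= w
    for _ in range(max_out):
        if logp(hi) <= y:
            break
        hi += w
    for _ in range(200):
        x1 = rng.uniform(lo, hi)
        if logp(x1) > y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1
    return x0


class _BlockAdapter:
    """Warm-up covariance adaptation for one participant block.

    The Cholesky factor of the (scaled) empirical posterior covariance sets
    both the direction distribution and the characteristic step width of
    the directional slice updates.
    """

    def __init__(self, K: int, init_diag):
        self.K = K
        self.chol = np.diag(np.asarray(init_diag, dtype=float))
        self.history = []

    def record(self, theta, adapting: bool):
        if not adapting:
            return
        self.history.append(theta.copy())
        if len(self.history) >= 100 and len(self.history) % 50 == 0:
            h = np.asarray(self.history[len(self.history) // 2:])
            cov = np.cov(h.T)
            cov += 1e-6 * np.diag(np.maximum(np.diag(cov), 1e-12))
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass


@njit(cache=False)
def _numba_seed(seed: int):
    np.random.seed(seed)


@njit(cache=False)
def _theta_logpost(x1, x2, rt, upper, th, mu, sigma,
                   ia, itau, iz0, iv0, iv1, iv2, iz1, ig,
                   use_ref: bool, err: float) -> float:
    """Participant-block likelihood plus (unnormalized) Gaussian prior."""
    a = math.exp(th[ia])
    tau = math.exp(th[itau])
    z0 = 1.0 / (1.0 + math.exp(-th[iz0]))
    v0 = th[iv0]
    v1 = th[iv1]
    v2 = th[iv2] if iv2 >= 0 else -v1
    z1 = th[iz1] if iz1 >= 0 else 0.0
    g = 1.0 / (1.0 + math.exp(-th[ig])) if ig >= 0 else 0.0
    lik = _block_loglik(x1, x2, rt, upper, a, tau, z0, z1, v0, v1, v2, g,
                        use_ref, err)
    if lik == -np.inf:
        return -np.inf
    lp = 0.0
    for k in range(th.shape[0]):
        d = (th[k] - mu[k]) / sigma[k]
        lp -= 0.5 * d * d
    return lik + lp


@njit(cache=False)
def _sweep_blocks(x1, x2, rt, upper, offsets, theta, chols, mu, sigma, lls,
                  n_updates: int, ia: int, itau: int, iz0: int, iv0: int,
                  iv1: int, iv2: int, iz1: int, ig: int, use_ref: bool,
                  err: float):
    """One sweep of directional-slice updates over every participant block.

    ``theta`` (P, K) and ``lls`` (P,) are updated in place; ``lls`` holds
    block LIKELIHOOD values (prior excluded) on exit.  Uses numba's global
    RNG, seeded per chain by the caller.
    """
    P, K = theta.shape
    for p in range(P):
        s = offsets[p]
        e = offsets[p + 1]
        th = theta[p].copy()
        prior = 0.0
        for k in range(K):
            d = (th[k] - mu[k]) / sigma[k]
            prior -= 0.5 * d * d
        lp = lls[p] + prior
        for _ in range(n_updates):
            # random direction from the adapted block covariance
            dvec = np.empty(K)
            for k in range(K):
                dvec[k] = np.random.normal()
            d = chols[p] @ dvec
            y = lp + math.log(np.random.random())
            u = np.random.random()
            lo = -u
            hi = 1.0 - u
            for _ in range(8):
                if _theta_logpost(x1[s:e], x2[s:e], rt[s:e], upper[s:e],
                                  th + lo * d, mu, sigma, ia, itau, iz0,
                                  iv0, iv1, iv2, iz1, ig, use_ref, err) <= y:
                    break
                lo -= 1.0
            for _ in range(8):
                if _theta_logpost(x1[s:e], x2[s:e], rt[s:e], upper[s:e],
                                  th + hi * d, mu, sigma, ia, itau, iz0,
                                  iv0, iv1, iv2, iz1, ig, use_ref, err) <= y:
                    break
                hi += 1.0
            for _ in range(100):
                sstep = lo + (hi - lo) * np.random.random()
                cand = th + sstep * d
                lp_cand = _theta_logpost(x1[s:e], x2[s:e], rt[s:e],
                                         upper[s:e], cand, mu, sigma, ia,
                                         itau, iz0, iv0, iv1, iv2, iz1, ig,
                                         use_ref, err)
                if lp_cand > y:
                    th = cand
                    lp = lp_cand
                    break
                if sstep < 0.0:
                    lo = sstep
                else:
                    hi = sstep
        theta[p] = th
        prior = 0.0
        for k in range(K):
            d = (th[k] - mu[k]) / sigma[k]
            prior -= 0.5 * d * d
        lls[p] = lp - prior


def fit(spec: ModelSpec, dataset: Dataset, priors: PriorSpec | None = None,
        n_chains: int = 4, n_iter: int = 2000, warmup_frac: float = 0.5,
        seed: int = 0, proposals_per_sweep: int = 6,
        standard_ms: float | None = None, hierarchical: bool | None = None,
        err: float = DEFAULT_ERR, max_init_tries: int = 200) -> PosteriorDraws:
    """Fit a model variant to a clean dataset by MCMC.

    Defaults follow common practice for hierarchical diffusion models:
    4 chains x 2000 iterations with the first 50% discarded as warm-up.
    Convergence is declared (``draws.converged``) only when every
    parameter's split R-hat is below 1.01.  With a single participant (or
    ``hierarchical=False``) the hierarchy is disabled and the hyper-mean
    priors act directly as individual-level priors, with a warning.

    The fit is deterministic given ``seed``.
    """
    priors = priors or PriorSpec()
    model = _HierarchicalModel(spec, priors, dataset, standard_ms=standard_ms,
                               err=err)
    if hierarchical is None:
        hierarchical = model.P >= 2
    if not hierarchical and model.P > 1:
        raise ValueError("non-hierarchical fits support a single participant")
    if hierarchical and model.P < 2:
        hierarchical = False
    if not hierarchical:
        warnings.warn("single participant: hierarchy disabled, hyper-mean "
                      "priors used as individual-level priors")

    n_warm = int(n_iter * warmup_frac)
    n_keep = n_iter - n_warm
    K, P = model.K, model.P
    theta_out = np.empty((n_chains, n_keep, P, K))
    mu_out = np.empty((n_chains, n_keep, K)) if hierarchical else None
    sig_out = np.empty((n_chains, n_keep, K)) if hierarchical else None

    # per-participant floor for non-decision-time initialization
    min_rt = [d["rt"].min() for d in model.data]

    for chain in range(n_chains):
        rng = np.random.default_rng([seed, chain])
        mu, sigma, theta, ll = _initialize(model, rng, min_rt, hierarchical,
                                           max_init_tries)
        # slice steps start at a fraction of each parameter's prior scale
        # so per-ms slope parameters move on their natural scale
        adapters = [_BlockAdapter(K, init_diag=0.05 * model.s0) for _ in range(P)]
        group_adapter = _GroupMoveAdapter(K, sigma.copy(), P)
        cat = model._concat()
        idx = tuple(model._i.get(n, -1)
                    for n in ("a", "tau", "z0", "v0", "v1", "v2", "z1", "g"))
        _numba_seed(int(rng.integers(0, 2**31 - 1)))
        for it in range(n_iter):
            adapting = it < n_warm
            prior_sd = sigma if hierarchical else model.s0
            prior_mean = mu if hierarchical else model.m0
            chols = np.stack([ad.chol for ad in adapters])
            _sweep_blocks(cat["x1"], cat["x2"], cat["rt"], cat["upper"],
                          cat["offsets"], theta, chols, prior_mean, prior_sd,
                          ll, proposals_per_sweep, *idx,
                          model.spec.use_internal_reference, model.err)
            for p in range(P):
                adapters[p].record(theta[p], adapting)
            if hierarchical:
                # conjugate Gibbs for hyper-means
                prec = 1.0 / model.s0 ** 2 + P / sigma ** 2
                mean = (model.m0 / model.s0 ** 2
                        + theta.sum(axis=0) / sigma ** 2) / prec
                mu = mean + rng.standard_normal(K) / np.sqrt(prec)
                # slice sampling for hyper-sds on the log scale
                for k in range(K):
                    dev2 = float(np.sum((theta[:, k] - mu[k]) ** 2))
                    s_hn = model.s_hn[k]

                    def logp(ls, dev2=dev2, s_hn=s_hn):
                        s = math.exp(ls)
                        return (-P * ls - dev2 / (2.0 * s * s)
                                - 0.5 * (s / s_hn) ** 2 + ls)

                    sigma[k] = math.exp(_slice_sample(math.log(sigma[k]), logp, rng))
                # interweaved (non-centered) group moves: the centered
                # Gibbs/block updates mix slowly along the direction where
                # mu and all theta shift together.  Cheap Metropolis moves
                # run every sweep; self-tuning slice versions every few
                # sweeps catch whatever the step-size adaptation misses.
                for _ in range(2):
                    mu, sigma, theta = _interweave_group_moves(
                        model, mu, sigma, theta, float(ll.sum()),
                        group_adapter, rng, adapting)
                    for p in range(P):
                        ll[p] = model.loglik_block(p, theta[p])
                if it % 3 == 0:
                    mu, sigma, theta = _interweave_group_slice(
                        model, mu, sigma, theta, rng)
                for p in range(P):
                    ll[p] = model.loglik_block(p, theta[p])
            if not adapting:
                j = it - n_warm
                theta_out[chain, j] = theta
                if hierarchical:
                    mu_out[chain, j] = mu
                    sig_out[chain, j] = sigma

    draws = PosteriorDraws(
        spec=spec, param_names=model.names, participants=model.participants,
        theta=theta_out, mu=mu_out, sigma=sig_out,
        metadata={"seed": seed, "n_chains": n_chains, "n_iter": n_iter,
                  "warmup_frac": warmup_frac,
                  "proposals_per_sweep": proposals_per_sweep,
                  "standard_ms": model.standard_ms,
                  "priors": priors.describe(),
                  "sampler": "blocked adaptive directional slice within Gibbs"})
    return draws


class _GroupMoveAdapter:
    """Warm-up step-size adaptation for the interweaved group moves."""

    def __init__(self, K: int, sigma0, P: int):
        self.log_step_shift = np.log(np.maximum(sigma0 / math.sqrt(P), 1e-3))
        self.log_step_scale = np.full(K, math.log(0.3))
        self.n = np.zeros((2, K))
        self.acc = np.zeros((2, K))

    def record(self, which: int, k: int, accepted: bool, adapting: bool):
        if not adapting:
            return
        self.n[which, k] += 1
        self.acc[which, k] += accepted
        if self.n[which, k] >= 20:
            rate = self.acc[which, k] / self.n[which, k]
            target = 0.44  # 1-d random-walk optimum
            step = 0.3
            arr = self.log_step_shift if which == 0 else self.log_step_scale
            arr[k] += step * (rate - target)
            self.n[which, k] = self.acc[which, k] = 0


def _interweave_group_moves(model: _HierarchicalModel, mu, sigma, theta,
                            cohort_ll: float, adapter: _GroupMoveAdapter,
                            rng, adapting: bool):
    """Ancillarity-sufficiency interweaving updates of the group level.

    For each parameter k, Metropolis-update (1) the group mean with the
    individual deviations theta_ik - mu_k held fixed, and (2) the group sd
    on the log scale with the standardized deviations held fixed.  Both
    moves leave the individual-level Gaussian terms invariant and push the
    whole cohort through the likelihood at once, breaking the slow
    shared-shift direction of the centered parametrization.
    """
    K = model.K
    base = theta.copy()
    for k in range(K):
        # group-shift move
        x_new = mu[k] + math.exp(adapter.log_step_shift[k]) * rng.standard_normal()
        base[:, k] = x_new + (theta[:, k] - mu[k])
        lik = model.cohort_loglik(base)
        d_prior = float(_normal_logpdf(x_new, model.m0[k], model.s0[k])
                        - _normal_logpdf(mu[k], model.m0[k], model.s0[k]))
        accept = (lik > -np.inf
                  and math.log(rng.uniform()) < lik - cohort_ll + d_prior)
        if accept:
            theta[:, k] = base[:, k]
            mu[k] = x_new
            cohort_ll = lik
        else:
            base[:, k] = theta[:, k]
        adapter.record(0, k, accept, adapting)
        # group-scale move (log sd random walk; half-normal prior+Jacobian)
        eta = (theta[:, k] - mu[k]) / sigma[k]
        ls_old = math.log(sigma[k])
        ls_new = ls_old + math.exp(adapter.log_step_scale[k]) * rng.standard_normal()
        s_new = math.exp(ls_new)
        base[:, k] = mu[k] + s_new * eta
        lik = model.cohort_loglik(base)
        d_prior = (-0.5 * (s_new / model.s_hn[k]) ** 2 + ls_new
                   + 0.5 * (sigma[k] / model.s_hn[k]) ** 2 - ls_old)
        accept = (lik > -np.inf
                  and math.log(rng.uniform()) < lik - cohort_ll + d_prior)
        if accept:
            theta[:, k] = base[:, k]
            sigma[k] = s_new
            cohort_ll = lik
        else:
            base[:, k] = theta[:, k]
        adapter.record(1, k, accept, adapting)
    return mu, sigma, theta


def _interweave_group_slice(model: _HierarchicalModel, mu, sigma, theta, rng):
    """Slice-sampling version of the interweaved group moves (no step-size
    tuning; costlier per sweep but robust to badly adapted scales)."""
    K = model.K
    P = model.P
    for k in range(K):
        delta = theta[:, k] - mu[k]
        base = theta.copy()

        def logp_shift(x, k=k, delta=delta, base=base):
            base[:, k] = x + delta
            lik = model.cohort_loglik(base)
            if lik == -np.inf:
                return -np.inf
            return lik + float(_normal_logpdf(x, model.m0[k], model.s0[k]))

        w = max(float(sigma[k]) / math.sqrt(P), 0.02 * float(model.s0[k]))
        mu[k] = _slice_sample(float(mu[k]), logp_shift, rng, w=w)
        theta[:, k] = mu[k] + delta

        eta = (theta[:, k] - mu[k]) / sigma[k]
        base = theta.copy()

        def logp_scale(ls, k=k, eta=eta, base=base):
            s = math.exp(ls)
            base[:, k] = mu[k] + s * eta
            lik = model.cohort_loglik(base)
            if lik == -np.inf:
                return -np.inf
            return lik - 0.5 * (s / model.s_hn[k]) ** 2 + ls

        sigma[k] = math.exp(_slice_sample(math.log(float(sigma[k])),
                                          logp_scale, rng, w=0.4))
        theta[:, k] = mu[k] + sigma[k] * eta
    return mu, sigma, theta


def fit_until_converged(spec: ModelSpec, dataset: Dataset,
                        n_iter: int = 2000, max_attempts: int = 3,
                        growth: float = 1.5, seed: int = 0,
                        **kwargs) -> PosteriorDraws:
    """Fit and, if any split R-hat is >= 1.01, refit with longer chains.

    Standard MCMC practice: a fit whose convergence diagnostic fails is
    not interpreted but rerun with more iterations.  Chain length grows by
    ``growth`` per attempt (fresh chains, attempt-specific seeds derived
    from ``seed``); after ``max_attempts`` the last (non-converged) fit is
    returned with a warning, and ``draws.converged`` stays False.
    """
    draws = None
    for attempt in range(max_attempts):
        draws = fit(spec, dataset, n_iter=int(round(n_iter * growth ** attempt)),
                    seed=seed + 7919 * attempt, **kwargs)
        if draws.converged:
            return draws
    warnings.warn(f"fit did not reach split R-hat < 1.01 in {max_attempts} "
                  "attempts; returning the last fit")
    return draws


def _initialize(model: _HierarchicalModel, rng, min_rt, hierarchical: bool,
                max_tries: int):
    """Draws from priors shrunk toward their means, retried until the
    likelihood is finite everywhere."""
    K, P = model.K, model.P
    tau_k = model._i.get("tau")
    for attempt in range(max_tries):
        # shrink successive attempts toward the prior means, which are a
        # feasible interior point (zero slopes, centered starting point)
        shrink = 0.3 * 0.7 ** (attempt // 5)
        mu = model.m0 + shrink * model.s0 * rng.standard_normal(K)
        sigma = (shrink * np.minimum(model.s_hn, model.s0)
                 * np.abs(1.0 + 0.5 * rng.standard_normal(K))
                 + 0.02 * model.s0)
        if tau_k is not None:
            # keep initial non-decision time safely below the fastest RT
            cap = math.log(0.5 * min(min_rt))
            mu[tau_k] = min(mu[tau_k], cap)
        theta = mu + (sigma if hierarchical else shrink * model.s0
                      ) * rng.standard_normal((P, K))
        if tau_k is not None:
            for p in range(P):
                theta[p, tau_k] = min(theta[p, tau_k], math.log(0.5 * min_rt[p]))
        ll = np.array([model.loglik_block(p, theta[p]) for p in range(P)])
        if np.all(np.isfinite(ll)):
            return mu, sigma, theta, ll
    raise RuntimeError(
        f"failed to find a finite-density initialization in {max_tries} tries; "
        "check RT floors against the non-decision-time prior")
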