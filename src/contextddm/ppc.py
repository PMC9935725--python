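"""Posterior predictive checks: simulate replicate datasets from posterior
draws and summarize choice probabilities and RT quantiles per design cell.

A "cell" is a (comparison level, presentation order) pair.  For each cell
the replicates yield a distribution of the probability of a
"comparison longer" response and of pooled RT quantiles (10/30/50/70/90%),
summarized by their mean/median and 95% highest-density intervals, and set
against the same statistics of the empirical data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import Dataset
from .inference import PosteriorDraws, hdi
from .psychophysics import _comparison_longer, _comparison_duration
from .wiener import simulate_experiment

__all__ = ["PpcSummary", "posterior_predictive_datasets", "ppc_summary"]

RT_QUANTILES = (0.10, 0.30, 0.50, 0.70, 0.90)

#: default number of posterior draws used for replicate datasets
DEFAULT_N_REP = 500


@dataclass
class PpcSummary:
    """Per-cell posterior predictive summaries vs. empirical statistics.

    ``table`` has one row per (comparison level, order, statistic) with the
    predicted point value, 95% HDI bounds, the empirical value, and a
    coverage flag.
    """

    table: pd.DataFrame
    n_replicates: int = 0
    coverage: dict = field(default_factory=dict)

    def coverage_rate(self, statistic: str = "p_comparison_longer") -> float:
        sub = self.table[self.table["statistic"] == statistic]
        sub = sub[sub["covered"].notna()]
        return float(sub["covered"].mean())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def posterior_predictive_datasets(spec, draws: PosteriorDraws, design,
                                  n_rep: int = DEFAULT_N_REP, rng=None,
                                  dt: float = 1e-4):
    """Simulate ``n_rep`` replicate datasets from randomly chosen draws.

    Draws are selected uniformly without replacement over the post-warm-up
    draws (with replacement, plus a warning, when ``n_rep`` exceeds the
    draw count); each replicate regenerates the full design for every
    fitted participant with that draw's individual-level parameters.
    """
    if spec.model_number != draws.spec.model_number:
        raise ValueError("spec does not match the fitted draws")
    rng = np.random.default_rng(rng)
    idx = draws.draw_indices()
    S = len(idx)
    if n_rep > S:
        warnings.warn(f"n_rep={n_rep} exceeds the {S} available draws; "
                      "sampling with replacement")
        chosen = rng.integers(0, S, size=n_rep)
    else:
        chosen = rng.choice(S, size=n_rep, replace=False)
    replicates = []
    for s in chosen:
        c, t = idx[s]
        params = draws.individual_parameters(c, t)
        replicates.append(simulate_experiment(design, spec, params,
                                              rng=rng, dt=dt))
    return replicates


def _cell_stats(ds: Dataset, standard_ms: float) -> pd.DataFrame:
    trials = ds.trials[ds.trials["response"].notna()]
    longer = _comparison_longer(trials)
    comparison = _comparison_duration(trials)
    df = pd.DataFrame({"comparison_ms": comparison,
                       "order": trials["order"].to_numpy(),
                       "longer": longer,
                       "rt": trials["rt_s"].to_numpy(float)})
    rows = []
    for (lvl, order), grp in df.groupby(["comparison_ms", "order"]):
        row = {"comparison_ms": lvl, "order": order,
               "p_comparison_longer": grp["longer"].mean(),
               "rt_median": grp["rt"].median()}
        for q in RT_QUANTILES:
            row[f"rt_q{int(q * 100)}"] = grp["rt"].quantile(q)
        rows.append(row)
    return pd.DataFrame(rows)


def ppc_summary(replicates, empirical: Dataset,
                standard_ms: float | None = None) -> PpcSummary:
    """Summarize replicate datasets against the empirical data per cell.

    For every cell and statistic the table reports the mean over
    replicates, the 95% HDI across replicates, the empirical value, and
    whether the empirical value falls inside the HDI.  Cells absent from
    the replicates or the data are flagged and excluded from coverage.
    """
    if standard_ms is None:
        standard_ms = (empirical.design.standard_ms if empirical.design
                       else 500.0)
    emp = _cell_stats(empirical, standard_ms).set_index(["comparison_ms", "order"])
    rep_tables = [_cell_stats(r, standard_ms).set_index(["comparison_ms", "order"])
                  for r in replicates]
    stats = [c for c in emp.columns]
    rows = []
    for cell in emp.index:
        for stat in stats:
            vals = np.array([t.loc[cell, stat] for t in rep_tables
                             if cell in t.index])
            emp_val = float(emp.loc[cell, stat])
            if vals.size < len(rep_tables):
                warnings.warn(f"cell {cell} missing from some replicates")
            if vals.size >= 50 and np.ptp(vals) > 0:
                lo, hi = hdi(vals, 0.95)
            else:
                lo = hi = float(np.median(vals)) if vals.size else np.nan
            covered = (lo <= emp_val <= hi) if np.isfinite(lo) else None
            rows.append({"comparison_ms": cell[0], "order": cell[1],
                         "statistic": stat,
                         "predicted": float(vals.mean()) if vals.size else np.nan,
                         "hdi_low": lo, "hdi_high": hi,
                         "empirical": emp_val, "covered": covered})
    table = pd.DataFrame(rows)
    cov = {s: float(table[(table["statistic"] == s)
                          & table["covered"].notna()]["covered"].mean())
           for s in stats}
    return PpcSummary(table=table, n_replicates=len(replicates), coverage=cov)
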