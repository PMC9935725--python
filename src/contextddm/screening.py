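"""Fast-guess detection by EWMA control charts and exclusion rules.

Very fast responses at chance accuracy ("fast guesses") bias diffusion-model
estimates, so each participant's responses are screened before fitting:
trials are sorted by ascending RT, response correctness (did the participant
choose the physically longer stimulus?) is tracked by an exponentially
weighted moving average initialized at chance (0.5), and the RT at which the
EWMA rises above its upper control limit -- and stays there -- is taken as
that participant's fast-guess cutoff.  Participants whose fast guesses
exceed 10% of all their responses are excluded entirely; for the rest,
responses faster than an absolute 100 ms floor are removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import Dataset

__all__ = ["ScreeningReport", "ewma_cutoff", "apply_exclusions"]

#: conventional EWMA control-chart settings for RT screening
DEFAULT_LAMBDA = 0.01
DEFAULT_L = 1.5

#: participant excluded when fast-guess proportion strictly exceeds this
FAST_GUESS_PROPORTION_LIMIT = 0.10

#: absolute floor: responses faster than this are removed (seconds)
ABSOLUTE_RT_FLOOR_S = 0.100

MIN_SCOREABLE_TRIALS = 20


class InsufficientDataError(ValueError):
    """Too few scoreable trials to run the EWMA chart."""


@dataclass
class ParticipantScreening:
    participant_id: object
    cutoff_s: float           # +inf when the chart never clears chance
    n_fast_guesses: int
    n_responses: int
    proportion_fast_guesses: float
    excluded: bool
    n_below_floor: int = 0

    def as_row(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "cutoff_s": self.cutoff_s,
            "n_fast_guesses": self.n_fast_guesses,
            "n_responses": self.n_responses,
            "proportion_fast_guesses": self.proportion_fast_guesses,
            "excluded": self.excluded,
            "n_below_floor": self.n_below_floor,
        }


@dataclass
class ScreeningReport:
    """Per-participant screening outcomes plus the settings used."""

    participants: list = field(default_factory=list)
    ewma_lambda: float = DEFAULT_LAMBDA
    ewma_L: float = DEFAULT_L
    proportion_limit: float = FAST_GUESS_PROPORTION_LIMIT
    floor_s: float = ABSOLUTE_RT_FLOOR_S

    @property
    def excluded_participants(self) -> list:
        return [p.participant_id for p in self.participants if p.excluded]

    @property
    def n_removed_trials(self) -> int:
        n = 0
        for p in self.participants:
            n += p.n_responses if p.excluded else p.n_below_floor
        return n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([p.as_row() for p in self.participants])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ewma_cutoff(trials: pd.DataFrame, ewma_lambda: float = DEFAULT_LAMBDA,
                L: float = DEFAULT_L, standard_ms: float | None = None) -> float:
    """Fast-guess RT cutoff for one participant's responded trials.

    Correctness is defined only on trials with unequal durations (choosing
    the physically longer stimulus); equal-duration trials are skipped.
    Trials are sorted by ascending RT and the EWMA of correctness, started
    at 0.5, is compared against the upper control limit

        0.5 + L * 0.5 * sqrt(lam / (2 - lam) * (1 - (1 - lam)^(2t))),

    the standard EWMA chart standard deviation under Bernoulli(0.5)
    variance.  The cutoff is the RT of the first trial from which the EWMA
    exceeds the limit for the remainder of the sequence; 0.0 if that holds
    from the first trial, ``inf`` if it never does (whole session at
    chance).
    """
    resp = trials[trials["response"].notna() & trials["rt_s"].notna()]
    unequal = resp[resp["dur1_ms"] != resp["dur2_ms"]]
    if len(unequal) < MIN_SCOREABLE_TRIALS:
        raise InsufficientDataError(
            f"only {len(unequal)} scoreable trials (< {MIN_SCOREABLE_TRIALS})")
    ordered = unequal.sort_values("rt_s", kind="mergesort")
    longer_first = ordered["dur1_ms"].to_numpy() > ordered["dur2_ms"].to_numpy()
    correct = (ordered["response"].to_numpy() == "first_longer") == longer_first
    rt = ordered["rt_s"].to_numpy(dtype=float)

    lam = ewma_lambda
    n = correct.shape[0]
    t = np.arange(1, n + 1)
    sd = 0.5 * np.sqrt(lam / (2.0 - lam) * (1.0 - (1.0 - lam) ** (2 * t)))
    limit = 0.5 + L * sd
    ewma = np.empty(n)
    state = 0.5
    for i in range(n):
        state = lam * correct[i] + (1.0 - lam) * state
        ewma[i] = state
    above = ewma > limit
    # first index from which the chart stays above the limit
    below_idx = np.nonzero(~above)[0]
    if below_idx.size == 0:
        return 0.0
    first_clear = below_idx[-1] + 1
    if first_clear >= n:
        return math.inf
    return float(rt[first_clear])


def apply_exclusions(dataset: Dataset, ewma_lambda: float = DEFAULT_LAMBDA,
                     L: float = DEFAULT_L,
                     proportion_limit: float = FAST_GUESS_PROPORTION_LIMIT,
                     floor_s: float = ABSOLUTE_RT_FLOOR_S):
    """Screen every participant and apply the exclusion rules.

    Participants whose proportion of fast guesses (responses faster than
    their EWMA cutoff, over ALL their responses) strictly exceeds
    ``proportion_limit`` are dropped entirely; for retained participants,
    responses faster than ``floor_s`` are removed.  Exactly-at-the-limit
    proportions are retained (strict inequality).

    Returns ``(clean_dataset, report)``.  Idempotent: re-screening the
    clean dataset removes nothing further when cutoffs are stable.
    """
    report = ScreeningReport(ewma_lambda=ewma_lambda, ewma_L=L,
                             proportion_limit=proportion_limit, floor_s=floor_s)
    kept = []
    for pid in dataset.participants:
        trials = dataset.participant_trials(pid)
        resp = trials[trials["response"].notna() & trials["rt_s"].notna()]
        cutoff = ewma_cutoff(trials, ewma_lambda=ewma_lambda, L=L)
        rt = resp["rt_s"].to_numpy(dtype=float)
        n_fast = int(np.sum(rt < cutoff))
        prop = n_fast / len(resp) if len(resp) else 0.0
        excluded = prop > proportion_limit
        below_floor = 0
        if not excluded:
            floor_mask = trials["rt_s"].notna() & (trials["rt_s"] < floor_s)
            below_floor = int(floor_mask.sum())
            kept.append(trials[~floor_mask])
        report.participants.append(ParticipantScreening(
            participant_id=pid, cutoff_s=cutoff, n_fast_guesses=n_fast,
            n_responses=len(resp), proportion_fast_guesses=prop,
            excluded=excluded, n_below_floor=below_floor))
    if kept:
        clean = pd.concat(kept, ignore_index=True)
    else:
        clean = dataset.trials.iloc[0:0]
    prov = dataset.provenance
    if report.excluded_participants or report.n_removed_trials:
        prov = (prov + "; " if prov else "") + (
            f"screened: excluded={report.excluded_participants}, "
            f"removed_trials={report.n_removed_trials}")
    return Dataset(clean, design=dataset.design, provenance=prov), report
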