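"""Trial-level containers, delimited-text I/O, and the two-interval
duration-discrimination design generator.

A dataset is a tidy :class:`pandas.DataFrame` with one row per trial and the
canonical columns::

    participant_id, trial_index, dur1_ms, dur2_ms, order, response, rt_s

``order`` is ``"sc"`` (standard presented first) or ``"cs"``; ``response``
is ``"first_longer"`` / ``"second_longer"`` or missing for design skeletons;
``rt_s`` is the response time in seconds measured from second-stimulus
offset.  Durations are physical milliseconds; centering on the standard
happens downstream in the model code, never in storage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "COLUMNS",
    "ExperimentDesign",
    "Dataset",
    "DatasetValidationError",
    "read_dataset",
    "write_dataset",
    "generate_design_trials",
]

COLUMNS = ["participant_id", "trial_index", "dur1_ms", "dur2_ms",
           "order", "response", "rt_s"]

_ORDERS = ("sc", "cs")
_RESPONSES = ("first_longer", "second_longer")


class DatasetValidationError(ValueError):
    """A dataset violates a trial-level invariant; rows are named."""


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a two-interval duration-discrimination session.

    Defaults emulate the classic auditory paradigm: a 500 ms standard, nine
    comparison durations equally spaced over 400-600 ms, a 1000 ms
    inter-stimulus interval (metadata only -- it never enters the model),
    and both presentation orders randomly intermixed.
    """

    standard_ms: float = 500.0
    comparison_levels_ms: tuple = tuple(np.linspace(400.0, 600.0, 9))
    n_trials_per_level_per_order: int = 10
    isi_ms: float = 1000.0
    order_scheme: str = "random_intermixed"
    seed: int = 0

    def __post_init__(self):
        if any(c <= 0 for c in self.comparison_levels_ms):
            raise ValueError("comparison levels must all be positive")
        if self.n_trials_per_level_per_order < 1:
            raise ValueError("need at least one trial per level per order")
        if self.order_scheme not in ("random_intermixed", "blocked_sc", "blocked_cs"):
            raise ValueError(f"unknown order scheme {self.order_scheme!r}")

    @property
    def n_trials_per_participant(self) -> int:
        n_orders = 2 if self.order_scheme == "random_intermixed" else 1
        return len(self.comparison_levels_ms) * n_orders * self.n_trials_per_level_per_order

    def with_(self, **kw) -> "ExperimentDesign":
        return replace(self, **kw)


@dataclass
class Dataset:
    """Ordered trials for one or more participants plus optional design."""

    trials: pd.DataFrame
    design: ExperimentDesign | None = None
    provenance: str = ""

    def __post_init__(self):
        self.trials = _coerce_and_validate(self.trials, self.design)

    @property
    def participants(self) -> list:
        return list(self.trials["participant_id"].unique())

    def participant_trials(self, pid) -> pd.DataFrame:
        sub = self.trials[self.trials["participant_id"] == pid]
        return sub.sort_values("trial_index").reset_index(drop=True)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def responded(self) -> "Dataset":
        """Subset with responses and RTs present (invariants re-checked)."""
        mask = self.trials["response"].notna() & self.trials["rt_s"].notna()
        return Dataset(self.trials[mask].reset_index(drop=True),
                       design=self.design, provenance=self.provenance)

    def equals(self, other: "Dataset") -> bool:
        a = self.trials[COLUMNS].reset_index(drop=True)
        b = other.trials[COLUMNS].reset_index(drop=True)
        if len(a) != len(b):
            return False
        for col in COLUMNS:
            x, y = a[col], b[col]
            if col in ("dur1_ms", "dur2_ms", "rt_s"):
                if not np.allclose(x.astype(float), y.astype(float),
                                   rtol=0, atol=1e-9, equal_nan=True):
                    return False
            elif not (x.fillna("~") == y.fillna("~")).all():
                return False
        return True


def _coerce_and_validate(df: pd.DataFrame, design: ExperimentDesign | None) -> pd.DataFrame:
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(f"missing required columns: {missing}")
    df = df[COLUMNS].copy()
    bad_rows = []
    for col in ("dur1_ms", "dur2_ms", "rt_s"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna() & (df[col].astype(str) != "")
        bad_rows.extend((int(i), f"{col} not numeric") for i in df.index[newly_bad])
        df[col] = coerced
    df["trial_index"] = pd.to_numeric(df["trial_index"], errors="raise").astype(int)

    for col, lab in (("dur1_ms", "dur1_ms"), ("dur2_ms", "dur2_ms")):
        bad = df.index[df[col] <= 0]
        bad_rows.extend((int(i), f"non-positive {lab}") for i in bad)
    bad = df.index[df["rt_s"].notna() & (df["rt_s"] <= 0)]
    bad_rows.extend((int(i), "non-positive rt_s") for i in bad)
    bad = df.index[~df["order"].isin(_ORDERS)]
    bad_rows.extend((int(i), f"order not in {_ORDERS}") for i in bad)
    has_resp = df["response"].notna()
    bad = df.index[has_resp & ~df["response"].isin(_RESPONSES)]
    bad_rows.extend((int(i), "unknown response label") for i in bad)

    if design is not None:
        s = design.standard_ms
        std_dur = np.where(df["order"] == "sc", df["dur1_ms"], df["dur2_ms"])
        bad = df.index[~np.isclose(std_dur, s)]
        bad_rows.extend((int(i), "order label inconsistent with standard duration")
                        for i in bad)

    if bad_rows:
        listing = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:20])
        raise DatasetValidationError(
            f"{len(bad_rows)} invalid rows: {listing}")

    for pid, grp in df.groupby("participant_id", sort=False):
        idx = grp["trial_index"].to_numpy()
        if np.any(np.diff(np.sort(idx)) == 0):
            raise DatasetValidationError(
                f"participant {pid}: duplicated trial_index values")
    return df.sort_values(["participant_id", "trial_index"]).reset_index(drop=True)


def read_dataset(path, dialect: dict | None = None,
                 design: ExperimentDesign | None = None) -> Dataset:
    """Read a delimited-text trial file into a validated :class:`Dataset`.

    ``dialect`` maps canonical column names to the file's headers, e.g.
    ``{"participant_id": "subj"}``; unmapped columns use canonical names.
    Rows violating invariants raise :class:`DatasetValidationError` with
    row numbers.
    """
    df = pd.read_csv(path)
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DatasetValidationError(
            f"{path}: missing columns after mapping: {missing}")
    return Dataset(df, design=design)


def write_dataset(dataset: Dataset, path) -> None:
    """Write the canonical column set as UTF-8 CSV, ordered by participant
    then trial index; missing values are empty fields."""
    df = dataset.trials[COLUMNS].sort_values(["participant_id", "trial_index"])
    df.to_csv(path, index=False, na_rep="")


def generate_design_trials(design: ExperimentDesign,
                           participant_ids=("p01",),
                           seed: int | None = None) -> Dataset:
    """Generate the trial skeleton of a session (responses missing).

    Every (comparison level x order) cell appears exactly
    ``n_trials_per_level_per_order`` times per participant.  With the
    ``random_intermixed`` scheme the cells are shuffled in a seeded
    pseudo-random permutation; blocked schemes fix the order label.
    """
    seed = design.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if design.order_scheme == "random_intermixed":
        orders = _ORDERS
    else:
        orders = ("sc",) if design.order_scheme == "blocked_sc" else ("cs",)
    cells = [(c, o) for c in design.comparison_levels_ms for o in orders
             for _ in range(design.n_trials_per_level_per_order)]
    rows = []
    for pid in participant_ids:
        perm = rng.permutation(len(cells))
        for t, j in enumerate(perm, start=1):
            comparison, order = cells[j]
            dur1, dur2 = ((design.standard_ms, comparison) if order == "sc"
                          else (comparison, design.standard_ms))
            rows.append((pid, t, dur1, dur2, order, None, None))
    df = pd.DataFrame(rows, columns=COLUMNS)
    return Dataset(df, design=design, provenance=f"generated seed={seed}")
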