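"""Synthetic two-arm competing-risks trials and their analytic truths.

A trial has two arms (verum = 1, control = 0) of equal size. Each subject
carries two independent latent exponential event times — the adverse event
of interest (cause 1) and death (cause 2) — with rates set from target
median times via ``h = log(2) / t_half``. The observed record is the
minimum of the two latent times and an administrative censoring horizon
(default 30 months); the event code identifies which was smallest.

Because the latent times are exponential, the induced cause-specific
hazards are constant, the true cause-specific hazard ratio between arms is
the inverse ratio of the medians, and the cumulative incidence functions
have the closed form used by :func:`true_cif` — which serves as the
analytic oracle for every estimator in the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("crsafety")

EVENT_CENSORED = 0
EVENT_AE = 1
EVENT_DEATH = 2

GROUP_CONTROL = 0
GROUP_VERUM = 1


def hazard_from_median(median: float) -> float:
    """Exponential hazard rate (per month) from a target median time.

    ``h = log(2) / t_half``. An infinite median is accepted as a sentinel
    for a cause that never fires (rate 0).

    Raises
    ------
    ValueError
        If ``median`` is not strictly positive.
    """
    if not median > 0:
        raise ValueError(f"median time must be strictly positive, got {median!r}")
    if math.isinf(median):
        return 0.0
    return math.log(2.0) / median


@dataclass(frozen=True)
class Condition:
    """One cell of the simulation design grid.

    Median times (months) to the adverse event in each arm, plus the death
    and censoring parameters held fixed across the grid: death medians of
    20 (verum) and 10 (control) months — a death hazard ratio of 0.5 in
    favour of verum — and administrative censoring at 30 months.
    """

    median_ae_verum: float
    median_ae_control: float
    median_death_verum: float = 20.0
    median_death_control: float = 10.0
    censor_time: float = 30.0

    def __post_init__(self) -> None:
        for name in (
            "median_ae_verum",
            "median_ae_control",
            "median_death_verum",
            "median_death_control",
            "censor_time",
        ):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
            if name == "censor_time" and not math.isfinite(v):
                raise ValueError("censor_time must be finite")

    def hazard(self, cause: int, group: int) -> float:
        """Cause-specific hazard rate for ``cause`` in arm ``group``."""
        if cause == EVENT_AE:
            m = self.median_ae_verum if group == GROUP_VERUM else self.median_ae_control
        elif cause == EVENT_DEATH:
            m = self.median_death_verum if group == GROUP_VERUM else self.median_death_control
        else:
            raise ValueError(f"unknown cause code {cause!r}")
        return hazard_from_median(m)


def condition_grid(
    grid_min: int = 1,
    grid_max: int = 20,
    grid_step: int = 1,
    **fixed,
) -> list[Condition]:
    """Enumerate the design grid of adverse-event medians.

    Conditions are ordered verum-major: for each verum median, control
    medians run from ``grid_min`` to ``grid_max``. The default 1..20 x 1..20
    grid yields exactly 400 conditions.
    """
    medians = range(grid_min, grid_max + 1, grid_step)
    return [
        Condition(median_ae_verum=float(mv), median_ae_control=float(mc), **fixed)
        for mv in medians
        for mc in medians
    ]


def true_cs_hr(condition: Condition) -> float:
    """True cause-specific hazard ratio (verum / control) for the adverse event.

    Equals ``median_ae_control / median_ae_verum``; values below 1 mean the
    verum arm is safer.
    """
    return condition.hazard(EVENT_AE, GROUP_VERUM) / condition.hazard(EVENT_AE, GROUP_CONTROL)


def true_death_hr(condition: Condition) -> float:
    """True cause-specific hazard ratio (verum / control) for death."""
    return condition.hazard(EVENT_DEATH, GROUP_VERUM) / condition.hazard(EVENT_DEATH, GROUP_CONTROL)


def true_cif(condition: Condition, group: int, cause: int, t) -> np.ndarray | float:
    """Analytic cumulative incidence of ``cause`` in arm ``group`` at time ``t``.

    For independent exponential latent times with rates ``h1`` (adverse
    event) and ``h2`` (death),

        CIF_k(t) = h_k / (h1 + h2) * (1 - exp(-(h1 + h2) * t)),

    the uncensored truth (the censoring horizon is not applied). The two
    causes' CIFs sum to the all-cause failure probability at every ``t``.
    """
    if cause not in (EVENT_AE, EVENT_DEATH):
        raise ValueError(f"unknown cause code {cause!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    h1 = condition.hazard(EVENT_AE, group)
    h2 = condition.hazard(EVENT_DEATH, group)
    h_all = h1 + h2
    hk = h1 if cause == EVENT_AE else h2
    if h_all == 0.0:
        out = np.zeros_like(t)
    else:
        out = hk / h_all * (-np.expm1(-h_all * t))
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SeedInfo:
    """Reproducibility record: master seed plus the substream key."""

    master_seed: int
    condition_index: int = 0
    replicate: int = 0

    def spawn_rng(self) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(
                [self.master_seed, self.condition_index, self.replicate]
            )
        )


@dataclass
class TrialDataset:
    """One simulated trial: parallel arrays of observed follow-up records.

    ``time`` is the observed follow-up in months, ``event`` the code
    (0 censored, 1 adverse event, 2 death) and ``group`` the arm
    (0 control, 1 verum). Exactly ``n_per_arm`` subjects per arm.
    """

    time: np.ndarray
    event: np.ndarray
    group: np.ndarray
    condition: Condition | None
    n_per_arm: int
    seed_info: SeedInfo | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int64)
        self.group = np.asarray(self.group, dtype=np.int64)
        n = len(self.time)
        if not (len(self.event) == len(self.group) == n):
            raise ValueError("time, event and group must have equal length")

    def __len__(self) -> int:
        return len(self.time)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self), dtype=np.int64),
                "time": self.time,
                "event": self.event,
                "group": self.group,
            }
        )

    def to_csv(self, path) -> None:
        """Write the long-format dialect (id, time, event, group)."""
        self.to_frame().to_csv(path, index=False)


def dataset_from_frame(
    df: pd.DataFrame,
    condition: Condition | None = None,
) -> TrialDataset:
    """Build a :class:`TrialDataset` from a long-format table.

    Required columns: ``time``, ``event``, ``group`` (an ``id`` column is
    accepted and ignored). Used both for round-tripping simulated trials
    and for ingesting user-supplied event tables; user tables carry no
    design ``condition`` and need not be balanced.
    """
    missing = {"time", "event", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if len(df) == 0:
        raise ValueError("event table is empty")
    try:
        time = df["time"].to_numpy(dtype=float)
        event = df["event"].to_numpy(dtype=np.int64)
        group = df["group"].to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric values in event table: {exc}") from exc

    def _bad_rows(mask: np.ndarray) -> str:
        rows = np.flatnonzero(mask)[:5] + 2  # 1-based, after the header line
        return f"lines {rows.tolist()}"

    if np.any(~(time > 0)):
        raise ValueError(f"times must be strictly positive ({_bad_rows(~(time > 0))})")
    bad = ~np.isin(event, [EVENT_CENSORED, EVENT_AE, EVENT_DEATH])
    if bad.any():
        raise ValueError(
            f"event codes must be 0 (censored), 1 (adverse event) or 2 (death) ({_bad_rows(bad)})"
        )
    bad = ~np.isin(group, [GROUP_CONTROL, GROUP_VERUM])
    if bad.any():
        raise ValueError(f"group codes must be 0 (control) or 1 (verum) ({_bad_rows(bad)})")
    n1 = int((group == GROUP_VERUM).sum())
    return TrialDataset(
        time=time,
        event=event,
        group=group,
        condition=condition,
        n_per_arm=max(n1, len(time) - n1),
    )


def read_csv(path, condition: Condition | None = None) -> TrialDataset:
    """Read the long-format CSV dialect written by :meth:`TrialDataset.to_csv`."""
    return dataset_from_frame(pd.read_csv(path), condition=condition)


def simulate_trial(
    condition: Condition,
    n_per_arm: int = 300,
    rng: np.random.Generator | None = None,
    seed_info: SeedInfo | None = None,
) -> TrialDataset:
    """Simulate one two-arm trial under ``condition``.

    Each subject draws independent latent exponential times for the
    adverse event and for death at the arm's cause-specific rates; the
    observed time is the minimum of the two and the administrative
    censoring horizon. A latent time exactly on the horizon (measure zero)
    counts as censored.
    """
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be at least 1")
    if rng is None:
        if seed_info is None:
            raise ValueError("provide either rng or seed_info")
        rng = seed_info.spawn_rng()

    group = np.repeat([GROUP_CONTROL, GROUP_VERUM], n_per_arm)
    n = 2 * n_per_arm
    latent = np.empty((n, 2))
    for cause_col, cause in enumerate((EVENT_AE, EVENT_DEATH)):
        for g in (GROUP_CONTROL, GROUP_VERUM):
            h = condition.hazard(cause, g)
            mask = group == g
            if h == 0.0:
                latent[mask, cause_col] = np.inf
            else:
                latent[mask, cause_col] = rng.exponential(scale=1.0 / h, size=n_per_arm)

    t_min = latent.min(axis=1)
    cause_min = latent.argmin(axis=1)  # 0 -> AE, 1 -> death
    censored = t_min >= condition.censor_time
    time = np.where(censored, condition.censor_time, t_min)
    event = np.where(censored, EVENT_CENSORED, cause_min + 1)
    return TrialDataset(
        time=time,
        event=event,
        group=group,
        condition=condition,
        n_per_arm=n_per_arm,
        seed_info=seed_info,
    )


def summarize_condition(replicates: Iterable[TrialDataset]) -> pd.DataFrame:
    """Descriptive medians across replicate trials of one condition.

    For each arm and cause, takes the per-replicate sample median of the
    observed event times among subjects who experienced that cause, then
    reports the across-replicate mean and standard deviation of those
    medians. Replicates with no events of a cause in an arm contribute a
    missing value and are excluded (with a logged warning).
    """
    rows = []
    for rep_idx, ds in enumerate(replicates):
        for g in (GROUP_CONTROL, GROUP_VERUM):
            for cause in (EVENT_AE, EVENT_DEATH):
                mask = (ds.group == g) & (ds.event == cause)
                if mask.any():
                    med = float(np.median(ds.time[mask]))
                else:
                    med = np.nan
                    logger.warning(
                        "replicate %d: no events of cause %d in group %d; "
                        "excluded from the median summary",
                        rep_idx, cause, g,
                    )
                rows.append({"replicate": rep_idx, "group": g, "cause": cause, "median": med})
    if not rows:
        raise ValueError("at least one replicate is required")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["group", "cause"])["median"]
        .agg(mean_median="mean", sd_median=lambda s: s.std(ddof=1), n_used="count")
        .reset_index()
    )
    return out
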