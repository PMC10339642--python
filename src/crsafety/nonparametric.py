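"""Non-parametric estimators: Kaplan–Meier, Nelson–Aalen, Aalen–Johansen.

These back the naive-versus-competing-risks incidence comparison: the
complement of a cause-specific Kaplan–Meier curve (competing events
censored) estimates the risk of the adverse event *as if nothing else
could happen first*, while the Aalen–Johansen cumulative incidence
accounts for subjects removed by death and is therefore never larger.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import EVENT_CENSORED, TrialDataset


@dataclass
class StepCurve:
    """A right-continuous step function estimate over event times.

    ``values[i]`` is the estimate at and after ``times[i]`` (up to the
    next step). ``kind`` is one of 'survival', 'incidence' or
    'cumhazard'; ``variance`` holds an optional pointwise variance.
    """

    times: np.ndarray
    values: np.ndarray
    kind: str
    variance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variance is not None:
            self.variance = np.asarray(self.variance, dtype=float)

    def at(self, t) -> np.ndarray | float:
        """Evaluate the step function at time(s) ``t``."""
        start = 1.0 if self.kind == "survival" else 0.0
        t_arr = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t_arr, side="right")
        out = np.concatenate(([start], self.values))[idx]
        return out if out.ndim else float(out)


def _select(dataset: TrialDataset, group: int | None) -> tuple[np.ndarray, np.ndarray]:
    if group is None:
        return dataset.time, dataset.event
    mask = dataset.group == group
    if not mask.any():
        raise ValueError(f"no subjects in group {group!r}")
    return dataset.time[mask], dataset.event[mask]


def _counts(time: np.ndarray, event: np.ndarray, cause: int | None):
    """Unique event times with at-risk and event counts.

    ``cause=None`` counts failures from any cause. Subjects censored at an
    event time are counted at risk there (standard convention).
    """
    fail = event != EVENT_CENSORED if cause is None else event == cause
    uniq, d = np.unique(time[fail], return_counts=True)
    t_sorted = np.sort(time)
    n_at_risk = len(time) - np.searchsorted(t_sorted, uniq, side="left")
    return uniq, n_at_risk.astype(float), d.astype(float)


def kaplan_meier(dataset: TrialDataset, cause: int, group: int | None = None) -> StepCurve:
    """Cause-specific Kaplan–Meier survival curve.

    Competing events are treated as censored, so ``1 - KM`` is the naive
    incidence of ``cause``. Pointwise variance is Greenwood's formula.
    """
    time, event = _select(dataset, group)
    uniq, n, d = _counts(time, event, cause)
    surv = np.cumprod(1.0 - d / n)
    # Greenwood: Var = S^2 * cumsum(d / (n (n - d))); undefined once S hits 0
    gw = np.where(n > d, d / (n * np.maximum(n - d, 1.0)), np.nan)
    var = np.where(surv > 0, surv**2 * np.cumsum(gw), np.nan)
    return StepCurve(times=uniq, values=surv, kind="survival", variance=var)


def nelson_aalen(dataset: TrialDataset, cause: int, group: int | None = None) -> StepCurve:
    """Nelson–Aalen cumulative cause-specific hazard, variance ``sum d/n^2``."""
    time, event = _select(dataset, group)
    uniq, n, d = _counts(time, event, cause)
    return StepCurve(
        times=uniq,
        values=np.cumsum(d / n),
        kind="cumhazard",
        variance=np.cumsum(d / n**2),
    )


def aalen_johansen_cif(dataset: TrialDataset, cause: int, group: int | None = None) -> StepCurve:
    """Aalen–Johansen cumulative incidence of ``cause``.

    ``CIF_k(t) = sum_{t_i <= t} S(t_i-) d_k,i / n_i`` with ``S`` the
    all-cause Kaplan–Meier. At every event time the causes' incidences and
    the all-cause survival sum to one. Ties between causes at the same
    time are handled within the same increment (each cause keeps its own
    event count; ``S(t-)`` is the survival just before the shared time).
    """
    time, event = _select(dataset, group)
    uniq, n, d_all = _counts(time, event, cause=None)
    cause_times = np.sort(time[event == cause])
    d_cause = (
        np.searchsorted(cause_times, uniq, side="right")
        - np.searchsorted(cause_times, uniq, side="left")
    ).astype(float)
    surv_all = np.cumprod(1.0 - d_all / n)
    surv_prev = np.concatenate(([1.0], surv_all[:-1]))
    cif = np.cumsum(surv_prev * d_cause / n)
    return StepCurve(times=uniq, values=cif, kind="incidence", variance=None)


def curves_to_frame(curves: dict[tuple, StepCurve]):
    """Tidy export: keys are (estimator, group, cause) tuples."""
    import pandas as pd

    rows = []
    for (estimator, group, cause), curve in curves.items():
        for i, t in enumerate(curve.times):
            rows.append(
                {
                    "time": t,
                    "estimate": curve.values[i],
                    "variance": curve.variance[i] if curve.variance is not None else np.nan,
                    "group": group,
                    "cause": cause,
                    "estimator": estimator,
                }
            )
    return pd.DataFrame(rows)
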