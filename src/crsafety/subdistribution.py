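"""Fine-Gray subdistribution hazard regression, censoring-complete variant.

The subdistribution hazard of the adverse event is modelled as
``lambda_k(t | x) = lambda_0k(t) * exp(gamma * x)``; ``exp(gamma)`` is the
subdistribution hazard ratio HR_sd and ``1 - exp(-Lambda_0k(t) e^{gamma x})``
is the model's cumulative incidence. The defining twist is the extended
risk set: a subject who dies remains at risk for the adverse event until
the end of follow-up, so the model tracks cumulative incidence rather
than the instantaneous rate among survivors.

This implementation targets trials with purely administrative censoring
at one common horizon (the censoring-complete regime): every subject's
potential censoring time is known, so a subject with the competing event
at time s simply stays in the risk set up to the horizon with weight 1,
and the estimating equation is an ordinary Cox partial likelihood on the
recoded data. No inverse-probability-of-censoring weighting is needed —
datasets with any other censoring pattern are rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .cause_specific import FitResult, _newton, _PartialLikelihood
from .simdata import EVENT_AE, EVENT_CENSORED, GROUP_VERUM, TrialDataset

logger = logging.getLogger("crsafety")


class NonAdministrativeCensoringError(ValueError):
    """Censoring pattern outside the supported censoring-complete regime.

    The estimator assumes all censoring is administrative at one common
    time; random censoring would require the inverse-probability-of-
    censoring-weighted (IPCW) extension, which is out of scope.
    """


@dataclass
class FineGrayFit(FitResult):
    """Fine-Gray fit: Wald inference on gamma plus the Breslow baseline.

    ``baseline_times`` / ``baseline_cum_subhazard`` give the step function
    estimate of the baseline cumulative subdistribution hazard
    (control arm, x = 0), zero before the first event time.
    """

    baseline_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    baseline_cum_subhazard: np.ndarray = field(default_factory=lambda: np.empty(0))
    risk_set_rule: str = "censoring-complete: competing events held at risk until the administrative horizon"


def _resolve_censor_time(dataset: TrialDataset, censor_time: float | None) -> float:
    if censor_time is None:
        if dataset.condition is not None:
            return dataset.condition.censor_time
        censored = dataset.time[dataset.event == EVENT_CENSORED]
        if censored.size == 0:
            return float(dataset.time.max())
        return float(censored[0])
    return float(censor_time)


def _check_administrative(dataset: TrialDataset, censor_time: float) -> None:
    censored_times = dataset.time[dataset.event == EVENT_CENSORED]
    if censored_times.size and not np.all(censored_times == censor_time):
        raise NonAdministrativeCensoringError(
            "censored subjects do not all share the administrative horizon "
            f"({censor_time} months); random censoring would need the IPCW "
            "extension of the estimator, which is not supported"
        )
    event_times = dataset.time[dataset.event != EVENT_CENSORED]
    if event_times.size and event_times.max() > censor_time:
        raise NonAdministrativeCensoringError(
            "events observed after the stated administrative horizon"
        )


def _extended_arrays(
    dataset: TrialDataset, cause: int, censor_time: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recode the data so an ordinary Cox fit sees the extended risk set.

    Subjects failing from the competing cause are moved to the horizon as
    censored: under censoring-complete administrative censoring this
    keeps them at risk at every event time of the cause of interest, which
    is exactly the Fine-Gray risk set.
    """
    status = dataset.event == cause
    competing = (dataset.event != cause) & (dataset.event != EVENT_CENSORED)
    time = np.where(competing, censor_time, dataset.time)
    return time, status, dataset.group


def fine_gray_partial_loglik(
    dataset: TrialDataset, cause: int, gamma: float, censor_time: float | None = None
) -> float:
    """Fine-Gray (censoring-complete) partial log likelihood at ``gamma``."""
    if not math.isfinite(gamma):
        raise ValueError("gamma must be finite")
    ct = _resolve_censor_time(dataset, censor_time)
    _check_administrative(dataset, ct)
    time, status, group = _extended_arrays(dataset, cause, ct)
    return _PartialLikelihood(time, status, group).loglik(gamma)


def fit_fine_gray(
    dataset: TrialDataset, cause: int = EVENT_AE, censor_time: float | None = None
) -> FineGrayFit:
    """Fit the Fine-Gray model for ``cause`` on the extended risk set.

    ``censor_time`` defaults to the dataset condition's administrative
    horizon. With zero competing events the extended risk set is the
    ordinary one and the fit coincides with the cause-specific Cox fit.
    """
    ct = _resolve_censor_time(dataset, censor_time)
    _check_administrative(dataset, ct)
    time, status, group = _extended_arrays(dataset, cause, ct)
    pl = _PartialLikelihood(time, status, group)
    gamma, se, converged, iters = _newton(pl)

    # Breslow baseline cumulative subdistribution hazard on the extended risk set
    t1 = np.sort(time[group == GROUP_VERUM])
    t0 = np.sort(time[group != GROUP_VERUM])
    et = time[status]
    uniq, d = np.unique(et, return_counts=True)
    n1 = len(t1) - np.searchsorted(t1, uniq, side="left")
    n0 = len(t0) - np.searchsorted(t0, uniq, side="left")
    denom = n0 + n1 * math.exp(gamma)
    cum = np.cumsum(d / denom)

    return FineGrayFit(
        log_hr=gamma,
        se=se,
        n_events=pl.n_events,
        converged=converged,
        iterations=iters,
        setting="sd",
        baseline_times=uniq,
        baseline_cum_subhazard=cum,
    )


def predict_cif(fit: FineGrayFit, x: int, t) -> np.ndarray | float:
    """Model-predicted cumulative incidence ``1 - exp(-Lambda0(t) e^{gamma x})``.

    ``x`` is the group code (0 control, 1 verum). Non-decreasing in ``t``
    and bounded in [0, 1] by construction.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    idx = np.searchsorted(fit.baseline_times, t_arr, side="right")
    lam0 = np.concatenate(([0.0], fit.baseline_cum_subhazard))[idx]
    out = -np.expm1(-lam0 * math.exp(fit.log_hr * x))
    return out if out.ndim else float(out)
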