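"""Cause-specific Cox regression for the adverse event of interest.

The cause-specific hazard of the adverse event is modelled as
``h(t | x) = h0(t) * exp(beta * x)`` with a single binary treatment-arm
covariate ``x``. Subjects who die are right-censored at their death time:
only subjects who have experienced no event of any type remain in the
risk set. ``exp(beta)`` is the cause-specific hazard ratio HR_cs.

The partial likelihood is maximized by Newton–Raphson with Efron's tie
correction. For a binary covariate the risk-set sums collapse to at-risk
counts per arm, so one fit costs a sort plus a handful of O(#events)
iterations — cheap enough for tens of thousands of Monte-Carlo fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simdata import EVENT_AE, GROUP_VERUM, TrialDataset

logger = logging.getLogger("crsafety")

#: hard cap on |log HR| for monotone-likelihood (separated) fits
BETA_CAP = 15.0
#: Newton-Raphson stopping rules
SCORE_TOL = 1e-9
STEP_TOL = 1e-10
MAX_ITER = 50


class EstimationError(ValueError):
    """Raised when a model cannot be estimated on the given data."""


@dataclass
class FitResult:
    """Wald inference for one fitted log hazard ratio.

    ``log_hr`` is the coefficient of the binary group covariate, ``se``
    its model-based standard error (inverse observed information). The
    confidence interval and two-sided p-value are normal-based on the
    log-HR scale. ``converged`` is False for capped monotone-likelihood
    fits, which the pooling stage excludes.
    """

    log_hr: float
    se: float
    n_events: int
    converged: bool
    iterations: int
    setting: str = "cs"

    @property
    def hr(self) -> float:
        return math.exp(self.log_hr)

    @property
    def ci_low(self) -> float:
        return math.exp(self.log_hr - 1.959963984540054 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.log_hr + 1.959963984540054 * self.se)

    @property
    def p_value(self) -> float:
        if self.se == 0.0:
            return 1.0 if self.log_hr == 0.0 else 0.0
        z = self.log_hr / self.se
        return float(2.0 * stats.norm.sf(abs(z)))

    def to_record(self) -> dict:
        return {
            "setting": self.setting,
            "log_hr": self.log_hr,
            "hr": self.hr,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_events": self.n_events,
            "converged": self.converged,
            "iterations": self.iterations,
        }


class _PartialLikelihood:
    """Efron-adjusted Cox partial likelihood for a binary covariate.

    Pre-computes, for every unique event time: the at-risk counts per arm
    (n0, n1) and the tied event counts per arm (d0, d1), then expands each
    tie group into its Efron terms l = 0..d-1. With no ties this reduces
    to the Breslow/exact likelihood.
    """

    def __init__(self, time: np.ndarray, status: np.ndarray, group: np.ndarray):
        t1 = np.sort(time[group == GROUP_VERUM])
        t0 = np.sort(time[group != GROUP_VERUM])
        et = time[status]
        eg = group[status]
        if et.size == 0:
            raise EstimationError("no events of the requested cause in the dataset")
        uniq, inv, d = np.unique(et, return_inverse=True, return_counts=True)
        d1 = np.bincount(inv, weights=(eg == GROUP_VERUM).astype(float), minlength=len(uniq))
        d0 = d - d1
        n1 = len(t1) - np.searchsorted(t1, uniq, side="left")
        n0 = len(t0) - np.searchsorted(t0, uniq, side="left")

        # Efron expansion: one row per (unique event time, l)
        rep = np.repeat(np.arange(len(uniq)), d)
        offsets = np.concatenate(([0], np.cumsum(d)[:-1]))
        l = np.arange(d.sum()) - np.repeat(offsets, d)
        frac = l / np.repeat(d, d)
        self.a0 = n0[rep] - frac * d0[rep]
        self.a1 = n1[rep] - frac * d1[rep]
        self.sum_x_events = float(d1.sum())
        self.n_events = int(d.sum())
        self.n_events_control = int(round(float(d0.sum())))
        self.n_events_verum = int(round(float(d1.sum())))

    def loglik(self, beta: float) -> float:
        eb = math.exp(beta)
        return self.sum_x_events * beta - float(np.log(self.a0 + self.a1 * eb).sum())

    def score_info(self, beta: float) -> tuple[float, float]:
        eb = math.exp(beta)
        p = self.a1 * eb / (self.a0 + self.a1 * eb)
        return self.sum_x_events - float(p.sum()), float((p * (1.0 - p)).sum())


def _extract(dataset, cause: int):
    if isinstance(dataset, TrialDataset):
        return dataset.time, dataset.event == cause, dataset.group
    raise TypeError("expected a TrialDataset (use simdata.dataset_from_frame for tables)")


def cox_partial_loglik(dataset: TrialDataset, cause: int, beta: float) -> float:
    """Cox partial log likelihood at ``beta`` (Efron tie convention).

    Competing events are treated as right censored. Exposed so the
    maximized objective can be audited by brute force on small inputs.
    """
    if not math.isfinite(beta):
        raise ValueError("beta must be finite")
    time, status, group = _extract(dataset, cause)
    return _PartialLikelihood(time, status, group).loglik(beta)


def _newton(pl: _PartialLikelihood) -> tuple[float, float, bool, int]:
    """Maximize the 1-D concave partial likelihood; returns (beta, se, converged, iters)."""
    # separation: all events in one arm -> monotone likelihood
    if pl.n_events_control == 0 or pl.n_events_verum == 0:
        beta = BETA_CAP if pl.n_events_control == 0 else -BETA_CAP
        _, info = pl.score_info(beta)
        se = 1.0 / math.sqrt(info) if info > 0 else math.inf
        return beta, se, False, 0

    beta = 0.0
    ll = pl.loglik(beta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        score, info = pl.score_info(beta)
        if abs(score) < SCORE_TOL:
            converged = True
            break
        step = score / info
        # step halving keeps the ascent monotone
        new_beta = beta + step
        new_ll = pl.loglik(new_beta) if abs(new_beta) <= BETA_CAP else -math.inf
        halvings = 0
        while new_ll < ll and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll = pl.loglik(new_beta) if abs(new_beta) <= BETA_CAP else -math.inf
            halvings += 1
        if abs(step) < STEP_TOL:
            beta = new_beta
            converged = True
            break
        beta, ll = new_beta, new_ll
    else:
        it = MAX_ITER

    if abs(beta) >= BETA_CAP:
        beta = math.copysign(BETA_CAP, beta)
        converged = False
    _, info = pl.score_info(beta)
    se = 1.0 / math.sqrt(info) if info > 0 else math.inf
    return beta, se, converged, it


def fit_cox_cause_specific(dataset: TrialDataset, cause: int = EVENT_AE) -> FitResult:
    """Fit the cause-specific Cox model for ``cause`` (default: adverse event).

    Subjects with a competing event are censored at their event time.
    Monotone likelihoods (all events of interest in one arm) yield a
    capped estimate flagged as non-converged; datasets with zero events of
    interest raise :class:`EstimationError`.
    """
    time, status, group = _extract(dataset, cause)
    pl = _PartialLikelihood(time, status, group)
    beta, se, converged, iters = _newton(pl)
    return FitResult(
        log_hr=beta,
        se=se,
        n_events=pl.n_events,
        converged=converged,
        iterations=iters,
        setting="cs",
    )
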