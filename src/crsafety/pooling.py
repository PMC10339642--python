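"""Rubin's-rules pooling of per-replicate log hazard ratios.

Each Monte-Carlo replicate of a design condition yields one estimated
log-HR and its standard error. Rubin's rules combine the m replicate
estimates into one pooled log-HR Qbar, a within variance W (mean squared
SE), a between variance B (sample variance of the estimates), total
variance T = W + (1 + 1/m) B, and a Student-t reference with the
classical degrees of freedom nu = (m - 1) (1 + W / ((1 + 1/m) B))^2.
Pooling happens on the coefficient (log-HR) scale; the pooled HR and its
confidence limits are exponentiated back.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .cause_specific import FitResult

logger = logging.getLogger("crsafety")


class UnanalyzableCondition(ValueError):
    """Raised when fewer than two converged replicates remain to pool."""


@dataclass
class PooledResult:
    """Rubin-pooled inference for one condition and one model setting."""

    m: int
    qbar: float
    W: float
    B: float
    T: float
    df: float
    ci_low: float
    ci_high: float
    p_value: float
    n_excluded: int = 0
    setting: str = "cs"

    @property
    def hr(self) -> float:
        return math.exp(self.qbar)

    def to_record(self) -> dict:
        return {
            "setting": self.setting,
            "m": self.m,
            "log_hr": self.qbar,
            "hr": self.hr,
            "W": self.W,
            "B": self.B,
            "T": self.T,
            "df": self.df,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_excluded": self.n_excluded,
        }


def pool_rubin(fits: Sequence[FitResult], alpha: float = 0.05) -> PooledResult:
    """Pool converged fits by Rubin's rules (classical degrees of freedom).

    Requires at least two fits. ``B = 0`` (identical estimates) falls back
    to a normal reference.
    """
    fits = list(fits)
    m = len(fits)
    if m < 2:
        raise UnanalyzableCondition(f"need at least 2 fits to pool, got {m}")
    q = np.array([f.log_hr for f in fits])
    se = np.array([f.se for f in fits])
    qbar = float(q.mean())
    W = float((se**2).mean())
    B = float(q.var(ddof=1))
    # snap numerically-zero between variance (identical estimates) to 0
    if B < (1e-12 * max(1.0, float(np.abs(q).max()))) ** 2:
        B = 0.0
    T = W + (1.0 + 1.0 / m) * B

    if B > 0.0:
        df = (m - 1) * (1.0 + W / ((1.0 + 1.0 / m) * B)) ** 2
        dist = stats.t(df)
    else:
        df = math.inf
        dist = stats.norm()

    se_T = math.sqrt(T)
    if se_T == 0.0:
        p = 1.0 if qbar == 0.0 else 0.0
        crit = 0.0
    else:
        p = float(2.0 * dist.sf(abs(qbar) / se_T))
        crit = float(dist.ppf(1.0 - alpha / 2.0))
    setting = fits[0].setting
    return PooledResult(
        m=m,
        qbar=qbar,
        W=W,
        B=B,
        T=T,
        df=df,
        ci_low=math.exp(qbar - crit * se_T),
        ci_high=math.exp(qbar + crit * se_T),
        p_value=p,
        setting=setting,
    )


def pool_condition(
    fits: Iterable[FitResult],
    alpha: float = 0.05,
    label: str = "",
) -> PooledResult:
    """Filter non-converged replicates, log exclusions, and pool the rest."""
    fits = list(fits)
    kept = [f for f in fits if f.converged]
    n_excluded = len(fits) - len(kept)
    if n_excluded:
        logger.warning(
            "%s: excluded %d of %d replicates (non-convergence)",
            label or "condition", n_excluded, len(fits),
        )
    if len(kept) < 2:
        raise UnanalyzableCondition(
            f"{label or 'condition'}: only {len(kept)} converged replicates; cannot pool"
        )
    pooled = pool_rubin(kept, alpha=alpha)
    pooled.n_excluded = n_excluded
    return pooled
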