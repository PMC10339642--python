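import numpy as np
import pytest

from crsafety import Condition, SeedInfo, TrialDataset, simulate_trial


def make_dataset(time, event, group, condition=None):
    """Hand-built trial dataset from parallel lists."""
    group = np.asarray(group)
    n1 = int((group == 1).sum())
    return TrialDataset(
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=np.int64),
        group=group,
        condition=condition,
        n_per_arm=max(n1, len(group) - n1),
    )


@pytest.fixture
def null_condition():
    """Equal adverse-event medians in both arms; default death/censoring design."""
    return Condition(median_ae_verum=10.0, median_ae_control=10.0)


@pytest.fixture
def small_trial(null_condition):
    """One deterministic 600-subject trial under the null condition."""
    return simulate_trial(null_condition, 300, seed_info=SeedInfo(7, 0, 0))


def brute_force_partial_loglik(time, event, group, cause, beta,
                               extended=False, censor_time=None):
    """Independent Cox / Fine-Gray partial log likelihood by risk-set enumeration.

    No tie handling: fixtures use distinct event times. With
    ``extended=True``, subjects failing from a competing cause stay in the
    risk set until ``censor_time`` (the censoring-complete Fine-Gray rule).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    group = np.asarray(group)
    risk_time = time.copy()
    if extended:
        competing = (event != 0) & (event != cause)
        risk_time[competing] = censor_time
    ll = 0.0
    for i in np.flatnonzero(event == cause):
        at_risk = risk_time >= time[i]
        ll += beta * group[i] - np.log(np.sum(np.exp(beta * group[at_risk])))
    return ll


def brute_force_mle(time, event, group, cause, extended=False, censor_time=None):
    """Grid-search maximizer of the brute-force partial likelihood, to ~1e-7."""
    lo, hi = -10.0, 10.0
    for _ in range(6):  # successive grid refinement
        grid = np.linspace(lo, hi, 401)
        vals = [
            brute_force_partial_loglik(
                time, event, group, cause, b, extended=extended, censor_time=censor_time
            )
            for b in grid
        ]
        k = int(np.argmax(vals))
        lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    return 0.5 * (lo + hi)
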