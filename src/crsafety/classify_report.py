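"""Outcome classification and the grid-level switching report.

Each pooled condition is classified, per model setting, as superiority
(pooled HR < 1 and p <= alpha), inferiority (HR > 1 and p <= alpha) or
equivalence (p > alpha). Crossing the cause-specific outcome with the
subdistribution outcome yields nine switching categories:

    =============  ============  =============  ============
    cs \\ sd        superiority   equivalence    inferiority
    =============  ============  =============  ============
    superiority         1              2              3
    equivalence         4              5              6
    inferiority         7              8              9
    =============  ============  =============  ============

The grid report assembles the per-condition table behind the study's
summary figures: the true-HR map, the HR_cs/HR_true ratio map, the
category map, and the marginal percentages.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pooling import PooledResult
from .simdata import Condition, true_cs_hr

logger = logging.getLogger("crsafety")


class Outcome(str, enum.Enum):
    SUPERIORITY = "superiority"
    INFERIORITY = "inferiority"
    EQUIVALENCE = "equivalence"


_CATEGORY = {
    (Outcome.SUPERIORITY, Outcome.SUPERIORITY): 1,
    (Outcome.SUPERIORITY, Outcome.EQUIVALENCE): 2,
    (Outcome.SUPERIORITY, Outcome.INFERIORITY): 3,
    (Outcome.EQUIVALENCE, Outcome.SUPERIORITY): 4,
    (Outcome.EQUIVALENCE, Outcome.EQUIVALENCE): 5,
    (Outcome.EQUIVALENCE, Outcome.INFERIORITY): 6,
    (Outcome.INFERIORITY, Outcome.SUPERIORITY): 7,
    (Outcome.INFERIORITY, Outcome.EQUIVALENCE): 8,
    (Outcome.INFERIORITY, Outcome.INFERIORITY): 9,
}


def classify_outcome(pooled: PooledResult, alpha: float = 0.05) -> Outcome:
    """Three-way decision rule on the pooled HR and two-sided p-value.

    p = alpha exactly counts as significant. A significant result with
    HR exactly 1 cannot occur under Wald inference (log-HR 0 gives p = 1),
    so no tie-break is needed.
    """
    if pooled.p_value > alpha:
        return Outcome.EQUIVALENCE
    return Outcome.SUPERIORITY if pooled.hr < 1.0 else Outcome.INFERIORITY


def cross_classify(cs: Outcome, sd: Outcome) -> int:
    """Switching category 1-9 for a (cause-specific, subdistribution) pair."""
    return _CATEGORY[(cs, sd)]


@dataclass
class CategoryTable:
    """Per-condition outcomes plus the marginal summaries of the grid run."""

    table: pd.DataFrame
    marginals: dict = field(default_factory=dict)
    n_missing: int = 0

    def map_frame(self, value: str) -> pd.DataFrame:
        """Tidy heat-map table: control median (x), verum median (y), value."""
        return self.table[["median_ae_control", "median_ae_verum", value]].rename(
            columns={value: "value"}
        )


def _percent(num: int, den: int) -> float:
    return 100.0 * num / den if den else float("nan")


def grid_report(
    results: list[tuple[Condition, PooledResult | None, PooledResult | None]],
    alpha: float = 0.05,
) -> CategoryTable:
    """Assemble the per-condition classification table and its marginals.

    ``results`` holds one (condition, pooled cause-specific, pooled
    subdistribution) triple per grid cell; ``None`` entries mark
    unanalyzable cells, which are excluded from the proportions with the
    denominators disclosed in the marginals.
    """
    rows = []
    n_missing = 0
    for condition, cs, sd in results:
        hr_true = true_cs_hr(condition)
        row = {
            "median_ae_verum": condition.median_ae_verum,
            "median_ae_control": condition.median_ae_control,
            "hr_true": hr_true,
        }
        if cs is None or sd is None:
            n_missing += 1
            logger.warning(
                "condition (verum %.0f, control %.0f): unanalyzable, excluded",
                condition.median_ae_verum, condition.median_ae_control,
            )
            row.update({"category": np.nan})
            rows.append(row)
            continue
        cs_out = classify_outcome(cs, alpha)
        sd_out = classify_outcome(sd, alpha)
        row.update(
            {
                "hr_cs": cs.hr,
                "p_cs": cs.p_value,
                "ci_low_cs": cs.ci_low,
                "ci_high_cs": cs.ci_high,
                "n_excluded_cs": cs.n_excluded,
                "mc_se_cs": math.sqrt(cs.B / cs.m),
                "hr_sd": sd.hr,
                "p_sd": sd.p_value,
                "ci_low_sd": sd.ci_low,
                "ci_high_sd": sd.ci_high,
                "n_excluded_sd": sd.n_excluded,
                "mc_se_sd": math.sqrt(sd.B / sd.m),
                "outcome_cs": cs_out.value,
                "outcome_sd": sd_out.value,
                "ratio_cs_true": cs.hr / hr_true,
                "category": cross_classify(cs_out, sd_out),
            }
        )
        rows.append(row)

    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["category"]) if rows else table
    n_ok = len(ok)

    truth = {
        "superiority": _percent(int((table["hr_true"] < 1).sum()), len(table)),
        "inferiority": _percent(int((table["hr_true"] > 1).sum()), len(table)),
        "equivalence": _percent(int((table["hr_true"] == 1).sum()), len(table)),
    }
    marginals: dict = {
        "n_conditions": len(table),
        "n_analyzable": n_ok,
        "truth_percent": truth,
    }
    for setting in ("cs", "sd"):
        col = ok[f"outcome_{setting}"] if n_ok else pd.Series(dtype=object)
        marginals[f"outcome_{setting}_percent"] = {
            o.value: _percent(int((col == o.value).sum()), n_ok) for o in Outcome
        }
        marginals[f"outcome_{setting}_count"] = {
            o.value: int((col == o.value).sum()) for o in Outcome
        }
    cat_counts = {
        k: int((ok["category"] == k).sum()) if n_ok else 0 for k in range(1, 10)
    }
    marginals["category_count"] = cat_counts
    marginals["category_percent"] = {k: _percent(v, n_ok) for k, v in cat_counts.items()}
    # share of each category within its cause-specific outcome row
    row_of = {1: "superiority", 2: "superiority", 3: "superiority",
              4: "equivalence", 5: "equivalence", 6: "equivalence",
              7: "inferiority", 8: "inferiority", 9: "inferiority"}
    within = {}
    for k, outcome in row_of.items():
        den = marginals["outcome_cs_count"][outcome]
        within[k] = _percent(cat_counts[k], den)
    marginals["category_percent_within_cs_outcome"] = within

    return CategoryTable(table=table, marginals=marginals, n_missing=n_missing)


def plot_heatmaps(category_table: CategoryTable, outdir) -> list[str]:
    """Optional PNG heat maps (true HR, ratio, category). Returns file paths.

    The canonical artifacts are the CSV map tables; these renderings are a
    convenience and nothing downstream depends on them.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    specs = [
        ("hr_true", "True hazard ratio (log scale)", True),
        ("ratio_cs_true", "HR_cs / HR_true", False),
        ("category", "Switching category", False),
    ]
    for value, title, log_scale in specs:
        if value not in category_table.table.columns:
            continue
        pivot = category_table.table.pivot(
            index="median_ae_verum", columns="median_ae_control", values=value
        )
        fig, ax = plt.subplots(figsize=(6, 5))
        data = np.log(pivot.to_numpy()) if log_scale else pivot.to_numpy()
        im = ax.imshow(data, origin="lower", aspect="auto", cmap="RdYlGn_r",
                       extent=[pivot.columns.min() - 0.5, pivot.columns.max() + 0.5,
                               pivot.index.min() - 0.5, pivot.index.max() + 0.5])
        ax.set_xlabel("median time to AE, control (months)")
        ax.set_ylabel("median time to AE, verum (months)")
        ax.set_title(title)
        fig.colorbar(im, ax=ax)
        path = outdir / f"heatmap_{value}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
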