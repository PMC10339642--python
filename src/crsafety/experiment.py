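"""Experiment orchestration: simulate -> fit -> pool -> classify -> report.

One :func:`run_experiment` call executes the whole grid study from a
:class:`ExperimentConfig`: for every condition it simulates the requested
replications, fits both the cause-specific and subdistribution models,
pools the replicate log-HRs by Rubin's rules, classifies the outcomes and
writes the per-condition table, the heat-map tables, a JSON summary and a
run manifest. Randomness flows from one master seed through per-condition,
per-replicate substreams, so any single cell is reproducible in isolation
and a re-run from the manifest reproduces every table bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cause_specific import EstimationError, FitResult, fit_cox_cause_specific
from .classify_report import CategoryTable, grid_report, plot_heatmaps
from .pooling import PooledResult, UnanalyzableCondition, pool_condition
from .simdata import (
    EVENT_AE,
    Condition,
    SeedInfo,
    TrialDataset,
    condition_grid,
    read_csv,
    simulate_trial,
    summarize_condition,
)
from .subdistribution import fit_fine_gray

logger = logging.getLogger("crsafety")

SETTINGS = ("cs", "sd")


class ConfigError(ValueError):
    """Invalid experiment configuration; message names the offending field."""


@dataclass
class ExperimentConfig:
    """Configuration of one grid experiment.

    Defaults mirror the reference study design: a 20x20 grid of
    adverse-event medians (1..20 months per arm), 300 patients per arm,
    death medians 20 (verum) / 10 (control) months, administrative
    censoring at 30 months, 1000 replications per condition, alpha 0.05.
    """

    grid_min: int = 1
    grid_max: int = 20
    grid_step: int = 1
    n_per_arm: int = 300
    median_death_verum: float = 20.0
    median_death_control: float = 10.0
    censor_time: float = 30.0
    replications: int = 1000
    alpha: float = 0.05
    seed: int = 20230713
    settings: tuple[str, ...] = SETTINGS
    plots: bool = False

    def __post_init__(self) -> None:
        self.settings = tuple(self.settings)
        checks = [
            ("grid_min", self.grid_min >= 1, "must be >= 1"),
            ("grid_max", self.grid_max >= self.grid_min, "must be >= grid_min"),
            ("grid_step", self.grid_step >= 1, "must be >= 1"),
            ("n_per_arm", self.n_per_arm >= 1, "must be >= 1"),
            ("median_death_verum", self.median_death_verum > 0, "must be > 0"),
            ("median_death_control", self.median_death_control > 0, "must be > 0"),
            ("censor_time", self.censor_time > 0, "must be > 0"),
            ("replications", self.replications >= 2, "must be >= 2 (Rubin pooling)"),
            ("alpha", 0.0 < self.alpha < 1.0, "must be in (0, 1)"),
            ("seed", isinstance(self.seed, int) and self.seed >= 0, "must be a non-negative integer"),
            ("settings", set(self.settings) <= set(SETTINGS) and len(self.settings) >= 1,
             "must be a non-empty subset of ('cs', 'sd')"),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigError(f"{name}: {msg} (got {getattr(self, name)!r})")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        """Load from YAML or JSON (by extension; YAML reads JSON too)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def conditions(self) -> list[Condition]:
        return condition_grid(
            self.grid_min,
            self.grid_max,
            self.grid_step,
            median_death_verum=self.median_death_verum,
            median_death_control=self.median_death_control,
            censor_time=self.censor_time,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["settings"] = list(self.settings)
        return d


@dataclass
class ExperimentResult:
    """In-memory result of a run: the category table plus per-cell summaries."""

    config: ExperimentConfig
    category_table: CategoryTable
    condition_summaries: pd.DataFrame
    outdir: Path | None = None


def _fit_replicates(
    condition: Condition,
    cond_idx: int,
    config: ExperimentConfig,
) -> tuple[dict[str, list[FitResult]], pd.DataFrame]:
    """Simulate all replicates of one condition and fit the requested settings."""
    fits: dict[str, list[FitResult]] = {s: [] for s in config.settings}
    datasets = []
    for rep in range(config.replications):
        seed_info = SeedInfo(config.seed, cond_idx, rep)
        ds = simulate_trial(condition, config.n_per_arm, seed_info=seed_info)
        datasets.append(ds)
        for setting in config.settings:
            try:
                if setting == "cs":
                    fits[setting].append(fit_cox_cause_specific(ds, EVENT_AE))
                else:
                    fits[setting].append(fit_fine_gray(ds, EVENT_AE))
            except EstimationError as exc:
                logger.warning(
                    "condition %d replicate %d (%s): %s; replicate excluded",
                    cond_idx, rep, setting, exc,
                )
    medians = summarize_condition(datasets)
    return fits, medians


def run_experiment(config: ExperimentConfig, outdir=None) -> ExperimentResult:
    """Run the full grid experiment; optionally write all artifacts to ``outdir``."""
    t_start = _time.time()
    conditions = config.conditions()
    logger.info(
        "running %d conditions x %d replications (settings: %s)",
        len(conditions), config.replications, ",".join(config.settings),
    )

    results: list[tuple[Condition, PooledResult | None, PooledResult | None]] = []
    summaries = []
    substream_seeds = {}
    for cond_idx, condition in enumerate(conditions):
        fits, medians = _fit_replicates(condition, cond_idx, config)
        substream_seeds[cond_idx] = [config.seed, cond_idx]
        pooled: dict[str, PooledResult | None] = {}
        for setting in SETTINGS:
            if setting not in config.settings:
                pooled[setting] = None
                continue
            label = f"condition {cond_idx} ({setting})"
            try:
                p = pool_condition(fits[setting], alpha=config.alpha, label=label)
                p.setting = setting
                pooled[setting] = p
            except UnanalyzableCondition as exc:
                logger.warning("%s", exc)
                pooled[setting] = None
        results.append((condition, pooled["cs"], pooled["sd"]))
        medians.insert(0, "condition", cond_idx)
        medians.insert(1, "median_ae_verum_design", condition.median_ae_verum)
        medians.insert(2, "median_ae_control_design", condition.median_ae_control)
        summaries.append(medians)
        if (cond_idx + 1) % 50 == 0 or cond_idx + 1 == len(conditions):
            logger.info("pooled %d / %d conditions", cond_idx + 1, len(conditions))

    # with a single requested setting, reuse it on both axes so the
    # classification table stays well-formed (categories then sit on the diagonal)
    if "sd" not in config.settings:
        results = [(c, cs, cs) for c, cs, _ in results]
    if "cs" not in config.settings:
        results = [(c, sd, sd) for c, _, sd in results]

    category_table = grid_report(results, alpha=config.alpha)
    condition_summaries = pd.concat(summaries, ignore_index=True)
    result = ExperimentResult(
        config=config,
        category_table=category_table,
        condition_summaries=condition_summaries,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.outdir = outdir
        category_table.table.to_csv(outdir / "conditions.csv", index=False)
        condition_summaries.to_csv(outdir / "condition_medians.csv", index=False)
        for value, name in [
            ("hr_true", "map_hr_true.csv"),
            ("ratio_cs_true", "map_ratio_cs_true.csv"),
            ("category", "map_category.csv"),
        ]:
            if value in category_table.table.columns:
                category_table.map_frame(value).to_csv(outdir / name, index=False)
        (outdir / "summary.json").write_text(
            json.dumps(category_table.marginals, indent=2, sort_keys=True) + "\n"
        )
        manifest = {
            "config": config.to_dict(),
            "master_seed": config.seed,
            "substream_rule": "SeedSequence([master_seed, condition_index, replicate])",
            "software_version": __version__,
            "started_utc": _time.strftime("%Y-%m-%dT%H:%M:%SZ", _time.gmtime(t_start)),
            "elapsed_seconds": round(_time.time() - t_start, 3),
            "n_conditions": len(conditions),
            "n_unanalyzable": category_table.n_missing,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        if config.plots:
            plot_heatmaps(category_table, outdir)
    logger.info("experiment finished in %.1f s", _time.time() - t_start)
    return result


def fit_file(
    path,
    setting: str = "cs",
    cause: int = EVENT_AE,
    censor_time: float | None = None,
) -> FitResult:
    """Fit one model to a user-supplied long-format CSV event table.

    ``setting`` is 'cs' (cause-specific Cox) or 'sd' (Fine-Gray). In the
    'sd' setting the table must carry purely administrative censoring.
    """
    if setting not in SETTINGS:
        raise ValueError(f"setting must be one of {SETTINGS}, got {setting!r}")
    try:
        dataset = read_csv(path)
    except (ValueError, KeyError) as exc:
        raise ValueError(f"{path}: malformed event table: {exc}") from exc
    if setting == "cs":
        return fit_cox_cause_specific(dataset, cause)
    return fit_fine_gray(dataset, cause, censor_time=censor_time)
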