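"""End-to-end orchestration: simulate -> exclude -> fit -> analyze -> report.

A single master seed drives every stage: the cohort simulator spawns
per-subject seeds from it, and per-subject fitting seeds are derived from
the master seed and the subject id.  Rerunning with the same RunConfig
therefore reproduces every output table bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .agents import CohortSpec, Stage2Policy
from .fitting import fit_cohort
from .stats import (
    cohort_performance,
    cohort_stay_table,
    compare_conditions,
    delta_ancova,
    delta_regression,
    exclude_perseverators,
    stay_anova,
)
from .task import TaskConfig, default_task_config, write_trials

logger = logging.getLogger("twostep")

BUNDLE_FILES = (
    "trials.csv",
    "ground_truth.csv",
    "fits.csv",
    "stay_table.csv",
    "performance.csv",
    "stats_report.csv",
    "stats_report.txt",
    "manifest.json",
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one full synthetic-cohort analysis."""

    task: TaskConfig = field(default_factory=default_task_config)
    n_subjects_per_condition: int = 26
    jitter: float = 1.0
    stage2: Stage2Policy = field(default_factory=Stage2Policy)
    n_restarts: int = 500
    exclusion_threshold: float = 0.95
    master_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "task": self.task.to_dict(),
            "n_subjects_per_condition": self.n_subjects_per_condition,
            "jitter": self.jitter,
            "stage2": {
                "learning_rate": self.stage2.learning_rate,
                "inverse_temperature": self.stage2.inverse_temperature,
            },
            "n_restarts": self.n_restarts,
            "exclusion_threshold": self.exclusion_threshold,
            "master_seed": self.master_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d:
            d["task"] = TaskConfig.from_dict(d["task"])
        if "stage2" in d:
            d["stage2"] = Stage2Policy(**d["stage2"])
        return cls(**d)


def analysis_tables(
    trials: pd.DataFrame, fits: pd.DataFrame, config: TaskConfig
) -> dict[str, pd.DataFrame]:
    """The statistics battery on an (already excluded) cohort.

    Returns the stay table, performance table, stay-probability mixed
    ANOVA, condition comparisons of performance and of fitted parameters,
    the gamma-adjusted treatment regression and the performance-adjusted
    ANCOVA on the model-free no-reward increment.
    """
    stay = cohort_stay_table(trials)
    perf = cohort_performance(trials, config)
    out: dict[str, pd.DataFrame] = {"stay_table": stay, "performance": perf}
    out["stay_anova"] = stay_anova(stay)
    out["performance_tests"] = compare_conditions(
        perf, ["total_points", "p_advantageous"]
    )
    out["parameter_tests"] = compare_conditions(
        fits, ["gamma", "d_plus_mf", "d_plus_mb", "d_minus_mf", "d_minus_mb"]
    )
    out["delta_regression"] = delta_regression(fits)
    out["delta_ancova"] = delta_ancova(fits, perf)
    return out


def _stats_report_frame(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    parts = []
    for name in (
        "stay_anova",
        "performance_tests",
        "parameter_tests",
        "delta_regression",
        "delta_ancova",
    ):
        t = tables[name].copy()
        t.insert(0, "analysis", name)
        parts.append(t)
    return pd.concat(parts, ignore_index=True)


def _stats_report_text(tables: dict[str, pd.DataFrame]) -> str:
    lines = []
    for name in (
        "stay_anova",
        "performance_tests",
        "parameter_tests",
        "delta_regression",
        "delta_ancova",
    ):
        lines.append(f"== {name} ==")
        lines.append(tables[name].to_string(index=False, float_format="%.4g"))
        lines.append("")
    return "\n".join(lines)


def run_reproduction(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full pipeline on a synthetic cohort and write the bundle.

    Writes the trial log, ground-truth parameters, fit table, stay and
    performance tables, the stats report (CSV and text) and a manifest with
    the config, seeds, exclusions, warnings and software versions.  Returns
    the manifest dictionary.
    """
    from .agents import simulate_cohort  # local import to keep cycles out

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []

    logger.info("stage 1/4: simulating cohort (seed=%d)", config.master_seed)
    cohort = CohortSpec(
        n_subjects_per_condition=config.n_subjects_per_condition,
        jitter=config.jitter,
        stage2=config.stage2,
        master_seed=config.master_seed,
    )
    trials, truth = simulate_cohort(cohort, config.task)
    write_trials(trials, out / "trials.csv")
    truth.to_csv(out / "ground_truth.csv", index=False)

    logger.info("stage 2/4: exclusion (threshold=%.2f)", config.exclusion_threshold)
    retained, excluded = exclude_perseverators(trials, config.exclusion_threshold)
    if excluded:
        warnings_log.append(f"excluded perseverators: {excluded}")

    logger.info("stage 3/4: fitting %d subjects", retained["subject_id"].nunique())
    fits = fit_cohort(retained, n_restarts=config.n_restarts, seed=config.master_seed)
    n_bad = int((fits["n_converged"] < fits["n_restarts"]).sum())
    if n_bad:
        warnings_log.append(f"{n_bad} subject(s) had non-converged restarts")
    fits.to_csv(out / "fits.csv", index=False)

    logger.info("stage 4/4: statistics")
    tables = analysis_tables(retained, fits, config.task)
    tables["stay_table"].to_csv(out / "stay_table.csv", index=False)
    tables["performance"].to_csv(out / "performance.csv", index=False)
    _stats_report_frame(tables).to_csv(out / "stats_report.csv", index=False)
    (out / "stats_report.txt").write_text(_stats_report_text(tables))

    manifest = {
        "config": config.to_dict(),
        "excluded_subjects": excluded,
        "n_subjects_analyzed": int(retained["subject_id"].nunique()),
        "warnings": warnings_log,
        "outputs": [f for f in BUNDLE_FILES if f != "manifest.json"],
        "versions": {
            "twostep": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def rerun_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Reproduce a bundle from its manifest alone."""
    manifest = json.loads(Path(manifest_path).read_text())
    return run_reproduction(RunConfig.from_dict(manifest["config"]), out_dir)
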