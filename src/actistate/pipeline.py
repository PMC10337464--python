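"""End-to-end pipeline orchestration: simulate -> preprocess -> evaluate.

Every stage writes delimited-text artifacts plus the resolved configuration
and seed that produced them, so any output directory is reproducible from
its own contents.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig
from .evaluate import MetricReport, run_experiment
from .preprocess import WeeklyObservations, preprocess_daily
from .synthetic import SyntheticCohort, generate_cohort

__all__ = ["simulate_stage", "preprocess_stage", "evaluate_stage", "run_pipeline"]

log = logging.getLogger(__name__)


def _write_config(config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config_resolved.yaml").write_text(config.to_yaml())


def simulate_stage(config: PipelineConfig, outdir: str | Path) -> SyntheticCohort:
    outdir = Path(outdir)
    cohort = generate_cohort(config.cohort)
    cohort.write(outdir)
    _write_config(config, outdir)
    log.info("simulated %d patients x %d weeks -> %s",
             config.cohort.n_patients, config.cohort.n_weeks, outdir)
    return cohort


def preprocess_stage(
    config: PipelineConfig, indir: str | Path, outdir: str | Path
) -> WeeklyObservations:
    indir, outdir = Path(indir), Path(outdir)
    daily = pd.read_csv(indir / "daily_features.csv")
    weekly = preprocess_daily(daily, config.preprocess)
    outdir.mkdir(parents=True, exist_ok=True)
    weekly.write(outdir / "weekly_observations.csv")
    _write_config(config, outdir)
    log.info("preprocessed %d patient-weeks (%d patients retained) -> %s",
             len(weekly.data), weekly.data["patient_id"].nunique(), outdir)
    return weekly


def evaluate_stage(
    config: PipelineConfig,
    weekly: WeeklyObservations,
    scores: pd.DataFrame,
    outdir: str | Path,
) -> MetricReport:
    outdir = Path(outdir)
    report = run_experiment(
        weekly,
        scores,
        experiment=config.experiment,
        rf_spec=config.rf,
        hmm_config=config.hmm,
    )
    report.write(outdir)
    _write_config(config, outdir)
    log.info("evaluation report written -> %s", outdir)
    return report


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> MetricReport:
    """Simulate a cohort, assemble weekly observations, run the experiment."""
    outdir = Path(outdir)
    try:
        cohort = simulate_stage(config, outdir)
    except Exception as exc:
        raise RuntimeError(f"simulate stage failed: {exc}") from exc
    try:
        weekly = preprocess_stage(config, outdir, outdir)
    except Exception as exc:
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc
    try:
        return evaluate_stage(config, weekly, cohort.scores, outdir)
    except Exception as exc:
        raise RuntimeError(f"evaluate stage failed: {exc}") from exc
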