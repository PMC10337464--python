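"""Configuration dataclasses for the simulation / preprocessing / evaluation
pipeline, with YAML round-tripping and field-level validation.

Defaults encode the study conventions: a 12-week cohort, the 15 daily
tracker features, week-drop at 3 missing days, patient exclusion at 3
dropped weeks, 40-observation bin merging, a 100-tree depth-25 forest and
10 evaluation repeats.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "CohortConfig",
    "PreprocessConfig",
    "RfSpec",
    "HmmConfig",
    "ExperimentConfig",
    "PipelineConfig",
]


class ConfigurationError(ValueError):
    """Invalid or missing configuration field."""


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(f"{name} must lie in [0, 1], got {value}")


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    The latent weekly severity of each patient follows a first-order Markov
    chain with self-transition weight ``persistence``; daily features linked
    to that severity shift their mean by ``effect_size`` standard deviations
    per state step, and weekly scores are drawn inside the generating
    state's bin with Gaussian noise of ``score_noise_sd`` t-score units.
    """

    n_patients: int = 250
    n_weeks: int = 12
    n_features: int = 15
    persistence: float = 0.85
    effect_size: float = 0.5
    score_noise_sd: float = 2.0
    p_missing_day: float = 0.10
    p_missing_survey: float = 0.15
    seed: int = 0
    #: features whose daily mean is linked to the latent state
    linked_features: tuple[str, ...] = ("steps_total", "activity_total_mins")
    #: PRO instruments to emit weekly scores for
    pro_names: tuple[str, ...] = (
        "pain_interference",
        "fatigue",
        "sleep_disturbance",
        "physical_function",
        "social_activity",
        "exercise",
    )
    #: "adjacent": ordinal random walk spreading 1-persistence over
    #: neighboring states; "iid": 1-persistence goes to a uniform draw, so
    #: persistence 0 yields independent states (no temporal signal).
    state_mixing: Literal["adjacent", "iid"] = "adjacent"
    #: optional per-week linear increase of the survey-skip probability
    #: (survey fatigue); 0 disables the ramp.
    survey_fatigue_ramp: float = 0.0

    def __post_init__(self) -> None:
        for name in ("persistence", "p_missing_day", "p_missing_survey"):
            _check_prob(name, getattr(self, name))
        if self.n_weeks < 2:
            raise ConfigurationError(f"n_weeks must be >= 2, got {self.n_weeks}")
        if self.n_features < 1:
            raise ConfigurationError(f"n_features must be >= 1, got {self.n_features}")
        if self.n_patients < 1:
            raise ConfigurationError(f"n_patients must be >= 1, got {self.n_patients}")
        if self.score_noise_sd < 0:
            raise ConfigurationError("score_noise_sd must be >= 0")
        if self.state_mixing not in ("adjacent", "iid"):
            raise ConfigurationError(f"unknown state_mixing {self.state_mixing!r}")
        self.linked_features = tuple(self.linked_features)
        self.pro_names = tuple(self.pro_names)


@dataclass
class PreprocessConfig:
    """Adherence-filtering and imputation thresholds."""

    #: day boundary for daily aggregation, hours after midnight (8 PM)
    boundary_hour: float = 20.0
    #: a week is dropped if any feature misses at least this many days
    missing_day_threshold: int = 3
    #: a patient is excluded at this many dropped weeks ("more than 2")
    dropped_week_threshold: int = 3
    #: previous-week imputation may use a dropped previous week's
    #: observed values
    impute_from_dropped_weeks: bool = True
    #: fall back to the cohort feature mean when a patient never observed
    #: a feature
    cohort_fallback: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.boundary_hour < 24:
            raise ConfigurationError("boundary_hour must lie in [0, 24)")
        if self.missing_day_threshold < 1 or self.dropped_week_threshold < 1:
            raise ConfigurationError("thresholds must be positive")


@dataclass
class RfSpec:
    """Random-forest hyperparameters (study defaults)."""

    n_estimators: int = 100
    criterion: str = "gini"
    max_depth: int = 25
    min_samples_split: int = 10
    seed: int = 0


@dataclass
class HmmConfig:
    """Transition-matrix smoothing for the forward-filter model."""

    alpha: float = 1.0  # add-alpha count smoothing
    #: optional Gaussian kernel bandwidth (in state units) smoothing counts
    #: over ordinal distance; None disables it
    kernel_bandwidth: float | None = None
    prior_floor: float = 1e-6
    emission_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ConfigurationError("alpha must be >= 0")
        if self.kernel_bandwidth is not None and self.kernel_bandwidth <= 0:
            raise ConfigurationError("kernel_bandwidth must be positive or None")


@dataclass
class ExperimentConfig:
    """Train/test repetition design for model comparison."""

    n_repeats: int = 10
    test_fraction: float = 0.2
    base_seed: int = 0
    pros: tuple[str, ...] | None = None  # None = every PRO in the cohort
    models: tuple[str, ...] = ("rf", "hmm")
    min_count: int = 40
    significance_test: Literal["t", "wilcoxon"] = "t"

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ConfigurationError("n_repeats must be >= 2 to report an SD")
        if not 0.0 < self.test_fraction < 1.0:
            raise ConfigurationError("test_fraction must lie in (0, 1)")
        for m in self.models:
            if m not in ("rf", "hmm"):
                raise ConfigurationError(f"unknown model {m!r}")
        if self.pros is not None:
            self.pros = tuple(self.pros)
        self.models = tuple(self.models)


@dataclass
class PipelineConfig:
    """Top-level configuration tying the pipeline stages together."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rf: RfSpec = field(default_factory=RfSpec)
    hmm: HmmConfig = field(default_factory=HmmConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    # -- YAML round trip -------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        def _clean(obj):
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [_clean(v) for v in obj]
            return obj

        return yaml.safe_dump(_clean(self.to_dict()), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {
            "cohort": CohortConfig,
            "preprocess": PreprocessConfig,
            "rf": RfSpec,
            "hmm": HmmConfig,
            "experiment": ExperimentConfig,
        }
        kwargs = {}
        for name, section_cls in sections.items():
            raw = d.get(name, {})
            if raw is None:
                raw = {}
            if not isinstance(raw, dict):
                raise ConfigurationError(f"section {name!r} must be a mapping")
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(raw) - known
            if unknown:
                raise ConfigurationError(
                    f"unknown field(s) {sorted(unknown)} in section {name!r}"
                )
            try:
                kwargs[name] = section_cls(**raw)
            except TypeError as exc:  # missing/duplicate field
                raise ConfigurationError(f"section {name!r}: {exc}") from exc
        extra = set(d) - set(sections)
        if extra:
            raise ConfigurationError(f"unknown configuration section(s) {sorted(extra)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if not isinstance(d, dict):
            raise ConfigurationError("top-level configuration must be a mapping")
        return cls.from_dict(d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())
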