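"""Synthetic cohort generator.

Emulates a 12-week remote-monitoring study of patients wearing an activity
tracker and answering weekly PRO surveys, with the statistical structure the
downstream models assume and which no deposited dataset provides:

* a latent weekly severity state per patient following a first-order Markov
  chain (ordinal random walk with configurable self-transition weight);
* 15 daily tracker features whose cohort means and SDs match the published
  feature table, a configurable subset of which shifts monotonically with
  the latent state;
* weekly PRO t-scores drawn uniformly inside the generating state's bin
  (so binning inverts generation exactly at zero noise) plus Gaussian
  noise, clipped to [0, 100];
* missing-completely-at-random non-wear days (all features of a day vanish
  together, as a device left on the charger) and skipped surveys.

All randomness flows from a single :class:`numpy.random.Generator` seeded
by the config, so a fixed config yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binning import PRO_DEFINITIONS, BinningScheme, make_scheme
from .config import CohortConfig, ConfigurationError

__all__ = [
    "TABLE1_FEATURES",
    "FEATURE_NAMES",
    "LatentStateSequence",
    "SyntheticCohort",
    "build_chain_matrix",
    "stationary_distribution",
    "generate_state_sequences",
    "generate_daily_features",
    "generate_pro_scores",
    "apply_missingness",
    "generate_cohort",
]

#: Daily-aggregated tracker features: name -> (cohort mean, SD).
TABLE1_FEATURES: dict[str, tuple[float, float]] = {
    "sleep_total_mins": (445.01, 130.02),
    "sleep_light_mins": (261.81, 78.14),
    "sleep_rem_mins": (84.89, 37.55),
    "sleep_deep_mins": (61.79, 27.57),
    "sleep_wake_mins": (24.21, 15.28),
    "steps_total": (5775.66, 4177.02),
    "calories_total": (2211.15, 615.05),
    "wear_mins": (1259.68, 411.19),
    "hr_min": (66.25, 10.32),
    "hr_max": (97.51, 12.51),
    "activity_total_mins": (246.78, 117.55),
    "activity_light_mins": (226.93, 102.60),
    "activity_moderate_mins": (22.53, 24.57),
    "activity_heavy_mins": (24.71, 54.41),
    "sedentary_mins": (1201.98, 127.03),
}

FEATURE_NAMES: list[str] = list(TABLE1_FEATURES)

#: heart-rate features are daily extrema, everything else a daily sum
HR_FEATURES = ("hr_min", "hr_max")


@dataclass(frozen=True)
class LatentStateSequence:
    """Ground-truth weekly states of one patient for one PRO chain."""

    patient_id: str
    pro_name: str
    states: tuple[int, ...]


def build_chain_matrix(
    n_states: int, persistence: float, mixing: str = "adjacent"
) -> np.ndarray:
    """Transition matrix of the latent chain.

    ``adjacent``: weight ``persistence`` on self, remainder split over the
    ordinal neighbors (all of it to the single neighbor at the ends), i.e.
    a lazy reflected random walk.  ``iid``: remainder goes to a uniform
    draw over all states, so persistence 0 gives independent states.
    """
    if not 0.0 <= persistence <= 1.0:
        raise ConfigurationError(f"persistence must lie in [0, 1], got {persistence}")
    if n_states < 2:
        raise ConfigurationError("n_states must be >= 2")
    p = persistence
    if mixing == "iid":
        return p * np.eye(n_states) + (1 - p) * np.full((n_states, n_states), 1 / n_states)
    if mixing != "adjacent":
        raise ConfigurationError(f"unknown mixing {mixing!r}")
    T = p * np.eye(n_states)
    for i in range(n_states):
        neighbors = [j for j in (i - 1, i + 1) if 0 <= j < n_states]
        for j in neighbors:
            T[i, j] += (1 - p) / len(neighbors)
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(T.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _patient_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def generate_state_sequences(
    config: CohortConfig,
    n_states: int,
    rng: np.random.Generator | None = None,
    pro_name: str = "__shared__",
) -> list[LatentStateSequence]:
    """Draw one latent weekly state sequence per patient.

    Initial states come from the chain's stationary distribution; with
    ``persistence = 1`` every sequence is constant.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    T = build_chain_matrix(n_states, config.persistence, config.state_mixing)
    pi = stationary_distribution(T)
    n = config.n_patients
    states = np.empty((n, config.n_weeks), dtype=int)
    states[:, 0] = rng.choice(n_states, size=n, p=pi)
    cum = np.cumsum(T, axis=1)
    for t in range(1, config.n_weeks):
        u = rng.random(n)
        states[:, t] = np.array(
            [np.searchsorted(cum[s], x, side="right") for s, x in zip(states[:, t - 1], u)]
        ).clip(0, n_states - 1)
    ids = _patient_ids(n)
    return [
        LatentStateSequence(pid, pro_name, tuple(int(s) for s in row))
        for pid, row in zip(ids, states)
    ]


def states_frame(sequences: Sequence[LatentStateSequence]) -> pd.DataFrame:
    """Long-format ground-truth table (patient_id, pro_name, week_index, state)."""
    rows = [
        {"patient_id": s.patient_id, "pro_name": s.pro_name, "week_index": t + 1, "state": st}
        for s in sequences
        for t, st in enumerate(s.states)
    ]
    return pd.DataFrame(rows)


def _clipped_normal_mean(m: np.ndarray, sd: float) -> np.ndarray:
    """E[max(X, 0)] for X ~ N(m, sd)."""
    from scipy.stats import norm

    z = np.asarray(m, dtype=float) / sd
    return m * norm.cdf(z) + sd * norm.pdf(z)


def _baseline_correction(
    mean: float, sd: float, shifts: np.ndarray, weights: np.ndarray
) -> float:
    """Offset c such that the zero-clipped mixture over state shifts has
    marginal mean exactly ``mean``:

        sum_s w_s E[max(N(mean + c + shift_s, sd), 0)] = mean.

    Keeps the published feature means exact despite the non-negativity
    clip (which otherwise inflates means of features with mass near 0).
    """
    from scipy.optimize import brentq

    span = float(np.max(np.abs(shifts))) if len(shifts) else 0.0

    def gap(c: float) -> float:
        return float(weights @ _clipped_normal_mean(mean + c + shifts, sd)) - mean

    return brentq(gap, -12 * sd - span - mean, 12 * sd + span)


def generate_daily_features(
    sequences: Sequence[LatentStateSequence],
    config: CohortConfig,
    rng: np.random.Generator,
    n_states: int = 8,
) -> pd.DataFrame:
    """Daily tracker features, 7 rows per patient-week.

    Features in ``config.linked_features`` have their daily mean shifted by
    ``effect_size * (state - center)`` SDs; the rest are state-independent
    Gaussian noise around the published means.  Minute/count features are
    clipped at zero, with the baseline analytically corrected so the
    cohort marginal mean still matches the published target.
    """
    features = FEATURE_NAMES[: config.n_features]
    n_pat = len(sequences)
    n_days = config.n_weeks * 7
    center = (n_states - 1) / 2.0
    state_arr = np.array([s.states for s in sequences], dtype=float)  # (pat, week)
    day_state = np.repeat(state_arr, 7, axis=1)  # (pat, days)

    T = build_chain_matrix(n_states, config.persistence, config.state_mixing)
    pi = stationary_distribution(T)

    data = {}
    for f in features:
        mean, sd = TABLE1_FEATURES[f]
        vals = mean + sd * rng.standard_normal((n_pat, n_days))
        linked = f in config.linked_features
        if linked:
            vals += config.effect_size * sd * (day_state - center)
        if f not in HR_FEATURES:
            shifts = (
                config.effect_size * sd * (np.arange(n_states) - center)
                if linked
                else np.zeros(1)
            )
            weights = pi if linked else np.ones(1)
            vals += _baseline_correction(mean, sd, shifts, weights)
            vals = np.clip(vals, 0.0, None)
        data[f] = vals.ravel()

    pats = np.repeat([s.patient_id for s in sequences], n_days)
    day_idx = np.tile(np.arange(1, n_days + 1), n_pat)
    df = pd.DataFrame(
        {
            "patient_id": pats,
            "date_index": day_idx,
            "week_index": (day_idx - 1) // 7 + 1,
            "day_of_week": (day_idx - 1) % 7 + 1,
            **data,
        }
    )
    df["worn"] = True
    return df


def generate_pro_scores(
    sequences: Sequence[LatentStateSequence],
    scheme: BinningScheme,
    config: CohortConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Weekly scores for one PRO: uniform within the generating state's bin
    (catch-all tails truncated to width 5) plus Gaussian noise, clipped to
    [0, 100]."""
    if scheme.n_states <= max(max(s.states) for s in sequences):
        raise ConfigurationError("scheme does not cover all generated states")
    labels = np.array(scheme.labels)
    rows = []
    for s in sequences:
        lo = labels[list(s.states)]
        scores = lo + 5.0 * rng.random(len(lo))
        if config.score_noise_sd > 0:
            scores = scores + config.score_noise_sd * rng.standard_normal(len(lo))
        scores = np.clip(scores, 0.0, 100.0)
        for t, sc in enumerate(scores):
            rows.append(
                {"patient_id": s.patient_id, "week_index": t + 1, "score": float(sc)}
            )
    return pd.DataFrame(rows)


def apply_missingness(
    daily: pd.DataFrame,
    scores: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask non-wear days and skipped surveys, MCAR.

    A masked day loses all features jointly (``worn`` False, values NaN);
    a skipped survey sets every PRO column of the week to NaN with the
    ``answered_*`` flag False.  With ``survey_fatigue_ramp`` > 0 the skip
    probability grows linearly with the week index.
    """
    daily = daily.copy()
    scores = scores.copy()
    feature_cols = [c for c in daily.columns if c in TABLE1_FEATURES]
    mask_day = rng.random(len(daily)) < config.p_missing_day
    daily.loc[mask_day, feature_cols] = np.nan
    daily["worn"] = ~mask_day

    pro_cols = [c for c in scores.columns if c in PRO_DEFINITIONS]
    p = config.p_missing_survey + config.survey_fatigue_ramp * (scores["week_index"] - 1)
    p = np.clip(p.to_numpy(dtype=float), 0.0, 1.0)
    for c in pro_cols:
        mask = rng.random(len(scores)) < p
        scores.loc[mask, c] = np.nan
        scores[f"answered_{c}"] = ~mask
    return daily, scores


@dataclass
class SyntheticCohort:
    """A generated cohort: daily features, weekly scores, ground truth."""

    config: CohortConfig
    daily: pd.DataFrame
    scores: pd.DataFrame
    latent: pd.DataFrame
    schemes: dict[str, BinningScheme]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.daily.to_csv(outdir / "daily_features.csv", index=False)
        self.scores.to_csv(outdir / "pro_scores.csv", index=False)
        self.latent.to_csv(outdir / "latent_states.csv", index=False)


def generate_cohort(config: CohortConfig, n_states: int = 8) -> SyntheticCohort:
    """Run the full generator: one shared severity chain per patient drives
    both the state-linked features and every PRO's weekly score (PROs of one
    patient are therefore correlated, as symptom instruments are in
    practice)."""
    rng = np.random.default_rng(config.seed)
    sequences = generate_state_sequences(config, n_states, rng)
    daily = generate_daily_features(sequences, config, rng, n_states)

    schemes = {name: make_scheme(PRO_DEFINITIONS[name]) for name in config.pro_names}
    scores = None
    for name in config.pro_names:
        tbl = generate_pro_scores(sequences, schemes[name], config, rng)
        tbl = tbl.rename(columns={"score": name})
        scores = tbl if scores is None else scores.merge(
            tbl, on=["patient_id", "week_index"]
        )
    assert scores is not None

    daily, scores = apply_missingness(daily, scores, config, rng)
    return SyntheticCohort(
        config=config,
        daily=daily,
        scores=scores,
        latent=states_frame(sequences),
        schemes=schemes,
    )
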