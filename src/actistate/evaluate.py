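"""Experimental harness: repeated train/test evaluation of the per-week
forest and the forward-filter HMM on every PRO, with the study's metric
set (ROC-AUC for the binary severe-vs-normal task; Pearson r and
quadratic-weighted kappa for the multiclass state task).

Each of the ``n_repeats`` rounds draws a fresh patient-level train/test
split (patient-disjoint, to prevent leakage across weeks of one patient),
fits the binning scheme's sparse-bin merges on the training partition,
trains the forest, estimates transitions and the class prior from training
sequences, and evaluates both models on the held-out patients' week
sequences.  Reported are per-PRO means and SDs over rounds plus a paired
two-sided t-test of HMM vs forest per metric.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binning import (
    PRO_DEFINITIONS,
    BinningScheme,
    ProDefinition,
    assign_state,
    binarize,
    make_scheme,
    merge_sparse_bins,
    state_counts,
)
from .config import ExperimentConfig, HmmConfig, RfSpec
from .forest import RfEmissionModel, feature_importance, predict_posterior, train_rf
from .hmm import class_prior, estimate_transitions, forward_filter, severe_probability
from .metrics import pearson_ordinal, quadratic_weighted_kappa, roc_auc
from .preprocess import KEY_COLS, WeeklyObservations

__all__ = [
    "split_patients",
    "summarize_columns",
    "MetricReport",
    "run_experiment",
]

log = logging.getLogger(__name__)

METRIC_TABLE_FILES = {
    "pearson": "table2_pearson.csv",
    "kappa": "table3_kappa.csv",
    "auc": "table4_auc.csv",
}


def split_patients(
    patient_ids: Sequence[str], fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Patient-disjoint train/test partition; ``fraction`` goes to test."""
    ids = sorted(set(patient_ids))
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = int(round(fraction * len(ids)))
    if n_test == 0 or n_test == len(ids):
        raise ValueError(
            f"test fraction {fraction} leaves an empty partition for {len(ids)} patients"
        )
    test = [ids[i] for i in sorted(perm[:n_test])]
    train = [ids[i] for i in sorted(perm[n_test:])]
    return train, test


def summarize_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Column mean and maximum of every numeric column — the same
    arithmetic used for the metric tables' summary rows."""
    num = df.select_dtypes(include=[np.number])
    return pd.DataFrame({"mean": num.mean(), "max": num.max()})


def _auto_severe_override(
    scheme: BinningScheme, train_scores: np.ndarray, pro: ProDefinition
) -> dict[int, bool]:
    """Assign merged bins that straddle the severity threshold to the side
    holding the majority of their training observations."""
    override: dict[int, bool] = {}
    sides = scheme.severe_states()
    if all(s is not None for s in sides):
        return override
    idx = assign_state(train_scores, scheme)
    for i, side in enumerate(sides):
        if side is not None:
            continue
        in_bin = train_scores[idx == i]
        if in_bin.size == 0:
            override[i] = False
        else:
            frac = np.mean([binarize(s, pro) for s in in_bin])
            override[i] = bool(frac >= 0.5)
        log.warning(
            "PRO %s: merged state %d straddles the threshold; assigned severe=%s "
            "by training majority",
            pro.name,
            i,
            override[i],
        )
    return override


def _patient_sequences(
    df: pd.DataFrame, state_col: str
) -> list[list[int | None]]:
    """Ordered per-patient state sequences; None where no state is usable."""
    seqs = []
    for _, g in df.groupby("patient_id", sort=True):
        g = g.sort_values("week_index")
        seqs.append([None if pd.isna(s) else int(s) for s in g[state_col]])
    return seqs


@dataclass
class MetricReport:
    """Per-PRO metric tables, repeat-level values, importances, summaries."""

    per_repeat: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    importances: pd.DataFrame
    summary: pd.DataFrame
    config: ExperimentConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for metric, fname in METRIC_TABLE_FILES.items():
            if metric in self.tables:
                self.tables[metric].to_csv(outdir / fname)
        self.importances.to_csv(outdir / "table5_importance.csv", index=False)
        self.summary.to_csv(outdir / "summary.csv")
        self.per_repeat.to_csv(outdir / "per_repeat.csv", index=False)


def _paired_p(hmm_vals: np.ndarray, rf_vals: np.ndarray, kind: str) -> float:
    """Two-sided paired test over repeat-level metric values; identical or
    degenerate inputs report p = 1."""
    ok = np.isfinite(hmm_vals) & np.isfinite(rf_vals)
    h, r = hmm_vals[ok], rf_vals[ok]
    if len(h) < 2 or np.allclose(h, r):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if kind == "wilcoxon":
            p = stats.wilcoxon(h, r).pvalue
        else:
            p = stats.ttest_rel(h, r).pvalue
    return 1.0 if not np.isfinite(p) else float(p)


def run_experiment(
    weekly: WeeklyObservations,
    scores: pd.DataFrame,
    experiment: ExperimentConfig | None = None,
    rf_spec: RfSpec | None = None,
    hmm_config: HmmConfig | None = None,
) -> MetricReport:
    """Run the repeated train/test comparison on a preprocessed cohort.

    ``scores`` is the weekly PRO table (one column per PRO, NaN for skipped
    surveys).  Weeks that are non-dropped but unanswered still contribute
    emissions to the forward filter; dropped weeks are pure prediction
    steps; only answered, non-dropped test weeks enter the metrics.
    """
    experiment = experiment or ExperimentConfig()
    rf_spec = rf_spec or RfSpec()
    hmm_config = hmm_config or HmmConfig()

    pro_names = experiment.pros or tuple(
        c for c in scores.columns if c in PRO_DEFINITIONS
    )
    if not pro_names:
        raise ValueError("no PRO columns found in the score table")

    df = weekly.data.merge(
        scores[["patient_id", "week_index", *pro_names]], on=KEY_COLS, how="left"
    ).sort_values(KEY_COLS)
    slots = weekly.slots
    patient_ids = df["patient_id"].unique()

    rows = []  # per-repeat metric records
    imp_acc: dict[str, list[pd.DataFrame]] = {p: [] for p in pro_names}

    for rep in range(experiment.n_repeats):
        seed = experiment.base_seed + rep
        train_ids, test_ids = split_patients(
            patient_ids, experiment.test_fraction, seed
        )
        in_train = df["patient_id"].isin(train_ids)
        in_test = df["patient_id"].isin(test_ids)

        for pro_name in pro_names:
            pro = PRO_DEFINITIONS[pro_name]
            answered = df[pro_name].notna()
            usable = ~df["dropped"] & answered

            train_mask = in_train & usable
            train_scores = df.loc[train_mask, pro_name].to_numpy(dtype=float)
            if train_scores.size == 0:
                raise ValueError(
                    f"repeat {rep}: no usable training weeks for PRO {pro_name!r}"
                )
            scheme = make_scheme(pro, min_count=experiment.min_count)
            scheme = merge_sparse_bins(scheme, state_counts(train_scores, scheme))
            S = scheme.n_states
            override = _auto_severe_override(scheme, train_scores, pro)

            y_train = assign_state(train_scores, scheme)
            try:
                model = train_rf(
                    df.loc[train_mask, slots].to_numpy(dtype=float),
                    y_train,
                    S,
                    RfSpec(
                        n_estimators=rf_spec.n_estimators,
                        criterion=rf_spec.criterion,
                        max_depth=rf_spec.max_depth,
                        min_samples_split=rf_spec.min_samples_split,
                        seed=seed,
                    ),
                    features=weekly.features,
                )
            except ValueError as exc:
                raise ValueError(
                    f"repeat {rep}, PRO {pro_name!r}: {exc}"
                ) from exc
            imp_acc[pro_name].append(feature_importance(model))

            # transition matrix and prior from training sequences
            tr = df[in_train].copy()
            tr["_state"] = np.where(
                ~tr["dropped"] & tr[pro_name].notna(),
                assign_state(tr[pro_name].fillna(0.0).to_numpy(dtype=float), scheme),
                np.nan,
            )
            transitions = estimate_transitions(
                _patient_sequences(tr, "_state"),
                S,
                alpha=hmm_config.alpha,
                kernel_bandwidth=hmm_config.kernel_bandwidth,
            )
            prior = class_prior(y_train, S, floor=hmm_config.prior_floor)

            # evaluate on held-out patients, week by week
            true_states: list[int] = []
            rf_preds: list[int] = []
            hmm_preds: list[int] = []
            rf_sev: list[float] = []
            hmm_sev: list[float] = []
            true_bin: list[bool] = []

            te = df[in_test]
            for _, g in te.groupby("patient_id", sort=True):
                g = g.sort_values("week_index")
                X = g[slots].to_numpy(dtype=float)
                observed = ~g["dropped"].to_numpy(dtype=bool)
                posteriors: list[np.ndarray | None] = [None] * len(g)
                if observed.any():
                    post = predict_posterior(model, X[observed])
                    for k, j in enumerate(np.flatnonzero(observed)):
                        posteriors[j] = post[k]
                belief = forward_filter(
                    posteriors,
                    transitions,
                    prior,
                    emission_floor=hmm_config.emission_floor,
                )
                g_scores = g[pro_name].to_numpy(dtype=float)
                for j in range(len(g)):
                    if posteriors[j] is None or not np.isfinite(g_scores[j]):
                        continue
                    sc = g_scores[j]
                    true_states.append(int(assign_state(sc, scheme)))
                    true_bin.append(binarize(sc, pro))
                    rf_preds.append(int(np.argmax(posteriors[j])))
                    hmm_preds.append(int(np.argmax(belief.beliefs[j])))
                    rf_sev.append(severe_probability(posteriors[j], scheme, override))
                    hmm_sev.append(
                        severe_probability(belief.beliefs[j], scheme, override)
                    )

            for model_name, preds, sev in (
                ("rf", rf_preds, rf_sev),
                ("hmm", hmm_preds, hmm_sev),
            ):
                if model_name not in experiment.models:
                    continue
                r = pearson_ordinal(preds, true_states)
                if np.isnan(r):
                    log.warning(
                        "repeat %d, PRO %s, model %s: zero-variance predictions; "
                        "Pearson r recorded as missing",
                        rep,
                        pro_name,
                        model_name,
                    )
                k = quadratic_weighted_kappa(preds, true_states, S)
                try:
                    a = roc_auc(true_bin, sev)
                except ValueError:
                    log.warning(
                        "repeat %d, PRO %s: single-class binary labels; "
                        "AUC recorded as missing",
                        rep,
                        pro_name,
                    )
                    a = np.nan
                rows.extend(
                    [
                        {"repeat": rep, "pro": pro_name, "model": model_name,
                         "metric": "pearson", "value": r},
                        {"repeat": rep, "pro": pro_name, "model": model_name,
                         "metric": "kappa", "value": k},
                        {"repeat": rep, "pro": pro_name, "model": model_name,
                         "metric": "auc", "value": a},
                    ]
                )

    per_repeat = pd.DataFrame(rows)
    tables = _build_tables(per_repeat, pro_names, experiment)
    summary = _build_summary(tables)
    importances = _build_importances(imp_acc)
    return MetricReport(
        per_repeat=per_repeat,
        tables=tables,
        importances=importances,
        summary=summary,
        config=experiment,
    )


def _build_tables(
    per_repeat: pd.DataFrame,
    pro_names: Sequence[str],
    experiment: ExperimentConfig,
) -> dict[str, pd.DataFrame]:
    tables = {}
    for metric in ("pearson", "kappa", "auc"):
        recs = {}
        for pro_name in pro_names:
            sub = per_repeat[
                (per_repeat["pro"] == pro_name) & (per_repeat["metric"] == metric)
            ]
            row = {}
            vals = {}
            for model in experiment.models:
                v = sub.loc[sub["model"] == model, "value"].to_numpy(dtype=float)
                vals[model] = v
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    row[f"{model}_mean"] = float(np.nanmean(v)) if v.size else np.nan
                    row[f"{model}_sd"] = (
                        float(np.nanstd(v, ddof=1)) if v.size > 1 else np.nan
                    )
            if {"rf", "hmm"} <= set(vals):
                row["p_value"] = _paired_p(
                    vals["hmm"], vals["rf"], experiment.significance_test
                )
            recs[pro_name] = row
        tables[metric] = pd.DataFrame(recs).T.rename_axis("pro")
    return tables


def _build_summary(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    parts = []
    for metric, tbl in tables.items():
        mean_cols = [c for c in tbl.columns if c.endswith("_mean")]
        s = summarize_columns(tbl[mean_cols])
        s.insert(0, "metric", metric)
        parts.append(s.rename_axis("column").reset_index())
    return pd.concat(parts, ignore_index=True)


def _build_importances(imp_acc: dict[str, list[pd.DataFrame]]) -> pd.DataFrame:
    parts = []
    for pro_name, tbls in imp_acc.items():
        if not tbls:
            continue
        merged = (
            pd.concat(tbls)
            .groupby("feature", sort=False)["importance"]
            .mean()
            .sort_values(ascending=False)
            .reset_index()
        )
        merged.insert(0, "pro", pro_name)
        merged["rank"] = np.arange(1, len(merged) + 1)
        parts.append(merged)
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["pro", "feature", "importance", "rank"]
    )
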