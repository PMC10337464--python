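# File formats

All artifacts are UTF-8 delimited text with a header row; missing values
are empty fields. Key columns are `patient_id` (string) and `week_index`
(1-based integer).

## daily_features.csv

One row per patient-day.

| column | meaning |
| --- | --- |
| `patient_id` | patient identifier |
| `date_index` | 1-based day within the study |
| `week_index` | 1-based week, `(date_index − 1) // 7 + 1` |
| `day_of_week` | 1..7 within the week |
| 15 feature columns | `sleep_total_mins`, `sleep_light_mins`, `sleep_rem_mins`, `sleep_deep_mins`, `sleep_wake_mins`, `steps_total`, `calories_total`, `wear_mins`, `hr_min`, `hr_max`, `activity_total_mins`, `activity_light_mins`, `activity_moderate_mins`, `activity_heavy_mins`, `sedentary_mins` |
| `worn` | False when the day is a non-wear day (all features empty) |

## pro_scores.csv

One row per patient-week: one column per PRO
(`pain_interference`, `fatigue`, `sleep_disturbance`,
`physical_function`, `social_activity`, `exercise`) plus a boolean
`answered_<pro>` flag per instrument; a skipped survey leaves the score
empty with the flag False.

## latent_states.csv

Simulator ground truth: `patient_id`, `pro_name`, `week_index`, `state`
(ordinal index 0..7 of the shared latent severity chain).

## weekly_observations.csv

One row per retained patient-week: the keys, 105 slot columns named
`<feature>_d<day>` in feature-major order, a boolean `dropped` flag, and
`imputed_slots` — a `;`-joined list of the slot names that were filled
by imputation.

## Evaluation outputs

`table2_pearson.csv`, `table3_kappa.csv`, `table4_auc.csv`: one row per
PRO with `rf_mean`, `rf_sd`, `hmm_mean`, `hmm_sd`, `p_value`.
`table5_importance.csv`: `pro`, `feature`, `importance`, `rank`.
`summary.csv`: column means and maxima of the per-model mean columns.
`per_repeat.csv`: long-format round-level metric values.
`config_resolved.yaml`: the exact configuration (including seeds) that
produced the directory.
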