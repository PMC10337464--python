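"""Generate a synthetic remote-monitoring cohort and look at its structure.

Builds 50 patients followed for 12 weeks: a latent weekly severity state
per patient (Markov chain, self-transition 0.85), 15 daily tracker
features two of which track the latent state, six weekly PRO scores, and
realistic missingness (10% non-wear days, 15% skipped surveys).
"""

from actistate import CohortConfig, generate_cohort

cohort = generate_cohort(CohortConfig(n_patients=50, seed=42))

print(f"daily feature rows : {len(cohort.daily)}")
print(f"weekly score rows  : {len(cohort.scores)}")
print(f"non-wear day frac  : {1 - cohort.daily['worn'].mean():.3f}")
print(f"skipped surveys    : {1 - cohort.scores['answered_fatigue'].mean():.3f}")
print("\nmean daily steps by latent state (monotone link):")
linked = cohort.daily.merge(cohort.latent, on=["patient_id", "week_index"])
print(linked.groupby("state")["steps_total"].mean().round(0).to_string())
# Higher latent states mean higher daily step counts; the gap between
# adjacent states is the generator's effect size (0.5 SD/state by default).
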