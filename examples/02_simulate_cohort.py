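"""Simulate the two-site study cohort (100 + 120 respondents).

Choices are drawn from the maxdiff pair logit on the study's published
pooled log-odds, so the synthetic data have the preference structure the
estimator assumes; the printed counts are the survey's bookkeeping.
"""

from bwsprefs import build_bibd, pooled_study_spec, simulate_cohort, statin_catalogue

catalogue = statin_catalogue()
design = build_bibd(13, 4)
ethiopia, switzerland = pooled_study_spec(seed=42)

table = simulate_cohort(ethiopia, design, catalogue).concat(
    simulate_cohort(switzerland, design, catalogue)
)
print(f"respondents: {table.responses['respondent_id'].nunique()}")
print(f"responses (respondent x scenario rows): {len(table.responses)}")
print("\nFirst three responses:")
print(table.responses.head(3).to_string(index=False))
print("\nCovariate summary by site (age in years):")
print(table.covariates.groupby('site')['age'].describe()[['count', 'mean', 'std']].round(1))
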