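"""Generate a synthetic EHR cohort and curate it into an analysis matrix.

The generator plants two correlated comorbidity blocks, independent noise
indicators, demographic columns and an outcome drawn from a logistic model;
curation applies the age filter, BMI categorization and complete-case
filtering, ledgering every dropped record and variable.
"""

from ehrnet import (
    BlockSpec,
    CohortSpec,
    CurationConfig,
    apply_curation,
    generate_cohort,
)

blocks = (
    BlockSpec("cardio", n_features=5, within_block_association=8.0, baseline_prevalence=0.30),
    BlockSpec("renal", n_features=5, within_block_association=8.0, baseline_prevalence=0.20),
)
betas = {f"cardio_{i}": 0.7 for i in range(1, 6)}
spec = CohortSpec(
    n_patients=3000,
    blocks=blocks,
    n_noise_features=15,
    outcome_coefficients=betas,
    outcome_intercept=-2.0,
    n_redundant=2,
    missing_rate=0.02,
    seed=42,
)

cohort, truth = generate_cohort(spec)
print(f"cohort: {cohort.n_records} records x {cohort.data.shape[1]} columns")
print(f"outcome prevalence: {cohort.data['outcome'].mean():.3f}")
print(f"cardio_1 prevalence: {cohort.data['cardio_1'].mean():.3f} (target 0.30)")
print(f"planted predictors: {sorted(truth.predictive_set)}")

curated = apply_curation(cohort, CurationConfig(min_age=18.0))
print(f"\ncurated: {curated.n_records} records x {curated.n_variables} variables")
print("drop ledger by reason:")
print(curated.ledger.groupby(["kind", "reason"]).size().to_string())
print(f"\nBMI indicator columns: {[c for c in curated.features.columns if c.startswith('bmi_')]}")
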