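# ehrnet

Feature selection and mutual-information comorbidity networks for
EHR-style binary cohorts.

Administrative health data reduces each patient to a row of mostly
dichotomous indicators — diagnosis codes, medication flags, a few
demographics — plus a binary outcome such as a type-2-diabetes label.
`ehrnet` implements an inference chain for asking two questions of such a
matrix: *which variables carry outcome signal*, and *how do those variables
cluster into comorbidity groups among the affected patients*. Because real
claims cohorts cannot be redistributed, the package ships a synthetic
cohort generator with planted ground truth, so every stage can be validated
end to end on data whose answers are known.

## The pipeline

1. **Simulate** (or load) a patient-by-variable cohort. Correlated
   comorbidity blocks are induced by a shared latent factor per block, with
   the mixing weight solved numerically to hit a requested within-block
   odds ratio while preserving each variable's marginal prevalence. The
   outcome is drawn from a logistic model over chosen variables; redundant
   near-duplicate columns and completely-at-random missingness are added on
   request.
2. **Curate**: drop excluded outcome labels and under-age records, apply
   dichotomization rules, convert BMI to four weight-category indicators,
   drop over-missing variables, then keep complete cases. Every dropped
   record and variable lands in a ledger with its reason.
3. **Select** outcome-associated variables with two independent arms:
   - *Random forest*: bagged CART trees with explicit bootstrap resamples;
     per-variable mean-decrease-accuracy (out-of-bag permutation) and
     Gini-decrease importances; selection by a boxplot-derived outlier
     threshold (`median + 1.58·IQR`) on each importance distribution.
   - *L1-logistic regression*: penalty path from `λ_max` downward, 10-fold
     cross-validated deviance, one-standard-error rule; selected variables
     are those with nonzero coefficients.
   Both arms are scored on a held-out split (accuracy, precision, recall,
   ROC AUC).
4. **Score** the selected variables jointly in one multivariable logistic
   regression; each gets a Wald z = β/SE and a two-sided p-value. Perfect
   separation is flagged and reported, never silently regularized.
5. **Network**: among significant variables, test every pair's mutual
   information on the *case* subpopulation with a Monte-Carlo permutation
   test (B permutations, add-one p-value), correct with Benjamini-Hochberg,
   and keep edges that are significant *and* share at least `min_patients`
   positive patients. Nodes carry |z| sizes and sex prevalence.
6. **Communities**: fast-greedy (bottom-up, merge-by-best-ΔQ) modularity
   maximization with a full dendrogram and best-cut partition. An
   exhaustive set-partition oracle is included for verification on small
   graphs.

A one-command orchestrator runs all stages with a single master seed
(per-stage salted sub-seeds) and writes byte-reproducible CSV/GraphML
artifacts plus a SHA-256 manifest.

## Worked example

`examples/feature_selection.py` plants 5 true predictors among 45 noise
indicators (n = 3,000) and runs both arms:

```text
--- RF arm ---
selected 4 variables
  true predictors found: ['sig_2', 'sig_3', 'sig_4', 'sig_5'] (4/5)
  false selections: []
  held-out metrics: {'accuracy': 0.6767, 'precision': 0.6582, 'recall': 0.7045, 'roc_auc': 0.7285}

--- LASSO arm ---
selected 7 variables
  true predictors found: ['sig_1', 'sig_2', 'sig_3', 'sig_4', 'sig_5'] (5/5)
  false selections: ['noise_1', 'noise_13']
  held-out metrics: {'accuracy': 0.7011, 'precision': 0.7021, 'recall': 0.675, 'roc_auc': 0.7615}
```

`examples/network_and_communities.py` plants two comorbidity blocks and
recovers them from the case-only MI network:

```text
cases: 908 of 2500 records
significant nodes (p < 0.05): 13 of 32 scored
network: 13 nodes, 70 edges
best modularity Q = 0.3821 at 2 communities:
  community cardio_1: ['cardio_1', ..., 'cardio_6', 'noise_19']
  community renal_1: ['renal_1', ..., 'renal_6']
```

See also `examples/simulate_and_curate.py` and `examples/full_pipeline.py`.

## Command line

```bash
ehrnet simulate --config spec.yaml --seed 2 --out simdir
ehrnet curate --in simdir/cohort.csv --config curation.yaml --out curdir
ehrnet select --in curdir/curated.csv --method both --seed 2 --out seldir
ehrnet score --in curdir/curated.csv --selected seldir/selected_rf.csv --out scores.csv
ehrnet network --in curdir/curated.csv --nodes scores.csv --out netdir
ehrnet communities --in netdir/network.graphml --out communities.csv
ehrnet run --config run.yaml --out outdir     # the whole flow at once
```

`run.yaml` mirrors `RunConfig` (see `examples/full_pipeline.py` for the
equivalent library call and `tests/test_cli.py` for a worked YAML).

## Tests and reproducing the headline numbers

```bash
python -m pytest -q tests/                 # unit, property and end-to-end statistical tests
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` reruns the main computations from a single seed and
writes the headline quantities (MI oracle agreement, permutation-null
calibration, modularity-oracle gap, planted-block community recovery,
planted-predictor selection recovery, null z-score rejection rate, pipeline
dimensions and byte-identity of a rerun) as JSON. All numbers in this
README come from the committed example scripts run as-is.

## Repository layout

```
src/ehrnet/       library (cohort, synth, curation, selection, scoring,
                  minet, communities, pipeline, cli)
examples/         narrative scripts, one per capability
scripts/          acceptance runner
tests/            pytest suite
docs/methods.md   model details, parameter defaults, design rationale
```

## Notes

The synthetic generator emulates the statistical shape of an administrative
diabetes cohort, not its clinical content; see `docs/methods.md` for the
model, the reasoning behind the selection thresholds, and known
limitations.
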