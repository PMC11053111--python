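# polarmace

Risk modelling of Major Adverse Cardiac Events (MACE) from quantitative
[82Rb]-PET myocardial-perfusion polar maps.

Quantitative myocardial perfusion imaging measures absolute blood flow
(mL/min/g) across the left ventricle, summarised as a polar ("bull's-eye")
map. The open question this package addresses is *how much of that map a
prognostic model should use*: a single global average, the 17 standard AHA
segments, dozens of radiomics descriptors, or a convolutional network over
the raw map. `polarmace` implements all four model families over three
candidate perfusion signals, together with the repeated-split validation
protocol needed to compare them fairly, and a calibrated synthetic-cohort
generator so every stage can be exercised without access to clinical data.

It is intended for researchers in cardiac imaging and medical image
analysis who want a tested, reproducible reference implementation of this
model-comparison pipeline.

## Data model and signals

A perfusion study is a pair of 16×36 matrices `S[m, n]` (stress and rest):
row `m` is the radial position (row 1 at the apex/pole, row 16 basal),
column `n` the angular position in 10° steps, with columns 1 and 36 being
spatial neighbours (periodic wrap). Raw 24×36 exports are truncated to
their first 16 rows on load. Three signals are derived per pixel:

- **sMBF** — stress myocardial blood flow (mL/min/g), used as measured;
- **MFR** — myocardial flow reserve, `sMBF / rMBF`, after the rest flow is
  normalised to a reference rate-pressure product of 8500 mmHg/min
  (`rMBF ← rMBF · 8500 / (HR · SBP)`);
- **MFC radius** — the flow-capacity radius `√(sMBF² + MFR²)`, a scalar
  summary of the two-dimensional flow-capacity representation.

## Model families

| family | features | estimator |
|---|---|---|
| `global` | 1 (LV mean) | ElasticNet logistic regression |
| `regional` | 17 (AHA segment means) | ElasticNet logistic regression |
| `radiomics_intensity` | 18 first-order statistics | ElasticNet logistic regression |
| `radiomics_all` | 93 (18 intensity + 75 texture) | ElasticNet logistic regression |
| `cnn1` / `cnn2` | raw 16×36 matrix | small CNNs (~19k / ~535k parameters) |
| `clinical` | 19 covariates (one-hot encoded) | ElasticNet logistic regression |
| `fused:<family>` | image + clinical | unweighted average of probabilities |

All linear families tune only the ElasticNet mixing parameter over the
sparsity-promoting grid `{0.50, 0.85, 0.9, 0.92, 0.95, 0.97, 0.98, 0.99,
0.995, 0.999, 1.0}` by stratified 5-fold cross-validation (AUC, or
Harrell's C-index for the Cox survival variants), then refit at the winner.
Texture features follow the IBSI-compatible GLCM/GLRLM/GLSZM/NGTDM/GLDM
definitions with fixed-bin-width discretization (pooled value range / 16).
CNN training sets are quadrupled by the two polar-map augmentations
(±10° column shifts with periodic wrap, and a radial stretch that erases
the 3 outer rows and re-interpolates 13 → 16 rows).

## Validation protocol

For each model family: 100 stratified 75/25 train-test splits with fixed,
shared per-repeat seeds; the minority (event) class triplicated in the
training set (234 cases with 47 events give 175 training cases → 245 after
oversampling, 105 positive); features standardized with training
statistics only; per split the test AUC and the Youden-index operating
point (or C-index) are recorded; means are reported with 95% percentile
bootstrap confidence intervals (1000 resamples), paired bootstrap tests
compare families on the shared splits, and median-score risk groups are
contrasted with Kaplan–Meier curves and a log-rank test.

## Worked example

```python
from polarmace import (
    GeneratorConfig, simulate_cohort, SplitPlan, ExperimentConfig, run_experiment,
)
from polarmace.evaluate import results_frame

records, truths = simulate_cohort(GeneratorConfig(seed=1))
print(f"patients: {len(records)}, events: {sum(r.outcome.event for r in records)}")

plan = SplitPlan(n_repeats=10)
for family in ("global", "regional"):
    results, summary, _ = run_experiment(
        records, family, plan, ExperimentConfig(signal="mfc_radius")
    )
    row = summary.means.loc[family]
    frame = results_frame(results)
    print(
        f"{family:<9} AUC {100*row['mean']:.1f}% [{100*row['ci_lo']:.1f}, {100*row['ci_hi']:.1f}]  "
        f"sens {100*frame['sensitivity'].mean():.1f}%  spec {100*frame['specificity'].mean():.1f}%"
    )
```

prints

```
patients: 234, events: 47
global    AUC 74.1% [70.2, 77.4]  sens 70.8%  spec 75.7%
regional  AUC 78.4% [74.9, 81.8]  sens 80.8%  spec 73.2%
```

i.e. on this synthetic cohort (focal territory defects plus a global-flow
effect driving risk) the 17-segment model outperforms the global average,
with the bracketed 95% bootstrap confidence intervals of the mean test AUC
across the 10 splits, and mean sensitivity/specificity at the per-split
Youden cutoffs.

The same pipeline is available from the shell:

```sh
polarmace simulate --n-patients 234 --seed 1 --out cohort/
polarmace run --cohort cohort/manifest.csv --models global,regional \
    --signal mfc_radius --n-repeats 100 --out results/
polarmace report --results results/
```

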