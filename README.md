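# patternreg

Wholebrain pattern-regression decoding of continuous clinical scores from
per-subject fMRI contrast maps, built as a reusable, fully tested pipeline:

- **Gaussian-process regression** with a linear kernel (evidence-maximized
  hyperparameters, constant mean at the training-target mean) and
  **dual-to-primal weight reconstruction** (`w = θ·Xᵀα`), plus a
  probit-Laplace **GP classifier** for the categorical comparison.
- **Scanner-balanced cross-validation** (2- and 5-fold): stratified dealing
  across folds with a t-test acceptance check that the target distribution
  does not differ between folds; predictions concatenated across folds.
- **Train/test-separated confound removal**: confound regressions are fit on
  training rows only and applied unchanged to test rows; targets are never
  residualized.
- **Permutation inference** on Pearson r and normalized MSE (mean squared
  error divided by the range of the predicted scores), with both the literal
  `count/n` p-value and the conservative `(count+1)/(n+1)` variant, and a
  Bonferroni threshold over scales × CV schemes.
- **Atlas-based weight localization**: fold-averaged unit-norm weight maps
  summarized per region as normalized weights (two modes: the literal
  double-size-normalized formula and the plain regional mean), ranked by
  their share of the total.
- **Synthetic cohort generator**: truncated-normal clinical scales calibrated
  to published per-group moments, zero-inflated clinician scales, a
  two-scanner split with an additive scanner image offset, gender-score
  association, frontal NaN-dropout patches, and a low-SNR spatially
  distributed score-linked signal — so the entire pipeline runs and is
  testable with no external data.

Quality-control stages mirror the source analysis: subjects with >15%
non-finite voxels (inside a scope mask) are excluded, and the feature matrix
uses only voxels finite in every remaining subject.

## Test

```bash
python -m pytest tests/
```

The suite includes per-module unit tests with independent oracles (dense
linear-algebra checks of the GP evidence, exhaustive loop oracles for
masking, hand-computed metric values), property tests (dual/primal
equivalence, permutation calibration on the achievable grid, mask
monotonicity) and `tests/test_acceptance.py` with one test per acceptance
criterion. The permutation-calibration criterion runs 200 null cohorts ×
100 permutations and takes ~4–5 minutes on one CPU; everything else is fast.

## Command-line usage

All stages are driven by one YAML config (any omitted key falls back to the
defaults in `patternreg.pipeline.DEFAULT_CONFIG`):

```yaml
# config.yaml
cohort:
  n_distressed: 82
  n_healthy: 72
  grid_shape: [12, 12, 12]
  signal_snr: 0.4
  n_signal_voxels: 60
  dropout_fraction: 0.1
atlas: {n_regions: 27}
decode:
  scales: [stai_t, stai_s, masq_d, ham_a, hdrs]
  cv_schemes: [2, 5]
  n_permutations: 1000
seeds: {cohort: 0, folds: 1, permutations: 2}
```

```bash
patternreg --config config.yaml simulate          # cohort + atlas on disk
patternreg --config config.yaml decode            # GPR grid + permutations
patternreg --config config.yaml classify          # distressed-vs-healthy GPC
patternreg --config config.yaml localize run/weights_whole_stai_t_k2.nii.gz
patternreg --config config.yaml report            # Table-style metrics grid
```

`decode` writes `report.json` (metrics, p-values, provenance with config
hash and seeds), per-cell weight maps (unit-norm NIfTI), fold and scatter
CSVs, the exclusion report and the common mask. Outputs are byte-identical
across reruns of the same config and seeds.

## Library usage

```python
import numpy as np
from patternreg import (
    CohortConfig, generate_cohort, make_balanced_folds,
    CrossValidator, GPRSpec, pearson_r, normalized_mse, permutation_test,
)
from patternreg.synthetic import cohort_to_table
from patternreg.masking import assemble_features, build_common_mask, default_scope_mask

records, truth = generate_cohort(CohortConfig(signal_snr=0.4, seed=0))
volumes = [r.volume for r in records]
table = cohort_to_table(records)
mask = build_common_mask(volumes, default_scope_mask(volumes))
features = assemble_features(volumes, mask)
folds = make_balanced_folds(table, k=2, target="stai_t", rng=np.random.default_rng(1))
cv = CrossValidator(features.values, table, ["age"], folds, GPRSpec())
result = cv.run(table["stai_t"].to_numpy())
print(pearson_r(result.predicted, result.actual))
```

`CrossValidator` precomputes everything target-independent (confound models,
per-fold kernels and their eigendecompositions), so permutation tests that
re-run the cross-validation thousands of times stay cheap.

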