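# acfkit

Missing-value tolerant classification of omics samples from **average
correlations as features (ACF)**, with the correlation-based comparators
(KNN, distribution-based classification), a block-structured correlation
simulator, and a repeated cross-validation benchmarking harness.

## Who this is for

Single-cell RNA-seq and (multiplexed) proteomics matrices often have large
fractions of missing entries, which breaks conventional classifiers.
Deleting every feature with a missing value loses most of the data;
imputation can fabricate signal. `acfkit` instead compares samples by
pairwise correlation under *pairwise deletion* — each pair is compared only
on the features observed in both — so classification tolerates arbitrarily
many missing values without imputing anything.

## The method

Assume the train correlation matrix is block-structured: the expected
correlation of two samples depends only on their classes,
`C[s1, s2] = mu(C1, C2) + eps` with Gaussian noise `eps`. Then a sample is
well summarised by its *average* correlation to each class,

    x(s) = ( mu_hat(s, C_1), ..., mu_hat(s, C_k) [, covariates...] ),

and ACF simply trains a tunable baseline classifier (SVC, random forest or
ridge) on these k-dimensional feature vectors — self-correlations excluded,
undefined correlations skipped. Because the features include *cross*-class
averages, ACF exploits "discriminative cross-correlations": classes A and B
may correlate identically with each other yet differ in their average
correlation to class C. Two variants:

* **F-ACF** — averages against a random subset of `n_ref` reference
  instances per class, making prediction cost independent of training-set
  size (`sum_C n_ref(C)` correlations per test sample);
* **B-ACF** — omits known-biased correlation entries (e.g. same-batch
  pairs in multiplexed proteomics) from the averages.

Comparators included: brute correlation-KNN (optionally with random
oversampling) and DBC, which compares intra-/inter-class correlation
histograms by Kullback–Leibler distance with a claiming scheme. The
simulator generates Gaussian instances around correlated class centers
(Cholesky construction) with MCAR missingness, and the evaluation harness
implements repeated stratified 10-fold CV with a 60-trial tree-structured
Parzen hyperparameter search per fold and corrected paired t-tests.
See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from acfkit import (ACFClassifier, SimulationConfig, generate_dataset,
                    train_correlation_matrix, block_stats, relative_noise)
from dataclasses import replace

# a 150-sample, 10,000-feature dataset: 3 correlated classes, 60% MCAR
cfg = SimulationConfig(class_sizes=(70, 30, 50), missing_fraction=0.6,
                       covariate=None, seed=0)
train = generate_dataset(cfg)
# fresh cohort from the same population: reuse the class centers
test = generate_dataset(replace(cfg, class_sizes=(20, 20, 20), seed=1),
                        centers=train.centers)

C = train_correlation_matrix(train.X)
stats = block_stats(C, train.labels.to_numpy())
print(stats.table["mean"].round(3).to_dict())
print("sigma_rel:", round(relative_noise(stats), 2))

model = ACFClassifier(baseline="svc", seed=0)
model.fit(train.X, train.labels.to_numpy())
preds = model.predict(test.X)
print("test accuracy:", (preds == test.labels.to_numpy()).mean())
```

prints

```
{('A', 'A'): 0.198, ('A', 'B'): 0.174, ('A', 'C'): 0.118,
 ('B', 'B'): 0.194, ('B', 'C'): 0.158, ('C', 'C'): 0.199}
sigma_rel: 1.03
test accuracy: 1.0
```

The block means show the attenuated center correlations (factor
1/(1+sigma_feature^2) = 1/5 of 1.0/0.9/0.6/0.8): classes A and B are nearly
indistinguishable directly (0.198 vs 0.174) but separate cleanly through
their correlation to C (0.118 vs 0.158) — and ACF classifies all 60 held-out
samples correctly at a relative noise of about 1.

The same workflow is available from the shell:

```bash
acf simulate --seed 0 --class-sizes 70,30,50 --missing-fraction 0.6 --out sim/
acf fit --matrix sim/matrix.csv --labels sim/labels.csv --seed 0 --out model.joblib
acf predict --model model.joblib --matrix sim/matrix.csv --out preds.csv
acf benchmark --sim-config cfg.yaml --estimators acf-svc,dbc,knn --seed 0 --out bench/
```

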