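"""Build the hybrid marker: per-patient quantile features -> per-marker PCA
at 85 % explained variance -> cross-validated LASSO feature selection.

Per patient and marker, the channels x windows matrix is summed per window
over the resected group (the clinician-recognized SOZ) and its complement;
each series contributes its 10 quantiles, giving 20 features.  The seven
retained markers (fragility + six band powers) are PCA-reduced, concatenated
and pruned by an L1-penalized regression of the outcome.
"""

import numpy as np

from sozmark.evaluation_stats import SplitSpec, make_splits, _standardize
from sozmark.feature_hybrid import lasso_select, pca_reduce
from sozmark.network_markers import SEVEN_HYBRID_MARKERS
from sozmark.pipeline import extract_cohort_features
from sozmark.synthetic_cohort import CohortConfig, simulate_cohort

cfg = CohortConfig(n_patients=20, n_channels=8, n_soz=3,
                   pre_onset_s=32.0, seizure_s=10.0, seed=4)
cohort = simulate_cohort(cfg)
features = extract_cohort_features(cohort, list(SEVEN_HYBRID_MARKERS))
print(f"{features.n_patients} patients, {len(features.features)} markers x 20 quantile features")

train, test, verif = make_splits(features.n_patients, SplitSpec(seed=0), 0)
blocks, names = [], []
for mk in SEVEN_HYBRID_MARKERS:
    X20 = features.features[mk]
    red = pca_reduce(X20[train], threshold=0.85)
    blocks.append(red.transform(X20))
    names += [f"{mk}:pc{i+1}" for i in range(red.n_components)]
    print(f"  {mk:15s} -> {red.n_components} components at 85% explained variance")

X = np.hstack(blocks)
X_train_std, = _standardize(X[train])
model = lasso_select(X_train_std, features.y[train], seed=0)
print(f"\nconcatenated hybrid space: {X.shape[1]} features")
print(f"LASSO (lambda={model.lam:.4f}) keeps {model.support.size}:")
for idx in model.support:
    print(f"  {names[idx]:20s} weight {model.weights[idx]:+.3f}")
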