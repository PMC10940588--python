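"""Run a scaled-down marker x model comparison and the hybrid experiment.

The full protocol: a fixed 20 % verification lock-box, 10 repeats of 70/10
training/test re-splits per combination, mean accuracies on both, the
top-25 % intersection, and paired statistics (McNemar, DeLong) between the
GA-trained network and the best baseline on the hybrid marker.
"""

import numpy as np

from sozmark.evaluation_stats import (
    SplitSpec,
    accuracy_matrix,
    delong_test,
    majority_vote,
    mcnemar_test,
    run_all_combinations,
    run_hybrid,
    top_quantile_intersection,
)
from sozmark.gnn_classifier import GAConfig
from sozmark.network_markers import SEVEN_HYBRID_MARKERS
from sozmark.pipeline import extract_cohort_features
from sozmark.synthetic_cohort import CohortConfig, simulate_cohort

cfg = CohortConfig(n_patients=24, n_channels=8, n_soz=3,
                   pre_onset_s=32.0, seizure_s=10.0, label_noise=0.1, seed=2)
cohort = simulate_cohort(cfg)
features = extract_cohort_features(cohort, list(SEVEN_HYBRID_MARKERS))
spec = SplitSpec(seed=2)
ga = GAConfig(population_size=30, generations=60, seed=2)

results = run_all_combinations(features, spec, repeats=5, ga_config=ga)
print("mean verification accuracy (markers x models):")
print(accuracy_matrix(results, "verification").round(2).to_string())
top = sorted(top_quantile_intersection(results, q=0.25))
print(f"\ntop-25% intersection over both accuracy tables: {top}")

hybrid = run_hybrid(features, spec, repeats=5, ga_config=ga)
ranked = sorted(hybrid.items(), key=lambda kv: -kv[1].mean_verification)
print("\nhybrid marker, mean verification accuracy per model:")
for mid, res in ranked:
    print(f"  {mid:5s} {res.mean_verification:.3f}")

gnn, best = hybrid["GNN"], ranked[0][1] if ranked[0][0] != "GNN" else ranked[1][1]
y_ver = features.y[np.asarray(gnn.verification_indices)]
_, p_mc = mcnemar_test(majority_vote(gnn) == y_ver, majority_vote(best) == y_ver)
p_gnn = np.asarray(gnn.verification_probabilities).mean(axis=0)
p_b = np.asarray(best.verification_probabilities).mean(axis=0)
auc_a, auc_b, p_dl = delong_test(p_gnn, p_b, y_ver)
print(f"\nGNN vs best baseline on the lock box: McNemar p={p_mc:.3f}, "
      f"AUCs {auc_a:.2f}/{auc_b:.2f}, DeLong p={p_dl:.3f}")
print("(small p would mean the two classifiers genuinely differ here)")
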