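"""Data-driven confirmation: k-means parcellation of vertex time series.

Clusters the concatenated, z-scored discovery time series and scores
recovery of the planted template by optimal cluster-network matching
(adjusted Rand index, per-network Dice).
"""

from interdigitate import (
    GeneratorParams,
    kmeans_parcellate,
    match_and_score,
    preprocess_study,
    simulate_study,
)

params = GeneratorParams(subdivision_level=3, n_subjects=1, n_sessions=8,
                         frames_per_run=300, master_seed=6)
study = simulate_study(params)
spp = preprocess_study(study)

res = kmeans_parcellate(spp.discovery(0), k=3, n_restarts=10, seed=7)
res = match_and_score(res, study.templates[0])

print(f"k = {res.k}, inertia = {res.inertia:.0f}")
print(f"cluster -> network mapping: {res.matched_mapping}")
print(f"adjusted Rand index vs planted template: {res.ari:.3f}")
print(f"per-network Dice: { {k: round(v, 3) for k, v in res.dice.items()} }")
print("ARI near 1 = the clustering rediscovers the planted interdigitated"
      " networks without any seed-based guidance")
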