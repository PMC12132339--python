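"""Calcium-imaging analysis: PSTH, responsiveness, ensembles, decoding,
trajectories.

Generates a raster with planted excited/inhibited/null neurons, z-scores
peri-event responses, calls responsiveness by signed-rank test, clusters
mean response profiles, decodes trial identity from train-only-PCA
projections, and measures trajectory geometry.
"""

import numpy as np

from fomopipe.neural import (
    call_responsive,
    cluster_ensembles,
    compute_psth,
    decode_trials,
    fit_global_pca,
    trajectory_geometry,
)
from fomopipe.simulate import GroundTruth, SimConfig, gen_neural, gen_schedule

cfg = SimConfig(seed=7, n_trials=20, habituation_s=10.0, n_neurons=60)
sched = gen_schedule(cfg)
truth = GroundTruth()
sess = gen_neural(cfg, sched, truth)

psth = compute_psth(sess, sched.onsets_s)  # [-5, +15] s, z on [-1, 0) baseline
resp = call_responsive(psth, alpha=0.05)
print("responsiveness calls:", resp["call"].value_counts().to_dict())
print(f"planted: {int((truth.neuron_sign == 1).sum())} excited, "
      f"{int((truth.neuron_sign == -1).sum())} inhibited, "
      f"{int((truth.neuron_sign == 0).sum())} null")

profiles = np.nanmean(psth.z, axis=1)  # neurons x timebins mean response
tree = cluster_ensembles(profiles, cutoff_frac=0.3)
print(f"ensemble clusters at 30%-of-max-linkage cutoff: {tree.n_clusters}")

# decode a synthetic attending/not split: label trials by planted half
x = np.transpose(psth.z, (1, 2, 0))  # trials x bins x neurons
labels = (np.arange(sched.n_trials) % 2 == 0).astype(int)
x = x + 1.5 * labels[:, None, None] * (truth.neuron_sign == 1)[None, None, :]
basis = fit_global_pca(np.nanmean(x, axis=0))
proj = np.stack([basis.project(x[i])[:, : basis.n_components] for i in range(len(x))])
res = decode_trials(proj, labels, classifier="glm", folds=5, seed=0)
print(f"decoder window auROC {np.nanmean(res.window_auroc):.2f} "
      f"(shuffled {np.nanmean(res.shuffled_window_auroc):.2f}; chance = 0.5)")

groups = {"attending": np.nanmean(x[labels == 1], axis=0),
          "not_attending": np.nanmean(x[labels == 0], axis=0)}
animal_ids = np.repeat(np.arange(4), cfg.n_neurons // 4)
ts = trajectory_geometry(basis, groups, animal_ids, n_bins=100)
for g, length in ts.lengths.items():
    loo = ts.loo_lengths[g]
    print(f"trajectory '{g}': geodesic length {length:.1f} "
          f"(LOO {loo.mean():.1f} +- {loo.std():.1f} over {len(loo)} animals)")
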