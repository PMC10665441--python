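"""Extract robust independent components from a noisy planted matrix.

Plants five sparse gene modules with distinct temporal activation shapes at a
member-weight to activity-noise ratio of 5, then runs the robust ensemble:
10 FastICA restarts, DBSCAN clustering of the pooled components under the
1 - |pearson r| distance, and a 10-fold repeat-consistency filter.
"""

import numpy as np

from dynica import (
    ExperimentDesign,
    IcaConfig,
    SyntheticConfig,
    generate_raw_fluorescence,
    generate_truth,
    preprocess,
    robust_ica,
    select_dimension,
)

cfg = SyntheticConfig(
    n_promoters=300, n_components=5, weight_sparsity=0.05,
    noise_sd=0.2, spike_prob=0.0, seed=1,
    shape_assignment={
        0: ("zinc", "fast"), 1: ("copper", "intermediate"),
        2: ("cadmium", "steady"), 3: ("iron", "steady"), 4: ("lead", "late"),
    },
)
design = ExperimentDesign(metals=cfg.metals)
truth = generate_truth(cfg, design)
series, control = generate_raw_fluorescence(truth, design, cfg)
X = preprocess(series, control, design)

k = select_dimension(X)
print(f"PCA dimension at 99% explained variance: k = {k}")

dec = robust_ica(X, IcaConfig.fast(base_seed=1))
print(f"robust components retained after clustering + repeat filter: "
      f"{dec.k_robust}")

Mt = truth.M_true.loc[X.index].to_numpy()
for i, comp in enumerate(dec.M.columns):
    rs = [abs(np.corrcoef(dec.M.iloc[:, i], Mt[:, j])[0, 1]) for j in range(5)]
    j = int(np.argmax(rs))
    metal, shape = cfg.shape_assignment[j]
    print(f"  {comp}: |r| = {max(rs):.3f} to planted module {j} "
          f"({metal}, {shape}); found in {dec.run_frequency[i]:.0%} of runs")
print("-> every planted module is recovered essentially exactly; the "
      "correlation measures gene-weight agreement over all 300 promoters")
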