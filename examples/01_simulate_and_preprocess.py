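"""Simulate a small promoter-reporter experiment and build the fold-change matrix.

Generates raw fluorescence for 40 reporter strains across six 4-h heavy-metal
induction windows (10-min imaging grid), runs the preprocessing chain
(background correction -> kernel-11 median filter -> promoterless
normalization -> windowed log2 fold change), and compares the result with the
planted truth.
"""

import numpy as np

from dynica import (
    ExperimentDesign,
    SyntheticConfig,
    generate_fold_change,
    generate_raw_fluorescence,
    generate_truth,
    preprocess,
)

cfg = SyntheticConfig(
    n_promoters=40, n_components=6, weight_sparsity=0.1,
    noise_sd=0.0, measurement_sd=0.0, spike_prob=0.0, seed=0,
)
design = ExperimentDesign(metals=cfg.metals)
truth = generate_truth(cfg, design)
series, control = generate_raw_fluorescence(truth, design, cfg)
print(f"raw series: {series.shape[0]} rows "
      f"({cfg.n_promoters} promoters x {series.shape[0] // cfg.n_promoters} "
      "time points, 10-min grid)")

X = preprocess(series, control, design, phase="induction")
print(f"induction fold-change matrix: {X.shape[0]} promoters x "
      f"{X.shape[1]} conditions (6 metals x 6 time points)")

planted = generate_fold_change(truth, noise_sd=0.0)
err = (X - planted.loc[X.index, X.columns]).abs().to_numpy().max()
print(f"max |recovered - planted| log2 fold change: {err:.2e}")
print("-> with no noise the preprocessing chain inverts the generator "
      "exactly at every sampled point")

member = sorted(truth.member_sets["c2"])[0]  # a cadmium 'steady' reporter
print(f"\nexample: promoter {member} (steady cadmium module), "
      "cadmium window log2 fold changes:")
print(np.round(X.loc[member, [f"cadmium:{j}" for j in range(1, 7)]].to_numpy(), 3))
print("-> a linear activation ramp scaled by the promoter's planted weight")
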