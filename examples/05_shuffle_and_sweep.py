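"""Is the transfer-resistance weighting specific? Shuffle null + δ sweep.

Reshuffles the weights among branchlets 1,000 times and compares the true
weighting's DI against the permutation null (normal fit by moment
matching); then sweeps the filtering percentile δ and reports the optimum.
On forward-model data generated with δ = 90 the sweep recovers it.
"""

import numpy as np

from vscable import (
    SynthRFSpec,
    filtering_sweep,
    make_branchlet_rfs,
    make_ground_truth_axon,
    shuffle_test,
)

seed = 1
rfs = make_branchlet_rfs(SynthRFSpec(n_branchlets=13, seed=seed))
weights = np.random.default_rng(seed).uniform(1.0, 3.0, 13)
target = make_ground_truth_axon(rfs, weights, delta=90.0, noise_sd=0.05,
                                seed=seed + 100)

report = shuffle_test(rfs, weights, target, delta=90.0, n_shuffles=1000,
                      seed=seed + 200)
print(f"true DI          : {report.true_di:.3f}")
print(f"shuffle null     : {report.null_mean:.3f} ± {report.null_sd:.3f} "
      f"(n = {report.n_shuffles})")
print(f"z-score          : {report.z_score:.2f}")
# z > 2: the true weighting beats random weight assignments by more than
# two null standard deviations — the weighting carries real information.

table, best = filtering_sweep(rfs, weights, target,
                              [float(d) for d in range(0, 100, 2)])
print(f"\nbest filtering δ : {best:.0f}%  "
      f"(DI = {table['di'].min():.3f}; generated with δ = 90)")
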