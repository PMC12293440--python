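"""From a coherence matrix to surrogate-normalized graph features.

One trial's delta-band connectivity matrix is proportionally
thresholded (top 20% of channel pairs), the six graph metrics are
computed, and each is z-scored against 100 degree-preserving surrogate
graphs that share the original's degree sequence and edge-weight
multiset.  A positive strength z-score means that node concentrates
more weight than the rewired null expects.
"""

import numpy as np

from erpgraph import PipelineConfig, coherence_tensor
from erpgraph.graphs import (
    graph_metrics,
    proportional_threshold,
    surrogate_ensemble,
    surrogate_zscore,
)
from erpgraph.synth import default_generator_spec, generate_epochs

spec = default_generator_spec(n_trials_per_condition=2, seed=5)
epochs = generate_epochs(spec)
tensor = coherence_tensor(epochs, PipelineConfig(component_combo=("P300",)))

trial_a = int(np.where(epochs.labels == "A")[0][0])
W = tensor.slice("P300", "delta")[trial_a]
W_thr = proportional_threshold(W, sparsity=0.2)
print(f"Thresholded graph: {(np.triu(W_thr, 1) > 0).sum()} of "
      f"{30 * 29 // 2} channel pairs kept")

metrics = graph_metrics(W_thr)
print(f"raw metrics: energy={metrics.energy:.2f}  "
      f"efficiency={metrics.efficiency:.3f}  "
      f"transitivity={metrics.transitivity:.3f}  "
      f"path length={metrics.path_length:.3f}")

ens = surrogate_ensemble(W_thr, n=100, seed=1)
z = surrogate_zscore(metrics, [graph_metrics(S) for S in ens.graphs])
names = epochs.montage.channel_names
order = np.argsort(z.strength)[::-1][:5]
print("top strength z-scores for this single trial:")
for i in order:
    print(f"  {names[i]:>4s}: z = {z.strength[i]:+.2f}")
print("(single-trial z-scores are noisy; averaged over trials the "
      "frontal assembly dominates in condition A)")
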