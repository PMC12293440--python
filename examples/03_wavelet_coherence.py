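"""Per-trial wavelet-coherence connectivity for ERP component windows.

Computes the trial x component x band coherence tensor and compares
the delta-band coherence of a pair inside the strongly-coupled frontal
assembly against an uncoupled pair, per condition.  Coherence is in
[0, 1]; the single-trial estimate has a finite-smoothing bias, so even
independent channels sit well above 0 — what matters is the contrast.
"""

import numpy as np

from erpgraph import PipelineConfig, coherence_tensor
from erpgraph.synth import default_generator_spec, generate_epochs

spec = default_generator_spec(n_trials_per_condition=30, seed=2)
epochs = generate_epochs(spec)
config = PipelineConfig(component_combo=("P300",))
tensor = coherence_tensor(epochs, config)
print("Coherence tensor:", tensor.values.shape,
      "(trials, components, bands, C, C)")

delta = tensor.slice("P300", "delta")
m = epochs.montage
coupled = delta[:, m.index("F3"), m.index("Fz")]
uncoupled = delta[:, m.index("F3"), m.index("O2")]
for cond in ("A", "B"):
    mask = epochs.labels == cond
    print(
        f"condition {cond}: delta coherence F3-Fz = "
        f"{coupled[mask].mean():.3f}, F3-O2 = {uncoupled[mask].mean():.3f}"
    )
print("\nThe frontal pair is strongly coupled in condition A only; the "
      "occipital pair stays at the background (bias) level in both.")

theta = tensor.slice("P300", "theta")
print(f"theta-band F3-Fz (no planted effect): "
      f"A = {theta[epochs.labels == 'A', m.index('F3'), m.index('Fz')].mean():.3f}, "
      f"B = {theta[epochs.labels == 'B', m.index('F3'), m.index('Fz')].mean():.3f}")
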