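"""Threshold-based artifact rejection on a contaminated session.

Eye-blink-like transients are injected into 10% of the trials; the
max-min rule (150 uV peak-to-peak in any channel) should recover
exactly those trials.  The variance-based channel and epoch rules run
on the same input, and the union of rejections is applied — the rules
are order-free by construction.
"""

from erpgraph.pipeline import preprocess_epochs
from erpgraph.synth import default_generator_spec, generate_epochs, inject_artifacts

spec = default_generator_spec(n_trials_per_condition=30, seed=7)
clean_session = generate_epochs(spec)
contaminated = inject_artifacts(clean_session, rate=0.1, amplitude=400.0,
                                seed=8)
print("Injected blink-like transients into trials:",
      contaminated.info["artifact_trials"])

kept, reports = preprocess_epochs(contaminated)
for r in reports:
    print(f"rule {r.rule!r}: rejected trials {list(r.rejected_trials)}, "
          f"channels {list(r.rejected_channels)}")
print(f"Kept {kept.n_trials}/{contaminated.n_trials} trials and "
      f"{kept.n_channels}/{contaminated.n_channels} channels.")
print("Baseline mean (pre-stimulus) after correction:",
      float(abs(kept.data[:, :, kept.times < 0].mean())), "(~0)")
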