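"""Generate a synthetic two-condition ERP session and the NT/ST/DT design.

The generator plants ERP-like deflections near 100/200/350 ms on every
channel, band-limited background activity, and a delta-band coupling
difference between the two conditions: a frontal channel assembly is
strongly synchronized in condition A, a parietal assembly in condition
B.  The session design mirrors the 600-trial cognitive protocol
(75% non-targets, 12.5% shallow and deep targets).
"""

from erpgraph.synth import (
    default_generator_spec,
    generate_epochs,
    generate_session_design,
)

design = generate_session_design(seed=1)
print("Cognitive session design:", design.n_trials, "trials ->",
      design.counts())
print("First 12 cases:", design.cases[:12])

spec = default_generator_spec(n_trials_per_condition=20, seed=1)
epochs = generate_epochs(spec)
print(
    f"\nEpochs: {epochs.n_trials} trials x {epochs.n_channels} channels "
    f"x {epochs.n_samples} samples at {epochs.fs:.0f} Hz "
    f"(t0 = {epochs.t0:.0f} ms)"
)
print("Condition labels:", [str(v) for v in epochs.labels[:6]], "...")

# the trial-average waveform shows the planted ERP morphology
mean_wave = epochs.data.mean(axis=(0, 1))
t_peak = epochs.times[mean_wave.argmax()]
t_trough = epochs.times[mean_wave.argmin()]
print(f"Average waveform: positive peak near {t_peak:.0f} ms "
      f"(planted P300-like bump), trough near {t_trough:.0f} ms")
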