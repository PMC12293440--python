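"""Seeded generator of two-condition single-trial EEG epochs.

Emulates the statistical structure of a visual-stimulation ERP session:
Gaussian-windowed ERP deflections near 100/200/300 ms, band-limited
background activity with condition-dependent inter-channel coupling
(a shared narrowband source mixed into a channel group), white sensor
noise, optional eye-blink-like low-frequency transients, and the
600-trial NT/ST/DT session design of the cognitive protocol.

The coupling model is common-source mixing: a channel with coupling
coefficient kappa receives ``kappa * s + sqrt(1 - kappa^2) * n`` where
``s`` is the group's shared narrowband source and ``n`` an independent
narrowband residual, so the expected magnitude coherence between two
group members is close to kappa^2 (before estimator bias).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import EpochSet, Montage, EMOTIONAL_30_CHANNELS

__all__ = [
    "ErpPeak",
    "CouplingGroup",
    "GeneratorSpec",
    "SessionDesign",
    "default_generator_spec",
    "generate_session_design",
    "generate_epochs",
    "inject_artifacts",
]


@dataclass(frozen=True)
class ErpPeak:
    """One Gaussian-windowed ERP deflection."""

    latency_ms: float
    width_ms: float
    amplitude_uv: float  # signed; negative for N components


@dataclass(frozen=True)
class CouplingGroup:
    """A set of channels sharing one narrowband source in one band.

    ``kappa`` maps condition label -> mixing coefficient in [0, 1].
    """

    channels: tuple
    band: tuple  # (f_low, f_high) Hz
    kappa: dict

    def __post_init__(self):
        for cond, k in self.kappa.items():
            if not (0.0 <= k <= 1.0):
                raise ValueError(
                    f"coupling for condition {cond!r} must be in [0,1], got {k}"
                )


@dataclass(frozen=True)
class GeneratorSpec:
    """Full specification of a synthetic two-condition session."""

    n_trials_per_condition: int = 200
    montage: Montage = field(
        default_factory=lambda: Montage(EMOTIONAL_30_CHANNELS)
    )
    fs: float = 250.0
    t_pre_ms: float = 200.0
    t_post_ms: float = 1000.0
    conditions: tuple = ("A", "B")
    erp_peaks: tuple = (
        ErpPeak(100.0, 30.0, -5.0),
        ErpPeak(200.0, 40.0, -4.0),
        ErpPeak(350.0, 80.0, 8.0),
    )
    coupling: tuple = ()  # tuple of CouplingGroup
    band_noise_uv: tuple = (
        ((1.0, 4.0), 5.0),
        ((4.0, 8.0), 4.0),
        ((8.0, 13.0), 6.0),
        ((13.0, 30.0), 3.0),
    )
    noise_sd: float = 2.0
    artifact_rate: float = 0.0
    artifact_amplitude_uv: float = 200.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if len(self.conditions) != 2:
            raise ValueError("exactly two conditions are required")

    @property
    def n_samples(self) -> int:
        return round((self.t_pre_ms + self.t_post_ms) / 1000.0 * self.fs)


#: Channel assemblies carrying the planted condition effect (delta band).
FRONTAL_MODULE = ("F7", "F3", "Fz", "F4", "F8", "FC3", "FCz", "FC4")
PARIETAL_MODULE = ("P7", "P3", "Pz", "P4", "P8", "CP3", "CPz", "CP4")


def default_generator_spec(
    kappa_a: float = 0.95,
    kappa_b: float = 0.35,
    n_trials_per_condition: int = 200,
    seed: int = 0,
    **kw,
) -> GeneratorSpec:
    """Study-condition generator: delta-band network reorganization.

    Emulates a condition-dependent reorganization of slow-oscillation
    synchrony: in condition ``A`` an 8-channel frontal assembly is
    strongly coupled (mixing kappa_a) and an 8-channel parietal
    assembly weakly (kappa_b); in condition ``B`` the roles swap.  The
    within-assembly coupling gap between conditions is
    kappa_a - kappa_b (default 0.6) in the delta band only; all other
    activity is condition-independent.
    """
    coupling = (
        CouplingGroup(
            channels=FRONTAL_MODULE,
            band=(1.0, 4.0),
            kappa={"A": kappa_a, "B": kappa_b},
        ),
        CouplingGroup(
            channels=PARIETAL_MODULE,
            band=(1.0, 4.0),
            kappa={"A": kappa_b, "B": kappa_a},
        ),
    )
    return GeneratorSpec(
        n_trials_per_condition=n_trials_per_condition,
        coupling=coupling,
        seed=seed,
        **kw,
    )


@dataclass(frozen=True)
class SessionDesign:
    """Randomized trial sequence of NT/ST/DT cases."""

    cases: tuple
    n_runs: int
    trials_per_run: int
    trial_duration_s: float = 1.25

    @property
    def n_trials(self) -> int:
        return len(self.cases)

    def counts(self) -> dict:
        out: dict = {}
        for c in self.cases:
            out[c] = out.get(c, 0) + 1
        return out

    def to_frame(self):
        """Design table with columns (run, trial, case)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "run": [i // self.trials_per_run + 1
                        for i in range(self.n_trials)],
                "trial": [i % self.trials_per_run + 1
                          for i in range(self.n_trials)],
                "case": list(self.cases),
            }
        )


def generate_session_design(
    n_runs: int = 5,
    trials_per_run: int = 120,
    mix: dict | None = None,
    seed: int = 0,
) -> SessionDesign:
    """Build the randomized NT/ST/DT session design.

    Default: 5 runs x 120 trials = 600 trials, 75% NT and 12.5% each
    ST/DT.  Exact case counts are round(p * total) with any rounding
    remainder assigned to NT; the order is shuffled by ``seed``.
    """
    if mix is None:
        mix = {"NT": 0.75, "ST": 0.125, "DT": 0.125}
    total_p = sum(mix.values())
    if abs(total_p - 1.0) > 1e-9:
        raise ValueError(f"case proportions must sum to 1, got {total_p}")
    n_total = n_runs * trials_per_run
    counts = {case: round(p * n_total) for case, p in mix.items()}
    remainder = n_total - sum(counts.values())
    if remainder != 0:
        nt_key = "NT" if "NT" in counts else max(counts, key=counts.get)
        counts[nt_key] += remainder
    cases = [c for case, n in sorted(counts.items()) for c in [case] * n]
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_total)
    shuffled = tuple(cases[i] for i in order)
    return SessionDesign(cases=shuffled, n_runs=n_runs, trials_per_run=trials_per_run)


def _narrowband(rng, n_samples, fs, f_low, f_high, shape):
    """White noise band-passed to [f_low, f_high], unit variance, shape+(n_samples,)."""
    if f_high >= fs / 2:
        raise ValueError(
            f"band ({f_low}, {f_high}) Hz is at or above Nyquist {fs / 2} Hz"
        )
    # pad to suppress filter edge transients inside the epoch
    pad = max(int(2 * fs / f_low), 64)
    x = rng.standard_normal(shape + (n_samples + 2 * pad,))
    sos = signal.butter(4, [f_low, f_high], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)[..., pad : pad + n_samples]
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def generate_epochs(spec: GeneratorSpec) -> EpochSet:
    """Generate the two-condition single-trial epoch set.

    Each trial is the sum of the ERP deflections (identical across
    conditions), per-band narrowband background with common-source
    coupling inside each :class:`CouplingGroup`, and white sensor noise.
    Trials alternate between conditions; output is deterministic for a
    given (spec, seed).
    """
    rng = np.random.default_rng(spec.seed)
    n_cond = spec.n_trials_per_condition
    n_trials = 2 * n_cond
    C = spec.montage.n_channels
    N = spec.n_samples
    fs = spec.fs
    t = (np.arange(N) / fs) * 1000.0 - spec.t_pre_ms  # ms

    # Deterministic ERP template, common to all channels and conditions.
    erp = np.zeros(N)
    for pk in spec.erp_peaks:
        erp += pk.amplitude_uv * np.exp(
            -0.5 * ((t - pk.latency_ms) / pk.width_ms) ** 2
        )

    labels = np.empty(n_trials, dtype=object)
    labels[0::2] = spec.conditions[0]
    labels[1::2] = spec.conditions[1]

    data = np.zeros((n_trials, C, N))
    data += erp[None, None, :]

    # Channels claimed by a coupling group per band get their narrowband
    # background from the group mix; the rest get independent noise.
    coupled = {}  # (band, ch_index) -> True
    for grp in spec.coupling:
        for name in grp.channels:
            coupled[(grp.band, spec.montage.index(name))] = True

    for (f_low, f_high), amp in spec.band_noise_uv:
        band = (f_low, f_high)
        groups_here = [g for g in spec.coupling if g.band == band]
        taken = np.zeros(C, dtype=bool)
        for grp in groups_here:
            idx = np.array([spec.montage.index(n) for n in grp.channels])
            taken[idx] = True
            shared = _narrowband(rng, N, fs, f_low, f_high, (n_trials,))
            resid = _narrowband(rng, N, fs, f_low, f_high, (n_trials, len(idx)))
            for tr in range(n_trials):
                k = grp.kappa.get(labels[tr], 0.0)
                mix = k * shared[tr][None, :] + math.sqrt(1.0 - k * k) * resid[tr]
                data[tr, idx, :] += amp * mix
        free = np.where(~taken)[0]
        if free.size:
            noise = _narrowband(rng, N, fs, f_low, f_high, (n_trials, free.size))
            data[:, free, :] += amp * noise

    data += spec.noise_sd * rng.standard_normal((n_trials, C, N))

    epochs = EpochSet(
        data=data,
        fs=fs,
        t0=-spec.t_pre_ms,
        labels=labels.astype(str),
        montage=spec.montage,
        subject_id="synthetic",
        info={"generator_seed": spec.seed},
    )
    if spec.artifact_rate > 0:
        epochs = inject_artifacts(
            epochs,
            rate=spec.artifact_rate,
            amplitude=spec.artifact_amplitude_uv,
            seed=spec.seed + 1,
        )
    return epochs


def inject_artifacts(
    epochs: EpochSet, rate: float, amplitude: float, seed: int = 0
) -> EpochSet:
    """Add eye-blink-like low-frequency transients to random trials.

    ceil(rate * n_trials) trials receive a Gaussian-windowed slow
    transient of the given peak amplitude (uV) on frontal channels
    (labels starting with "FP"/"Fp", else the first two channels).
    Affected trial indices are recorded in ``info['artifact_trials']``.
    """
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must be in [0, 1]")
    out = epochs.copy()
    n_marked = math.ceil(rate * epochs.n_trials)
    if n_marked == 0:
        out.info["artifact_trials"] = []
        return out
    rng = np.random.default_rng(seed)
    marked = np.sort(rng.choice(epochs.n_trials, size=n_marked, replace=False))
    frontal = [
        i
        for i, name in enumerate(epochs.montage.channel_names)
        if name.upper().startswith("FP")
    ] or [0, min(1, epochs.n_channels - 1)]
    t = np.arange(epochs.n_samples) / epochs.fs
    center = t[epochs.n_samples // 2]
    blink = amplitude * np.exp(-0.5 * ((t - center) / 0.15) ** 2)
    for tr in marked:
        for ch in frontal:
            out.data[tr, ch, :] += blink
    out.info["artifact_trials"] = [int(i) for i in marked]
    return out
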