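"""Shared data model for ERP wavelet-coherence network analysis.

Defines the montage, frequency-band and ERP-component-window conventions,
the epoch container, and the pipeline configuration consumed by every
downstream stage.  Time is expressed in milliseconds relative to stimulus
onset; sample indexing is 0-based with half-open ranges; all channel x
channel matrices are indexed in montage order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Montage",
    "BandSpec",
    "ComponentWindow",
    "EpochSet",
    "PipelineConfig",
    "DEFAULT_BANDS",
    "DEFAULT_WINDOWS",
    "EMOTIONAL_30_CHANNELS",
    "COGNITIVE_62_CHANNELS",
    "window_to_samples",
    "validate_config",
    "save_config",
    "load_config",
]

#: 30-channel 10-20 montage of the emotional recording profile.
EMOTIONAL_30_CHANNELS = (
    "FP1", "FP2", "F3", "Fz", "F4", "FC3", "FCz", "FC4", "F7", "F8",
    "FT7", "FT8", "C3", "Cz", "C4", "CP3", "CPz", "CP4", "T7", "T8",
    "P3", "Pz", "P4", "TP7", "TP8", "P7", "P8", "O1", "Oz", "O2",
)

#: 62-channel montage of the cognitive recording profile (EOG excluded).
COGNITIVE_62_CHANNELS = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8", "F9", "F7", "F5", "F3",
    "F1", "Fz", "F2", "F4", "F6", "F8", "F10", "FT7", "FC5", "FC3",
    "FC1", "FCz", "FC2", "FC4", "FC6", "FT8", "C5", "C3", "C1", "Cz",
    "C2", "C4", "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2",
    "CP4", "CP6", "TP8", "P9", "P7", "P5", "P3", "P1", "Pz", "P2",
    "P4", "P6", "P8", "P10", "PO7", "PO3", "POz", "PO4", "PO8", "O1",
    "Oz", "O2",
)


@dataclass(frozen=True)
class Montage:
    """Ordered scalp-channel layout.

    The channel order is the single source of truth for row/column
    indexing of every connectivity matrix and per-channel feature.

    Parameters
    ----------
    channel_names : sequence of str
        Unique channel labels in recording order.
    positions : array-like of shape (n_channels, 2), optional
        Unitless 2-D layout coordinates (for plotting only).
    """

    channel_names: tuple
    positions: tuple | None = None

    def __init__(self, channel_names: Sequence[str], positions=None):
        names = tuple(channel_names)
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel labels: {dup}")
        object.__setattr__(self, "channel_names", names)
        if positions is not None:
            pos = tuple(map(tuple, np.asarray(positions, dtype=float)))
            if len(pos) != len(names):
                raise ValueError("positions length must match channel_names")
            object.__setattr__(self, "positions", pos)
        else:
            object.__setattr__(self, "positions", None)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        return self.channel_names.index(name)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band [f_low, f_high] in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self):
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got ({self.f_low}, {self.f_high})"
            )


@dataclass(frozen=True)
class ComponentWindow:
    """An ERP-component time window in ms post-stimulus."""

    name: str
    t_start: float
    t_end: float

    def __post_init__(self):
        if not (0 <= self.t_start < self.t_end):
            raise ValueError(
                f"window {self.name!r}: need 0 <= t_start < t_end, "
                f"got ({self.t_start}, {self.t_end})"
            )


# Standard clinical band partition, consistent with a 0.1-40 Hz passband.
DEFAULT_BANDS = (
    BandSpec("delta", 1.0, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
)

# Conventional windows spanning the ~100/170/230-270 ms ERP latencies.
DEFAULT_WINDOWS = (
    ComponentWindow("N100", 70.0, 140.0),
    ComponentWindow("N200", 150.0, 250.0),
    ComponentWindow("P300", 250.0, 500.0),
)

#: Minimum samples a component window must contain at the working rate.
MIN_WINDOW_SAMPLES = 8


@dataclass
class EpochSet:
    """Labeled single-trial epochs.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample relative to stimulus onset, in ms
        (negative for a pre-stimulus baseline).
    labels : ndarray, shape (n_trials,)
        Per-trial condition tag; at most two distinct values.
    montage : Montage
    subject_id : str
    info : dict
        Free-form provenance (e.g. injected-artifact trial indices).
    """

    data: np.ndarray
    fs: float
    t0: float
    labels: np.ndarray
    montage: Montage
    subject_id: str = "synthetic"
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (self.data.shape[0],):
            raise ValueError("labels must have one entry per trial")
        if self.data.shape[1] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[1]} channels but montage has "
                f"{self.montage.n_channels}"
            )
        if len(np.unique(self.labels)) > 2:
            raise ValueError("labels must take at most 2 distinct values")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0 + 1000.0 * np.arange(self.n_samples) / self.fs

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            fs=self.fs,
            t0=self.t0,
            labels=self.labels.copy(),
            montage=self.montage,
            subject_id=self.subject_id,
            info=dict(self.info),
        )


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults mirror the reference analysis: four clinical bands, three
    ERP-component windows, proportional sparsity 0.2, 100 surrogate
    graphs, ReliefF top-20 feature selection, SVM-RBF, and stratified
    10-fold cross-validation repeated 100 times.
    """

    bands: tuple = DEFAULT_BANDS
    windows: tuple = DEFAULT_WINDOWS
    component_combo: tuple = ("N100", "N200", "P300")
    sparsity: float = 0.2
    n_surrogates: int = 100
    n_top_features: int = 20
    selector: str = "relieff"
    classifier: str = "svm_rbf"
    cv_folds: int = 10
    cv_repeats: int = 100
    seed: int = 0
    omega0: float = 6.0
    cycles: float = 3.0
    voices_per_octave: int = 12
    scale_smoothing: bool = True
    single_precision: bool = True
    n_scales: int | None = None

    def __post_init__(self):
        if not (0 < self.sparsity < 1):
            raise ValueError("sparsity must be in (0, 1)")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.n_top_features < 1:
            raise ValueError("n_top_features must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.selector not in ("ttest", "relieff", "mrmr"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if self.classifier not in ("svm_rbf", "lda", "knn"):
            raise ValueError(f"unknown classifier {self.classifier!r}")

    def replace(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)

    def window(self, name: str) -> ComponentWindow:
        for w in self.windows:
            if w.name == name:
                return w
        raise KeyError(f"no component window named {name!r}")


def save_config(config: PipelineConfig, path) -> None:
    """Write a configuration as a key-value YAML file.

    The file mirrors :class:`PipelineConfig` field-for-field; bands and
    windows are lists of ``[name, low, high]`` triples.  Writing the
    default ``PipelineConfig()`` produces a template with every default
    filled in.
    """
    import yaml

    payload = {
        "bands": [[b.name, b.f_low, b.f_high] for b in config.bands],
        "windows": [[w.name, w.t_start, w.t_end] for w in config.windows],
        "component_combo": list(config.component_combo),
        "sparsity": config.sparsity,
        "n_surrogates": config.n_surrogates,
        "n_top_features": config.n_top_features,
        "selector": config.selector,
        "classifier": config.classifier,
        "cv_folds": config.cv_folds,
        "cv_repeats": config.cv_repeats,
        "seed": config.seed,
        "omega0": config.omega0,
        "cycles": config.cycles,
        "voices_per_octave": config.voices_per_octave,
        "scale_smoothing": config.scale_smoothing,
        "single_precision": config.single_precision,
        "n_scales": config.n_scales,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    """Read a configuration written by :func:`save_config`."""
    import yaml

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    kw = dict(payload)
    if "bands" in kw:
        kw["bands"] = tuple(BandSpec(n, lo, hi) for n, lo, hi in kw["bands"])
    if "windows" in kw:
        kw["windows"] = tuple(
            ComponentWindow(n, t0, t1) for n, t0, t1 in kw["windows"]
        )
    if "component_combo" in kw:
        kw["component_combo"] = tuple(kw["component_combo"])
    unknown = set(kw) - {f.name for f in fields(PipelineConfig)}
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**kw)


def window_to_samples(
    window: ComponentWindow, fs: float, t0: float, n_samples: int | None = None
) -> tuple[int, int]:
    """Convert an ERP-component window to a half-open sample range.

    ``i_start`` is the index of the first sample at time >= ``t_start``;
    ``i_end`` the first at time >= ``t_end`` (exclusive).

    Raises
    ------
    ValueError
        If the window lies outside the epoch span or contains fewer
        than ``MIN_WINDOW_SAMPLES`` samples.
    """
    i_start = math.ceil((window.t_start - t0) * fs / 1000.0 - 1e-9)
    i_end = math.ceil((window.t_end - t0) * fs / 1000.0 - 1e-9)
    if i_start < 0 or (n_samples is not None and i_end > n_samples):
        span = (
            f"[{t0}, {t0 + 1000.0 * n_samples / fs}] ms"
            if n_samples is not None
            else f"starting at {t0} ms"
        )
        raise ValueError(
            f"window {window.name!r} [{window.t_start}, {window.t_end}] ms "
            f"lies outside the epoch span {span}"
        )
    if i_end - i_start < MIN_WINDOW_SAMPLES:
        raise ValueError(
            f"window {window.name!r} contains {i_end - i_start} samples at "
            f"{fs} Hz; at least {MIN_WINDOW_SAMPLES} are required"
        )
    return i_start, i_end


def validate_config(config: PipelineConfig, epochs: EpochSet) -> PipelineConfig:
    """Check a configuration against a concrete epoch set.

    Collects every violation (bands above Nyquist, windows outside the
    epoch, empty component combo, unknown combo names) and raises one
    error listing all of them; returns the config unchanged if valid.
    """
    problems: list[str] = []
    nyquist = epochs.fs / 2.0
    for band in config.bands:
        if band.f_high > nyquist:
            problems.append(
                f"band {band.name!r} f_high={band.f_high} Hz exceeds the "
                f"Nyquist frequency {nyquist} Hz"
            )
    for w in config.windows:
        try:
            window_to_samples(w, epochs.fs, epochs.t0, epochs.n_samples)
        except ValueError as exc:
            problems.append(str(exc))
    if not config.component_combo:
        problems.append("component_combo is empty")
    known = {w.name for w in config.windows}
    for name in config.component_combo:
        if name not in known:
            problems.append(f"component_combo names unknown window {name!r}")
    if problems:
        raise ValueError(
            "invalid pipeline configuration:\n  - " + "\n  - ".join(problems)
        )
    return config
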