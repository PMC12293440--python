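"""Filtering, epoching, baseline correction and threshold-based rejection.

All filters are applied forward-backward (zero phase) so ERP latencies
are not distorted.  The rejection rules are pure predicates evaluated on
the input epoch set: applying them in any order and unioning the results
gives the same kept set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import EpochSet

__all__ = [
    "RejectionReport",
    "bandpass",
    "notch",
    "extract_epochs",
    "baseline_correct",
    "reject_maxmin",
    "reject_low_variance_channels",
    "reject_high_variance_epochs",
    "apply_rejections",
]


@dataclass
class RejectionReport:
    """Outcome of one rejection rule."""

    rule: str
    thresholds: dict
    rejected_trials: tuple = ()
    rejected_channels: tuple = ()
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "thresholds": self.thresholds,
            "rejected_trials": list(self.rejected_trials),
            "rejected_channels": list(self.rejected_channels),
            "details": self.details,
        }


def bandpass(x: np.ndarray, f_low: float, f_high: float, fs: float,
             order: int = 6) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    ``order`` is the design order passed to the Butterworth band-pass
    prototype; forward-backward application squares the magnitude
    response, so the effective roll-off is doubled.
    """
    nyq = fs / 2.0
    if not (0 < f_low < f_high):
        raise ValueError(f"need 0 < f_low < f_high, got ({f_low}, {f_high})")
    if f_high >= nyq:
        raise ValueError(
            f"f_high={f_high} Hz is at or above the Nyquist frequency {nyq} Hz"
        )
    sos = signal.butter(order, [f_low, f_high], btype="bandpass", fs=fs,
                        output="sos")
    x = np.asarray(x, dtype=float)
    # a low f_low pole rings for several of its periods; pad accordingly
    padlen = int(min(x.shape[-1] - 1, max(3 * fs / f_low, 6 * order + 1)))
    return signal.sosfiltfilt(sos, x, axis=-1, padlen=padlen)


def notch(x: np.ndarray, f0: float, fs: float, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch (quality factor ``q``) at ``f0`` Hz."""
    if f0 >= fs / 2.0:
        raise ValueError(
            f"notch frequency {f0} Hz is at or above Nyquist {fs / 2.0} Hz"
        )
    b, a = signal.iirnotch(f0, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float), axis=-1)


def extract_epochs(
    x: np.ndarray,
    events: np.ndarray,
    pre_ms: float,
    post_ms: float,
    fs: float,
    labels=None,
    montage=None,
    subject_id: str = "unknown",
) -> EpochSet:
    """Cut stimulus-locked epochs from a continuous recording.

    Parameters
    ----------
    x : ndarray, shape (n_channels, n_samples)
    events : array of int
        Stimulus onset sample indices.
    pre_ms, post_ms : float
        Baseline and post-stimulus spans; each epoch has
        ``round((pre_ms + post_ms) / 1000 * fs)`` samples and t0=-pre_ms.

    Events whose margins fall outside the recording are skipped with a
    warning and counted in ``info['skipped_events']``.
    """
    from .core import Montage

    x = np.atleast_2d(np.asarray(x, dtype=float))
    events = np.asarray(events, dtype=int)
    n_pre = round(pre_ms / 1000.0 * fs)
    n_len = round((pre_ms + post_ms) / 1000.0 * fs)
    kept, skipped = [], []
    for k, ev in enumerate(events):
        start = ev - n_pre
        if start < 0 or start + n_len > x.shape[1]:
            skipped.append(k)
            continue
        kept.append(k)
    if skipped:
        warnings.warn(
            f"{len(skipped)} event(s) too close to the recording edge were "
            f"skipped: {skipped}"
        )
    data = np.stack([x[:, events[k] - n_pre : events[k] - n_pre + n_len]
                     for k in kept]) if kept else np.empty((0, x.shape[0], n_len))
    if labels is not None:
        labels = np.asarray(labels)[kept]
    else:
        labels = np.zeros(len(kept), dtype=int)
    if montage is None:
        montage = Montage([f"ch{i}" for i in range(x.shape[0])])
    return EpochSet(
        data=data, fs=fs, t0=-pre_ms, labels=labels, montage=montage,
        subject_id=subject_id,
        info={"skipped_events": skipped, "event_indices": [int(events[k]) for k in kept]},
    )


def baseline_correct(epochs: EpochSet, window_ms: tuple | None = None) -> EpochSet:
    """Subtract the per-trial, per-channel mean over a baseline window.

    Default window is the full pre-stimulus span [t0, 0) ms.
    """
    if window_ms is None:
        window_ms = (epochs.t0, 0.0)
    t = epochs.times
    lo, hi = window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1000.0 / epochs.fs + 1e-9:
        raise ValueError(
            f"baseline window {window_ms} ms lies outside the epoch span "
            f"[{t[0]}, {t[-1]}] ms"
        )
    mask = (t >= lo - 1e-9) & (t < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"baseline window {window_ms} ms contains no samples")
    out = epochs.copy()
    out.data -= out.data[:, :, mask].mean(axis=2, keepdims=True)
    return out


def reject_maxmin(
    epochs: EpochSet, range_threshold: float = 150.0, channels=None
) -> RejectionReport:
    """Max-min amplitude criterion.

    A trial is rejected iff (max - min) strictly exceeds the threshold
    in at least one of the inspected channels (all channels by default;
    pass a channel-label subset to apply e.g. a 100 uV EOG rule).
    """
    if range_threshold <= 0:
        raise ValueError("range_threshold must be > 0")
    if channels is None:
        idx = slice(None)
        ch_names = list(epochs.montage.channel_names)
    else:
        idx = [epochs.montage.index(c) for c in channels]
        ch_names = list(channels)
    span = epochs.data[:, idx, :].max(axis=2) - epochs.data[:, idx, :].min(axis=2)
    bad = np.where((span > range_threshold).any(axis=1))[0]
    return RejectionReport(
        rule="maxmin",
        thresholds={"range_uv": range_threshold, "channels": ch_names},
        rejected_trials=tuple(int(i) for i in bad),
    )


def reject_low_variance_channels(
    epochs: EpochSet, var_threshold: float = 0.5, trial_fraction: float = 0.10
) -> RejectionReport:
    """Dead-channel criterion.

    A channel is removed iff its per-trial variance is below
    ``var_threshold`` (uV^2) in strictly more than ``trial_fraction``
    of the trials.
    """
    if var_threshold <= 0 or trial_fraction <= 0:
        raise ValueError("thresholds must be positive")
    var = epochs.data.var(axis=2)  # trials x channels
    frac_low = (var < var_threshold).mean(axis=0)
    bad = np.where(frac_low > trial_fraction)[0]
    if len(bad) == epochs.n_channels:
        raise ValueError(
            "every channel fails the low-variance criterion; the pipeline "
            "cannot proceed"
        )
    return RejectionReport(
        rule="low_variance_channels",
        thresholds={"var_uv2": var_threshold, "trial_fraction": trial_fraction},
        rejected_channels=tuple(int(i) for i in bad),
        details={"fraction_low_per_channel": frac_low.tolist()},
    )


def reject_high_variance_epochs(
    epochs: EpochSet, channel_fraction: float = 0.20, z_cut: float = 3.0
) -> RejectionReport:
    """Muscle-artifact criterion.

    Per channel, trial variances are z-scored across trials; a trial is
    rejected iff strictly more than ``channel_fraction`` of its channels
    have variance z-score above ``z_cut``.
    """
    if not (0 < channel_fraction < 1):
        raise ValueError("channel_fraction must be in (0, 1)")
    if epochs.n_trials < 3:
        raise ValueError(
            "variance z-scores require at least 3 trials, got "
            f"{epochs.n_trials}"
        )
    var = epochs.data.var(axis=2)  # trials x channels
    mu = var.mean(axis=0, keepdims=True)
    sd = var.std(axis=0, ddof=1, keepdims=True)
    sd[sd == 0] = np.inf  # constant-variance channel is never "excessive"
    z = (var - mu) / sd
    frac_excessive = (z > z_cut).mean(axis=1)
    bad = np.where(frac_excessive > channel_fraction)[0]
    return RejectionReport(
        rule="high_variance_epochs",
        thresholds={"channel_fraction": channel_fraction, "z_cut": z_cut},
        rejected_trials=tuple(int(i) for i in bad),
    )


def apply_rejections(epochs: EpochSet, reports) -> EpochSet:
    """Drop the union of rejected trials/channels from the epoch set."""
    bad_trials: set = set()
    bad_channels: set = set()
    for r in reports:
        bad_trials.update(r.rejected_trials)
        bad_channels.update(r.rejected_channels)
    keep_t = [i for i in range(epochs.n_trials) if i not in bad_trials]
    keep_c = [i for i in range(epochs.n_channels) if i not in bad_channels]
    from .core import Montage

    montage = Montage(
        [epochs.montage.channel_names[i] for i in keep_c],
        None if epochs.montage.positions is None
        else [epochs.montage.positions[i] for i in keep_c],
    )
    info = dict(epochs.info)
    info["rejected_trials"] = sorted(int(i) for i in bad_trials)
    info["rejected_channels"] = sorted(int(i) for i in bad_channels)
    return EpochSet(
        data=epochs.data[np.ix_(keep_t, keep_c)],
        fs=epochs.fs,
        t0=epochs.t0,
        labels=epochs.labels[keep_t],
        montage=montage,
        subject_id=epochs.subject_id,
        info=info,
    )
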