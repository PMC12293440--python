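"""Morlet continuous wavelet transform and wavelet coherence.

The connectivity measure is the magnitude of the time-smoothed wavelet
cross-spectrum normalized by the smoothed auto-spectra,

    WCoh_xy(t, f) = |W_xy(t, f)| / sqrt(W_xx(t, f) * W_yy(t, f)),

where W_ab(t, f) integrates S_a(tau, f) * conj(S_b(tau, f)) over a
time window of width delta = c / f centered on t (c = number of
integration cycles, truncated at the segment edges).  Without the
smoothing the ratio is identically 1; the window width sets the
bias/variance trade-off of the estimator.

The CWT uses an analytic Morlet prototype (center-frequency parameter
omega0, default 6) evaluated in the frequency domain.  The scale grid
has floor(log2(N)) - 1 logarithmically spaced scales; the lowest
center frequency defaults to one full cycle per signal duration and the
highest to the Nyquist frequency.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    BandSpec,
    ComponentWindow,
    EpochSet,
    Montage,
    PipelineConfig,
    window_to_samples,
)

__all__ = [
    "CWTCoefficients",
    "SmoothedSpectrum",
    "CoherenceTensor",
    "scale_grid",
    "filterbank_grid",
    "morlet_cwt",
    "smoothed_spectrum",
    "coherence",
    "band_component_coherence",
    "coherence_tensor",
]


@dataclass
class CWTCoefficients:
    """Complex CWT coefficients, scales x samples.

    ``center_frequencies`` are strictly decreasing with scale index.
    """

    values: np.ndarray
    center_frequencies: np.ndarray
    fs: float
    omega0: float = 6.0


@dataclass
class SmoothedSpectrum:
    """Time-smoothed wavelet auto- or cross-spectrum, scales x samples."""

    values: np.ndarray
    center_frequencies: np.ndarray
    fs: float
    kind: str  # "auto" | "cross"
    cycles: float


@dataclass
class CoherenceTensor:
    """Per-trial connectivity: trials x components x bands x C x C.

    Every matrix is symmetric with unit diagonal and entries in [0, 1].
    """

    values: np.ndarray
    component_names: tuple
    band_names: tuple
    montage: Montage
    meta: dict = field(default_factory=dict)

    def slice(self, component: str, band: str) -> np.ndarray:
        """(trials, C, C) block for one component window and band."""
        ci = self.component_names.index(component)
        bi = self.band_names.index(band)
        return self.values[:, ci, bi]


def scale_grid(
    N: int,
    fs: float,
    n_scales: int | None = None,
    f_min: float | None = None,
    f_max: float | None = None,
    omega0: float = 6.0,
) -> np.ndarray:
    """Center frequencies (Hz, strictly decreasing) of the CWT scale grid.

    The default count is floor(log2(N)) - 1.  Endpoints: the lowest
    center frequency is limited jointly by the signal length and the
    wavelet's time-frequency extent — the largest scale is
    T / (2 sqrt(2)) seconds (the filterbank convention), i.e.
    f_min = omega0 * sqrt(2) / (pi * T) — and the highest by the
    Nyquist frequency.
    """
    if N < 8:
        raise ValueError(f"need at least 8 samples for a scale grid, got {N}")
    if n_scales is None:
        n_scales = int(math.floor(math.log2(N))) - 1
    if n_scales < 1:
        raise ValueError("scale grid is empty")
    if f_max is None:
        f_max = fs / 2.0
    if f_min is None:
        T = N / fs
        f_min = omega0 * math.sqrt(2.0) / (math.pi * T)
    if not (0 < f_min < f_max <= fs / 2.0 + 1e-12):
        raise ValueError(
            f"invalid frequency limits ({f_min}, {f_max}) for fs={fs}"
        )
    if n_scales == 1:
        return np.array([f_max])
    ratio = (f_min / f_max) ** (1.0 / (n_scales - 1))
    return f_max * ratio ** np.arange(n_scales)


def morlet_cwt(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    omega0: float = 6.0,
    n_scales: int | None = None,
) -> CWTCoefficients:
    """Analytic Morlet CWT of one or more equal-length signals.

    Parameters
    ----------
    x : ndarray, shape (..., N)
        Input signal(s); the transform runs along the last axis.
    freqs : ndarray, optional
        Center frequencies; default :func:`scale_grid`.

    Returns
    -------
    CWTCoefficients with values of shape (..., n_scales, N).

    The transform is linear and computed in the frequency domain with
    an L2-normalized analytic Morlet window (only positive frequencies
    retained), so coefficients are complex-analytic.
    """
    x = np.asarray(x, dtype=float)
    N = x.shape[-1]
    if N < 8:
        raise ValueError(f"input too short for CWT: {N} samples")
    if freqs is None:
        freqs = scale_grid(N, fs, n_scales=n_scales, omega0=omega0)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty scale grid")

    xf = np.fft.fft(x, axis=-1)
    omega = 2.0 * np.pi * np.fft.fftfreq(N, d=1.0 / fs)  # rad/s
    # scales in seconds; center frequency f_c = omega0 / (2 pi s)
    s = omega0 / (2.0 * np.pi * freqs)
    # analytic Morlet in the frequency domain, L2-normalized per scale
    arg = s[:, None] * omega[None, :] - omega0
    win = (np.pi ** -0.25) * np.sqrt(2.0 * np.pi * s[:, None] * fs) * np.exp(
        -0.5 * arg ** 2
    )
    win[:, omega < 0] = 0.0
    coeff = np.fft.ifft(xf[..., None, :] * win, axis=-1)
    return CWTCoefficients(
        values=coeff, center_frequencies=freqs, fs=fs, omega0=omega0
    )


def _box_smooth(values: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """Per-scale centered moving sum with edge truncation.

    ``values`` has shape (..., n_scales, N); ``widths`` gives the window
    length in samples for each scale.
    """
    N = values.shape[-1]
    zeros = np.zeros(values.shape[:-1] + (1,), dtype=values.dtype)
    cs = np.concatenate([zeros, np.cumsum(values, axis=-1)], axis=-1)
    out = np.empty_like(values)
    t = np.arange(N)
    for si, w in enumerate(widths):
        w = max(1, int(w))
        lo = np.clip(t - (w // 2), 0, N)
        hi = np.clip(t - (w // 2) + w, 0, N)
        out[..., si, :] = cs[..., si, hi] - cs[..., si, lo]
    return out


def smoothed_spectrum(
    a: CWTCoefficients, b: CWTCoefficients | None = None, cycles: float = 3.0
) -> SmoothedSpectrum:
    """Time-smoothed wavelet auto- (b is None or a) or cross-spectrum.

    At each (t, f) the product S_a * conj(S_b) is integrated over the
    window [t - delta/2, t + delta/2] with delta = cycles / f, truncated
    at the segment edges.  The auto case yields real non-negative
    values.
    """
    if cycles <= 0:
        raise ValueError("cycles must be > 0")
    auto = b is None or b is a
    if b is None:
        b = a
    if a.values.shape != b.values.shape or not np.allclose(
        a.center_frequencies, b.center_frequencies
    ):
        raise ValueError("coefficient grids do not match")
    prod = a.values * np.conj(b.values)
    if not auto and np.shares_memory(a.values, b.values):
        auto = True
    if auto:
        prod = prod.real
    widths = np.round(cycles / a.center_frequencies * a.fs).astype(int)
    sm = _box_smooth(prod, widths) / a.fs  # integral, dt = 1/fs
    if auto:
        sm = np.maximum(sm.real, 0.0)
    return SmoothedSpectrum(
        values=sm,
        center_frequencies=a.center_frequencies,
        fs=a.fs,
        kind="auto" if auto else "cross",
        cycles=cycles,
    )


def coherence(
    Wxy: SmoothedSpectrum | np.ndarray,
    Wxx: SmoothedSpectrum | np.ndarray,
    Wyy: SmoothedSpectrum | np.ndarray,
) -> np.ndarray:
    """WCoh = |Wxy| / sqrt(Wxx * Wyy), clipped to [0, 1].

    Points where an auto-spectrum vanishes are set to 0 (counted in a
    warning).
    """
    xy = Wxy.values if isinstance(Wxy, SmoothedSpectrum) else np.asarray(Wxy)
    xx = Wxx.values if isinstance(Wxx, SmoothedSpectrum) else np.asarray(Wxx)
    yy = Wyy.values if isinstance(Wyy, SmoothedSpectrum) else np.asarray(Wyy)
    denom = np.sqrt(np.abs(xx) * np.abs(yy))
    bad = denom <= 0
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} time-frequency point(s) with zero auto-spectrum set to 0"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(xy) / denom
    coh[bad] = 0.0
    return np.clip(coh, 0.0, 1.0)


def _band_scale_mask(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    mask = (freqs >= band.f_low) & (freqs <= band.f_high)
    if not mask.any():
        raise ValueError(
            f"no CWT scale has its center frequency inside band "
            f"{band.name!r} [{band.f_low}, {band.f_high}] Hz; grid: "
            f"{np.round(freqs, 3).tolist()} Hz"
        )
    return mask


def _trial_coherence_stack(
    trial_data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    omega0: float,
    cycles: float,
    scale_smooth: int = 1,
) -> np.ndarray:
    """(C, C, n_scales, N) coherence for one trial's (C, N) data.

    ``scale_smooth`` > 1 applies a moving average of that many scales to
    the smoothed auto- and cross-spectra (before the ratio), mirroring
    the scale smoothing of standard wavelet-coherence estimators; it
    raises the effective degrees of freedom of each estimate.
    """
    cwt = morlet_cwt(trial_data, fs, freqs=freqs, omega0=omega0)
    S = cwt.values  # (C, n_scales, N)
    widths = np.round(cycles / freqs * fs).astype(int)
    auto = _box_smooth((S * np.conj(S)).real, widths)
    cross = np.einsum("isn,jsn->ijsn", S, np.conj(S))
    cross_sm = _box_smooth(cross, widths)
    if scale_smooth > 1 and freqs.size > 1:
        from scipy.ndimage import uniform_filter1d

        w = min(scale_smooth, freqs.size)
        auto = uniform_filter1d(auto, w, axis=-2, mode="nearest")
        cross_sm = uniform_filter1d(cross_sm.real, w, axis=-2,
                                    mode="nearest") + 1j * uniform_filter1d(
            cross_sm.imag, w, axis=-2, mode="nearest"
        )
        auto = np.maximum(auto, 0.0)
    denom = np.sqrt(auto[:, None] * auto[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(cross_sm) / denom
    coh[~np.isfinite(coh)] = 0.0
    return np.clip(coh, 0.0, 1.0)


def filterbank_grid(
    bands,
    N: int,
    fs: float,
    voices_per_octave: int = 12,
    omega0: float = 6.0,
) -> np.ndarray:
    """Multi-voice center-frequency grid covering the analysis bands.

    Frequencies are log-spaced at ``voices_per_octave`` per octave,
    spanning the union of the band edges padded by half an octave on
    each side, clipped to the wavelet-extent lower bound (see
    :func:`scale_grid`) and the Nyquist frequency.  Descending order.
    """
    if voices_per_octave < 1:
        raise ValueError("voices_per_octave must be >= 1")
    T = N / fs
    f_ext = omega0 * math.sqrt(2.0) / (math.pi * T)
    lo = max(min(b.f_low for b in bands) / math.sqrt(2.0), f_ext)
    hi = min(max(b.f_high for b in bands) * math.sqrt(2.0), fs / 2.0)
    if lo >= hi:
        names = [b.name for b in bands]
        raise ValueError(
            f"no CWT scale can be placed inside bands {names}: the "
            f"analyzable range is empty (wavelet-extent lower bound "
            f"{f_ext:.3g} Hz, Nyquist {fs / 2:.3g} Hz, N={N})"
        )
    n = int(math.floor(math.log2(hi / lo) * voices_per_octave)) + 1
    return hi * 2.0 ** (-np.arange(n) / voices_per_octave)


def _trial_band_window_coherence(
    trial_data: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    omega0: float,
    cycles: float,
    scale_smooth: int,
    band_masks,
    window_ranges,
    single_precision: bool = True,
) -> np.ndarray:
    """(n_windows, n_bands, C, C) aggregated coherence for one trial.

    Streams over scales with a rolling scale-smoothing window so that
    no (C, C, scales, samples) array is ever materialized: per scale the
    smoothed spectra of a centered block of ``scale_smooth`` scales
    (truncated at the grid ends) are averaged before the ratio, and the
    resulting coherence is accumulated into every (window, band) cell
    whose band contains the scale's center frequency.
    """
    S = morlet_cwt(trial_data, fs, freqs=freqs, omega0=omega0).values
    cdtype = np.complex64 if single_precision else np.complex128
    fdtype = np.float32 if single_precision else np.float64
    S = S.astype(cdtype)
    n_scales = freqs.size
    widths = np.round(cycles / freqs * fs).astype(int)
    C = trial_data.shape[0]
    N = trial_data.shape[1]
    half = (min(scale_smooth, n_scales) - 1) // 2 if scale_smooth > 1 else 0
    in_any_band = np.logical_or.reduce([np.asarray(m) for m in band_masks])
    # the ratio is only ever read inside the component windows
    j0 = min(i0 for i0, _ in window_ranges)
    j1 = max(i1 for _, i1 in window_ranges)

    def _slices(si):
        Ss = S[:, si, :]
        auto = _box_smooth(
            (Ss * np.conj(Ss)).real[:, None, :], widths[si : si + 1]
        )[:, 0, :]
        cross = np.einsum("in,jn->ijn", Ss, np.conj(Ss))
        cross = _box_smooth(cross[:, :, None, :], widths[si : si + 1])[:, :, 0, :]
        return auto, cross

    cache: dict = {}

    def _get(si):
        if si not in cache:
            cache[si] = _slices(si)
        return cache[si]

    out = np.zeros((len(window_ranges), len(band_masks), C, C))
    counts = np.zeros((len(window_ranges), len(band_masks)))
    auto_sum = np.zeros((C, N), dtype=fdtype)
    cross_sum = np.zeros((C, C, N), dtype=cdtype)
    prev_lo, prev_hi = 0, 0
    for si in range(n_scales):
        lo, hi = max(0, si - half), min(n_scales, si + half + 1)
        for sj in range(prev_hi, hi):  # entering the window
            a, x = _get(sj)
            auto_sum += a
            cross_sum += x
        for sj in range(prev_lo, lo):  # leaving the window
            a, x = _get(sj)
            auto_sum -= a
            cross_sum -= x
            del cache[sj]
        prev_lo, prev_hi = lo, hi
        if not in_any_band[si]:
            continue
        auto_pos = np.maximum(auto_sum[:, j0:j1], 0.0)
        denom = np.sqrt(auto_pos[:, None, :] * auto_pos[None, :, :])
        with np.errstate(divide="ignore", invalid="ignore"):
            coh = np.abs(cross_sum[:, :, j0:j1]) / denom
        coh[~np.isfinite(coh)] = 0.0
        np.clip(coh, 0.0, 1.0, out=coh)
        for bi, mask in enumerate(band_masks):
            if not mask[si]:
                continue
            for wi, (i0, i1) in enumerate(window_ranges):
                out[wi, bi] += coh[:, :, i0 - j0 : i1 - j0].mean(axis=2)
                counts[wi, bi] += 1
    out /= counts[:, :, None, None]
    return out


def band_component_coherence(
    epochs: EpochSet,
    window: ComponentWindow,
    band: BandSpec,
    cycles: float = 3.0,
    omega0: float = 6.0,
    n_scales: int | None = None,
) -> np.ndarray:
    """Per-trial channel x channel coherence for one window and band.

    The CWT is computed on the full epoch (reducing edge effects inside
    the component window) and coherence is averaged over the window's
    time samples and over scales whose center frequency lies in the
    band.  Output shape (n_trials, C, C); symmetric, unit diagonal.
    """
    cfg = PipelineConfig(
        windows=(window,), bands=(band,), component_combo=(window.name,),
        cycles=cycles, omega0=omega0, n_scales=n_scales,
    )
    tensor = coherence_tensor(epochs, cfg)
    return tensor.slice(window.name, band.name)


def coherence_tensor(epochs: EpochSet, config: PipelineConfig) -> CoherenceTensor:
    """Full coherence tensor: trials x components x bands x C x C.

    One CWT and one smoothed-spectrum pass per trial are shared by all
    component windows and bands.
    """
    N = epochs.n_samples
    fs = epochs.fs
    if config.n_scales is not None:
        freqs = scale_grid(N, fs, n_scales=config.n_scales,
                           omega0=config.omega0)
        smooth = 1
    else:
        freqs = filterbank_grid(
            config.bands, N, fs,
            voices_per_octave=config.voices_per_octave,
            omega0=config.omega0,
        )
        smooth = config.voices_per_octave if config.scale_smoothing else 1
    comps = [config.window(name) for name in config.component_combo]
    windows_idx = [
        window_to_samples(w, fs, epochs.t0, N) for w in comps
    ]
    band_masks = [_band_scale_mask(freqs, b) for b in config.bands]

    C = epochs.n_channels
    out = np.empty(
        (epochs.n_trials, len(comps), len(config.bands), C, C)
    )
    for tr in range(epochs.n_trials):
        agg = _trial_band_window_coherence(
            epochs.data[tr], fs, freqs, config.omega0, config.cycles,
            smooth, band_masks, windows_idx,
            single_precision=config.single_precision,
        )
        for ci in range(len(comps)):
            for bi in range(len(config.bands)):
                m = agg[ci, bi]
                m = 0.5 * (m + m.T)
                np.fill_diagonal(m, 1.0)
                out[tr, ci, bi] = m
    return CoherenceTensor(
        values=out,
        component_names=tuple(w.name for w in comps),
        band_names=tuple(b.name for b in config.bands),
        montage=epochs.montage,
        meta={
            "cycles": config.cycles,
            "omega0": config.omega0,
            "center_frequencies_hz": freqs.tolist(),
            "fs": fs,
        },
    )
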