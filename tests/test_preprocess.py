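"""Filtering, rejection, artifact correction and surface Laplacian."""

import numpy as np
import pytest

from ecnet import (EEGRecording, bandpass, default_montage,
                   pca_artifact_correct, reject_amplitude, rrmse,
                   surface_laplacian)
from ecnet.preprocess import csd_operator
from ecnet.simulate import blink_waveform, frontal_topography, inject_blinks


def _sine(freq, fs=256.0, seconds=8.0, n_ch=2):
    t = np.arange(int(seconds * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return EEGRecording(np.tile(x, (n_ch, 1)), fs=fs,
                        labels=[f"ch{i}" for i in range(n_ch)])


class TestBandpass:
    def test_dc_removed(self):
        rec = EEGRecording(np.full((2, 2048), 42.0), 256.0, ["a", "b"])
        out = bandpass(rec, 0.5, 48.0)
        assert abs(out.data.mean()) < 1e-6

    def test_passband_tone_preserved(self):
        rec = _sine(10.0)
        out = bandpass(rec, 0.5, 48.0)
        mid = slice(512, -512)  # avoid filter edge transients
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert abs(ratio - 1.0) < 0.05

    def test_stopband_tone_attenuated(self):
        rec = _sine(60.0, fs=256.0)
        out = bandpass(rec, 0.5, 48.0)
        mid = slice(512, -512)
        ratio = out.data[0, mid].std() / rec.data[0, mid].std()
        assert ratio < 0.10

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_sine(10.0), 0.5, 200.0)


class TestRejectAmplitude:
    def test_below_threshold_empty_mask(self, rng):
        rec = EEGRecording(rng.uniform(-99, 99, (3, 1000)), 250.0,
                          ["a", "b", "c"])
        _, mask = reject_amplitude(rec, 100.0)
        assert not mask.any()

    def test_excursion_flags_its_window(self, rng):
        data = rng.uniform(-50, 50, (2, 1000))
        data[1, 700] = 150.0
        rec = EEGRecording(data, 250.0, ["a", "b"])
        _, mask = reject_amplitude(rec, 100.0, window=250)
        assert mask[500:750].all() and not mask[:500].any()

    def test_boundary_sample_kept(self):
        data = np.zeros((1, 100))
        data[0, 50] = 100.0  # exactly at the limit: "exceeding" is strict
        rec = EEGRecording(data, 100.0, ["a"])
        _, mask = reject_amplitude(rec, 100.0)
        assert not mask.any()

    def test_infinite_limit_is_identity(self, rng):
        rec = EEGRecording(rng.normal(0, 500, (2, 500)), 100.0, ["a", "b"])
        _, mask = reject_amplitude(rec, np.inf)
        assert not mask.any()


class TestRRMSE:
    def test_identity_zero_and_scaling_cases(self, rng):
        X = rng.standard_normal((4, 100))
        assert rrmse(X, X) == 0.0
        assert rrmse(X, np.zeros_like(X)) == pytest.approx(100.0)
        assert rrmse(X, X / 2) == pytest.approx(50.0)

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            rrmse(np.zeros((2, 5)), np.ones((2, 5)))


class TestPCAArtifactCorrect:
    @pytest.fixture()
    def contaminated(self, montage, rng):
        n = 30 * 128
        clean = rng.standard_normal((29, n)) * 5.0
        rec = EEGRecording(clean, 128.0, montage.channels)
        topo = frontal_topography(montage)
        dirty, events = inject_blinks(rec, rate=12.0, topography=topo,
                                      amplitude=120.0, seed=7)
        return clean, dirty, events

    def test_correction_improves_similarity_to_clean(self, contaminated):
        clean, dirty, events = contaminated
        corrected, report, _ = pca_artifact_correct(dirty, events, 0.95)

        def corr(a, b):
            return np.corrcoef(a.ravel(), b.ravel())[0, 1]

        assert corr(corrected.data, clean) > corr(dirty.data, clean)
        assert report.components_removed >= 1

    def test_full_threshold_removes_template_variance(self, contaminated):
        _, dirty, events = contaminated
        corrected, _, model = pca_artifact_correct(dirty, events, 1.0)
        # the retained topographies span the artifact template: the corrected
        # data has (numerically) no projection onto them
        proj = model.topographies.T @ corrected.data
        assert np.abs(proj).max() < 1e-8

    def test_no_artifact_gives_negligible_change(self, montage, rng):
        rec = EEGRecording(rng.standard_normal((29, 2000)) * 5.0, 128.0,
                          montage.channels)
        corrected, report, _ = pca_artifact_correct(
            rec, events=np.array([3.0, 6.0, 9.0, 12.0]), var_threshold=0.95)
        # random "events" carry no consistent topography: the noise floor
        # rejects every component and the change is negligible
        assert report.components_removed == 0
        assert report.rrmse_pct < 1.0

    def test_requires_two_events(self, noise_recording):
        with pytest.raises(ValueError, match="2"):
            pca_artifact_correct(noise_recording, np.array([1.0]))


class TestSurfaceLaplacian:
    def test_constant_pattern_maps_to_zero(self, montage):
        rec = EEGRecording(np.full((29, 100), 7.7), 100.0, montage.channels)
        out = surface_laplacian(rec, montage)
        assert np.abs(out.data).max() < 1e-10

    def test_reference_free(self, montage, rng):
        data = rng.standard_normal((29, 200))
        a = surface_laplacian(EEGRecording(data, 100.0, montage.channels),
                              montage)
        b = surface_laplacian(EEGRecording(data + 11.0, 100.0,
                                           montage.channels), montage)
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)

    def test_commutes_with_temporal_filtering(self, montage, rng):
        data = rng.standard_normal((29, 4096))
        rec = EEGRecording(data, 256.0, montage.channels)
        a = surface_laplacian(bandpass(rec, 1.0, 40.0), montage)
        b = bandpass(surface_laplacian(rec, montage), 1.0, 40.0)
        np.testing.assert_allclose(a.data, b.data, atol=1e-8)

    def test_spherical_harmonic_near_eigenfunction(self, montage):
        """A low-degree spherical-harmonic scalp pattern comes back
        proportional to itself, with the ratio matching a direct evaluation
        of the spline operator."""
        pos = montage.position_array()
        pattern = pos[:, 2]  # Y_1^0 at the electrode sites
        rec = EEGRecording(np.outer(pattern, np.ones(10)), 100.0,
                          montage.channels)
        out = surface_laplacian(rec, montage).data[:, 0]
        L = csd_operator(montage)
        direct = L @ (pattern - pattern.mean())
        np.testing.assert_allclose(out, direct, atol=1e-10)
        # proportionality: dominant direction of the output is the input
        cos = pattern @ out / np.linalg.norm(pattern) / np.linalg.norm(out)
        assert abs(cos) > 0.98

    def test_matches_reference_csd_implementation(self, montage, rng):
        """Cross-implementation check against mne's spherical-spline CSD
        (same stiffness, series length and regularization); the analytic
        unit factor is 1e6 * r^2 for a head radius r in meters."""
        mne = pytest.importorskip("mne")
        data = rng.standard_normal((29, 64))
        mine = surface_laplacian(
            EEGRecording(data, 256.0, montage.channels), montage).data
        r = 0.095
        info = mne.create_info(list(montage.channels), 256.0, "eeg")
        raw = mne.io.RawArray(data * 1e-6, info, verbose="error")
        raw.set_montage(mne.channels.make_dig_montage(
            ch_pos={c: p * r for c, p in zip(montage.channels,
                                             montage.position_array())},
            coord_frame="head"))
        csd = mne.preprocessing.compute_current_source_density(
            raw, stiffness=4, lambda2=1e-5, n_legendre_terms=50,
            sphere=(0.0, 0.0, 0.0, r), verbose="error")
        theirs = csd.get_data() * 1e6 * r ** 2
        np.testing.assert_allclose(mine, theirs, rtol=1e-6, atol=1e-9)

    def test_too_few_channels_rejected(self, montage):
        sub = montage.subset(list(montage.channels[:8]))
        rec = EEGRecording(np.zeros((8, 10)), 100.0, sub.channels)
        with pytest.raises(ValueError, match="16"):
            surface_laplacian(rec, sub)


class TestBlinkInjection:
    def test_zero_rate_identity(self, noise_recording, montage):
        out, times = inject_blinks(noise_recording, 0.0,
                                   frontal_topography(montage), 100.0, seed=1)
        assert len(times) == 0
        np.testing.assert_array_equal(out.data, noise_recording.data)

    def test_deterministic_under_seed(self, noise_recording, montage):
        topo = frontal_topography(montage)
        _, t1 = inject_blinks(noise_recording, 15.0, topo, 120.0, seed=42)
        _, t2 = inject_blinks(noise_recording, 15.0, topo, 120.0, seed=42)
        np.testing.assert_array_equal(t1, t2)
        assert len(t1) > 0

    def test_large_blinks_trip_amplitude_rejection(self, montage, rng):
        rec = EEGRecording(rng.uniform(-20, 20, (29, 20 * 256)), 256.0,
                          montage.channels)
        dirty, times = inject_blinks(rec, 20.0, frontal_topography(montage),
                                     150.0, seed=3)
        assert len(times) > 0
        _, mask = reject_amplitude(dirty, 100.0)
        assert mask.any()

    def test_negative_rate_rejected(self, noise_recording, montage):
        with pytest.raises(ValueError):
            inject_blinks(noise_recording, -1.0,
                          frontal_topography(montage), 100.0, seed=1)
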