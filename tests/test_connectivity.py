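"""Cross-spectra, coherency, PSI and thresholding."""

import numpy as np
import pytest

from ecnet import (EEGRecording, PipelineConfig, cross_spectra,
                   pooled_coherency, psi, psi_all_bands, threshold_adjacency)
from ecnet.connectivity import PSIMatrix
from ecnet.simulate import Coupling, CouplingSpec, simulate_coupled_eeg
from ecnet.montage import default_montage


@pytest.fixture()
def cs_noise(rng):
    data = rng.standard_normal((4, 40 * 128))
    rec = EEGRecording(data, 128.0, ["a", "b", "c", "d"])
    return cross_spectra(rec, df=0.5, overlap=0.5)


class TestCrossSpectra:
    def test_hermitian_at_every_bin(self, cs_noise):
        for k in (0, cs_noise.n_segments - 1):
            S = cs_noise.segment_matrix(k)
            np.testing.assert_allclose(S, np.conj(np.swapaxes(S, -1, -2)),
                                       atol=1e-9)
        Sp = cs_noise.pooled
        np.testing.assert_allclose(Sp, np.conj(np.swapaxes(Sp, -1, -2)),
                                   atol=1e-9)
        diag = np.einsum("fii->fi", Sp)
        assert np.all(np.abs(diag.imag) < 1e-9)
        assert np.all(diag.real >= 0)

    def test_duplicated_channel_saturates_cross_power(self, rng):
        x = rng.standard_normal(20 * 128)
        rec = EEGRecording(np.vstack([x, x]), 128.0, ["a", "a2"])
        cs = cross_spectra(rec)
        S = cs.pooled
        np.testing.assert_allclose(np.abs(S[:, 0, 1]), S[:, 0, 0].real,
                                   rtol=1e-8)

    def test_tone_peaks_at_its_bin(self):
        fs = 128.0
        t = np.arange(int(20 * fs)) / fs
        rec = EEGRecording(np.sin(2 * np.pi * 10.0 * t)[None, :], fs, ["a"])
        cs = cross_spectra(rec, df=0.5)
        auto = cs.pooled[:, 0, 0].real
        assert cs.freqs[np.argmax(auto)] == pytest.approx(10.0)

    def test_spectral_resolution_is_fs_over_nfft(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((1, 16384)),
                          2048.0, ["a"])
        cs = cross_spectra(rec, df=0.5)
        assert cs.df == pytest.approx(2048.0 / 4096)
        assert cs.seg_spectra.shape[-1] == 4096 // 2 + 1

    def test_mask_excludes_epochs(self, rng):
        data = rng.standard_normal((2, 20 * 128))
        rec = EEGRecording(data, 128.0, ["a", "b"])
        full = cross_spectra(rec, df=0.5)
        mask = np.zeros(rec.n_samples, dtype=bool)
        mask[:1000] = True
        part = cross_spectra(rec, df=0.5, mask=mask)
        assert part.n_epochs < full.n_epochs

    def test_too_short_recording_rejected(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 300)), 128.0, ["a", "b"])
        with pytest.raises(ValueError, match="epoch"):
            cross_spectra(rec, df=0.5)


class TestCoherency:
    def test_self_coherence_is_one(self, cs_noise):
        coh = pooled_coherency(cs_noise)
        diag = np.einsum("fii->fi", coh)
        np.testing.assert_allclose(diag.real, 1.0, atol=1e-9)
        np.testing.assert_allclose(diag.imag, 0.0, atol=1e-9)

    def test_magnitude_bounded_and_hermitian(self, cs_noise):
        coh = pooled_coherency(cs_noise)
        assert np.nanmax(np.abs(coh)) <= 1.0 + 1e-9
        np.testing.assert_allclose(np.abs(coh[:, 0, 1]), np.abs(coh[:, 1, 0]),
                                   atol=1e-12)

    def test_independence_bias_matches_segment_count(self, rng):
        # E[|Coh|^2] ~ 1/K for independent signals and K independent segments
        data = rng.standard_normal((2, 60 * 128))
        rec = EEGRecording(data, 128.0, ["a", "b"])
        cs = cross_spectra(rec, df=1.0, overlap=0.0, epoch_segments=1)
        coh = pooled_coherency(cs)
        m = np.mean(np.abs(coh[5:50, 0, 1]) ** 2)
        assert 0.5 / cs.n_segments < m < 2.0 / cs.n_segments


class TestPSI:
    def test_skew_symmetric_zero_diagonal_on_noise(self, cs_noise):
        pm = psi(cs_noise, (8.0, 13.0), "alpha")
        np.testing.assert_allclose(pm.psi, -pm.psi.T, atol=1e-10)
        np.testing.assert_allclose(np.diag(pm.psi), 0.0, atol=1e-12)
        np.testing.assert_allclose(pm.psi_raw, -pm.psi_raw.T, atol=1e-12)
        assert np.all(np.isfinite(pm.psi))

    def test_band_bins_are_interior_pairs(self, cs_noise):
        pm = psi(cs_noise, (8.0, 13.0), "alpha")
        # every used bin f has f >= lo and f + df < hi
        assert pm.freqs_used.min() >= 8.0
        assert pm.freqs_used.max() + cs_noise.df < 13.0

    def test_lagged_coupling_recovers_direction_and_scaling_invariance(self):
        spec = CouplingSpec(
            couplings=[Coupling("Fp1", "O1", 30.0, 0.8, "alpha")],
            duration=60.0, fs=256.0)
        rec, truth = simulate_coupled_eeg(spec, seed=5)
        i = rec.labels.index("Fp1")
        j = rec.labels.index("O1")
        # oracle for the sign: peak cross-correlation lag of the two channels
        a, b = rec.data[i], rec.data[j]
        lags = np.arange(-64, 65)
        xc = [np.dot(a[64:-64], b[64 + L:len(b) - 64 + L]) for L in lags]
        assert lags[np.argmax(np.abs(xc))] > 0  # b lags behind a

        cs = cross_spectra(rec)
        pm = psi(cs, (8.0, 13.0), "alpha")
        assert pm.psi[i, j] > 2.0
        # amplitude scaling leaves the normalized index unchanged
        cs2 = cross_spectra(rec.copy_with(rec.data * 37.0))
        pm2 = psi(cs2, (8.0, 13.0), "alpha")
        np.testing.assert_allclose(pm2.psi, pm.psi, rtol=1e-8)

    def test_reversed_coupling_flips_sign(self):
        fwd = CouplingSpec(
            couplings=[Coupling("Fp1", "O1", 30.0, 0.8, "alpha")],
            duration=60.0, fs=256.0)
        rev = CouplingSpec(
            couplings=[Coupling("O1", "Fp1", 30.0, 0.8, "alpha")],
            duration=60.0, fs=256.0)
        rec_f, _ = simulate_coupled_eeg(fwd, seed=11)
        rec_r, _ = simulate_coupled_eeg(rev, seed=11)
        i = rec_f.labels.index("Fp1")
        j = rec_f.labels.index("O1")
        pf = psi(cross_spectra(rec_f), (8.0, 13.0)).psi[i, j]
        pr = psi(cross_spectra(rec_r), (8.0, 13.0)).psi[i, j]
        assert pf > 0 > pr

    def test_coupling_confined_to_its_band(self):
        """An alpha-band coupling must not create a theta-band edge."""
        spec = CouplingSpec(
            couplings=[Coupling("Fp1", "O1", 30.0, 0.8, "alpha")],
            duration=60.0, fs=256.0)
        hits = 0
        for s in range(20):
            rec, _ = simulate_coupled_eeg(spec, seed=100 + s)
            i = rec.labels.index("Fp1")
            j = rec.labels.index("O1")
            cs = cross_spectra(rec)
            hits += abs(psi(cs, (4.0, 8.0), "theta").psi[i, j]) > 2.0
        assert hits <= 4  # ~ null rate, generous binomial bound

    def test_degenerate_input_raises(self):
        t = np.arange(2048) / 256.0
        x = np.sin(2 * np.pi * 10 * t)
        rec = EEGRecording(np.vstack([x, x]), 256.0, ["a", "b"])
        with pytest.raises(ValueError):
            psi(cross_spectra(rec, df=1.0), (8.0, 13.0))


class TestThreshold:
    def _pm(self, mat):
        mat = np.asarray(mat, dtype=float)
        return PSIMatrix(psi_raw=mat, jackknife_sd=np.ones_like(mat),
                         psi=mat, band="alpha",
                         freqs_used=np.array([8.0]),
                         labels=tuple(str(i) for i in range(len(mat))))

    def test_subthreshold_matrix_gives_empty_graph(self):
        m = np.array([[0.0, 1.5], [-1.5, 0.0]])
        adj = threshold_adjacency(self._pm(m), 2.0)
        assert adj.edge_count == 0

    def test_single_significant_pair_gives_one_directed_edge(self):
        m = np.array([[0.0, 3.0], [-3.0, 0.0]])
        adj = threshold_adjacency(self._pm(m), 2.0)
        assert adj.matrix[0, 1] == 3.0
        assert adj.matrix[1, 0] == 0.0
        assert adj.edge_count == 1

    def test_fully_significant_29_nodes_gives_406_edges(self, rng):
        m = rng.uniform(2.5, 9.0, (29, 29))
        m = np.triu(m, 1)
        m = m - m.T
        adj = threshold_adjacency(self._pm(m), 2.0)
        assert adj.edge_count == 406

    def test_no_reciprocal_edges_ever(self, rng):
        m = rng.standard_normal((10, 10)) * 3
        m = np.triu(m, 1)
        m = m - m.T
        adj = threshold_adjacency(self._pm(m), 2.0)
        assert not np.any((adj.matrix > 0) & (adj.matrix.T > 0))


class TestAllBands:
    def test_default_config_yields_five_bands(self, rng):
        rec = EEGRecording(rng.standard_normal((3, 30 * 128)) * 10, 128.0,
                          ["a", "b", "c"])
        adjs = psi_all_bands(rec)
        assert sorted(adjs) == ["alpha", "beta", "delta", "gamma", "theta"]
        for adj in adjs.values():
            assert not np.any((adj.matrix > 0) & (adj.matrix.T > 0))

    def test_band_restriction_respected(self, rng):
        rec = EEGRecording(rng.standard_normal((3, 30 * 128)) * 10, 128.0,
                          ["a", "b", "c"])
        cfg = PipelineConfig()
        adjs = psi_all_bands(rec, cfg, bands={"theta": (4.0, 8.0),
                                              "alpha": (8.0, 13.0)})
        assert sorted(adjs) == ["alpha", "theta"]
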