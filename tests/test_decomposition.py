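"""ICA recovery, RMS normalization, multitaper spectra, concatenation, PCA."""

import numpy as np
import pytest

import icmap
from icmap.containers import ICDecomposition, ComponentMatrix, SegmentSet
from icmap.decomposition import multitaper_psd, orient_rows


def _segments_from(X, fs=250.0, L=500):
    n = X.shape[1] // L
    return SegmentSet(segments=[X[:, i * L:(i + 1) * L] for i in range(n)],
                      segment_len_s=L / fs,
                      source_offsets=list(range(0, n * L, L)), fs=fs)


class TestRunICA:
    def test_noiseless_mixture_amari_below_005(self):
        rng = np.random.default_rng(0)
        S = rng.laplace(size=(3, 20000))
        A = rng.normal(size=(8, 3))
        segs = _segments_from(A @ S)
        dec = icmap.run_ica(segs, n_components=3, seed=0)
        assert icmap.amari_index(dec.unmixing @ A) < 0.05

    def test_identity_mixing_recovers_sources(self):
        rng = np.random.default_rng(1)
        S = rng.laplace(size=(4, 20000))
        segs = _segments_from(S.copy())
        dec = icmap.run_ica(segs, n_components=4, seed=1)
        # greedy max-|correlation| assignment between estimated and true rows
        C = np.abs(np.corrcoef(dec.sources, S)[:4, 4:])
        used = set()
        for c in range(4):
            k = int(np.argmax([C[c, j] if j not in used else -1 for j in range(4)]))
            used.add(k)
            assert C[c, k] > 0.95

    def test_unmixing_mixing_near_identity(self):
        rng = np.random.default_rng(2)
        S = rng.laplace(size=(3, 15000))
        A = rng.normal(size=(6, 3))
        dec = icmap.run_ica(_segments_from(A @ S), n_components=3, seed=2)
        np.testing.assert_allclose(dec.unmixing @ dec.mixing_est, np.eye(3),
                                   atol=1e-8)

    def test_rank_deficient_data_rejected(self):
        one = np.random.default_rng(3).normal(size=4000)
        X = np.vstack([one, one, one, one])  # rank 1
        with pytest.raises(ValueError):
            icmap.run_ica(_segments_from(X), n_components=3, seed=0)


class TestRmsNormalize:
    def test_direct_arithmetic(self):
        out = icmap.rms_normalize(np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(out, [[3.0, 4.0]] / np.sqrt(12.5))

    def test_idempotent_and_unit_rms(self):
        rng = np.random.default_rng(4)
        W = rng.normal(size=(35, 256))
        out = icmap.rms_normalize(W)
        np.testing.assert_allclose(np.sqrt(np.mean(out**2, axis=1)), 1.0,
                                   atol=1e-12)
        np.testing.assert_allclose(icmap.rms_normalize(out), out, atol=1e-12)

    def test_zero_row_rejected(self):
        with pytest.raises(ValueError):
            icmap.rms_normalize(np.array([[0.0, 0.0], [1.0, 2.0]]))


class TestOrientRows:
    def test_largest_entry_made_positive(self):
        W = np.array([[1.0, -3.0], [2.0, 1.0]])
        out = orient_rows(W)
        np.testing.assert_array_equal(out, [[-1.0, 3.0], [2.0, 1.0]])
        np.testing.assert_array_equal(orient_rows(out), out)


class TestComponentSpectra:
    def test_default_grid_has_101_bins(self):
        rng = np.random.default_rng(5)
        dec = ICDecomposition(unmixing=rng.normal(size=(3, 8)),
                              mixing_est=rng.normal(size=(8, 3)),
                              sources=rng.normal(size=(3, 5000)), fs=250.0)
        sm = icmap.component_spectra(dec)
        assert sm.rows.shape == (3, 101)
        np.testing.assert_allclose(sm.freqs, np.arange(101.0))

    def test_pure_tone_peaks_at_its_frequency(self):
        t = np.arange(10000) / 250.0
        x = np.sin(2 * np.pi * 50.0 * t)
        freqs, p = multitaper_psd(x, 250.0)
        assert freqs[np.argmax(p)] == pytest.approx(50.0)

    def test_white_noise_spectrum_flat_within_3db(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=250 * 120)
        freqs, p = multitaper_psd(x, 250.0)
        band = (freqs >= 5) & (freqs <= 95)
        db = 10 * np.log10(p[band])
        assert np.ptp(db) < 3.0

    def test_fmax_above_nyquist_rejected(self):
        x = np.zeros(5000)
        with pytest.raises(ValueError):
            multitaper_psd(x, 250.0, f_max=130.0)


class TestConcatenateSessions:
    @staticmethod
    def _fake_dec(rng, sid, C=3, N=8, T=2000):
        return ICDecomposition(unmixing=rng.normal(size=(C, N)),
                               mixing_est=rng.normal(size=(N, C)),
                               sources=rng.normal(size=(C, T)), fs=250.0,
                               session_id=sid)

    def test_row_stacking_and_bookkeeping(self):
        rng = np.random.default_rng(7)
        decs = [self._fake_dec(rng, f"s{i}") for i in range(4)]
        mat, sm = icmap.concatenate_sessions(decs)
        assert mat.rows.shape == (12, 8)
        assert sm.rows.shape == (12, 101)
        assert mat.row_index == sm.row_index
        assert mat.row_index[:4] == [("s0", 0), ("s0", 1), ("s0", 2), ("s1", 0)]

    def test_single_session_identity(self):
        rng = np.random.default_rng(8)
        dec = self._fake_dec(rng, "only")
        mat, _ = icmap.concatenate_sessions([dec])
        np.testing.assert_allclose(
            mat.rows, orient_rows(icmap.rms_normalize(dec.unmixing)))

    def test_mismatched_channel_count_rejected(self):
        rng = np.random.default_rng(9)
        decs = [self._fake_dec(rng, "a", N=8), self._fake_dec(rng, "b", N=10)]
        with pytest.raises(ValueError):
            icmap.concatenate_sessions(decs)


class TestPcaReduce:
    def test_shapes_and_monotone_explained_variance(self):
        rng = np.random.default_rng(10)
        mat = ComponentMatrix(rows=rng.normal(size=(200, 50)),
                              row_index=[("s", i) for i in range(200)])
        red, ev = icmap.pca_reduce(mat, n_keep=10)
        assert red.shape == (200, 10)
        assert np.all(np.diff(ev) <= 1e-12)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(200, 50))
        mat = ComponentMatrix(rows=X, row_index=[("s", i) for i in range(200)])
        red, ev = icmap.pca_reduce(mat, n_keep=6)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(np.cov(Xc, rowvar=False))
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(ev, evals[:6], rtol=1e-10)
        # scores agree up to the sign convention
        ref = Xc @ evecs[:, :6]
        for j in range(6):
            assert (np.allclose(red[:, j], ref[:, j], atol=1e-8)
                    or np.allclose(red[:, j], -ref[:, j], atol=1e-8))

    def test_exact_low_rank_captured(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 20))
        mat = ComponentMatrix(rows=X, row_index=[("s", i) for i in range(40)])
        red, ev = icmap.pca_reduce(mat, n_keep=3)
        Xc = X - X.mean(axis=0)
        total = np.sum(Xc**2) / (X.shape[0] - 1)
        assert np.sum(ev) == pytest.approx(total, rel=1e-10)

    def test_n_keep_too_large_rejected(self):
        mat = ComponentMatrix(rows=np.zeros((5, 4)),
                              row_index=[("s", i) for i in range(5)])
        with pytest.raises(ValueError):
            icmap.pca_reduce(mat, n_keep=10)


def test_amari_index_zero_for_scaled_permutation():
    P = np.array([[0.0, 2.0, 0.0], [0.0, 0.0, -0.5], [3.0, 0.0, 0.0]])
    assert icmap.amari_index(P) == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(13)
    assert icmap.amari_index(rng.normal(size=(5, 5))) > 0.1
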