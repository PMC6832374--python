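"""Cluster summaries, spectrum median filtering, harmonic-spacing detection."""

import json

import numpy as np
import pytest

import icmap
from icmap.containers import (
    ClusterAssignment,
    ComponentMatrix,
    EmbeddingMap,
    SpectraMatrix,
)


def _comb_spectrum(freqs, peak_freqs, peak_db=20.0, base_db=-10.0):
    spec = np.full(freqs.size, base_db)
    for f in peak_freqs:
        spec[np.argmin(np.abs(freqs - f))] = peak_db
    return spec


class TestMedianFilterSpectrum:
    def test_kernel_one_is_identity(self):
        spec = np.random.default_rng(0).normal(size=101)
        np.testing.assert_array_equal(icmap.median_filter_spectrum(spec, 1), spec)

    def test_impulse_removed(self):
        spec = np.zeros(101)
        spec[50] = 30.0
        out = icmap.median_filter_spectrum(spec, 5)
        assert out[50] == 0.0

    def test_matches_bruteforce_window_median(self):
        rng = np.random.default_rng(1)
        spec = rng.normal(size=60)
        out = icmap.median_filter_spectrum(spec, 5)
        padded = np.concatenate([[spec[0]] * 2, spec, [spec[-1]] * 2])
        expected = np.array([np.median(padded[i:i + 5]) for i in range(60)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            icmap.median_filter_spectrum(np.zeros(20), 4)


class TestHarmonicSpacing:
    def test_known_harmonics_spacing_18(self):
        freqs = np.arange(101.0)
        spec = _comb_spectrum(freqs, [36, 54, 72, 90])
        peaks, spacing = icmap.harmonic_spacing(spec, freqs)
        assert peaks == [36.0, 54.0, 72.0, 90.0]
        assert spacing == pytest.approx(18.0)
        assert max(peaks) == 90.0

    def test_flat_spectrum_no_peaks(self):
        freqs = np.arange(101.0)
        peaks, spacing = icmap.harmonic_spacing(np.zeros(101), freqs)
        assert peaks == []
        assert spacing is None

    def test_synthetic_comb_pitch_recovered_within_one_bin(self):
        freqs = np.arange(0.0, 100.5, 0.5)
        pitch = 7.0
        spec = _comb_spectrum(freqs, np.arange(pitch, 100.0, pitch))
        _, spacing = icmap.harmonic_spacing(spec, freqs)
        assert abs(spacing - pitch) <= 0.5

    def test_single_peak_gives_no_spacing(self):
        freqs = np.arange(101.0)
        peaks, spacing = icmap.harmonic_spacing(
            _comb_spectrum(freqs, [50]), freqs)
        assert peaks == [50.0]
        assert spacing is None


def _toy_inputs(rng, n_rows=8, n_ch=6, n_freq=21):
    rows = rng.normal(size=(n_rows, n_ch))
    idx = [("s0", i) for i in range(n_rows)]
    mat = ComponentMatrix(rows=rows, row_index=idx)
    spectra = SpectraMatrix(rows=rng.normal(size=(n_rows, n_freq)),
                            freqs=np.linspace(0, 100, n_freq), row_index=idx)
    return mat, spectra


class TestClusterStats:
    def test_singleton_cluster(self):
        rng = np.random.default_rng(2)
        mat, spectra = _toy_inputs(rng)
        labels = np.array([0] + [-1] * 7)
        (summ, noise) = icmap.cluster_stats(mat, spectra,
                                            ClusterAssignment(labels=labels))
        np.testing.assert_array_equal(summ.mean_topomap, mat.rows[0])
        np.testing.assert_array_equal(summ.median_topomap, mat.rows[0])
        np.testing.assert_allclose(summ.var_topomap, 0.0)
        assert noise.is_noise and noise.size == 7

    def test_row_and_negation_average_to_zero(self):
        rng = np.random.default_rng(3)
        mat, spectra = _toy_inputs(rng, n_rows=2)
        mat.rows[1] = -mat.rows[0]
        labels = np.zeros(2, dtype=int)
        (summ,) = icmap.cluster_stats(mat, spectra,
                                      ClusterAssignment(labels=labels))
        np.testing.assert_allclose(summ.mean_topomap, 0.0, atol=1e-12)

    def test_member_order_invariance(self):
        rng = np.random.default_rng(4)
        mat, spectra = _toy_inputs(rng, n_rows=10)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])
        ref = icmap.cluster_stats(mat, spectra, ClusterAssignment(labels=labels))
        perm = rng.permutation(10)
        mat2 = ComponentMatrix(rows=mat.rows[perm],
                               row_index=[mat.row_index[i] for i in perm])
        sp2 = SpectraMatrix(rows=spectra.rows[perm], freqs=spectra.freqs,
                            row_index=mat2.row_index)
        got = icmap.cluster_stats(mat2, sp2,
                                  ClusterAssignment(labels=labels[perm]))
        for a, b in zip(ref, got):
            np.testing.assert_allclose(a.mean_topomap, b.mean_topomap, atol=1e-12)
            np.testing.assert_allclose(a.median_topomap, b.median_topomap, atol=1e-12)
            np.testing.assert_allclose(a.var_topomap, b.var_topomap, atol=1e-12)

    def test_variance_topomap_nonnegative(self):
        rng = np.random.default_rng(5)
        mat, spectra = _toy_inputs(rng)
        labels = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        for s in icmap.cluster_stats(mat, spectra,
                                     ClusterAssignment(labels=labels)):
            assert np.all(s.var_topomap >= 0.0)

    def test_misaligned_inputs_rejected(self):
        rng = np.random.default_rng(6)
        mat, spectra = _toy_inputs(rng)
        with pytest.raises(ValueError):
            icmap.cluster_stats(mat, spectra,
                                ClusterAssignment(labels=np.zeros(5, dtype=int)))


class TestRenderReport:
    def test_bundle_layout_and_determinism(self, tmp_path):
        rng = np.random.default_rng(7)
        mat, spectra = _toy_inputs(rng)
        labels = np.array([0, 0, 0, 1, 1, 1, -1, -1])
        assign = ClusterAssignment(labels=labels)
        summaries = icmap.cluster_stats(mat, spectra, assign)
        emb = EmbeddingMap(Y=rng.normal(size=(8, 2)), kl_trace=np.zeros(1),
                           perplexity=5.0, seed=0, params={})
        out1 = icmap.render_report(summaries, emb, assign, tmp_path / "a")
        out2 = icmap.render_report(summaries, emb, assign, tmp_path / "b")
        for rel in ["summary.json", "embedding_labels.tsv",
                    "clusters/00/mean_topomap.tsv",
                    "clusters/00/mean_spectrum.tsv",
                    "clusters/01/members.tsv",
                    "clusters/noise/median_topomap.tsv"]:
            assert (out1 / rel).exists()
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()
        idx = json.loads((out1 / "summary.json").read_text())
        assert idx["n_clusters"] == 2
        assert idx["n_noise"] == 2

    def test_all_noise_assignment(self, tmp_path):
        rng = np.random.default_rng(8)
        mat, spectra = _toy_inputs(rng)
        assign = ClusterAssignment(labels=np.full(8, -1))
        summaries = icmap.cluster_stats(mat, spectra, assign)
        emb = EmbeddingMap(Y=rng.normal(size=(8, 2)), kl_trace=np.zeros(1),
                           perplexity=5.0, seed=0, params={})
        out = icmap.render_report(summaries, emb, assign, tmp_path / "noise")
        idx = json.loads((out / "summary.json").read_text())
        assert idx["n_clusters"] == 0
        assert [c["is_noise"] for c in idx["clusters"]] == [True]
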