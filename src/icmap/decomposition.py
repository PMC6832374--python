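"""Per-session ICA and the cross-session component matrices.

Each session's selected segments are unmixed by extended Infomax ICA after
PCA whitening; the rows of the resulting channel-space unmixing matrix are
the component topomaps.  Topomap rows are RMS-normalized and stacked across
sessions (e.g. 54 sessions x 35 components x 256 channels -> 1890 x 256),
multitaper power spectra of the component time series are computed on a
0-100 Hz / 1 Hz grid (101 bins) and stacked row-aligned, and the topomap
matrix is optionally PCA-reduced (default 45 dimensions) before embedding.
"""

from __future__ import annotations

import warnings

import numpy as np
from mne.preprocessing import infomax
from scipy.signal.windows import dpss

from .containers import (
    ComponentMatrix,
    FloatArray,
    ICDecomposition,
    SegmentSet,
    SpectraMatrix,
)

#: Multitaper half-bandwidth in Hz (DPSS NW = half_bandwidth * block length).
MT_HALF_BANDWIDTH_HZ = 2.0
MT_BLOCK_S = 2.0


def run_ica(segments: SegmentSet, n_components: int = 35,
            seed: int = 0, max_iter: int = 500) -> ICDecomposition:
    """Extended-Infomax ICA on the concatenated segments.

    The data are demeaned per channel, PCA-whitened to ``n_components``
    dimensions, and unmixed by the natural-gradient extended Infomax
    algorithm with kurtosis-based sub/super-Gaussian switching.  The
    returned unmixing acts on the original channel space; the estimated
    mixing is its pseudo-inverse.
    """
    X = segments.concatenated()
    n_ch, n_samp = X.shape
    if n_samp < 20 * n_components:
        raise ValueError("need at least 20 samples per component")
    X = X - X.mean(axis=1, keepdims=True)

    # PCA whitening
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    tol = max(n_ch, n_samp) * np.finfo(float).eps * s[0]
    if np.sum(s > tol) < n_components:
        raise ValueError(
            f"data rank {int(np.sum(s > tol))} below n_components={n_components}")
    K = (U[:, :n_components] / s[:n_components]).T * np.sqrt(n_samp)  # (C, N)
    Xw = K @ X  # whitened components x samples

    W = infomax(Xw.T, extended=True, max_iter=max_iter, rng=seed,
                verbose="error")
    unmixing = W @ K
    mixing_est = np.linalg.pinv(unmixing)
    sources = unmixing @ X
    return ICDecomposition(unmixing=unmixing, mixing_est=mixing_est,
                           sources=sources, fs=segments.fs)


def rms_normalize(weights: FloatArray) -> FloatArray:
    """Divide each row by its root-mean-square so every topomap has RMS 1."""
    weights = np.asarray(weights, dtype=float)
    rms = np.sqrt(np.mean(weights**2, axis=1))
    if np.any(rms == 0):
        raise ValueError("cannot RMS-normalize an all-zero row")
    return weights / rms[:, None]


def orient_rows(weights: FloatArray) -> FloatArray:
    """Fix the ICA sign indeterminacy: flip each row so its largest-magnitude
    entry is positive.

    Without a convention, the same artifact appears as two antipodal topomap
    groups across sessions (w and -w are equally valid), splitting each
    family into a pair of inverse-shaped clusters in the embedded map.
    """
    weights = np.asarray(weights, dtype=float)
    peak = weights[np.arange(weights.shape[0]),
                   np.argmax(np.abs(weights), axis=1)]
    sign = np.where(peak >= 0, 1.0, -1.0)
    return weights * sign[:, None]


def match_to_ground_truth(dec: ICDecomposition, mixing_true: FloatArray,
                          labels: list[str]) -> list[tuple[str, float]]:
    """Label each component by the true source whose topography its estimated
    mixing column best matches (absolute Pearson correlation)."""
    out = []
    for c in range(dec.n_components):
        col = dec.mixing_est[:, c]
        corr = [abs(float(np.corrcoef(col, mixing_true[:, k])[0, 1]))
                for k in range(mixing_true.shape[1])]
        k = int(np.argmax(corr))
        out.append((labels[k], corr[k]))
    return out


def multitaper_psd(x: FloatArray, fs: float, f_max: float = 100.0,
                   df: float = 1.0, block_s: float = MT_BLOCK_S,
                   half_bandwidth_hz: float = MT_HALF_BANDWIDTH_HZ,
                   ) -> tuple[FloatArray, FloatArray]:
    """Segment-averaged DPSS multitaper power spectral density.

    The series is cut into non-overlapping ``block_s`` blocks; each block is
    tapered by 2*NW-1 DPSS windows (NW = half_bandwidth * block_s), the
    eigenspectra are averaged over tapers and blocks, and the result is
    interpolated onto the uniform grid 0..f_max step df.
    Returns (freqs, power).
    """
    if f_max > fs / 2:
        raise ValueError("f_max above Nyquist")
    x = np.asarray(x, dtype=float)
    win = int(round(block_s * fs))
    if x.size < win:
        raise ValueError(f"need at least {block_s} s of samples")
    nw = half_bandwidth_hz * block_s
    n_tapers = max(int(2 * nw - 1), 1)
    tapers = dpss(win, nw, n_tapers)  # (K, win)
    n_blocks = x.size // win
    blocks = x[: n_blocks * win].reshape(n_blocks, win)
    blocks = blocks - blocks.mean(axis=1, keepdims=True)
    # (n_blocks, K, win) tapered, then one-sided periodograms
    tapered = blocks[:, None, :] * tapers[None, :, :]
    spec = np.fft.rfft(tapered, axis=2)
    psd = (np.abs(spec) ** 2) / fs  # tapers are unit-energy
    psd[..., 1:-1] *= 2.0
    psd = psd.mean(axis=(0, 1))
    native_freqs = np.fft.rfftfreq(win, d=1.0 / fs)
    grid = np.arange(0.0, f_max + 0.5 * df, df)
    return grid, np.interp(grid, native_freqs, psd)


def component_spectra(dec: ICDecomposition, f_max: float = 100.0,
                      df: float = 1.0) -> SpectraMatrix:
    """Multitaper power spectrum of every component on the 0..f_max grid."""
    rows = []
    for c in range(dec.n_components):
        grid, p = multitaper_psd(dec.sources[c], dec.fs, f_max=f_max, df=df)
        rows.append(p)
    power = np.vstack(rows)
    db = 10.0 * np.log10(np.maximum(power, 1e-30))
    idx = [(dec.session_id, c) for c in range(dec.n_components)]
    return SpectraMatrix(rows=db, freqs=grid, row_index=idx, units="dB")


def concatenate_sessions(decs: list[ICDecomposition], f_max: float = 100.0,
                         df: float = 1.0, orient_signs: bool = True,
                         ) -> tuple[ComponentMatrix, SpectraMatrix]:
    """Stack RMS-normalized topomap rows and spectra across sessions.

    Row order is session order with component order preserved inside each
    session, and the two matrices share the same row index.  By default the
    sign convention of :func:`orient_rows` is applied so that one artifact
    family maps to one topomap cluster rather than an antipodal pair.
    """
    if not decs:
        raise ValueError("need at least one decomposition")
    n_ch = decs[0].n_channels
    weight_rows, spec_rows, index = [], [], []
    grid = None
    for d in decs:
        if d.n_channels != n_ch:
            raise ValueError("all sessions must share the channel count")
        w = rms_normalize(d.unmixing)
        weight_rows.append(orient_rows(w) if orient_signs else w)
        sm = component_spectra(d, f_max=f_max, df=df)
        if grid is None:
            grid = sm.freqs
        spec_rows.append(sm.rows)
        index.extend(sm.row_index)
    mat = ComponentMatrix(rows=np.vstack(weight_rows), row_index=list(index))
    spectra = SpectraMatrix(rows=np.vstack(spec_rows), freqs=grid,
                            row_index=list(index), units="dB")
    return mat, spectra


def pca_reduce(mat: ComponentMatrix, n_keep: int = 45,
               ) -> tuple[FloatArray, FloatArray]:
    """Project column-centered topomap rows onto the top principal axes.

    Sign convention: the largest-magnitude loading of each axis is positive.
    Returns (reduced (n_rows, n_keep), explained-variance vector).
    """
    X = mat.rows
    if n_keep > min(X.shape):
        raise ValueError("n_keep exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(n_keep), np.argmax(np.abs(Vt[:n_keep]), axis=1)])
    reduced = (U[:, :n_keep] * s[:n_keep]) * flip
    explained = s[:n_keep] ** 2 / (X.shape[0] - 1)
    return reduced, explained


def amari_index(P: FloatArray) -> float:
    """Permutation/scale-invariant ICA recovery error of P = unmixing @ mixing.

    Zero iff P is a scaled permutation; values below ~0.05 indicate clean
    source recovery.
    """
    P = np.abs(np.asarray(P, dtype=float))
    n = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * n * (n - 1)))
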