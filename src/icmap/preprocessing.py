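"""Supervised preprocessing of a multichannel recording.

The chain mirrors standard practice for EEG acquired during fMRI once the
template-based artifact removal has been done elsewhere: zero-phase FIR
bandpass (0.5-100 Hz), polyphase downsampling (1 kHz -> 250 Hz), rejection
of high-variance channel-windows by Tukey's fence with neighbor-weighted
interpolation, and uniform random selection of short segments (150 sections
x 2 s = 5 min per record) to feed ICA.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import FloatArray, Recording, SegmentSet


def bandpass_filter(rec: Recording, f_low: float = 0.5, f_high: float = 100.0,
                    order: int | None = None) -> Recording:
    """Two-way (forward-backward) zero-phase FIR bandpass.

    The filter is a Hamming-windowed sinc with ``order`` taps (default
    ``3 * fs / f_low``, enough transition sharpness to attenuate below the
    low edge); applying it in both directions cancels the group delay.
    """
    nyq = rec.fs / 2.0
    if not (0 < f_low < f_high < nyq):
        raise ValueError("band edges must satisfy 0 < f_low < f_high < fs/2")
    if order is None:
        order = int(3 * rec.fs / f_low)
    if order % 2 == 0:
        order += 1  # odd tap count keeps a type-I linear-phase FIR
    b = signal.firwin(order, [f_low, f_high], pass_zero=False, fs=rec.fs)
    padlen = min(3 * order, rec.n_samples - 1)
    out = signal.filtfilt(b, [1.0], rec.data, axis=1, padlen=padlen)
    return Recording(data=out, fs=rec.fs, layout=rec.layout,
                     annotations=list(rec.annotations))


def downsample(rec: Recording, target_fs: float = 250.0) -> Recording:
    """Anti-aliased polyphase resampling to ``target_fs``."""
    if target_fs >= rec.fs:
        raise ValueError("target_fs must be below the current sampling rate")
    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return Recording(data=out, fs=target_fs, layout=rec.layout,
                     annotations=list(rec.annotations))


def crop_recording(rec: Recording, start_s: float, end_s: float) -> Recording:
    """Crop to [start_s, end_s); used to drop annotated spans such as the
    gradient residue of initial dummy scans."""
    i0 = int(round(start_s * rec.fs))
    i1 = int(round(end_s * rec.fs))
    if not (0 <= i0 < i1 <= rec.n_samples):
        raise ValueError("crop window outside the recording")
    return Recording(data=rec.data[:, i0:i1].copy(), fs=rec.fs, layout=rec.layout)


def tukey_reject_interpolate(rec: Recording, window_s: float = 1.0,
                             fence: float = 1.5,
                             ) -> tuple[Recording, np.ndarray]:
    """Flag high-variance channel-windows by Tukey's fence and interpolate.

    Variance is computed per channel per non-overlapping window; within each
    channel, windows whose variance exceeds Q3 + ``fence``*IQR of that
    channel's window-variance population are flagged and replaced by the
    neighbor-weighted average (layout adjacency weights) of unflagged
    neighbors.  Returns the cleaned recording and the boolean
    (n_channels, n_windows) rejection mask.
    """
    win = int(round(window_s * rec.fs))
    if win < 4:
        raise ValueError("window too short: need at least 4 samples")
    n_win = rec.n_samples // win
    if n_win < 4:
        raise ValueError("need at least 4 windows for a variance population")
    X = rec.data[:, : n_win * win].reshape(rec.n_channels, n_win, win)
    variances = X.var(axis=2)
    q1 = np.percentile(variances, 25, axis=1, keepdims=True)
    q3 = np.percentile(variances, 75, axis=1, keepdims=True)
    mask = variances > q3 + fence * (q3 - q1)

    out = rec.data.copy()
    for w in range(n_win):
        flagged = np.where(mask[:, w])[0]
        if len(flagged) == rec.n_channels:
            warnings.warn(f"window {w}: all channels flagged, left unchanged")
            continue
        sl = slice(w * win, (w + 1) * win)
        for ch in flagged:
            nbrs = [(j, wt) for j, wt in rec.layout.neighbor_graph[ch]
                    if not mask[j, w]]
            if not nbrs:
                warnings.warn(f"window {w}, channel {ch}: no clean neighbors")
                continue
            total = sum(wt for _, wt in nbrs)
            acc = np.zeros(win)
            for j, wt in nbrs:
                acc += (wt / total) * rec.data[j, sl]
            out[ch, sl] = acc
    return Recording(data=out, fs=rec.fs, layout=rec.layout,
                     annotations=list(rec.annotations)), mask


def select_segments(rec: Recording, n_sections: int = 150,
                    segment_len_s: float = 2.0, seed: int = 0) -> SegmentSet:
    """Partition the record into ``n_sections`` uniform sections and draw one
    random ``segment_len_s`` segment from each (deterministic under seed)."""
    L = int(round(segment_len_s * rec.fs))
    if rec.n_samples < n_sections * L:
        raise ValueError("recording too short for the requested segments")
    rng = np.random.default_rng(seed)
    sec_len = rec.n_samples // n_sections
    segments, offsets = [], []
    for i in range(n_sections):
        start = i * sec_len
        hi = start + sec_len - L
        off = int(rng.integers(start, hi + 1)) if hi > start else start
        segments.append(rec.data[:, off:off + L].copy())
        offsets.append(off)
    return SegmentSet(segments=segments, segment_len_s=segment_len_s,
                      source_offsets=offsets, fs=rec.fs)
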