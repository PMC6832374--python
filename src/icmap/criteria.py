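"""Per-component artifact criteria and their projection onto the map.

Four scalar criteria characterize each independent component:

* **RMS energy** — root-mean-square of the component time series (uV).
* **Autocorrelation** — lagged-product sum at a 20 ms lag; physiological
  components tend to score high, broadband artifacts low.
* **Focal topography** — maximum channel-wise Z-score of the topomap row;
  high when the component's energy concentrates in one or a few channels.
* **Focal trial activity** — maximum segment-wise Z-score of the per-segment
  peak-to-peak range; high when the activity is bursty rather than evenly
  distributed over time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    CriteriaTable,
    EmbeddingMap,
    FloatArray,
    ICDecomposition,
)


def rms_energy(x: FloatArray, mean_square: bool = False) -> float:
    """Root-mean-square of a time series (``mean_square=True`` omits the root)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty time series")
    ms = float(np.mean(x**2))
    return ms if mean_square else float(np.sqrt(ms))


def autocorrelation(x: FloatArray, lag_ms: float = 20.0, fs: float = 250.0,
                    normalized: bool = False) -> float:
    """Lagged-product sum sum_t x(t) x(t-l) at lag l = round(lag_ms * fs / 1000).

    ``normalized=True`` divides by the zero-lag sum, giving a correlation-like
    value in [-1, 1] for long stationary series.
    """
    x = np.asarray(x, dtype=float)
    lag = int(round(lag_ms * fs / 1000.0))
    if lag >= x.size:
        raise ValueError("lag must be shorter than the series")
    num = float(np.dot(x[lag:], x[: x.size - lag]))
    if not normalized:
        return num
    denom = float(np.dot(x, x))
    return num / denom if denom > 0 else 0.0


def _max_zscore(values: FloatArray) -> float:
    values = np.asarray(values, dtype=float)
    sd = values.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(np.max((values - values.mean()) / sd))


def focal_topography(w: FloatArray, squared: bool = False) -> float:
    """Maximum channel Z-score of a topomap row (``squared=True`` scores
    energy, i.e. squared weights, instead of raw weights)."""
    w = np.asarray(w, dtype=float)
    if w.size < 2:
        raise ValueError("need at least 2 channels")
    return _max_zscore(w**2 if squared else w)


def focal_trial_activity(segments: FloatArray | list[FloatArray]) -> float:
    """Maximum segment Z-score of per-segment peak-to-peak range."""
    seg = [np.asarray(s, dtype=float) for s in segments]
    if len(seg) < 2:
        raise ValueError("need at least 2 segments")
    ranges = np.array([np.ptp(s) for s in seg])
    return _max_zscore(ranges)


def compute_criteria(dec: ICDecomposition, segment_len_s: float = 2.0,
                     lag_ms: float = 20.0, normalized_autocorr: bool = False,
                     ) -> CriteriaTable:
    """All four criteria for every component of one session.

    The component time series (concatenated selected segments) is cut back
    into its ``segment_len_s`` segments for the focal-trial criterion.
    """
    L = int(round(segment_len_s * dec.fs))
    n_seg = dec.sources.shape[1] // L
    if n_seg < 2:
        raise ValueError("need at least 2 segments of sources")
    rms_v, ac_v, ft_v, fc_v = [], [], [], []
    for c in range(dec.n_components):
        x = dec.sources[c]
        rms_v.append(rms_energy(x))
        ac_v.append(autocorrelation(x, lag_ms=lag_ms, fs=dec.fs,
                                    normalized=normalized_autocorr))
        fc_v.append(focal_topography(dec.unmixing[c]))
        segs = x[: n_seg * L].reshape(n_seg, L)
        ft_v.append(focal_trial_activity(segs))
    idx = [(dec.session_id, c) for c in range(dec.n_components)]
    return CriteriaTable(rms_energy=np.array(rms_v), autocorr=np.array(ac_v),
                         focal_topo=np.array(fc_v), focal_trial=np.array(ft_v),
                         row_index=idx, lag_ms=lag_ms)


def concat_criteria(tables: list[CriteriaTable]) -> CriteriaTable:
    """Stack per-session criteria tables in session order."""
    return CriteriaTable(
        rms_energy=np.concatenate([t.rms_energy for t in tables]),
        autocorr=np.concatenate([t.autocorr for t in tables]),
        focal_topo=np.concatenate([t.focal_topo for t in tables]),
        focal_trial=np.concatenate([t.focal_trial for t in tables]),
        row_index=[i for t in tables for i in t.row_index],
        lag_ms=tables[0].lag_ms,
    )


def _safe_log10(v: FloatArray) -> FloatArray:
    """log10 with an offset guard for non-positive entries."""
    v = np.asarray(v, dtype=float)
    lo = v.min()
    offset = (1e-12 - lo) if lo <= 0 else 0.0
    return np.log10(v + offset)


def criteria_map(table: CriteriaTable, emb: EmbeddingMap) -> pd.DataFrame:
    """Embedded coordinates joined with raw and log-scaled criteria.

    The log10 transform is applied to focal topography and autocorrelation —
    the two criteria whose dynamic range otherwise hides structure on a
    color-mapped embedding.
    """
    n = len(table.row_index)
    if emb.Y.shape[0] != n:
        raise ValueError("criteria table and embedding are misaligned")
    cols = {"session_id": [s for s, _ in table.row_index],
            "component_id": [c for _, c in table.row_index]}
    for d in range(emb.Y.shape[1]):
        cols[f"y{d + 1}"] = emb.Y[:, d]
    cols["rms_energy"] = table.rms_energy
    cols["autocorr"] = table.autocorr
    cols["focal_topo"] = table.focal_topo
    cols["focal_trial"] = table.focal_trial
    cols["log10_autocorr"] = _safe_log10(table.autocorr)
    cols["log10_focal_topo"] = _safe_log10(table.focal_topo)
    return pd.DataFrame(cols)
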