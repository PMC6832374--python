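"""Per-cluster interpretation artifacts.

For every DBSCAN cluster the member topomap rows are summarized by
element-wise mean, median and variance, the member spectra by their mean
(dB), and the mean spectrum is scanned for harmonically spaced peaks —
the fingerprint of gradient-coil residue, whose comb sits at multiples of
the slice frequency (36 slices / 2-s TR -> 18 Hz spacing, top in-band
harmonic at 90 Hz).  Narrowband artifacts (gradient comb, 50 Hz mains)
are assessed on the unfiltered spectrum; a median filter is available to
smooth broadband shapes for visual inspection of higher frequencies.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import argrelextrema

from .containers import (
    ClusterAssignment,
    ClusterSummary,
    ComponentMatrix,
    CriteriaTable,
    EmbeddingMap,
    FloatArray,
    SpectraMatrix,
)

DEFAULT_MEDIAN_KERNEL = 5
DEFAULT_PROMINENCE_DB = 6.0


def median_filter_spectrum(spec: FloatArray, kernel_bins: int = DEFAULT_MEDIAN_KERNEL,
                           ) -> FloatArray:
    """Sliding-window median with edge replication; kernel must be odd."""
    spec = np.asarray(spec, dtype=float)
    if kernel_bins % 2 == 0:
        raise ValueError("kernel must be odd")
    if kernel_bins >= spec.size:
        raise ValueError("kernel larger than the spectrum")
    if kernel_bins == 1:
        return spec.copy()
    return median_filter(spec, size=kernel_bins, mode="nearest")


def harmonic_spacing(spec: FloatArray, freqs: FloatArray,
                     min_prominence_db: float = DEFAULT_PROMINENCE_DB,
                     background_bins: int = 11,
                     ) -> tuple[list[float], float | None]:
    """Detect harmonically spaced peaks in a dB spectrum.

    Local maxima standing at least ``min_prominence_db`` above the local
    median background are kept; the spacing estimate is the median of
    consecutive peak-frequency differences (None with fewer than 2 peaks).
    """
    spec = np.asarray(spec, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    background = median_filter(spec, size=background_bins, mode="nearest")
    (cand,) = argrelextrema(spec, np.greater_equal, order=1)
    # strict local maxima only (greater_equal admits plateaus at both ends)
    peaks = []
    for i in cand:
        if 0 < i < spec.size - 1 and spec[i] - background[i] >= min_prominence_db:
            if spec[i] >= spec[i - 1] and spec[i] >= spec[i + 1]:
                peaks.append(i)
    # collapse adjacent-bin plateaus to one peak
    dedup: list[int] = []
    for i in peaks:
        if dedup and i - dedup[-1] == 1:
            if spec[i] > spec[dedup[-1]]:
                dedup[-1] = i
        else:
            dedup.append(i)
    freqs_out = [float(freqs[i]) for i in dedup]
    if len(freqs_out) < 2:
        return freqs_out, None
    spacing = float(np.median(np.diff(freqs_out)))
    return freqs_out, spacing


def cluster_stats(mat: ComponentMatrix, spectra: SpectraMatrix,
                  assign: ClusterAssignment,
                  criteria: CriteriaTable | None = None,
                  min_prominence_db: float = DEFAULT_PROMINENCE_DB,
                  ) -> list[ClusterSummary]:
    """Mean/median/variance topomaps and mean spectra per cluster.

    The noise group (label -1) is summarized last and marked as non-cluster.
    Harmonic peaks are detected on each cluster's unfiltered mean spectrum.
    """
    if mat.rows.shape[0] != len(assign.labels) or spectra.rows.shape[0] != len(assign.labels):
        raise ValueError("matrix, spectra and assignment are misaligned")
    summaries = []
    ids = sorted(set(int(l) for l in assign.labels if l >= 0)) + (
        [-1] if assign.n_noise else [])
    for cid in ids:
        members = [int(i) for i in np.where(assign.labels == cid)[0]]
        if not members:
            warnings.warn(f"cluster {cid} is empty; skipped")
            continue
        W = mat.rows[members]
        S = spectra.rows[members]
        mean_spec = S.mean(axis=0)
        peaks, spacing = harmonic_spacing(mean_spec, spectra.freqs,
                                          min_prominence_db=min_prominence_db)
        stats = None
        if criteria is not None:
            stats = {name: {"mean": float(np.mean(v[members])),
                            "median": float(np.median(v[members]))}
                     for name, v in [("rms_energy", criteria.rms_energy),
                                     ("autocorr", criteria.autocorr),
                                     ("focal_topo", criteria.focal_topo),
                                     ("focal_trial", criteria.focal_trial)]}
        summaries.append(ClusterSummary(
            cluster_id=cid, member_rows=members,
            mean_topomap=W.mean(axis=0), median_topomap=np.median(W, axis=0),
            var_topomap=W.var(axis=0), mean_spectrum_db=mean_spec,
            freqs=spectra.freqs, harmonic_peaks=peaks,
            harmonic_spacing=spacing, criteria_stats=stats))
    return summaries


def render_report(summaries: list[ClusterSummary], emb: EmbeddingMap,
                  assign: ClusterAssignment, out_dir: str | Path,
                  make_figures: bool = False) -> Path:
    """Write the per-cluster TSV bundle and an index JSON.

    Layout: ``clusters/<id>/{mean,median,var}_topomap.tsv``,
    ``mean_spectrum.tsv``, ``members.tsv`` and a top-level ``summary.json``
    plus the embedding coordinates with labels.  File contents are
    deterministic for identical inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = {"n_clusters": assign.n_clusters, "n_noise": assign.n_noise,
             "perplexity": emb.perplexity, "clusters": []}
    coords = np.column_stack([emb.Y, assign.labels])
    hdr = "\t".join([f"y{d + 1}" for d in range(emb.Y.shape[1])] + ["label"])
    np.savetxt(out / "embedding_labels.tsv", coords, delimiter="\t",
               header=hdr, comments="", fmt="%.8g")
    for s in summaries:
        name = "noise" if s.is_noise else f"{s.cluster_id:02d}"
        cdir = out / "clusters" / name
        cdir.mkdir(parents=True, exist_ok=True)
        for tag, vec in [("mean_topomap", s.mean_topomap),
                         ("median_topomap", s.median_topomap),
                         ("var_topomap", s.var_topomap)]:
            np.savetxt(cdir / f"{tag}.tsv", vec[None, :], delimiter="\t", fmt="%.8g")
        np.savetxt(cdir / "mean_spectrum.tsv",
                   np.column_stack([s.freqs, s.mean_spectrum_db]),
                   delimiter="\t", header="freq_hz\tpower_db", comments="",
                   fmt="%.8g")
        np.savetxt(cdir / "members.tsv", np.asarray(s.member_rows, dtype=int)[:, None],
                   delimiter="\t", fmt="%d")
        index["clusters"].append({
            "id": s.cluster_id, "size": s.size, "is_noise": s.is_noise,
            "harmonic_peaks_hz": s.harmonic_peaks,
            "harmonic_spacing_hz": s.harmonic_spacing,
            "criteria": s.criteria_stats})
    with open(out / "summary.json", "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    if make_figures:
        _render_figures(summaries, emb, assign, out)
    return out


def _render_figures(summaries, emb, assign, out: Path) -> None:
    """Optional embedding scatter and per-cluster scalp maps (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    sc = ax.scatter(emb.Y[:, 0], emb.Y[:, 1], c=assign.labels, cmap="tab20", s=12)
    ax.set_xlabel("y1")
    ax.set_ylabel("y2")
    fig.colorbar(sc, ax=ax, label="cluster")
    fig.savefig(out / "embedding.png", dpi=120)
    plt.close(fig)
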