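"""Reading and writing the pipeline's on-disk formats.

Recordings travel either as standard EEG files (EDF / BrainVision, read
through mne) or as a plain delimited numeric matrix (channels x samples)
with a JSON sidecar holding the sampling rate and the 2D sensor layout.
Intermediate matrices (topomap rows, spectra, embeddings, labels) are
tab-separated text with a (session_id, component_id) row-index sidecar, so
every stage can be rerun or inspected with ordinary tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .containers import (
    ClusterAssignment,
    ComponentMatrix,
    EmbeddingMap,
    Recording,
    SensorLayout,
    SpectraMatrix,
)
from .synthetic import make_layout


def write_layout_json(layout: SensorLayout, path: str | Path) -> None:
    doc = {"channels": [{"name": f"E{i + 1}",
                         "x": float(layout.positions[i, 0]),
                         "y": float(layout.positions[i, 1])}
                        for i in range(layout.n_channels)],
           "neighbors": {str(i): [[j, w] for j, w in nbrs]
                         for i, nbrs in layout.neighbor_graph.items()}}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_layout_json(path: str | Path) -> SensorLayout:
    doc = json.loads(Path(path).read_text())
    pos = np.array([[ch["x"], ch["y"]] for ch in doc["channels"]], dtype=float)
    if "neighbors" in doc:
        graph = {int(i): [(int(j), float(w)) for j, w in nbrs]
                 for i, nbrs in doc["neighbors"].items()}
    else:  # rebuild adjacency from positions
        graph = make_layout(max(pos.shape[0], 8)).neighbor_graph
    return SensorLayout(positions=pos, neighbor_graph=graph)


def write_recording(rec: Recording, data_path: str | Path,
                    meta_path: str | Path) -> None:
    """Recording as a channels x samples TSV plus a JSON meta/layout sidecar."""
    np.savetxt(data_path, rec.data, delimiter="\t", fmt="%.8g")
    meta = {"fs": rec.fs,
            "annotations": [list(a) for a in rec.annotations]}
    Path(meta_path).write_text(json.dumps(meta))
    write_layout_json(rec.layout, str(meta_path) + ".layout.json")


def read_recording(data_path: str | Path, meta_path: str | Path) -> Recording:
    data = np.atleast_2d(np.loadtxt(data_path, delimiter="\t"))
    meta = json.loads(Path(meta_path).read_text())
    layout = read_layout_json(str(meta_path) + ".layout.json")
    rec = Recording(data=data, fs=float(meta["fs"]), layout=layout,
                    annotations=[tuple(a) for a in meta.get("annotations", [])])
    rec.validate()
    return rec


def read_eeg_file(path: str | Path, layout: SensorLayout | None = None) -> Recording:
    """Read an EDF or BrainVision recording via mne.

    EEG files carry no 2D layout; pass one, or a quasi-uniform disk layout
    with matching channel count is generated.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported EEG file format: {path.suffix}")
    data = raw.get_data() * 1e6  # volts -> microvolts
    if layout is None:
        layout = make_layout(data.shape[0], seed=0)
    return Recording(data=data, fs=float(raw.info["sfreq"]), layout=layout)


def _write_indexed(rows: np.ndarray, index: list[tuple[str, int]],
                   path: str | Path) -> None:
    np.savetxt(path, rows, delimiter="\t", fmt="%.8g")
    with open(str(path) + ".index.tsv", "w") as fh:
        fh.write("session_id\tcomponent_id\n")
        for sid, cid in index:
            fh.write(f"{sid}\t{cid}\n")


def write_component_matrix(mat: ComponentMatrix, path: str | Path) -> None:
    _write_indexed(mat.rows, mat.row_index, path)


def read_component_matrix(path: str | Path) -> ComponentMatrix:
    rows = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    index = _read_index(str(path) + ".index.tsv")
    return ComponentMatrix(rows=rows, row_index=index)


def write_spectra_matrix(sm: SpectraMatrix, path: str | Path) -> None:
    _write_indexed(sm.rows, sm.row_index, path)
    np.savetxt(str(path) + ".freqs.tsv", sm.freqs, delimiter="\t", fmt="%.8g")


def read_spectra_matrix(path: str | Path, units: str = "dB") -> SpectraMatrix:
    rows = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    freqs = np.loadtxt(str(path) + ".freqs.tsv", delimiter="\t")
    index = _read_index(str(path) + ".index.tsv")
    return SpectraMatrix(rows=rows, freqs=freqs, row_index=index, units=units)


def _read_index(path: str) -> list[tuple[str, int]]:
    index = []
    with open(path) as fh:
        next(fh)
        for line in fh:
            sid, cid = line.rstrip("\n").split("\t")
            index.append((sid, int(cid)))
    return index


def write_embedding(emb: EmbeddingMap, path: str | Path,
                    row_index: list[tuple[str, int]] | None = None) -> None:
    """Coordinates as TSV plus a JSON run-metadata sidecar."""
    n, d = emb.Y.shape
    with open(path, "w") as fh:
        cols = ["session_id", "component_id"] if row_index else []
        fh.write("\t".join(cols + [f"y{i + 1}" for i in range(d)]) + "\n")
        for r in range(n):
            pre = [row_index[r][0], str(row_index[r][1])] if row_index else []
            fh.write("\t".join(pre + [f"{v:.8g}" for v in emb.Y[r]]) + "\n")
    meta = {"perplexity": emb.perplexity, "seed": emb.seed,
            "final_kl": float(emb.kl_trace[-1]), "params": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in emb.params.items()}}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_embedding_coords(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    ycols = [i for i, c in enumerate(header) if c.startswith("y")]
    return np.atleast_2d(np.loadtxt(path, delimiter="\t", skiprows=1,
                                    usecols=ycols))


def write_labels(assign: ClusterAssignment, path: str | Path,
                 row_index: list[tuple[str, int]] | None = None) -> None:
    with open(path, "w") as fh:
        cols = ["session_id", "component_id"] if row_index else []
        fh.write("\t".join(cols + ["label"]) + "\n")
        for r, lab in enumerate(assign.labels):
            pre = [row_index[r][0], str(row_index[r][1])] if row_index else []
            fh.write("\t".join(pre + [str(int(lab))]) + "\n")
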