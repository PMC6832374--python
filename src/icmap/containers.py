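"""Shared data containers for the IC-mapping pipeline.

Every stage of the pipeline communicates through the small dataclasses
defined here: a sensor layout and multichannel recording on the input
side, per-session ICA decompositions in the middle, and concatenated
weight/spectra matrices, embeddings, cluster assignments and criteria
tables on the analysis side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

FloatArray = npt.NDArray[np.floating]

#: Artifact/source families the simulator knows how to generate.
SOURCE_FAMILIES = (
    "eog_vertical",
    "eog_horizontal",
    "blink",
    "emg",
    "ecg",
    "gradient",
    "line_noise",
    "alpha",
    "pink_background",
)


@dataclass
class SensorLayout:
    """2D scalp sensor geometry on the unit disk.

    Positions use a head-centric frame: +y is anterior (nose), -y posterior,
    +x is the right ear.  ``neighbor_graph`` maps each channel index to a
    list of ``(neighbor_index, weight)`` pairs; weights are positive and sum
    to one per channel, and the neighbor relation is symmetric.
    """

    positions: FloatArray  # (n_channels, 2)
    neighbor_graph: dict[int, list[tuple[int, float]]]

    @property
    def n_channels(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        r = np.linalg.norm(self.positions, axis=1)
        if not np.all(r <= 1.0 + 1e-9):
            raise ValueError("all sensor positions must lie within the unit disk")
        for ch, nbrs in self.neighbor_graph.items():
            if not nbrs:
                raise ValueError(f"channel {ch} has no neighbors")
            w = sum(wt for _, wt in nbrs)
            if abs(w - 1.0) > 1e-8:
                raise ValueError(f"neighbor weights of channel {ch} sum to {w}, not 1")
            for j, _ in nbrs:
                if ch not in [i for i, _ in self.neighbor_graph[j]]:
                    raise ValueError("neighbor relation is not symmetric")


@dataclass
class SourceSpec:
    """One simulated source: family tag, spatial topography and waveform recipe."""

    family: str
    topography: FloatArray  # (n_channels,)
    waveform_params: dict
    amplitude: float  # microvolts (RMS of the projected waveform scale)

    def __post_init__(self) -> None:
        if self.family not in SOURCE_FAMILIES:
            raise ValueError(f"unknown source family {self.family!r}")
        if not np.all(np.isfinite(self.topography)):
            raise ValueError("topography must be finite")
        if self.family == "gradient":
            if self.waveform_params.get("n_slices", 0) < 1:
                raise ValueError("gradient source needs n_slices >= 1")
            if self.waveform_params.get("tr_s", 0.0) <= 0:
                raise ValueError("gradient source needs TR > 0")


@dataclass
class GroundTruth:
    """Known mixing used to synthesize a recording: X = A @ S before sensor noise."""

    mixing: FloatArray  # (n_channels, n_sources)  -- A
    sources: FloatArray  # (n_sources, n_samples)  -- S
    labels: list[str]
    seed: int


@dataclass
class Recording:
    """Multichannel EEG signal in microvolts with its sampling rate and layout."""

    data: FloatArray  # (n_channels, n_samples)
    fs: float
    layout: SensorLayout
    annotations: list[tuple[float, float, str]] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def validate(self) -> None:
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording data must be finite")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[0] != self.layout.n_channels:
            raise ValueError("data rows must match layout.n_channels")


@dataclass
class SegmentSet:
    """Equal-length segments drawn from a recording, one per uniform section."""

    segments: list[FloatArray]  # each (n_channels, L)
    segment_len_s: float
    source_offsets: list[int]  # start sample of each segment in the recording
    fs: float

    @property
    def n_sections(self) -> int:
        return len(self.segments)

    def concatenated(self) -> FloatArray:
        return np.concatenate(self.segments, axis=1)


@dataclass
class ICDecomposition:
    """Per-session ICA result in original channel space.

    ``unmixing`` rows are the inverse weights W_c whose spatial pattern is
    the component topomap; ``sources`` holds the component time series
    Z = W @ X.
    """

    unmixing: FloatArray  # (C, N)
    mixing_est: FloatArray  # (N, C)
    sources: FloatArray  # (C, T)
    fs: float
    session_id: str = "session"

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    @property
    def n_channels(self) -> int:
        return self.unmixing.shape[1]


@dataclass
class ComponentMatrix:
    """RMS-normalized inverse-weight rows stacked across sessions."""

    rows: FloatArray  # (sum_sessions C, N)
    row_index: list[tuple[str, int]]  # (session_id, component_id) per row


@dataclass
class SpectraMatrix:
    """Component power spectra aligned row-for-row with a ComponentMatrix."""

    rows: FloatArray  # (n_rows, F)
    freqs: FloatArray  # (F,)
    row_index: list[tuple[str, int]]
    units: str = "dB"  # "dB" (10*log10 power) or "power"


@dataclass
class AffinityModel:
    """Perplexity-calibrated Gaussian affinities for t-SNE."""

    P_conditional: FloatArray  # (n, n), row-stochastic, zero diagonal
    P_joint: FloatArray  # (n, n), symmetric, sums to 1
    sigma: FloatArray  # (n,) per-point bandwidths
    perplexity: float


@dataclass
class EmbeddingMap:
    """Low-dimensional t-SNE coordinates plus the optimization trace."""

    Y: FloatArray  # (n, d), d in {2, 3}
    kl_trace: FloatArray
    perplexity: float
    seed: int
    params: dict


@dataclass
class ClusterParams:
    """DBSCAN parameters: neighborhood radius and minimum neighbor count."""

    eps: float
    k: int = 20

    def validate(self, dim: int) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.k < dim + 1:
            raise ValueError(f"k must be at least dim + 1 = {dim + 1}")


@dataclass
class ClusterAssignment:
    """Per-point DBSCAN labels; -1 marks the noise group."""

    labels: npt.NDArray[np.integer]

    @property
    def n_clusters(self) -> int:
        return int(len(set(self.labels[self.labels >= 0])))

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == -1))


@dataclass
class CriteriaTable:
    """The four per-component criteria, row-aligned with a ComponentMatrix."""

    rms_energy: FloatArray
    autocorr: FloatArray
    focal_topo: FloatArray
    focal_trial: FloatArray
    row_index: list[tuple[str, int]]
    lag_ms: float = 20.0


@dataclass
class ClusterSummary:
    """Interpretation artifacts for one cluster (or the noise group)."""

    cluster_id: int  # -1 for noise
    member_rows: list[int]
    mean_topomap: FloatArray
    median_topomap: FloatArray
    var_topomap: FloatArray
    mean_spectrum_db: FloatArray
    freqs: FloatArray
    harmonic_peaks: list[float]
    harmonic_spacing: float | None
    criteria_stats: dict | None = None

    @property
    def size(self) -> int:
        return len(self.member_rows)

    @property
    def is_noise(self) -> bool:
        return self.cluster_id == -1
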