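"""Forward-model simulator for high-density EEG recorded during fMRI.

Real recordings of this kind are contaminated — even after standard
template-based cleanup — by residual gradient artifact from the scanner
coils (a harmonic comb at multiples of the slice frequency, here
36 slices / 2-s TR = 18 Hz), cardioballistic pulses near 1 Hz, ocular
steps and blinks, edge-channel muscle activity, 50 Hz mains interference,
and the 1/f + alpha physiological background.  This module generates such
sessions with *known* mixing: each source family gets a canonical scalp
topography built from the sensor geometry and a family-specific waveform,
and the recording is X = A @ S plus optional white sensor noise.  The
returned :class:`~icmap.containers.GroundTruth` makes every downstream
stage of the pipeline checkable against the truth.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial import Delaunay

from .containers import (
    SOURCE_FAMILIES,
    FloatArray,
    GroundTruth,
    Recording,
    SensorLayout,
    SourceSpec,
)

# Default session-level amplitudes in microvolts (residual level, i.e. after
# the template-based gradient/cardioballistic cleanup such data receives).
DEFAULT_AMPLITUDES = {
    "eog_vertical": 30.0,
    "eog_horizontal": 25.0,
    "blink": 40.0,
    "emg": 15.0,
    "ecg": 10.0,
    "gradient": 8.0,
    "line_noise": 6.0,
    "alpha": 12.0,
    "pink_background": 10.0,
}


# ---------------------------------------------------------------------------
# Sensor layout
# ---------------------------------------------------------------------------

def make_layout(n_channels: int, seed: int = 0) -> SensorLayout:
    """Quasi-uniform sensor positions on the unit disk with a neighbor graph.

    Positions follow a golden-angle sunflower spiral (deterministic) with a
    small seeded jitter; adjacency comes from a Delaunay triangulation, with
    a k-nearest (k=4) fallback for degenerate geometries.  Neighbor weights
    are inverse-distance, normalized to sum to one per channel.
    """
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    rng = np.random.default_rng(seed)
    idx = np.arange(1, n_channels + 1, dtype=float)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    r = 0.95 * np.sqrt((idx - 0.5) / n_channels)
    theta = golden * idx + rng.uniform(-0.02, 0.02, size=n_channels)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    pos += rng.normal(scale=0.005, size=pos.shape)
    # keep the jittered points inside the disk
    rad = np.linalg.norm(pos, axis=1)
    over = rad > 0.999
    pos[over] *= (0.999 / rad[over])[:, None]

    edges: set[tuple[int, int]] = set()
    try:
        tri = Delaunay(pos)
        for simplex in tri.simplices:
            for a in range(3):
                i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
                edges.add((min(i, j), max(i, j)))
    except Exception:  # degenerate geometry: fall back to symmetric k-NN
        pass
    if not edges:
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        for i in range(n_channels):
            for j in np.argsort(d[i])[:4]:
                edges.add((min(i, int(j)), max(i, int(j))))

    graph: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_channels)}
    for i, j in sorted(edges):
        dist = float(np.linalg.norm(pos[i] - pos[j]))
        w = 1.0 / max(dist, 1e-6)
        graph[i].append((j, w))
        graph[j].append((i, w))
    for i in range(n_channels):
        total = sum(w for _, w in graph[i])
        graph[i] = [(j, w / total) for j, w in sorted(graph[i])]

    layout = SensorLayout(positions=pos, neighbor_graph=graph)
    layout.validate()
    return layout


# ---------------------------------------------------------------------------
# Topographies
# ---------------------------------------------------------------------------

def _gauss2d(pos: FloatArray, center: tuple[float, float], width: float) -> FloatArray:
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))


def _family_topography(family: str, layout: SensorLayout,
                       rng: np.random.Generator) -> FloatArray:
    """Canonical spatial pattern of a source family on this layout.

    +y is anterior.  Vertical EOG and blinks load frontally; horizontal EOG
    is a left-right frontal dipole; EMG concentrates in edge-channel patches;
    the cardioballistic pattern is a smooth front-to-back ramp; mains pickup
    is near-uniform; alpha is occipital.  The gradient-residue pattern is a
    broad antero-posterior dipole (a modeling choice — no published scalp
    map of the residue exists to copy).
    """
    pos = layout.positions
    x, y = pos[:, 0], pos[:, 1]
    r = np.linalg.norm(pos, axis=1)
    if family in ("eog_vertical", "blink"):
        w = _gauss2d(pos, (0.0, 1.0), 0.45 if family == "eog_vertical" else 0.35)
    elif family == "eog_horizontal":
        w = _gauss2d(pos, (0.6, 0.7), 0.35) - _gauss2d(pos, (-0.6, 0.7), 0.35)
    elif family == "emg":
        # two edge-concentrated patches at seeded rim angles
        angles = rng.uniform(0, 2 * np.pi, size=2)
        w = np.zeros_like(x)
        for a in angles:
            w += _gauss2d(pos, (0.9 * np.cos(a), 0.9 * np.sin(a)), 0.25)
        w *= r**2  # suppress any center leakage
    elif family == "ecg":
        w = 0.5 * (y + 1.0) + 0.15  # descending performance front to back
    elif family == "gradient":
        w = np.tanh(y / 0.4)
    elif family == "line_noise":
        w = np.ones_like(x) + rng.normal(scale=0.05, size=x.shape)
    elif family == "alpha":
        w = _gauss2d(pos, (0.0, -0.85), 0.45)
    elif family == "pink_background":
        # smooth low-order random field
        c = rng.normal(size=6)
        w = c[0] + c[1] * x + c[2] * y + c[3] * x * y + c[4] * (x**2 - 0.5) + c[5] * (y**2 - 0.5)
    else:
        raise ValueError(f"unknown source family {family!r}")
    w = np.asarray(w, dtype=float)
    rms = np.sqrt(np.mean(w**2))
    return w / max(rms, 1e-12)


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------

def _unit_rms(x: FloatArray) -> FloatArray:
    rms = np.sqrt(np.mean(x**2))
    return x / max(rms, 1e-12)


def _step_waveform(t: FloatArray, rate_hz: float, rng: np.random.Generator) -> FloatArray:
    """Random telegraph signal: rectangular steps at Poisson switch times."""
    n = t.size
    out = np.empty(n)
    level = rng.normal()
    i = 0
    fs = 1.0 / (t[1] - t[0])
    while i < n:
        hold = max(int(rng.exponential(1.0 / rate_hz) * fs), int(0.1 * fs))
        out[i:i + hold] = level
        level = rng.normal()
        i += hold
    return out


def _blink_waveform(t: FloatArray, rate_hz: float, rng: np.random.Generator) -> FloatArray:
    fs = 1.0 / (t[1] - t[0])
    n = t.size
    out = np.zeros(n)
    width = int(0.25 * fs)  # ~250 ms blink
    pulse = np.hanning(width)
    i = int(rng.exponential(1.0 / rate_hz) * fs)
    while i < n:
        j = min(i + width, n)
        out[i:j] += pulse[: j - i]
        i += max(int(rng.exponential(1.0 / rate_hz) * fs), width)
    return out


def _pulse_train(t: FloatArray, bpm: float, jitter: float,
                 rng: np.random.Generator) -> FloatArray:
    """Sharp biphasic cardioballistic pulse train with per-beat jitter."""
    fs = 1.0 / (t[1] - t[0])
    n = t.size
    out = np.zeros(n)
    period = 60.0 / bpm
    width = int(0.08 * fs)
    tt = np.linspace(-2.5, 2.5, width)
    pulse = -tt * np.exp(-tt**2)  # derivative-of-Gaussian wavelet
    pulse /= np.abs(pulse).max()
    pos = 0.0
    while True:
        i = int(round(pos * fs))
        if i >= n:
            break
        j = min(i + width, n)
        out[i:j] += pulse[: j - i]
        pos += period * (1.0 + rng.uniform(-jitter, jitter))
    return out


def _gradient_waveform(t: FloatArray, n_slices: int, tr_s: float, fs: float,
                       rng: np.random.Generator) -> FloatArray:
    """Band-limited periodic slice residue: damped harmonics of n_slices/TR."""
    f_slice = n_slices / tr_s
    f_max = min(0.45 * fs, 100.0 + f_slice)  # keep the comb below Nyquist
    waves = np.zeros_like(t)
    m = 1
    while m * f_slice <= f_max:
        phase = rng.uniform(0, 2 * np.pi)
        waves += np.exp(-0.12 * m) * np.cos(2 * np.pi * m * f_slice * t + phase)
        m += 1
    return waves


def _bandpassed_noise(t: FloatArray, lo: float, hi: float, fs: float,
                      rng: np.random.Generator) -> FloatArray:
    from scipy.signal import butter, filtfilt

    x = rng.normal(size=t.size)
    hi = min(hi, 0.49 * fs)
    b, a = butter(4, [lo / (fs / 2), hi / (fs / 2)], btype="band")
    return filtfilt(b, a, x)


def _burst_envelope(t: FloatArray, rate_hz: float, fs: float,
                    rng: np.random.Generator, floor: float = 0.15) -> FloatArray:
    """Smooth on/off envelope for bursty activity (EMG twitches, waxing alpha).

    The modulation makes the waveform super-Gaussian, as in real recordings —
    a stationary Gaussian source would be unidentifiable by ICA.
    """
    from scipy.ndimage import gaussian_filter1d

    gate = (_step_waveform(t, rate_hz, rng) > 0).astype(float)
    env = gaussian_filter1d(gate, sigma=0.2 * fs) + floor
    return env / env.max()


def _pink_noise(n: int, rng: np.random.Generator) -> FloatArray:
    spec = np.fft.rfft(rng.normal(size=n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    return np.fft.irfft(spec / np.sqrt(f), n=n)


def _family_waveform(spec: SourceSpec, t: FloatArray, fs: float,
                     rng: np.random.Generator) -> FloatArray:
    p = spec.waveform_params
    fam = spec.family
    if fam in ("eog_vertical", "eog_horizontal"):
        x = _step_waveform(t, p.get("step_rate_hz", 0.3), rng)
    elif fam == "blink":
        x = _blink_waveform(t, p.get("blink_rate_hz", 0.25), rng)
    elif fam == "emg":
        x = _bandpassed_noise(t, p.get("band_lo_hz", 20.0), p.get("band_hi_hz", 100.0), fs, rng)
        x *= _burst_envelope(t, p.get("burst_rate_hz", 0.5), fs, rng)
    elif fam == "ecg":
        x = _pulse_train(t, p.get("bpm", 60.0), p.get("beat_jitter", 0.05), rng)
    elif fam == "gradient":
        x = _gradient_waveform(t, p["n_slices"], p["tr_s"], fs, rng)
    elif fam == "line_noise":
        f0 = p.get("mains_hz", 50.0)
        am = 1.0 + 0.1 * np.sin(2 * np.pi * 0.1 * t + rng.uniform(0, 2 * np.pi))
        x = am * np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
    elif fam == "alpha":
        x = _bandpassed_noise(t, p.get("alpha_hz", 10.0) - 2.0, p.get("alpha_hz", 10.0) + 2.0, fs, rng)
        x *= _burst_envelope(t, p.get("wax_rate_hz", 0.4), fs, rng, floor=0.3)
    elif fam == "pink_background":
        x = _pink_noise(t.size, rng)
    else:
        raise ValueError(f"unknown source family {fam!r}")
    return _unit_rms(x) * spec.amplitude


# ---------------------------------------------------------------------------
# Source bank and simulation
# ---------------------------------------------------------------------------

def make_source_bank(layout: SensorLayout, families: list[str],
                     seed: int = 0) -> list[SourceSpec]:
    """One :class:`SourceSpec` per requested family, topographies from geometry.

    Family defaults: gradient 36 slices / 2-s TR (slice frequency 18 Hz),
    mains 50 Hz, heart rate 60 beats/min with 5% per-beat jitter,
    EMG band 20-100 Hz, alpha 10 Hz.
    """
    if not families:
        raise ValueError("families must be non-empty")
    for fam in families:
        if fam not in SOURCE_FAMILIES:
            raise ValueError(f"unknown source family {fam!r}")
    rng = np.random.default_rng(seed)
    bank = []
    for fam in families:
        params: dict = {}
        if fam == "gradient":
            params = {"n_slices": 36, "tr_s": 2.0}
        elif fam == "line_noise":
            params = {"mains_hz": 50.0}
        elif fam == "ecg":
            params = {"bpm": 60.0, "beat_jitter": 0.05}
        elif fam == "emg":
            params = {"band_lo_hz": 20.0, "band_hi_hz": 100.0}
        elif fam == "alpha":
            params = {"alpha_hz": 10.0}
        elif fam in ("eog_vertical", "eog_horizontal"):
            params = {"step_rate_hz": 0.3}
        elif fam == "blink":
            params = {"blink_rate_hz": 0.25}
        bank.append(SourceSpec(
            family=fam,
            topography=_family_topography(fam, layout, rng),
            waveform_params=params,
            amplitude=DEFAULT_AMPLITUDES[fam],
        ))
    return bank


def slice_frequency(spec: SourceSpec) -> float:
    """Slice frequency n_slices/TR of a gradient source, in Hz."""
    if spec.family != "gradient":
        raise ValueError("slice_frequency is defined for gradient sources only")
    return spec.waveform_params["n_slices"] / spec.waveform_params["tr_s"]


def _max_source_frequency(bank: list[SourceSpec]) -> float:
    f = 0.0
    for s in bank:
        p = s.waveform_params
        if s.family == "gradient":
            f = max(f, slice_frequency(s))
        elif s.family == "line_noise":
            f = max(f, p.get("mains_hz", 50.0))
        elif s.family == "emg":
            f = max(f, p.get("band_lo_hz", 20.0))
        elif s.family == "alpha":
            f = max(f, p.get("alpha_hz", 10.0))
    return f


def simulate_recording(bank: list[SourceSpec], layout: SensorLayout,
                       duration_s: float = 300.0, fs: float = 250.0,
                       sensor_noise_uv: float = 1.0,
                       seed: int = 0) -> tuple[Recording, GroundTruth]:
    """Mix the bank's sources through their topographies: X = A @ S + noise."""
    if duration_s < 2.0:
        raise ValueError("duration must be at least 2 s")
    if fs < 2.0 * _max_source_frequency(bank):
        raise ValueError("sampling rate below twice the highest source frequency")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    A = np.column_stack([s.topography for s in bank])
    S = np.vstack([_family_waveform(s, t, fs, rng) for s in bank])
    X = A @ S
    if sensor_noise_uv > 0:
        X = X + rng.normal(scale=sensor_noise_uv, size=X.shape)
    rec = Recording(data=X, fs=fs, layout=layout)
    truth = GroundTruth(mixing=A, sources=S, labels=[s.family for s in bank], seed=seed)
    return rec, truth


def session_seed(master_seed: int, session: int) -> int:
    """Deterministic per-session child seed derived from a master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(session,))
    return int(ss.generate_state(1)[0] % (2**31))


def jitter_amplitudes(bank: list[SourceSpec], seed: int,
                      spread: float = 0.3) -> list[SourceSpec]:
    """Log-normal amplitude jitter mimicking inter-subject variance."""
    rng = np.random.default_rng(seed)
    out = []
    for s in bank:
        out.append(SourceSpec(
            family=s.family,
            topography=s.topography,
            waveform_params=dict(s.waveform_params),
            amplitude=float(s.amplitude * np.exp(rng.normal(scale=spread))),
        ))
    return out


def simulate_session_batch(n_sessions: int, layout: SensorLayout,
                           families: list[str], seed: int = 0,
                           duration_s: float = 300.0, fs: float = 250.0,
                           sensor_noise_uv: float = 1.0,
                           ) -> list[tuple[Recording, GroundTruth]]:
    """Independent sessions sharing one source bank, amplitudes jittered."""
    if n_sessions < 1:
        raise ValueError("need at least one session")
    bank = make_source_bank(layout, families, seed=seed)
    out = []
    for i in range(n_sessions):
        child = session_seed(seed, i)
        jittered = jitter_amplitudes(bank, seed=child)
        out.append(simulate_recording(jittered, layout, duration_s=duration_s,
                                      fs=fs, sensor_noise_uv=sensor_noise_uv,
                                      seed=child))
    return out
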