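# Methods

## Signal model

A recording is modeled as an instantaneous linear mixture X = A·S of C
source time courses S through scalp topographies A (N channels × C), plus
white sensor noise. ICA estimates the inverse: Z = A⁻¹·X, where each row
W_c of the unmixing matrix is the spatial fingerprint (topomap) of one
independent component. The package's object of study is the set of all
topomap rows (and component spectra) pooled across many sessions; artifact
families recur across sessions with near-identical spatial patterns, so
they form dense groups that a nonlinear embedding plus density clustering
can expose without supervision.

## The synthetic hdEEG/fMRI generator

The simulator emulates EEG **after** template-based gradient and
cardioballistic cleanup, i.e. residual-level artifacts:

| family | topography (from layout geometry) | waveform |
|---|---|---|
| eog_vertical / blink | frontal Gaussian (+y pole) | random telegraph steps (0.3 Hz) / 250 ms Hanning pulses |
| eog_horizontal | left–right frontal dipole | telegraph steps |
| emg | rim-concentrated patches | 20–100 Hz noise under a burst envelope (0.5 Hz) |
| ecg | smooth front-to-back ramp | biphasic pulse train, 60 beats/min, ±5 % per-beat jitter |
| gradient | broad antero-posterior dipole | damped harmonics of n_slices/TR = 36/2 s = 18 Hz |
| line_noise | near-uniform | 50 Hz sine, slow amplitude modulation |
| alpha | occipital Gaussian | 8–12 Hz noise under a waxing/waning envelope |
| pink_background | smooth low-order random field | 1/f noise |

Waveforms are unit-RMS before scaling by the family amplitude (defaults
5–40 µV, residual scale); session batches jitter amplitudes log-normally
(σ = 0.3) to mimic inter-subject variance. Sensor positions follow a
golden-angle sunflower spiral on the unit disk with Delaunay adjacency and
inverse-distance neighbor weights.

Two modeling choices deserve emphasis. First, no published scalp map of
the gradient residue exists, so its antero-posterior dipole topography is
a convention, not a measured fact. Second, EMG and alpha carry burst
envelopes: beyond realism (muscle twitches, waxing alpha), a stationary
Gaussian source would be unidentifiable by ICA, and real EEG sources are
non-Gaussian precisely in this way. The simulator omits realistic head-model
(BEM/FEM) forward physics, raw full-amplitude gradient artifact, and
helium-pump/ventilation tones — passing tests therefore demonstrate that the
pipeline recovers *linearly mixed, spatially stable* artifact families, not
that it handles volume-conduction subtleties or nonstationary topographies.

## Preprocessing

* Bandpass: Hamming-windowed sinc FIR, default band 0.5–100 Hz, order
  3·fs/f_low taps, applied forward–backward (zero phase).
* Downsampling: polyphase anti-aliased resampling (default 1 kHz → 250 Hz).
* Tukey rejection: per-channel window variances (1-s windows); windows above
  Q3 + 1.5·IQR of that channel's variance population are replaced by the
  inverse-distance-weighted average of unflagged neighbors. Fences are
  per-channel (a pooled variant would weight high-variance channels
  unequally); if every channel in a window is flagged it is left unchanged
  with a warning.
* Segment selection: the record is split into n equal sections and one
  segment is drawn uniformly per section (defaults 150 × 2 s = 5 min).

## Decomposition

Extended Infomax (natural-gradient, kurtosis-switched) runs on PCA-whitened
data reduced to C dimensions; the implementation is mne's, with the
whitening, channel-space composition, pseudo-inverse mixing and seeding
handled here. C is a fixed parameter (default 35). Rows are RMS-normalized,
and a deterministic sign convention (largest-magnitude entry positive) is
applied before pooling: ICA's sign indeterminacy would otherwise split each
family into a pair of antipodal, inverse-shaped topomap clusters. The
convention is exposed (`orient_signs=False`) for studying that effect.

Spectra use segment-averaged DPSS multitapers: 2-s blocks, half-bandwidth
2 Hz (NW = 4, 7 tapers), eigenspectra averaged over tapers and blocks and
interpolated onto the 0–100 Hz / 1 Hz grid (101 bins); stored in dB. The
PCA reduction (default 45 columns) centers columns and uses an SVD with a
largest-|loading|-positive sign convention. PCA is applied to topomaps
only; spectra go to the embedding un-reduced (101 columns is already small).

## Embedding

Exact O(n²) t-SNE. Bandwidths are calibrated by bisection on the precision
until the realized perplexity matches the target within 1e-4 relative
(≤ 64 iterations); duplicate points get tie-breaking jitter with a warning.
Optimization: seeded Gaussian init (σ = 1e-4; PCA init available), early
exaggeration ×12 for 250 iterations, momentum 0.5 → 0.8 at iteration 250,
adaptive gains, 1000 iterations default. The learning rate defaults to
max(n/12, 50): the classical fixed η = 200 over-expands maps with tens of
points while matching the usual regime near n ≈ 2000. KL(P‖Q) against the
unexaggerated P is recorded every iteration.

## Clustering

DBSCAN (self-inclusive neighborhood counts; border points join the first
discovered core's cluster; label −1 is noise). Eps comes from the knee —
the maximum distance-to-chord point — of the descending sorted k-dist curve
(k = 20 by default; k = 4 is used at desk scale where clusters have ~6
members). For maps too small for knee detection (< 10 points) the median
k-dist is used. The default Eps = 7 applies to the full-scale reduced
topomap space; any radius can be supplied explicitly.

## Criteria

RMS energy is implemented as a true root-mean-square; a mean-square variant
(no root) is available behind `mean_square=True` for compatibility with
conventions that report the squared form. Autocorrelation is the literal
lagged-product sum Σ x(t)·x(t−l) with l = round(lag_ms·fs/1000) (20 ms
default); `normalized=True` divides by the zero-lag sum. Focal topography
and focal trial activity are maximum Z-scores (sample SD, n−1) over raw
channel weights and over per-segment peak-to-peak ranges respectively;
zero-variance inputs score 0. A squared-weight variant of focal topography
exists for scoring energy rather than signed weights. On the map export,
log10 is applied to focal topography and autocorrelation (offset-guarded
for non-positives).

## Cluster reports

Per cluster: element-wise mean/median/variance topomaps, mean spectrum
(dB), member list, and a harmonic report. Peaks are local maxima at least
6 dB above the local median background (11-bin window); the spacing
estimate is the median of consecutive peak differences. Narrowband
fingerprints (gradient comb, mains) are assessed on the unfiltered
spectrum; a 5-bin median filter is available for smoothing broadband
shapes. Variance topomaps are emitted for completeness but carry no
quantitative contract beyond non-negativity.

## Problem sizes and validation

Desk-scale defaults used throughout the test suite: 16–24 channels, 6
sessions × 60 s, 7 components per session — enough for every family to
appear once per session while keeping an ICA run at a few seconds.
End-to-end validation matches each component to the simulated source whose
true topography its estimated mixing column best resembles (absolute
Pearson correlation); a component is *artifact-dominated* when that
correlation exceeds 0.95, i.e. its spatial pattern is essentially one
source's. On those components the adjusted Rand index between DBSCAN
clusters and true families is required to reach 0.7; mixed components have
no single true family and are excluded from the score. Full-scale
bookkeeping (54 × 35 × 256 → 1890×256, PCA → 45) is exercised on synthetic
unmixing matrices, where the stacking and reduction — not ICA — are under
test.

## Known limitations

* The simulator's spatial patterns are deterministic given the layout;
  real inter-subject topographic variability (electrode placement, anatomy)
  is only approximated by amplitude jitter.
* Gradient-residue topography is a convention (see above).
* Exact t-SNE is O(n²) per iteration; fine to a few thousand rows, not for
  orders of magnitude more.
* ICA model order is fixed, not estimated; components beyond the number of
  strong sources absorb background noise.
* EDF export is not provided; simulated sessions are written as delimited
  matrices with a layout JSON sidecar (EDF/BrainVision reading is
  supported via mne).
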