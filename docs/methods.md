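# Methods

This note documents the models and procedures implemented in `earseiz`,
the parameter choices that matter, and what the synthetic cohort can and
cannot demonstrate.

## Signal model and montages

Recordings are referential: each electrode trace is a potential in µV
against a common reference (Fpz), sampled at 250 Hz. All analysis operates
on bipolar derivations — anode minus cathode — so any common-reference
contribution cancels. Two montages are defined: the 22-channel clinical
longitudinal montage (10–20 electrodes plus sphenoidal Sph1/Sph2) and the
4-channel behind-the-ear montage (cross-head LC-RC and LT-RT; unilateral
LT-LC and RT-RC). Time is measured in seconds from recording start with
half-open windows `[t0, t1)`; sample *k* of a window maps to
`floor(t·fs)`, which keeps slicing exact.

Sphenoidal electrodes are ordinary labeled electrodes here; they only ever
appear as montage members. Behind-the-ear electrodes are assumed to share
the clinical amplifier's reference, so ear channels are plain differences
of referential traces.

EDF files are written by a built-in encoder (16-bit samples, 1 s data
records, per-channel symmetric physical range) and read back through MNE,
so every file this package writes is validated by an independent EDF
implementation; round-trip error is bounded by the declared quantization
step. Partial trailing seconds are zero-padded to a whole record, as EDF
has no partial records.

## Preprocessing

**BSS-CCA muscle-artifact removal.** Within non-overlapping 10 s windows,
the multichannel signal is decomposed into sources that are maximally
correlated with their one-sample-delayed copy (canonical correlation
analysis between `X[:, :-1]` and `X[:, 1:]`). The canonical correlation of
a source equals its lag-one autocorrelation; ongoing EEG rhythms score
near 1 (a 10 Hz rhythm at 250 Hz has lag-1 autocorrelation ≈ 0.97) while
broadband muscle activity scores near 0. Sources below the threshold
(default 0.30) are zeroed and the window is reconstructed. The
decomposition is computed in the numerically non-null principal subspace
(eigenvalues above `1e-9` of the maximum), so mixtures of fewer sources
than channels are handled exactly; a window with fewer than two non-null
dimensions is passed through unchanged with a warning. Because the
canonical directions are orthonormal in the whitened space, zeroing
sources can only reduce the (mean-removed) signal power. Scalp and ear
channels are denoised jointly (all 26 derived channels in one
decomposition); this is configurable.

**Band-pass.** 4th-order Butterworth, 0.5–35 Hz, applied
forward–backward (`sosfiltfilt`) for zero phase, preserving waveform
morphology. The band retains the delta–beta range the features use and
removes drift and most residual EMG.

**Epoching.** One fixed-length epoch per seizure, with onset anchored at
50% of the epoch (clipped, not padded, at recording edges; the anchor
seizure is listed first in the epoch's annotations). Seizure-free epochs
are sampled uniformly over admissible start times, disjoint and at least a
guard interval away from every seizure, deterministically per seed. At
clinical scale epochs are 1 h with a 1800 s guard; the synthetic benchmark
uses 10-minute seizure epochs, 5-minute non-seizure epochs and a 60 s
guard (see "Problem sizes" below).

## Blink-EOG quantification

FastICA decomposes the scalp montage into unit-variance sources. The blink
source is selected automatically as the component with maximal absolute
correlation with the frontopolar channel (Fp2-F8), sign-aligned so blinks
deflect positively, and rescaled to µV by its least-squares projection
onto that channel (for an exact decomposition this equals the mixing
weight). A correlation below 0.2 flags the selection low-confidence; a
manual component index can override the automatic choice. Blink peaks are
local maxima of the scaled source between 30 and 80 µV with a 0.25 s
refractory interval (physiological blink separation). Per channel, epochs
from 0.2 s before to 0.2 s after each peak are averaged (edge-truncated
epochs dropped), and the channel's *EOG amplitude* is the mean of the
averaged waveform over ±0.1 s around the peak. Amplitudes are compared
across channels with a two-sided Wilcoxon signed-rank test, exact null for
n ≤ 25, zero differences dropped before ranking.

Note that ICA sources are mean-centered, so the 30–80 µV detection range
applies to deflections above the component's baseline. FastICA frequently
fails its formal convergence test on EEG whose background is close to
Gaussian — near-Gaussian sources are not identifiable — while still
isolating the strongly super-Gaussian blink source; the decomposition
therefore retries from three deterministic starts and can be run in a
non-strict mode that keeps the final unmixing with a warning.

## Spectral similarity

Power spectral densities and cross-spectra use Welch averaging with 2 s
Hann segments and 50% overlap (0.5 Hz resolution, ≥ 3 bins per 1 Hz
feature band). Magnitude-squared coherence
`Cxy = |Gxy|²/(Gxx·Gyy)` is averaged over 2–20 Hz (closed band); a
single-segment estimate is identically 1 and is rejected, and fewer than
8 segments draws a bias warning (the coherence bias is roughly
1/segments). For each ear channel, band-mean coherence is computed per
seizure over the annotated ictal interval and averaged across seizures;
the scalp channel with the highest average is the best matchup, ties
resolving to montage order. Report tables use the sample SD (n−1) and
half-up rounding to two decimals.

## Detection

Features per 2 s window and channel: fifteen mean PSD values over the
bands 1–2, 1.5–2.5, …, 7–8, 8–14, 14–20 Hz plus the peak frequency in
1–20 Hz, from a single Hann-tapered periodogram (Welch sub-averaging
inside a 2 s window would leave fewer than 3 bins per band). Band
membership is by bin-center inclusion on closed intervals. "Mean power"
is the mean of PSD bins, not the band integral; an all-zero window
reports zero band powers and 0 Hz peak frequency. Per-channel blocks are
concatenated channel-major: 16·m features (352 for the scalp montage, 64
for the ear montage).

Training follows leave-one-seizure-out: positives are the three
non-overlapping 2 s windows in the first 6 s after onset of every
non-withheld seizure; negatives are all windows of all seizure-free
epochs; the withheld seizure epoch is the test set. Features are z-scored
on training statistics (an RBF kernel needs comparable scales). The SVM
uses `K(x,y) = exp(−‖x−y‖²/2σ²)`; `c` and `σ` are selected by stratified
inner cross-validation (5 folds, reduced to the minority-class count when
positives are fewer) over 7 log-spaced values per axis in [10⁻³, 10³],
minimizing the balanced error rate — with hundreds of negatives per
positive the raw error rate would always prefer the all-negative
classifier — with ties resolved toward smaller `c`, then smaller `σ`.
Class weights are inversely proportional to class frequency for the same
reason. The grid search reuses one pairwise squared-distance matrix
across the σ grid (the kernel is re-exponentiated per σ and folds index
into it), which is algebraically identical to refitting an RBF SVC per
grid point; the selected pair is refit as a plain RBF SVC on all training
data.

Runs of at least 2 consecutive positive windows (≥ 4 s) are declared
events; events closer than 30 s merge. A seizure counts as detected if
any event overlaps its annotation; every non-overlapping event is one
false detection. Sensitivity is detected/total seizures per patient; the
false-detection rate divides total false detections by the hours of
tested seizure epochs (not total recording time). Patients with a single
seizure cannot be evaluated strictly out-of-sample: their one seizure's
onset windows enter training and the same epoch is tested; such reports
carry a `single_seizure_protocol` flag. Montage comparisons
(scalp vs ear, and each ear channel alone with unilateral channels
relabeled ipsi-/contralateral to the patient's focus) use paired
two-sided signed-rank tests across patients.

## Synthetic cohort

The generator produces referential EEG with the statistical structure the
pipeline assumes, on a schematic 2-D head layout (unit head radius,
mirror-symmetric about the midline):

* **Background**: ten latent 1/f^β sources (β = 1.2) at fixed scalp
  locations projected through Gaussian distance gains (decay 0.45 head
  radii), 12 µV RMS per electrode, plus 15% independent sensor noise and
  an 8–12 Hz source near the occiput (8 µV at O1/O2). The fairly local
  patches make neighboring *bipolar* channels share broadband activity,
  as volume conduction does on real scalp.
* **Blinks**: raised-cosine bumps (300 ms, default 60 µV at the
  frontopolar electrodes, Poisson 12/min, ≥ 0.5 s apart, 5% amplitude
  jitter) projected through a fixed topography table. The table is
  mirror-symmetric — so with zero left–right asymmetry the cross-head ear
  channels cancel exactly — and decreases from front to back, with the
  upper-ear gain (0.10) deliberately above the ear-center gain (0.02) so
  the unilateral ear channels retain the faint averaged blink residual
  (a few µV against ~60 µV frontally) seen clinically. A single smooth
  distance kernel cannot produce both the near-total frontal dominance
  and that measurable unilateral residual, hence the table.
* **Ictal discharges**: amplitude-modulated rhythm at 3–5 Hz with a weak
  second harmonic, ramping over the first tenth of the event, 70 µV at
  the focus electrode, spatial Gaussian decay 0.5 head radii from a
  focus placed by lobe and side — so ipsilateral channels always exceed
  contralateral ones.
* **EMG bursts**: 20–45 Hz noise bursts (2 s, 25 µV, Hann-tapered) on
  temporal and peri-auricular electrodes.
* **Electrode faults**: a high-amplitude rhythmic or step artifact on one
  electrode, producing the clinical phase-reversal signature between the
  two derived channels that share it.

All injectors are additive and draw from sub-seeds derived from the
master seed with fixed per-injector tags, so they commute and every event
list is reproducible. The generator does **not** model biophysical head
volume conduction, sleep architecture, cardiac artifacts, inter-seizure
variability of the ictal pattern, or spectral overlap between seizures
and movement artifacts. Passing the detection benchmark therefore shows
the pipeline is correct and well-calibrated under its own assumptions —
near-perfect separability at high ictal SNR is expected by construction —
not that the same sensitivity would be reached on hospital recordings,
where artifacts and ictal variability dominate the error budget.

## Problem sizes

The benchmark cohort has 12 pseudo-patients with seizure counts
[1, 3, 3, 1, 2, 2, 3, 3, 2, 1, 3, 3] (the clinical cohort's counts capped
at three), 10-minute seizure epochs, and two 5-minute seizure-free epochs
per patient. These sizes keep a complete leave-one-seizure-out run over
six montage variants (scalp, ear, four single ear channels) to a few
minutes on one CPU while preserving every structural property of the
full-scale protocol, including single-seizure patients.

## Numerical choices and degenerate inputs

* Welch/periodogram tapers are periodic Hann windows with constant
  detrending per segment.
* CCA whitening keeps eigenvalues above `1e-9` of the maximum; SVD of the
  whitened cross-covariance gives canonical correlations clipped to
  [0, 1].
* Identical-pair coherence equals 1 to ~1e-16; the estimator is invariant
  under per-channel scaling and symmetric in its arguments (tested
  against a direct-DFT oracle to < 1e-8).
* The signed-rank test drops zero differences; all-zero differences give
  p = 1.
* Single-patient coherence columns report SD 0 with an explicit
  `sd_defined=False` flag.
* All report rounding is decimal half-up.

## Known limitations

* The event-declaration rule (2 consecutive windows, 30 s merge) is a
  package choice; clinical deployments would tune it, and both knobs are
  exposed in `SvmConfig`.
* The blink topography and ictal gain profiles are stylized surrogates;
  absolute synthetic amplitudes are free parameters, so only relative
  and recovery properties are asserted.
* FastICA identifiability is limited on near-Gaussian backgrounds (see
  above); blink selection is robust but other components are not
  interpretable.
* The single-seizure evaluation protocol is optimistic by construction
  and flagged in every report that uses it.
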