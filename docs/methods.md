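# Methods

This note records the models, conventions and numerical choices behind
`thetaloco`, including every place where a published procedure left a
detail open and this package had to fix one.

## Spectral analysis and the entrainment-fidelity statistic

Per-epoch PSDs use the multitaper method: K = 2·NW − 1 = 5 unit-energy
Slepian tapers with time-halfbandwidth NW = 3 on 8,192-sample windows of
the 1,250 Hz LFP (≈ 6.55 s), one-sided scaling such that the trapezoidal
integral of the PSD approximates the signal variance. A 10-s epoch holds
two half-overlapping windows; the per-epoch PSD is their mean. The 50%
overlap is this package's choice — window and epoch lengths are fixed by
the protocol, the overlap is not.

Entrainment fidelity is the ratio of the cumulative PSD within ±0.5 Hz of
the stimulation frequency to the cumulative PSD over 5–12 Hz. Band
integrals are trapezoidal with the integrand linearly interpolated at the
band edges, so a flat spectrum yields exactly the band-width ratio
(1 Hz / 7 Hz = 1/7) regardless of grid alignment. The numerator is clipped
to [5, 12] Hz so the statistic can never exceed 1; consequently fidelity at
a band-edge stimulation frequency (e.g. 12 Hz) integrates a half-width
numerator. Stimulation frequencies are accepted in [5, 12] Hz; the
protocol's non-theta frequencies (2, 4, 20 Hz) are generated and delivered
but fidelity is not defined for them.

The theta/delta power ratio uses theta = 5–10 Hz (matching the Hilbert
filtering band) and delta = 1–4 Hz. The delta band is nowhere specified in
the source procedures; 1–4 Hz is this package's definition. A flat spectrum
therefore gives ratio 5/3. Zero delta power returns +inf, which passes the
≥ 6 gate.

Epoch gating: consecutive non-overlapping 10-s epochs; dominant frequency
is the PSD argmax over 1–20 Hz. Hard exclusions (`included = False`) are a
dominant peak ≤ 5 Hz, and — for epochs actually carrying theta-band
pulses — fidelity < 0.3. A theta/delta ratio < 6 does not exclude the
epoch; it only removes it from phase–amplitude-coupling analysis
(`pac_eligible = False`). Every fired rule is recorded as a
machine-readable reason string. When a session-level stimulation frequency
is known, fidelity is also computed for unstimulated epochs against that
reference (the natural analogue for control recordings); the 0.3 gate
never applies to them, nor to control-light epochs, whose light cannot
entrain.

Two-site coherence is magnitude-squared coherence from multitaper auto-
and cross-spectra averaged over tapers and half-overlapping windows of the
whole recording.

## Theta cycles and phase

Cycles are detected on the 5–15 Hz zero-phase (4th-order Butterworth,
`sosfiltfilt`) band-passed signal: alternating local maxima and minima are
paired into peak → trough → next-peak triplets; cycles whose peak-to-peak
interval implies a frequency outside 4–14 Hz are rejected. The 5–15 Hz
detection band is wide enough for 12 Hz entrainment while suppressing
double peaks. Cycle amplitude is the band-passed value at the peak (not
peak-to-trough). If the 5–15 Hz band holds less than 0.25% of the signal
variance, detection returns an empty table rather than chasing filter
ripple. Filter transients can distort the outermost cycle at each edge of
a recording; analyses that need exact amplitudes should ignore the first
and last cycles.

Phase convention: peak = 0°, trough = 180°, for both definitions, applied
identically to spikes, laser pulses and gamma peaks. Interpolated phase
ramps linearly 0°→180° peak→trough and 180°→360° trough→next peak, and is
undefined (NaN) outside detected cycles. Hilbert phase is the analytic
angle of the 5–10 Hz band-passed signal (a cosine's maxima sit at angle 0,
so no shift is needed). The two coincide on symmetric stationary waves and
diverge mid-cycle on asymmetric waves — both behaviours are tested.

## Theta–gamma phase–amplitude coupling

Gamma events are local maxima of the 35–85 Hz band-passed signal with
positive amplitude. Each gamma peak carries its Hilbert theta phase and
the amplitude of the concurrent theta cycle (the cycle whose peak most
recently precedes it). Cycle amplitudes are z-scored within each eligible
epoch before pooling — this is the package's reading of "standardized"
amplitude binning, whose exact recipe the source literature delegates to a
reference that does not state it. Gamma peaks are binned into 5 quantile
bins of standardized theta amplitude and 18 phase bins of 20°; a bin needs
at least 50 gamma peaks, otherwise its coefficient is NaN and flagged. The
modulation coefficient is (max − min)/(max + min) of the phase-binned mean
gamma-peak amplitude: scale-invariant, 0 for a constant profile (clamped
exactly to 0 below 1e-12 to absorb float residue), and approximately equal
to the generator's coupling depth c for an envelope 1 + c·cos φ. Null
calibration uses phase-permutation shuffles (re-pairing amplitudes with
phases), which preserve both marginals and destroy coupling.

## Circular statistics

Resultant length and mean phase are the first trigonometric moment. The
Rayleigh p-value uses Zar's small-sample-corrected formula
p = exp(√(1 + 4n + 4(n² − Rn²)) − (1 + 2n)). Watson–Williams uses the
standard F approximation with the (1 + 3/8κ) correction, κ estimated from
the pooled resultant by Fisher's inverse; a pooled resultant below 0.45
attaches a validity warning. The two-sample Watson U² is computed from
cumulative-fraction differences on the pooled sorted sample; its p-value
is the label-permutation exceedance (1 + #{U²perm ≥ U²obs})/(n_perm + 1).
All three reproduce their nominal null behaviour in the test suite
(type-I error 0.05 ± 0.01 at n = 100 over 5,000 replicates; KS-uniform
null p distributions). An independent implementation (pingouin) serves as
the oracle for the descriptive statistics and the Rayleigh test.

## Pairwise cycle-amplitude / spike-count regression

Each spike is assigned the concurrent theta cycle and kept only if its
phase lies within ±30° of the peak (0°) or trough (180°). A neuron with
fewer than 10 spikes in either phase bin is excluded, with its bin counts
reported. For all cycle pairs (i, j) and each bin type, S = S_i − S_j and
A = A_i − A_j; the regression slope of S on A over all pairs is computed
through the algebraic identity with the within-bin-centered cycle-level
regression (all-pairs OLS of differences equals centered OLS on the
originals), which is O(n) and exact. Because pairwise differences are
heavily dependent, a t-test at pair-level degrees of freedom would be
drastically anticonservative; the slope p-value therefore uses cycle-level
degrees of freedom (n_cycles − 2 per pooled bin set), which simulation
shows is correctly calibrated (≈ 5% null rejections at α = 0.05). The
A-binned mean-S summary profile is built from an explicit pair
enumeration, uniformly subsampled to at most 10⁶ pairs with a fixed-seed
generator when sessions exceed that count.

Unit classification: putative pyramidal cells need a mean rate strictly
below 3.5 Hz and an autocorrelogram burst index (spike pairs at 2–10 ms
lags over pairs at 40–50 ms lags) above 1.5 — the burst-index form and
threshold are this package's operationalization of "identified by their
autocorrelograms". Fast-firing interneurons are units at ≥ 10 Hz. Units
with under 50 spikes stay unclassified.

## Firing maps

Rate maps live on a 2 × 2 cm grid over the 48 × 30 cm arena. Tracking
samples with speed ≤ 2 cm/s, and spikes emitted during them, are excluded.
Spatial coherence is the Fisher z-transform of the Pearson correlation
between each visited pixel's rate and the mean rate of its visited
8-neighbours. Sparsity is the Skaggs form (Σ pᵢ rᵢ)² / Σ pᵢ rᵢ², pᵢ the
occupancy probability: 1 for uniform firing, 1/N for firing confined to
one of N equally occupied pixels.

## Locomotion

Instantaneous speed: per-frame velocity components from 25 Hz tracking,
zero-phase low-pass filtered (4th-order Butterworth, 2 Hz) *before* taking
the Euclidean magnitude. Filtering the components rather than the
rectified magnitude matters: rhythmic head swings (5–12 Hz) average out in
the components, whereas rectification would fold their power into DC. The
2 Hz cutoff is the package's choice — it removes head-swing artefacts
while preserving second-scale locomotor dynamics. Running is speed >
2 cm/s; per-epoch metrics (mean speed, CV, fraction running, longest bout,
path length) use running samples only.

Run-initiation contingency: an onset is analyzable only if the preceding
20 s contain less than 10% running samples; it counts as "Run" when speed
exceeds 2 cm/s continuously for at least 1 s within 15 s after onset. The
1-s sustain criterion operationalizes "moved", which the source leaves
undefined. The 2 × 2 χ² uses df = 1 without continuity correction; an
expected cell below 5 attaches a warning.

Frequency–speed correlation per condition uses each epoch's mean
detected-cycle frequency rather than the PSD argmax: the PSD grid is
quantized at ≈ 0.15 Hz, which collapses to zero variance (undefined r)
when stimulation pins the rhythm, while the cycle-based estimate retains
natural jitter. Amplitude-variability profiles bin included epochs by
theta-amplitude CV into fixed-width bins (range/8 by default); bins with
fewer than 3 epochs are dropped, at least 3 bins are required, and bin
means are fitted with a degree-2 polynomial (R² reported).

## Synthetic sessions

The generator produces the statistical structure the analyses assume —
not a biophysical model. The theta component is cos φ(t) · A(t) with a
cycle-stepped clock: per cycle, frequency is an AR(1) process (lag-1
correlation 0.7) around the centre frequency with CV `freq_cv`, and the
envelope a log-normal AR(1) with CV `amp_cv`, interpolated linearly
between peaks so the value at each peak is the cycle's amplitude exactly.
Entrainment blends the clock, not the waveform: the stochastic next-peak
time is pulled toward the nearest point of the laser phase ramp with
weight `entrain_gain` (gain 1 ⇒ peaks exactly on the pulse grid), and the
envelope contracts toward its mean by the same factor, so fidelity rises
and amplitude CV falls monotonically with gain. Gamma is 35–85 Hz
band-limited noise with envelope 1 + `gamma_coupling`·cos φ at 15% of the
theta amplitude; broadband Gaussian noise (sd 0.05 V) is added last.

Sessions alternate 60-s blocks of spontaneous, entrained and
control-light condition (30-ms pulses at `stim_freq_hz` in the latter
two; control light never entrains). An epoch-level log-AR(1) (lag-1 0.5,
log-sd 0.4) modulates the amplitude CV around `amp_cv`, shrunk by
(1 − gain) in entrained epochs; the per-epoch target mean speed and speed
CV both rise with that epoch's amplitude CV through `speed_amp_cv_gain`
(centred on the session mean so the average speed stays at
`speed_base_cm_s` = 8 cm/s, CV floor `speed_cv_base` = 0.15); and the
spontaneous-theta centre frequency follows the epoch's target speed
through `freq_speed_gain` = 0.3, reproducing the frequency–speed
correlation of free theta while entrained epochs carry none.

Spikes: per cycle, counts are Poisson with mean (base_rate / f_cycle) ·
(1 + `amp_rate_slope` · ã), ã the mean-normalized cycle amplitude
(negative means clamped at 0 and logged); phases are von Mises about a
preferred phase with concentration `spike_kappa` (κ = 0 uniform, κ = ∞
degenerate), mapped to times by the peak→trough→peak linear convention.
An optional burst probability appends a 4–8 ms companion spike, giving
pyramidal-like autocorrelograms; the default session has four such
bursty low-rate units and two fast-firing units. Locomotion is a
reflective random walk at 25 Hz in the 48 × 30 cm arena: log-normal AR(1)
speed magnitude (lag-1 0.97, chosen so the 2 Hz speed filter passes the
generated variability nearly unattenuated) and a heading random walk
(0.12 rad/frame, slow enough that component filtering does not shorten
the path appreciably).

All randomness flows from one `numpy.random.SeedSequence`, spawned into
separate generators for epoch structure, LFP, spikes and tracking, so a
fixed config is reproducible bit-for-bit, and files written twice have
identical checksums.

What the generator does *not* emulate: waveform asymmetry of real theta,
non-stationary behavioural states (immobility, grooming), theta harmonics,
spike sorting artefacts, measurement noise in tracking, and volume
conduction between sites. Passing tests therefore validate the estimators
against the assumed generative structure, not against every property of
in-vivo recordings; statistics of real recordings (specific correlation
magnitudes, cell counts) are outside what synthetic sessions can certify.

## Problem sizes used in tests and the acceptance script

Closed-form checks run on 10–20 s constructed signals. Generator
calibrations average 5–6 seeds of 300-s traces. The pairwise-regression
recovery simulation uses 100 sessions of 900 s (≈ 7,200 cycles each) with
base rate 3 Hz, κ = 1 and slope 0.5 — sized by a power calculation to
give ≈ 95%+ detection — and the null calibration 500 spike-train draws
over five 300-s sessions. The end-to-end contrast uses two 1,200-s
sessions (full pipeline) plus fifty 360-s sessions for the binned
amplitude-CV → speed-CV profile. The full test suite runs in about two
minutes on one CPU; the acceptance script in about two minutes.

## Known limitations

* The fidelity numerator at band-edge stimulation frequencies is
  asymmetric (clipped to [5, 12] Hz); comparing fidelities across
  stimulation frequencies near the edges is biased low by construction.
* The pairwise-regression p-value treats the two phase-bin series of the
  same cycles as independent blocks; the residual dependence between peak
  and trough counts of one cycle is ignored (simulation shows the net
  calibration is nonetheless accurate).
* Watson–Williams is unreliable for diffuse samples (warning below pooled
  resultant 0.45); use the U² permutation test there.
* The run-initiation contingency is implemented and tested on constructed
  speed traces; default synthetic sessions contain no immobility periods,
  so the session report does not include it.
* `spatial_coherence_z` loops over pixels in Python; fine for the 24 × 15
  arena grid, not meant for high-resolution maps.
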