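# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `pacpipe`. It is written for someone who wants to understand
or audit what the code computes, not how to call it (see the README for
that).

## The coupling statistic

Phase–amplitude coupling (PAC) is quantified with the Kullback–Leibler
modulation index. For one channel and one (low-frequency, high-frequency)
pair, each 2-s segment yields a low-frequency phase series LFϕ(t) and a
high-frequency amplitude series HF_amp(t). Phases are binned into N = 18
intervals of 20° spanning [−180°, 180°); the mean amplitude per bin is
averaged across the recording's 30 segments, normalized to a probability
vector P, and scored as

    MI = (log N − H(P)) / log N,   H(P) = −Σ P(b) log P(b),

with the convention 0·log 0 = 0. MI is 0 iff P is uniform (no coupling) and
1 when all amplitude concentrates in a single phase bin; it is invariant to
amplitude rescaling.

Raw MI is biased by spectral power, noise level, and data length, so it is
normalized against a time-shift surrogate null: each segment's amplitude
series is circularly shifted by an independent uniform draw of 0.1–1.9 s
(25–475 samples at 250 Hz), and the binning → averaging → MI chain is
repeated; 200 such surrogate MI values give μ(MI_surr) and SD(MI_surr), and

    MI_norm = (MI_raw − μ(MI_surr)) / SD(MI_surr)

(sample SD, n−1; at n = 200 the population/sample distinction is
negligible). The circular shift preserves each segment's amplitude marginal
and autocorrelation while destroying its alignment with phase.

**Phase max** is the center of the phase bin holding the largest mean
amplitude ({−170°, −150°, …, 170°}); ties break toward the smallest bin
center and set an explicit flag. Phase-max values aggregate across
recordings by the circular mean (argument of the mean unit vector); a mean
resultant length below 10⁻⁹ (antipodally balanced input) raises an error
rather than returning an arbitrary direction.

## Filter bank

Phase and amplitude are extracted with a complex zero-phase FIR filter
pair: a cosine-carrier kernel (even → zero phase) and a sine-carrier kernel
(odd → exact 90° shift), under a common Blackman window, applied by
symmetric convolution with reflection padding. The window duration is
1.65/bandwidth seconds (207 taps at 250 Hz for the 2-Hz-wide low-frequency
bands, 21 taps for the 20-Hz-wide high-frequency bands). The kernel is
normalized to unit amplitude gain for an in-band cosine, so the complex
output's modulus is instantaneous amplitude and its argument is
instantaneous phase, 0° at the waveform peak and increasing with time.

The default grid is 10 low-frequency centers (2–20 Hz, 2-Hz steps) × 16
high-frequency centers (40–100 Hz, 4-Hz steps). A pair is analyzable only
if the two filters' magnitude-response supports — the band where the
response is ≥ 5% of peak (−26 dB), evaluated on a 0.05-Hz grid — are
disjoint. With the kernel design above the 5% supports are, e.g.,
[5.3, 10.7] Hz for the 8-Hz filter and [36.5, 91.6] Hz for the 64-Hz
filter; pairs such as (20, 40) Hz are excluded.

### Edge transients

A 2-s segment filtered per segment carries edge transients over the
filter's half-kernel span (~0.41 s per end for the low-frequency filters).
All binned PAC statistics — real and surrogate alike — therefore exclude
that span at each segment end and use the central ~1.2 s. This matters
whenever the low-frequency phase at segment boundaries is not random:
simulated carriers at 2/4/8/16 Hz complete an integer number of cycles per
2-s window, so every boundary has identical phase, and without the
exclusion the edge transients masquerade as coupling (on uncoupled
signals MI_norm averaged +1.17 instead of 0). With the exclusion, MI_norm
on uncoupled signals is calibrated (mean ≈ 0, ~95% within ±1.96). The
surrogate shift itself still operates circularly over the full segment.

## Segment QC

Joint-probability rejection scores each (segment, electrode) by the
improbability of its samples under a Gaussian kernel density estimate of a
reference distribution, along two dimensions: *across* (reference = that
electrode pooled over all segments; scores z-scored over segments) and
*within* (reference = all electrodes within the segment; scores z-scored
over electrodes, skipped below 3 electrodes where the z is degenerate). A
segment is rejected if any |z| exceeds 3.

The improbability score is a symmetrically 2%-trimmed mean of the
per-sample negative log-likelihood. The untrimmed mean is essentially the
segment's energy, whose chi-square-like skew inflates the 3-SD tail
(~2% of clean segments rejected); trimming restores the intended
calibration (0–1% on homogeneous data) while leaving genuine artifacts at
z ≈ 10. The reference is strided-subsampled to ≤ 2000 points for
tractability. Rejection is single-pass; recordings left with fewer than 30
clean segments are excluded from analysis, and exactly 30 segments are
drawn uniformly without replacement from the survivors.

## Cluster-based PAC+ inference

Resting data has no task/baseline contrast, so μ(MI_surr) serves as the
comparison condition. Per (channel, LF, HF) cell, a **paired** two-sided
t-test compares MI_raw with μ(MI_surr) across recordings (the two values
are intrinsically paired within a recording). Cells with p < 0.05 (strict)
are grouped per channel by 4-connectivity on the (LF, HF) grid — no
diagonals, no cross-channel links, and excluded pairs never connect cells.
Cluster mass is Σ(t − t_crit) over the cluster, t_crit being the two-sided
critical value at α for df = N − 1.

The null distribution comes from flip-half permutations: ⌊N/2⌋ recordings
chosen uniformly have MI_raw and μ(MI_surr) swapped at every cell, the
t → threshold → label → mass chain is re-run, and this repeats 200 times.
Two null modes are provided: `pooled` (default) collects every cluster
mass from every permutation — the literal "distribution of cluster
statistics" — while `max` keeps each permutation's maximum for standard
family-wise control. A permutation with no supra-threshold cluster
contributes a single 0. Observed clusters with mass at or above the null's
95th percentile (computed globally across channels, since permutations
flip whole recordings) form the PAC+ mask. Cells with zero difference
variance are flagged and excluded rather than assigned infinite t.

## Age trends

Each recording is summarized by the arithmetic mean of MI_norm over PAC+
cells and correlated with age (Pearson, two-sided). For phase preference,
the fraction of a recording's PAC+ cells with phase max in each of the 18
bins is correlated with age bin by bin; significance uses the Bonferroni
threshold 0.05/18. Regional variants restrict to the anterior
(Fp1, Fp2, F3, F4, F7, F8, Fz) or posterior (P3, P4, P7, P8, Pz, O1, O2)
10–20 sets; recordings with no PAC+ cell in a region are excluded from that
region's trend (their proportion vector is undefined). Bins with constant
proportions are flagged untestable rather than given a correlation. The
plotting helper for the MI–age figure shows the median with interquartile
shading; the correlation itself uses the mean.

## Synthetic data

The generator produces

    x(t) = cos(2π f_lf t)
         + a_hf · (1 + m·cos(2π f_lf t − φ_pref)) · cos(2π f_hf t)
         + pink noise,

the simplest smooth unimodal modulation model: the high-frequency envelope
peaks exactly where the low-frequency phase equals φ_pref. Defaults:
HF/LF amplitude ratio a_hf = 0.5, modulation depth m = 0.8 for single-signal
validation, pink-noise SD 1.0 relative to the unit LF amplitude — chosen as
a realistic scalp-EEG-like regime (background comparable to the rhythm,
gamma weaker than the slow rhythm) and held fixed. Pink noise is
synthesized spectrally (Gaussian Fourier coefficients shaped by f^(−1/2),
standardized to the requested SD); its log–log PSD slope is −1 within
±0.2 over 1–100 Hz.

Cohorts assign ages round-robin over the collection time points
{3, 6, 9, 12, 18, 24, 36} months; coupling depth for age a is
base_depth + slope·(a − 3), validated to stay in [0, 1] (defaults span
0.2 → 0.8 from 3 to 36 months); anterior channels couple at −110°,
posterior at +70°. Every channel gets an independently seeded noise
realization; all generators are bit-reproducible from a single seed.

What the generator does **not** emulate: volume conduction and channel
covariance, non-stationarity and vigilance-state changes, heteroskedastic
artifact structure, multi-frequency or bimodal coupling, and recording-to-
recording variance in noise level. Passing tests therefore demonstrate the
correctness and calibration of the *analysis* under the stated generative
model, not robustness to every property of real infant EEG.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to make the suite routinely
runnable: surrogate calibration uses 50 replicates of 60-s single-channel
signals at the full 200 surrogates; cluster-null calibration uses 50
uncoupled cohorts of 12 subjects × 4 channels on a reduced 3 × 4 frequency
grid with 100 surrogates and 200 permutations; slope/preference recovery
uses 20 cohorts of 16 subjects × 4 channels on the (8, 64) Hz pair at 200
surrogates. These sizes were fixed as part of the test design, with the
acceptance thresholds (calibration bands, ≥90% recovery) unchanged.

## Known limitations

- The joint-probability score is a reconstruction of the cited artifact-
  rejection idea from its description (density model unspecified there);
  only the 3-SD rule is treated as normative.
- Filter kernel length, window, and edge policy are design choices; the
  simulated phase-preference harness (`validate_filters`) is the arbiter
  that they preserve coupling phase, and it passes all 16 conditions
  (4 LFs × 4 preferences; bin-center preferences recovered exactly at
  LF ≥ 4 Hz, within one bin at 2 Hz and for bin-edge preferences).
- Group-level age associations are cross-sectional; nothing here supports
  within-individual developmental claims.
- EDF input is read-only (via MNE) and not resampled; the analysis assumes
  preprocessed, average-referenced input at 250 Hz.
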