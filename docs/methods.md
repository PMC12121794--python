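# Methods

This note documents the models, estimators, numerical choices and known
limitations of `seegcoh`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Study design assumed by the pipeline

A session is one continuous multichannel recording (µV, 2,000 Hz native by
default) containing a resting baseline (3 min by default) followed by
5-second stimulation trials at five vibration frequencies (2/6/12/20/40 Hz),
30 trials per frequency in randomized order, separated by 5-second off
periods. Off-period data is generated and recorded but never analyzed; the
epoch is the unit of analysis throughout.

## Preprocessing

Stage order is fixed and tested: highpass → line-noise channel detection →
label-based channel exclusion → common average reference (CAR) → notch →
epoching → amplitude rejection → downsampling.

* **Highpass**: fourth-order Butterworth at 0.5 Hz. All filters are applied
  forward–backward (`sosfiltfilt`/`filtfilt`), so preprocessing is zero
  phase; squared magnitude responses are therefore the single-pass response
  squared (the 0.5 Hz highpass attenuates a 0.1 Hz tone by
  (1 + (0.5/0.1)⁸)⁻¹ ≈ 2.6·10⁻⁶ in amplitude).
* **Line-noise screen**: per channel, Welch PSD integrated over 59–61 Hz; a
  channel is excluded when its power exceeds the cross-channel **median** by
  more than 3 × the **mean absolute deviation about the median**. The phrase
  "mean absolute deviations above the median" is read literally; a
  median-absolute-deviation variant is available (`dispersion="median_abs"`).
  The screen runs **before** CAR so contaminated channels cannot leak into
  the reference. It presumes contamination is a minority of channels —
  with, say, 2 of 6 channels contaminated the robust dispersion itself is
  inflated and detection degrades (the tests use ≥ 10 : 1 clean ratios).
* **CAR**: each kept channel minus the instantaneous mean of kept channels;
  excluded channels are dropped entirely. CAR is idempotent and leaves the
  cross-channel mean identically zero.
* **Notch**: second-order IIR at 60 Hz, quality factor Q = 30 (configurable).
  Harmonics (120/180 Hz) are *not* notched by default even though the gamma
  band spans 70–170 Hz; a single mains notch is the protocol default.
* **Epoching**: the baseline segment is split into consecutive
  non-overlapping 5-s epochs (36 from a 3-min baseline); each stimulation
  event contributes exactly one epoch.
* **Amplitude rejection**: a (channel, epoch) slot is discarded iff its
  absolute peak **strictly exceeds** 500 µV ("exceeding"; a peak of exactly
  500 µV is kept). Rejection is evaluated on the preprocessed (post-CAR,
  post-notch) signal, consistent with the stage order. A per-channel
  rejection-proportion summary is emitted.
* **Downsampling**: epochs are decimated from 2,000 to 500 Hz with the
  zero-phase order-8 Chebyshev-I anti-alias lowpass at 0.8 × the new
  Nyquist; the native rate must be an integer multiple of the target.

## Coherence estimation

Magnitude-squared coherence is estimated per epoch by Welch's method:
2.5-s segments, 70% overlap, periodic Hamming taper, constant detrend per
segment. For a 5-s epoch at 500 Hz this gives K = 4 segments on a 0.4 Hz
grid. The implementation computes segment FFTs once per channel and forms
all pairwise cross-spectra at once; it is verified bin-for-bin (atol 1e-10)
against `scipy.signal.coherence`.

Two estimator facts drive the design:

* **K = 1 degeneracy**: a single-segment MSC is identically 1 for any pair
  of signals; the estimator refuses K = 1 with an error.
* **O(1/K) bias**: for weakly coherent signals the estimate is biased
  upward by roughly (1 − C)²/K_eff; at K = 4 overlapping segments the null
  expectation of a band mean is ≈ 0.35, not 0. Per-epoch values are
  therefore never interpreted as absolute coherence; baseline subtraction
  cancels the bias because baseline and stimulation epochs share the
  estimator. A **pooled mode** (`pooled_coherence`) instead pools segments
  across all epochs of a condition (K = 120 for 30 epochs), giving a nearly
  unbiased level estimate; it is used wherever a coherence *level* is
  compared to an analytic value. Pooled baseline subtraction should use
  comparable epoch counts on both sides: with very unequal counts the
  residual bias difference (1/K_stim − 1/K_base) no longer cancels and can
  approach the 0.01 seed-map mask.

Band averages are unweighted means over bins with low ≤ f < high; the
half-open convention resolves the 8 Hz and 13 Hz edges shared by adjacent
bands. Electrode-pair Δ values are averaged into region pairs (within-region
pairs of distinct contacts populate the diagonal; self-pairs never enter),
and region-pair tables are averaged across covering subjects at the group
level, recording the contributing-subject count. The "global distribution"
over region pairs excludes the diagonal by default
(`include_within_region=True` includes it); the intended composition cannot
be pinned down from the protocol, so both modes exist.

## Nonparametric statistics

All procedures are implemented from their defining formulas, with
`scipy.stats` (and `pingouin`/`statsmodels` where applicable) serving as
independent cross-checks in the tests, never as the implementation.

* **Friedman** and **Kruskal–Wallis** use average ranks with the standard
  tie corrections; completely tied inputs return statistic 0 and p = 1 with
  a warning rather than failing, because thresholded coherence maps can be
  constant.
* **Wilcoxon signed-rank**: zero differences are dropped by default (the
  classic reduced-sample rule; a Pratt mode is available). For N ≤ 25 the
  exact conditional null is computed by the generating-polynomial DP over
  all 2^N sign assignments (tied ranks handled by doubling to integers);
  beyond that, the tie-corrected normal approximation without continuity
  correction (a continuity flag exists — with it, exact and approximate
  p agree within 0.01 at N = 20–25). Effect size is always r = |Z|/√N with
  N the number of non-zero differences.
* **Exact multinomial**: full enumeration of all C(n+k−1, k−1) outcomes;
  the p-value sums the probabilities of outcomes with
  P(outcome) ≤ P(observed) · (1 + 1e-12) (probability-ordering extremeness;
  the float guard keeps equal-probability outcomes in the tail). Enumeration
  is capped at 5·10⁶ outcomes.
* **Cohen's d** uses the pooled (n−1) standard deviation.
* **Bonferroni** families: 10 for the pairwise condition post-hocs (all
  unordered pairs of 5 conditions), 5 for the one-sample-vs-zero family.

## Responders, SNR, hubs, seed maps

* A **responder** electrode pair has Cohen's d > 0.2 (strict) comparing its
  per-epoch MSC distribution under a condition to its baseline distribution.
  Note the small-effect threshold has a substantial sampling floor: under
  the null with 30 stimulation and 36 baseline epochs, SD(d̂) ≈ 0.25, so
  ≈ 21% of null pairs exceed 0.2 by chance. Responder percentages are
  comparative (across conditions and subjects), not detection claims.
* **SNR** per condition is mean/SD of responder percentages across subjects
  (sample SD by default, population SD selectable). The permutation test
  shuffles each subject's condition labels independently per iteration;
  p is the proportion of iterations with permuted SNR strictly greater than
  observed. Because the strict rule yields p = 0 for degenerate inputs, a
  `geq` mode (ties count) and an add-one mode ((b+1)/(n+1), recommended)
  are provided.
* **Best-frequency ranking**: per subject, the argmax condition of the
  responder percentage (ties go to the lowest frequency with a warning);
  counts across subjects are tested with the exact multinomial against
  uniform fifths.
* **Hub pairs**: region pairs with Δ ≥ mean + 2 SD of the same
  (condition, band) global distribution; sample SD by default. A **hub
  region** participates in ≥ 2 qualifying pairs. Note that with sample SD,
  k equal outliers among n pairs require enough null pairs to qualify
  (2 of 10 never can; 2 of 45 comfortably do).
* **Seed maps** report Δ from a seed region to every *other* covered region,
  masked to |Δ| strictly greater than 0.01, sign preserved. Condition
  comparisons use Kruskal–Wallis on the threshold-applied Δ distributions;
  when the omnibus test is significant at 0.05, pairwise two-group
  Kruskal–Wallis tests (equivalent to a tie-corrected rank-sum test) are
  Bonferroni-corrected over the condition pairs. The rank-sum form is used
  because thresholding leaves unequal, unpaired samples per condition.

## Synthetic sessions and their ground truth

Each channel carries unit-shape 1/f^α Gaussian noise (α = 1 default, the
shape flattened below 1 Hz to keep total power finite), synthesized by
frequency-domain shaping and scaled to a per-channel power of 2,500 µV²
(50 µV RMS — large enough that the 500 µV spike bound is far in the tail of
the background). Channels of one region additionally share a weak common
source (relative amplitude 0.3) so baseline within-region coherence is
non-trivial. The trial schedule is a seeded permutation with exactly the
configured count per condition; a fixed seed reproduces the session
bit-for-bit.

A **coupling** adds a · s(t) to every channel of two regions during the ON
epochs of one condition only, where s is unit-variance band-limited noise
drawn independently per epoch. For x = a·s + n₁, y = a·s + n₂ with
independent noise of in-band power σn², the in-band MSC is

  C = (a²σs² / (a²σs² + σn²))².

The source is built by **brick-wall frequency-domain masking** of white
noise rather than a Butterworth bandpass: a bandpass filter's edge rolloff
makes the in-band SNR non-uniform, and because C is concave in the SNR the
band mean then falls measurably short of the closed form (a Jensen loss of
about 0.03 at C = 0.25); a spectrally flat source keeps the analytic oracle
exact. The generator records, per coupling, the expected in-band noise power
— computed from the very spectral weights it synthesizes with, including
the shared-source contribution — and the resulting expected band MSC, so
parameter-recovery tests need no fitted constants.

Artifacts: line noise is a 60 Hz sinusoid of configured amplitude (random
phase) over the whole recording on designated channels; spikes are biphasic
raised-cosine transients (40 ms default width, peak-normalized to the
configured amplitude) centered in designated epochs.

What the generator does **not** emulate: nonstationary background spectra,
realistic interictal spike morphology and propagation, volume conduction,
electrode drift, or the auditory confound of an audible vibration motor.
Passing recovery tests therefore demonstrates the pipeline's correctness
and sensitivity under its own assumptions, not clinical validity on real
recordings.

## Validation design choices

* **Analytic recovery** is asserted on the pooled estimator over the 30 ON
  epochs of a session (mean over six seeded sessions, tolerance ±0.05
  around the 0.25 closed form), with a white (α = 0) background so the
  in-band SNR is exactly flat.
* **Null calibration** runs 100 zero-coupling sessions (20 channels, 10
  epochs per condition) through the full pipeline and applies the one-sample
  Wilcoxon to Δ over a maximal matching of channel-**disjoint** electrode
  pairs. This restriction is essential: electrode pairs sharing a channel
  are positively dependent, and the all-pairs signed-rank test is
  substantially anticonservative under the null (empirically ~3–5× the
  nominal rate) — a structural property of all-pairs connectivity testing
  worth remembering when reading whole-brain p-values, here and elsewhere.
  Disjoint pairs restore the independence the test assumes, and the
  rejection rate is checked against the exact binomial band around 5%.
* **End-to-end recovery** injects one amygdala–hippocampus theta coupling
  gated by the 20 Hz condition into a 59-channel montage and requires, over
  20 seeds: responder sensitivity ≥ 90% at the coupled pairs, recovery as a
  ≥ 2 SD hub pair, and survival as the **sole** seed-map target in that
  condition and band. The montage keeps the coupled channels a small
  fraction (4/59) of the CAR reference: the common average subtracts a
  fraction p of the coupling source from every channel, which otherwise
  induces spurious coherence of order ((1−p)p·SNR)² between the coupled and
  all other channels — with p ≈ 0.07 this leakage sits near 0.002, safely
  under the 0.01 seed-map mask. CAR leakage is a real phenomenon on real
  montages too; it argues for caution when a strong focal source dominates
  a small reference set.
* Problem sizes in the test suite (reduced channel counts, 500 Hz native
  rate for synthetic sessions, single analysis band where only one band is
  probed) are the package's own validation choices; every protocol default
  in `RunConfig` remains the published value.

## Known limitations

* The all-pairs one-sample Wilcoxon on Δ is anticonservative (see above);
  the pipeline still reports it at the group level, as the protocol
  prescribes, and this note is the caveat.
* The d > 0.2 responder rule has a ~21% false-positive floor at the
  protocol's epoch counts; responder percentages are relative measures.
* Per-epoch MSC at K = 4 is strongly biased; only Δ and pooled values are
  interpretable as levels.
* EDF bundles are read-only (via `mne`); the package writes the raw
  float32 + TSV bundle format.
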