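# Methods

This note documents the models, statistics and numerical choices behind
`mmntrack`: what the synthetic data emulate, how the detection statistics
are defined, and which design decisions were genuinely open.

## The paradigm and its synthetic model

A recording block is a passive multi-deviant auditory oddball sequence:
2,400 tones at a regular 450 ms stimulus onset asynchrony, 82% standard
tones and 6% each of duration, frequency and intensity deviants.  Counts
are exact — `round(n_tones × p)` per deviant with the rounding remainder
assigned to standards (1,968 + 3 × 144 at defaults) — rather than
Bernoulli draws, so block composition is deterministic.  Deviant positions
are drawn uniformly over all arrangements with at least one standard
between consecutive deviants (standard oddball practice, switchable off);
the uniform draw uses the bijection between non-adjacent k-subsets of
`range(n)` and arbitrary k-subsets of `range(n−k+1)`.  Each standard is
tagged `post_deviant` so either convention for the standard average (keep
or drop post-deviant standards) can be tested downstream; the default
keeps all unrejected standards.

### ERP templates

Epochs span −100 to +600 ms at 512 Hz: samples `t_k = −100 + k·(1000/rate)`
for `k = 0 … floor(0.7·rate)` (359 samples at the default rate).  Each
component is a Gaussian pulse with a configured peak latency, signed
amplitude and per-channel weight over the six-channel frontocentral
montage (F3, Fz, F4, C3, Cz, C4, all weight 1 by default).  `width_ms` is
the pulse's full width at half maximum — 50 ms for N1/MMN/DRN, 80 ms for
P3a.  (Interpreting those widths as Gaussian SDs instead makes the MMN and
P3a pulses overlap so strongly that the difference-wave extremum shifts
tens of ms away from the configured latency; the FWHM reading keeps
rendered peaks within one sample of their configuration, which is a tested
contract.)

Default morphology: every condition carries an obligatory N1 (−1.5 µV at
100 ms).  Duration deviants add a dissociated MMN (−2.5 µV at 205 ms) and
P3a (+3.0 µV at 300 ms); frequency and intensity deviants add a
deviant-related negativity (DRN, the N1/MMN summation) at 105 ms (−1.6 and
−2.0 µV respectively) and a P3a (+2.0 / +2.2 µV).  Amplitudes are ordered
frequency < intensity < duration, matching the relative reliability of the
three deviants in multi-deviant paradigms.  The obligatory N1 is identical
across conditions, so with the presence gain at zero a deviant trial is
*distributionally identical* to a standard trial — exactly the
exchangeability the null-calibration suites rely on.

### Noise and presence modulation

Per trial and channel the generator adds white noise (SD 4 µV/sample) and
1/f-power "pink" noise (SD 6 µV/sample), the latter via spectrally shaped
complex Gaussian rFFT spectra (amplitude ∝ f^−1/2, zero DC) normalised
analytically to the requested per-sample SD.  A multiplicative trial
jitter (SD 0.1) scales each trial's whole template.  The
`block_presence_gain ∈ [0, 1]` scales deviance-related components only:
gain 1 is a fully present response, gain 0 an absent one; alternating
gains across blocks emulate the waxing/waning phenomenology seen in
comatose patients.  The noise defaults were chosen so that single-block
*group* detection succeeds essentially always while *single-trial* tests
remain non-trivial.

Group fixtures additionally draw one amplitude scale per subject from a
rectified normal `max(0, N(1, 0.5))`, applied to deviance components.
Real between-subject MMN variability is what keeps group-level effect
sizes at realistic magnitudes: without it, averaging ~2,000 trials drives
trial noise to near zero and the paired standardized effect explodes
(δ > 30), which no human dataset shows.  With the default SD of 0.5 the
programmed duration-MMN group effect is ≈ 1.5–1.9 depending on block
length — large, consistent with duration deviants being the most reliable
elicitor and with per-block group detection succeeding in every block.

### What the generator does *not* model

No ocular or muscle artifacts (rejection is exercised with injected
spikes), no continuous raw EEG, no latency/width variability between
subjects, no scalp topography beyond the frontocentral montage (optional
extra channels carry configurable gains), and no autocorrelation of noise
across trials.  Consequently, passing tests show that the *statistical
machinery* behaves correctly under its assumptions — exchangeability under
the null, programmed effects under the alternative — not that real
ICU-grade EEG meets those assumptions.

### Programmed effect size

For the paired group design the generator can state the population
standardized effect it programs:

δ = Δ·E[s] / sqrt((Δ·SD[s])² + σ_r²)

where Δ is the band-passed deviance template's mean over the 100 ms
peak-centred window minus its baseline mean (the band-pass is applied
because that is the signal the pipeline sees), s the rectified-normal
subject scale (moments in closed form), and σ_r the trial-noise
contribution to a subject's evoked difference: the per-trial window-mean
noise SD — estimated by passing noise-only trials through the same
filter/baseline chain (4,000 trials, fixed internal seed, ~1% precision) —
scaled by sqrt(1/n_dev + 1/n_std).  Effect-size recovery is assessed with
the small-sample bias-corrected estimator (Hedges g; the raw d estimator
exceeds δ by the known factor ≈ 1 + 3/(4ν−1), about 5% at n = 17).

## Preprocessing

Filter → baseline → reject → average, bit-identical on re-run.  The filter
is a 4th-order Butterworth band-pass (0.1–30 Hz) applied forward-backward
(zero phase) as second-order sections; passband gain at 10 Hz is within
±1 dB and stopband attenuation at 50 Hz exceeds 20 dB (both contracts are
tested against the analytic response).  Baseline correction subtracts each
trial × channel mean over −100–0 ms.  Artifact rejection flags any trial
whose peak-to-peak amplitude on any channel exceeds 200 µV (configurable;
common ERP practice).  Averaging is the arithmetic mean over unrejected
trials per condition and block, with trial bookkeeping
(`n_averaged + n_rejected = n_input`) enforced.  Data are assumed already
referenced; ICA-based ocular correction is an optional external hook, not
implemented here.  When the generator's float32 mode is used the filter
runs its cascade in single precision (~0.1% response error) for a large
speed gain on Monte-Carlo suites; the default path is full double
precision.

## Detection statistics

All statistics operate on the unweighted mean of the six frontocentral ROI
channels.

**Serial permutation t-tests with Tmax correction.**  A one-tailed t
statistic is computed at every sample (paired: one-sample t on per-subject
difference waves; independent: Welch t across trials, chosen over pooled
variance because of the ~1,968-vs-144 group imbalance, with a
pooled-variance switch).  The null is built from B = 1,000 seeded
resamplings — random sign-flips of difference waves (paired) or random
relabellings preserving group sizes (independent) — and per resampling the
*extreme* of the signed statistic in the tail direction over the tested
family is recorded.  Corrected p-values use the add-one convention
`p = (1 + #{extreme ≥ t_obs}) / (B + 1)`, so `p ≥ 1/(B+1)` and
`p_corr ≥ p_uncorr` everywhere.  The tested family defaults to the entire
epoch (−100 to 600 ms) so that the permutation test is exact over the
family actually reported; it can be restricted (e.g. to post-stimulus
samples).  Two one-tailed passes share one set of permutation draws:
negative for MMN/DRN, positive for P3a.  Exhaustive enumeration (all 2^n
sign patterns, or all C(n, n_a) relabellings) replaces sampling on small
designs and then reports exact `p = count / #enumerated`, the identity
being part of the enumeration.  Degenerate samples with zero variance
define t = 0 when the mean is also zero and ±∞ otherwise.

**Peaks and effect sizes.**  The component peak is the most negative
(MMN/DRN) or most positive (P3a) sample of the evoked ROI difference
within the search window (MMN 80–230 ms, P3a 250–350 ms), ties broken
toward the earliest latency.  Cohen's d is computed on window-mean
amplitudes over 50 and 100 ms peak-centred windows: paired
`mean(diff)/SD(diff)` across subjects, independent
`(mean_a − mean_b)/pooled SD` across trials; windows clipped at epoch
bounds are flagged, zero variance yields signed infinity with a flag, and
the bias-corrected Hedges g is carried alongside.

**Bayes factors.**  Per-sample BF10 uses the BIC (unit-information, "flat
prior") closed form `BF10 = (1 + t²/ν)^{n/2} / √n` — derived from the
Gaussian likelihoods of H1 (free mean) vs H0 (zero mean), n the total
observation count, ν the t's degrees of freedom — computed in log space
(t values can be enormous on noiseless fixtures).  For the independent
design the BF uses the pooled-variance t, which is the exact BIC mapping,
even though the permutation route defaults to Welch.  The windowed maximum
and its latency feed the Lee–Wagenmakers category (half-open bins, lower
bound inclusive; BF10 < 1 reported as favors-null).  A JZS
(Cauchy-prior) alternative is available through pingouin; the two agree in
their ordering of |t| at fixed n but not numerically, and the BIC form is
the documented default rather than a claim about any particular
toolbox's prior.

**Presence decisions.**  Permutation route: present iff a contiguous run
of corrected-significant samples of the correct polarity, at least
`min_duration_ms = 10` ms long (≈5 samples at 512 Hz; set 0 for raw
any-sample behaviour), intersects the component search window.  Bayes
route: present iff the windowed maximum BF10 ≥ 3 (the anecdotal/moderate
boundary; configurable, and reported alongside so an anecdotal-inclusive
tally can be formed).  Manual-visual calls are ingested from annotation
CSVs and must carry an annotator tag.  Exactly one decision per
(subject, block, deviant, component, method) is enforced.

## Longitudinal analysis

Mean amplitudes are exported over ±50 ms around the group-average peak:
180–230 ms for the duration MMN, 80–130 ms for frequency/intensity (DRN).
The habituation test is a balanced two-way within-subject ANOVA
(deviant × block, subject random) computed by direct sums-of-squares
decomposition — kept self-contained so all SS components are available;
their conservation to SS_total is a tested invariant at 1e-8 relative.
Complete cases only (listwise deletion, logged); with 13 complete subjects
the deviant effect has df (2, 24).  Greenhouse–Geisser ε is computed per
effect from the covariance of the subject scores projected onto an
orthonormal effect basis (Helmert contrasts; Kronecker product for the
interaction), clipped to [1/df, 1]; both uncorrected and GG-corrected
p-values are always reported, GG applied whenever ε < 1.  Partial η² is
SS_effect/(SS_effect + SS_error).  When the deviant effect is significant,
Bonferroni-corrected pairwise paired t-tests run on the deviant marginal
means (averaged over blocks); mean differences are signed (first − second)
of the named pair, as stated in the output header.  The implementation
matches R's `car::Anova` Greenhouse–Geisser values exactly; pingouin
agrees on F, p and main-effect ε (its two-way interaction ε uses a
different approximation that pingouin itself flags as potentially
inaccurate).

Detection rates divide presence counts by the number of subjects *with
that block* — subjects who did not record a block leave its denominator.

## Numerical and reproducibility choices

All randomness flows from one root seed through `SeedSequence` spawning
(per-subject, per-block substreams; derived integers kept below 2^31).
Identical seeds give bit-identical sequences, epochs and tables.  The
independent-samples permutation engine computes group sums for all
relabellings as one 0/1-matrix multiplication (a single BLAS call), which
is what makes 1,000 relabellings of ~2,100 trials × 359 samples routine.
Fixture datasets round-trip losslessly as an `epochs.npy` tensor plus JSON
sidecar.  EDF(+)/BrainVision recordings are read through mne and epoched
at annotation markers in-package.

## Problem sizes in the validation suites

The Monte-Carlo validation suites (tests and `scripts/acceptance.py`) use
these sizes, chosen as the smallest designs that leave each property's
pass/fail margin dominated by the property rather than by sampling noise:

* **Null calibration (FWER)** — 200 simulations of 600-tone blocks with
  gain 0.  A permutation test's exactness under exchangeability does not
  depend on block length, so short blocks test the same property.
* **Group power and effect recovery** — 100 seeds × 17 subjects ×
  600-tone blocks.  The paired design's power and programmed δ are
  dominated by between-subject variability; the programmed-effect formula
  accounts for the trial-noise term at the actual block length.
* **Waxing/waning recovery** — 60 seeds × 5 *full-length* (2,400-tone)
  blocks.  Single-subject power rests on the 144 deviant trials per
  block, so this suite cannot be shortened without changing the property.
* **Permutation oracle** — 6-subject fixtures against the exact 2^6
  enumeration; agreement is asserted in aggregate (mean |error| ≤ 2× mean
  Monte-Carlo SE) plus a per-sample ~4-SE binomial band, since a pointwise
  2-SE band is violated somewhere by any finite sampling with ~5%
  probability per null atom.
* **Closed-form oracles** — Bayes factors against likelihood-level BIC
  computation (20 random (t, n) pairs, 1e-10 relative); ANOVA against a
  loop-based cell-means oracle (20 random designs, 1e-8 relative).

## Known limitations

Cluster-based permutation correction, multivariate decoding and source
localisation are out of scope.  The Bayes factor's "flat prior" form is
the BIC approximation, documented as such.  Between-subject variability is
amplitude-only; latency jitter across subjects would smear group averages
and lower effective power relative to these simulations.  The visual
inspection route exists only as manual annotation ingestion — the package
takes no position on a waveform's visual identifiability.
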