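# Methods

## The detection problem

Sustained attention (SA) in infants and toddlers has a reliable cardiac
signature: attention orienting is marked by a rapid heart-rate (HR)
deceleration, HR then stabilises at the lower level for roughly 2–20 s, and
disengagement is marked by a rapid re-acceleration; body movement is
reduced during the attentive period.  This package detects those
heart-rate-defined SA periods from a chest-worn sensor's ECG and triaxial
accelerometer (both 500 Hz), with no behavioural video required at
inference time.

Detection runs in three stages:

1. **Change-point segmentation.**  The beat-indexed instantaneous HR
   (60 / inter-beat interval) is segmented by wild binary segmentation
   (WBS2) with steepest-drop-to-low-levels (SDLL) model selection, and the
   human coding rules are applied automatically: an SA candidate opens at a
   mean-HR drop of at least 5 bpm (or 3–5 bpm with a peak-to-peak drop
   above 5 bpm, in which case the onset moves to the HR peak just before
   the change point), the earliest of consecutive qualifying drops fixes
   the onset, a symmetric rise terminates it, and candidates shorter than
   2 s are discarded.
2. **Point-wise classification.**  Every 0.5 s grid point is classified
   attention/inattention by logistic regression on 51 features: HR and
   acceleration magnitude, their level-4 maximal-overlap wavelet packet
   decompositions (16 bands each, Daubechies filter with two vanishing
   moments), 12 scales of Fisher-z time-varying wavelet coherence between
   HR and movement, session SDRR, the Stage-1 binary with segment duration
   and latency covariates, and age in months.  Features are selected by
   L1-penalised logistic regression (importance = mean absolute
   standardised coefficient across five CV folds, cut at 0.03) with SMOTE
   class balancing; the final model is an unpenalised refit on the
   selected features.
3. **Refinement.**  Predicted segments no more than 2.5 s apart are merged,
   and any Stage-1 SA segment more than 90 % covered by predictions is
   promoted to a full SA period unless the resulting contiguous span would
   exceed 50 s (the cap vetoes a promotion; it never truncates one).

## Change-point machinery

The CUSUM contrast for a split of `x[s:e]` at `p` is the usual scaled
two-sample mean difference.  WBS2 evaluates, within every current stretch,
the best split over the stretch itself plus 100 randomly drawn
sub-intervals, records the winner and recurses on both sides until
stretches are shorter than `2 * min_seg` (`min_seg = 2` beats).  Change
points run on the beat-indexed HR, not the 2 Hz grid: the heartbeat is the
fundamental resolution at which a mean shift is observable, and change
points are mapped to seconds afterwards through the beat times.

SDLL scales the sorted candidate magnitudes by a robust noise estimate
(sigma = MAD of first differences / (sqrt(2) x 0.6745)) and compares them
with the universal threshold `T = 1.3 * sqrt(2 log n)`.  No candidate above
`T` means no change points.  Otherwise the kept number K maximises the drop
ratio `s_k / s_{k+1}` among drops that leave signal level for low levels
(`s_k >= T > s_{k+1}`); since the sequence is sorted this pins K at the
threshold crossing.  We evaluated the unrestricted variant (any drop whose
successor is below `T`) and found it pathological on frequent-change-point
series: near-zero tail magnitudes produce the largest ratios and K jumps to
essentially all candidates.  The noise scale is floored at `1e-8` of the
top raw magnitude and `1e-9` of the series scale so that floating-point
residue on noise-free signals cannot register as evidence.

Direction labels use the local slope (mean of the two beats after the
change point minus the mean of the two before).  The "local HR peak" used
by the 3–5 bpm screening rules is the extremum of the beat-indexed HR
within 5 beats of the change point.  Onset/termination pairing is greedy
left-to-right; a candidate still open at session end is discarded.

## Wavelet features

No installed library offers a non-decimated wavelet *packet* transform, so
it is computed in the Fourier domain: the equivalent transfer function of
each level-4 packet node is the product of the appropriately upsampled
quadrature-mirror filter responses (filters rescaled by 1/sqrt(2) per
level), with sequency ordering so the 16 bands tile 0–1 Hz in 0.0625 Hz
steps at the 2 Hz analysis rate.  Two outputs are exposed because no single
non-decimated series set satisfies both classical identities:

* `modwpt_bands` returns the multiresolution **details**
  (`ifft(X * |H_b|^2)`), which sum to the input exactly and are the
  feature columns;
* `modwpt_coefficients` returns the **coefficients** (`ifft(X * H_b)`),
  whose band energies sum exactly to the input energy.

Series are extended by repeated reflection to a power of two and cropped
back, so boundaries are handled without discontinuities.

Time-varying coherence follows the locally stationary wavelet estimator:
non-decimated Haar wavelet coefficients of both series at the 12 finest
dyadic scales, evolutionary auto- and cross-spectra smoothed by a centred
30 s moving average, coherence clipped to |rho| <= 1 - 1e-6 and Fisher
z-transformed (atanh).  Requiring 2^12 native samples would forbid sessions
shorter than ~34 min, so the reflection tiling also serves here: any
session of at least 32 s is padded up to 4096 samples.  Coherence at scales
longer than the session is then boundary-dominated and near-constant, which
the classifier simply ignores.

## Classifier

The penalty weight lambda is glmnet-convention (per-observation); the
sklearn `C` is `1 / (lambda * n)`.  Auto-selection scans 50 logarithmic
points over 1e-6..1e-1 and applies the one-standard-error rule: the largest
lambda whose mean cross-validated deviance is within one standard error of
the minimum.  The plain minimum-deviance lambda keeps noticeably more pure
noise features past the 0.03 importance cut (rejection ~87 % on planted
noise versus >= 95 % with the 1-SE rule); the 1-SE rule is the standard
sparsity-favouring choice for exactly this reason.

SMOTE (k = 5 minority neighbours, synthetic points uniform on segments
between neighbour pairs) is applied only to training rows — inside each CV
fold during selection and once on the full training set for the final
refit — never to validation or test data.  Standardisation statistics are
pooled over all training rows.  The decision threshold is a fixed 0.5.

Session-level train/test splitting is stratified on the five study age
bins (6, 9, 12, 24, 36 months) with largest-remainder quota allocation,
~1/9 of sessions held out.

## Evaluation

Point-wise metrics come from the 2x2 confusion counts on the 2 Hz grid with
masked (gap) points excluded pairwise; undefined ratios are reported as
missing.  Cohen's kappa uses marginal-product chance agreement.  The
duration-distribution comparison is a two-sample KS test on pooled interval
durations; the p-value is exact for small samples and asymptotic for large
ones (the convention of standard statistical software, against which the
implementation is tested to 1e-9).

Interval-level inter-rater agreement treats each coder's session as an
alternating sequence of attention/inattention periods.  Every period of
either coder contributes one equally weighted tally: agreement when the
other coder has an overlapping period of the same class (any degree of
overlap), otherwise the other coder's majority class within the period.
A strict elementary-period partition was rejected because boundary slivers
then carry the same weight as real periods and kappa collapses on
near-identical codings.

## Synthetic sessions

The generator produces what the detector assumes about real recordings and
is the substrate of all tests:

* baseline HR linear in age, 140 bpm at 6 months to 110 bpm at 36 months;
* two HRV bands, 0.03–0.15 Hz (rms 2.5 bpm) and 0.3–0.6 Hz (rms 1.5 bpm),
  as band-passed Gaussian noise;
* a piecewise-constant mean-reverting jump process (rate 0.3 /s, innovation
  2.5 bpm, reversion 0.6) reproducing the jagged beat-scale texture of
  infant HR — this is what gives change-point detection its realistic rate
  of roughly one change point per 8–15 heartbeats;
* SA episodes with Poisson-like arrivals, a 5 s refractory gap, truncated
  log-normal durations on [2, 20] s (median 8 s), uniform 5–15 bpm depths,
  and raised-cosine ramps of 1.5 s placed just outside the labelled
  interval; the episode gap is derived analytically so the long-run
  attention prevalence is 0.29;
* white HR noise of 1 bpm; beat times by integrating the instantaneous
  rate;
* movement as a bursty envelope suppressed by 50 % during SA, sharing a
  sub-0.1 Hz component with HR to induce the slow HR-movement coupling;
* optionally a 500 Hz ECG trace (Gaussian R-waves plus white noise at a
  chosen amplitude SNR) and an egocentric stream of smooth random maps and
  fixations with a planted attention-saliency effect in within-frame SD
  units.  The maps are temporally smoothed (~2 s persistence) because real
  egocentric scenes change slowly relative to the 5 s analysis window —
  with independent per-frame maps a fixated region's value would be
  averaged away across the window's frames — and the effect is planted on
  the disc-averaged field at the analysis mask radius, the scale at which
  the windowing pipeline actually measures fixated saliency.

What the generator does **not** emulate: respiratory sinus arrhythmia as an
explicit respiration channel, movement artifacts in the ECG, age-dependent
HRV power, non-stationary drift of the baseline over a session, and any
visual structure in the egocentric maps beyond spatial smoothness.  Passing
tests therefore demonstrate that the chain recovers the cardiac SA
signature it models, not that it handles every pathology of field
recordings.

## Experiment sizes and numerics

The end-to-end experiment used by the tests and the acceptance script is
20 training plus 4 held-out sessions of 30 minutes each at the default
conditions — large enough for stable selection (about 72k training points)
while keeping a full run in minutes.  The duration-distribution
(restoration) check uses fifty 10-minute sessions against a model trained
once.  R-peak detection needs at least 2 s of signal and a 100 Hz sampling
rate; artifact correction bounds HR to 60–250 bpm and flags IBI jumps
beyond 40 % of the local median, interpolating missed beats linearly.
Spans longer than 3 s without a detected beat are masked as gaps, as are
declared dropouts; masked grid points are excluded from training, metrics,
and predictions.

## Known limitations

* The artifact-correction filter is a deliberately simple
  bounds-plus-median rule; it will not fix pathological ECG (electrode
  detachment, sustained arrhythmia).
* The egocentric map backend bundled here is a trivial gradient-energy map;
  saliency/clutter models are pluggable per-frame scalar map providers.
* The refinement constants (2.5 s merge gap, 90 % coverage, 50 s cap) are
  configuration with study defaults; no re-optimisation procedure is
  included.
* Coherence features at the coarsest scales are only meaningful for
  sessions of several minutes or longer.
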