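# Methods

`popsumstats` reimplements, end to end, a population-coding analysis of how
visual cortical populations encode the summary statistics of random-dot
motion — the ensemble **mean** direction, the ensemble **variance**
(direction heterogeneity), and the learned **category** (left vs right of a
vertical boundary). Because the kind of data it targets (head-fixed rodent
one-photon calcium imaging during a motion-categorization task) is rarely
public, the package ships a synthetic-session generator with known ground
truth, and every analysis stage is validated by parameter recovery and
analytic identities rather than by a reference dataset.

## The synthetic session generator

A session consists of 8 mean directions (22.5°–337.5° in 45° steps) × two
variance conditions. Homogeneous trials move all dots in the mean direction;
heterogeneous trials draw each of the 500 dot directions uniformly from a
90°, 180°, or 270° window centered on the mean (draws exactly equal to the
mean are rejected and resampled, so no single dot carries the global
direction). The default schedule is 20 trials per direction per condition
(160 + 160 trials), pseudo-randomized so that no two consecutive trials share
both the direction and the variance condition. Pure rejection-resampling of
the whole sequence has acceptance probability ≈ e⁻¹⁹ at this size, so the
scheduler shuffles once and then repairs violations by targeted swaps, with a
restart cap; the constraint itself is unchanged.

Trial timing is 2 s inter-trial interval, 4 s stimulus, 2 s response/reward
epoch, at a 30 Hz frame rate. The post-stimulus epoch matters: with a GCaMP
decay constant of 0.6 s, omitting it leaves enough fluorescence carryover at
the next trial's pre-stimulus window that decoders reconstruct the *previous*
trial's direction there.

Neurons are von-Mises-shaped tuning bumps `exp(κ(cos Δ − 1))` (default
κ = 2, a single free width parameter; the bump peaks at 1 and never goes
negative). Four generative coding modes span the hypotheses the analyses are
meant to separate:

* `linear_sum` — rate = baseline + amplitude × mean over dots of the tuning
  function (a neuron that merely pools local motion; for cosine tuning this
  attenuates the tuning amplitude by sin(r/2)/(r/2) for window width r);
* `sharpened_mean` — tuning evaluated at the dots' circular mean, scaled by
  a per-range gain (default 1.0 / 1.0 / 0.85 / 0.6 for 0°/90°/180°/270°) —
  a population that genuinely encodes the ensemble mean;
* `untuned` — baseline only;
* `category` — two rate levels keyed to the trial's category.

`sharpened_mean` additionally supports `attraction_deg`: the represented
mean is displaced toward the nearest horizontal category center (capped at
the center itself) before tuning evaluation. This is the generative analogue
of a learned categorical bias and turns the bias analysis into a
parameter-recovery problem with known δ.

Rates are converted to dF/F by convolution with a causal exponential kernel
(unit value at lag 0, τ = 0.6 s), plus a slow sinusoidal drift (0.05 dF/F,
120 s period, random phase per neuron) and i.i.d. Gaussian noise (default
0.3 dF/F). Choices follow P(right) = (1 − λ)Φ(s/σ) + λ/2, where s is the
signed distance of the mean direction from the vertical boundary folded onto
[−90°, +90°] (σ = 22.5°, lapse λ = 0.05 by default).

**What the generator does not emulate:** dot kinematics (positions,
lifetimes, wrap-around), eye and body movements, reward dynamics, correlated
("information-limiting") neural noise, and non-stationary tuning. Passing
tests therefore certify the *analysis machinery* — its algebra, calibration,
and recovery behavior — not robustness to every nuisance in real recordings.

## Preprocessing

Baseline drift is removed by subtracting the 8th percentile within a
centered 900-frame sliding window (edges truncated; computed with an exact
rolling quantile, linear interpolation between order statistics), followed
by Savitzky–Golay smoothing (order 3, length 11). Event detection mirrors
all negative dF/F values, takes 3× the interquartile range of that symmetric
sample as the per-neuron noise threshold, retains supra-threshold values and
zeroes the rest. An "event" is a maximal run of consecutive supra-threshold
frames — the counting unit needed for QC: a neuron fails if its negative
events exceed 5% of its positive events. A trace with no negative samples
has an undefined noise estimate; it is flagged and passed through with
threshold 0.

## Single-cell tuning

Responses are AUCs: the trial-averaged 0–4 s signal's mean × 4 s (equal, up
to the bin width constant, to trapezoidal integration). DSI =
(R_pref − R_antipref)/R_pref. The tuning slope averages offset pairs ±45°,
±90°, ±135° and fits an OLS line over offsets −180°…0°; selectivity requires
DSI > 0.4 *and* slope above the 95th percentile of direction-label-shuffled
nulls (labels permuted within condition, preserving cell counts). Peak ties
resolve to the lowest direction and are flagged.

The linear-summation simulation transforms homogeneous tuning curves by
averaging them over a uniform window of width r. The 8-point curve is
treated as band-limited: harmonic m is multiplied by sin(mr/2)/(mr/2)
(trigonometric interpolation). Piecewise-linear interpolation was rejected
because its trapezoid error at 45° spacing biases the cosine attenuation by
≈5%; the harmonic factor is exact for cosine components, the identity at
r = 0, and the circular mean at r = 360°. Peak amplitude is the aligned
curve's value at offset 0 minus its circular mean.

## Population response curve (PRC) and categorical bias

Preferred directions are derived per condition from the 4-s tuning curves.
For each trial, neurons are grouped by preferred direction and averaged
within group first, then re-indexed by the wrapped offset
(preferred − presented) and averaged over trials (correct trials only by
default, matching the task analyses; a flag admits all trials for passive
sessions). The PRC slope uses the same ±offset pair-averaging and −180°…0°
OLS line as the single-neuron slope; positive slope means the population
peaks at the presented direction. Offsets are reported on −180°…135° (the
+180° and −180° bins are the same wrapped bin).

For bias estimation the per-direction PRC is averaged over 0–4 s,
re-anchored to absolute direction, and fitted with
amplitude · Σₖ exp(−(θ−µ+360k)²/2σ²) + offset, k ∈ [−3, 3] (terms beyond
|k| = 3 are negligible for σ ≤ 90°; amplitude and offset absorb the PRC's
arbitrary scale and baseline — only µ feeds downstream). µ is initialized at
the empirical argmax and optimized within ±180° of it, avoiding 360°
aliasing at wrap-adjacent peaks. The signed bias maps µ − θ_sample to
[−180°, 180°) and is positive when displaced toward the nearest horizontal
category center (0° for right, 180° for left) — unambiguous for all eight
stimulus directions. Group summaries apply a Tukey fence (1.5 × IQR) per
condition, then one-sample (and optionally paired task-vs-passive) t-tests
with Benjamini–Hochberg correction across conditions.

## Inverted encoding model

Eight channel basis functions cos⁶(Δ/2) centered on the stimulus directions
define B = WC. Because cos⁶ contains direction harmonics 0–3 only, the
eight channel profiles span a 7-dimensional space and C₁C₁ᵀ is exactly rank
7; the weight estimate Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁺ and the inversion
Ĉ₂ = (ŴᵀŴ)⁺ŴᵀB₂ therefore use pseudoinverses, which are exact on the basis
span (the round trip Ĉ₂ = C holds to machine precision for any full-rank
population). Training requires all 8 distinct directions. Reconstruction runs
per time bin (train and test at the same bin), leave-one-trial-out on
homogeneous trials, with heterogeneous trials tested on hom-trained weights.
CTFs are zero-centered on the presented direction and summarized by the
8-point slope convention: offsets +45/+90/+135 are reflected onto their
negatives (duplicated points, unlike the PRC's pair-averaging — both
conventions are kept deliberately, each matching its analysis) and an OLS
line with intercept runs from −180° to 0°. Note the CTF slope's natural
scale is ~1/180 per degree for a unit-amplitude channel profile.

A numerical caution documented here because it shapes the tests: inverting
weights fit to *uninformative* labels (label shuffles, pre-stimulus bins) is
ill-conditioned, so single-session slope nulls are zero-mean but wide. The
tests therefore assert that the shuffle distribution is centered on zero and
average pre-stimulus slopes across sessions, rather than asserting a single
shuffled slope is tiny.

## SVM decoding, WCD/BCD, temporal generalization

Linear-kernel SVMs (C = 1, class-weight balanced) decode variance (hom vs
het, leave-one-out over all trials) and category (left vs right: LOO on hom,
hom-trained transfer to het) per time bin. Within- vs between-category
discrimination uses the four 90°-apart direction pairs on each side of the
boundary (within: {22.5°, 292.5°}, {67.5°, 337.5°}, {112.5°, 202.5°},
{157.5°, 247.5°}; between: {22.5°, 112.5°}, {67.5°, 157.5°},
{202.5°, 292.5°}, {247.5°, 337.5°}) under repeated stratified 5-fold CV on
homogeneous trials (default 100 repetitions; per-repeat seeds derive from
one master generator), with fold models transferred to heterogeneous trials;
accuracies average over pairs and the BCD − WCD difference is reported.
Temporal generalization trains at bin t and tests at bin t′: for the IEM and
category SVM on the disjoint hom→het transfer (so the diagonal equals the
time-resolved transfer series exactly); for the variance SVM on stratified
random splits averaged over partitions.

## RSA

Trials of each of the 16 conditions are split into four trial-order-
stratified chunks (the CV folds); pseudo-trials average a random 25% of each
chunk (at least one trial), 500 per condition by default. Pairwise LDA
(least-squares solver with Ledoit–Wolf shrinkage, which keeps the
discriminant defined when neurons approach the pseudo-trial count) yields a
16 × 16 accuracy RDM per time bin. Model RDMs: mean = 1 − cosine similarity
of channel-basis response vectors, rescaled to [0, 1] (identical across
variance pairings); variance and category binary. Only upper-triangle
off-diagonal entries enter an OLS with intercept on the z-scored model
vectors. The mean and category models are intrinsically correlated
(cross-category pairs are also far apart in direction); the WCD/BCD contrast
exists precisely to break that collinearity.

## Cluster-mass permutation tests

Bin-wise t-tests at an uncorrected two-tailed p < 0.05 form contiguous
clusters (4-connectivity in 2-D); each cluster's mass (sum of t) is compared
against the permutation distribution of the maximum cluster statistic under
subject sign-flips (one-sample/paired) or group-label exchange (two-sample,
Welch t). P-values use the add-one rule (1 + #null ≥ obs)/(1 + n_perm);
positive and negative clusters are formed separately; cluster *extent* is
available as an alternative statistic. The 2-D test on a 1-bin-thick map
reduces exactly to the 1-D test. Under a pure null (10 subjects × 100 bins)
the family-wise false-positive rate is calibrated to the nominal 0.05 (see
the acceptance suite).

## Problem sizes and numerical choices

Defaults follow the study conditions (320-trial sessions, 5000 permutations,
500 pseudo-trials, 100 CV repetitions). The test and benchmark suites run
the same machinery at smaller sizes chosen for a single CPU: 20–40 neuron
populations, 500-permutation calibrations (200 null datasets), 40
pseudo-trials and ~10 CV repeats, 0.5 s analysis bins (decimation 15 of the
30 Hz frames), and 10 synthetic subjects for the group-level dissociation.
The RSA/WCD-BCD recovery subjects use a response amplitude of 0.003 dF/F —
much lower than the 1.0 used for single-cell analyses — because with
independent per-neuron noise (no information-limiting correlations) pairwise
decoding otherwise saturates at 100%, where the RDM regression carries no
information and accuracy compression loads spuriously on the category model.
Scaling down sizes changes statistical power, not the conditions being
tested.

Other numerical conventions: IQR with linear interpolation between order
statistics (thresholds bit-reproducible); tie-breaks toward the numerically
smallest direction, flagged; psychometric σ bounded in [0.5°, 10⁴°] with
perfect-separation and flat-data flags; d′ proportions clipped at 1/(2N);
all randomness flows through `numpy.random.Generator` objects, with
session-level seeds fanned out by `SeedSequence.spawn` so stages are
independently reproducible.

## Known limitations

* The generator's noise is independent across neurons; absolute decoding
  accuracies are therefore optimistic relative to real cortical data, and
  the chosen amplitudes should be read as placing analyses in realistic
  *accuracy* regimes rather than realistic dF/F regimes.
* The selective-neuron overlap test (binomial against the product of
  marginal proportions) is one reading of "chance level of overlap"; other
  nulls (hypergeometric conditioning) differ slightly at small counts.
* The linear mixed-effects modeling of d′ (stimulus type × difficulty ×
  session with subject random effects) is out of scope; `summarize_behavior`
  exports the per-subject d′ table shaped for external fitting.
* `pairwise_rdm` always applies shrinkage LDA rather than falling back on
  degenerate covariance; with very few neurons this is mildly conservative.
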