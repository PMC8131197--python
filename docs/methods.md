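# Methods

This note documents the models implemented in `catlearn`, their
assumptions, the defaults that matter, and the numerical choices made where
the design was genuinely open. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Task model and stimulus space

Stimuli are sinusoidal gratings on a factorial grid of orientations ×
spatial frequencies. The standard training grid is 6 × 6
(orientations [0, 15, 30, 60, 75, 90]°; spatial frequencies
[0.023, 0.027, 0.033, 0.06, 0.1, 0.25] cyc/°, 36 gratings); the dense probe
grid is 7 × 7 with levels that fall exactly on the category boundary
(orientations include 45°, spatial frequencies include 0.043 cyc/°,
49 gratings). A rule labels each grating Go or NoGo by thresholding one
feature at its boundary (45° or 0.043 cyc/°); on the standard grid each
rule splits the 36 gratings 18/18. In dense mode, gratings exactly on the
boundary belong to both categories: each presentation is assigned to a
random category, so a Go response to them is rewarded on half of the
trials. Outside dense mode, a boundary that coincides with a grid level is
rejected as ambiguous.

Distances to the boundary are measured on the **rank index** of the
relevant feature's levels, normalized to [−1, 1], not in raw units: the
orientation levels are linearly spaced but the spatial frequencies are
roughly geometric, and rank distance treats steps on either feature
symmetrically. The psychometric machinery and the choice model both use
this convention.

## Synthetic behavior

The generator emulates the Go/NoGo session structure with a logistic choice
model: P(Go) = σ(k·d), where d is the signed rank distance of the presented
grating to the boundary. The slope k is solved by root finding so that the
session's *expected* d′ — z(mean Go probability over Go gratings) minus
z(mean over NoGo gratings) — equals the requested target; the bias is zero,
which on the symmetric grids makes hit and correct-rejection rates mirror
images. Calibration uses only non-boundary gratings because session d′ is
defined on Go/NoGo-category trials. Empirical d′ is monotone in the target
and matches it to within sampling error (the suite checks ±0.2 at 2000
trials).

Stimulus order is pseudorandom with never more than three same-category
gratings in a row. This is enforced by constrained sequential sampling (the
fourth repeat is forced to the other category) with a mild self-balancing
term (gain 0.02 per trial of count imbalance) that keeps each category's
share within a few percent of one half in any window of a couple hundred
trials. Whole-sequence rejection sampling was rejected: for n trials the
expected number of ≥4-runs grows like n/16, so the acceptance probability
of a full random order vanishes already for a few hundred trials.

Licks on Go-choice trials are a Poisson burst (8 Hz for ~0.8 s) after a
lognormal reaction time; running speed is Gaussian per trial (6 ± 2 cm/s,
clipped at 0). Uninstructed behavioral predictors (pupil diameter, eye
position, …) are standardized AR(1) processes (lag-1 coefficient 0.9) with
an optional choice-locked component, purely to give the variance-partition
stage known structure.

## Synthetic neurons and the learning series

Each neuron belongs to one ground-truth class — Go- or NoGo-preferring
category (for rule 1 or rule 2), choice, reward, mixed (category + choice),
or untuned — and its trial-wise rate is

    rate = max(0, baseline + w·x + ε),  ε ~ N(0, noise_scale²)

with x the trial's binary category/choice/reward predictors and
standardized running speed. Defaults: baseline 1.0 a.u./s, selectivity
amplitude 1.0 a.u./s, noise_scale 0.25 a.u./s, 400 trials per session.
These were chosen once so that a planted unit-amplitude category cell is a
strong but not noiseless responder: with means ~1 vs ~2 and trial sd 0.25,
the exponential-likelihood decoder's threshold ln(2)/(1 − 1/2) ≈ 1.39
yields single-neuron accuracy around 0.96 — the regime of a clearly
category-selective cell. An exponential noise mode (rate drawn from an
exponential with the linear predictor as mean) exists for
decoder-consistency checks; the default stays rectified Gaussian because
the decoding stage assumes only that trial-averaged rates are well *fit*
by exponentials, not that they are generated that way.

The learning series simulates the eight imaging points T1–T8: full grid at
T1 (naive, d′ 0), growing per-category stimulus subsets (1, 3, 9, 18) for
rule 1 up to the generalization test at T5, then the rule switches and the
progression repeats (1, 9, 18) for rule 2. Stage subsets take the most
boundary-distant gratings per category, cycling across irrelevant-feature
levels. Per-stage d′ targets default to (0, 1.8, 2.0, 2.2, 2.5, 1.8, 2.2,
2.5); per-stage trial counts are configuration, not an asserted property.
Selectivity amplitudes are scaled per neuron by one of three characteristic
time-course templates over T1–T8 (all 0 at T1, max 1):

- **ad hoc** (choice/reward): (0, 1, 1, 1, 1, 1, 1, 1) — acquired with the
  first rewarded training, unaffected by the rule switch;
- **rule 1**: (0, 0.25, 0.5, 0.75, 1, 0.5, 0.25, 0) — grows with
  categorization demand, peaks at the rule-1 generalization test, decays
  after the switch;
- **rule 2**: (0, 0, 0, 0, 0, ⅓, ⅔, 1) — appears only during rule-2
  training.

Category drive always follows the *currently active* rule; the neuron's
rule identity lives entirely in its template. This matches how measured
selectivity behaves across the series (old-rule selectivity fades, new
selectivity appears) and makes template regression on measured selectivity
time courses a well-posed recovery problem.

The fluorescence generator expands trial rates into per-frame Poisson
spikes (3 s inter-trial interval, 1.3 s stimulus, 10 Hz frames), convolves
them with an AR(1) kernel (decay time 0.7 s), and adds a constant offset
(100 a.u.), a slow shared neuropil component scaled by the contamination
fraction (0.7), optional sinusoidal drift, and white noise. It does not
model indicator nonlinearity, saturation, pixel-level imaging, or motion —
so passing round-trip tests demonstrate correctness of the processing
chain, not robustness to those real-data artifacts.

## Behavioral metrics

d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate). Rates of exactly 0 or 1 are
clipped to 1/(2N) and 1 − 1/(2N) (N = trials of that category) before the
quantile transform — the standard psychophysics convention for perfect
sessions; the choice is documented here, not asserted as canonical. When
two imaging regions are recorded at one time point, the displayed learning
curve value is the mean of the two sessions' d′.

The fraction of correct Go choices is hits/(hits + false alarms); with no
Go choices it is undefined (an error, never 0). The session criterion is
*strict*: the first session with fraction > 0.66 counts, a session at
exactly 0.66 does not, and a never-reached criterion is reported as an
explicit missing value rather than a count.

Fraction-chosen maps report Go choices per presentation per stimulus;
unpresented stimuli are absent (NaN), never imputed as 0. Psychometric
curves average the map along the other feature's levels with equal
per-stimulus weight, so the mean of a curve over its levels reproduces the
grand mean of the map.

Learning curves are fitted with y(x) = p₁ + p₂/(1 + e^{p₃(x−p₄)}), p₁
frozen at 0 by default, via multi-start nonlinear least squares (5 starts
over slopes −2…−0.1 and inflection quantiles of the session range,
tolerance 1e−8); rule-1 and rule-2 segments are fitted independently by the
caller. Non-convergence of every start is flagged with an infinite RMSE
sentinel rather than an exception.

## Imaging preprocessing

Neuropil correction: F_c = F − r·F_neu + r·median(F_neu) with r = 0.7
(configurable). Re-adding the scaled median keeps the corrected trace at
its original baseline level so the ΔF/F denominator stays positive.
Dark-current subtraction and line-shift correction are collapsed into a
single configurable scalar offset, since raw-scanner artifacts are not
simulated.

ΔF/F = (F_c − F₀)/F₀ with F₀ the 25th percentile in a *centered* 60 s
sliding window, truncated at the recording edges (the alignment convention
was open; centered windows avoid a systematic baseline lag). A non-positive
baseline anywhere is an error instructing the caller to offset the trace.

Spike inference solves

    min_s ½‖Ks − y‖² + λ·Σs   subject to s ≥ 0,

with K the causal AR(1) convolution matrix, by an online
pool-adjacent-violators scheme that merges frames sharing one transient
(the L1 term folds into a shift of the observations). The per-frame decay γ
is estimated from the lag-2/lag-1 autocovariance ratio, clamped to
[0.5, 0.98], unless given. By default λ = 0 and small events are suppressed
by a greedy event floor s_min = 3× the noise sd estimated from the
high-frequency half of the power spectrum; s_min = 0 recovers the exact
convex solution, which the suite verifies against a brute-force
non-negative least-squares oracle on 50-frame traces (objective agreement
to 1e−6). No parity with any specific published deconvolution
implementation is claimed; hyperparameter defaults are documented, not
asserted as faithful to the original analysis.

Trial responses are the mean inferred rate over frames with timestamps in
the half-open stimulus window [on, off) — half-open so a frame on a shared
boundary is never counted twice. Lick-bouts are maximal runs of licks with
inter-lick gaps ≤ 500 ms (inclusive); lick-triggered averages drop
segments that would cross a recording edge.

## Category-tuning index

For per-stimulus mean rates r_i under a rule, *within* is the mean of
|r_i − r_j| over all unordered same-category pairs **pooled across both
categories** (the per-category weighting was open; pooling was chosen and
is flagged for sensitivity testing), *across* is the mean over
cross-category pairs, and CTI = (across − within)/(across + within).
"Mean difference" is taken as the mean of *absolute* pairwise differences:
only that reading gives the stated [−1, 1] range and the ideal-cell value
of 1. A silent or perfectly uniform cell (denominator ≤ 1e−12 relative to
the rate scale) is defined to have CTI 0. The implementation uses the
sorted-coefficient identity for pairwise sums and is checked against
explicit pair enumeration to 1e−12.

Selectivity requires CTI strictly above 0.1 (ties at the threshold are
excluded); preference is the sign of the Go-minus-NoGo trial-mean
difference, with exact ties left undefined and counted. At time points
where only part of the grid is presented the CTI is undefined; selectivity
is *approximated* by the contrast index
(mean Go − mean NoGo)/(mean Go + mean NoGo) and never mixed with full-grid
CTIs in one comparison. Population overlap between two selective sets is
tested against a null that redraws both sets' identities uniformly
(preserving their sizes) 1000 times with a fixed seed, reporting the 95th
percentile with linear interpolation.

## Bayesian decoder

Per neuron and category, p(r|c) is an exponential density whose mean is the
training-set sample mean (the MLE), floored at 1e−6 of the grand mean so
densities stay proper for silent cells. Priors default to training-set
category frequencies (a uniform option exists). Group decoding multiplies
per-neuron likelihoods — conditional independence across neurons, stated
explicitly as a modeling choice. Performance is the fraction of correctly
predicted test trials under stratified 70/30 splits, averaged over 100
repeats by default, with neuron subsets drawn without replacement per
repeat; the shuffle control permutes category labels before the split and
is otherwise identical. Exact posterior ties go to the first category and
are counted (`n_ties_`), keeping results reproducible. Decoding is
invariant to a common positive rescaling of all responses because the
exponential scale refits on the same data.

## Encoding models

The trial GLM is ordinary least squares of a neuron's trial-wise rate on
category (0/1), choice (0/1), reward (0/1) and continuous running speed; a
positive weight means more activity when the predictor is higher.
Per-predictor significance uses the partial F-test of dropping that
predictor from the full model. Rank-deficient designs are an error naming
the collinear predictors. Weight normalization has two explicit modes,
never inferred: rule-switch analyses divide by the sum of absolute weights
*including the intercept*; task-change analyses divide by the maximum
weight.

Clustering of normalized weight vectors includes only neurons with
R² > 0.05. Linkage is agglomerative with Euclidean distance and single
linkage by default (mirroring the default of the cited clustering routine;
Ward is available). The number of clusters is the smallest k with
Gap(k) ≥ Gap_max − s.e.(Gap_max), where Gap(k) = E*[log W_k] − log W_k,
W_k is the within-cluster dispersion (summed squared distances to cluster
centroids), the expectation runs over B = 100 uniform reference draws on
the observed per-feature bounding box, and s.e. is the reference sd scaled
by √(1 + 1/B).

The task-change model concatenates the Go/NoGo generalization session and
the left/right session and runs forward–backward stepwise OLS over
{category, Go (any lick), reward, GoRight, GoLeft}, with F-test entry at
α = 0.05 and removal at α = 0.10 (forward-only vs forward-backward was
open; forward–backward was chosen, and the removal threshold is a
documented convention). GoRight/GoLeft are 0 for all Go/NoGo-session
trials; missed left/right trials carry Go = GoRight = GoLeft = 0, enabling
the category-without-choice contrast. A neuron is "uniquely
category-modulated" when category is selected and no choice/motor
predictor is.

Variance partitioning uses 10-fold cross-validated R² at the trial level
(fold count was open; 10 is a documented default). For predictor group g,
cvR²(g) is the CV R² of the model with every *other* group trial-shuffled
(its maximum predictive power), and ΔR²(g) is the full-model CV R² minus
the CV R² with *only* g shuffled (its unique contribution). Shuffling
permutes trial labels jointly within a group — grouped shuffling was
chosen for the multi-column body/eye parameters — and results average over
10 permutations. Constant predictors get 0 for both quantities, with a
warning. ΔR² of an irrelevant predictor is centered at 0 and can be
slightly negative through CV noise; shared variance between correlated
predictors appears in both cvR² values but in neither ΔR².

## Pipeline

The `catlearn` CLI chains simulate → behavior → selectivity → decode → glm
→ report inside one output directory. Trial tables are CSV with a JSON
rule sidecar; arrays live in an HDF5 container (`/rates`, `/fluo/F`,
`/fluo/Fneu`, `/events`, frame-rate and seed attributes); the manifest
records the configuration hash and SHA-256 checksums of every output, and
re-running with an unchanged configuration skips stages whose outputs
verify — runs are byte-reproducible under a fixed seed. Exit codes: 0 ok,
2 configuration error, 3 data error.

## Problem sizes in the test suite

The suite exercises the chain at desk scale: sessions of 100–2000 trials
(42,000 for the boundary-reward measurement, to collect >10,000 boundary
presentations), populations of 100–500 neurons, learning series of 8 × 250
trials with 120 tracked neurons, 100-seed recovery ensembles for GLM
weights and sigmoid fits, 400–1000-seed ensembles for stepwise type-I
calibration, and 50-frame traces for the exact deconvolution oracle. These
sizes make every statistical check stable at its stated tolerance while
the whole suite runs in well under a minute per module.

## Known limitations

- The deconvolution is a convex AR(1) approximation with a greedy event
  floor; it does not reproduce any specific constrained-deconvolution
  implementation's hyperparameters.
- The generator's neurons are linear-rectified with stationary noise; real
  populations show adaptation, correlated noise, and nonstationary
  baselines that none of the recovery results here speak to.
- The behavioral model has no lapse/bias parameters beyond the calibrated
  logistic; reaction times are decorative.
- Biological findings from the original recordings (fractions of selective
  cells, Go/NoGo splits, unique category modulation percentages) are
  properties of real data; the generator's presets only mirror their
  structure and nothing here reproduces those numbers.
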