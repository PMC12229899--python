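# Methods

This note documents the models, parameter choices and numerical decisions
behind `rewardremap`, in the order the pipeline runs. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic sessions

The generator (`rewardremap.synthetic`) emulates the hidden-reward-zone
switch task at the level the analyses consume: per-frame behavior and
per-neuron activity at 15.5 Hz, with full trial structure.

**Behavior.** Each trial is a 450-cm traversal. Running speed is a base
speed (per-trial draw ~N(45, 4) cm/s) scaled down by a Gaussian slowdown
(depth 0.7, s.d. 25 cm) centered just after the reward-zone start, plus
frame noise; after reward delivery the animal pauses (~1 s at <2 cm/s) to
consume. Licking is Bernoulli per frame: baseline 0.015, ramping to ~0.58
across the 50-cm anticipatory window, 0.55 inside the zone before reward,
0.8 during consumption. Reward is delivered at the first in-zone lick (at
the zone end if the animal never licks), withheld on omission trials
(default probability 0.15, drawn per trial). Trials end in a teleport
period of uniform 1–5 s (5–10 s after omissions) during which position is
undefined but running continues. The zone switches after trial 30 by
default. `behavior_remap_trial` and `neural_remap_trial` let the overt
behavior or the neural map adopt the new zone on a different trial than the
actual reward switch, which is how behavioral-lag study conditions are
constructed.

**Neurons.** Each neuron belongs to exactly one tuning class. Tuned classes
fire as a circular Gaussian bump (s.d. 20 cm) over track phase, with a
per-trial multiplicative lognormal gain (σ = 0.3) and per-trial Gaussian
field jitter (s.d. 10 cm — large enough that spatial peaks are estimable
but noisy, which exercises the shuffle tests near threshold). RR cells
anchor the bump at a fixed reward-relative phase (60% of anchors drawn
from (0, 1.5] rad to reproduce post-reward over-representation); TR cells
at a fixed track phase; appearing/disappearing cells gate their amplitude
by epoch; random-remap cells draw independent anchors per epoch; untuned
cells fire at ~0.5 Hz everywhere; speed-coupled cells (putative
interneurons) fire proportionally to running speed. Peak rate defaults to
8 Hz on top of a 0.05-Hz baseline — event counts are Poisson draws per
frame. ΔF/F is the event train filtered by a single-exponential calcium
kernel (τ = 0.7 s — one plausible indicator decay; configurable) with
additive Gaussian noise (σ = 0.05).

**Randomness.** One `SeedSequence` per session spawns separate behavior and
per-neuron substreams, so adding neurons never perturbs the behavior and
sessions are bit-reproducible.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: optical artifacts (neuropil contamination, motion
residuals, bleaching), deconvolution error (event rates are generated
directly), non-Poisson burst statistics, theta-timescale structure,
experience-dependent plasticity within an epoch (fields are stationary
apart from gain/jitter), and the slow behavioral learning curve (the
simulated mouse licks well from trial 1, and switches its behavior in a
single step rather than gradually). Recovery rates measured on it
characterize the pipeline's statistical machinery, not biological effect
sizes.

## Signal processing

ΔF/F uses a maximin baseline per trial: centered rolling minimum then
rolling maximum over a 20-s window, windows truncated at trial edges (edge
behavior is a choice; truncation avoids borrowing samples across the
teleport). ΔF/F = (F − baseline)/|baseline|, guarded where the baseline is
exactly 0 (value set to 0 and flagged), then smoothed with a 2-sample
(~0.13 s) Gaussian. Spatial binning averages samples within each 10-cm bin
per trial — the mean over samples is occupancy normalization — excluding
frames below 2 cm/s and teleport frames; unoccupied bins are NaN, never 0.
Bins are half-open [lo, hi) with position 450 cm wrapping to bin 0.
Tuning-curve smoothing uses circular (wrap-mode) Gaussians, consistent with
the periodic coordinates.

Correlation matrices z-score each trial across its spatial (or
spatial × neuron) profile and form `AAᵀ/(m−1)`; single-cell matrices are
smoothed at 20 cm s.d., population matrices at 10 cm s.d. Profiles with
NaN bins fall back to pairwise-complete Pearson correlation rather than
fabricating zeros. Neurons whose ΔF/F correlates with running speed at
r > 0.5 are excluded as putative interneurons; constant traces (undefined
r) are kept and flagged.

## Place cells

SI is computed from deconvolved-event tuning with occupancy from the whole
session (per-trial occupancy probabilities averaged across trials, so long
trials do not dominate); both occupancy and activity use the ≥2 cm/s
filter. The null circularly shifts each trial's activity relative to
position by an independent offset between ⌈frame rate⌉ samples (~1 s) and
the trial length, 100 shuffles per cell, and pools the null across all
cells of the session; a cell is significant when its true SI exceeds the
pooled 95th percentile. Pooling is what calibrates the false-positive rate
(the acceptance suite verifies 2–9% on 500 untuned cells) while remaining
more stringent than per-cell nulls for weakly active cells, whose SI
estimates are upward-biased at low rates. Trial sets are pre-/post-switch
(session halves on non-switch days); a place cell is significant in either
set. Spatial peaks use unsmoothed trial-averaged binned ΔF/F, argmax with
ties broken to the lowest bin.

## Remapping classification

Periodic coordinates map 0 cm to −π and 450 cm to π, so 50 cm is
0.698132 rad; all "≤50 cm" thresholds are evaluated in phase space.
Reward alignment rotates the zone start to phase 0; because zone starts are
multiples of the bin width, alignment is an exact circular roll of bins.

The taxonomy: TR — significant both sets, track peaks ≤50 cm apart;
disappearing — significant before only and mean post ΔF/F below the median
of per-trial pre means; appearing — significant after only and mean post
above pre mean + 1 s.d.; remap-near-reward — significant both, each epoch's
peak within 50 cm of that epoch's zone start; remap-far — significant
both, neither TR nor near-reward. RR cells additionally satisfy: (1)
reward-relative peaks ≤0.698 rad apart, and (2) the circular
cross-correlogram of reward-aligned trial-averaged ΔF/F peaks above the
97.5th percentile of a null (each post-switch trial circularly shifted by
1–44 bins, 500 shuffles) at |lag| ≤ 5 bins. A 45-bin shift on a 45-bin
circle is the identity, so the null's offsets stop at 44. RR takes
precedence over remap-near/far and appearing/disappearing (cells with
reliable reward-locked structure are reassigned RR); TR is never
reassigned — on this track geometry the smallest zone shift (120 cm)
exceeds the 50-cm windows, so the two labels cannot genuinely collide.

The population chance test keeps cells significant in both sets, removes
putative TR cells, and compares the count of reward-relative peak shifts
within ±0.698 rad to a null that keeps each pre peak and shifts the post
tuning by a uniform 0–44 bins. The above-chance fraction is
(true count − mean shuffle count)/N_place, significant when the true count
exceeds the shuffle's 95th percentile. Shifting the averaged tuning curve
is used rather than per-trial shifts: a rigid shift moves the argmax with
it, making the two equivalent for peak-based statistics at 1000× lower
cost.

## Sequences, ROI matching

Sequence sorts come from odd pre-switch trials and are evaluated on even
pre-switch and post-switch trial averages (unsmoothed ΔF/F, circular track
coordinates). Order preservation is the Jammalamadaka–SenGupta
circular–circular correlation; its significance is a cell-identity
permutation test, `P = (n_{|ρ_shuf|≥|ρ_obs|} + 1)/(N_perm + 1)`, two-tailed,
1000 permutations (floor 1/1001). Density curves are smoothed (1-bin
Gaussian) for plots only, never before statistics. Cross-day ROI matching
is greedy by pixel IoU with the best-vs-second-best acceptance rule: a
match is kept only when its IoU strictly exceeds every competing
second-best for both ROIs. Cross-day sequence statistics require ≥5
followed cells.

## Decoding

The decoder is linear ridge regression (λ = 10⁻³, unpenalized intercept)
from population event rates onto (cos y, sin y) with an atan2 readout — a
deliberately simple parameterization of circular–linear regression; an
iterated circular regression would be the natural alternative and was not
needed at the SNRs tested. Samples are restricted to >2 cm/s and
occupancy-matched by seeded downsampling to the minimum count across the
45 RR-phase bins. `within_before` runs 10-fold cross-validation inside the
pre-switch trials; `before_after` trains on pre-switch and tests on the
last 30 post-switch trials (matching trial counts). The null refits the
whole protocol on 100 datasets in which each cell's time series is
independently circularly shifted by ≥1 sample; scores are z-scored against
this null overall and per RR bin. On short, highly regular simulated
sessions a circular shift can leave residual spatial tuning (the lap
structure is nearly periodic in time), which biases the shuffle scores of
cross-epoch decoding; at the default 80-trial scale with jittered teleports
this effect is negligible.

## Place fields

Fields are contiguous regions ≥20 cm of the 10-cm-smoothed trial-averaged
event tuning above 20% of its max. Reliability requires the cell to be
significantly active in the field in ≥8 of the 30 trials, where a trial is
active when any raw in-field sample exceeds the pooled in-field
mean + 1 s.d. An alternative rule — comparing per-trial *mean* in-field
activity to that threshold — rejects steady fields wholesale (a constant
signal never exceeds its own mean + 1 s.d.), so the sample-level rule is
used. The same logic means the self-referential threshold detects *changes*
in activity; a cell equally active on every trial has no identifiable
formation lap, which is the intended semantics of a formation analysis.
Formation laps use per-trial mean activity within the field ±10 cm,
threshold mean + 1 s.d. across the post-switch trials only (pre-switch
statistics describe a different map), first 5-trial window with ≥3 active
trials, returning the window's first active trial. Field COM shifts use
raw sample-level activity-weighted positions within the bounds (maximum
spatial resolution); shift = COM(last 30 trials) − COM(formation lap),
negative = backward.

## Trial warping and the RO index

Warping aligns trials on the position-bin axis with monotone
piecewise-linear maps of increasing complexity: shift, linear, and 1–3
interior knots (uniform fixed knot x-positions, free monotone y-values,
which makes each family contain the previous one). Fitting alternates
per-trial multi-scale coordinate descent (21 candidates per parameter,
search range halving each sweep) with template updates (mean of warped
trials), 15 alternations, 10 restarts, and each family warm-starts from the
previous family's solution — so the fitted MSE is non-increasing from shift
to piecewise-3, the property the model-selection analysis relies on. No
regularization beyond monotonicity is applied. Rewarded and omission trials
are fit jointly on speed profiles; the fitted warps are then applied
(linear interpolation, edge clipping) to the neural tensor — the warp never
sees the neural data. The RO index sums warped trial-averaged activity over
bins from the zone start to the track end; eligibility requires ≥3 omission
trials and (when peaks are supplied) a spatial peak at or beyond the zone
start. RO is worth computing on both warped and raw activity; the pipeline
reports the warped version and the raw one is one `apply_warp`-free call
away.

## Poisson encoding model

The design matrix is exactly 156 columns: 45 circular raised-cosine bases
(half-width 1.5 bin widths, unit-sum normalized) for track position and
for RR position; the position bases multiplied by the rewarded indicator
(1 from reward delivery to trial end, 0 throughout omission trials); and
7 cubic B-spline bases (5 knots) on the quantile-transformed speed,
acceleration (both pre-smoothed with a 5-sample Gaussian) and lick rate
(2-sample Gaussian). Teleport frames are excluded. Columns are z-scored
with statistics from the training split only, to avoid leakage.

Fitting is ridge-penalized Poisson regression (log link) solved jointly
for all neurons by L-BFGS with analytic gradients and warm starts along a
4-value penalty path (0.03–30), the penalty chosen per neuron by fivefold
cross-validated deviance inside an 85/15 trial-grouped split stratified
over rewarded-before/rewarded-after/omission trials. An L1 component was
considered and rejected: with heavily overlapping cosine bases the ridge
solution is stabler, and the ablation statistic needs no sparsity. FDE =
1 − dev_model/dev_null on held-out trials, null = constant training-mean
rate; constant cells (dev_null = 0) are defined to have FDE 0 and flagged.
Ablation zeroes one variable group's coefficients in the stored CV-fold
models (no refit) and evaluates
(dev_ablated − dev_full)/(dev_null − dev_full) on the fold validation
data, overall and per 10-cm track bin; downstream summaries keep cells
with FDE > 0.15.

## Remap-trial detection

Population tensors (10-cm-smoothed events, each neuron min–max scaled over
the session; constant neurons set to 0 and flagged) are clustered by
k-means with k = 2 over trials, best of 100 restarts, cluster 1 relabeled
to the first cluster appearing in the session. Model validity uses a
speckled (element-wise) 10% holdout over 50 repetitions: centroids are fit
with observation-weighted Lloyd iterations on the observed entries and
scored by uncentered R² on the held-out entries, against a null that
applies a Haar-random orthogonal rotation across the trial axis; sessions
pass when real beats null by a one-sided Wilcoxon signed-rank test at
P < 0.05.

The distance score projects each trial's population vector onto the
inter-centroid axis, scaled to −1 at the first centroid, +1 at the second
and 0 at the midpoint:
`P_i = 2 (X_i − (V1+V2)/2)·(V2−V1) / ‖V2−V1‖²`. A 4-parameter logistic
`a + (b−a)/(1+exp(−s(t−t₀)))` is fit to the score series (bounds
t₀ ∈ [0, n_trials−1], s ∈ (0, 50]; initialized at the largest score step);
t₀ is the remap trial. Fits whose step |b−a| ≤ 0.2 or whose series is
nearly flat are flagged non-converged and excluded, as are sessions where
any of the population-vector, licking or speed fits fails. Licking and
speed maps run through the identical scale → cluster → score → sigmoid
pipeline, and lags are reported as the neural *lead* (behavioral remap
trial − neural remap trial; positive = the map updates first). The
silhouette comparison of k = 2 vs 3–4 is available as a diagnostic through
`factorized_kmeans` with other k.

## Problem sizes

Default analysis conditions are the task's: 80 trials, switch at 30, 45
bins, 100 SI shuffles, 500 cross-correlogram shuffles, 1000 permutations,
100 decoder shuffles, 100 k-means restarts. The test suite's recovery
checks run five 400-neuron sessions for classification, one 80-cell
session for decoding, ten 40-cell sessions for remap timing, and one
20-cell session for the GLM — sizes chosen so the whole suite completes in
a few minutes on one core while keeping binomial error well inside the
asserted margins.

## Known limitations

- The decoder's shuffle null inherits temporal regularity from the
  simulator (see Decoding); real sessions with variable lap durations are
  closer to the intended null.
- The warp optimizer is a desk-scale coordinate-descent implementation;
  it is deterministic and respects model nesting but is not tuned for
  hundreds of trials times thousands of bins.
- Cross-day analyses operate on caller-supplied masks/labels; the
  simulator does not generate multi-day sessions with ROI turnover.
- The GLM's movement regressors are quantile-transformed per session, so
  coefficients are comparable across sessions only in rank, not in
  physical units.
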