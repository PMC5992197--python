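# Methods

This note documents the models and procedures implemented in `mazerecall`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The analysis problem

Rats learn reward rules on a Y-maze (three symmetrical arms, 85 cm long,
separated by 120°). After every trial the animal makes a self-paced return
from the chosen goal arm to the start arm — the inter-trial interval (ITI).
The analyses ask whether medial prefrontal cortex population activity
during ITIs carries a reinforcement-gated short-term memory signature:

1. does a similar pattern of pairwise neuron co-activity recur across ITIs,
   preferentially after rewarded trials (recall analysis)?
2. when does that recalled pattern appear and disappear within a session
   (change-point analysis)?
3. does behaviour show an abrupt learning transition, and where (behavioural
   analysis)?
4. which task features — previous or next outcome, arm choice, light-cue
   side — can a linear decoder read out from ITI firing-rate vectors, and at
   which maze positions (decoding analysis)?

## Recall analysis

**Core population.** Only neurons with at least one spike in every ITI are
analysed (`core_population`; the threshold is configurable). This fixes the
matrix dimension across intervals, which the pattern comparison requires.

**Spike-density functions.** Each spike train is convolved with a Gaussian
kernel (σ = 100 ms by default; the σ-sweep range is 20–240 ms) and sampled
on a per-interval grid with dt = 10 ms. Kernels are evaluated analytically
at grid points and truncated at 6σ (relative error < 2·10⁻⁸); no padding is
applied beyond interval edges. Densities are z-scored per neuron with mean
and SD pooled over all ITIs (`zscore_over_itis`). Because the Pearson
correlation within an interval is invariant to any per-neuron affine
transform, this normalisation cannot change a similarity matrix; the
engine therefore correlates raw densities directly and the z-scoring op is
exposed (and tested) as an explicit inspection step.

**Similarity and recall.** For ITI t, S_t(i,j) = max(0, Pearson correlation
of neurons i and j's densities within t) — rectified so that recall
measures *co-activity*, not shared anti-correlation. The recall value
R(t,u) is the rectified Pearson correlation between the upper-triangle
vectors of S_t and S_u; over all ITI pairs this forms the recall matrix R.
A neuron constant within one interval gets zero similarity entries there
(dimension is preserved); a constant upper-triangle vector gives recall 0
with a warning.

**Duration null and residual recall.** ITIs after correct trials are much
longer than after errors (the animal lingers at the reward site), which
biases similarity estimates. The null model re-orders each spike train's
inter-spike intervals within each ITI (first spike anchored at its original
offset), preserving spike count, ISI multiset, and duration while
destroying cross-neuron temporal alignment. The expected recall matrix is
the mean over 1000 such shuffles (configurable; the validation experiments
use 20–100 to keep runtimes practical), and the residual recall matrix is
R̃ = R − R̂, with entries in [−1, 1].

**Group comparisons.** ITIs are grouped by prior outcome, prior arm, prior
cue, next outcome (last ITI excluded), or a median split of return-path
length. Block values are the within-group interval pairs — by default the
off-diagonal upper triangle of each group's block; a full-block option
(including the diagonal) is provided because the source convention is
ambiguous (its reported pair counts imply full blocks, but one printed
count, 17×17 = 238, is internally inconsistent). Δ_R is the difference of
block means, and a two-sample KS test (asymptotic) compares the block
distributions. Note that recall pairs sharing an ITI are not independent,
so these p-values are descriptive rather than exactly calibrated.

**Cross-session test.** Given per-session Δ_R values and a distinguished
subset (e.g. learning sessions), the permutation test draws subsets of the
same size without replacement (10,000 times by default) and reports the
fraction in which all drawn sessions have Δ_R > 0 — the Monte-Carlo version
of the hypergeometric probability C(k,m)/C(n,m).

**Reward site vs return trip.** Each ITI can be clipped to the dwell within
a disc (default radius 10 cm, first-exit convention) around the chosen
goal-arm end, or to the remaining return trip, and the recall pipeline
re-run on the clipped intervals.

## Change-point analysis

With the residual recall matrix in trial order, each admissible dividing
ITI s (≥3 ITIs strictly before, ≥5 from s on) splits the recall pairs into
those among earlier and those among later ITIs. The signed KS distance
sup[F_before − F_after] measures an increase of recall at s (and its
negation a decrease). The onset is the split with the maximum increase
distance among those whose one-sided KS p passes a Bonferroni-corrected
α = 0.05 (ties → earliest); the offset likewise for the decrease. Onset and
offset are searched independently; their ordering is reported, not
enforced.

Two departures from the naive sweep were necessary. Without correction the
family-wise false-positive rate on structureless matrices approaches 50%
(≈37 dependent tests at α = 0.05). And because admissible splits range from
~3 to ~1000 pairs per side, the *unnormalised* maximum distance is
dominated by the chance sup-ECDF inflation of tiny samples at the sweep
edges; the Bonferroni screening removes exactly those splits, after which
the maximum distance with earliest-tie-break identifies a perfect step at
its first elevated interval.

## Behavioural analysis

`cumulative_reward` is the running count of correct trials. The original
learning-trial criterion selects the first of three consecutive correct
trials from which performance is ≥80% correct through session end (the
threshold window includes those three trials; a config flag moves the
window start past them, since the source description is ambiguous). The
steepest-change criterion fits two regression lines to the cumulative curve
on each side of every candidate split (≥5 trials per side) and selects the
split maximising r_after − r_before.

Reported slopes default to Huber-loss IRLS (statsmodels RLM), the standard
robust fit. The split *search* defaults to plain least squares: cumulative
count curves have bounded increments and no outliers, and a resistant
estimator downweights the mis-assigned minority of a mixed segment, so the
slope-increase objective plateaus across several splits instead of peaking
at the true change point (a Theil–Sen slope is worst; Huber still plateaus
over ±2 trials). On a noiseless two-slope curve the detected split is the
kink trial — the last point shared by both segments.

Sessions are classified `learning` (original criterion met),
`minor_learning` (some admissible split has a positive slope increase), or
`other`. Two inherent limitations of the original criterion, measured by
the test suite at stationary 50% performance: a lucky final correct triple
alone satisfies it (≥12.5% false-positive floor), and the realised outcome
sequence's own steepest inflection can sit a few trials away from the
generating transition, bounding split-recovery precision.

## Decoding analysis

The ITI return path (chosen goal-arm end → choice point → start-arm end,
170 cm) is linearised into five equal-length sections; section 1 is the
goal-arm end and section 3 is centred on the choice point. Tracking samples
farther than 15 cm from the skeleton are unassigned. Per ITI and section,
the decoder input is the core population's firing-rate vector: spike counts
within the section's 30 Hz frame occupancy divided by the occupancy;
zero-occupancy (ITI, section) cases are excluded from that section for both
true and shuffled fits.

Four deterministic linear decoders are provided: logistic regression (ridge
penalty C = 1 so separable data keeps finite weights; threshold 0.5), LDA,
linear-kernel SVM, and 1-nearest-neighbour. Accuracy is leave-one-out
cross-validated; chance is the same LOOCV on label permutations (50 by
default), and relative accuracy = accuracy − mean(chance), which absorbs
the class imbalance of the animal's own behaviour. Single-neuron tuning at
a section is a per-neuron two-sample KS test between label groups
(α = 0.05).

## Synthetic sessions

The generator produces the statistical structure the analyses assume, with
ground truth for recovery tests:

* **Behaviour.** Outcomes are Bernoulli with p_correct switching from
  `p_correct_before` to `p_correct_after` at a configurable learning trial;
  cues are fair coins; arms follow deterministically from rule, cue and
  outcome. Trials last ~4 s. ITI durations are gamma-distributed
  (shape 4 — positive and right-skewed, matching lingering at the reward
  site) with outcome-dependent means, 79.1 s post-correct and 48.4 s
  post-error by default.
* **Tracking.** 30 Hz positions along the maze skeleton: outward run during
  the trial, a reward-site dwell (50% of the ITI after correct trials, 25%
  after errors), then a constant-speed return. Optional isotropic jitter on
  the return; with zero jitter the travelled return path is exactly the
  170 cm skeleton length.
* **Spikes.** Inhomogeneous Poisson on a 10 ms grid, rates lognormal
  (median 1.5 Hz, clipped to 0.4–10 Hz) unless given. The *gated ensemble*
  multiplies member rates by exp(c·z(t) − c²/2), z an Ornstein–Uhlenbeck
  latent with 100 ms correlation time and unit variance, only during ITIs
  that follow a correct trial and fall inside `ensemble_window` — the
  reinforcement-gated co-activity the recall analysis targets. Tuning rules
  multiply chosen neurons' rates in chosen maze sections of ITIs whose
  retrospective/prospective feature matches, for the decoding analyses.
  Spike times are quantised to the 0.1 ms recording resolution.
* **Background co-fluctuation.** All neurons additionally share a weak
  outcome-independent OU-driven log-rate modulation with per-neuron weights
  (`background_coupling`, default 0.4 — pairwise density correlations of
  roughly 0.01–0.05, the order of cortical noise correlations). This is
  deliberate: for *independent* Poisson trains the expected recall between
  two intervals is essentially duration-independent (the 1/duration scaling
  of the rectified-similarity pattern and of the estimator noise cancels),
  so a population with no shared structure at all shows no duration bias
  for the residual correction to remove. The bias arises when a real, weak,
  outcome-independent co-activity pattern is estimated more reliably in
  longer intervals — the background term supplies exactly that. Its
  corollary, stated openly: an ISI shuffle cannot reproduce cross-neuron
  structure, so the expected-recall matrix removes only the
  count/duration-driven component, and the residual Δ_R on such null
  sessions is centred near, not exactly at, zero.

Randomness is a single master seed split deterministically into behaviour,
tracking, and spike streams; identical seeds give identical sessions.

What the generator does **not** emulate: place-field maps and realistic
spatial codes (tuning is piecewise-constant per section), bursting and
refractory structure, non-stationary rates across a session other than the
configured gating, sleep/rest epochs, and electrode drift. Passing recovery
tests therefore show the estimators behave correctly under the assumed
statistical structure, not that the biological claims hold in real
recordings.

## Numerical choices and problem sizes

* Density grid dt = 10 ms; kernel truncation 6σ; all similarity algebra in
  float64. The density accumulation uses a numba-jitted kernel with a pure
  numpy fallback (cross-checked in the tests to ~10⁻⁸).
* KS p-values: asymptotic two-sample formula for block comparisons; exact
  one-sided small-sample p-values inside the change-point sweep.
* Validation experiments run at reduced problem sizes chosen once: 12-neuron
  populations, 16–45 trial sessions, 20–100 ISI shuffles, 20 label
  shuffles, 4000 permutation draws. The package defaults remain at the
  full-scale values (1000 ISI shuffles, 50 label shuffles, 10,000
  permutations).
* The cross-session permutation test vectorises subset draws via
  `argpartition` on uniform keys.

## Known limitations

* Recall pairs sharing an ITI are dependent; KS p-values on blocks of pairs
  are therefore liberal. The change-point sweep's Bonferroni correction is
  computed against the same liberal per-split p-values; its false-positive
  rate is calibrated on i.i.d.-valued matrices, and full null *sessions*
  (with background co-fluctuation) retain a modestly higher detection rate.
* The residual recall correction removes duration/count effects only (see
  above); claims of outcome-specific recall rest on the contrast between
  groupings, not on the residual being exactly centred.
* The original learning-trial criterion has an irreducible false-positive
  floor from end-of-session correct runs.
* The file schema cannot represent a neuron with zero spikes in a session.
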