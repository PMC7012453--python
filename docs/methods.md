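# Methods

`funcgroups` implements a single-trial analysis of population calcium
imaging built around *functional groups*: sets of neurons whose measured
pairwise coactivity, rather than the stimulus or locomotion, carries most of
the information about a target neuron's moment-to-moment fluorescence.  The
pipeline has five stages — simulate, graph, encode, permute, decode — each
usable in isolation.

## Functional weights and lags

For a pair of neurons (x, y) and one stimulus block (trial), the
**trial-specific partial correlation** is computed from the 5×5 correlation
matrix Ω of: the two trial traces, each neuron's leave-one-out trial-mean
trace (its stimulus-locked component, estimated from all *other* blocks at
the same within-block frame positions), and the within-trial population mean
excluding the pair (global/locomotor state):

    ρ_xy = −(Ω⁻¹)_xy / sqrt((Ω⁻¹)_xx (Ω⁻¹)_yy)

The **functional weight** is the mean of ρ_xy over blocks; it is a
noise-correlation-like quantity, conditioned on stimulus and population
state.  Numerical choices: Ω gets a ridge of 1e−8·I when its condition
number exceeds 1e12 (near-duplicate series otherwise blow up the precision
matrix); a still-singular Ω yields weight 0 with a logged degeneracy flag;
zero-variance series raise a degenerate-input error and exclude the block
from the mean.  The vectorized all-pairs path assembles every pair's Ω from
per-block Gram matrices and is tested to agree with the scalar definition to
machine precision.

The **functional lag** of a pair is the argmax over integer lags in
[−17, +17] frames of the Pearson cross-correlogram of the two *block-mean*
traces (each lag computed on mean-subtracted overlapping segments; the
normalization is our choice, the correlogram itself being standard).  The
lag's sign orients the edge (positive: y follows x); lag 0 marks a
bidirectional edge.  Ties go to the smallest |lag| and then to the positive
lag — an explicit tie policy because the argmax is otherwise ambiguous on
exactly periodic or duplicated traces.

Every unordered pair carries exactly one edge.  **Strong** edges are those
with |weight| at or above the 75th percentile of pooled magnitudes
(inclusive of ties).  A neuron's **functional group** is the set of sources
of edges directed toward it; bidirectional edges count for both endpoints.

## Encoding-model ladder

Each neuron's normalized trace is modeled as

    r_i(t) = c + β₀·W_i⁰ᵀr(t) + β₁·W_i¹ᵀr(t−1) + Ψ·s(t) + Γ·v(t) + ε_t

where W_i⁰, W_i¹ hold the measured incoming weights at lags 0 and 1 (lags
above 1 are rare and excluded by default; an all-lag control refits with all
18 lag features).  The coupling weights are *data*, not parameters: only the
five scalars (c, β₀, β₁, Ψ, Γ) are fitted, by ordinary least squares on a
training split.  Default split: 70/30 by whole blocks, earliest blocks to
train; a seeded random-block mode and a presentation-granularity 50/50 split
(equal presentation counts per label in each half) are provided.  The first
frame of each block is excluded from fitting and evaluation because the
lag-1 feature is undefined there; lagged features never cross block
boundaries.

Stimulus term, two models: (a) **average response** — per-direction training
mean for tuned neurons, the mean of the 12 per-direction means for untuned
neurons, 0 on grey frames; (b) **block-averaged trace** — the framewise mean
over a split's presentations of the same direction, preserving
within-presentation dynamics; grey frames are excluded entirely under this
model and averages are taken within the split being evaluated.  Tuned flags
come from the simulation's ground truth when available; otherwise a
surrogate one-way ANOVA across the 12 directions on per-presentation mean
responses (α = 0.01) stands in for the original tuning-significance
procedure, which is out of scope.  Running term, two models: the rotary
encoder speed, or the average population trace with the target neuron
excluded.

Variants: stimulus-/run-/coupling-restricted (drop one term), LM₀/LM₁ (one
coupling lag), LM⁺/LM⁻ (one coupling sign; all lags treated as lag 0),
all-lag control, a nonnegative refit (term coefficients ≥ 0 via bounded
least squares; the intercept stays free because it models baseline
fluorescence), and Gaussian GLMs with reciprocal (1/Y = Xβ) and cube
(Y³ = Xβ) links fitted by IRLS.  The reciprocal link floors the linear
predictor at 1e−6 before inverting; a diverging IRLS is flagged and falls
back to an OLS fit of the linked response, so a non-convergent variant still
reports a usable (bad) MSE rather than dying.  Each variant's importance is
the per-neuron percent change in test MSE relative to its baseline model
(the unrestricted LM; the nonnegative run-restricted variant baselines
against the nonnegative unrestricted fit), summarized by the population
median and IQR, over all frames or restricted subsets (stimulus frames,
running frames with v(t) > 0, the first ⌈frame-rate⌉ frames of each
presentation).  The least-squares nesting property — adding a term can never
raise training MSE — is checked on every suite run.

## Permutation stress tests

Strong edges are pooled across all functional groups and shuffled two ways:

- **weights**: a uniform permutation of the (weight, lag) pairs over the
  strong edges; topology fixed, bidirectionality follows the permuted lag,
  and a directed edge receiving a nonzero lag keeps its stored orientation.
- **edges**: a uniform permutation of the strong edges' terminal neurons;
  each (weight, lag) stays attached to its source, so functional-group
  memberships change while per-source strong multisets are preserved.

Collision policy for the edges scheme: because the estimated graph carries
an edge for every pair, full rejection sampling of collision-free
permutations is infeasible (the no-collision probability is essentially zero
once strong edges outnumber neurons).  Instead, assignments that would
create a self-edge are repaired by swapping targets with another randomly
chosen strong edge; two strong edges landing on the same directed slot
simply sum in the incoming-weight matrices; and the weak edge on a landing
pair is superseded for that permuted graph.

Without refitting (default 1000 permutations; 200 in the shipped acceptance
run), the original unrestricted coefficients are applied to the permuted
coupling features and the percent change in *training* MSE is recorded —
refitting would let the coefficients absorb the shuffle.  The headline
summary is the median over permutations of the per-permutation median over
neurons, with the IQR of those medians.  With refitting (default 100
permutations), coefficients are refit on the training split, *test* MSE is
compared, and the summary is the grand median/IQR pooled over neurons and
permutations.  Permutation p draws its own generator from (root seed, p), so
any single permutation is reproducible in isolation.

## Bayesian decoding

Both decoders place a uniform prior over the 13 conditions and decode each
frame by MAP under a Gaussian likelihood, by default over *all* frames
(training and test), with a test-only mode for generalization reporting.

- **Coupled**: the condition-s mean at frame t is the unrestricted-LM
  prediction with the stimulus term evaluated at candidate s (grey uses 0)
  while the coupling and running terms use the observed data at t; the
  covariance is the full per-condition covariance of the training traces.
- **Uncoupled**: per-neuron per-condition means and variances; the diagonal
  covariance factorizes the likelihood (conditional independence).

Covariance conditioning: the per-condition sample covariance is shrunk
toward its own diagonal with a Ledoit-Wolf data-driven intensity (the
diagonal target preserves per-neuron variances; a scaled-identity target
would not), plus a 1e−8 diagonal loading escalated only if the Cholesky
factorization still fails.  The intensity can be fixed or set to zero.
Posterior ties break toward the lowest condition index (grey, then ascending
direction).  Non-finite log-posteriors flag the frame and exclude it from
summaries.  Decoders are compared by overall accuracy, a row-normalized
percent confusion matrix, and the plug-in mutual information of the
empirical joint of true and decoded labels (base 2, 0·log 0 := 0), which is
bounded by log₂13 ≈ 3.7004 bits.

## Synthetic data generator

The generator realizes the structure the analysis assumes, with known ground
truth.  Protocol: identical repeated blocks of the 12 grating directions in
one seeded pseudo-random order, each direction preceded by a grey interval.
Defaults: 10 blocks, 30 Hz, 45 presentation + 30 grey frames per direction —
900 frames (30 s) per block, 9,000 frames total.  These are scaled-down
stand-ins for 5-minute blocks; presentation and grey durations within a
block are not constrained by any published value and stay configurable.

Per neuron i and frame t the intrinsic drive is
u_i(t) = baseline + tuning_i(label(t)) + run_gain·v(t) + η_i(t), with
von-Mises direction tuning for the tuned half of the population
(concentration 2, gains uniform on [0.1, 0.5]), flat responses for the
untuned half, and private drive noise η of SD 0.5 — the trial-to-trial
variability that coupling propagates.  Planted coupling adds one-step
propagation of the sources' intrinsic drives:
d_i(t) = u_i(t) + Σ w_ki·u_k(t − lag_ki).  A literal simultaneous (lag-0)
recurrence would require the planted weight matrix to have spectral radius
below one, which paper-like densities and weights violate; one-step mixing
plants the same pairwise correlation structure at any weight scale and keeps
the ground truth exactly the drawn weights.  Defaults: edge probability 0.08
per pair, lags {0: 0.7, 1: 0.3}, 85% positive signs, magnitudes uniform on
[0.15, 0.6].  The drive is passed through a causal single-exponential
calcium kernel (τ = 0.2 s, reset at block boundaries — biophysical realism
is out of scope; only the temporal smearing matters for lag estimation),
measurement noise of SD 0.05 is added, and traces are z-scored per neuron
(zero-variance traces are flagged and left at zero).  Locomotion is a seeded
two-state renewal process (exponential still/run durations, mean 10 s/5 s,
one positive speed per bout), so mice "run" about a third of the time;
running modulates the drive through a per-neuron gain, 0 by default and 0.3
in the shared-variability decoding condition.

What the generator does *not* emulate: spiking biophysics, nonlinear
calcium-to-fluorescence transforms, slow drift and photobleaching,
orientation-tuned (180°-ambiguous) cells, and distance-dependent coupling.
Passing tests therefore show that the estimators recover the structure they
assume when it is present, and stay null when it is absent — not that real
cortical data satisfies those assumptions.

## Study conditions and problem sizes

The shipped analyses run at 100 neurons × 10 blocks (≈9,000 frames): the
graph stage handles all 4,950 pairs in well under a minute, and the
acceptance run (ladder + 2×200 no-refit and 2×100 refit permutations +
decoders) completes in a few minutes on one CPU.  Two named conditions
cover the headline claims: the **default** condition (running gain 0)
carries the coupling-recovery, model-ladder, and permutation analyses; the
**run-modulated** condition (running gain 0.3, same scale) adds
population-wide shared variability and carries the coupled-vs-uncoupled
decoder comparison — without a shared mode, an independence-assuming
decoder over 100 weakly coupled neurons is hard to beat, which is itself a
useful negative control but not the regime of interest.

## Known limitations

- Functional weights are estimated per pair without multiple-comparison
  control; significance testing of individual edges is out of scope.
- The block-averaged stimulus model averages over the split containing the
  evaluated frames (as defined), so its test-set averages include the
  evaluated presentation; this mild optimism is inherent to the method.
- The reciprocal-link GLM is numerically fragile on z-scored (sign-mixed)
  responses; its huge percent changes are expected and reported as-is.
- Real datasets with unequal block lengths are truncated to the shortest
  block for trial alignment (logged).
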