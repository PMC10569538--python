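# Methods

## The estimand and the estimator

Let t^p be the (unobservable) true stimulus-evoked response vector of
animal p, and s^p_j the average of the j-th disjoint half of its trials.
The quantity of interest is the consistency of the *true* signals under a
mapping class M, `Corr(M(t^A; t^B), t^B)` on held-out stimuli — the
degree to which animal A's reliable signal, passed through an allowed
transform, accounts for animal B's reliable signal. Since t is never
observed, the package estimates it as

    Corr(M(s1^A; s1^B), s2^B)
    ----------------------------------------------------------
    sqrt( SB[Corr(M(s1^A;s1^B), M(s2^A;s2^B))] * SB[Corr(s1^B, s2^B)] )

with SB(r) = 2r/(1+r). The derivation substitutes noisy half-averages
for true responses step by step, using the transitivity of positive
correlations and the identity `Corr(s1, s2) ≈ Corr(t, s2)^2`, both of
which hold for additive Gaussian trial noise and large stimulus counts.
The two denominator terms are each split-half reliabilities of a single
underlying process (the fitted mapping; the target population), so each
is Spearman–Brown corrected to its full-trial equivalent before the
square root. The numerator is a cross-system correlation and is not
corrected.

**Square-root scope.** The square root is taken over the *product* of
the two corrected reliabilities (geometric mean). A
`sqrt_scope="mapping_only"` flag applies the root to the mapping
reliability alone for sensitivity analyses; on the synthetic cohorts the
two conventions differ by well under the bootstrap s.e.m. whenever both
terms are near 1, and the product form is the package default.

**Model predictivity** is the same computation with the source animal
replaced by a deterministic stimuli × features matrix: the mapping is
fit once per target trial-half (`M(r; s1^B)`, `M(r; s2^B)`), the
mapping-reliability term then reflects only fit instability, and the
best layer for an area is the argmax of the median over concatenated
target units. **RSA mode** applies the identical correction at the level
of RDM upper-triangle correlations, with the identity mapping (unit
counts may differ) and, for deterministic features, a source reliability
fixed at exactly 1. RSA yields one value per target *animal*, since the
score already pools over units.

## Averaging, aggregation, exclusion

- Each evaluation pairs a fresh random disjoint trial halving with one
  of the stimulus splits, cycling through the splits; the defaults (100
  halvings, 10 splits of 50% train) give 100 evaluations, ten per split.
  Trial halves are resampled independently per evaluation rather than
  fixed even/odd, so the bootstrap sees halving variability.
- The corrected *ratio* is averaged per target unit over evaluations
  first; the median and s.e.m. (sd / √n_units) are then taken across
  units concatenated over target animals. Each unit therefore carries a
  single averaged value.
- The ratio is unstable when a reliability term is near zero, so an
  evaluation is excluded for a unit whenever either denominator term is
  nonpositive or undefined; a unit excluded in more than half of its
  evaluations is dropped and reported. No clipping is applied to
  surviving ratios — null distributions stay centred at zero.
- Odd trial counts drop one randomly chosen trial per halving (logged).

## The synthetic cohort

Animals share a stimuli × n_latent standard-normal latent; animal p sees
it through its own mixing matrix with N(0, 1/n_latent) entries (unit
signal variance in expectation), optionally through a pointwise
nonlinearity (`rectify`, `squash`) to create mapping mismatch that a
linear transform cannot absorb. Trials add i.i.d. Gaussian noise with
per-unit sd — a scalar, a (low, high) uniform range for heteroscedastic
populations straddling the 0.3 selection threshold, or an explicit
vector. Under this model the expected split-half correlation has the
closed form v/(v + w/(n/2)) (signal variance v, noise variance w, n
trials halved), which anchors all recovery tests. `shared_signal=False`
gives each animal an independent latent: the null condition.

Defaults mirror a natural-scenes session: 118 stimuli, 50 trials,
n_latent = 20, noise sd 1. One master seed spawns per-animal substreams;
trial-halving streams are keyed by (plan seed, evaluation index, animal
id), which makes the pooled-source computation with two animals reduce
*bitwise* to the pairwise one.

What the simulator does not emulate: calcium-indicator dynamics, spike
count statistics (noise is Gaussian, not Poisson-like), correlated noise
across units, adaptation across repeats, and behavioural covariates
beyond a per-presentation scalar. Passing recovery tests therefore shows
the estimators are correct under their stated assumptions, not that real
recordings satisfy those assumptions.

## Mapping transforms

- `one_to_one`: per target unit, the source unit with maximal *signed*
  Pearson correlation on training stimuli (ties to the lowest index;
  an `one_to_one_abs` flag switches to absolute value), then a
  univariate least-squares rescaling. Constant target units are flagged
  and predicted as NaN, feeding the exclusion machinery.
- `ridge`: α = 1 (scikit-learn convention), intercept fitted, no feature
  standardisation — responses are already on a common trial-averaged
  scale.
- `pls`: 25 components, capped at min(requested, n_train − 1,
  n_source_units) and at the numerical rank of the centred training
  matrix, so small or rank-deficient problems stay well-posed; cap
  events are logged.
- Zero-variance source units are dropped before multivariate fits.

## Dataset conditioning

Units are kept when their Spearman–Brown corrected split-half
consistency (averaged over 100 halvings) reaches 0.3 and, when a
behavioural covariate is supplied, when their preferred-stimulus
responses are not significantly modulated by it (p > 0.05). The
modulation test is a stand-in — no specific test is prescribed by the
selection criterion — implemented as a two-sided permutation test
(1,000 permutations) on the Spearman correlation between the covariate
and the unit's responses at its preferred stimulus (maximal trial-mean
response, ties to the lowest stimulus index). Time-binned recordings are
averaged over the largest contiguous run of bins (10 ms, up to 250 ms)
whose population-median corrected consistency reaches 0.3, earliest run
on ties. Specimens are kept per area when their unit count reaches the
75th percentile (linear interpolation, inclusive comparison) of that
area's counts.

## Extrapolation

Consistency as a function of the unit-subsampling factor n is fit by
f(n) = a·log₁₀(n) + b via least squares; reported predictions are capped
at 1 (flagged when the cap binds). The CLI `extrapolate` subcommand also
reports the sample-size factor at which the fitted curve reaches 1.

## StreamNet and the training objectives

The architecture table maps a 64 px input to shallow 7×7 (conv 64, 11,
4, 2 + max-pool 3/2), intermediate 3×3 ([(192,5,1,2) + pool,
(384,3,1,1)] per stream) and deep 3×3; the pool after the first
intermediate conv follows the AlexNet placement and is what produces the
printed 3×3 intermediate size. The deep module has two inputs per
stream — (256,3,1,1) from the intermediate block and (256,3,2,0)
directly from the shallow module — whose outputs are summed per stream
and concatenated across streams (6 × 256 channels for six streams)
before the adaptive 6×6 average-pool readout. The longest convolutional
path is 4. Untrained instantiation uses centred Gaussian fan-in-scaled
weights from seeded per-layer substreams and a plain numpy forward pass
(im2col convolution, ReLU after every convolution including both deep
branches before their sum); the shape calculator and the forward pass
are tested against each other.

The objectives are implemented exactly as their formulas state, with two
documented resolutions: the instance-recognition normalisation constant
Z is estimated once as bank_size × mean(exp(u·z/τ)) over a seeded
subsample of bank entries and then frozen (explicit override available);
VICReg, which has no printed formula, follows its three named terms
(invariance MSE, std hinge at threshold 1, off-diagonal covariance)
with coefficients (25, 25, 1) that are the method's customary defaults,
not values from this package's source data. Barlow Twins uses the
printed normaliser √(Σ_b z²) without batch-mean centring; a
`center=True` flag provides the reference-implementation variant.
Reference training hyperparameters (optimisers, schedules, batch sizes,
bank size 4096 negatives, MoCo queue 65,536) are metadata only — the
package evaluates objectives, it does not train networks. Desk-scale
tests shrink bank/queue sizes through the explicit size parameters.

## Stimulus preprocessing

Models trained at ImageNet geometry: shortest edge to 256 → centre crop
224 → resize 64×64. Models trained at CIFAR geometry: shortest edge to
64, aspect preserved, with the long edge truncated (floor) rather than
rounded — a 918 × 1174 input yields 64 × 81. Interpolation is bilinear
with anti-aliasing; the chain is deterministic and idempotent at target
geometry.

## Transfer readouts

Features above 1000 dimensions are PCA-reduced, the PCA fit on the
training portion of each outer split only (avoiding leakage; the
fitting scope was an open choice). Classification uses a linear
max-margin classifier with C from the 32-value grid {1e-8, 5e-8, …,
5e8} chosen by inner 5-fold cross-validation; regression uses ridge
with α = 1/C over the same grid and scores Pearson correlation averaged
over output dimensions. Scores average over ten class-balanced outer
splits (75/25); the best layer is the argmax of the averaged score,
selected on the same splits used for reporting.

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` run the full estimator
at the nominal session scale — 118 stimuli × 50 trials, 100 units per
animal, 3 animals pooled for the ceiling, 100 halvings × 10 splits —
and use larger stimulus counts where a limit statement needs them
(1,000 for the closed-form reliability check, 10,000 for the Gaussian
split-half identity, 600 for the planted reliability mixture). The
remaining unit tests use smaller cohorts chosen to keep the suite quick
while leaving every code path exercised at realistic shapes.

## Known limitations

- The noise correction assumes additive Gaussian, unit-independent
  trial noise; correlated or non-Gaussian noise biases the denominator
  in ways the simulator does not probe.
- The one-to-one assignment is greedy per target unit (the field's
  convention), not a global matching.
- The behavioural-modulation test is a documented stand-in (see above).
- Best-layer selection shares splits with reporting, so it carries the
  usual small optimism of a max over layers; an independent-split mode
  would quantify it but is not the default.
- Pooled-source consistency concatenates raw units without reweighting;
  animals with more units dominate the pseudo-population.
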