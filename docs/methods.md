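# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical choices and the known limitations of `pbmkit`.

## Spot statistics and normalization

Each spot contributes net intensities `fg − bg` per channel (plain
foreground-minus-background of the GenePix median columns; no convolution
background model). A spot with a non-positive net in either channel is
*missing*, not an error. For usable spots, M = log2(green/red) and
A = ½(log2 green + log2 red); positive M means protein signal in excess of
the DNA amount.

**Within-slide loess.** The analysis assumes the protein/DNA log ratio is
independent of total fluorescence, so any smooth trend of M versus A is dye
bias. It is removed by subtracting a loess fit — local *linear* regression
with tricube weights over a window containing a `span` fraction of spots
(delegated to `statsmodels.nonparametric.lowess`, which implements exactly
this estimator). Defaults: `span = 0.3`, one robustness iteration — a common
two-colour choice; both are configurable. Fitted values within 1% of the A
range are linearly interpolated (the `delta` device of R's `lowess`); at
array scale this is numerically indistinguishable from refitting every spot
and can be disabled (`delta=0`). At least 10 finite spots are required.

Note a structural property: loess removes the M-vs-A *trend*, so when a
non-negligible fraction of spots carries genuine signal, a small share of
that signal is absorbed into the fit (the corrected M of a signal spot is
its offset minus the offset's local share of the fit). This is inherent to
trend normalization, not an implementation artifact.

**Between-slide quantile normalization.** The rank-k value of every slide's
vector is replaced by the mean rank-k value across slides; tied entries
receive the average of their tied reference quantiles, which makes the map
well defined and idempotent. By default the normalization is applied to
per-spot M values (ratio level); per-channel normalization of the log2 net
intensities — motivated by the superimposed channel distributions replicate
slides show after normalization — is available via `quantile="channel"`, and
`"none"` disables the step. Only spots finite on *every* slide enter the
quantile map; other spots pass through loess-corrected.

Forcing identical M distributions across slides attenuates genuine
between-group differences when the groups are pooled into one reference
distribution: with 2-fold (|M| = 1) effects planted in 5% of sequences under
a 4-vs-8 slide design, the estimated |M| averages ≈ 0.87. Consequently a
strict |M| > 1 selection sits at the attenuated effect's upper tail and
sensitivity for exactly-2-fold effects is low (a few percent), while effects
comfortably above 2-fold are recovered well (the demo's 2.5-fold plants reach
~70% sensitivity). False-discovery control is unaffected.

**Replicate aggregation.** The ~20 replicate spots of a sequence on a slide
are collapsed by the median of their M values (robust to the occasional bad
spot; mean available). Channel CVs are 100·SD/mean of the net intensities
over replicates (sample SD, ddof 1), reported missing below 2 replicates.
Sequences missing on more than 50% of slides are dropped from downstream
testing with a warning.

## Binding and differential-binding tests

Per sequence, ordinary least squares on the slide-level binding values:
one-group (binding call) — effect = mean, s² = sample variance, df = n−1,
standard-error multiplier c = 1/√n; two-group (differential call) —
effect = mean₁ − mean₂, pooled s², df = n₁+n₂−2, c = √(1/n₁+1/n₂). Every
tested group needs ≥ 2 slides.

**Variance moderation.** The hierarchical model is
s² | σ² ~ σ²·χ²_df/df with σ² ~ s₀²·d₀/χ²_d₀, whose marginal is
s²/s₀² ~ F(df, d₀). Hyperparameters are estimated by matching the first two
moments of log s²: with e = log s² − ψ(df/2) + log(df/2),
var(e) = ψ′(df/2) + ψ′(d₀/2) and mean(e) = log s₀² + ψ(d₀/2) − log(d₀/2).
The trigamma inversion uses Newton iteration. If the observed var(e) does
not exceed ψ′(df/2), d₀ = ∞ (full shrinkage); if all s² are equal the model
is flagged degenerate with s₀² = s². `prior_df` can force d₀ = 0 (classical
t test; verified to reproduce scipy's pooled two-sided t to < 1e−12) or
d₀ = ∞. At least ~50 positive variances are recommended for stable
estimation (a warning is issued below that). The recovery test draws 5000
variances at d₀ = 4, s₀² = 0.25 and checks the moment estimates against both
the generation truth and a numerical maximum-likelihood oracle.

**Testing and selection.** t = effect/(s̃·c) referred to t with df + d₀
degrees of freedom (normal when d₀ = ∞), two-sided; sequences with zero
posterior variance and zero effect get p = 1 rather than NaN. Multiplicity
is handled by Benjamini–Hochberg step-up adjustment (statsmodels). Because
several thousand sequences are tested simultaneously, selection thresholds
apply to adjusted values by default, with a raw-p option. The binding call
keeps positive effects only (binding is directional: protein above the DNA
baseline); the differential call requires |effect| > 1 log2 unit (2-fold)
*and* significance, and also returns the fold-only superset for MA-plot
style rendering.

## Motif scanning

PWM scores are additive per-position base scores in the matrix's native
units — deliberately no log-odds transform or background model, because
published low/high thresholds for such matrices are quoted in native units.
The scanner scores every window on both strands (minus strand = forward
score of the reverse complement, implemented by scoring with the
row-and-column-reversed matrix); N bases contribute the position's minimum
entry. Ties are broken by smallest start position, then the plus strand.
`score_window` accumulates positions in the same order as the sliding
scanner so the two agree bit-for-bit, including on exact score ties.
Positions are 0-based half-open throughout; BED output follows the same
convention with the score in column 5 and strand in column 6.

Classification is *low* iff score < threshold (strict). Piggyback candidates
— sequences a factor may bind indirectly via protein–protein contact with a
DNA-bound partner — are those with a low best score for the primary matrix
and a high best score for the partner matrix. The partner is scored by a
single generic PWM; dimeric-site models for factors like p53 are out of
scope and approximated by that single matrix. The shipped example matrices
are synthetic constructions (see `examples/*_synthetic.pwm`): scaled so
their documented thresholds (30, 50) sit near the 90th percentile of
best-score distributions on random 1-kb sequences, i.e. planted consensus
sites always classify high while ~10% of random sequences do.

## Equilibrium affinities

Titrations (≥ 4 points, ≥ 3 distinct concentrations) are fitted with the
Langmuir isotherm R(C) = Rmax·C/(Kd + C) by bounded least squares
(`scipy.optimize.least_squares`, xtol/ftol/gtol 1e−12), initialized at
Rmax⁰ = max response and Kd⁰ = the concentration nearest half-max. Only the
equilibrium plateau is modelled — on high-density surfaces off-rates can be
undetectably slow, so kinetic fitting is deliberately absent. Zero-signal
titrations and fits with no curvature over the measured range (fitted Kd
more than 10⁴× the highest concentration) raise a non-identifiability
error; C = 0 points are retained as baseline anchors. The fit is
scale-equivariant in Rmax and satisfies R(Kd) = Rmax/2 identically. A
percentile bootstrap (default 200 seeded resamples) provides Kd intervals.

Relative affinity is (1/Kd)/max(1/Kd) ∈ (0, 1]; the definition of the
"relative affinity" axis is a documented convention of this package. PBM
values are regressed on relative affinities by OLS with Pearson r reported;
the PBM value scale defaults to the aggregated linear/log2 values the
caller supplies (no transform is imposed).

## Synthetic-data generator

The generator emulates a two-colour PBM study design: ~6000 regulatory
sequences of ~1000 bp, each spotted 20 times per slide in a fixed random
layout shared by all slides, 3 replicate slides for a purified-protein
experiment, and an unbalanced 4 "normal" / 8 "cancer" design for tissue
extracts. Per spot (log2 scale):

    red   = 2^(10 + seq_level + deposition)
    green = red · 2^(true_M + dye_bias(log2 red) + slide_effect + noise)

- `seq_level ~ N(0, dna_log2_sd=0.5)` per sequence per slide spans a
  realistic A range (no intensity distribution is published for such
  arrays; lognormal is an assumption, not an inference);
- `deposition ~ N(0, deposition_log2_sd=0.05)` per spot sets the replicate
  CV of the DNA channel at ~3.5%, reproducing the "majority of CVs under
  5%" regime on the red channel;
- `dye_bias` is a smooth sinusoid-plus-trend in spot intensity scaled by
  `dye_bias_amplitude` (default 0.5 log2 units) — any smooth shape
  exercises loess equally, the shape itself is unidentified;
- `slide_effect ~ N(0, slide_scale_sd=0.1)` per slide;
- `noise ~ N(0, spot_noise_sd=0.25)` multiplicative per spot. This is the
  binding-noise knob the validation conditions set (0.25–0.3); it puts the
  green-channel replicate CV near 18%, i.e. the protein channel in this
  emulation is noisier than the scanner-reproducibility regime real slides
  show — a deliberate trade-off so that the statistical machinery is
  exercised at meaningful noise.

A `frac_bound` fraction of sequences (default 5%) carries true M =
`bound_effect` (default 1); a `frac_differential` fraction (default 5%)
additionally differs between groups by `differential_effect` with random
sign, applied to group 2 only (both directions occur in real comparisons).
Backgrounds are 5% of foreground, jittered per channel only when spot noise
is on, so with all noise and bias parameters zero every spot M equals the
planted effect *exactly* — the strongest available end-to-end identity
check. Fixing the seed fixes every emitted byte.

What the generator does **not** emulate: sequence composition (GC content,
repeats), spatial slide-surface artifacts, print-tip effects, saturation,
and antibody-detection chemistry. Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under a clean generative
model, not robustness to those real-data pathologies.

Motif fixtures: `simulate_sequences_with_sites` plants the matrix's
maximal-score word (reverse complemented on minus-strand plants) at recorded
positions in uniform-random DNA. Titrations follow the Langmuir model with
multiplicative noise.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run the generator at 2000
sequences × 20 spots with 4-vs-4 or 4-vs-8 slide designs (null calibration
over 20 and 10 seeds respectively), 100 random-split replications, 1000
(tests) / 300 (script) brute-force scanner comparisons on 200-bp sequences,
20 noisy titrations and 200 affinity-correlation replications — sizes chosen
as the package's own trade-off between Monte-Carlo error and a suite that
runs in a few minutes on one core.

## Known limitations and open choices

- The unadjusted-vs-adjusted status of published significance cut-offs for
  this kind of study is usually ambiguous; defaults here use BH-adjusted
  values with a raw-p flag.
- Whether between-slide quantile normalization is best applied to ratios or
  per channel is not settled; both are implemented, ratio is the default.
- Replicate spots enter the linear model as one aggregated value per slide
  (no duplicate-correlation modelling); designs beyond one or two groups are
  out of scope.
- Identifier matching in set comparisons is exact string equality after case
  folding — no gene-symbol aliasing. Reference lists are user-supplied flat
  files.
- The random-split noise control reports a single seeded split by default;
  `replicates` averages over several splits.
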