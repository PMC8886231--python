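# Methods

This note records the models, estimators, and numerical choices behind
`climniche`, and what the synthetic data do and do not emulate.

## Data model

Analyses run on a `Chronogram`: a rooted, ultrametric tree with branch
durations in Myr. Ultrametricity is enforced within a relative tolerance
of 1e-6 of the root age (configurable): dating software emits rounding
noise well below this level, while genuine violations sit far above it, so
sub-tolerance spread is accepted silently and anything larger is an error
(or a warning, per call). A `TreeEnsemble` couples an MCC summary tree
with an ordered posterior sample sharing the same tip set; every statistic
is reported for the MCC tree plus the distribution (and 95% HPD) over the
posterior trees, which is how dating and topology uncertainty enter the
results. All trees, including posterior samples, are validated on load.

Trait inputs are accession-level records. Per OTU and variable we use the
mean (and, for the rate variants, the minimum and maximum) of the
accession values. The sampling error of an OTU mean is `s_p / sqrt(n_i)`
with `s_p²` the pooled within-OTU variance over all OTUs with at least two
accessions, pooled **per variable** because variances differ across
variables by orders of magnitude. Pooling is what gives singleton OTUs a
finite, non-zero error — with 1 accession there is no within-OTU
information, so the clade-wide within-OTU spread is the natural stand-in.
The phrase "pooled variance divided by √n" is sometimes read literally
(a variance, not an SD, in the numerator); that reading is dimensionally
inconsistent for a standard error but is available as
`se_formula="var_over_sqrt_n"` for reproducibility. Missing values are
excluded per variable, never per OTU, and never imputed as zero.

## Phylogenetic signal

Blomberg's K compares the ratio of ordinary to phylogenetically corrected
trait variance against its Brownian expectation on the same tree; K = 1
under Brownian drift, K → 0 when trait values are independent of the
phylogeny. Sampling error enters in two steps: the Brownian rate σ² is
estimated by ML under the covariance `σ²C + diag(se²)` (root state
profiled by GLS, 1-D bounded search on log σ² over
[1e-8, 1e8]·var(x)/T), then K is computed on the inflated structure
`C̃ = C + diag(se²)/σ̂²`. With se = 0 this reduces exactly to the classical
statistic (verified against an independent dense-matrix implementation to
1e-10 and against phytools).

Significance against K = 0 comes from jointly permuting (x, se) pairs
across tips (default 1000 permutations); shuffling the errors with the
values keeps the error structure attached to the data. p is the plain
proportion of permutations with K at least the observed value (it can be
0); a smoothed (count+1)/(n+1) option exists. σ² is re-estimated per
permutation by default — the permuted dataset is a new dataset — with a
flag to reuse the observed-data estimate.

## Disparity through time

Disparity of a tip set is the mean squared difference over unordered
pairs (equivalently twice the sample variance). The DTT curve is defined
on the grid of internal-node times (root = 0, present = 1): at each time,
every lineage alive then (an edge crossing that time) contributes the
disparity of its descendant tips, and the curve value is the lineage mean
divided by the whole-clade disparity. The curve starts at 1 by
construction and is pinned to 0 at the present. MDI is the signed area
between the observed curve and the pointwise median of Brownian
simulations on the same tree (left-Riemann sum by default; trapezoid
available). The Brownian null uses the ML σ² from the observed data;
p is the proportion of simulations whose MDI does not exceed the observed
one, i.e. the probability of a negative MDI as extreme, with 1−p the
relevant tail for positive MDI. The per-simulation MDI distribution is
kept on the result object for audit. Sampling error is not injected into
the DTT analysis by default (it is a pattern description of the tip
means); a flag adds se-noise to the simulations. No time cutoff is applied
before the most recent divergences.

## Trait-evolution models

Three single-optimum Gaussian models, in tip-covariance form on an
ultrametric tree of age T (C = root-to-MRCA path lengths):

- **BM**: V = σ²C. Parameters σ² (trait-units²/Myr) and root state z0; k = 2.
- **OU**: non-stationary, root state free, zero variance at the root:
  V_ij = σ²/(2α)·exp(−2α(T−C_ij))·(1−exp(−2α·C_ij)), α in 1/Myr; k = 3.
  A stationary variant sits behind a flag. On an ultrametric tree this
  likelihood is identical to an accelerating-rates model, so "OU support"
  cannot be separated from exponentially increasing rates; the
  accelerating branch is reachable via `allow_ac=True` on the EB model and
  the equivalence is asserted in the tests.
- **EB**: rate σ²e^(at) with a ≤ 0; V_ij = σ²(exp(a·C_ij)−1)/a; k = 3.
  a = 0 reduces exactly to BM.

Known sampling error is a fixed diagonal added to V (not estimated; a free
nuisance-variance parameter is deliberately out of scope). z0 is profiled
by GLS at every parameter value; with se = 0, σ² is profiled analytically
(σ̂² = quadratic form / n), otherwise by a nested bounded search on
log σ². The remaining shape parameter is optimized by a 24-point grid
(log-spaced for α ∈ [1e-8, 50/T]; linear for a ∈ [ln(1e-5)/T, 0]) followed
by Brent polishing in the bracketing interval, with the grid optimum and
both bounds re-checked — flat likelihood surfaces near the BM limit are
the common corner case, and this scheme cannot do worse than the grid.
Likelihoods use Cholesky factorizations throughout; non-positive-definite
covariances raise with the offending eigenvalue.

Model support uses AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) and weights
w_i = exp(−Δ_i/2)/Σexp(−Δ_j/2). Ties break toward the simpler model.
Fits are fingerprinted by their data so weights cannot silently mix
variables or trees.

## Ancestral states and rates

Ancestral states are GLS/conditional-mean reconstructions under the
best-fit model: x̂_v = ẑ0 + Cov(v, tips)·V⁻¹·(x − ẑ0·1), with closed-form
node–tip covariances for all three models (for OU,
Cov(v,i) = σ²/(2α)·e^(−α(t_v−s))·e^(−α(t_i−s))·(1−e^(−2αs)) with s the
MRCA depth). This is the "transform the tree, then reconstruct" recipe
done in covariance space: the non-stationary OU covariance is not exactly
representable as a rescaled tree, and every consumer here accepts a
covariance, so exactness wins over cosmetic fidelity to tree surgery.
When the best fit used sampling error, the reconstruction includes it by
default (consistency), with a flag to disable.

The absolute rate of a tip is |tip value − reconstructed parent-node
state| divided by the tip's branch duration **on the original
chronogram** — using transformed EB/OU "durations" would destroy the
per-Myr unit (a `denominator="transformed"` option exists for
comparison). The "immediate ancestor" is the parent node, read literally.
Tips on zero-length terminal branches yield NaN with a warning rather
than an infinite rate. Rates are computed for mean, minimum, and maximum
per-OTU values, with the winning model refitted per basis.

95% HPD intervals use the shortest-window rule on the sorted sample
(⌈0.95·N⌉ points, leftmost window on ties). σ² comparisons between paired
variables report the MCC point estimates, per-variable HPDs over the
posterior trees, the fraction of trees with σ²_A < σ²_B, and an HPD
overlap fraction (0 = fully segregated) — the overlap is reported, not
tested, since segregation is a description, not a hypothesis.

## Synthetic data

The generator reproduces the *shape* of a genus-level niche dataset:
81-tip birth–death chronograms (birth 0.15/Myr, death 0.05/Myr,
conditioned on the tip count, rescaled to a 100-Myr crown age — a
plausible order for an old algal genus; the absolute age only sets the
units), a pseudo-posterior made by multiplying internal-node ages by
independent unit-mean lognormal factors (children clamped below parents,
so trees stay exactly ultrametric and the root age is unbiased across the
ensemble; optional NNI moves perturb topology), 19 climate variables
built from six latent group factors evolving on the tree (drift-like BM
for the annual/extreme thermal-humidity groups, strong OU for the
seasonality/isothermality groups) plus independent tip noise, and
accession counts from a rounded lognormal with mean ≈ 29 clipped to
[1, 454] — matching the reported minimum/mean/maximum of the emulated
archive; the exact law is ours. A deterministic count profile summing to
2,359 over 81 OTUs supports the worked arithmetic (29.1 accessions/OTU).

What this does **not** emulate: spatial autocorrelation of climate
rasters, shared geographic sampling bias across variables, realistic
inter-group correlation (group membership is configuration, not
inference), OTU delimitation error, or posterior tree samples with real
topological structure. Passing tests therefore demonstrate the estimators
are correct and calibrated under their assumed generating models — not
that any particular empirical dataset satisfies those assumptions.

## Problem sizes and determinism

Simulation-based checks use sizes chosen to make their Monte-Carlo error
small relative to the tolerances asserted: 500 replicates for the K
calibration, 200×200 for the DTT type-I error on a 50-tip tree, 100–200
replicates for recovery and model-selection fractions, 100 pseudo-posterior
trees for ensemble contrasts. Every stochastic path takes an explicit seed
(or Generator); the pipeline derives all stage/variable/tree streams from
one master seed via `SeedSequence`, so partial reruns and parallel runs
reproduce identical numbers, and generators are bit-reproducible given a
seed.

## Known limitations

- Single-optimum OU only; no rate shifts, multi-regime models, or
  λ/κ/δ transforms; each variable is analyzed univariately.
- The K measurement-error treatment fixes σ̂² at its ML value rather than
  integrating over its uncertainty.
- The randomization p for K and the simulation p for MDI are
  Monte-Carlo estimates; with the default 1000 draws their resolution
  is 0.001.
- Posterior ensembles are treated as exchangeable samples; no tree
  weighting is attempted.
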