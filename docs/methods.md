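# Methods

This note records the statistical model behind `rmtgsa`, the conventions
the implementation fixes where the underlying theory leaves a choice, and
what the synthetic-data studies do and do not demonstrate.

## Data model and hypotheses

Measurements for *p* genomic variables on *n* independent samples are held
in an *n* × *p* matrix **X**, modeled as draws from a *p*-variate
distribution with covariance **Σ**; **C** is the column-mean-centered
matrix and **S** = (1/*n*)**C**ᵀ**C** the sample covariance.  A gene set
picks out *g* columns; **S**₉₉ denotes the corresponding block of **S**.
The mean vector plays no role (every statistic uses centered data), so
simulated data are zero-mean.

Two null hypotheses are supported:

- **Self-contained**: **Σ**₉₉ = **I**.  Then *n***S**₉₉ = **C**ᵀ**C**
  restricted to the set is white Wishart with *m* = *n* − 1 degrees of
  freedom, and its eigenvalues carry all the evidence.
- **Competitive**: the population eigenvalue distribution of **Σ**₉₉
  equals that of a uniformly random size-*g* subset of all *p* variables.
  This null can hold even when both blocks are far from identity.

## Statistics

**MLRT.** `n(trace(S₉₉) − log|S₉₉| − g)` with natural logarithms,
asymptotically χ²_{g(g+1)/2} as *n* → ∞ with *g* fixed.  Computed from the
eigenvalues of **S**₉₉; a zero eigenvalue (*n* − 1 < *g*, or collinear
columns) is an error, not a silent drop.

**TWT.** λ̂₁ of *n***S**₉₉, centered by μ(g,n) = (√(n−1) + √g)² and scaled
by σ(g,n) = (√(n−1) + √g)(1/√(n−1) + 1/√g)^{1/3}; under the self-contained
null the statistic follows the Tracy-Widom law of order 1 in the
proportional-limit regime.  F₁ is evaluated by solving the Painlevé II
representation (Hastings-McLeod solution, `q'' = xq + 2q³`, `q ~ Ai` at
+∞) once with a high-order ODE solver on x ∈ [−13, 8] and caching a
monotone cubic interpolant; the tabulation reproduces the published GOE
mean (−1.20653), variance (1.60778) and quantiles to ~1e−5 and is never
re-solved at call time.

*Centering accuracy.* The first-order constants above are a half-step off
the Johnstone convention for a Wishart with *m* = *n* − 1 degrees of
freedom.  At g = 10, n = 100 the empirical KS distance of the scaled λ̂₁
to F₁ is ≈ 0.09 with the first-order constants and ≈ 0.03 with the
second-order convention √(m − ½) + √(g − ½), available as
`tw_scaling(g, n, corrected=True)`.  The test statistic keeps the
first-order form; the offset is deterministic and rank-preserving, so
competitive p-values are identical under either convention, and only the
self-contained TWT p-value inherits a small bias at this size.

**MPDT.** The eigenvalues of **C**ᵀ**C** are divided by *m* = *n* − 1 (the
Wishart degrees of freedom — the scale on which the Marčenko-Pastur limit
at γ = g/m lives) and their empirical distribution is compared to the MP
law by the exact one-sample Kolmogorov-Smirnov distance, evaluated at both
sides of every jump of the step function.  The MP CDF has no closed form
here; it is computed by Simpson quadrature under the substitution
x = 1 + γ − 2√γ·cos θ, which maps the support [(1−√γ)², (1+√γ)²] to
[0, π] and removes the square-root edge behavior (normalization error
< 1e−13; grids are memoized per γ, since the competitive loop evaluates
the same law tens of thousands of times).  γ > 1 (g > n − 1) is refused —
the rank-deficient regime is outside the method's assumptions.  The
nominal KS p-value is reported but flagged: the eigenvalues are mutually
dependent, so it is anti-conservative and the statistic is primarily a
ranking device; it becomes a calibrated test only inside the competitive
procedure.  The MP comparison also presumes data on the unit-variance
scale; spectra far from the support (e.g. raw genotype counts) quantize
the distance into ties and degenerate the ranking — see the genotype
normalization below.

## Competitive procedure

For a set of size *g*: compute the observed statistic; draw *B* uniform
random *g*-combinations of the *p* genes (repeats across draws permitted,
the true set not excluded); compute each subset's statistic on the same
matrix; report `p = #{T_b > T_obs}/B`.  Ties count as non-exceedances and
p = 0 is attainable; an optional `(count+1)/(B+1)` mode keeps p positive
for −log weighting (the default weighting path instead floors p at
1/(2B)).  Internally one p × p gram matrix is formed per data set and all
subsets become a stacked batch of g × g eigendecompositions, from which
every requested statistic is derived simultaneously — this is what makes
1000-replicate studies with B = 500 run in seconds per design.  Each set's
permutation stream is keyed by (seed, crc32(set id)), so collection
results are independent of testing order.

## SGSE benchmark

The spectral enrichment benchmark scores a set through the principal
components of the full matrix: per PC, gene-level statistics are
Fisher-transformed gene-PC correlations; a Welch two-sample t-test
compares members to non-members; PC-level p-values are combined by the
weighted Z-method with weight = PC variance × the lower-tailed Tracy-Widom
p-value of the PC's eigenvalue (so only PCs with significantly large
eigenvalues contribute).  Two deliberate simplifications: the
correlation-adjusted t-test of the original method is replaced by the
plain Welch test, and the test is two-sided so the score is invariant to
the arbitrary sign of each PC.  The benchmark reproduces the expected
qualitative behavior (strong on single-block structure, near-powerless on
anti-correlated blocks) and its single-block power matches the published
figure to within Monte-Carlo error, but exact reproduction is not claimed.

## P-value weighting and weighted FDR

Weights w_i = −log(u_i)/mean(−log(u)) average exactly 1 (the log base
cancels).  Supervised p-values are weighted as **s\* = s/w**, clipped to
[0, 1], with w = 0 sending s\* to 1, and ordinary BH (statsmodels) applied
to s\*.  The division direction is the one validated by the
Genovese-Roeder-Wasserman argument — for null-uniform s,
P(s/w ≤ t) = E[min(tw, 1)] ≤ t·E[w] = t — and the one under which larger
weights help the promoted sets; the multiplicative form is
anti-conservative for null sets (E[1/w] ≥ 1 by Jensen) and measurably
inflates FDR in simulation, so it is not offered.  Competitive p-values of
exactly zero are floored at 1/(2B) before logging.

## Synthetic-data generators

**Covariance structures.**  Identity, scaled identity (all variances α),
compound symmetry (one covariance for every gene pair), single block
(first *g* genes: variance σ², pairwise covariance ρ; identity
elsewhere), multi-block (sub-blocks inside the set, zero between),
anti-correlated multi-block (negative covariance between sub-blocks),
repeated block (every disjoint size-*g* block correlated), and inverted
single block.  Matrices are validated symmetric and positive
semi-definite (eigenvalue floor −1e−10); infeasible parameters are
rejected with the offending eigenvalue named.

**Multivariate normal.**  Eigenfactor square root times i.i.d. normals;
tolerant of semi-definite covariances, reproducible under a seed.

**Correlated binomial (SNP-like).**  Two generators serve different
purposes:

- `sample_mv_binomial` targets a specified *binomial-scale* covariance:
  two independent latent normal replicates are dichotomized at the
  upper-prob quantile and summed, with the latent correlation calibrated
  by deterministic root-finding on the analytic orthant probability
  2(Φ₂(−t, −t; r) − prob²) — exact marginals, covariance matched to
  quadrature accuracy.
- `sample_binomial_from_latent` — the generator behind the simulation
  designs — draws one latent normal vector with the design's covariance
  structure on the unit-variance scale and maps it through the
  Binomial(2, 0.25) quantile function.  A latent covariance of 0.1
  induces a genotype covariance of ≈ 0.026: the design tables quote the
  latent ρ and the binomial marginal variance 0.375.  This convention is
  the one consistent with the published power ordering of the SNP design
  relative to its normal analogue; targeting 0.1 on the binomial scale
  would make the SNP design's correlation (0.27) stronger than any normal
  design, which the reported orderings exclude.

**Genotype normalization.**  In the study pipeline, additively coded
genotype matrices are divided by the known marginal standard deviation
√(2·prob·(1−prob)) before testing — the standard additive-coding
normalization.  It is a global constant per data set, so the competitive
TWT and MLRT are unchanged (rank invariance); its sole effect is to place
the spectrum on the white-Wishart scale the MPDT compares against.

## Simulation studies

Null designs define *p*/*g* = 10 disjoint sets, all null; the type-I error
is the rejection fraction at α = 0.05 pooled over sets and replicates.
Power designs define one truly enriched set (the first ten genes), except
the repeated-block design where all ten disjoint sets are non-null and
power is averaged over them; set membership is fixed by construction, not
re-sampled per replicate.  Full scale is 1000 replicates with B = 500;
replicate *r* uses seed master + *r*, so any scheduling leaves results
unchanged.  The test suite runs the same studies at 300 replicates and
B = 200 with Monte-Carlo-widened bands (±0.035 for type-I rates, ±0.09
for power); the acceptance script runs full scale.  α defaults to 0.05
and is configurable.

## What the synthetic studies do and do not show

The generators emulate exchangeable, homoscedastic blocks in otherwise
white data — the cleanest realization of the covariance structures the
tests target.  Real expression data add heavy tails, batch structure,
mean-variance coupling and pervasive weak correlation among "null" genes;
real genotype data add linkage-disequilibrium structure that is nothing
like exchangeable.  Passing the studies therefore demonstrates
calibration and relative power under the stated covariance models, not
performance guarantees on any particular real data set.  Two power rows
of the reference study resist reproduction under the stated generators
(the repeated-block design, where this implementation and an independent
brute-force re-implementation agree on substantially higher power than
reported, and a smaller deficit on the multi-block design); the
simulation engine reports what the stated designs actually produce.

## Numerical choices and degenerate inputs

Eigenvalues in [−1e−8, 0) are clipped to zero (symmetric-eigensolver
noise); anything more negative is an error.  Zero-variance (constant)
gene columns are an error rather than silently dropped.  Statistics
operate on covariance, not correlation.  The KS supremum is exact (both
sides of every jump), never grid-based.  MLRT uses natural logs.  The F₁
and MP evaluators are cached module-level singletons; quantile functions
invert the cached monotone interpolants.  All randomness flows through
numpy Generators seeded explicitly; no global state.

## Known limitations

Self-contained MPDT p-values are anti-conservative by construction
(documented, flagged in results).  The rank-deficient regime g > n − 1 is
refused rather than approximated.  SGSE is a simplified benchmark, not a
reference implementation.  The competitive test's B = 500 default bounds
p-value resolution at 0.002; weighting workflows should use the 1/(2B)
floor or the +1 mode.
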