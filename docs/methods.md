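# Methods

## Model

Each variant site j of a case–control SNP panel carries a latent influence
state Sⱼ ∈ {−1, 0, +1}. The states form a first-order Markov chain along the
genome with initial distribution π and row-stochastic transition matrix A;
self-transition mass makes influential sites cluster into blocks. The
observation at site j is its 2×3 phenotype-by-genotype contingency table,
emitted as a product of two multinomials: controls from the site's null
genotype distribution p⃗ʲ (a point on the 2-simplex) and cases from a tilted
distribution q⃗ determined by the state and four global influence strengths
θ₀⁻, θ₁⁻, θ₀⁺, θ₁⁺ ≥ 0. A Negative Influence state multiplies p₀ by e^{θ₀⁻}
and p₂ by e^{−θ₁⁻} before renormalizing (cases depleted of minor alleles);
Positive Influence is the mirror image. With all strengths 0 the three states
are indistinguishable, which motivates the lower threshold θ_min.

Assumptions worth stating: one minor allele per site; diploid autosomal
genotypes; complete data (no missing genotypes — inputs with anything other
than 0/1/2 are rejected); conditional independence of tables given states;
homogeneous transition probabilities (physical inter-site distance is not
used); a single global strength vector shared by all sites in the same state.

## Fitting

One fitting run iterates:

1. evaluate all log emissions (log-space throughout; log-gamma for
   factorials, log-sum-exp as the only probability summation);
2. forward–backward for the marginal posteriors γⱼ(k) and the master
   objective (the observed-data log likelihood), and Viterbi for the decoded
   path (ties broken toward No Influence, then Negative, then Positive);
3. a generalized-EM update: π ← γ₁; Baum–Welch closed form for A from the
   pairwise posteriors ξ; the strength pairs by two cycles of bounded Brent
   coordinate ascent on [θ_min, 10]; the per-site nulls by a
   minorize–maximize fixed point on the simplex (each −log Z term linearized
   at the current point; the surrogate maximizer is
   pᵢ ∝ (nᵢ+mᵢ)/(λ+dᵢ) with λ solved by bisection), run to stationarity with
   a cap of 30 passes — every piece is monotone in the expected
   complete-data objective, so the likelihood never decreases before
   clamping;
4. threshold enforcement: strengths clamped at θ_min, transition diagonals
   raised to a_min with off-diagonal mass rescaled proportionally.

The loop stops when the objective improves by less than ε (a decrease, which
clamping can cause, also stops it); the iteration with the highest objective
supplies the reported states, posteriors and parameters. The driver runs one
Default start and `n_random_starts` Random starts (sub-seeds seed, seed+1, …)
and keeps the run with the highest best objective.

Default initials: nulls from control-row frequencies with pseudocount 0.5 in
empty cells (then renormalized — dividing by N alone would leave the simplex);
per-site strength maximizers found by vectorized golden-section coordinate
ascent, with each global strength the median of per-site values exceeding
θ_min (θ_min if none); π and A from site-independent posterior proxies
floored at e^{−30}. Random initials: per-site nulls as descending sorted
uniform triples, strengths U(0,1), π with its mode on No Influence, transition
diagonals U(0.5, 1).

### Tunable parameters

| parameter | default | meaning |
|---|---|---|
| θ_min | 0.15 | minimum strength; below it influence states collapse into No Influence. Benchmarks sweep 0.1/0.15/0.2 |
| a_min | 0.5 | minimum self-transition probability; larger values favor longer blocks |
| ε | 0.01 | absolute log-likelihood improvement at which iteration stops |
| max_iterations | 500 | safety cap; typical fits stop after 15–45 iterations |
| n_random_starts | 3 | Random restarts besides the deterministic Default start |
| update_nulls | True | set False to freeze p⃗ at its initial estimate (sensitivity analysis) |

## Baselines

`fisher_exact_2x3` is the two-sided Freeman–Halton exact test: conditional on
all margins, the p-value is the total probability of case rows at most as
probable as the observed one (relative tie tolerance 10⁻⁷). The conditional
space is enumerated exactly (a compiled kernel over the two smallest column
ranges) up to 2×10⁵ tables; beyond that the p-value is a 10⁵-draw Monte Carlo
estimate (hits+1)/(B+1) under a fixed sub-seed. While the space remains
enumerable the hit count is drawn from its exact Binomial(B, p) law rather
than by per-table sampling — the same distribution at a fraction of the cost;
truly huge spaces fall back to explicit nested hypergeometric draws. The MC
granularity (p-value floor 1/(B+1), ties at multiples of it) is part of the
documented estimator and matters for multiple testing: see Limitations.
Bonferroni calls a site when p < α/p_sites (strict, as the rule is stated);
FDR uses the standard Benjamini–Hochberg step-up at α = 0.05.

## Simulators

The HMM-model generator draws parameters from documented priors (sorted
uniform triples for nulls; strengths U(0.05, 1); transition diagonals
0.5+0.5·Beta(99,1) for No Influence and 0.5+0.5·Beta(90,10) for the influence
states), samples a 1024-site chain, samples each table from its two
multinomials, and fills genotype columns by shuffling subjects within each
phenotype group so rebuilt tables match the draws exactly.

The block-model generator plants 1–4 non-overlapping blocks (Poisson lengths;
zero-length draws become 1; uniform placement by rejection) whose total
targets a count drawn from an empirical distribution built from 10⁴ HMM-model
chains (counts above 300 discarded; the draw is scaled by 1/(1−impurity),
i.e. 4/3 at impurity 0.25 and 2 at 0.5). Genotypes are independent
Hardy–Weinberg draws with MAF q = 0.001·500ᵘ (mixed) or 0.001·10ᵘ (low),
u ~ U(0,1); influential-site effects are |βⱼ| = 0.3·|log₁₀ q| (rarer ⇒
stronger) or U(0.6, 1.2), signed by the block's state. Phenotypes follow
logit P(Y=1) = β₀ + Σ βⱼGⱼ (+ 0.5·X₁ + 0.5·X₂ noise when enabled) with
β₀ = −μ + log(b/a), μ estimated from 1000 fresh genotypes; subjects are
accepted one at a time until the control and case quotas fill, and
monomorphic sites are dropped together with their truth labels. Nine
benchmark groups cover balanced, imbalanced (1500/500, 200/100), small
(150/150) and large low-MAF (2500/2500) designs, with and without noise and
block impurity.

What the generators emulate — and what they do not: genotypes are independent
across sites (no linkage disequilibrium within or between blocks), there is
no population structure, no covariates beyond the two noise terms, and no
missing data. Passing benchmarks therefore demonstrates block recovery under
the stated sampling models, not robustness to the correlation structure of
real genotype panels.

## Evaluation

Negative and Positive Influence are collapsed into one "influential" class
before scoring, so a sign confusion counts as a true positive (the
uncollapsed 3×3 confusion matrix is kept for diagnostics). Sensitivity and
MCC are NA when the truth has no influential site, specificity is NA when it
has no null site, and NA entries are excluded from aggregate means (they
reduce the divisor). An otherwise-defined MCC with a zero denominator factor
is set to 0. Aggregates report per-method means and the sample SD of MCC.

## Numerical choices

Emissions returning −∞ (zero-probability cell facing a positive count) are
tolerated and simply zero out a path; a site whose three states are all
impossible raises a fitting error naming the site. The MM null update floors
components at 10⁻¹², bounding its theoretical non-monotonicity far below the
10⁻⁶ test tolerance. Coordinate-ascent steps keep the incumbent value unless
the optimizer strictly improves it. Trellis recursions and the exact-test
enumeration are numba-compiled; everything else is vectorized numpy/scipy.

## Benchmark scale

The shipped acceptance checks regenerate group 1 at 20 trials, groups 2, 5
and 9 at 10 trials and group 7 at 40 trials, with 1024 sites throughout —
sizes chosen so the whole sweep completes in a few minutes on one CPU while
keeping Monte-Carlo error on the reported means within the stated tolerances.

## Known limitations

* With exact Freeman–Halton p-values, Benjamini–Hochberg rejects far fewer
  borderline sites than it does with granular Monte-Carlo p-values, whose
  ties at multiples of 1/(B+1) make the step-up rule cascade and also admit
  more false positives. Benchmarks built on approximate per-site p-values
  will therefore show noticeably higher FDR-baseline sensitivity (and lower
  FDR specificity) than this package's exact tests produce.
* About 9% of HMM-model state chains contain no influential site. In the
  block model such draws still plant 1–4 singleton blocks, which are often
  undetectable by any method, so block-group metric means carry a heavy
  lower tail across trials.
* A single global strength vector underfits data whose per-site effects vary
  widely (e.g. MAF-dependent strengths); the posterior then trades
  sensitivity for block purity, especially at higher θ_min.
* The quota sampler's rejection loop can be slow when the case rate implied
  by the intercept is far from the target ratio; an attempt cap (default
  10⁷ subjects) turns pathological settings into an explicit error.
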