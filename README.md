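# blockhmm

Block-wise genotype–phenotype association detection from case–control SNP
data with a three-state hidden Markov model.

## The problem

Single-site association tests (Fisher's exact test with Bonferroni or FDR
correction) ignore that variant sites influencing a phenotype tend to be
spatially clustered into blocks, e.g. through linkage disequilibrium.
`blockhmm` treats the unknown per-site association state as a latent Markov
chain along the genome and labels every site as **Negative Influence (−1)**,
**No Influence (0)** or **Positive Influence (+1)** — the minor allele
lowering, not affecting, or raising the odds of the phenotype. It is aimed at
statistical geneticists who want block-aware site classification without
specifying block locations or window sizes in advance.

## The model

The data are a genotype matrix *G* (n subjects × p sites, entries 0/1/2 =
minor-allele copies) and a binary phenotype vector *y*, summarized per site by
a 2×3 contingency table with control counts (n₀,n₁,n₂) and case counts
(m₀,m₁,m₂). Conditional on the latent state *S*ⱼ the table is emitted by two
multinomials,

    f(x_j | S_j) = C(N; n) · p₀^n₀ p₁^n₁ p₂^n₂ · C(M; m) · q₀^m₀ q₁^m₁ q₂^m₂,

where p⃗ʲ is the site's null (control) genotype distribution and the case
distribution q⃗ is a tilt of p⃗ governed by influence strengths
θ = (θ₀⁻, θ₁⁻, θ₀⁺, θ₁⁺):

* S = 0:  q⃗ = p⃗
* S = −1: q⃗ ∝ (e^{θ₀⁻} p₀, p₁, e^{−θ₁⁻} p₂)
* S = +1: q⃗ ∝ (e^{−θ₀⁺} p₀, p₁, e^{θ₁⁺} p₂)

The chain has initial distribution π and transition matrix *A*. Fitting is by
generalized EM (Baum–Welch forms for π and *A*, bounded coordinate ascent for
θ, a monotone MM step for the p⃗ʲ), with identifiability thresholds
θ ≥ θ_min (default 0.15) and diag(A) ≥ a_min (default 0.5) enforced each
iteration, and stopping when the log-likelihood improves by less than
ε = 0.01. The fit is repeated from one deterministic ("Default") and several
random starting points; the run with the highest objective wins, and the
Viterbi path of its best iteration is the output. Per-site posterior state
probabilities γⱼ(k) are exported alongside.

The package also ships the two benchmark simulators (an HMM-model generator
and a logistic block-model generator with Hardy–Weinberg genotypes), the
Freeman–Halton exact test baselines with Bonferroni/Benjamini–Hochberg
classification, and the evaluation metrics (sensitivity, specificity, MCC
with the two influence signs collapsed).

## Worked example

```bash
# simulate one dataset from the influence model (48 sites, 80+80 subjects)
blockhmm simulate-hmm --sites 48 --controls 80 --cases 80 --seed 4 --out-prefix toy

# fit the HMM (1 Default + 1 Random start) and decode the state sequence
blockhmm fit --genotypes toy_genotypes.tsv --phenotypes toy_phenotypes.tsv \
             --theta-min 0.15 --random-starts 1 --out-prefix toy

# score the decoded states against the simulated truth
blockhmm evaluate --truth toy_truth.tsv --calls toy_states.tsv
```

The `fit` step prints:

```
selected run random-1, objective -473.336, 7 influential sites
```

meaning the random restart beat the Default start on the master objective
(log-likelihood −473.336) and the Viterbi path labels 7 of the 48 sites as
influential. The `evaluate` step then prints:

```
sensitivity	1.0
specificity	0.9111111111111111
mcc	0.6248809410409238
```

i.e. all 3 truly influential sites were recovered, 41 of the 45 No Influence
sites were left uncalled, and the Matthews correlation between truth and
calls is 0.62 (four false positives on a small panel are costly). The same
operations are available in Python via `blockhmm.fit`, `blockhmm.simulators`
and `blockhmm.evaluation`.

`blockhmm benchmark --group G --trials T` reproduces a full benchmark table
(HMM at θ_min ∈ {0.1, 0.15, 0.2} plus Bonferroni and FDR baselines) for any
of the nine simulation groups.

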