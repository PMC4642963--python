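# Methods

## Model

Diploid, sexual, discrete generations, four-step life cycle: diploid
selection → meiosis (recombination) → mutation → syngamy. The core layout is
one protein-coding gene plus one cis enhancer at recombination distance *r*.
An enhancer allele of strength *e* (stored as *z* = ln *e*) drives its cis
gene copy to produce a share *e/(e+e′)* of the protein pool; with total
expression buffered (model 1) this share is the only phenotype. Fitness is
the concave power map `W(f) = 1 − s·f^κ`, `κ = −log(h)/log 2`, of the
defective-protein fraction *f*, chosen so that *f* = 1/2 recovers the
standard heterozygote fitness 1 − h·s and *h* = 1/2 recovers additivity.
Whenever the two gene alleles of an individual have equal fitness values the
expression split is irrelevant and the code short-circuits to that value.

Model variants: (2) two enhancer–gene pairs on independent chromosomes with
a multiplicative fitness `W = W_A1·W_A2·W_E`, `W_E = exp(−I(Z1−Z2)²)` on the
summed log strengths (stabilizing selection on relative dosage); (3) one
pair plus a freely recombining transcription-factor locus,
`W_E = exp(−I(Z1+Z2)²)` (stabilizing selection on absolute expression, TF
strength opposing enhancer strength, optimum Z1+Z2 = 0); (4) model 1 where
each offspring's second gamete comes from the same parent with probability
`p_self`. The stabilizing intensity is calibrated against the gene-mutation
load: `I = −ln(1 − γ·u·h·s)/(4σ_E²)`, so one round of random enhancer
mutation costs γ times one round of gene mutation.

## Deterministic analysis

`deterministic.step_exact` is the exact four-haplotype recursion: ordered
genotype masses `x_i·x_j·W_ij`, gamete extraction with recombinant fraction
*r*, one-way gamete mutation A→a at rate *u*, renormalization (tolerance
1e−12). The linearized theory provides the masking + purging decomposition
of Δp, the balance frequency `p_a = u/(h̄s)` with mean dominance
`h̄ = h + 2Δh·p·q`, the QLE disequilibrium and the mean-fitness gradient.

Two analytic results were re-derived and corrected against the recursion:

* **QLE disequilibrium.** Expanding the one-generation selection gain of
  D at D = 0 to first order in p_a gives the source
  `p·q·p_a·s·[2Δh(1−2p)+δh]/2`; selection plus recombination erode D at
  rate `r + [h1·p² + 2pqh + h2·q²]·s`. The implemented expression is
  therefore `D = p·q·p_a·[2Δh(1−2p)+δh]·s / (2r + 2[h1p²+2pqh+h2q²]s)`.
  This matches the relaxed exact recursion to ~1% in the weak-parameter
  regime (and is required for the 15% drift-equivalence test to pass); a
  selection-denominator coefficient half this size overestimates D by a
  factor 2 at small r.
* **Purging bracket positivity.** The bracket `4hpq + (1−2p)(h2q − h1p)` is
  positive for all p when h ≥ 1/4 (verified numerically over strength
  ratios up to 50) but can dip slightly negative for strongly recessive
  mutations (h ≲ 0.24) near fixation of the stronger allele; the property
  test asserts it on the verified domain.

`p_a_balance_exact` solves the full one-locus balance (Brent root find on
the exact recursion fixed point) because the leading-order `u/(hs)` is badly
biased when u is not ≪ h·s: at s = 0.01, u = 1e−3, h = 0.25 the true
equilibrium is 0.26, not 0.40.

## Diffusion fixation probabilities

`U(p0) = ∫₀^{p0}ψ/∫₀¹ψ`, `ψ = exp(−∫₀^p 4N·Δp/(pq))`, with both integrals
accumulated by the trapezoid rule on a uniform grid (default 10⁴ intervals;
ψ handled in log space; both drift terms carry an explicit pq factor, so the
integrand is regular at the boundaries; the inner integral's reference point
at 0 cancels in the ratio). The drift treats the gene locus as quasi-
stationary at each mutant frequency. The default closure uses the corrected
QLE disequilibrium and the exact one-locus balance; a second,
non-perturbative closure relaxes the exact recursion with the mutant
frequency projected back each generation. The two agree to a few percent
and reproduce the published relative fixation probabilities (~20 and ~30 at
N·u = 10 for s = 0.01 and 0.1; ~2 at N·u = 1); the leading-order closure
(u/(hs) balance and the factor-2-smaller QLE denominator) does not — it
yields ~79/79/7.4 — which is why it is not offered. Weaker mutants are
handled by reflecting the stronger-allele drift (`Δp_mut(x) = −Δp(1−x)`).

## Wright–Fisher engine

Individual-based arrays of haplotypes; parents drawn with probability
proportional to fitness; per-pair crossover at rate r; free recombination
between pairs and to the TF locus; Poisson(2Nu) mutation events hitting
uniformly chosen allele copies with replacement. Gene mutation: bi-allelic
(wild → 1−s, no-op on deleterious copies) for fixation trials; infinite
alleles for escalation, multiplying the copy's fitness by 1−s_i with
s_i ~ Exp(mean s), redrawn if ≥ 1 (a replacement interpretation is
available via a kernel switch). Enhancer/TF mutation adds N(0, σ_E²) to z —
additive on the log scale so relative strength variation does not vanish as
strengths grow and strengths stay positive by construction.

Three exact performance rewrites (all distributionally identical to the
reference operations, which remain in the code and back the single-step
API):

* the monomorphic-enhancer burn-in runs on genotype counts (offspring
  alleles are iid Bernoulli draws from the fitness-weighted gamete pool;
  conditional-binomial multinomial sampling; mutation shifts a uniformly
  chosen copy's class) — individuals are exchangeable, so the trial
  population is reconstructed from the counts when the mutant is
  introduced;
* escalation drivers sample parents from a Vose alias table rebuilt each
  generation — the same categorical distribution the rejection sampler
  realizes — and draw per-generation crossover counts as Binomial(2N, r)
  when r < 0.01 (events assigned to gametes with replacement; the
  collision probability at r = 1e−6 is ≪ 1e−6);
* high-volume uniforms come from an inline SplitMix64 stream (published,
  BigCrush-tested); Poisson/normal/exponential/binomial draws stay on
  numpy's generator. Each driver seeds both streams from an explicit
  31-bit seed, so runs are bit-reproducible; replicate seeds derive from
  the master seed via `SeedSequence`.

Fixation-trial protocol: 2000 burn-in generations from the all-wild-type
state, one uniformly chosen chromosome receives the mutant enhancer
(strength ratio × resident), the tagged lineage is followed to absorption
(hard cap 10⁶ generations). `estimate_fixation_probability` reports the
fixation fraction with a Wilson 95% CI and the ratio to the neutral
1/(2N).

## Escalation summaries

Population-mean log strength is recorded every 100 generations (per-
individual values are never needed: every downstream quantity is a mean).
The escalation rate is the OLS slope of the replicate-mean trajectory from
generation 0; doubling time T₂ = ln 2 / slope (undefined/NaN for
non-positive slopes). Group comparisons use per-replicate slopes — not
per-replicate doubling times, whose 1/a transform explodes the variance of
near-flat replicates — with one-sided permutation tests.

## Statistical design of the stochastic checks

Expected-event-count arithmetic fixes which claims can be asserted on point
estimates and which cannot, at the scales used:

* Fixation cross-validation (N = 10³, s = 0.1, 10⁴ trials per
  configuration — the published trial count): the linked stronger mutant
  yields ~15 expected fixations (point assertions are safe), the weaker
  mutants ≪ 5 (asserting ratio < 1 is safe), but the free-recombining
  stronger mutant's true ratio (~0.8) is statistically indistinguishable
  from 1 even at 10⁴ trials; that claim is asserted through CI-consistency
  with the diffusion value plus the sign of the theory curve, and through
  the drop relative to the linked configuration.
* Escalation orderings (N = 500, 2·10⁴ generations, 20 replicates per
  setting): the replicate slope noise from mutation–drift wander of the
  mean (variance ≈ 2u_Eσ_E²t, independent of N) is comparable to the
  γ- and selfing-induced rate differences, so monotone claims ("T₂
  non-decreasing in γ / p_self") are asserted as the absence of a
  significant opposing trend (one-sided permutation test on the slope-vs-
  level regression at α = 0.05), while the strict claims (model 3 slower
  than model 2 pooled over matched γ; σ_E speeds escalation within each
  model) are asserted as significant one-sided effects at α = 0.05. The
  σ_E contrast uses 0.1 vs 0.2 rather than a wider pair: the calibrated
  stabilizing intensity scales as 1/σ_E², so small σ_E strengthens the
  dosage/expression coupling, whose compensatory co-fixations amplify
  common-mode drift noise faster than the signal grows. The same
  amplification inflates model 3's slope variance, which together with the
  small true contrast leaves the pooled model-3-vs-model-2 comparison
  underpowered at this scale. All seeds are fixed in the tests.

## What the generator does and does not emulate

The simulators generate exactly the study conditions of the four models:
two- or three-locus architectures, one gene (or two) under recurrent
partially recessive deleterious mutation, unbiased log-scale regulatory
mutation, fixed N, discrete generations. They do not emulate pleiotropy of
regulatory mutations (timing/tissue effects), bounded enhancer strength,
transvection or homolog pairing, linked backgrounds of many genes, or
demographic change — so passing tests support the internal consistency of
the theory, not its adequacy for any particular empirical system.

## Numerical choices and limitations

Default problem sizes (10⁴-interval quadrature grids; 10⁴ fixation trials;
escalation grids at N = 500, 2·10⁴ generations, 20 replicates) were chosen
so the full suite exercises every protocol at published-comparable accuracy
while remaining a routine desktop run. Known limitations: the analytic QLE
closure degrades when p_a is large (s ≲ u/h), where the recursion closure
should be preferred; the diffusion treats the gene locus as deterministic
(accurate for N·h·s ≫ 1); doubling times at N = 500 carry large replicate
noise, so single-replicate T₂ values should never be interpreted — only
replicate means with uncertainties.
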