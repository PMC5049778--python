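# Methods

## Model

A sequencing experiment is summarized by an m × k count matrix R: rows are
entities (genes, miRNAs, ChIP-seq regions, …), columns are conditions, and
R_c = Σ_i R_ic is the sequencing depth of condition c (supplied explicitly
when the matrix is a window into a larger transcriptome). Each cell is
modeled as

    R_ic ~ Binomial(R_c, p_ic),

where p_ic is the latent fraction of condition-c reads attributable to
entity i. Beliefs over p_ic are independent conjugate Betas per cell: prior
Beta(α⁰_ic, β⁰_ic), posterior Beta(α⁰_ic + R_ic, β⁰_ic + R_c − R_ic), with
posterior mean E(p_ic|c) = α/(α+β) and variance
Var(p_ic|c) = αβ/((α+β)²(α+β+1)).

The **Bayesian correlation** of entities i ≠ j is the correlation of their
latent fractions, with the condition c treated as uniform on its k values
and the posterior uncertainty folded in through the laws of total
covariance/variance:

    r^b_ij = Cov(E(p_ic|c), E(p_jc|c)) /
             sqrt( [E Var(p_ic|c) + Var E(p_ic|c)] · [same for j] ).

Independence of the per-entity Betas makes the within-condition covariance
term vanish, so the numerator is the (1/k-weighted) covariance of posterior
means across conditions. The E Var term in each denominator is the average
measurement uncertainty; it is what shrinks |r^b| below the Pearson
correlation of the empirical fractions R_ic/R_c when counts are low or
depths shallow, and it vanishes (so r^b → Pearson) as depths grow at fixed
composition.

All sums over conditions use population 1/k weights, in **both** variance
terms. This is forced by self-consistency (r^b_ii must reduce to Var/Var = 1)
and is the convention that reproduces the reference values on the built-in
toys (0.971/0.378/0.367 and 0.859/0.948).

## Priors

| scheme | α⁰_ic | β⁰_ic | rationale |
|---|---|---|---|
| `uniform` | 1 | 1 | flat belief on [0,1] |
| `dirichlet_marginal` | 1/m | 1 − 1/m | marginal of a symmetric Dirichlet over all m entities: a read has prior probability 1/m of coming from entity i |
| `zero_count` | (R_c+1)/(R_max+1) | 1 | built so the prior-mean share of the posterior mean is the constant 1/(2+R_max) in every condition |

`zero_count` (the default everywhere) has the strongest guarantees: the
constant prior-mean term cancels out of every covariance, so an entity with
zero counts in all conditions is **exactly** uncorrelated with everything,
and the correlation of any sparse pair obeys the explicit bound evaluated by
`theorem1_bound` (n_i n_j · 4R_max²/(k R_min²) · (k1/k + k2/k + k3/k² + k4)).
The engine exploits the cancellation algebraically: for this scheme it
centers the data term R_ic/(α⁰+β⁰+R_c) rather than the full posterior mean —
identical in exact arithmetic, but it makes the all-zero-row zeros exact in
floating point instead of ~1e−30 residues.

The `uniform` prior is retained as the cautionary baseline: for entities
with (near-)zero counts its posterior mean ≈ 1/R_c tracks the depth profile,
so under heterogeneous depths all such entities appear mutually correlated.
`zero_count_prior1_approx` evaluates the closed form of that artifact,

    var(1/R_c) / ( mean(1/R_c²) + var(1/R_c) ),

which is exactly 0 at equal depths and agrees with the exact all-zero-row
correlation to < 10⁻³ for depths ≥ 10⁴ (the dropped +1/+2 offsets decay as
1/R_c).

### Accuracy of the 1/m suppression claim

For two all-zero rows the Dirichlet-marginal prior suppresses the uniform
prior's artifact by a factor of order 1/m. The order statement is exact, but
the constant is not 1: writing D₁ for the mean within-condition variance and
A₁ for the across-condition variance under the uniform prior
(r^b1 = A₁/(D₁+A₁)), the exact ratio is

    r^b2 / r^b1 = (1/m) (D₁+A₁) / (D₁ + A₁/m)  →  (1/m) · 1/(1 − r^b1).

So r^b2 ≈ r^b1/m to 10% only when r^b1 ≲ 0.09 (near-homogeneous depths);
with depths spanning two orders of magnitude r^b1 ≈ 0.33–0.45 and the
constant is 1.5–1.8 regardless of m. The acceptance test asserting the 10%
version under heterogeneous depths therefore fails by design and is left in
place; a companion assertion verifies the exact relation above.

## Kernel property

`feature_embedding` constructs the witness vectors: g_ic = E(p_ic|c) −
E(p_ic), φ_i = g_i/√(k·V_i) (the 1/k condition weight must sit inside the
normalization for ⟨φ_i, φ_j⟩ to equal r^b_ij), and ψ_i ∈ ℝ^{k+m} appending
a single identity-indexed coordinate √(1 − ⟨φ_i, φ_i⟩) = √(E Var / V_i),
computed in that nonnegative-by-construction form. The Gram matrix of ψ
equals the correlation matrix (diagonal included), which proves positive
semidefiniteness — so 1 − r is a legitimate dissimilarity and the matrix
can feed kernel-based learners directly.

## Plausible intervals

For a single measurement, the exact two-sided binomial test of a
hypothesized expected count T sums the probabilities of all outcomes at most
as probable as the observed one under Binomial(R_c, T/R_c) (ties included;
delegated to `scipy.stats.binomtest`, which uses a 1+1e−7 relative tie
tolerance). The plausible interval is the set of non-rejected T at a given
level; endpoints are located by bisection on the acceptance indicator with
brackets found by geometric expansion from the observed count, to absolute
tolerance 1e−4 on the count scale by default. The p-value is piecewise
continuous in T with occasional small upward jumps (≈1e−4) where an outcome
enters the tie set; bisection on the indicator is insensitive to these. For
an observed count of zero the lower endpoint is pinned at the tolerance and
only the upper endpoint is searched; the relative uncertainty (interval
width over observed count, in percent) is NaN in that case.

The continuous bisection boundaries for the two reference vignettes are
[0.05129, 5.75589] (1 read of 10⁶) and [99413.39, 100589.89] (10⁵ of 10⁶).
The reference values [0.0520, 5.7550] and [99413, 100589] correspond to
scanning T at granularities of 10⁻³ and 1 respectively; tests therefore
assert agreement to within one scan step, not to the printed digits, and the
relative uncertainty rounds to the quoted 1.18% either way.

## Numerical choices

- Correlations are clipped to [−1, 1]; the diagonal is set to exactly 1
  (for classical methods only on non-degenerate rows); the matrix is
  symmetrized (½(C+Cᵀ)) before clipping.
- Classical (Pearson/Spearman) values within 8 ulps of ±1 are snapped to
  exactly ±1: proportional rows are mathematically at 1 and should read so.
- Zero-variance rows make Pearson/Spearman undefined: those entries (and
  the row's diagonal) are NaN and a RuntimeWarning is emitted. The Bayesian
  estimator never degenerates because posterior variances are strictly
  positive.
- Conditions with zero total counts are rejected for any correlation
  analysis (the posterior there is pure prior; empirical fractions are
  undefined).
- All-pairs computation is a single centered cross-product matrix multiply,
  O(m²k); an optional `block_size` assembles the result in row blocks
  (identical to round-off) to cap working memory for m beyond ~2×10⁴.
- Duplicate-row and all-zero-row removal are available but **off by
  default**, so the exact-zero guarantees of the zero-count prior remain
  observable.

## Synthetic data

`simulate_counts` draws each cell independently as
Binomial(depth_c, p_ic) under a seeded generator — exactly the sampling
model the estimator assumes, with per-column latent fractions constrained to
sum to at most 1. `resample_replicates` emulates technical replicates by
multinomial resampling of each condition's attributed reads at its own
total. What these generators deliberately do **not** model: biological
variability across replicates, overdispersion (negative-binomial noise),
amplification artifacts, or attribution ambiguity. Passing tests on this
synthetic data therefore demonstrate correctness of the estimator under its
own sampling assumptions, not robustness to real-data noise sources. The
qualitative prior comparison (uniform-prior spurious mass among unexpressed
entities under depths logspaced across two orders of magnitude, 10²–10⁴
reads, with ~1/3 of entities expressed at fractions ≤ 0.01) uses matrices of
60–80 entities × 6 conditions — large enough for stable medians of the
zero-block correlation distribution, small enough that the full suite runs
in seconds. The complexity check times the all-pairs engine at
m ∈ {100, 200, 400, 800}, k = 10 (best of 9 runs per size) and requires a
log–log slope of 2 ± 0.3.

## Known limitations

- Beliefs are independent Betas, not a joint Dirichlet, so within-condition
  covariances are assumed zero; entity fractions that are strongly
  competing (sum near 1) violate this.
- Replicates are treated as additional conditions; no replicate-aware noise
  model is provided.
- Only Pearson-type similarity is made precision-aware; Spearman is offered
  as a classical baseline without uncertainty handling.
- The plausible-interval machinery expects integer counts; fractional
  attribution is accepted by the correlation machinery but not by the exact
  binomial test.
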