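# Methods

## The model

The package treats each pair of binary disease indicators (A, B) as a
double dichotomization of a standard bivariate normal: A is present iff
X > τ_A, B iff Y > τ_B, with corr(X, Y) = ρ. The tetrachoric correlation is
the maximum-likelihood estimate of ρ from the observed 2×2 table. This is
the standard two-step estimator: the thresholds are fixed at the marginal
probits, τ_A = Φ⁻¹(1 − p_A), and ρ alone maximizes the multinomial
log-likelihood

ℓ(ρ) = n₁₁ log p₁₁(ρ) + n₁₀ log p₁₀(ρ) + n₀₁ log p₀₁(ρ) + n₀₀ log p₀₀(ρ),

with p₁₁(ρ) = P(X > τ_A, Y > τ_B; ρ) and the other cells by the margin
identities. Profiling the thresholds keeps the optimization one-dimensional
and matches the canonical definition of the statistic.

Disease networks connect pairs whose likelihood-ratio statistic
2(ℓ(ρ̂) − ℓ(0)) exceeds the χ²₁ quantile for p < 0.01. A stratum's patterns
are the communities of its network under weighted Newman–Girvan modularity
(resolution 1), found by Louvain.

## Numerical choices

* **Orthant probabilities.** P(X > h, Y > k; ρ) is computed from
  Plackett's derivative identity, integrated after the substitution
  r = sin θ:
  P = Q(h)Q(k) + (1/2π) ∫₀^{asin ρ} exp(−(h² − 2hk sin θ + k²)/(2cos²θ)) dθ.
  The integrand is smooth on the whole interval, so two 48-point
  Gauss–Legendre panels reach well below the 1e−8 contract for
  |ρ| ≤ 0.999 (tests verify machine-precision agreement with the arcsin
  closed form at h = k = 0 and with an Owen's-T identity elsewhere).
* **Optimization.** ρ̂ is found by bounded derivative-free bracketing
  (Brent) on [−0.999, 0.999] with xatol 1e−9, followed by one Newton polish
  step on the numerical gradient for interior optima; the gradient at the
  reported optimum is checked in tests. The ±0.999 clamp guards the
  unbounded likelihood near |ρ| = 1.
* **Empty cells.** A table with any zero cell gets 0.5 added to every cell
  (continuity correction, flagged on the result); without it the MLE
  diverges to ±1. Degenerate margins (a disease present in no or every
  patient) raise an estimation error before the correction is applied —
  degeneracy is judged on the observed table.
* **Standard error and test.** The SE comes from the observed information
  (numerical second derivative of ℓ at ρ̂). The default ρ = 0 test is the
  likelihood-ratio test with one degree of freedom; it is internal to the
  ML machinery and asymptotically equivalent to the Pearson χ² independence
  test on 2×2 tables, which is exposed as an alternative
  (`test_rho_zero(..., method="pearson")`). Which test the original
  analyses of this kind use is typically unstated; the choice matters
  little at administrative-data sample sizes. The fixed 0.01 cut-off is a
  stricter-alpha guard against multiple comparisons, not a formal FWER
  procedure; no further adjustment is applied by default.

## Network construction

* The prevalence filter is **strict**: a disease in exactly 1% of the
  stratum's patients is dropped. It is applied per stratum; a cohort-wide
  alternative would keep node sets identical across strata, but per-stratum
  filtering matches per-stratum analysis and is the default.
* Only positive significant correlations become edges by default
  (comorbidity is co-occurrence, and modularity assumes non-negative
  weights). `edge_sign="both"` admits negative correlations with |ρ̂| as
  weight; the sign is preserved in the `rho` attribute.
* Isolated prevalent diseases stay in the network and become singleton
  patterns.

## Louvain

Phase 1 sweeps nodes in seed-shuffled order, moving each to the
neighbouring community with the largest positive modularity gain (ties:
stay put if staying ties the best; among movers, lowest community id).
Phase 2 aggregates communities into super-nodes (intra-community weight
becomes self-loop weight) and repeats. Two exact identities are asserted at
run time: modularity never decreases across passes, and the aggregated
graph's modularity equals the original graph's under the induced partition.
Passes stop when the absolute gain falls below 1e−10.

Single-run Louvain is a greedy heuristic and can land in local optima even
on 6–8-node graphs (reference implementations in other libraries show the
same behaviour). The package therefore exposes `louvain_best_of` and the
pipeline defaults to **best-of-5 restarts**, with restart seeds derived
deterministically from the master seed and the stratum label (CRC-32 of the
label, so results are independent of stratum processing order and of
Python's per-process hash salt). Resolution is fixed at 1 by default and
exposed. A brute-force enumerator over all set partitions (feasible to
~10 nodes, Bell(10) = 115 975) serves as the exact oracle in tests.

## Synthetic cohorts

The generator draws, per stratum, Z ~ N(0, Σ) with Σ the planted
block-correlation matrix (unit diagonal, ρ_within inside a block,
ρ_between across; positive-definiteness verified and violations rejected
with the offending parameters named). Disease j is present iff the j-th
latent coordinate exceeds Φ⁻¹(1 − prevalence_j). Sampling uses the lower
Cholesky factor applied to a single row-major `standard_normal((n, d))`
block from a Generator seeded by `SeedSequence([seed, crc32("SEX|BAND")])` —
the documented, fixed stream order; a stratum's draw depends only on the
master seed and its own label, so subsetting strata never changes results.

Defaults emulate the shape of a stratified EHR cohort at desk scale:
3 blocks × 8 diseases, prevalences cycling over {5%, 10%, 20%, 30%}
(typical chronic-category prevalences, all above the 1% floor), ρ_within =
0.5 (the single published correlation magnitude in this literature is a
near-ceiling 0.99; 0.5 is a deliberately moderate planted signal),
ρ_between = 0, 5000 patients per stratum for recovery experiments. Because
the tetrachoric estimator is exactly the inverse of this generative model,
parameter recovery (|bias| < 0.05 at n = 5000) and planted-pattern recovery
(ARI ≥ 0.9) are valid end-to-end tests of the whole chain.

What the generator does **not** emulate: realistic ICD-9-CM code streams
(each synthetic disease is its own code, mapped through an identity
lookup), care-seeking behaviour, longitudinal onset, age/sex-dependent
prevalence gradients, or the heavy-tailed degree structure of real
comorbidity networks. A green end-to-end test therefore establishes that
the machinery is correct under the stated latent-Gaussian world, not that
real cohorts would yield the same patterns.

## Record grouping

Sex and age band must be constant per patient; conflicts are a hard error
rather than first-seen-wins, since silent misstratification is worse than a
failed run. Raw ages are banded with inclusive bounds [0,2], [3,10],
[11,17], [18,65], (65,∞) — interval-boundary conventions are rarely stated
in source materials, so the package fixes and documents this one. The
cohort-defining index disease, when designated on the lookup
(`index_category_id`), is excluded from matrices by default: a condition
present in ~100% of patients has degenerate margins and no estimable
correlations. Unmapped and non-chronic codes are reported with counts, not
silently dropped.

## Known limitations

* No polychoric (>2 level) generalization, no exact small-sample p-values,
  no signed-graph modularity, no overlapping or hierarchical communities.
* The pattern report orders diseases by prevalence within each pattern;
  clinical naming of patterns is inherently a human step and out of scope.
* GEXF round trips preserve node/edge attributes but not graph-level
  metadata; GraphML preserves both.
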