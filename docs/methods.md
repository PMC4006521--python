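# Methods

## Penetrance models

A purely epistatic model over m loci assigns penetrance (probability of
disease given genotype) to each of the 3^m joint genotypes such that every
single-locus marginal — the table averaged over the other loci with
Hardy-Weinberg weights — is constant and equal to the population prevalence
K. The built-in family (orders 2, 3, 4; causative allele frequency fixed at
0.5) puts mass on three cells per order:

| order | nonzero cells (minor-allele counts) | values |
|---|---|---|
| 2 | (0,2), (1,1), (2,0) | 4K, 2K, 4K |
| 3 | (0,2,0), (1,1,1), (2,0,2) | 16K, 4K, 16K |
| 4 | (0,2,0,2), (1,1,1,1), (2,0,2,0) | 64K, 8K, 64K |

Writing the pattern as penetrance = K·M, the HWE mean of M is exactly 1 and
its HWE variance is c ∈ {2, 9, 35}, so prevalence = K and the broad-sense
heritability on the penetrance scale is h² = Var(pen)/(K(1−K)) = cK/(1−K).
`build_pure_epistasis_model` computes c numerically from the pattern (not
hard-coded) and solves K = h²/(c + h²); for h² = 0.01 this gives
K = 0.01/2.01, 0.01/9.01 and 0.01/35.01. Construction fails if the implied
maximum penetrance would exceed 1 (order 2: h² > 2/3). The three- and
four-locus models deliberately retain non-flat two-locus marginals — the
two-locus marginal of either higher-order model is exactly the order-2
pattern — which is what makes them detectable by a pairwise scan.

## Simulator

The generator emulates probability-based case-control simulation. Controls
are drawn unconditionally from the population: each SNP independently under
HWE, causative SNPs at frequency 0.5, non-causative SNPs at a per-SNP MAF
drawn once per dataset uniformly from [0.05, 0.5]. (Conditioning controls
on being unaffected would change genotype frequencies by order K ≈ 5e-3 and
is omitted.) Cases are split into per-component quotas
round(mix_j · n_cases), any rounding remainder going to the
largest-proportion component; each component's causative genotypes are
rejection-sampled — draw from the population, accept with probability equal
to the penetrance — so accepted tuples follow P(g|case) = f(g)pen(g)/K, and
every other SNP (including the other component's causative SNPs) is drawn
from the population. A draw cap (default 10^7 per component) guards against
(near-)zero-penetrance tables; at K ≈ 5e-3 a quota of 800 cases needs
~1.6e5 draws, and the order-4 model (K ≈ 2.9e-4) ~2.8e6. SNPs are unlinked
by construction: the simulator reproduces neither LD structure, nor missing
genotypes, nor covariates, so passing tests say nothing about those aspects
of real data. What the simulated conditions do preserve end-to-end is pure
epistasis: single-locus p-values at causative SNPs are uniform (tested by a
Kolmogorov–Smirnov check over 200 replicates).

Scenario grids enumerate component order pairs 2&2 … 4&4 and case-mix
ratios 1:1, 1:3, 3:1; the first-listed (lower-order) component receives
r/(r+s). For equal-order pairs, r:s and s:r describe the same scenario and
are deduplicated.

## Two-locus test and screens

The pair statistic is Pearson's χ² on the 2 × 9 case/control ×
joint-genotype table with dof = (non-empty columns − 1): empty joint
genotypes are common even at 1,600 samples, and a fixed dof of 8 with
zero-expectation cells is undefined. No continuity correction or minimum
expected count is applied — the permutation layer, not the asymptotic
p-value, carries the final inference; the asymptotic p is used for ranking
and Bonferroni screening. Missing genotypes (file-based data only) are
excluded pairwise; the vectorised scan kernels require complete data. MAF
is computed on all samples. The SNP screen retains MAF ≥ 0.1, single-locus
uncorrected p > 0.05 and control-sample HWE p ≥ 0.001 by default; the HWE α
has no canonical value and is exposed as a parameter. LD (D′, r²) comes
from EM haplotype-frequency estimation on the 3 × 3 unphased table
(tolerance 1e-8, 1,000-iteration cap, flagged if not converged); LD should
be assessed in controls, since in cases the disease model itself correlates
interacting loci.

## Omnibus permutation test

Corrected p-values are combined with Fisher's function T = −2 Σ log p̃; a
corrected p of exactly 0 (χ² tail underflow) is floored at 1e-300 and
flagged. The t permutations preserve class counts; replicate i is generated
from seed sequence (seed, i) so any replicate is reproducible in isolation.

Replicate statistics are *re-ranked*: T_i^(k) combines the k smallest
corrected p-values within replicate i, computed over the same pair universe
as the observed ranking. This makes the permutation test selection-aware:
the observed top-k statistic is the maximum over a large search space, and
comparing it against replicates that are denied the same optimisation would
be anti-conservative to the point of uselessness (the minimum of ~C(n,2)
uniform p-values is almost always "significant" against a fixed-pair null).
With re-ranking, the scan's type-I error on null datasets is at the nominal
α (calibration test over 200 null datasets). The incremental identity
T_i^(k) = T_i^(k−1) − 2 log p̃_i,(k) is preserved and tested against
from-scratch recomputation for exact equality.

Raw and global p-values follow the counting definitions: p₀ᵉ is the
fraction of replicates with T ≥ T₀ (ties count; 0 is possible and rendered
"< 1/t"); per-replicate p-values use the pooled reference set that includes
the observed data (row 0), so the observed row of the replicate p-matrix
equals the raw p-value; the global p-value compares each replicate's
minimum p over the explored ensembles with the observed minimum.

The best-ensemble search adds pairs in order of corrected p (ties broken by
χ² descending, then index) and stops at the first strict increase of either
p-value, or when candidates are exhausted; if the first ensemble is already
non-significant the result is "no association". Candidates are pairs with
corrected p < α (at least the top pair). The rationale for the α-threshold:
under a strongly associated dataset both permutation p-values sit at 0/t,
the stop-on-increase rule can never fire, and an unbounded candidate list
would absorb every pair into the "best" ensemble, destroying the
parsimonious output that makes the pair-graph interpretation meaningful; a
pair that is not individually significant after Bonferroni correction
contributes nothing that the ensemble test can measure at resolution 1/t.
This cap is what produces the characteristic power pattern: the pair
carried by the smaller case subgroup enters the ensemble exactly when its
corrected p clears α, which grows harder as the Bonferroni factor C(n,2)
grows.

For large panels the replicate re-ranking universe can optionally be capped
(`perm_pair_cap`) to the strongest observed pairs. The observed statistic
is exact; the replicate null is then computed over a reduced universe,
which biases raw p-values downward. This approximation is intended for
strongly associated large-n datasets where detection is not in question; it
is not used in the calibration tests.

## Interpretation and power

Connected components of the best ensemble's pair graph are reported as
independent interactions (an m-SNP component = an m-locus interaction).
Against simulated truth, a pair "recovers" a disease component when both
its SNPs are in that component's causative set — the only reading
consistent with disjoint causative sets; the ensemble-edge (not merely
same-component nodes) reading is used, the stricter of the two. "Two
interactions detected" requires distinct components each recovered by some
pair; such pairs are automatically disjoint. Output-SNP and
correct-causative-SNP counts are recorded per dataset and are zero when no
association is declared. Power over replicate datasets is the fraction of
verdicts at each level; per-dataset audit records (seeds, verdicts, counts,
p-values) are kept so every aggregate can be recomputed exactly.

## Problem sizes and numerical choices

Reference conditions: 20 SNPs, 1,600 balanced samples, h² = 0.01, α = 0.05,
t = 10,000 permutations, 100 datasets per scenario (the acceptance script
runs exactly this). The test suite uses reduced sizes chosen as a
compute/precision trade-off: 30 datasets with t = 500 for the 20-SNP power
cells, 20 datasets with t = 150 and a 2,000-pair permutation cap for the
1,000-SNP cells, 3 datasets with t = 100 for the 10,000-SNP cell, with
tolerances of three binomial standard errors at the reduced count.
Stochastic assertions are seeded. The pairwise kernels store condensed
per-pair statistics (float64 up to ~4e6 pairs, float32 beyond, with
counting done exactly in either case) so a 10,000-SNP scan stays within a
few GB of memory; beyond the Bonferroni-saturated tail of a very large
panel the pair ordering is deterministic but not fully tie-broken, which no
downstream step can observe.

## Known limitations

- The simulator's idealisations above (no LD, complete data, HWE controls).
- The re-ranked permutation null is exact only when computed over all
  pairs; `perm_pair_cap` trades exactness for tractability on large panels.
- Candidate selection at corrected p < α means the method cannot assemble
  ensembles from individually non-significant pairs, by design.
- The asymptotic χ² p-values used for ranking are inaccurate for very
  sparse tables; the permutation layer absorbs this for inference but the
  reported per-pair p-values inherit it.
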