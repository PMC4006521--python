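# epiomb

Detection of **pure epistasis** and **genetic heterogeneity** in case-control
SNP data by an omnibus permutation test on ensembles of two-locus χ²
analyses.

## The problem

Some multi-locus disease models carry no single-locus signal at all: each
causative SNP's marginal penetrance is exactly the population prevalence
*K*, so genome-wide single-SNP scans are blind to them ("pure epistasis").
When, in addition, two *independent* interactions each explain a different
subgroup of the cases ("genetic heterogeneity"), the signal per interaction
is further diluted. This package implements, for geneticists and
methodologists working on interaction detection:

- the purely epistatic two-, three- and four-locus penetrance models
  (baseline *K* solved from a target heritability *h²*, causative allele
  frequency 0.5),
- a probability-based case-control simulator with two independent disease
  components mixed into the case group at a chosen ratio,
- the omnibus scan itself, and the screening (MAF, marginal effects,
  control HWE, gene proximity) and LD (D′, r² via EM haplotype
  frequencies) steps that surround it in a real-data workflow,
- power evaluation over replicate datasets with the
  one-interaction/two-interaction detection criteria.

## The statistic

For *n* SNPs, all C(n,2) pairs are tested with Pearson's χ² on the 2 × 9
case/control × joint-genotype table (dof = non-empty columns − 1), and each
p-value is Bonferroni-corrected: p̃ = min(C(n,2)·p, 1). An *ensemble* of the
k best pairs is scored with Fisher's combining function

    T = −2 Σ log p̃_i .

Significance comes from t label permutations. Within each permutation the
pairs are **re-ranked**, so replicate i's statistic combines *its own* k
smallest corrected p-values — the observed statistic, built from the k best
observed pairs, is thereby compared against its selection-aware null
(Westfall–Young style). The raw p-value of ensemble e is

    p₀ᵉ = |{i : Tᵢᵉ ≥ T₀ᵉ}| / t ,

and, because the search explores ensembles of several sizes, a min-p global
adjustment over the explored ensembles yields p_global. The ensemble grows
pair by pair (candidates: pairs individually significant after Bonferroni
correction) until the raw or global p-value increases; association is
declared when both are below α. Disconnected components of the resulting
pair graph are independent interactions — the signature of genetic
heterogeneity.

## Worked example

```sh
python examples/02_simulate_and_scan.py
```

prints (seed 42; two hidden two-locus interactions on SNPs 0&1 and 2&3,
cases mixed 1:3):

```
dataset: 1600 samples x 20 SNPs, causative SNPs (0, 1, 2, 3)
detected: True
best ensemble pairs: ((2, 3), (0, 1))
raw p: <0.0005   global p: <0.0005
independent interactions: 2 -> (frozenset({0, 1}), frozenset({2, 3}))
verdict vs truth: two
```

Both planted pairs are recovered as two disjoint graph components — two
independent interactions — with permutation p-values below the 1/t
resolution. The other examples build the penetrance models
(`01_penetrance_models.py`), estimate power over replicate datasets
(`03_power_study.py`), and run the full screen → gene-interval filter →
scan → LD workflow on synthetic data (`04_screen_and_ld.py`).

A thin CLI mirrors the library:
`epiomb {simulate, screen, scan, power, ld}`, each writing a run manifest
(seed, parameters, input digests) next to its output.

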