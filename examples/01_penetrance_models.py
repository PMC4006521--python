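"""Build the purely epistatic penetrance models and inspect their structure.

A purely epistatic model hides all association signal in joint genotypes:
every single-locus marginal penetrance equals the population prevalence K,
so no single-SNP test can see the causative loci.
"""

import numpy as np

from epiomb import (
    build_pure_epistasis_model,
    heritability_of,
    marginal_penetrance,
    prevalence_of,
)

for order in (2, 3, 4):
    model = build_pure_epistasis_model(order, heritability=0.01)
    print(f"\n{order}-locus model (heritability 0.01)")
    print(f"  baseline K (prevalence): {model.k_baseline:.6g}")
    print(f"  recomputed prevalence:   {prevalence_of(model):.6g}")
    print(f"  recomputed heritability: {heritability_of(model):.6g}")
    marg = marginal_penetrance(model, [0])
    print(f"  single-locus marginal:   {np.round(marg, 8)}  (flat = pure epistasis)")
    if order > 2:
        pair = marginal_penetrance(model, [0, 1])
        print(f"  two-locus marginal range: {pair.min():.3g} .. {pair.max():.3g} "
              "(non-flat: a two-locus scan can find it)")

# The printed K values are the solved baselines: 0.01/2.01, 0.01/9.01 and
# 0.01/35.01 for orders 2, 3 and 4 — each model trades a lower prevalence
# for the same heritability as the interaction order grows.
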