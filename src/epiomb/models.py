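"""Purely epistatic penetrance models.

A purely epistatic model assigns a disease probability (penetrance) to every
joint genotype of a set of interacting loci such that *no single locus carries
any marginal effect*: averaging the penetrance table over all loci but one,
with Hardy-Weinberg genotype weights, yields a constant equal to the population
prevalence K.  Association signal therefore exists only in joint genotype
distributions, which is what makes these models the canonical stress test for
interaction-detection methods.

The two-, three- and four-locus model family implemented here places all
penetrance mass on three joint genotypes.  Writing genotypes as counts of the
minor allele (0, 1, 2) and fixing the causative allele frequency at 0.5, the
nonzero cells are::

    order 2:  (0,2) -> 4K   (1,1) -> 2K     (2,0) -> 4K
    order 3:  (0,2,0) -> 16K  (1,1,1) -> 4K   (2,0,2) -> 16K
    order 4:  (0,2,0,2) -> 64K  (1,1,1,1) -> 8K  (2,0,2,0) -> 64K

Each pattern has population prevalence exactly K and broad-sense heritability
h2 = c*K/(1-K) on the penetrance scale, with a pattern constant c (2, 9 and 35
for orders 2, 3 and 4).  ``build_pure_epistasis_model`` computes c numerically
from the pattern and solves for the K that yields a requested heritability.
The three- and four-locus models retain marginal *two-locus* effects (their
two-locus marginals reproduce the order-2 pattern), which is what a two-locus
scan exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce
from itertools import product
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PenetranceModel",
    "build_pure_epistasis_model",
    "heritability_of",
    "prevalence_of",
    "marginal_penetrance",
    "model_to_config",
    "model_from_config",
]

#: nonzero penetrance cells of each model order, in units of the baseline K.
PATTERNS: dict[int, dict[tuple[int, ...], float]] = {
    2: {(0, 2): 4.0, (1, 1): 2.0, (2, 0): 4.0},
    3: {(0, 2, 0): 16.0, (1, 1, 1): 4.0, (2, 0, 2): 16.0},
    4: {(0, 2, 0, 2): 64.0, (1, 1, 1, 1): 8.0, (2, 0, 2, 0): 64.0},
}


def _genotype_weights(allele_freq: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for minor-allele counts 0, 1, 2."""
    q = allele_freq
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])


def _joint_weights(order: int, allele_freq: float) -> np.ndarray:
    """HWE weight array of shape (3,)*order for independent, unlinked loci."""
    w1 = _genotype_weights(allele_freq)
    return reduce(np.multiply.outer, [w1] * order)


@dataclass(frozen=True)
class PenetranceModel:
    """A genotype -> penetrance table for a set of interacting loci.

    Parameters
    ----------
    order
        Number of interacting loci (2, 3 or 4 for the built-in family).
    table
        Array of shape ``(3,)*order``; entry ``table[g1, ..., gm]`` is the
        probability of disease given ``gi`` copies of the minor allele at
        locus ``i``.
    k_baseline
        Population prevalence K implied by the table under HWE.
    heritability
        Broad-sense heritability on the penetrance scale,
        ``Var(pen) / (K (1 - K))``.
    allele_freq
        Causative (minor) allele frequency; 0.5 for the built-in family.
    """

    order: int
    table: np.ndarray
    k_baseline: float
    heritability: float
    allele_freq: float = 0.5

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        if table.shape != (3,) * self.order:
            raise ValueError(
                f"table shape {table.shape} does not match order {self.order}"
            )
        if np.any(table < 0) or np.any(table > 1):
            raise ValueError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "table", table)

    @property
    def weights(self) -> np.ndarray:
        return _joint_weights(self.order, self.allele_freq)


def prevalence_of(model: PenetranceModel) -> float:
    """Population prevalence K = sum_g f(g) pen(g) under HWE weights."""
    return float(np.sum(model.weights * model.table))


def heritability_of(model: PenetranceModel) -> float:
    """Broad-sense heritability of a penetrance table on the penetrance scale.

    Returns ``sum_g f(g) (pen(g) - K)^2 / (K (1 - K))`` with
    ``K = sum_g f(g) pen(g)``.  Raises for K = 0 or K = 1, where the quantity
    is undefined.
    """
    w = model.weights
    k = float(np.sum(w * model.table))
    if k <= 0.0 or k >= 1.0:
        raise ValueError(f"heritability undefined for prevalence K={k}")
    var = float(np.sum(w * (model.table - k) ** 2))
    return var / (k * (1.0 - k))


def _pattern_table(order: int) -> np.ndarray:
    """Penetrance pattern in units of K (i.e. the table for K = 1)."""
    m = np.zeros((3,) * order)
    for cell, coef in PATTERNS[order].items():
        m[cell] = coef
    return m


def build_pure_epistasis_model(
    order: int, heritability: float, allele_freq: float = 0.5
) -> PenetranceModel:
    """Construct the purely epistatic model of a given order and heritability.

    The baseline K is solved from the pattern itself: with pattern table M
    (penetrance = K*M), prevalence is ``a*K`` and penetrance variance is
    ``v*K**2`` where ``a = E[M]`` and ``v = Var(M)`` under HWE weights, so

        h2 = v K / (a (1 - a K))   =>   K = h2 a / (v + h2 a**2).

    For the built-in family a = 1 exactly and v = c in {2, 9, 35}, giving
    K = h2 / (c + h2).

    Raises
    ------
    ValueError
        For an unsupported order, a non-positive heritability, or a
        heritability large enough that some penetrance would exceed 1.
    """
    if order not in PATTERNS:
        raise ValueError(f"unsupported model order {order}; expected one of {sorted(PATTERNS)}")
    if not 0.0 < heritability < 1.0:
        raise ValueError("heritability must lie in (0, 1)")
    m = _pattern_table(order)
    w = _joint_weights(order, allele_freq)
    a = float(np.sum(w * m))
    v = float(np.sum(w * m ** 2) - a ** 2)
    k = heritability * a / (v + heritability * a ** 2)
    table = k * m
    if table.max() > 1.0:
        raise ValueError(
            f"heritability {heritability} implies a penetrance of {table.max():.3g} > 1"
        )
    return PenetranceModel(
        order=order,
        table=table,
        k_baseline=k,
        heritability=heritability,
        allele_freq=allele_freq,
    )


def marginal_penetrance(
    model: PenetranceModel, loci: Sequence[int]
) -> np.ndarray:
    """Marginal penetrance table over a proper subset of the model's loci.

    Averages the full table over the complementary loci with HWE weights:
    ``pen_S(g_S) = sum_{g_C} f(g_C) pen(g_S, g_C)``.  The result has shape
    ``(3,)*len(loci)`` indexed in the order given by ``loci``.
    """
    loci = tuple(loci)
    if len(loci) == 0:
        raise ValueError("loci subset must be non-empty")
    if len(set(loci)) != len(loci):
        raise ValueError("loci subset contains duplicates")
    if any(l < 0 or l >= model.order for l in loci):
        raise ValueError(f"loci {loci} out of range for order {model.order}")
    if len(loci) == model.order:
        raise ValueError("loci must be a proper subset of the model's loci")

    complement = [l for l in range(model.order) if l not in loci]
    w1 = _genotype_weights(model.allele_freq)
    table = model.table
    # weight complementary axes, then sum them out
    for axis in complement:
        shape = [1] * model.order
        shape[axis] = 3
        table = table * w1.reshape(shape)
    marg = table.sum(axis=tuple(complement))
    # reorder remaining axes to follow the requested loci order
    kept = [l for l in range(model.order) if l in loci]
    perm = [kept.index(l) for l in loci]
    return np.transpose(marg, perm)


def model_to_config(model: PenetranceModel) -> dict:
    """Plain JSON-serialisable description of a model."""
    return {
        "order": model.order,
        "heritability": model.heritability,
        "allele_freq": model.allele_freq,
        "k_baseline": model.k_baseline,
        "table": model.table.tolist(),
    }


def model_from_config(config: Mapping) -> PenetranceModel:
    """Build a model from a config mapping.

    Accepts either the compact form ``{"order": 2, "heritability": 0.01}``
    (pattern family, K solved) or an explicit ``"table"`` with nested lists,
    whose prevalence and heritability are then computed, not trusted.
    """
    allele_freq = float(config.get("allele_freq", 0.5))
    if "table" in config:
        table = np.asarray(config["table"], dtype=float)
        order = table.ndim
        probe = PenetranceModel(
            order=order, table=table, k_baseline=0.0, heritability=0.0,
            allele_freq=allele_freq,
        )
        k = prevalence_of(probe)
        h2 = heritability_of(probe)
        return PenetranceModel(
            order=order, table=table, k_baseline=k, heritability=h2,
            allele_freq=allele_freq,
        )
    return build_pure_epistasis_model(
        int(config["order"]), float(config["heritability"]), allele_freq
    )
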