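"""Probability-based case-control genotype simulation with genetic heterogeneity.

The generator emulates the probability-based mode of penetrance-driven
case-control simulators: genotypes are drawn from the population distribution
and a sample is accepted into the case group with probability equal to its
penetrance, repeated until the requested number of cases is reached.  Two (or
more) independent purely epistatic disease components share the case group in
fixed proportions, which is the genetic-heterogeneity setting: disjoint sets of
causative SNPs, each responsible for a different subgroup of cases.

Defaults follow the study conditions the models were designed for: causative
allele frequencies of 0.5, non-causative minor-allele frequencies uniform on
[0.05, 0.5], unlinked SNPs, balanced case/control samples and controls drawn
from the population under Hardy-Weinberg equilibrium (prevalence is of order
5e-3, so conditioning controls on being unaffected would be a negligible
correction).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .models import PenetranceModel, build_pure_epistasis_model

__all__ = [
    "DiseaseArchitecture",
    "TruthInfo",
    "GenotypeDataset",
    "simulate_dataset",
    "simulate_null_dataset",
    "scenario_grid",
]

logger = logging.getLogger(__name__)

#: guard against an infinite rejection loop for (near-)zero penetrance tables.
DEFAULT_ATTEMPT_CAP = 10_000_000


@dataclass(frozen=True)
class DiseaseArchitecture:
    """Disease model for one simulated dataset.

    ``components`` pairs each penetrance model with the (disjoint) indices of
    its causative SNPs; ``case_mix`` gives the proportion of case samples
    attributable to each component (genetic heterogeneity); remaining SNPs are
    non-causative with per-SNP minor-allele frequencies drawn uniformly from
    ``noncausative_maf_range``.
    """

    components: tuple[tuple[PenetranceModel, tuple[int, ...]], ...]
    case_mix: tuple[float, ...]
    n_snps: int
    noncausative_maf_range: tuple[float, float] = (0.05, 0.5)
    scenario_id: str | None = None

    def __post_init__(self) -> None:
        components = tuple(
            (model, tuple(int(i) for i in idx)) for model, idx in self.components
        )
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "case_mix", tuple(float(p) for p in self.case_mix))
        if len(self.case_mix) != len(self.components):
            raise ValueError("case_mix must have one proportion per component")
        if self.components and not math.isclose(sum(self.case_mix), 1.0, rel_tol=1e-9):
            raise ValueError("case_mix must sum to 1")
        seen: set[int] = set()
        for model, idx in self.components:
            if len(idx) != model.order:
                raise ValueError("causative index tuple length must equal model order")
            if any(i < 0 or i >= self.n_snps for i in idx):
                raise ValueError("causative SNP index out of range")
            if seen.intersection(idx):
                raise ValueError("causative SNP sets must be disjoint across components")
            seen.update(idx)

    @property
    def causative_indices(self) -> tuple[int, ...]:
        """Sorted union of causative SNP indices over all components."""
        out: set[int] = set()
        for _, idx in self.components:
            out.update(idx)
        return tuple(sorted(out))

    @property
    def component_index_sets(self) -> tuple[frozenset[int], ...]:
        return tuple(frozenset(idx) for _, idx in self.components)


@dataclass(frozen=True)
class TruthInfo:
    """Ground truth attached to a simulated dataset.

    ``case_component[s]`` is the disease component responsible for sample
    ``s`` (an index into ``architecture.components``), or -1 for controls.
    """

    architecture: DiseaseArchitecture
    case_component: np.ndarray


@dataclass
class GenotypeDataset:
    """Samples x SNPs additive-coded genotype matrix with case/control labels.

    ``genotypes`` holds minor-allele counts in {0, 1, 2} (int8; -1 marks a
    missing genotype in data read from files — simulated data has none).
    ``phenotype`` is 1 for cases, 0 for controls.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    truth: TruthInfo | None = None
    seed: int | None = None
    snp_chrom: list[str] | None = None
    snp_pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D samples x SNPs matrix")
        if self.genotypes.shape[0] != self.phenotype.shape[0]:
            raise ValueError("genotypes and phenotype disagree on sample count")
        if len(self.snp_ids) != self.genotypes.shape[1]:
            raise ValueError("snp_ids length must equal the SNP count")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))


def _case_quotas(case_mix: Sequence[float], n_cases: int) -> list[int]:
    """Per-component case quotas; rounding remainder goes to the largest mix."""
    quotas = [int(round(p * n_cases)) for p in case_mix]
    remainder = n_cases - sum(quotas)
    if remainder != 0:
        j = int(np.argmax(case_mix))
        quotas[j] += remainder
        logger.info(
            "case quota rounding left a remainder of %d; assigned to component %d",
            remainder, j,
        )
    if any(q < 0 for q in quotas):
        raise ValueError(f"case_mix {case_mix} yields a negative quota for n_cases={n_cases}")
    return quotas


def _sample_case_genotypes(
    model: PenetranceModel,
    quota: int,
    rng: np.random.Generator,
    attempt_cap: int,
) -> np.ndarray:
    """Rejection-sample causative-locus genotypes for `quota` case samples.

    Draws genotype tuples from the population (HWE at the model's allele
    frequency) and accepts each with probability equal to its penetrance, so
    accepted tuples follow P(g | case) = f(g) pen(g) / K.
    """
    if model.table.max() <= 0.0:
        raise ValueError("penetrance table is identically zero; no case can be drawn")
    accepted = np.empty((quota, model.order), dtype=np.int8)
    n_got = 0
    attempts = 0
    # batch sized for the expected acceptance rate (= prevalence K)
    k = max(float(np.sum(model.weights * model.table)), 1e-12)
    batch = int(min(max(2.0 * quota / k, 10_000), 2_000_000))
    while n_got < quota:
        if attempts >= attempt_cap:
            raise RuntimeError(
                f"rejection sampling exceeded the attempt cap ({attempt_cap}) "
                f"with {n_got}/{quota} cases accepted"
            )
        b = int(min(batch, attempt_cap - attempts))
        g = rng.binomial(2, model.allele_freq, size=(b, model.order)).astype(np.int8)
        pen = model.table[tuple(g.T)]
        keep = rng.random(b) < pen
        attempts += b
        take = g[keep][: quota - n_got]
        accepted[n_got : n_got + take.shape[0]] = take
        n_got += take.shape[0]
    return accepted


def simulate_dataset(
    arch: DiseaseArchitecture,
    n_cases: int,
    n_controls: int,
    seed: int,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
) -> GenotypeDataset:
    """Simulate one case-control dataset under a disease architecture.

    Controls are drawn per SNP under HWE (causative SNPs at the model allele
    frequency, others at a per-SNP frequency drawn once uniformly from the
    architecture's MAF range).  Cases are filled per component: the component's
    causative genotypes by rejection sampling against its penetrance table,
    every other SNP from the population.  Ground truth (architecture plus each
    case's component) is attached.
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must both be positive")
    if not arch.components:
        raise ValueError("architecture has no disease components; use simulate_null_dataset")
    rng = np.random.default_rng(seed)

    freqs = rng.uniform(*arch.noncausative_maf_range, size=arch.n_snps)
    for model, idx in arch.components:
        freqs[list(idx)] = model.allele_freq

    quotas = _case_quotas(arch.case_mix, n_cases)

    n_total = n_cases + n_controls
    genotypes = np.empty((n_total, arch.n_snps), dtype=np.int8)
    case_component = np.full(n_total, -1, dtype=np.int64)

    row = 0
    for j, ((model, idx), quota) in enumerate(zip(arch.components, quotas)):
        if quota == 0:
            continue
        causative = _sample_case_genotypes(model, quota, rng, attempt_cap)
        block = rng.binomial(2, freqs, size=(quota, arch.n_snps)).astype(np.int8)
        block[:, list(idx)] = causative
        genotypes[row : row + quota] = block
        case_component[row : row + quota] = j
        row += quota
    genotypes[row:] = rng.binomial(2, freqs, size=(n_controls, arch.n_snps)).astype(np.int8)

    phenotype = np.zeros(n_total, dtype=np.int8)
    phenotype[:n_cases] = 1
    snp_ids = [f"snp{i}" for i in range(arch.n_snps)]
    truth = TruthInfo(architecture=arch, case_component=case_component)
    return GenotypeDataset(
        genotypes=genotypes, phenotype=phenotype, snp_ids=snp_ids,
        truth=truth, seed=seed,
    )


def simulate_null_dataset(
    n_snps: int,
    n_cases: int,
    n_controls: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> GenotypeDataset:
    """Dataset with no disease signal: every SNP HWE, labels uninformative."""
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("n_cases and n_controls must both be positive")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(*maf_range, size=n_snps)
    n_total = n_cases + n_controls
    genotypes = rng.binomial(2, freqs, size=(n_total, n_snps)).astype(np.int8)
    phenotype = np.zeros(n_total, dtype=np.int8)
    phenotype[:n_cases] = 1
    return GenotypeDataset(
        genotypes=genotypes, phenotype=phenotype,
        snp_ids=[f"snp{i}" for i in range(n_snps)], seed=seed,
    )


_VALID_ORDER_PAIRS = {(2, 2), (2, 3), (2, 4), (3, 3), (3, 4), (4, 4)}
_VALID_RATIOS = {"1:1", "1:3", "3:1"}


def scenario_grid(spec: Mapping) -> list[DiseaseArchitecture]:
    """Enumerate disease architectures from a scenario description.

    ``spec`` names SNP counts (``"snps"``), component order pairs
    (``"orders"``, tokens like ``"2&3"`` with the lower order first) and case
    mixing ratios (``"ratios"``, tokens ``"1:1"``, ``"1:3"``, ``"3:1"``).  A
    ratio r:s assigns proportion r/(r+s) to the first-listed (lower-order)
    component, so ``"1:3"`` and ``"3:1"`` are distinct scenarios for unequal
    orders.  Optional keys: ``"heritability"`` (default 0.01) and
    ``"maf_range"`` (default [0.05, 0.5]).
    """
    h2 = float(spec.get("heritability", 0.01))
    maf_range = tuple(spec.get("maf_range", (0.05, 0.5)))
    out: list[DiseaseArchitecture] = []
    for n_snps in spec["snps"]:
        for token in spec["orders"]:
            try:
                o1, o2 = (int(x) for x in token.split("&"))
            except ValueError as exc:
                raise ValueError(f"malformed order token {token!r}") from exc
            if (min(o1, o2), max(o1, o2)) not in _VALID_ORDER_PAIRS:
                raise ValueError(f"unknown order pair {token!r}")
            # for equal-order components r:s and s:r are the same scenario
            seen_mixes: set[tuple[float, ...]] = set()
            for ratio in spec["ratios"]:
                if ratio not in _VALID_RATIOS:
                    raise ValueError(f"unknown ratio token {ratio!r}")
                r, s = (int(x) for x in ratio.split(":"))
                mix = (r / (r + s), s / (r + s))
                key = mix if o1 != o2 else tuple(sorted(mix))
                if key in seen_mixes:
                    continue
                seen_mixes.add(key)
                m1 = build_pure_epistasis_model(o1, h2)
                m2 = build_pure_epistasis_model(o2, h2)
                idx1 = tuple(range(o1))
                idx2 = tuple(range(o1, o1 + o2))
                out.append(
                    DiseaseArchitecture(
                        components=((m1, idx1), (m2, idx2)),
                        case_mix=mix,
                        n_snps=int(n_snps),
                        noncausative_maf_range=maf_range,  # type: ignore[arg-type]
                        scenario_id=f"{n_snps}snp_{token}_{ratio}",
                    )
                )
    return out
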