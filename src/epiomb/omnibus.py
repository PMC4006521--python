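"""Omnibus permutation test on ensembles of two-locus analyses.

The test aggregates the strongest two-locus signals in a case-control dataset
into a single statistic and calibrates it by label permutation:

1. Every SNP pair is tested with the 2 x 9 chi2 and its p-value is
   Bonferroni-corrected by the number of pairs.
2. An *ensemble* of the k best pairs is scored with Fisher's combining
   function T = -2 sum log(corrected p).
3. T is recomputed on t label permutations.  Within each permutation the
   pairs are re-ranked: replicate i's statistic combines the k smallest
   corrected p-values *of that replicate*, so the observed statistic — itself
   built from the k best observed pairs — is compared against its true
   selection-aware null.  The raw p-value of ensemble e is
   ``p0_e = |{i: T_i >= T_0}| / t``.
4. Because the search examines ensembles of several sizes, a min-p (Westfall-
   Young style) adjustment converts raw p-values into a global p-value: each
   replicate's minimum p over the explored ensembles (computed against the
   pooled reference set that includes the observed data) is compared with the
   observed minimum.

The best-ensemble search grows the ensemble pair by pair in order of
corrected p, stopping as soon as the raw or global p-value increases, or when
the candidate pairs are exhausted.  Candidates are the pairs that are
individually significant after Bonferroni correction (corrected p < alpha;
always at least the top pair): with a strongly associated dataset the
permutation p-values sit at 0/t, so the increase rule alone cannot terminate
the search, and admitting non-significant pairs would only dilute the
ensemble without any measurable change in its p-values.

Association is declared when the best ensemble has both raw and global
p-values below alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
from scipy import stats

from .assoc import PairScan, pair_chi2_perm, pairwise_scan
from .simulate import GenotypeDataset

__all__ = [
    "PermutationSet",
    "Ensemble",
    "ScanResult",
    "fisher_statistic",
    "make_permutations",
    "raw_p",
    "replicate_p_matrix",
    "global_p",
    "scan",
]

logger = logging.getLogger(__name__)

#: floor for Bonferroni-corrected p-values before taking logs, so that a
#: chi2 tail underflowing to 0 keeps the Fisher statistic finite.
P_FLOOR = 1e-300


def fisher_statistic(corrected_ps: Sequence[float]) -> float:
    """Fisher's combining function -2 sum log(p_i).

    A pair at corrected p = 1 contributes nothing.  Zero p-values are floored
    at :data:`P_FLOOR` (and flagged in the log) to keep the statistic finite.
    """
    ps = np.asarray(corrected_ps, dtype=float)
    if ps.size == 0:
        return 0.0
    if np.any(ps < 0) or np.any(ps > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(ps == 0):
        logger.warning("corrected p-value of 0 floored at %.0e", P_FLOOR)
    return float(-2.0 * np.sum(np.log(np.maximum(ps, P_FLOOR))))


@dataclass(frozen=True)
class PermutationSet:
    """t phenotype permutations preserving the case/control counts.

    Replicate ``i`` is generated from the seed sequence ``(seed, i)``, so any
    single replicate is reproducible without generating its predecessors.
    """

    t: int
    labels: np.ndarray  # (t, n_samples) int8
    seed: int


def make_permutations(phenotype: np.ndarray, t: int, seed: int) -> PermutationSet:
    """Uniform label permutations; replicate i reproducible from (seed, i)."""
    if t < 1:
        raise ValueError("t must be at least 1")
    y = np.asarray(phenotype, dtype=np.int8)
    labels = np.empty((t, y.shape[0]), dtype=np.int8)
    for i in range(t):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        labels[i] = rng.permutation(y)
    return PermutationSet(t=t, labels=labels, seed=seed)


def raw_p(ensemble_T0: float, per_replicate_T: np.ndarray) -> float:
    """Permutation p-value p0 = |{i: T_i >= T_0}| / t (ties count)."""
    T = np.asarray(per_replicate_T, dtype=float)
    if T.size < 1:
        raise ValueError("need at least one permutation replicate")
    return float(np.count_nonzero(T >= ensemble_T0) / T.size)


def replicate_p_matrix(all_T: np.ndarray) -> np.ndarray:
    """Per-replicate p-values p_i^e = |{j != i: T_j^e >= T_i^e}| / t.

    ``all_T`` has shape (t+1, E) with row 0 the observed data; the observed
    row participates in every replicate's reference set, and row 0 of the
    result equals the raw p-value of each ensemble.
    """
    T = np.asarray(all_T, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    t = T.shape[0] - 1
    if t < 1:
        raise ValueError("need at least one permutation replicate")
    out = np.empty_like(T)
    for e in range(T.shape[1]):
        col = T[:, e]
        s = np.sort(col)
        # #{j: T_j >= T_i} over all t+1 rows, self included exactly once
        count_ge = col.size - np.searchsorted(s, col, side="left")
        out[:, e] = (count_ge - 1) / t
    return out


def global_p(p_matrix: np.ndarray) -> float:
    """Min-p global adjustment: |{i >= 1: min_e p_i^e <= min_e p_0^e}| / t."""
    P = np.asarray(p_matrix, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    t = P.shape[0] - 1
    if t < 1:
        raise ValueError("need at least one permutation replicate")
    p_min = P.min(axis=1)
    return float(np.count_nonzero(p_min[1:] <= p_min[0]) / t)


@dataclass(frozen=True)
class Ensemble:
    """An ordered set of SNP pairs with its Fisher statistic and p-values."""

    pairs: tuple[tuple[int, int], ...]
    T0: float
    p_raw: float
    p_global: float
    per_replicate_T: np.ndarray  # (t,)

    @property
    def snps(self) -> tuple[int, ...]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.update((i, j))
        return tuple(sorted(out))


@dataclass
class ScanResult:
    """Outcome of the omnibus scan on one dataset."""

    best_ensemble: Ensemble | None
    detected: bool
    alpha: float
    explored: list[Ensemble]
    n_permutations: int
    pair_scan: PairScan
    seed: int
    #: optional diagnostics (populated with keep_null=True)
    null_T: np.ndarray | None = None  # (t+1, K) cumulative re-ranked statistics
    null_corrected_p: np.ndarray | None = None  # (t+1, U) corrected p per pair

    def format_p(self, p: float) -> str:
        """Render a permutation p-value, '<1/t' when the count is zero."""
        return f"<{1.0 / self.n_permutations:g}" if p == 0.0 else f"{p:g}"


def _corrected_p_rows(
    genotypes: np.ndarray,
    pairs: np.ndarray,
    label_rows: np.ndarray,
    n_snps: int,
) -> np.ndarray:
    """Bonferroni-corrected chi2 p for each pair under each labelling."""
    chi2, dof = pair_chi2_perm(genotypes, pairs, label_rows)
    p = np.ones_like(chi2)
    ok = dof >= 1
    if np.any(ok):
        p[:, ok] = stats.chi2.sf(chi2[:, ok], dof[ok][None, :])
    pb = np.minimum(comb(n_snps, 2) * p, 1.0)
    return np.maximum(pb, P_FLOOR)


def _eq2_column(T: np.ndarray, t: int) -> np.ndarray:
    s = np.sort(T)
    count_ge = T.size - np.searchsorted(s, T, side="left")
    return (count_ge - 1) / t


def scan(
    dataset: GenotypeDataset | tuple[np.ndarray, np.ndarray],
    alpha: float = 0.05,
    t: int = 10_000,
    seed: int = 0,
    candidate_alpha: float | None = None,
    perm_pair_cap: int | None = None,
    keep_null: bool = False,
) -> ScanResult:
    """Run the full omnibus scan on a case-control genotype matrix.

    Parameters
    ----------
    dataset
        A :class:`~epiomb.simulate.GenotypeDataset` or a ``(genotypes,
        phenotype)`` tuple.
    alpha
        Significance level for both the raw and global p-values.
    t
        Number of permutation replicates.
    seed
        Seed for the permutation set (the single source of randomness).
    candidate_alpha
        Bonferroni-corrected p threshold for a pair to be eligible for the
        ensemble (defaults to ``alpha``); the top pair is always eligible.
    perm_pair_cap
        If set, the permutation replicates re-rank only the strongest
        ``perm_pair_cap`` observed pairs instead of all C(n,2).  This is an
        approximation for large SNP panels: the observed statistic is exact
        but the replicate null is computed over a reduced pair universe,
        biasing raw p-values downward.  Leave unset for exact inference.
    keep_null
        Attach the permutation statistic matrices to the result (used by
        calibration tests and audits).
    """
    if isinstance(dataset, tuple):
        G, y = dataset
    else:
        G, y = dataset.genotypes, dataset.phenotype
    G = np.asarray(G)
    y = np.asarray(y)
    if G.shape[1] < 2:
        raise ValueError("need at least 2 SNPs")
    if t < 1:
        raise ValueError("t must be at least 1")

    pair_stats = pairwise_scan(G, y)
    n = pair_stats.n_snps
    if candidate_alpha is None:
        candidate_alpha = alpha
    n_candidates = max(int(np.count_nonzero(pair_stats.p_bonferroni < candidate_alpha)), 1)

    universe = pair_stats.n_pairs
    if perm_pair_cap is not None:
        universe = min(max(perm_pair_cap, n_candidates), pair_stats.n_pairs)
        if universe < pair_stats.n_pairs:
            logger.info(
                "permutation pair universe capped at %d of %d pairs (approximate null)",
                universe, pair_stats.n_pairs,
            )
    universe_pairs = pair_stats.pairs[:universe]

    perms = make_permutations(y, t, seed)
    label_rows = np.vstack([(y == 1).astype(np.int8), perms.labels])
    pb = _corrected_p_rows(G, universe_pairs, label_rows, n)  # (t+1, U)

    # re-ranked cumulative Fisher statistics: row i uses its own k smallest
    # corrected p-values; row 0's ranking coincides with the observed sort.
    k_max = n_candidates
    if k_max < pb.shape[1]:
        part = np.partition(pb, k_max - 1, axis=1)[:, :k_max]
    else:
        part = pb
    smallest = np.sort(part, axis=1)
    cum_T = np.cumsum(-2.0 * np.log(smallest), axis=1)  # (t+1, k_max)

    explored: list[Ensemble] = []
    p_min = None
    best: Ensemble | None = None
    prev: Ensemble | None = None
    for k in range(1, k_max + 1):
        T_col = cum_T[:, k - 1]
        p_col = _eq2_column(T_col, t)
        p_raw_k = float(p_col[0])
        p_min = p_col if p_min is None else np.minimum(p_min, p_col)
        p_global_k = float(np.count_nonzero(p_min[1:] <= p_min[0]) / t)
        ens = Ensemble(
            pairs=tuple((int(i), int(j)) for i, j in pair_stats.pairs[:k]),
            T0=float(T_col[0]),
            p_raw=p_raw_k,
            p_global=p_global_k,
            per_replicate_T=T_col[1:].copy(),
        )
        explored.append(ens)
        if k == 1:
            if p_raw_k >= alpha or p_global_k >= alpha:
                best = None
                break
            best = ens
        else:
            assert prev is not None
            if p_raw_k > prev.p_raw or p_global_k > prev.p_global:
                best = prev
                break
            best = ens
        prev = ens

    detected = (
        best is not None and best.p_raw < alpha and best.p_global < alpha
    )
    return ScanResult(
        best_ensemble=best,
        detected=detected,
        alpha=alpha,
        explored=explored,
        n_permutations=t,
        pair_scan=pair_stats,
        seed=seed,
        null_T=cum_T if keep_null else None,
        null_corrected_p=pb if keep_null else None,
    )
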