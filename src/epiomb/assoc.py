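"""Single- and two-locus association statistics, screens and LD measures.

The two-locus test compares the joint genotype distribution of a SNP pair
between cases and controls in a 2 x 9 contingency table with Pearson's chi2.
Degrees of freedom are (number of non-empty joint-genotype columns - 1):
columns empty in the pooled sample are dropped rather than contributing
undefined zero-expectation terms.  Per-pair p-values are Bonferroni-corrected
by the number of pairs, min(C(n,2) * p, 1).

Two scan kernels back the omnibus test:

* :func:`pairwise_scan` — all C(n,2) pairs against one label vector, written
  as nine genotype-indicator matrix products so BLAS carries the O(m n^2)
  cost (m samples, n SNPs).
* :func:`pair_chi2_perm` — a fixed list of pairs against many label vectors
  at once (the permutation replicates), same algebra with the replicate
  matrix on the left.

Both exploit that for a 2 x K table with fixed margins the statistic reduces
to  chi2 = N^2/(R1 R0) * sum_k (O1k - R1 Ck / N)^2 / Ck,  where only the
case-row counts O1k depend on the labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairStat",
    "LDResult",
    "PairScan",
    "two_locus_chi2",
    "single_locus_chi2",
    "bonferroni_correct",
    "hwe_test",
    "minor_allele_frequency",
    "screen_snps",
    "ld_measures",
    "pairwise_scan",
    "pair_chi2_perm",
]

logger = logging.getLogger(__name__)

MISSING = -1  # genotype code for a missing call


@dataclass(frozen=True)
class PairStat:
    """chi2 result for one SNP pair."""

    snp_i: int
    snp_j: int
    chi2: float
    dof: int
    p_uncorrected: float
    p_bonferroni: float
    flagged: bool = False  # statistic undefined (fewer than 2 non-empty columns)


@dataclass(frozen=True)
class LDResult:
    """Pairwise linkage disequilibrium summary from unphased genotypes."""

    d_prime: float
    r2: float
    haplotype_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    converged: bool = True


def bonferroni_correct(p: float, n_snps: int) -> float:
    """min(C(n_snps, 2) * p, 1) — the two-locus multiple-testing correction."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if n_snps < 2:
        raise ValueError("n_snps must be at least 2")
    return min(comb(n_snps, 2) * p, 1.0)


def _chi2_2xk(case_counts: np.ndarray, ctrl_counts: np.ndarray) -> tuple[float, int, float, bool]:
    """Pearson chi2 on a 2 x K table, dropping empty columns.

    Returns (chi2, dof, p, flagged); flagged marks an undefined statistic
    (fewer than two non-empty columns), reported as chi2=0, p=1.
    """
    case_counts = np.asarray(case_counts, dtype=float)
    ctrl_counts = np.asarray(ctrl_counts, dtype=float)
    totals = case_counts + ctrl_counts
    keep = totals > 0
    k = int(keep.sum())
    if k < 2:
        return 0.0, 0, 1.0, True
    o1, o0, c = case_counts[keep], ctrl_counts[keep], totals[keep]
    r1, r0 = o1.sum(), o0.sum()
    n = r1 + r0
    if r1 == 0 or r0 == 0:
        raise ValueError("both phenotype classes must be present")
    e1 = r1 * c / n
    e0 = r0 * c / n
    chi2 = float(np.sum((o1 - e1) ** 2 / e1) + np.sum((o0 - e0) ** 2 / e0))
    dof = k - 1
    p = float(stats.chi2.sf(chi2, dof))
    return chi2, dof, p, False


def _valid_mask(*genotype_vectors: np.ndarray) -> np.ndarray:
    mask = np.ones(genotype_vectors[0].shape[0], dtype=bool)
    for g in genotype_vectors:
        mask &= g >= 0
    return mask


def two_locus_chi2(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    phenotype: np.ndarray,
    snp_i: int = 0,
    snp_j: int = 1,
    n_snps: int | None = None,
) -> PairStat:
    """Two-locus 2 x 9 chi2 test of joint-genotype distribution by status.

    Samples missing either genotype are excluded pairwise.  If ``n_snps`` is
    given, the Bonferroni-corrected p-value uses C(n_snps, 2) tests;
    otherwise the uncorrected p is carried over.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    y = np.asarray(phenotype)
    if not (gi.shape == gj.shape == y.shape):
        raise ValueError("genotype and phenotype vectors must have equal length")
    ok = _valid_mask(gi, gj)
    gi, gj, y = gi[ok], gj[ok], y[ok]
    if np.unique(y[y >= 0]).size < 2:
        raise ValueError("both phenotype classes must be present")
    codes = 3 * gi.astype(np.int64) + gj.astype(np.int64)
    case_counts = np.bincount(codes[y == 1], minlength=9)
    ctrl_counts = np.bincount(codes[y == 0], minlength=9)
    chi2, dof, p, flagged = _chi2_2xk(case_counts, ctrl_counts)
    if flagged:
        logger.debug("pair (%d, %d): <2 non-empty genotype columns; p set to 1", snp_i, snp_j)
    p_bonf = bonferroni_correct(p, n_snps) if n_snps is not None else p
    return PairStat(snp_i, snp_j, chi2, dof, p, p_bonf, flagged)


def single_locus_chi2(
    genotypes: np.ndarray, phenotype: np.ndarray
) -> tuple[float, int, float]:
    """2 x 3 genotypic chi2 test; returns (chi2, dof, p)."""
    g = np.asarray(genotypes)
    y = np.asarray(phenotype)
    ok = _valid_mask(g)
    g, y = g[ok], y[ok]
    if np.unique(y).size < 2:
        raise ValueError("both phenotype classes must be present")
    case_counts = np.bincount(g[y == 1], minlength=3)
    ctrl_counts = np.bincount(g[y == 0], minlength=3)
    chi2, dof, p, _ = _chi2_2xk(case_counts, ctrl_counts)
    return chi2, dof, p


def hwe_test(genotype_counts: Sequence[int]) -> tuple[float, float, bool]:
    """1-dof chi2 goodness of fit against Hardy-Weinberg expectation.

    ``genotype_counts`` is (n0, n1, n2) for 0/1/2 copies of the minor allele.
    Returns (chi2, p, monomorphic); a monomorphic SNP is reported as p = 1
    with the flag set.
    """
    n0, n1, n2 = (float(x) for x in genotype_counts)
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("genotype counts sum to zero")
    q = (n1 + 2 * n2) / (2 * n)
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0, True
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
    observed = np.array([n0, n1, n2])
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, 1))
    return chi2, p, False


def minor_allele_frequency(genotypes: np.ndarray) -> float:
    """MAF of an additive-coded SNP, missing codes excluded."""
    g = np.asarray(genotypes)
    g = g[g >= 0]
    if g.size == 0:
        raise ValueError("no called genotypes")
    freq = float(g.mean() / 2.0)
    return min(freq, 1.0 - freq)


def screen_snps(
    dataset,
    maf_min: float = 0.1,
    single_locus_alpha: float = 0.05,
    hwe_alpha: float = 0.001,
) -> tuple[list[int], pd.DataFrame]:
    """SNP quality/marginal-effect screen ahead of the two-locus scan.

    Retains SNPs with MAF >= ``maf_min`` (all samples), no marginal
    single-locus effect (uncorrected chi2 p > ``single_locus_alpha``), and a
    control-sample genotype distribution compatible with HWE
    (p >= ``hwe_alpha``).  Returns retained indices plus a per-SNP report
    with the failing rule(s).
    """
    for name, v in (("maf_min", maf_min), ("single_locus_alpha", single_locus_alpha),
                    ("hwe_alpha", hwe_alpha)):
        if not 0.0 < v < 1.0:
            raise ValueError(f"{name} must lie in (0, 1)")
    G = dataset.genotypes
    y = dataset.phenotype
    controls = y == 0
    rows = []
    retained: list[int] = []
    for j in range(G.shape[1]):
        g = G[:, j]
        maf = minor_allele_frequency(g)
        _, _, p_single = single_locus_chi2(g, y)
        gc = g[controls]
        gc = gc[gc >= 0]
        counts = np.bincount(gc, minlength=3)[:3]
        _, p_hwe, mono = hwe_test(counts)
        reasons = []
        if maf < maf_min:
            reasons.append("MAF")
        if p_single <= single_locus_alpha:
            reasons.append("single-locus")
        if p_hwe < hwe_alpha:
            reasons.append("HWE")
        if not reasons:
            retained.append(j)
        rows.append(
            {
                "snp": j, "snp_id": dataset.snp_ids[j], "maf": maf,
                "p_single_locus": p_single, "p_hwe_controls": p_hwe,
                "monomorphic": mono, "retained": not reasons,
                "failed": ",".join(reasons),
            }
        )
    if not retained:
        logger.warning("screen retained no SNPs")
    return retained, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def ld_measures(
    genotypes_i: np.ndarray,
    genotypes_j: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDResult:
    """D' and r^2 from unphased genotypes via EM haplotype-frequency estimation.

    The only ambiguous configuration in a two-SNP unphased sample is the
    double heterozygote, which the E-step splits between the coupling (AB/ab)
    and repulsion (Ab/aB) phases in proportion to the current haplotype
    frequencies.  Alleles are labelled so that A/B are the code-0 alleles.
    """
    gi = np.asarray(genotypes_i)
    gj = np.asarray(genotypes_j)
    ok = _valid_mask(gi, gj)
    gi, gj = gi[ok], gj[ok]
    n = gi.shape[0]
    if n == 0:
        raise ValueError("no jointly called samples")
    if np.unique(gi).size < 2 or np.unique(gj).size < 2:
        raise ValueError("both SNPs must be polymorphic")

    # 3x3 unphased genotype counts; index = copies of the minor allele
    counts = np.zeros((3, 3))
    np.add.at(counts, (gi.astype(np.int64), gj.astype(np.int64)), 1.0)

    # haplotypes: 0=AB, 1=Ab, 2=aB, 3=ab with A,B = major (code-0) alleles
    p_a = float((2 * counts.sum(1) @ [0, 0.5, 1]) / (2 * n))  # freq of minor allele a
    p_b = float((2 * counts.sum(0) @ [0, 0.5, 1]) / (2 * n))
    hap = np.array(
        [(1 - p_a) * (1 - p_b), (1 - p_a) * p_b, p_a * (1 - p_b), p_a * p_b]
    )

    n_dh = counts[1, 1]  # double heterozygotes
    # haplotype counts from the 8 phase-unambiguous cells
    base = np.zeros(4)
    unambiguous = {
        (0, 0): {0: 2}, (0, 1): {0: 1, 1: 1}, (0, 2): {1: 2},
        (1, 0): {0: 1, 2: 1}, (1, 2): {1: 1, 3: 1},
        (2, 0): {2: 2}, (2, 1): {2: 1, 3: 1}, (2, 2): {3: 2},
    }
    for (a, b), contrib in unambiguous.items():
        for h, mult in contrib.items():
            base[h] += counts[a, b] * mult

    converged = False
    for _ in range(max_iter):
        # E-step: split double heterozygotes by phase
        coupling = hap[0] * hap[3]
        repulsion = hap[1] * hap[2]
        denom = coupling + repulsion
        w = 0.5 if denom == 0 else coupling / denom
        full = base.copy()
        full[0] += n_dh * w
        full[3] += n_dh * w
        full[1] += n_dh * (1 - w)
        full[2] += n_dh * (1 - w)
        new_hap = full / (2 * n)
        if np.max(np.abs(new_hap - hap)) < tol:
            hap = new_hap
            converged = True
            break
        hap = new_hap
    if not converged:
        logger.warning("LD EM did not converge in %d iterations", max_iter)

    p_ab = hap[0]
    p_a1 = hap[0] + hap[1]  # freq of major allele at locus i
    p_b1 = hap[0] + hap[2]
    d = p_ab - p_a1 * p_b1
    if d >= 0:
        d_max = min(p_a1 * (1 - p_b1), (1 - p_a1) * p_b1)
    else:
        d_max = min(p_a1 * p_b1, (1 - p_a1) * (1 - p_b1))
    d_prime = 0.0 if d_max == 0 else abs(d) / d_max
    denom = p_a1 * (1 - p_a1) * p_b1 * (1 - p_b1)
    r2 = 0.0 if denom == 0 else d * d / denom
    return LDResult(
        d_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        haplotype_freqs=tuple(float(h) for h in hap),  # type: ignore[arg-type]
        converged=converged,
    )


# ---------------------------------------------------------------------------
# vectorised scans


@dataclass
class PairScan:
    """Exhaustive two-locus scan result: arrays over all C(n,2) pairs.

    Arrays are sorted ascending by (p_bonferroni, -chi2, i, j) so that
    ``pairs[k]`` is the (k+1)-th best pair.
    """

    pairs: np.ndarray  # (P, 2) integer, i < j
    chi2: np.ndarray
    dof: np.ndarray
    p_uncorrected: np.ndarray
    p_bonferroni: np.ndarray
    n_snps: int

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_i": self.pairs[:, 0], "snp_j": self.pairs[:, 1],
                "chi2": self.chi2, "dof": self.dof,
                "p_uncorrected": self.p_uncorrected,
                "p_bonferroni": self.p_bonferroni,
            }
        )


def _p_from_chi2(chi2: np.ndarray, dof: np.ndarray) -> np.ndarray:
    p = np.ones_like(chi2, dtype=float)
    ok = dof >= 1
    if np.any(ok):
        p[ok] = stats.chi2.sf(chi2[ok], dof[ok])
    return p


#: above this many pairs the fully tie-broken sort is restricted to the
#: significant head (see pairwise_scan notes).
_FULL_SORT_LIMIT = 4_000_000


def pairwise_scan(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    block: int = 1024,
) -> PairScan:
    """chi2 over all SNP pairs against one case/control labelling.

    Requires complete genotypes (no missing codes); datasets with missing
    calls should be screened/cleaned first or analysed pair by pair with
    :func:`two_locus_chi2`.

    Results are streamed into condensed per-pair arrays (float32 statistics),
    so memory stays linear in the number of pairs even for 10^4-SNP panels.
    Pairs are ordered by (p_bonferroni, -chi2, i, j); for panels above
    ~4e6 pairs, only the head of the ordering — every pair not saturated at
    corrected p = 1, plus a wide margin — carries the full tie-break, and the
    saturated tail (which no downstream step distinguishes) follows in
    deterministic but unspecified order.
    """
    G = np.ascontiguousarray(genotypes)
    y = np.asarray(phenotype)
    if np.any(G < 0):
        raise ValueError("pairwise_scan requires complete genotypes (no missing codes)")
    n_samples, n = G.shape
    if n < 2:
        raise ValueError("need at least 2 SNPs")
    ycol = (y == 1).astype(np.float32)
    r1 = float(ycol.sum())
    r0 = n_samples - r1
    if r1 == 0 or r0 == 0:
        raise ValueError("both phenotype classes must be present")

    A = [(G == a).astype(np.float32) for a in range(3)]
    Ay = [a * ycol[:, None] for a in A]

    n_pairs = comb(n, 2)
    # float32 condensed statistics only where the pair count makes float64
    # storage a memory burden; small panels keep full precision.
    stat_dtype = np.float64 if n_pairs <= _FULL_SORT_LIMIT else np.float32
    offsets = np.concatenate([[0], np.cumsum(np.arange(n))])  # pair block per column j
    chi2v = np.empty(n_pairs, dtype=stat_dtype)
    nonempty = np.empty(n_pairs, dtype=np.int8)
    scale = n_samples * n_samples / (r1 * r0)
    for j0 in range(0, n, block):
        j1 = min(j0 + block, n)
        acc = np.zeros((n, j1 - j0), dtype=np.float64)
        ne = np.zeros((n, j1 - j0), dtype=np.int8)
        for a in range(3):
            for b in range(3):
                # counts are exact integers in float32; promote before arithmetic
                c_ab = (A[a].T @ A[b][:, j0:j1]).astype(np.float64)
                o1_ab = (Ay[a].T @ A[b][:, j0:j1]).astype(np.float64)
                pos = c_ab > 0
                ne += pos
                e1 = r1 * c_ab / n_samples
                with np.errstate(divide="ignore", invalid="ignore"):
                    term = np.where(pos, (o1_ab - e1) ** 2 / np.maximum(c_ab, 1e-300), 0.0)
                acc += term
        acc *= scale
        for jj in range(j0, j1):  # condensed layout: pairs (i, j) grouped by j, i < j
            chi2v[offsets[jj]:offsets[jj] + jj] = acc[:jj, jj - j0]
            nonempty[offsets[jj]:offsets[jj] + jj] = ne[:jj, jj - j0]
    del A, Ay

    pair_i = np.empty(n_pairs, dtype=np.int32)
    pair_j = np.empty(n_pairs, dtype=np.int32)
    for j in range(1, n):
        pair_i[offsets[j]:offsets[j] + j] = np.arange(j, dtype=np.int32)
        pair_j[offsets[j]:offsets[j] + j] = j

    dof = nonempty.astype(np.int16) - 1
    flagged = dof < 1
    if np.any(flagged):
        chi2v[flagged] = 0.0
        dof[flagged] = 0
    p = np.empty(n_pairs, dtype=stat_dtype)
    for k0 in range(0, n_pairs, 5_000_000):
        k1 = min(k0 + 5_000_000, n_pairs)
        p[k0:k1] = _p_from_chi2(
            chi2v[k0:k1].astype(np.float64), dof[k0:k1].astype(np.int64)
        )
    p_bonf = np.minimum(np.float64(n_pairs) * p, 1.0).astype(stat_dtype)

    if n_pairs <= _FULL_SORT_LIMIT:
        order = np.lexsort((pair_j, pair_i, -chi2v, p_bonf))
    else:
        head = int(np.count_nonzero(p_bonf < 1.0))
        m = min(n_pairs, max(head + 1000, 100_000))
        top = np.argpartition(p_bonf, m - 1)[:m]
        top = top[np.lexsort((pair_j[top], pair_i[top], -chi2v[top], p_bonf[top]))]
        mask = np.ones(n_pairs, dtype=bool)
        mask[top] = False
        order = np.concatenate([top, np.flatnonzero(mask)])

    pairs = np.column_stack([pair_i[order], pair_j[order]])
    return PairScan(
        pairs=pairs,
        chi2=chi2v[order],
        dof=dof[order].astype(np.int64),
        p_uncorrected=p[order],
        p_bonferroni=p_bonf[order],
        n_snps=n,
    )


def pair_chi2_perm(
    genotypes: np.ndarray,
    pairs: np.ndarray,
    label_rows: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """chi2 for given SNP pairs under many case/control labelings at once.

    ``label_rows`` is an (R, n_samples) 0/1 matrix whose rows are label
    vectors (row 0 is conventionally the observed labelling).  Returns
    (chi2 of shape (R, P), dof of shape (P,)).  Pooled column totals do not
    depend on the labelling, so dof is shared across rows.
    """
    G = np.asarray(genotypes)
    pairs = np.asarray(pairs)
    Y = np.ascontiguousarray(label_rows, dtype=np.float32)
    if np.any(G < 0):
        raise ValueError("pair_chi2_perm requires complete genotypes")
    n_samples = G.shape[0]
    codes = (3 * G[:, pairs[:, 0]].astype(np.int16) + G[:, pairs[:, 1]]).astype(np.int8)
    r1 = Y.sum(axis=1).astype(np.float64)  # per-row case counts
    r0 = n_samples - r1
    if np.any(r1 == 0) or np.any(r0 == 0):
        raise ValueError("every labelling must contain both classes")

    chi2 = np.zeros((Y.shape[0], pairs.shape[0]), dtype=np.float64)
    nonempty = np.zeros(pairs.shape[0], dtype=np.int64)
    for v in range(9):
        xv = (codes == v).astype(np.float32)
        cv = xv.sum(axis=0).astype(np.float64)
        pos = cv > 0
        if not np.any(pos):
            continue
        nonempty += pos
        o1 = (Y @ xv).astype(np.float64)
        e1 = np.outer(r1, cv) / n_samples
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(pos[None, :], (o1 - e1) ** 2 / np.maximum(cv, 1e-300)[None, :], 0.0)
        chi2 += term
    chi2 *= (n_samples * n_samples / (r1 * r0))[:, None]
    dof = nonempty - 1
    bad = dof < 1
    if np.any(bad):
        chi2[:, bad] = 0.0
        dof = np.where(bad, 0, dof)
    return chi2, dof
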