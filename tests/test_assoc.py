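"""Association statistics against naive oracles, plus screen and LD checks."""

import numpy as np
import pytest
from scipy import stats

from epiomb import (
    bonferroni_correct,
    hwe_test,
    ld_measures,
    pairwise_scan,
    screen_snps,
    simulate_null_dataset,
    single_locus_chi2,
    two_locus_chi2,
)
from epiomb.assoc import pair_chi2_perm


def naive_chi2_2xk(case_counts, ctrl_counts):
    """Oracle: Pearson sum over non-empty columns, written as explicit loops."""
    chi2 = 0.0
    k = 0
    r1 = sum(case_counts)
    r0 = sum(ctrl_counts)
    n = r1 + r0
    for o1, o0 in zip(case_counts, ctrl_counts):
        c = o1 + o0
        if c == 0:
            continue
        k += 1
        e1 = r1 * c / n
        e0 = r0 * c / n
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    return chi2, k - 1


def random_dataset(rng, n=200, n_snps=2):
    g = rng.integers(0, 3, size=(n, n_snps)).astype(np.int8)
    y = np.zeros(n, dtype=np.int8)
    y[: n // 2] = 1
    rng.shuffle(y)
    return g, y


def test_two_locus_chi2_matches_oracle_on_random_tables(rng):
    for _ in range(100):
        g, y = random_dataset(rng, n=int(rng.integers(40, 300)))
        res = two_locus_chi2(g[:, 0], g[:, 1], y, n_snps=20)
        codes = 3 * g[:, 0].astype(int) + g[:, 1]
        case_counts = np.bincount(codes[y == 1], minlength=9)
        ctrl_counts = np.bincount(codes[y == 0], minlength=9)
        chi2, dof = naive_chi2_2xk(case_counts, ctrl_counts)
        assert res.chi2 == pytest.approx(chi2, rel=1e-10)
        assert res.dof == dof
        assert res.p_uncorrected == pytest.approx(stats.chi2.sf(chi2, dof), rel=1e-10)
        assert res.p_bonferroni == pytest.approx(min(190 * res.p_uncorrected, 1.0))


def test_single_locus_chi2_matches_oracle(rng):
    for _ in range(100):
        g, y = random_dataset(rng, n=int(rng.integers(30, 200)), n_snps=1)
        chi2, dof, p = single_locus_chi2(g[:, 0], y)
        case_counts = np.bincount(g[y == 1, 0], minlength=3)
        ctrl_counts = np.bincount(g[y == 0, 0], minlength=3)
        ref_chi2, ref_dof = naive_chi2_2xk(case_counts, ctrl_counts)
        assert chi2 == pytest.approx(ref_chi2, rel=1e-10)
        assert dof == ref_dof


def test_two_locus_chi2_agrees_with_scipy_contingency(rng):
    """Independent route: scipy's chi2_contingency on the reduced table."""
    for _ in range(25):
        g, y = random_dataset(rng, n=150)
        res = two_locus_chi2(g[:, 0], g[:, 1], y)
        codes = 3 * g[:, 0].astype(int) + g[:, 1]
        table = np.stack(
            [np.bincount(codes[y == 1], minlength=9),
             np.bincount(codes[y == 0], minlength=9)]
        )
        table = table[:, table.sum(0) > 0]
        ref = stats.chi2_contingency(table, correction=False)
        assert res.chi2 == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_uncorrected == pytest.approx(ref.pvalue, rel=1e-8)


def test_identical_distributions_give_zero_statistic():
    # duplicate every joint genotype across both classes
    g_half = np.array([[0, 0], [1, 2], [2, 1], [1, 1], [0, 2]], dtype=np.int8)
    g = np.vstack([g_half, g_half])
    y = np.array([1] * 5 + [0] * 5, dtype=np.int8)
    res = two_locus_chi2(g[:, 0], g[:, 1], y)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_uncorrected == pytest.approx(1.0)


def test_symmetry_and_relabelling_invariance(rng):
    g, y = random_dataset(rng, n=240)
    a = two_locus_chi2(g[:, 0], g[:, 1], y)
    b = two_locus_chi2(g[:, 1], g[:, 0], y)
    assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)
    # consistent genotype-code permutation in both classes
    perm = np.array([2, 0, 1], dtype=np.int8)
    c = two_locus_chi2(perm[g[:, 0]], perm[g[:, 1]], y)
    assert a.chi2 == pytest.approx(c.chi2, rel=1e-12)


def test_missing_genotypes_excluded_pairwise(rng):
    g, y = random_dataset(rng, n=100)
    g_miss = g.copy()
    g_miss[:10, 0] = -1
    res = two_locus_chi2(g_miss[:, 0], g_miss[:, 1], y)
    ref = two_locus_chi2(g[10:, 0], g[10:, 1], y[10:])
    assert res.chi2 == pytest.approx(ref.chi2, rel=1e-12)


def test_undefined_statistic_flagged():
    g = np.zeros((40, 2), dtype=np.int8)  # single joint genotype column
    y = np.array([1] * 20 + [0] * 20, dtype=np.int8)
    res = two_locus_chi2(g[:, 0], g[:, 1], y)
    assert res.flagged and res.p_uncorrected == 1.0 and res.chi2 == 0.0


def test_bonferroni_examples_and_monotonicity():
    assert bonferroni_correct(0.001, 20) == pytest.approx(0.19)
    assert bonferroni_correct(0.01, 1000) == 1.0
    assert bonferroni_correct(0.0, 17) == 0.0
    ps = np.linspace(0, 1e-4, 20)
    corr = [bonferroni_correct(p, 50) for p in ps]
    assert np.all(np.diff(corr) >= 0)
    assert bonferroni_correct(1e-4, 100) >= bonferroni_correct(1e-4, 50)
    with pytest.raises(ValueError):
        bonferroni_correct(0.5, 1)


def test_hwe_examples():
    chi2, p, mono = hwe_test((25, 50, 25))
    assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0) and not mono
    chi2, p, mono = hwe_test((50, 0, 50))
    assert chi2 == pytest.approx(100.0) and p < 1e-10
    chi2, p, mono = hwe_test((100, 0, 0))
    assert p == 1.0 and mono


def test_hwe_matches_oracle_on_random_counts(rng):
    for _ in range(100):
        counts = rng.integers(0, 200, size=3)
        if counts.sum() == 0:
            continue
        n0, n1, n2 = (int(x) for x in counts)
        n = n0 + n1 + n2
        q = (n1 + 2 * n2) / (2 * n)
        chi2, p, mono = hwe_test((n0, n1, n2))
        if q in (0.0, 1.0):
            assert mono
            continue
        exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q ** 2]
        ref = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
        assert chi2 == pytest.approx(ref, rel=1e-10)


def test_null_two_locus_pvalues_are_calibrated(rng):
    """Type-I error of the asymptotic 2x9 chi2 at alpha=0.05 under permutation."""
    n = 600
    g = rng.integers(0, 3, size=(n, 2)).astype(np.int8)
    hits = 0
    n_tables = 2000
    base_y = np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int8)
    for _ in range(n_tables):
        y = rng.permutation(base_y)
        if two_locus_chi2(g[:, 0], g[:, 1], y).p_uncorrected < 0.05:
            hits += 1
    rate = hits / n_tables
    se = np.sqrt(0.05 * 0.95 / n_tables)
    assert abs(rate - 0.05) <= 3 * se + 0.01


class TestScreen:
    def test_all_pass_identity(self):
        ds = simulate_null_dataset(10, 300, 300, seed=3, maf_range=(0.3, 0.5))
        retained, report = screen_snps(ds, single_locus_alpha=1e-6)
        assert retained == list(range(10))
        assert report["retained"].all()

    def test_low_maf_snp_removed_with_reason(self):
        ds = simulate_null_dataset(5, 300, 300, seed=4, maf_range=(0.3, 0.5))
        g = ds.genotypes.copy()
        rng = np.random.default_rng(0)
        g[:, 2] = (rng.random(600) < 0.05).astype(np.int8)  # MAF ~ 0.025
        ds.genotypes = g
        retained, report = screen_snps(ds, single_locus_alpha=1e-6)
        assert 2 not in retained
        assert "MAF" in report.loc[report.snp == 2, "failed"].item()

    def test_hwe_violating_snp_removed(self):
        ds = simulate_null_dataset(5, 200, 400, seed=5, maf_range=(0.3, 0.5))
        g = ds.genotypes.copy()
        controls = np.flatnonzero(ds.phenotype == 0)
        g[controls, 1] = np.where(np.arange(len(controls)) % 2 == 0, 0, 2)  # no hets
        ds.genotypes = g
        retained, report = screen_snps(ds, single_locus_alpha=1e-9)
        assert 1 not in retained
        assert "HWE" in report.loc[report.snp == 1, "failed"].item()


class TestLD:
    def test_identical_snps_in_perfect_ld(self, rng):
        g = rng.integers(0, 3, size=400).astype(np.int8)
        res = ld_measures(g, g)
        assert res.d_prime == pytest.approx(1.0, abs=1e-6)
        assert res.r2 == pytest.approx(1.0, abs=1e-6)

    def test_independent_snps_show_low_r2(self, rng):
        n = 10_000
        g1 = rng.binomial(2, 0.3, size=n).astype(np.int8)
        g2 = rng.binomial(2, 0.4, size=n).astype(np.int8)
        res = ld_measures(g1, g2)
        assert res.r2 < 0.05

    def test_em_matches_direct_counts_without_double_heterozygotes(self):
        # phased-unambiguous sample: no (1,1) cell, so haplotypes are countable
        gi = np.array([0, 0, 0, 2, 2, 1, 1, 0, 2, 2], dtype=np.int8)
        gj = np.array([0, 0, 2, 0, 2, 0, 2, 2, 0, 2], dtype=np.int8)
        res = ld_measures(gi, gj)
        # direct haplotype counting oracle
        hap_counts = np.zeros(4)  # AB, Ab, aB, ab with A,B = code-0 alleles
        contrib = {
            (0, 0): {0: 2}, (0, 1): {0: 1, 1: 1}, (0, 2): {1: 2},
            (1, 0): {0: 1, 2: 1}, (1, 2): {1: 1, 3: 1},
            (2, 0): {2: 2}, (2, 1): {2: 1, 3: 1}, (2, 2): {3: 2},
        }
        for a, b in zip(gi, gj):
            for h, m in contrib[(a, b)].items():
                hap_counts[h] += m
        expected = hap_counts / hap_counts.sum()
        assert np.allclose(res.haplotype_freqs, expected, atol=1e-6)

    def test_monomorphic_snp_rejected(self):
        with pytest.raises(ValueError):
            ld_measures(np.zeros(50, dtype=np.int8), np.ones(50, dtype=np.int8))


def test_pairwise_scan_consistent_with_single_pair_tests(rng):
    ds = simulate_null_dataset(8, 120, 120, seed=8)
    scan_res = pairwise_scan(ds.genotypes, ds.phenotype)
    for (i, j), chi2, dof, pb in zip(
        scan_res.pairs, scan_res.chi2, scan_res.dof, scan_res.p_bonferroni
    ):
        ref = two_locus_chi2(
            ds.genotypes[:, i], ds.genotypes[:, j], ds.phenotype, n_snps=8
        )
        assert chi2 == pytest.approx(ref.chi2, rel=1e-9, abs=1e-12)
        assert dof == ref.dof
        assert pb == pytest.approx(ref.p_bonferroni, rel=1e-9, abs=1e-12)
    # sorted ascending by corrected p
    assert np.all(np.diff(scan_res.p_bonferroni) >= 0)


def test_pair_chi2_perm_row_equals_observed(rng):
    ds = simulate_null_dataset(6, 100, 100, seed=9)
    scan_res = pairwise_scan(ds.genotypes, ds.phenotype)
    rows = np.vstack(
        [(ds.phenotype == 1).astype(np.int8),
         rng.permutation(ds.phenotype),
         rng.permutation(ds.phenotype)]
    )
    chi2, dof = pair_chi2_perm(ds.genotypes, scan_res.pairs, rows)
    assert np.allclose(chi2[0], scan_res.chi2, rtol=1e-9)
    assert np.array_equal(dof, scan_res.dof)
    # permuted rows differ from the observed one
    assert not np.allclose(chi2[1], chi2[0])
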