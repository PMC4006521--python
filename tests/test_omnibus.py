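"""Omnibus permutation machinery: Fisher statistic, p-value formulas, search."""

import numpy as np
import pytest

from epiomb import (
    DiseaseArchitecture,
    build_pure_epistasis_model,
    fisher_statistic,
    global_p,
    make_permutations,
    raw_p,
    replicate_p_matrix,
    scan,
    simulate_dataset,
    simulate_null_dataset,
)


class TestFisherStatistic:
    def test_all_ones_give_zero(self):
        assert fisher_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_closed_form(self):
        assert fisher_statistic([0.05]) == pytest.approx(-2 * np.log(0.05))

    def test_p_of_one_contributes_nothing(self):
        assert fisher_statistic([0.19, 1.0]) == pytest.approx(fisher_statistic([0.19]))

    def test_zero_p_is_floored_finite(self):
        assert np.isfinite(fisher_statistic([0.0]))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fisher_statistic([1.2])


class TestRawP:
    def test_direct_count(self):
        assert raw_p(2.5, [1, 2, 3, 4]) == 0.5

    def test_ties_count(self):
        assert raw_p(4.0, [1, 2, 3, 4]) == 0.25

    def test_zero_possible(self):
        assert raw_p(10.0, [1, 2, 3, 4]) == 0.0


class TestReplicateAndGlobalP:
    def test_printed_counting_example(self):
        # rows 0..2 (t=2), one ensemble: T = [5, 3, 7]
        p = replicate_p_matrix(np.array([5.0, 3.0, 7.0]))
        assert p[:, 0].tolist() == [0.5, 1.0, 0.0]

    def test_all_ties_give_one(self):
        p = replicate_p_matrix(np.full(6, 2.0))
        assert np.all(p == 1.0)

    def test_row_zero_equals_raw_p(self, rng):
        T = rng.random(101)
        p = replicate_p_matrix(T)
        assert p[0, 0] == raw_p(T[0], T[1:])

    def test_global_p_single_column_example(self):
        col = np.array([0.25, 1.0, 0.5, 0.75, 0.25])
        assert global_p(col) == 0.25

    def test_global_p_extremes(self):
        assert global_p(np.array([0.01, 0.5, 0.6, 0.7])) == 0.0
        assert global_p(np.array([1.0, 0.2, 0.9, 0.4])) == 1.0

    def test_global_p_matches_brute_force_double_loop(self, rng):
        """E=1: Eq.-style counting against an explicit two-level loop."""
        T = rng.random(51)
        p = replicate_p_matrix(T)
        t = len(T) - 1
        # brute force
        pvals = []
        for i in range(t + 1):
            count = sum(1 for j in range(t + 1) if j != i and T[j] >= T[i])
            pvals.append(count / t)
        assert np.allclose(p[:, 0], pvals)
        p0_min = pvals[0]
        brute_global = sum(1 for i in range(1, t + 1) if pvals[i] <= p0_min) / t
        assert global_p(p) == brute_global
        assert global_p(p) >= p[0, 0]  # with E=1, ties make p_global >= p_raw

    def test_multi_ensemble_min_p(self, rng):
        T = rng.random((41, 3))
        p = replicate_p_matrix(T)
        t = T.shape[0] - 1
        p_min = p.min(axis=1)
        expected = np.count_nonzero(p_min[1:] <= p_min[0]) / t
        assert global_p(p) == expected


class TestPermutations:
    def test_counts_preserved(self):
        y = np.array([1] * 30 + [0] * 70, dtype=np.int8)
        ps = make_permutations(y, 50, seed=3)
        assert ps.labels.shape == (50, 100)
        assert np.all(ps.labels.sum(axis=1) == 30)

    def test_replicate_reproducible_from_seed_and_index(self):
        y = np.array([1] * 10 + [0] * 10, dtype=np.int8)
        a = make_permutations(y, 20, seed=5)
        b = make_permutations(y, 5, seed=5)
        assert np.array_equal(a.labels[:5], b.labels)

    def test_invalid_t(self):
        with pytest.raises(ValueError):
            make_permutations(np.array([1, 0]), 0, seed=1)


class TestScan:
    def test_plant_and_recover_single_interaction(self):
        m = build_pure_epistasis_model(2, 0.01)
        arch = DiseaseArchitecture(
            components=((m, (4, 11)),), case_mix=(1.0,), n_snps=20
        )
        ds = simulate_dataset(arch, 800, 800, seed=77)
        res = scan(ds, alpha=0.05, t=300, seed=1)
        assert res.detected
        assert tuple(sorted(res.best_ensemble.pairs[0])) == (4, 11)
        assert res.best_ensemble.p_raw == 0.0  # reported as < 1/t
        assert res.format_p(0.0).startswith("<")

    def test_two_planted_interactions_recovered_without_common_snps(
        self, dataset_2and2
    ):
        res = scan(dataset_2and2, alpha=0.05, t=300, seed=2)
        assert res.detected
        pair_sets = [frozenset(p) for p in res.best_ensemble.pairs]
        assert frozenset({0, 1}) in pair_sets
        assert frozenset({2, 3}) in pair_sets
        assert pair_sets[0] & pair_sets[1] == frozenset()

    def test_incremental_statistics_equal_recomputation(self, dataset_2and2):
        res = scan(dataset_2and2, alpha=0.05, t=100, seed=3, keep_null=True)
        pb = res.null_corrected_p
        t = res.n_permutations
        smallest = np.sort(pb, axis=1)
        for k, ens in enumerate(res.explored, start=1):
            # from-scratch: sequentially accumulate each row's k smallest
            # corrected p-values (same addition order as the incremental path,
            # so equality is exact, not approximate)
            T_scratch = np.zeros(pb.shape[0])
            for m in range(k):
                T_scratch += -2.0 * np.log(smallest[:, m])
            assert np.array_equal(res.null_T[:, k - 1], T_scratch)
            assert ens.T0 == T_scratch[0]
            assert np.array_equal(ens.per_replicate_T, T_scratch[1:])

    def test_p_values_lie_on_the_permutation_grid(self, dataset_2and2):
        t = 64
        res = scan(dataset_2and2, alpha=0.05, t=t, seed=4)
        for ens in res.explored:
            assert (ens.p_raw * t) == int(round(ens.p_raw * t))
            assert (ens.p_global * t) == int(round(ens.p_global * t))

    def test_scan_deterministic(self, dataset_2and2):
        a = scan(dataset_2and2, t=100, seed=9)
        b = scan(dataset_2and2, t=100, seed=9)
        assert a.detected == b.detected
        assert a.best_ensemble.pairs == b.best_ensemble.pairs
        assert a.best_ensemble.T0 == b.best_ensemble.T0
        assert a.best_ensemble.p_global == b.best_ensemble.p_global

    def test_null_dataset_usually_not_detected(self):
        ds = simulate_null_dataset(20, 200, 200, seed=123)
        res = scan(ds, alpha=0.05, t=200, seed=5)
        # a single null dataset: detection must at least obey the verdict rule
        if res.detected:
            assert res.best_ensemble.p_raw < 0.05
            assert res.best_ensemble.p_global < 0.05
        else:
            assert res.best_ensemble is None or not (
                res.best_ensemble.p_raw < 0.05
                and res.best_ensemble.p_global < 0.05
            )

    def test_degenerate_inputs_rejected(self, dataset_2and2):
        with pytest.raises(ValueError):
            scan(dataset_2and2, t=0, seed=1)
        with pytest.raises(ValueError):
            scan((dataset_2and2.genotypes[:, :1], dataset_2and2.phenotype), t=10)
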