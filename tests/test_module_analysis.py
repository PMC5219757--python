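import numpy as np
import pandas as pd
import pytest

from cobind.module_analysis import (
    ModuleGroups,
    call_main_drivers,
    call_module_usage,
    call_participation,
    group_modules,
    module_labels,
    multi_module_census,
    pca_modules,
    region_module_matrix,
    zscore,
)
from cobind.topic_model import ModuleTFMatrix


def mtm_from(counts, factors=None):
    counts = np.asarray(counts)
    factors = factors or [f"F{i}" for i in range(counts.shape[1])]
    return ModuleTFMatrix(counts=counts, factors=factors)


class TestZScore:
    def test_basic_vector(self):
        z = zscore(np.array([[1.0], [2.0], [3.0]]), axis=0)
        assert np.allclose(z.ravel(), [-1, 0, 1])

    def test_constant_vector_zeros(self):
        z = zscore(np.array([[5.0], [5.0], [5.0]]), axis=0)
        assert np.allclose(z, 0)

    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        x = rng.random((20, 7))
        for axis in (0, 1):
            z = zscore(x, axis=axis)
            assert np.allclose(z.mean(axis=axis), 0, atol=1e-12)
            assert np.allclose(z.std(axis=axis, ddof=1), 1, atol=1e-12)

    def test_empty_matrix_error(self):
        with pytest.raises(ValueError):
            zscore(np.empty((0, 0)))


class TestParticipation:
    def test_concentrated_factor(self):
        counts = np.zeros((10, 1))
        counts[3, 0] = 10
        part = call_participation(mtm_from(counts))
        # z = (10 - 1) / sqrt(10) = 2.85 in the hot module, elsewhere negative
        assert part[3, 0]
        assert part.sum() == 1

    def test_uniform_factor_no_calls(self):
        part = call_participation(mtm_from(np.full((5, 2), 4)))
        assert not part.any()

    def test_zcut_minus_inf_all_true(self):
        part = call_participation(mtm_from(np.arange(12).reshape(4, 3)), z_cut=-np.inf)
        assert part.all()


class TestMainDrivers:
    def test_dominant_factor_row(self):
        # (A:90, B:10, 18 zeros): only A clears row z > 1 (z_B = 0.25)
        counts = np.zeros((2, 20))
        counts[0, 0], counts[0, 1] = 90, 10
        counts[1, :] = 1
        factors = ["A", "B"] + [f"F{i}" for i in range(18)]
        drivers = call_main_drivers(mtm_from(counts, factors))
        assert drivers[0] == ["A"]

    def test_two_strong_factors_ranked(self):
        counts = np.zeros((2, 20))
        counts[0, 0], counts[0, 1] = 90, 60
        counts[1, :] = 1
        factors = ["A", "B"] + [f"F{i}" for i in range(18)]
        drivers = call_main_drivers(mtm_from(counts, factors))
        assert drivers[0] == ["A", "B"]

    def test_uniform_row_empty(self):
        drivers = call_main_drivers(mtm_from(np.full((3, 4), 2)))
        assert drivers == [[], [], []]
        labels = module_labels(mtm_from(np.full((3, 4), 2)))
        assert labels == ["module_0", "module_1", "module_2"]

    def test_column_order_invariance(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(5, 8))
        factors = [f"F{i}" for i in range(8)]
        drivers = call_main_drivers(mtm_from(counts, factors))
        perm = rng.permutation(8)
        drivers_p = call_main_drivers(mtm_from(counts[:, perm], [factors[i] for i in perm]))
        assert drivers == drivers_p

    def test_label_caps_at_eight(self):
        counts = np.zeros((2, 30))
        counts[0, :12] = 100
        counts[1, :] = 1
        labels = module_labels(mtm_from(counts))
        assert len(labels[0].split("+")) <= 8


class TestRegionModuleMatrix:
    def table(self):
        return pd.DataFrame(
            {
                "region_id": ["r1", "r1", "r1", "r2"],
                "site_index": [0, 1, 2, 0],
                "factor": ["A", "A", "B", "C"],
                "module": [0, 0, 1, 1],
            }
        )

    def test_counts(self):
        rmm = region_module_matrix(self.table())
        assert rmm.loc["r1"].tolist() == [2, 1]
        assert rmm.loc["r2"].tolist() == [0, 1]

    def test_row_sums_conserve_sites(self):
        table = self.table()
        rmm = region_module_matrix(table)
        assert rmm.to_numpy().sum() == len(table)

    def test_deterministic_rebuild(self):
        a = region_module_matrix(self.table())
        b = region_module_matrix(self.table())
        pd.testing.assert_frame_equal(a, b)

    def test_missing_columns_error(self):
        with pytest.raises(ValueError):
            region_module_matrix(pd.DataFrame({"region_id": []}))


class TestModuleUsage:
    def test_concentrated_region(self):
        rmm = pd.DataFrame(np.zeros((1, 10)))
        rmm.iloc[0, 0] = 5
        used = call_module_usage(rmm)
        assert used.iloc[0, 0]
        assert used.to_numpy().sum() == 1

    def test_count_rule_blocks(self):
        rmm = pd.DataFrame([[2, 1] + [0] * 8])
        assert not call_module_usage(rmm).to_numpy().any()

    def test_uniform_region_no_usage(self):
        rmm = pd.DataFrame([[3, 3, 3]])
        assert not call_module_usage(rmm).to_numpy().any()

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(2)
        rmm = pd.DataFrame(rng.integers(0, 8, size=(40, 6)))
        base = call_module_usage(rmm, min_sites=3, z_cut=1.0).to_numpy()
        stricter_z = call_module_usage(rmm, min_sites=3, z_cut=1.5).to_numpy()
        stricter_n = call_module_usage(rmm, min_sites=4, z_cut=1.0).to_numpy()
        assert not (stricter_z & ~base).any()
        assert not (stricter_n & ~base).any()

    def test_module_axis_option(self):
        rmm = pd.DataFrame(np.array([[5, 0], [5, 0], [0, 5], [0, 4]], dtype=float))
        used = call_module_usage(rmm, usage_z_axis="module")
        assert used.shape == rmm.shape
        with pytest.raises(ValueError):
            call_module_usage(rmm, usage_z_axis="bogus")


class TestCensus:
    def test_histogram(self):
        usage = pd.DataFrame(
            [[True, False], [True, True], [False, False]], columns=[0, 1]
        )
        assert multi_module_census(usage) == {0: 1, 1: 1, 2: 1}

    def test_total_equals_regions(self):
        rng = np.random.default_rng(3)
        usage = pd.DataFrame(rng.random((25, 4)) > 0.5)
        census = multi_module_census(usage)
        assert sum(census.values()) == 25


def brute_force_average_linkage(rows, cutoff):
    """Naive UPGMA on correlation distance, cut at ``cutoff`` (oracle)."""
    def dist(i, j):
        return 1 - np.corrcoef(rows[i], rows[j])[0, 1]

    clusters = [[i] for i in range(len(rows))]
    while len(clusters) > 1:
        best, pair = None, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist(i, j) for i in clusters[a] for j in clusters[b]])
                if best is None or d < best:
                    best, pair = d, (a, b)
        if best > cutoff:
            break
        a, b = pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return {i: c for c, members in enumerate(clusters) for i in members}


class TestGroupModules:
    def test_identical_rows_grouped(self):
        counts = np.array([[1, 2, 3], [2, 4, 6], [9, 1, 1]])
        groups = group_modules(mtm_from(counts))
        assert groups.group_of[0] == groups.group_of[1]
        assert groups.group_of[0] != groups.group_of[2]

    def test_anticorrelated_separate(self):
        counts = np.array([[1, 2, 3, 4], [4, 3, 2, 1]])
        groups = group_modules(mtm_from(counts), cutoff=0.5)
        assert groups.n_groups == 2

    def test_single_module(self):
        groups = group_modules(mtm_from(np.array([[1, 2]])))
        assert groups.group_of == {0: 1}

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 30, size=(6, 10)).astype(float)
        got = group_modules(mtm_from(counts), cutoff=0.5).group_of
        want = brute_force_average_linkage(counts, cutoff=0.5)
        # same partition up to label permutation
        def canon(mapping):
            groups = {}
            for i in sorted(mapping):
                groups.setdefault(mapping[i], []).append(i)
            return sorted(tuple(v) for v in groups.values())

        assert canon(got) == canon(want)


class TestPCA:
    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        res = pca_modules(mtm_from(rng.integers(0, 20, size=(8, 12))))
        assert np.isclose(res.explained_variance_ratio.sum(), 1.0)
        assert ((res.explained_variance_ratio >= 0) & (res.explained_variance_ratio <= 1)).all()

    def test_rank_one_single_component(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        counts = np.outer([1, 2, 3], base)
        res = pca_modules(mtm_from(counts))
        assert np.isclose(res.explained_variance_ratio[0], 1.0)

    def test_components_orthonormal(self):
        rng = np.random.default_rng(5)
        res = pca_modules(mtm_from(rng.integers(0, 20, size=(6, 9))))
        gram = res.components @ res.components.T
        assert np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
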