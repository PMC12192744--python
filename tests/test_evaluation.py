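"""Evaluation metrics: overlap, consistency, LOOCV, method comparison."""

import numpy as np
import pytest
from scipy import stats

import pssmap as pm
from pssmap.sweetspot import SweetSpot


def _sphere_mask(grid, center, radius):
    xyz = grid.voxel_centers_mm()
    return np.linalg.norm(xyz - np.asarray(center), axis=-1) <= radius


class TestDice:
    def test_identity_and_disjoint(self, small_grid):
        a = _sphere_mask(small_grid, (0, 0, 0), 2.0)
        b = _sphere_mask(small_grid, (4, 0, 0), 1.0)
        assert pm.dice(a, a) == 1.0
        assert pm.dice(a, b) == 0.0
        assert pm.dice(a & False, a & False) == 0.0  # both empty

    def test_counting_example(self):
        a = np.zeros(30, dtype=bool).reshape(30, 1, 1)
        b = np.zeros(30, dtype=bool).reshape(30, 1, 1)
        a[:10] = True
        b[6:12] = True  # |a|=10 |b|=6 overlap=4
        assert pm.dice(a, b) == pytest.approx(0.5)

    def test_symmetry(self, small_grid):
        rng = np.random.default_rng(0)
        a = rng.random(small_grid.shape) > 0.7
        b = rng.random(small_grid.shape) > 0.7
        assert pm.dice(a, b) == pm.dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(pm.GridMismatchError):
            pm.dice(np.zeros((2, 2, 2), dtype=bool), np.zeros((3, 2, 2), dtype=bool))


class TestCentroidVolume:
    def test_single_voxel_centroid(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[3, 4, 5] = True
        expected = small_grid.voxel_centers_mm()[3, 4, 5]
        assert np.allclose(pm.centroid_mm(mask, small_grid), expected)

    def test_symmetric_pair_centroid_is_midpoint(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[2, 5, 5] = True
        mask[8, 5, 5] = True
        xyz = small_grid.voxel_centers_mm()
        mid = (xyz[2, 5, 5] + xyz[8, 5, 5]) / 2
        assert np.allclose(pm.centroid_mm(mask, small_grid), mid)

    def test_eight_voxels_is_one_mm3(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        assert pm.volume_mm3(mask, small_grid) == pytest.approx(1.0)

    def test_empty_centroid_undefined(self, small_grid):
        with pytest.raises(pm.CohortValidationError):
            pm.centroid_mm(np.zeros(small_grid.shape, dtype=bool), small_grid)


class TestVolumeCV:
    def test_fixture_values(self):
        assert pm.volume_cv([10, 10, 10]) == 0.0
        # sample std of (20, 30) is 7.0711 -> 28.2843 %
        assert pm.volume_cv([20, 30]) == pytest.approx(100 * np.sqrt(50) / 25)
        assert pm.volume_cv([20, 30]) == pytest.approx(28.284271247461902)

    def test_scale_invariance(self):
        v = [12.0, 15.0, 19.0, 22.0]
        assert pm.volume_cv(v) == pytest.approx(pm.volume_cv([3 * x for x in v]))

    def test_zero_mean_undefined(self):
        with pytest.raises(pm.CohortValidationError):
            pm.volume_cv([0.0, 0.0])


class TestSpearman:
    def test_rank_difference_fixture(self):
        # x=(1,2,3), y=(3,1,2): sum d^2 = 6 -> rho = 1 - 36/24 = -0.5
        rho, _ = stats.spearmanr([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)


class TestConsistency:
    def test_identical_masks(self, small_grid):
        mask = _sphere_mask(small_grid, (0, 0, 0), 2.0)
        pss = [SweetSpot(grid=small_grid, mask=mask) for _ in range(4)]
        res = pm.consistency_metrics(pss)
        assert res.volume_cv_pct == 0.0
        assert len(res.pairwise_dice) == 6  # k(k-1)/2
        assert all(d == 1.0 for d in res.pairwise_dice)
        assert all(d == 0.0 for d in res.pairwise_norm_centroid_dist_pct)

    def test_offset_spheres_normalized_distance(self, small_grid):
        a = _sphere_mask(small_grid, (0, 0, 0), 2.0)
        b = _sphere_mask(small_grid, (1.0, 0, 0), 2.0)  # 1 mm offset, equal volume
        pss = [SweetSpot(grid=small_grid, mask=a), SweetSpot(grid=small_grid, mask=b)]
        res = pm.consistency_metrics(pss)
        vol = pm.volume_mm3(a, small_grid)
        expected = 100 * 1.0 / pm.equivalent_sphere_diameter_mm(vol)
        assert res.pairwise_norm_centroid_dist_pct[0] == pytest.approx(expected, rel=1e-6)

    def test_empty_pss_excluded(self, small_grid):
        a = _sphere_mask(small_grid, (0, 0, 0), 2.0)
        pss = [SweetSpot(grid=small_grid, mask=a),
               SweetSpot(grid=small_grid, mask=np.zeros(small_grid.shape, dtype=bool)),
               SweetSpot(grid=small_grid, mask=a)]
        res = pm.consistency_metrics(pss)
        assert res.n_used == 2 and res.n_input == 3

    def test_too_few_non_empty(self, small_grid):
        a = SweetSpot(grid=small_grid, mask=_sphere_mask(small_grid, (0, 0, 0), 2))
        with pytest.raises(pm.CohortValidationError):
            pm.consistency_metrics([a])


class TestCompareMethods:
    def test_identical_distributions_no_difference(self):
        rng = np.random.default_rng(0)
        base = rng.normal(50, 5, 30)
        res = pm.compare_methods({"a": base, "b": base.copy(), "c": base.copy()})
        assert res.p_value > 0.05 or res.test_used == "none"

    def test_large_shift_flagged_in_posthoc(self):
        rng = np.random.default_rng(1)
        groups = {k: rng.normal(50, 2, 25) for k in ("a", "b")}
        groups["c"] = rng.normal(70, 2, 25)  # 10 SDs away
        res = pm.compare_methods(groups)
        assert res.p_value < 0.001
        if res.test_used == "anova":
            assert res.posthoc is not None
            flagged = res.posthoc[res.posthoc["reject"] == True]  # noqa: E712
            assert {"c"} <= set(flagged["group1"]) | set(flagged["group2"])

    def test_heavy_tailed_takes_kruskal_branch(self):
        rng = np.random.default_rng(2)
        heavy = {k: stats.cauchy.rvs(size=40, random_state=rng.integers(1e6))
                 for k in ("a", "b", "c")}
        res = pm.compare_methods(heavy)
        assert res.test_used == "kruskal"
        assert not res.assumptions["normal"]

    def test_all_identical_reports_no_difference(self):
        res = pm.compare_methods({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert res.test_used == "none"


class TestLOOCV:
    @pytest.fixture(scope="class")
    def loocv_result(self, tiny_cohort):
        cohort, _ = tiny_cohort
        cfg = pm.RunConfig(seed=3, n_perm=30)
        builder = pm.make_pss_builder(pm.MethodSpec("t", "perm"), cfg)
        return cohort, pm.loocv_overlap_correlation(cohort, builder)

    def test_one_fold_per_patient(self, loocv_result):
        cohort, res = loocv_result
        assert res.folds == cohort.patients
        assert len(res.fold_pss) == cohort.n_patients
        assert len(res.overlaps) == len(cohort.records)

    def test_trimming_excludes_top_tail(self, loocv_result):
        _, res = loocv_result
        if res.trim_threshold is not None and res.trim_threshold > 0:
            assert res.n_used <= len(res.overlaps)
            kept = res.overlaps[res.overlaps < res.trim_threshold]
            assert res.n_used == kept.size

    def test_needs_three_patients(self, tiny_cohort):
        cohort, _ = tiny_cohort
        two = cohort.subset_patients(cohort.patients[:2])
        with pytest.raises(pm.CohortValidationError):
            pm.loocv_overlap_correlation(two, lambda c: None)

    def test_monotone_pairs_give_unit_rho(self, small_grid):
        overlaps = np.array([0.0, 0.1, 0.2, 0.3, 0.4])
        rho, _ = stats.spearmanr(overlaps, overlaps * 100)
        assert rho == pytest.approx(1.0)

    def test_shuffled_labels_center_rho_at_zero(self, tiny_cohort):
        """With improvement labels shuffled, overlap carries no signal."""
        from pssmap.cohort_io import Cohort, StimulationRecord
        import dataclasses
        cohort, _ = tiny_cohort
        rng = np.random.default_rng(0)
        imps = np.array([r.improvement_pct for r in cohort.records])
        rhos = []
        for rep in range(3):
            shuffled_imps = rng.permutation(imps)
            records = [dataclasses.replace(r, improvement_pct=float(v))
                       for r, v in zip(cohort.records, shuffled_imps)]
            shuffled = Cohort(grid=cohort.grid, records=records,
                              ef_volumes=cohort.ef_volumes)
            cfg = pm.RunConfig(seed=rep, n_perm=20)
            res = pm.loocv_overlap_correlation(
                shuffled, pm.make_pss_builder(pm.MethodSpec("t", "perm"), cfg),
                trim_pct=None)
            if np.isfinite(res.spearman_rho):
                rhos.append(res.spearman_rho)
        if rhos:
            assert abs(np.mean(rhos)) < 0.25
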