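"""Statistical mapping methods against independent oracles."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import stdtr

import pssmap as pm
from pssmap.psm import (_prepare, _t_pvalues, _w_pvalues,
                        wilcoxon_p_from_counts, _fit_lmm_voxel)


def brute_force_signed_rank_p(sample, mu0):
    """One-sided signed-rank p by full enumeration of sign assignments.

    Pratt handling: |differences| (zeros included) receive midranks, zeros
    are then dropped; every remaining difference is independently +/- under
    the null and p = P(W+ >= observed).
    """
    d = np.asarray(sample, dtype=float) - mu0
    ranks = stats.rankdata(np.abs(d))
    nz = np.abs(d) > 1e-12
    w_obs = ranks[nz & (d > 0)].sum()
    nz_ranks = ranks[nz]
    k = len(nz_ranks)
    if k == 0:
        return 1.0
    count = 0
    for bits in range(2**k):
        w = sum(r for i, r in enumerate(nz_ranks) if bits >> i & 1)
        count += w >= w_obs - 1e-9
    return count / 2**k


class TestTMap:
    def test_degenerate_conventions(self):
        assert pm.t_pvalue([75, 75, 75], 75) == 1.0
        assert pm.t_pvalue([100, 100, 100], 75) == 0.0
        assert pm.t_pvalue([50, 50, 50], 75) == 1.0

    def test_known_sample(self):
        # mean 85, sd 22.3607, t = 1.0, df = 4
        p = pm.t_pvalue([100, 100, 50, 75, 100], 75)
        assert p == pytest.approx(float(stdtr(4, -1.0)), abs=1e-12)
        assert p == pytest.approx(0.1869504831500295, abs=1e-9)

    def test_matches_closed_form_on_random_samples(self):
        """Vectorized map p-values agree with the t distribution closed
        form to 1e-12 on 1000 random voxel samples."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(3, 30)
            x = rng.choice([0, 25, 50, 75, 100], n) + rng.normal(0, 1, n)
            p = pm.t_pvalue(x, 75)
            t_ref = (x.mean() - 75) / (x.std(ddof=1) / np.sqrt(n))
            assert p == pytest.approx(float(stdtr(n - 1, -t_ref)), abs=1e-12)

    def test_map_matches_per_voxel_scipy(self, tiny_stack):
        m = pm.tmap(tiny_stack)
        vox = np.argwhere(m.valid_mask)[::37]
        for ijk in vox:
            sample = [o[1] for o in tiny_stack.observations(tuple(ijk))]
            ref = stats.ttest_1samp(sample, 75, alternative="greater")
            if np.ptp(sample) > 0:
                assert m.stat[tuple(ijk)] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_min_n_marks_voxels_invalid(self, tiny_stack):
        m = pm.tmap(tiny_stack, min_n=5)
        n = tiny_stack.n_map
        assert not m.valid_mask[n < 5].any()
        assert m.valid_mask[n >= 5].all()
        assert np.isnan(m.stat[~m.valid_mask]).all()


class TestWilcoxonMap:
    def test_three_identical_above(self):
        # all diffs +25: only the all-positive assignment reaches W+ = max
        assert pm.wilcoxon_pvalue([100, 100, 100], 75) == pytest.approx(0.125)

    def test_all_below_has_no_evidence(self):
        assert pm.wilcoxon_pvalue([50, 50, 50], 75) >= 0.5

    def test_all_zero_differences(self):
        assert pm.wilcoxon_pvalue([75, 75, 75], 75) == 1.0

    def test_matches_enumeration_small_n(self):
        """Exact tie-aware implementation equals brute-force enumeration of
        all 2^n sign assignments for n <= 10."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(3, 11))
            x = rng.choice([0, 25, 50, 75, 100], n).astype(float)
            assert pm.wilcoxon_pvalue(x, 75) == pytest.approx(
                brute_force_signed_rank_p(x, 75), abs=1e-12), x

    def test_normal_approximation_close_to_exact_at_cutover(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x = rng.choice([25, 50, 75, 100], 24).astype(float)
            exact = pm.wilcoxon_pvalue(x, 75, exact_max_n=25)
            approx = pm.wilcoxon_pvalue(x, 75, exact_max_n=5)
            assert approx == pytest.approx(exact, abs=0.02)

    def test_map_agrees_with_scalar_path(self, tiny_stack):
        m = pm.wmap(tiny_stack)
        vox = np.argwhere(m.valid_mask)[::37]
        for ijk in vox:
            sample = [o[1] for o in tiny_stack.observations(tuple(ijk))]
            assert m.stat[tuple(ijk)] == pytest.approx(
                pm.wilcoxon_pvalue(sample, 75), abs=1e-12)


class TestBayesFactor:
    def test_symmetric_sample_gives_unit_bf(self):
        for sample in ([50, 75, 100], [55, 95, 75],
                       [50, 50, 100, 100], [70, 80]):
            assert pm.bayes_factor_directional(sample, 75) == pytest.approx(1.0, rel=0.05)

    def test_prior_scale_cancels_for_symmetric_sample(self):
        for scale in (10.0, 25.0, 50.0):
            bf = pm.bayes_factor_directional([50, 75, 100], 75,
                                             prior=pm.PriorSpec(scale=scale))
            assert bf == pytest.approx(1.0, rel=0.05)

    def test_strong_sample_exceeds_threshold(self):
        rng = np.random.default_rng(1)
        sample = np.clip(100 - np.abs(rng.normal(0, 0.5, 20)), 0, 100)
        assert pm.bayes_factor_directional(sample, 75) > 10

    def test_monotone_in_sample_mean(self):
        base = np.array([60.0, 70.0, 80.0, 90.0])
        bfs = [pm.bayes_factor_directional(base + s, 75)
               for s in (-20, -10, -5, 0, 5, 10, 20)]
        assert np.all(np.diff(bfs) > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(pm.CohortValidationError):
            pm.bayes_factor_directional([50.0, np.nan], 75)

    def test_quadrature_and_mcmc_agree(self):
        for sample in ([80, 85, 90, 75, 70], [60, 55, 70, 65, 80]):
            lq = np.log(pm.bayes_factor_directional(sample, 75))
            lm = np.log(pm.bayes_factor_directional(sample, 75,
                                                    backend="mcmc", seed=3))
            assert abs(lq - lm) <= max(0.1 * abs(lq), 0.1)

    def test_bmap_respects_min_n(self, tiny_stack):
        m = pm.bmap(tiny_stack, min_n=4)
        assert not m.valid_mask[tiny_stack.n_map < 4].any()
        v = m.valid_mask
        assert np.all(m.stat[v] > 0)


class TestPriorSensitivity:
    def test_consistent_classification_and_determinism(self):
        rng = np.random.default_rng(2)
        strong = list(np.clip(100 - np.abs(rng.normal(0, 1, 12)), 0, 100))
        symmetric = [50.0, 75.0, 100.0]
        res = pm.prior_sensitivity([strong, symmetric])
        table = res.table
        strong_rows = table[table["sample"] == 0]
        assert (strong_rows["bf10"] >= 10).all()
        sym_rows = table[table["sample"] == 1]
        assert np.allclose(sym_rows["bf10"], 1.0, rtol=0.05)
        assert res.summary["same_classification"].all()
        # identical prior passed twice gives identical rows
        res2 = pm.prior_sensitivity(
            [strong], priors={"a": pm.PriorSpec(), "b": pm.PriorSpec()})
        a, b = res2.table.iloc[0], res2.table.iloc[1]
        assert a["bf10"] == b["bf10"]


class TestLMM:
    def test_slope_recovery_noise_free(self):
        rng = np.random.default_rng(0)
        ef = np.tile(np.linspace(0.2, 1.0, 6), 8)
        pat = np.repeat(np.arange(8), 6)
        imp = 50 + 20 * ef + rng.normal(0, 5, 8)[pat]
        slope, p, _ = _fit_lmm_voxel(imp, ef, pat)
        assert slope == pytest.approx(20.0, rel=0.05)
        assert p < 0.01

    def test_constant_improvement_per_patient_gives_null_slope(self):
        rng = np.random.default_rng(1)
        ef = np.tile(np.linspace(0.2, 1.0, 6), 8)
        pat = np.repeat(np.arange(8), 6)
        imp = rng.normal(60, 10, 8)[pat]  # EF varies, improvement does not
        slope, p, _ = _fit_lmm_voxel(imp, ef, pat)
        assert abs(slope) < 3.0
        assert p > 0.05

    def test_negative_slope_not_selected(self, small_grid):
        from pssmap.cohort_io import Cohort, EFVolume, StimulationRecord
        records, volumes = [], {}
        rng = np.random.default_rng(3)
        i = 0
        for p_idx in range(6):
            for ef_val in (0.3, 0.6, 0.9):
                ref = f"r{i}"; i += 1
                field = np.zeros(small_grid.shape)
                field[8, 8, 8] = ef_val
                imp = float(np.clip(round((80 - 40 * ef_val
                                           + rng.normal(0, 2)) / 5) * 5, 0, 100))
                records.append(StimulationRecord(
                    patient_id=f"P{p_idx}", lead_id=f"P{p_idx}_l",
                    tract_id="central", depth_mm=0.0, amplitude_mA=1.0,
                    improvement_pct=imp, ef_volume_ref=ref))
                volumes[ref] = EFVolume(grid=small_grid, values=field, record_ref=ref)
        stack = pm.build_stack(Cohort(grid=small_grid, records=records,
                                      ef_volumes=volumes))
        m = pm.lmm_map(stack)
        assert m.valid_mask[8, 8, 8]
        assert m.slope[8, 8, 8] < 0
        assert m.stat[8, 8, 8] < 0.05
        sig = pm.significant_voxels(m)
        assert not sig[8, 8, 8]  # significant but negative: excluded


class TestOrderInvariance:
    def test_maps_invariant_to_observation_order(self, tiny_cohort):
        from pssmap.cohort_io import Cohort
        cohort, _ = tiny_cohort
        shuffled = Cohort(grid=cohort.grid,
                          records=list(reversed(cohort.records)),
                          ef_volumes=cohort.ef_volumes)
        sa, sb = pm.build_stack(cohort), pm.build_stack(shuffled)
        for fn in (pm.tmap, pm.wmap):
            assert np.allclose(fn(sa).stat, fn(sb).stat, equal_nan=True)
        assert np.allclose(pm.bmap(sa).stat, pm.bmap(sb).stat,
                           equal_nan=True, rtol=1e-9)
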