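import numpy as np
import pytest

from braingp import (
    AccuracyRecord,
    EvaluationSummary,
    SimSpec,
    VoxelMap,
    compare_modes,
    correlate_maps,
    density_map,
    electrode_density,
    fisher_z,
    information_scores,
    loo_accuracy,
    make_ground_truth,
    simulate_dataset,
    top_fraction_intersection,
)
from braingp.evaluate import ACROSS, WITHIN

from conftest import make_recording


class TestLooAccuracy:
    def test_modes_align_one_to_one(self, small_cohort):
        _, recs, _ = small_cohort
        across = loo_accuracy(recs, mode=ACROSS)
        within = loo_accuracy(recs, mode=WITHIN)
        a_keys = [(r.patient_id, r.electrode_id) for r in across.records]
        w_keys = [(r.patient_id, r.electrode_id) for r in within.records]
        assert a_keys == w_keys
        n_elec = sum(r.n_electrodes for r in recs)
        assert len(a_keys) == n_elec

    def test_shared_structure_yields_positive_accuracy(self, small_cohort):
        from scipy import stats

        _, recs, _ = small_cohort
        summary = loo_accuracy(recs, mode=ACROSS)
        z = summary.per_patient_mean_z(ACROSS)
        t, p = stats.ttest_1samp(z.to_numpy(), 0.0, alternative="greater")
        assert p < 0.01
        assert summary.mean_r(ACROSS) > 0.2

    def test_independent_noise_gives_near_zero_accuracy(self):
        # K_true = identity: nothing to recover
        rng = np.random.default_rng(0)
        gt = make_ground_truth(seed=1, smoothness=1e-9, lowrank_weight=0.0)
        recs = []
        for s in range(4):
            sub = rng.choice(gt.n_locations, 8, replace=False)
            v = rng.standard_normal((5000, 8))
            recs.append(make_recording(v, gt.locations[sub], patient_id=f"p{s}"))
        summary = loo_accuracy(recs, mode=ACROSS)
        assert abs(summary.mean_r(ACROSS)) < 0.05

    def test_anti_circularity_in_provenance(self, small_cohort):
        _, recs, _ = small_cohort
        summary = loo_accuracy(recs[:4], mode=ACROSS)
        for held_out, merged in summary.model_log[ACROSS].items():
            assert held_out not in merged
            assert len(merged) == 3

    def test_preconditions(self, small_cohort):
        _, recs, _ = small_cohort
        with pytest.raises(ValueError, match=">= 2 patients"):
            loo_accuracy(recs[:1], mode=ACROSS)
        two = recs[0].subset_electrodes([0, 1])
        with pytest.raises(ValueError, match=">= 3 electrodes"):
            loo_accuracy([two], mode=WITHIN)

    def test_aggregate_is_z_space_session_average(self):
        rec = AccuracyRecord("p", "e", np.zeros(3), [0.0, 0.6], ACROSS)
        assert rec.aggregate_r == pytest.approx(1.0 / 3.0, abs=1e-12)


class TestCompareModes:
    def test_identical_modes_give_zero_paired_t(self):
        records = []
        for i, r in enumerate([0.3, 0.5, 0.4]):
            for mode in (ACROSS, WITHIN):
                records.append(AccuracyRecord(f"p{i}", "e0", np.zeros(3), [r], mode))
        comp = compare_modes(EvaluationSummary(records=records))
        assert comp.paired_t == 0.0
        assert comp.paired_df == 2

    def test_matches_hand_computed_paired_t(self):
        a_vals = [0.5, 0.6, 0.4, 0.55, 0.45]
        w_vals = [0.3, 0.35, 0.25, 0.4, 0.3]
        records = []
        for i, (a, w) in enumerate(zip(a_vals, w_vals)):
            records.append(AccuracyRecord(f"p{i}", "e0", np.zeros(3), [a], ACROSS))
            records.append(AccuracyRecord(f"p{i}", "e0", np.zeros(3), [w], WITHIN))
        comp = compare_modes(EvaluationSummary(records=records))
        d = fisher_z(np.array(a_vals)) - fisher_z(np.array(w_vals))
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert comp.paired_t == pytest.approx(expected_t, abs=1e-10)
        assert comp.paired_df == 4
        t1, df1, _ = comp.one_sample[ACROSS]
        za = fisher_z(np.array(a_vals))
        assert t1 == pytest.approx(za.mean() / (za.std(ddof=1) / np.sqrt(5)), abs=1e-10)
        assert df1 == 4

    def test_needs_two_patients(self):
        records = [AccuracyRecord("p0", "e0", np.zeros(3), [0.5], ACROSS)]
        with pytest.raises(ValueError, match=">= 2 patients"):
            compare_modes(EvaluationSummary(records=records))


class TestDensityMaps:
    def test_single_electrode_at_voxel_center(self):
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(3, 3, 3), spacing=4.0)
        dm = density_map(np.array([[4.0, 4.0, 4.0]]), grid)
        assert dm.values[1, 1, 1] == 1.0

    def test_proportion_and_strict_radius(self):
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(1, 1, 1), spacing=4.0)
        locs = np.zeros((10, 3))
        locs[3:, 0] = 50.0  # 7 electrodes out of range
        dm = density_map(locs, grid)
        assert dm.values[0, 0, 0] == pytest.approx(0.3)
        just_out = np.array([[20.1, 0.0, 0.0]])
        dm2 = density_map(just_out, grid)
        assert dm2.values[0, 0, 0] == 0.0
        on_boundary = np.array([[20.0, 0.0, 0.0]])  # closed ball includes ties
        dm3 = density_map(on_boundary, grid)
        assert dm3.values[0, 0, 0] == 1.0

    def test_electrode_density_proportions(self):
        loc = np.zeros(3)
        others = np.zeros((8, 3))
        others[4:, 0] = 100.0
        assert electrode_density(loc, others) == 0.5
        assert electrode_density(loc, np.zeros((3, 3))) == 1.0
        assert electrode_density(loc, np.full((3, 3), 100.0)) == 0.0
        with pytest.raises(ValueError, match="empty"):
            electrode_density(loc, np.zeros((0, 3)))

    def test_density_map_agrees_with_electrode_density(self):
        rng = np.random.default_rng(1)
        others = rng.uniform(-30, 30, (20, 3))
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(1, 1, 1), spacing=4.0)
        assert density_map(others, grid).values[0, 0, 0] == pytest.approx(
            electrode_density(np.zeros(3), others))


class TestInformationScores:
    def grid(self):
        return VoxelMap.box(origin=(0, 0, 0), shape=(1, 1, 1), spacing=4.0)

    def test_single_patient_score_is_its_accuracy(self):
        records = [AccuracyRecord("p0", f"e{i}", np.zeros(3), [0.4], ACROSS)
                   for i in range(3)]
        vmap = information_scores(EvaluationSummary(records=records), self.grid())
        assert vmap.values[0, 0, 0] == pytest.approx(0.4)

    def test_electrode_count_weighting(self):
        records = []
        # patient a: accuracy 0.6, 3 electrodes near the voxel
        for i in range(3):
            records.append(AccuracyRecord("a", f"e{i}", np.zeros(3), [0.6], ACROSS))
        # patient b: accuracy 0.2, 1 electrode near the voxel
        records.append(AccuracyRecord("b", "e0", np.zeros(3), [0.2], ACROSS))
        vmap = information_scores(EvaluationSummary(records=records), self.grid())
        assert vmap.values[0, 0, 0] == pytest.approx((3 * 0.6 + 1 * 0.2) / 4)

    def test_uncovered_voxel_missing(self):
        records = [AccuracyRecord("a", "e0", np.array([100.0, 0, 0]), [0.5], ACROSS)]
        vmap = information_scores(EvaluationSummary(records=records), self.grid())
        assert np.isnan(vmap.values[0, 0, 0])


class TestMapComparisons:
    def ramp_map(self, n=27):
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(3, 3, 3), spacing=4.0)
        return grid.with_values(np.arange(n, dtype=float))

    def test_identical_maps_intersection_is_top_set(self):
        m = self.ramp_map()
        inter = top_fraction_intersection(m, m, fraction=0.1)
        vals = inter.in_mask_values()
        assert vals.sum() == np.ceil(0.1 * 27)

    def test_reversed_ranks_empty_intersection(self):
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(10, 1, 1), spacing=4.0)
        a = grid.with_values(np.arange(10, dtype=float))
        b = grid.with_values(np.arange(10, dtype=float)[::-1].copy())
        inter = top_fraction_intersection(a, b, fraction=0.1)
        assert inter.in_mask_values().sum() == 0

    def test_intersection_bounded_by_fraction(self):
        rng = np.random.default_rng(2)
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(5, 5, 4), spacing=4.0)
        a = grid.with_values(rng.standard_normal(100))
        b = grid.with_values(rng.standard_normal(100))
        inter = top_fraction_intersection(a, b, fraction=0.1)
        assert inter.in_mask_values().sum() <= np.ceil(0.1 * 100)

    def test_correlate_maps(self):
        m = self.ramp_map()
        r, n = correlate_maps(m, m)
        assert r == pytest.approx(1.0)
        assert n == 27
        neg = m.with_values(-m.in_mask_values())
        r2, _ = correlate_maps(m, neg)
        assert r2 == pytest.approx(-1.0)

    def test_disjoint_maps_error(self):
        grid = VoxelMap.box(origin=(0, 0, 0), shape=(4, 1, 1), spacing=4.0)
        a_vals = np.array([1.0, 2.0, np.nan, np.nan])
        b_vals = np.array([np.nan, np.nan, 1.0, 2.0])
        with pytest.raises(ValueError, match="shared"):
            correlate_maps(grid.with_values(a_vals), grid.with_values(b_vals))

    def test_grid_mismatch_errors(self):
        a = VoxelMap.box(shape=(3, 3, 3))
        b = VoxelMap.box(shape=(4, 4, 4))
        with pytest.raises(ValueError, match="grid"):
            correlate_maps(a, b)
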