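"""Dose differences, DVH endpoints, gamma analysis, fluence MAE, reports."""

import numpy as np
import pytest

from fluenceforge.dose_engine import FieldDoseSet
from fluenceforge.evaluation import (
    EvalRegion,
    PredictedPlan,
    aggregate_reports,
    dvh_curve,
    dvh_metrics,
    evaluate_case,
    fluence_mae,
    gamma_2d,
    voxel_dose_difference,
)

from gamma_oracle import gamma_oracle


class TestVoxelDoseDifference:
    def test_identical_zero(self):
        d = np.random.default_rng(0).random((4, 4, 2)) * 100
        assert voxel_dose_difference(d, d, np.ones_like(d)) == 0.0

    def test_hand_computed(self):
        # 2 voxels, bench [100, 50], pred [90, 60]: (10+10)/2 = 10% of Rx
        bench = np.array([100.0, 50.0])
        pred = np.array([90.0, 60.0])
        assert voxel_dose_difference(bench, pred, np.ones(2)) == pytest.approx(
            10.0, rel=1e-12
        )

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        a, b = rng.random(10) * 100, rng.random(10) * 100
        m = np.ones(10)
        assert voxel_dose_difference(a, b, m) == voxel_dose_difference(b, a, m)

    def test_homogeneous_in_prescription_scale(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(10) * 100, rng.random(10) * 100
        m = np.ones(10)
        base = voxel_dose_difference(a, b, m, d_rx=100.0)
        scaled = voxel_dose_difference(3 * a, 3 * b, m, d_rx=300.0)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_empty_region_error(self):
        with pytest.raises(ValueError, match="empty"):
            voxel_dose_difference(np.ones(3), np.ones(3), np.zeros(3))


class TestDVH:
    def test_uniform_dose(self):
        m = dvh_metrics(np.full(200, 66.0), np.ones(200, dtype=bool))
        assert m.d_mean == m.d_max_01cc == m.d_95 == 66.0

    def test_sorted_list_hand_computed(self):
        # 100 voxels of 0.002 cc with doses 1..100: the hottest 0.1 cc is 50
        # voxels (min 51), d95 is the nearest-rank 5th percentile (5)
        dose = np.arange(1.0, 101.0)
        m = dvh_metrics(dose, np.ones(100, dtype=bool), voxel_cc=0.002)
        assert m.d_max_01cc == 51.0
        assert m.d_95 == 5.0
        assert m.d_mean == pytest.approx(50.5)

    def test_small_structure_fallback_warns(self):
        dose = np.array([10.0, 20.0, 30.0])
        with pytest.warns(UserWarning, match="0.1 cc"):
            m = dvh_metrics(dose, np.ones(3, dtype=bool), voxel_cc=0.002)
        assert m.d_max_01cc == 30.0

    def test_mask_restriction(self):
        dose = np.concatenate([np.arange(1.0, 101.0), np.zeros(50)])
        mask = np.zeros(150, dtype=bool)
        mask[:100] = True
        m_full = dvh_metrics(np.arange(1.0, 101.0), np.ones(100, dtype=bool),
                             0.002)
        m_masked = dvh_metrics(dose, mask, 0.002)
        assert m_full == m_masked

    def test_plateau_equals_plain_max(self):
        # hottest 50 voxels share one value -> D_max(0.1cc) = plain max
        dose = np.concatenate([np.full(60, 80.0), np.arange(40)])
        m = dvh_metrics(dose, np.ones(100, dtype=bool), 0.002)
        assert m.d_max_01cc == 80.0 == dose.max()

    def test_empty_mask_error(self):
        with pytest.raises(ValueError, match="empty"):
            dvh_metrics(np.ones(4), np.zeros(4, dtype=bool))

    def test_dvh_curve_monotone(self):
        rng = np.random.default_rng(3)
        dose = rng.random(500) * 110
        edges, frac = dvh_curve(dose, np.ones(500, dtype=bool))
        assert frac[0] == 1.0
        assert np.all(np.diff(frac) <= 1e-12)


def _smooth_map(rng, n=32, pixel_mm=2.5):
    from scipy import ndimage

    m = ndimage.gaussian_filter(rng.random((n, n)), 3.0)
    m -= m.min()
    return m / m.max() * 100.0


class TestGamma:
    def test_identical_maps_all_pass(self):
        ref = _smooth_map(np.random.default_rng(0))
        res = gamma_2d(ref, ref)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_subcriterion_offset_passes(self):
        ref = _smooth_map(np.random.default_rng(1))
        ev = ref + 0.029 * ref.max()
        res = gamma_2d(ref, ev)
        assert res.pass_rate == 100.0
        assert np.nanmax(res.gamma_map) < 1.0

    def test_shifted_cliff_fails(self):
        # a steep cliff shifted by 4 mm (> 3 mm criterion at matching dose)
        ref = np.zeros((24, 24))
        ref[:, :12] = 100.0
        ev = np.zeros((24, 24))
        ev[:, :8] = 100.0    # cliff retracted by 4 px at 1 mm/px
        res = gamma_2d(ref, ev, pixel_mm=1.0)
        gm = res.gamma_map
        # reference pixels 4 mm from the evaluated cliff must fail
        assert np.all(gm[:, 11] > 1.0)
        # while pixels within 3 mm of it still pass
        assert np.all(gm[:, 9] <= 1.0)
        assert res.pass_rate < 100.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        ref = _smooth_map(rng)
        ev = ref * (1 + 0.05 * rng.standard_normal(ref.shape))
        r1 = gamma_2d(ref, ev)
        r2 = gamma_2d(10 * ref, 10 * ev)
        assert r1.pass_rate == r2.pass_rate
        assert np.allclose(np.nan_to_num(r1.gamma_map),
                           np.nan_to_num(r2.gamma_map), rtol=1e-9)

    def test_zero_reference_error(self):
        with pytest.raises(ValueError, match="zero"):
            gamma_2d(np.zeros((8, 8)), np.ones((8, 8)))

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="shape"):
            gamma_2d(np.ones((8, 8)), np.ones((9, 8)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle_small(self, seed):
        rng = np.random.default_rng(seed)
        ref = _smooth_map(rng, n=16)
        ev = ref * (1 + 0.03 * rng.standard_normal(ref.shape))
        ev = np.clip(ev + 1.0 * rng.standard_normal(ref.shape), 0, None)
        res = gamma_2d(ref, ev, pixel_mm=2.5)
        omap, orate = gamma_oracle(ref, ev, pixel_mm=2.5)
        sel = ~np.isnan(res.gamma_map)
        assert np.array_equal(res.gamma_map[sel] <= 1.0, omap[sel] <= 1.0)
        assert res.pass_rate == orate


class TestFluenceMAE:
    def test_exact_zero(self):
        y = np.array([1.0, 0.5, 0.0])
        assert fluence_mae(y, y) == 0.0

    def test_hand_computed(self):
        y_bench = np.array([1.0, 0.5, 0.0])
        y_pred = np.array([0.9, 0.5, 0.0])
        assert fluence_mae(y_bench, y_pred) == pytest.approx(0.05, rel=1e-12)

    def test_no_positive_error(self):
        with pytest.raises(ValueError, match="positive"):
            fluence_mae(np.zeros(3), np.ones(3))


class _FakeBenchmark:
    def __init__(self, field_doses, fluences):
        self.field_doses = field_doses
        self.fluences = fluences


@pytest.fixture(scope="module")
def eval_setup(request):
    case = request.getfixturevalue("coarse_phantom")
    rng = np.random.default_rng(4)
    shape = (9,) + case.grid.shape
    roi = case.roi().voxels > 0
    per_beam = rng.random(shape) * 12 * roi[None]
    fluences = np.zeros((9, 32, 32))
    fluences[:, 10:22, 10:22] = rng.random((9, 12, 12)) * 10
    bench = _FakeBenchmark(FieldDoseSet(per_beam=per_beam, grid=case.grid),
                           fluences)
    return case, bench


class TestEvaluateCase:
    def test_identical_plans_zero_everywhere(self, eval_setup):
        case, bench = eval_setup
        plan = PredictedPlan(total=bench.field_doses.total,
                             per_beam=bench.field_doses.per_beam,
                             fluences=bench.fluences)
        df = evaluate_case(case, bench, {"fd_cnn_dose": plan},
                           gamma_pixel_mm=7.5)
        diffs = df[df.metric.str.contains("diff|dd")]
        assert np.allclose(diffs.value, 0.0, atol=1e-9)
        gamma = df[df.metric == "gamma_pass_pct"]
        assert (gamma.value == 100.0).all()

    def test_schema_and_absent_marker(self, eval_setup):
        case, bench = eval_setup
        plan = PredictedPlan(total=bench.field_doses.total)
        df = evaluate_case(
            case, bench,
            {"fd_cnn_dose": plan, "fm_cnn_plan": None,
             "model_predicted_plan": None},
        )
        assert set(df.plan) == {"fd_cnn_dose", "fm_cnn_plan",
                                "model_predicted_plan"}
        absent = df[df.metric == "absent"]
        assert set(absent.plan) == {"fm_cnn_plan", "model_predicted_plan"}
        regions = set(df[df.plan == "fd_cnn_dose"].region)
        assert {"PTV", "OAR", "ROI"} <= regions

    def test_cohort_mean_identity(self, eval_setup):
        # with equal region sizes the cohort mean voxel difference equals
        # the difference over the concatenated voxel list
        rng = np.random.default_rng(5)
        n = 50
        bench = [rng.random(n) * 100 for _ in range(4)]
        pred = [rng.random(n) * 100 for _ in range(4)]
        mask = np.ones(n)
        per_case = [voxel_dose_difference(b, p, mask)
                    for b, p in zip(bench, pred)]
        concat = voxel_dose_difference(np.concatenate(bench),
                                       np.concatenate(pred), np.ones(4 * n))
        assert np.mean(per_case) == pytest.approx(concat, rel=1e-12)

    def test_aggregate_mean_sd(self, eval_setup):
        case, bench = eval_setup
        plan = PredictedPlan(total=bench.field_doses.total * 1.01)
        reports = [evaluate_case(case, bench, {"fd_cnn_dose": plan})
                   for _ in range(2)]
        summary = aggregate_reports(reports)
        assert {"mean", "std", "count"} <= set(summary.columns)
        assert (summary["count"] == 2).all()


def test_eval_region_rejects_empty():
    with pytest.raises(ValueError, match="empty"):
        EvalRegion("PTV", np.zeros((3, 3)))
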