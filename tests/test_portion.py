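"""Portion estimation: calibration, robust fitting, fusion, splits, metrics."""

import math

import numpy as np
import pytest

from trayintake import (
    AreaWeightModel,
    CalibrationError,
    CalibrationSolid,
    DataError,
    MaskModel,
    MaskObservation,
    PairingError,
    PredictionError,
    SplitError,
    SplitSpec,
    calibrate_view,
    evaluate,
    fit_area_weight,
    intake_from_images,
    mask_metrics,
    meal_level_split,
    predict_weight,
    smooth_l1,
)


def obs(area, view="top", cls="pasta", conf=1.0, item="it", tray="T1"):
    return MaskObservation(
        tray_id=tray, item_name=item, food_class=cls, view_id=view,
        area_px=area, confidence=conf,
    )


class TestCalibration:
    def test_cube(self):
        r = calibrate_view([CalibrationSolid("cube", 5.0, 5.0, 2500.0)])
        assert r.scale_cm2_per_px == pytest.approx(0.01)

    def test_cylinder(self):
        area = math.pi * 25.0 / 0.01
        r = calibrate_view([CalibrationSolid("cylinder", 10.0, 8.0, area)])
        assert r.scale_cm2_per_px == pytest.approx(0.01)

    def test_mean_of_solids_with_residuals(self):
        s1 = CalibrationSolid("cube", 5.0, 5.0, 2500.0)        # 0.010
        s2 = CalibrationSolid("cube", 6.0, 6.0, 3000.0)        # 0.012
        r = calibrate_view([s1, s2])
        assert r.scale_cm2_per_px == pytest.approx(0.011)
        assert sorted(np.round(r.residuals, 6)) == pytest.approx([-0.001, 0.001])

    def test_zero_area_rejected(self):
        with pytest.raises(CalibrationError):
            CalibrationSolid("cube", 5.0, 5.0, 0.0)

    def test_no_solids_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_view([])


class TestSmoothL1:
    @pytest.mark.parametrize(
        "r,beta,expected", [(0, 1, 0.0), (2, 1, 1.5), (0.5, 1, 0.125), (-2, 1, 1.5)]
    )
    def test_closed_form(self, r, beta, expected):
        assert smooth_l1(r, beta) == pytest.approx(expected)

    def test_invalid_beta(self):
        with pytest.raises(DataError):
            smooth_l1(1.0, 0.0)

    def test_bounded_by_absolute_loss(self):
        r = np.linspace(-5, 5, 201)
        losses = smooth_l1(r, 1.0)
        assert np.all(losses <= np.abs(r) + 1e-12)
        beyond = np.abs(r) >= 1.0 + 1e-9
        # equality holds only beyond the transition region, up to the 0.5β offset
        assert np.allclose(losses[beyond], np.abs(r[beyond]) - 0.5)
        inside = (np.abs(r) < 1.0) & (np.abs(r) > 1e-9)
        assert np.all(losses[inside] < np.abs(r[inside]))


SCALES = {"top": 0.01, "lat": 0.02}


def synth_pairs(slope, intercept, n, view, noise_sd, rng, cls="pasta"):
    w = rng.uniform(20, 400, n)
    # invert: area such that slope*(area*scale)+intercept = w + noise
    area = ((w - intercept) / slope + rng.normal(0, noise_sd / slope, n)) / SCALES[view]
    area = np.clip(area, 0, None)
    return [(obs(a, view=view, cls=cls), wi) for a, wi in zip(area, w)]


class TestFit:
    def test_noiseless_recovery(self, rng):
        pairs = synth_pairs(2.0, 5.0, 30, "top", 0.0, rng)
        model = fit_area_weight(pairs, SCALES)
        slope, intercept = model.coefficients[("pasta", "top")]
        assert slope == pytest.approx(2.0, abs=1e-6)
        assert intercept == pytest.approx(5.0, abs=1e-4)

    def test_robustness_against_outliers_vs_least_squares(self, rng):
        pairs = synth_pairs(2.0, 0.0, 100, "top", 1.0, rng)
        # 10% gross outliers at 5× weight
        bad = [(o, 5 * w) for o, w in pairs[:10]]
        train = bad + pairs[10:]
        model = fit_area_weight(train, SCALES, loss_beta=1.0)
        slope_sl1, _ = model.coefficients[("pasta", "top")]
        x = np.array([o.area_px * SCALES["top"] for o, _ in train])
        y = np.array([w for _, w in train])
        slope_ols = np.polyfit(x, y, 1)[0]
        assert abs(slope_sl1 - 2.0) < abs(slope_ols - 2.0)

    def test_fusion_weights_favor_low_noise_view(self, rng):
        train = synth_pairs(2.0, 0.0, 200, "top", 5.0, rng) + synth_pairs(
            2.0, 0.0, 200, "lat", 20.0, rng
        )
        val = synth_pairs(2.0, 0.0, 200, "top", 5.0, rng) + synth_pairs(
            2.0, 0.0, 200, "lat", 20.0, rng
        )
        model = fit_area_weight(train, SCALES, val=val)
        fw = model.fusion_weights["pasta"]
        # inverse-variance arithmetic: 1/25 vs 1/400 → ≈ 0.94
        assert fw["top"] > 0.8
        assert fw["top"] + fw["lat"] == pytest.approx(1.0)

    def test_underdetermined_view_falls_back_to_pooled(self, rng):
        train = synth_pairs(2.0, 0.0, 30, "top", 0.0, rng) + synth_pairs(
            2.0, 0.0, 3, "lat", 0.0, rng
        )
        with pytest.warns(UserWarning, match="pooled"):
            model = fit_area_weight(train, SCALES)
        assert "pasta" in model.pooled_classes
        # pooled coefficients shared by both views
        assert model.coefficients[("pasta", "top")] == model.coefficients[("pasta", "lat")]

    def test_model_serialization_round_trip(self, rng, tmp_path):
        train = synth_pairs(2.0, 5.0, 30, "top", 1.0, rng)
        model = fit_area_weight(train, SCALES)
        path = tmp_path / "model.json"
        model.save(path)
        back = AreaWeightModel.load(path)
        assert back.coefficients == model.coefficients
        assert back.fusion_weights == model.fusion_weights
        assert back.scales == model.scales


class TestPredict:
    def _two_view_model(self):
        return AreaWeightModel(
            coefficients={("pasta", "top"): (2.0, 0.0), ("pasta", "lat"): (2.0, 0.0)},
            fusion_weights={"pasta": {"top": 0.5, "lat": 0.5}},
            scales=SCALES,
        )

    def test_single_view_equals_multi_with_one_view(self):
        model = self._two_view_model()
        o = obs(5000.0, "top")  # 5000 px × 0.01 cm²/px × 2 g/cm² = 100 g
        assert predict_weight(model, [o], "multi_view") == pytest.approx(100.0)
        assert predict_weight(model, [o], "single_view") == pytest.approx(100.0)

    def test_equal_weights_average(self):
        model = self._two_view_model()
        o1 = obs(4500.0, "top")   # 90 g
        o2 = obs(2750.0, "lat")   # 110 g
        assert predict_weight(model, [o1, o2]) == pytest.approx(100.0)

    def test_zero_confidence_view_ignored(self):
        model = self._two_view_model()
        o1 = obs(4500.0, "top", conf=0.0)
        o2 = obs(2750.0, "lat")
        assert predict_weight(model, [o1, o2]) == pytest.approx(110.0)

    def test_unknown_class_rejected(self):
        model = self._two_view_model()
        with pytest.raises(PredictionError):
            predict_weight(model, [obs(100.0, "top", cls="soup")])

    def test_mixed_classes_rejected(self):
        model = self._two_view_model()
        with pytest.raises(PairingError):
            predict_weight(model, [obs(1.0, "top"), obs(1.0, "lat", cls="rice")])

    def test_negative_prediction_clamped(self):
        model = AreaWeightModel(
            coefficients={("pasta", "top"): (2.0, -50.0)},
            fusion_weights={"pasta": {"top": 1.0}},
            scales=SCALES,
        )
        assert predict_weight(model, [obs(0.0, "top")]) == 0.0


class TestIntakeFromImages:
    def _model(self):
        return AreaWeightModel(
            coefficients={("pasta", "top"): (2.0, 0.0)},
            fusion_weights={"pasta": {"top": 1.0}},
            scales=SCALES,
        )

    def test_empty_post_masks_mean_full_consumption(self):
        model = self._model()
        pre = [obs(5000.0, "top")]
        assert intake_from_images(model, pre, []) == pytest.approx(100.0)

    def test_identical_pre_post_zero(self):
        model = self._model()
        pre = [obs(5000.0, "top")]
        assert intake_from_images(model, pre, pre) == pytest.approx(0.0)

    def test_class_mismatch_rejected(self):
        model = self._model()
        pre = [obs(5000.0, "top", item="a")]
        post = [obs(100.0, "top", item="a", cls="rice")]
        with pytest.raises(PairingError):
            intake_from_images(model, pre, post)

    def test_noiseless_end_to_end(self):
        """Zero generator noise ⇒ consumed-weight error < 1e-6 g."""
        from trayintake import GeneratorConfig, generate_cohort
        from trayintake.synthetic import default_mask_model

        mm = default_mask_model()
        mm.cv = {k: 0.0 for k in mm.cv}
        cfg = GeneratorConfig(n_patients=8, mask_model=mm, seed=21)
        cohort = generate_cohort(cfg, include_masks=True)
        model = fit_area_weight(
            cohort.mask_items(), {v: 0.01 for v in cfg.views}
        )
        truth = dict(zip([t.tray_id for t in cohort.trays], cohort.true_intake_g))
        for tray in cohort.trays[:10]:
            pred = intake_from_images(
                model,
                cohort.tray_masks(tray.tray_id, "pre"),
                cohort.tray_masks(tray.tray_id, "post"),
            )
            assert pred == pytest.approx(truth[tray.tray_id], abs=1e-6)


class TestSplit:
    def test_sizes_and_disjointness(self):
        ids = [f"T{i}" for i in range(10)]
        tr, va, te = meal_level_split(ids, SplitSpec((0.8, 0.1, 0.1), seed=0))
        assert (len(tr), len(va), len(te)) == (8, 1, 1)
        assert set(tr) | set(va) | set(te) == set(ids)
        assert not (set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te))

    def test_largest_remainder_at_study_scale(self):
        ids = [f"T{i}" for i in range(362)]
        tr, va, te = meal_level_split(ids, SplitSpec((0.7, 0.15, 0.15), seed=1))
        assert (len(tr), len(va), len(te)) == (254, 54, 54)

    def test_seed_determinism(self):
        ids = [f"T{i}" for i in range(50)]
        spec = SplitSpec(seed=9)
        assert meal_level_split(ids, spec) == meal_level_split(ids, spec)

    def test_no_leakage_over_many_seeds(self):
        ids = [f"T{i}" for i in range(37)]
        for seed in range(200):
            parts = meal_level_split(ids, SplitSpec(seed=seed))
            seen = [x for part in parts for x in part]
            assert sorted(seen) == sorted(ids)

    def test_too_few_trays(self):
        with pytest.raises(SplitError):
            meal_level_split(["T1", "T2"], SplitSpec())

    def test_bad_fractions(self):
        with pytest.raises(SplitError):
            SplitSpec((0.5, 0.5, 0.5))


class TestMaskMetrics:
    def test_identical_masks(self):
        m = np.zeros((8, 8), bool)
        m[2:5, 2:5] = True
        r = mask_metrics(m, m)
        assert r.accuracy == 1.0 and r.f1 == 1.0

    def test_disjoint_half_masks(self):
        p = np.zeros((2, 4), bool)
        t = np.zeros((2, 4), bool)
        p[:, :2] = True
        t[:, 2:] = True
        r = mask_metrics(p, t)
        assert r.accuracy == 0.0 and r.f1 == 0.0

    def test_superset_prediction(self):
        t = np.zeros(100, bool)
        t[:50] = True
        p = np.ones(100, bool)  # TP=50, FP=50, FN=0
        r = mask_metrics(p, t)
        assert r.f1 == pytest.approx(2 * 50 / 150)

    def test_both_empty_convention(self):
        r = mask_metrics(np.zeros((3, 3), bool), np.zeros((3, 3), bool))
        assert r.accuracy == 1.0 and r.f1 == 1.0 and r.degenerate

    def test_shape_mismatch(self):
        with pytest.raises(DataError):
            mask_metrics(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        pairs = synth_pairs(2.0, 0.0, 30, "top", 0.0, rng)
        model = fit_area_weight(pairs, SCALES)
        test_items = [([o], w) for o, w in pairs[:10]]
        rep = evaluate(model, test_items)
        assert rep.mae_g == pytest.approx(0.0, abs=1e-6)
        assert rep.mape_pct == pytest.approx(0.0, abs=1e-6)

    def test_constant_offset_error(self):
        model = AreaWeightModel(
            coefficients={("pasta", "top"): (2.0, 10.0)},  # +10 g everywhere
            fusion_weights={"pasta": {"top": 1.0}},
            scales=SCALES,
        )
        items = [([obs(100.0 / 0.02, "top")], 100.0) for _ in range(5)]
        rep = evaluate(model, items)
        assert rep.mae_g == pytest.approx(10.0)
        assert rep.mape_pct == pytest.approx(10.0)
        assert set(rep.per_view["view_id"]) == {"top"}

    def test_empty_test_set(self):
        with pytest.raises(DataError):
            evaluate(AreaWeightModel(), [])


class TestScaleInvariance:
    def test_resolution_change_cancels(self, rng):
        """4× pixel areas with re-observed calibration solids: predictions equal."""
        pairs_lo = synth_pairs(2.0, 5.0, 40, "top", 2.0, rng)
        cal_lo = calibrate_view([CalibrationSolid("cube", 5.0, 5.0, 2500.0)])
        pairs_hi = [(obs(o.area_px * 4, "top"), w) for o, w in pairs_lo]
        cal_hi = calibrate_view([CalibrationSolid("cube", 5.0, 5.0, 10000.0)])
        m_lo = fit_area_weight(pairs_lo, {"top": cal_lo.scale_cm2_per_px, "lat": 1.0})
        m_hi = fit_area_weight(pairs_hi, {"top": cal_hi.scale_cm2_per_px, "lat": 1.0})
        for (o_lo, _), (o_hi, _) in zip(pairs_lo[:10], pairs_hi[:10]):
            assert predict_weight(m_lo, [o_lo]) == pytest.approx(
                predict_weight(m_hi, [o_hi]), abs=1e-9
            )


class TestFusionDominance:
    def test_multi_view_beats_best_single_view(self, mask_cohort):
        """Fused MAE ≤ best single-view MAE + 1 SE on an independent-noise cohort."""
        cohort = mask_cohort
        cfg = cohort.config
        ids = [t.tray_id for t in cohort.trays]
        train_ids, val_ids, test_ids = meal_level_split(ids, SplitSpec(seed=4))
        scales = {v: 0.01 for v in cfg.views}
        model = fit_area_weight(
            cohort.mask_items(train_ids), scales, val=cohort.mask_items(val_ids)
        )
        test_items = cohort.mask_items(test_ids)
        errs_multi = np.array(
            [abs(predict_weight(model, o, "multi_view") - w) for o, w in test_items]
        )
        best_single = np.inf
        for v in cfg.views:
            errs_v = np.array(
                [
                    abs(predict_weight(model, [x for x in o if x.view_id == v],
                                       "single_view", view=v) - w)
                    for o, w in test_items
                ]
            )
            best_single = min(best_single, errs_v.mean())
        se = errs_multi.std(ddof=1) / np.sqrt(len(errs_multi))
        assert errs_multi.mean() <= best_single + se
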