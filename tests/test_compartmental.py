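"""Triexponential fits, profile extension, time scaling, direct mapping."""

import numpy as np
import pytest

import ivivc
from ivivc import (
    CompartmentalIVIVRModel,
    DEPSConfig,
    TimeScaling,
    TimeSeriesProfile,
    TriexpModel,
    extend_profile,
    fit_scaling_constants,
    fit_time_scaling,
    fit_triexponential,
    predict_plasma_compartmental,
)


def conc_profile(times, values, unit="min"):
    return TimeSeriesProfile(
        np.asarray(times, float), np.asarray(values, float),
        "mg/mL", "concentration", unit,
    )


class TestTriexpFit:
    def test_recovers_generating_curve(self):
        """Known rise-and-fall triexponential with f(0)=0; the contract is
        curve agreement, not parameter equality (sums of exponentials are
        not identifiable)."""
        truth = TriexpModel((-20.0, 12.0, 8.0), (0.5, 0.05, 0.049))
        t = np.linspace(0.0, 120.0, 30)
        y = truth.evaluate(t)
        model = fit_triexponential(
            conc_profile(t, y),
            DEPSConfig(population_size=30, max_generations=400, seed=1),
        )
        peak = np.abs(y).max()
        assert model.fit_rmse < 1e-3 * peak
        assert np.abs(model.evaluate(t) - y).max() < 5e-3 * peak
        assert abs(sum(model.amplitudes)) < 1e-6 * peak  # f(0)=0 constraint

    def test_zero_profile_fits_exactly(self):
        t = np.linspace(0.0, 60.0, 10)
        model = fit_triexponential(conc_profile(t, np.zeros_like(t)))
        assert model.fit_rmse == 0.0
        assert np.all(model.evaluate(t) == 0.0)

    def test_monoexponential_data_absorbed(self):
        t = np.linspace(0.0, 100.0, 25)
        y = 5.0 * np.exp(-0.03 * t)
        model = fit_triexponential(
            conc_profile(t, y),
            DEPSConfig(population_size=30, max_generations=400, seed=3),
            constrain_origin=False,
        )
        assert model.fit_rmse < 1e-3 * y.max()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="6 points"):
            fit_triexponential(conc_profile([0, 1, 2, 3, 4], [0, 1, 2, 1, 0]))


class TestExtendProfile:
    def reference(self):
        return TriexpModel(
            (-20.0, 12.0, 8.0), (0.5, 0.05, 0.02),
            fitted_window=(0.0, 215.0),
        )

    def test_zero_points_is_identity(self):
        prof = conc_profile([0, 10, 20], [0, 1, 2])
        assert extend_profile(prof, self.reference(), n_points=0) is prof

    def test_requires_reference(self):
        with pytest.raises(ValueError, match="reference"):
            extend_profile(conc_profile([0, 10], [0, 1]), None)

    def test_pure_exponential_extension_lies_on_true_curve(self):
        """A truncated exponential extended with a reference of the same
        rate continues exactly on the true curve."""
        k = 0.03
        ref = TriexpModel(
            (5.0, 1e-9, 1e-9), (k, 1.0, 2.0), fitted_window=(0.0, 200.0)
        )
        t = np.linspace(0.0, 50.0, 11)
        prof = conc_profile(t, 5.0 * np.exp(-k * t))
        ext = extend_profile(prof, ref, n_points=2)
        assert len(ext) == 13
        assert np.allclose(
            ext.values[-2:], 5.0 * np.exp(-k * ext.times[-2:]), rtol=1e-6
        )

    def test_extension_slope_matches_reference_terminal_slope(
        self, full_buffered_dataset
    ):
        """A 43 min jejunum curve extended with the 215 min reference decays
        at the reference's terminal log-slope."""
        jej_full = full_buffered_dataset.compartments["jejunum"].dissolved_amount
        ref = fit_triexponential(
            jej_full, DEPSConfig(population_size=30, max_generations=400, seed=5)
        )
        short = ivivc.simulate_transit(
            ivivc.truncated_method(), ivivc.buffered_crystal()
        ).compartments["jejunum"].dissolved_amount
        ext = extend_profile(short, ref, n_points=2)
        seg = np.diff(np.log(ext.values[-3:])) / np.diff(ext.times[-3:])
        ref_slope = ref.log_slope(ref.fitted_window[1])
        assert seg == pytest.approx(ref_slope, rel=0.01)


class TestTimeScaling:
    def test_anchor_pair_solved_to_tolerance(self):
        sc = fit_time_scaling(13.0, 0.75, 43.0, 12.0)
        assert sc.map(0.75) == pytest.approx(13.0, abs=1e-8)
        assert sc.map(12.0) == pytest.approx(43.0, abs=1e-8)

    def test_map_inverse_identity(self):
        sc = fit_time_scaling(13.0, 0.75, 43.0, 12.0)
        rng = np.random.default_rng(7)
        t = rng.uniform(0.0, 12.0, 100)
        assert np.abs(sc.inverse(sc.map(t)) - t).max() < 1e-9

    def test_linear_compatible_anchors_reduce_to_linear_map(self):
        # peak/end ratios equal on both axes: the map is a pure stretch
        sc = fit_time_scaling(10.0, 1.0, 120.0, 12.0)
        t = np.linspace(0.0, 12.0, 50)
        assert np.allclose(sc.map(t), 10.0 * t, rtol=1e-6)

    def test_unsolvable_anchors_rejected(self):
        with pytest.raises(ValueError, match="anchors"):
            fit_time_scaling(13.0, 2.0, 43.0, 1.0)  # in vivo end before peak

    def test_strictly_increasing(self):
        sc = fit_time_scaling(13.0, 0.75, 43.0, 12.0)
        t = np.linspace(0.0, 12.0, 200)
        assert np.all(np.diff(sc.map(t)) > 0)


def triexp_family():
    out = {}
    for fid, amp, kmul in (
        ("slow", 0.8, 0.85), ("medium", 1.0, 1.0), ("fast", 1.25, 1.2)
    ):
        out[fid] = TriexpModel(
            (-30.0 * amp, 18.0 * amp, 12.0 * amp),
            (0.30 * kmul, 0.030 * kmul, 0.012 * kmul),
            fitted_window=(0.0, 215.0),
        )
    return out


class TestScalingConstants:
    def setup_method(self):
        self.scaling = fit_time_scaling(13.0, 0.75, 43.0, 12.0)
        self.t_vivo = np.arange(0.0, 12.0 + 1e-9, 0.25)
        self.family = triexp_family()

    def synth_plasma(self, model, c1=50.0, c2=0.0):
        vals = c1 * model.evaluate(self.scaling.map(self.t_vivo)) + c2
        return TimeSeriesProfile(
            self.t_vivo, np.maximum(vals, 0.0), "ng/mL", "concentration", "h"
        )

    def test_self_consistent_recovery(self):
        """Plasma synthesized exactly as const1*f(scaled t) with const1=50,
        const2=0 is recovered to 1e-6."""
        models = {k: self.family[k] for k in ("slow", "fast")}
        plasma = {k: self.synth_plasma(m) for k, m in models.items()}
        res = fit_scaling_constants(models, plasma, self.scaling)
        assert res.const1 == pytest.approx(50.0, abs=1e-6)
        assert res.const2 == pytest.approx(0.0, abs=1e-6)

    def test_fixing_const2_never_improves_fit(self):
        models = {k: self.family[k] for k in ("slow", "fast")}
        plasma = {k: self.synth_plasma(m, c1=45.0, c2=3.0) for k, m in models.items()}
        free = fit_scaling_constants(models, plasma, self.scaling)
        fixed = fit_scaling_constants(
            models, plasma, self.scaling, fix_const2=True
        )
        assert fixed.const2 == 0.0
        assert fixed.pooled_rmse >= free.pooled_rmse - 1e-12

    def test_requires_exactly_two_formulations(self):
        models = self.family
        plasma = {k: self.synth_plasma(m) for k, m in models.items()}
        with pytest.raises(ValueError, match="two formulations"):
            fit_scaling_constants(models, plasma, self.scaling)


class TestPredict:
    def setup_method(self):
        self.scaling = fit_time_scaling(13.0, 0.75, 43.0, 12.0)
        self.family = triexp_family()

    def test_const1_zero_is_invalid(self):
        with pytest.raises(ValueError, match="const1"):
            CompartmentalIVIVRModel(self.scaling, 0.0, 1.0)

    def test_near_linear_scaling_retimes_the_in_vitro_curve(self):
        sc = fit_time_scaling(10.0, 1.0, 120.0, 12.0)  # pure stretch x10
        model = CompartmentalIVIVRModel(sc, 1.0, 0.0)
        tri = self.family["medium"]
        t_h = np.linspace(0.0, 12.0, 40)
        pred = predict_plasma_compartmental(model, tri, t_h)
        assert np.allclose(
            pred.values, np.maximum(tri.evaluate(10.0 * t_h), 0), rtol=1e-5,
            atol=1e-8,
        )

    def test_prediction_peak_at_inverse_of_in_vitro_peak(self):
        """Order preservation: the predicted Tmax is the inverse image of
        the in vitro peak time."""
        tri = self.family["medium"]
        t_grid = np.linspace(0.0, 215.0, 20000)
        t_peak_vitro = t_grid[np.argmax(tri.evaluate(t_grid))]
        model = CompartmentalIVIVRModel(self.scaling, 50.0, 0.0)
        t_h = np.linspace(0.0, 12.0, 4000)
        pred = predict_plasma_compartmental(model, tri, t_h)
        _, tmax = ivivc.cmax_tmax(pred)
        assert tmax == pytest.approx(
            self.scaling.inverse(t_peak_vitro), abs=0.01
        )

    def test_outside_calibrated_window_rejected(self):
        model = CompartmentalIVIVRModel(self.scaling, 50.0, 0.0)
        with pytest.raises(ivivc.ProfileRangeError, match="window"):
            predict_plasma_compartmental(
                model, self.family["medium"], np.linspace(0.0, 24.0, 10)
            )

    def test_json_roundtrip(self):
        model = CompartmentalIVIVRModel(
            self.scaling, 48.5, 1.25, self.family, ("slow", "fast")
        )
        back = CompartmentalIVIVRModel.from_json(model.to_json())
        assert back.const1 == model.const1
        assert back.const2 == model.const2
        assert back.scaling.alpha == pytest.approx(model.scaling.alpha)
        t_h = np.linspace(0.0, 12.0, 10)
        a = predict_plasma_compartmental(model, self.family["medium"], t_h)
        b = predict_plasma_compartmental(back, self.family["medium"], t_h)
        assert np.allclose(a.values, b.values)
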