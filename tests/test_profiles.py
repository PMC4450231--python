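"""Profile containers, arithmetic, cumulative curves, and CSV round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ivivc
from ivivc import (
    CompartmentalDissolutionDataset,
    CompartmentRecord,
    ProfileParseError,
    ProfileRangeError,
    SamplingEvent,
    TimeSeriesProfile,
    auc_trapezoid,
    cmax_tmax,
    cumulative_fraction,
    resample_linear,
)


def profile(points, **kw):
    t, v = zip(*points)
    return TimeSeriesProfile(np.array(t, float), np.array(v, float), **kw)


class TestTimeSeriesProfile:
    @pytest.mark.parametrize(
        "times,values,msg",
        [
            ([0, 1], [1], "length"),
            ([0], [1], "two samples"),
            ([1, 0], [0, 0], "increasing"),
            ([-1, 0], [0, 0], "nonnegative"),
            ([0, 1], [0, np.nan], "finite"),
        ],
    )
    def test_invariants_rejected(self, times, values, msg):
        with pytest.raises(ValueError, match=msg):
            TimeSeriesProfile(np.array(times, float), np.array(values, float))

    def test_fraction_bounds(self):
        with pytest.raises(ValueError, match="fraction"):
            profile([(0, 0.0), (1, 1.2)], kind="fraction")
        with pytest.warns(UserWarning, match="exceeds 1"):
            profile([(0, 0.0), (1, 1.02)], kind="fraction")

    def test_time_unit_conversion_roundtrip(self):
        p = profile([(0, 1), (30, 2), (90, 3)], time_unit="min")
        q = p.in_time_unit("h")
        assert np.allclose(q.times, [0, 0.5, 1.5])
        assert np.allclose(q.in_time_unit("min").times, p.times)


class TestResample:
    @pytest.mark.parametrize(
        "points,at,expected",
        [
            ([(0, 0), (10, 10)], 5.0, 5.0),  # linear midpoint
            ([(0, 0), (10, 10)], 0.0, 0.0),  # identity at knot
            ([(0, 0), (4, 8), (10, 8)], 7.0, 8.0),  # flat segment
        ],
    )
    def test_values(self, points, at, expected):
        out = resample_linear(profile(points), [at, points[-1][0]])
        assert out.values[0] == pytest.approx(expected)

    def test_extrapolation_forbidden(self):
        with pytest.raises(ProfileRangeError, match="12"):
            resample_linear(profile([(0, 0), (10, 10)]), [0, 12])

    @given(
        st.lists(
            st.floats(min_value=-50, max_value=50),
            min_size=3,
            max_size=8,
        )
    )
    def test_resample_at_knots_is_identity(self, values):
        t = np.arange(len(values), dtype=float)
        p = TimeSeriesProfile(t, np.array(values))
        out = resample_linear(p, t)
        assert np.allclose(out.values, p.values)


class TestAuc:
    @pytest.mark.parametrize(
        "points,window,expected",
        [
            ([(0, 2), (10, 2)], (0, 10), 20.0),  # rectangle
            ([(0, 0), (1, 1), (2, 0)], (0, 2), 1.0),  # triangle
            # hand trapezoid: 0.5*(1.5+3)/2 + 2*3 + 1*(3+2)/2 = 9.625
            ([(0, 0), (1, 3), (3, 3), (5, 1)], (0.5, 4), 9.625),
        ],
    )
    def test_values(self, points, window, expected):
        assert auc_trapezoid(profile(points), *window) == pytest.approx(expected)

    def test_refined_grid_oracle(self):
        # brute-force trapezoid on a dense resampled grid must agree
        p = profile([(0, 0), (1, 3), (3, 3), (5, 1)])
        dense = resample_linear(p, np.linspace(0.5, 4.0, 20001))
        brute = np.trapezoid(dense.values, dense.times)
        assert auc_trapezoid(p, 0.5, 4.0) == pytest.approx(brute, abs=1e-6)

    def test_window_outside_range(self):
        with pytest.raises(ProfileRangeError):
            auc_trapezoid(profile([(0, 1), (5, 1)]), 0, 6)

    @given(
        st.lists(st.floats(min_value=0, max_value=10), min_size=4, max_size=9),
        st.floats(min_value=0.05, max_value=0.95),
    )
    def test_additivity(self, values, split):
        t = np.arange(len(values), dtype=float)
        p = TimeSeriesProfile(t, np.array(values))
        a, c = float(t[0]), float(t[-1])
        b = a + split * (c - a)
        whole = auc_trapezoid(p, a, c)
        parts = auc_trapezoid(p, a, b) + auc_trapezoid(p, b, c)
        assert whole == pytest.approx(parts, abs=1e-9)


class TestCmaxTmax:
    def test_basic(self):
        assert cmax_tmax(profile([(0, 0), (1, 5), (2, 3)])) == (5.0, 1.0)

    def test_all_zero_tie_to_earliest(self):
        assert cmax_tmax(profile([(0, 0), (1, 0), (2, 0)])) == (0.0, 0.0)

    def test_analytic_tmax_of_oral_curve(self):
        # one-compartment oral curve: Tmax = ln(ka/k10)/(ka - k10)
        ka, k10 = 3.0, 0.4
        t = np.arange(0.0, 12.0 + 1e-9, 0.01)
        p = ivivc.generate_synthetic_pk(
            ivivc.OralPKParams(ka_per_h=ka, k10_per_h=k10,
                               k12_per_h=0.0, k21_per_h=0.0),
            t,
        )
        _, tmax = cmax_tmax(p)
        assert tmax == pytest.approx(np.log(ka / k10) / (ka - k10), abs=0.011)


def tiny_dataset(dose=80.0):
    """Hand-built two-compartment dataset: terminal dissolved 32 + 8 mg."""
    t = np.array([0.0, 10.0, 20.0])

    def rec(diss, vol=50.0):
        return CompartmentRecord(
            dissolved_amount=TimeSeriesProfile(t, np.array(diss), "mg", "amount"),
            volume=TimeSeriesProfile(t, np.full(3, vol), "mL", "amount"),
            ph=TimeSeriesProfile(t, np.full(3, 6.5), "pH", "concentration"),
        )

    return CompartmentalDissolutionDataset(
        formulation_id="tiny",
        dose_mg=dose,
        compartments={"a": rec([0, 16, 32.0]), "b": rec([0, 4, 8.0])},
    )


class TestCumulativeFraction:
    def test_terminal_fraction_is_dissolved_over_dose(self):
        cum = cumulative_fraction(tiny_dataset())
        assert cum.values[-1] == pytest.approx(0.5)

    def test_excluding_a_compartment_subtracts_its_share(self):
        cum = cumulative_fraction(tiny_dataset(), include_compartments=["a"])
        assert cum.values[-1] == pytest.approx(0.4)

    def test_unknown_compartment_rejected(self):
        with pytest.raises(ivivc.ConfigurationError, match="stomach"):
            cumulative_fraction(
                tiny_dataset(), include_compartments=["stomach"]
            )

    def test_withdrawal_bookkeeping_oracle(self, full_buffered_dataset):
        """Corrected curve equals uncorrected plus a replay of the ledger."""
        ds = full_buffered_dataset
        corrected = cumulative_fraction(ds, apply_withdrawal_correction=True)
        plain = cumulative_fraction(ds, apply_withdrawal_correction=False)
        replay = np.zeros_like(corrected.values)
        for ev in ds.sampling_events:
            conc = ds.compartments[ev.compartment].dissolved_amount.value_at(
                ev.time_min
            ) / ds.compartments[ev.compartment].volume.value_at(ev.time_min)
            replay[corrected.times > ev.time_min] += (
                conc * ev.withdrawn_mL / ds.dose_mg
            )
        assert np.allclose(corrected.values, plain.values + replay, atol=1e-9)

    def test_nondecreasing_and_bounded_on_simulator_data(
        self, full_buffered_dataset
    ):
        cum = cumulative_fraction(full_buffered_dataset)
        assert np.all(np.diff(cum.values) >= -1e-12)
        assert cum.values.max() <= 1 + 1e-6


class TestCsvRoundTrip:
    def test_dataset_roundtrip(self, tmp_path, full_buffered_dataset):
        path = tmp_path / "run.csv"
        ivivc.write_profiles_csv(full_buffered_dataset, path)
        back = ivivc.read_profiles_csv(path)
        assert back.formulation_id == full_buffered_dataset.formulation_id
        assert back.dose_mg == full_buffered_dataset.dose_mg
        for name, rec in full_buffered_dataset.compartments.items():
            assert np.allclose(
                back.compartments[name].dissolved_amount.values,
                rec.dissolved_amount.values,
            )
            assert np.allclose(
                back.compartments[name].volume.values, rec.volume.values
            )
        assert len(back.sampling_events) == len(
            full_buffered_dataset.sampling_events
        )

    def test_plasma_roundtrip(self, tmp_path, synthetic_pk_profile):
        path = tmp_path / "pk.csv"
        ivivc.write_profiles_csv(synthetic_pk_profile, path)
        back = ivivc.read_profiles_csv(path)
        assert np.allclose(back.times, synthetic_pk_profile.times)
        assert np.allclose(back.values, synthetic_pk_profile.values)

    def test_shuffled_rows_sorted_canonically(self, tmp_path):
        path = tmp_path / "d.csv"
        path.write_text(
            "time_min,compartment,dissolved_mg,volume_mL,pH\n"
            "20,a,4,50,6.5\n0,a,0,50,6.5\n10,a,2,50,6.5\n"
        )
        ds = ivivc.read_profiles_csv(path, dose_mg=80.0)
        assert np.allclose(
            ds.compartments["a"].dissolved_amount.values, [0, 2, 4]
        )

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compartment,dissolved_mg,volume_mL,pH\na,0,50,6.5\n")
        with pytest.raises(ProfileParseError, match="time_min"):
            ivivc.read_profiles_csv(path, dose_mg=80.0)

    def test_negative_volume_names_row(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(
            "time_min,compartment,dissolved_mg,volume_mL,pH\n"
            "0,a,0,50,6.5\n10,a,1,-2,6.5\n"
        )
        with pytest.raises(ProfileParseError, match="row 3"):
            ivivc.read_profiles_csv(path, dose_mg=80.0)

    def test_duplicate_time_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "time_min,compartment,dissolved_mg,volume_mL,pH\n"
            "0,a,0,50,6.5\n0,a,1,50,6.5\n"
        )
        with pytest.raises(ProfileParseError, match="non-monotone"):
            ivivc.read_profiles_csv(path, dose_mg=80.0)
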