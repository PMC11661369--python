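import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phantomforge.errors import (
    DomainError,
    InsufficientDataError,
    RankDeficiencyError,
)
from phantomforge.mixing import (
    LinearMixingModel,
    MixingRatio,
    OpticalProperties,
    PropertyFit,
    TitrationRecord,
    feasible_range,
    fit_linear_mixing,
    fit_mixing_model,
    invert,
    predict,
    read_titration_csv,
    relative_error,
    summarize_roi,
    write_titration_csv,
)
from phantomforge.synth import (
    SynthConfig,
    default_titration_ratios,
    published_model,
    synth_titration,
)


def make_records(coeffs_mua, coeffs_musp, ratios):
    model = LinearMixingModel.from_coefficients(coeffs_mua, coeffs_musp)
    return [
        TitrationRecord(ratio=r, measured=predict(model, r), label=str(i))
        for i, r in enumerate(ratios)
    ]


class TestMixingRatio:
    def test_valid(self):
        r = MixingRatio(26, 40, 34)
        assert r.as_tuple() == (26, 40, 34)
        assert r.channel_weights() == (0.26, 0.40, 0.34)

    def test_sum_enforced(self):
        with pytest.raises(ValueError, match="sum to 100"):
            MixingRatio(4, 11, 49)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            MixingRatio(-5, 55, 50)

    def test_from_gray_white(self):
        assert MixingRatio.from_gray_white(30, 20).rt == 50

    def test_rounded_sums_to_100(self):
        r = MixingRatio.from_gray_white(26.4, 40.3).rounded()
        assert r.rg + r.rw + r.rt == 100
        assert float(r.rg).is_integer()


class TestOpticalProperties:
    def test_positive_required(self):
        with pytest.raises(ValueError):
            OpticalProperties(0.0, 1.0)
        with pytest.raises(ValueError):
            OpticalProperties(0.01, -1.0)


class TestFit:
    def test_noiseless_exact(self):
        ratios = [
            MixingRatio.from_gray_white(rg, rw)
            for rg, rw in [(0, 0), (100, 0), (0, 100), (50, 50)]
        ]
        records = make_records((0.0078, 0.00095, 0.0056), (0.036, 0.034, 0.35), ratios)
        fit = fit_linear_mixing(records, "mua")
        assert fit.A == pytest.approx(0.0078, rel=1e-12)
        assert fit.B == pytest.approx(0.00095, rel=1e-12)
        assert fit.C == pytest.approx(0.0056, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_sixteen_point_design_recovers_reported_mua_coefficients(self):
        records = make_records(
            (0.0078, 0.00095, 0.0056), (0.036, 0.034, 0.35), default_titration_ratios()
        )
        assert len(records) == 16
        fit = fit_linear_mixing(records, "mua")
        assert (fit.A, fit.B, fit.C) == pytest.approx(
            (0.0078, 0.00095, 0.0056), rel=1e-9
        )

    def test_insufficient_records(self):
        records = make_records(
            (0.01, 0.001, 0.005),
            (0.03, 0.03, 0.3),
            [MixingRatio.from_gray_white(0, 0), MixingRatio.from_gray_white(10, 0)],
        )
        with pytest.raises(InsufficientDataError):
            fit_linear_mixing(records, "mua")

    def test_collinear_design_names_direction(self):
        ratios = [MixingRatio.from_gray_white(rg, rg) for rg in (0, 10, 20, 30)]
        records = make_records((0.01, 0.001, 0.005), (0.03, 0.03, 0.3), ratios)
        with pytest.raises(RankDeficiencyError, match="collinear"):
            fit_linear_mixing(records, "mua")

    def test_noisy_recovery_mean_within_5pct(self):
        # simulation oracle: 100 seeded replicates at 5% multiplicative noise
        true = published_model()
        estimates = []
        for seed in range(100):
            config = SynthConfig(seed=seed, noise_model="multiplicative", noise_sigma=0.05)
            records = synth_titration(true, config=config)
            fit = fit_linear_mixing(records, "mua")
            estimates.append(fit.A)
        assert abs(np.mean(estimates) - true.mua.A) / true.mua.A < 0.05

    def test_negative_intercept_warns_not_fails(self):
        ratios = [
            MixingRatio.from_gray_white(rg, rw)
            for rg, rw in [(10, 0), (20, 10), (30, 0), (40, 20)]
        ]
        model = LinearMixingModel.from_coefficients((0.01, 0.001, 0.05), (0.03, 0.03, 0.3))
        records = []
        for r in ratios:
            p = predict(model, r)
            # shift values down so the extrapolated intercept goes negative
            records.append(
                TitrationRecord(
                    ratio=r,
                    measured=OpticalProperties(max(p.mua - 0.15, 1e-4), p.musp),
                )
            )
        with pytest.warns(UserWarning, match="intercept"):
            fit_linear_mixing(records, "mua")

    def test_weighted_fit_runs(self):
        records = [
            TitrationRecord(
                ratio=r,
                measured=predict(published_model(), r),
                mua_sd=0.001,
                musp_sd=0.01,
            )
            for r in default_titration_ratios()
        ]
        fit = fit_linear_mixing(records, "mua", weighted=True)
        assert fit.A == pytest.approx(0.0078, rel=1e-9)


class TestPredict:
    def test_pure_gray(self, model):
        props = predict(model, MixingRatio(100, 0, 0))
        assert props.mua == pytest.approx(0.7856, rel=1e-12)
        assert props.musp == pytest.approx(3.95, rel=1e-12)

    def test_pure_translucent(self, model):
        props = predict(model, MixingRatio(0, 0, 100))
        assert props.mua == pytest.approx(0.0056, rel=1e-12)
        assert props.musp == pytest.approx(0.35, rel=1e-12)

    def test_half_half(self, model):
        # hand evaluation: 0.0078*50 + 0.00095*50 + 0.0056 = 0.4431
        #                  0.036*50 + 0.034*50 + 0.35 = 3.85
        props = predict(model, MixingRatio(50, 50, 0))
        assert props.mua == pytest.approx(0.4431, rel=1e-12)
        assert props.musp == pytest.approx(3.85, rel=1e-12)


class TestInvert:
    def test_round_trip_exact(self, model):
        target = predict(model, MixingRatio(26, 40, 34))
        result = invert(model, target, rounding="none")
        assert result.continuous_ratio.rg == pytest.approx(26, abs=1e-6)
        assert result.continuous_ratio.rw == pytest.approx(40, abs=1e-6)
        assert result.objective == pytest.approx(0.0, abs=1e-12)

    def test_unreachable_target_flagged(self, model):
        result = invert(model, OpticalProperties(2.0, 3.0))
        assert not result.feasible

    def test_low_absorption_target(self, model):
        # published usage: (mua 0.01, musp 0.5) printed as (0/G, 5/W, 95/T)
        result = invert(model, OpticalProperties(0.01, 0.5), rounding="integer")
        assert result.ratio.rg == 0
        assert abs(result.ratio.rw - 5) <= 1

    def test_achieved_equals_forward_prediction(self, model):
        result = invert(model, OpticalProperties(0.1, 1.5), rounding="integer")
        again = predict(model, result.ratio)
        assert result.achieved.mua == again.mua
        assert result.achieved.musp == again.musp

    def test_nonpositive_target_rejected(self, model):
        class _Broken:
            mua = -0.1
            musp = 1.0

        with pytest.raises(DomainError):
            invert(model, _Broken())  # type: ignore[arg-type]

    def test_integer_result_sums_to_100(self, model):
        result = invert(model, OpticalProperties(0.21, 2.0), rounding="integer")
        r = result.ratio
        assert r.rg + r.rw + r.rt == pytest.approx(100)
        assert float(r.rg).is_integer() and float(r.rw).is_integer()


class TestRelativeError:
    def test_identity(self):
        assert relative_error(0.1, 0.1) == 0

    def test_above(self):
        assert relative_error(0.115, 0.1) == pytest.approx(0.15)

    def test_below_symmetric(self):
        assert relative_error(0.085, 0.1) == pytest.approx(0.15)

    def test_zero_predicted(self):
        with pytest.raises(DomainError):
            relative_error(0.1, 0.0)


class TestFeasibleRange:
    def test_published_ranges(self, model):
        ranges = feasible_range(model)
        assert ranges["mua"] == pytest.approx((0.0056, 0.7856), rel=1e-12)
        assert ranges["musp"] == pytest.approx((0.35, 3.95), rel=1e-12)

    def test_degenerate_constant_model(self):
        m = LinearMixingModel.from_coefficients((0, 0, 0.01), (0, 0, 0.5))
        ranges = feasible_range(m)
        assert ranges["mua"] == (0.01, 0.01)
        assert ranges["musp"] == (0.5, 0.5)


class TestSummarizeRoi:
    def test_published_roi_area(self):
        arr = np.ones((100, 100))
        summary = summarize_roi(arr, (10, 10, 45, 45), pixel_area_mm2=0.035)
        assert summary.pixel_count == 2025
        assert summary.area_mm2 == pytest.approx(70.875)
        assert round(summary.area_mm2 / 100.0, 1) == 0.7  # cm^2

    def test_constant_map(self):
        arr = np.full((20, 20), 3.3)
        s = summarize_roi(arr, (0, 0, 20, 20), 1.0)
        assert s.median == 3.3
        assert s.std == pytest.approx(0.0, abs=1e-12)

    def test_median_of_small_map(self):
        arr = np.arange(1, 10).reshape(3, 3)
        assert summarize_roi(arr, (0, 0, 3, 3), 1.0).median == 5

    def test_roi_out_of_bounds(self):
        with pytest.raises(ValueError):
            summarize_roi(np.ones((10, 10)), (5, 5, 10, 10), 1.0)

    def test_empty_roi(self):
        with pytest.raises(ValueError):
            summarize_roi(np.ones((10, 10)), (0, 0, 0, 5), 1.0)


class TestSerialization:
    def test_model_json_round_trip(self, model):
        text = model.to_json()
        back = LinearMixingModel.from_json(text)
        assert back.mua.A == model.mua.A
        assert back.musp.C == model.musp.C
        assert json.loads(text)["units"] == "mm^-1"

    def test_titration_csv_round_trip(self, tmp_path, model):
        records = [
            TitrationRecord(
                ratio=r, measured=predict(model, r), mua_sd=0.01, musp_sd=0.02,
                label=f"s{i}",
            )
            for i, r in enumerate(default_titration_ratios())
        ]
        path = tmp_path / "titration.csv"
        write_titration_csv(records, path)
        assert path.read_text().startswith("#")
        back = read_titration_csv(path)
        assert len(back) == len(records)
        assert back[3].ratio.as_tuple() == records[3].ratio.as_tuple()
        assert back[3].measured.mua == pytest.approx(records[3].measured.mua)

    def test_csv_missing_columns(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("label,Rg\nfoo,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_titration_csv(p)


# ---------------------------------------------------------------------------
# property-based invariants

ratio_strategy = st.tuples(
    st.floats(0, 100), st.floats(0, 100)
).filter(lambda t: t[0] + t[1] <= 100)


@settings(max_examples=50, deadline=None)
@given(ratio_strategy)
def test_round_trip_property(rgrw):
    model = published_model()
    ratio = MixingRatio.from_gray_white(*rgrw)
    target = predict(model, ratio)
    result = invert(model, target, rounding="none")
    assert result.continuous_ratio.rg == pytest.approx(ratio.rg, abs=1e-6)
    assert result.continuous_ratio.rw == pytest.approx(ratio.rw, abs=1e-6)


@settings(max_examples=25, deadline=None)
@given(
    st.floats(1e-4, 0.02),
    st.floats(1e-5, 0.002),
    st.floats(1e-4, 0.02),
    st.floats(0.005, 0.05),
    st.floats(0.005, 0.05),
    st.floats(0.05, 0.5),
)
def test_fit_exactness_property(a1, b1, c1, a2, b2, c2):
    records = make_records((a1, b1, c1), (a2, b2, c2), default_titration_ratios())
    fitted = fit_mixing_model(records)
    for got, want in [
        (fitted.mua, (a1, b1, c1)),
        (fitted.musp, (a2, b2, c2)),
    ]:
        assert got.A == pytest.approx(want[0], rel=1e-9, abs=1e-12)
        assert got.B == pytest.approx(want[1], rel=1e-9, abs=1e-12)
        assert got.C == pytest.approx(want[2], rel=1e-9, abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(st.floats(0, 99), st.floats(0.01, 1.0))
def test_monotone_in_gray_property(rg, step):
    model = published_model()
    step = min(step, 100 - rg)
    lo = predict(model, MixingRatio.from_gray_white(rg, 0))
    hi = predict(model, MixingRatio.from_gray_white(rg + step, 0))
    if step > 0:
        assert hi.mua > lo.mua


@settings(max_examples=50, deadline=None)
@given(st.floats(0.01, 10), st.floats(0.0001, 1.0))
def test_relative_error_symmetry_property(p, frac):
    d = frac * p * 0.99
    assert relative_error(p + d, p) == pytest.approx(relative_error(p - d, p))
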