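"""Temperature and moisture response factors and their fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soildeg import (
    ExpRateLaw,
    IllPosedFitError,
    InvalidInputError,
    MoistureResponse,
    RangeError,
    TemperatureResponse,
    combined_rate,
    fit_moisture_response,
    fit_rate_temperature,
    fit_response_surface,
    moisture_factor,
    temperature_factor,
)


class TestTemperatureFactor:
    def test_unity_at_optimum(self):
        resp = TemperatureResponse(q10=2.0, t_opt=30.0)
        assert temperature_factor(30.0, resp) == pytest.approx(1.0)

    def test_one_decade_halves(self):
        resp = TemperatureResponse(q10=2.0, t_opt=30.0)
        assert temperature_factor(20.0, resp) == pytest.approx(0.5)

    def test_half_decade(self):
        resp = TemperatureResponse(q10=2.0, t_opt=30.0)
        assert temperature_factor(25.0, resp) == pytest.approx(2 ** -0.5, rel=1e-12)

    def test_above_optimum_needs_flag(self):
        resp = TemperatureResponse()
        with pytest.raises(RangeError):
            temperature_factor(35.0, resp)
        assert temperature_factor(35.0, resp, extrapolate=True) > 1.0

    def test_below_zero_rejected(self):
        with pytest.raises(RangeError):
            temperature_factor(-5.0, TemperatureResponse())

    @given(st.floats(min_value=0.0, max_value=20.0))
    @settings(max_examples=50, derandomize=True)
    def test_q10_ratio_exact(self, t):
        resp = TemperatureResponse(q10=2.3, t_opt=30.0)
        assert temperature_factor(t + 10, resp) / temperature_factor(t, resp) == (
            pytest.approx(2.3, rel=1e-12)
        )


class TestMoistureFactor:
    def test_unity_at_extremum(self):
        resp = MoistureResponse(a=4.84, b=2.35)
        assert moisture_factor(resp.w_opt, resp) == pytest.approx(1.0, rel=1e-12)

    def test_hand_value_at_half_saturation(self):
        resp = MoistureResponse(a=4.84, b=2.35)
        assert moisture_factor(0.5, resp) == pytest.approx(0.64, abs=5e-3)

    def test_vanishes_at_endpoints(self):
        resp = MoistureResponse(a=2.0, b=1.0)
        assert moisture_factor(0.0, resp) == 0.0
        assert moisture_factor(1.0, resp) == 0.0

    def test_out_of_domain_rejected(self):
        with pytest.raises(InvalidInputError):
            moisture_factor(1.2, MoistureResponse(a=2, b=1))

    @pytest.mark.parametrize(
        "a, b, w_opt",
        [(4.84, 2.35, 0.67), (4.27, 1.53, 0.74), (2.54, 1.09, 0.70)],
    )
    def test_extremum_identity_for_reported_fits(self, a, b, w_opt):
        resp = MoistureResponse(a=a, b=b)
        assert round(resp.w_opt, 2) == w_opt

    def test_inconsistent_w_opt_rejected(self):
        with pytest.raises(InvalidInputError):
            MoistureResponse(a=4.0, b=2.0, w_opt=0.5)

    def test_unimodal_on_dense_grid(self):
        resp = MoistureResponse(a=3.1, b=1.7)
        w = np.linspace(1e-4, 1 - 1e-4, 2000)
        f = moisture_factor(w, resp)
        i_opt = int(np.argmax(f))
        assert np.all(np.diff(f[: i_opt + 1]) > 0)
        assert np.all(np.diff(f[i_opt:]) < 0)


class TestCombinedRate:
    def test_maximum_at_joint_optimum(self):
        tr = TemperatureResponse(q10=2.0, t_opt=30.0, u_max=30.0)
        mr = MoistureResponse(a=4.84, b=2.35)
        assert combined_rate(30.0, mr.w_opt, tr, mr) == pytest.approx(30.0)

    def test_product_one_decade(self):
        tr = TemperatureResponse(q10=2.0, t_opt=30.0, u_max=30.0)
        mr = MoistureResponse(a=4.84, b=2.35)
        assert combined_rate(20.0, mr.w_opt, tr, mr) == pytest.approx(15.0)

    def test_grid_argmax_is_joint_optimum(self):
        """Brute-force search over the domain must land at (t_opt, w_opt)."""
        tr = TemperatureResponse(q10=2.0, t_opt=30.0, u_max=10.0)
        mr = MoistureResponse(a=4.0, b=2.0)
        t = np.linspace(0, 30, 61)
        w = np.linspace(0.01, 0.99, 99)
        tt, ww = np.meshgrid(t, w, indexing="ij")
        u = combined_rate(tt.ravel(), ww.ravel(), tr, mr)
        i = int(np.argmax(u))
        assert tt.ravel()[i] == pytest.approx(30.0)
        assert ww.ravel()[i] == pytest.approx(mr.w_opt, abs=0.01)


class TestFitMoistureResponse:
    def test_noise_free_recovery(self):
        truth = MoistureResponse(a=4.84, b=2.35, u_max=25.0)
        w = np.linspace(0.05, 0.95, 19)
        u = truth.u_max * moisture_factor(w, truth)
        fit = fit_moisture_response(w, u, u_max_mode="fit")
        assert fit.response.a == pytest.approx(truth.a, rel=1e-4)
        assert fit.response.b == pytest.approx(truth.b, rel=1e-4)
        assert fit.response.u_max == pytest.approx(truth.u_max, rel=1e-4)
        assert fit.r_squared > 1 - 1e-8

    def test_reported_fit_extremum(self):
        resp = MoistureResponse(a=4.27, b=1.53)
        assert resp.w_opt == pytest.approx(4.27 / 5.80, rel=1e-12)
        assert round(resp.w_opt, 2) == 0.74

    def test_one_sided_data_ill_posed(self):
        truth = MoistureResponse(a=4.0, b=2.0, u_max=10.0)
        w = np.linspace(0.05, 0.5, 8)  # rising limb only
        u = truth.u_max * moisture_factor(w, truth)
        with pytest.raises(IllPosedFitError):
            fit_moisture_response(w, u)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_moisture_response([0.2, 0.5, 0.8], [1.0, 2.0, 1.0])

    def test_noisy_r2_band_monte_carlo(self):
        """5% noise, 30 points: R2 should populate the 0.96-0.99 band."""
        from soildeg import gen_response_grid

        truth_m = MoistureResponse(a=4.84, b=2.35, u_max=30.0)
        truth_t = TemperatureResponse(q10=2.0, t_opt=30.0, u_max=30.0)
        r2s = []
        for seed in range(200):
            df, _ = gen_response_grid(
                seed, moisture=truth_m, temperature=truth_t,
                w_grid=np.linspace(0.08, 0.95, 30), t_grid=[30.0], noise_sd=0.05,
            )
            fit = fit_moisture_response(df["w_rel"].to_numpy(), df["u_m"].to_numpy(),
                                        u_max_mode="fit")
            r2s.append(fit.r_squared)
        r2s = np.asarray(r2s)
        assert np.median(r2s) > 0.95
        assert ((r2s >= 0.96) & (r2s <= 0.995)).mean() > 0.5

    def test_normalized_default_mode_pins_umax(self):
        truth = MoistureResponse(a=3.0, b=1.5, u_max=20.0)
        w = np.linspace(0.05, 0.95, 15)
        w = np.sort(np.append(w, truth.w_opt))  # include the optimum point
        u = truth.u_max * moisture_factor(w, truth)
        fit = fit_moisture_response(w, u)
        assert fit.response.u_max == pytest.approx(truth.u_max)
        assert fit.response.a == pytest.approx(truth.a, rel=1e-4)

    def test_parameter_coverage_monte_carlo(self):
        """~95% of fits put truth inside +/-2 s.e. intervals for a and b."""
        rng_seeds = range(120)
        truth = MoistureResponse(a=4.84, b=2.35, u_max=30.0)
        w = np.linspace(0.08, 0.95, 30)
        covered_a = covered_b = total = 0
        for seed in rng_seeds:
            rng = np.random.default_rng(seed)
            u = truth.u_max * moisture_factor(w, truth) + rng.normal(0, 1.5, w.size)
            try:
                fit = fit_moisture_response(w, u, u_max_mode="fit")
            except Exception:
                continue
            total += 1
            if abs(fit.response.a - truth.a) <= 2 * fit.stderr["a"]:
                covered_a += 1
            if abs(fit.response.b - truth.b) <= 2 * fit.stderr["b"]:
                covered_b += 1
        assert total >= 110
        assert covered_a / total >= 0.85
        assert covered_b / total >= 0.85


class TestFitRateTemperature:
    def test_self_consistency_on_printed_law(self):
        law_true = ExpRateLaw(k0=0.2834, s=0.0435)
        t = np.array([20.0, 30.0, 37.0])
        law, r2 = fit_rate_temperature(t, law_true(t))
        assert law.k0 == pytest.approx(0.2834, rel=1e-6)
        assert law.s == pytest.approx(0.0435, rel=1e-6)
        assert r2 > 1 - 1e-10

    def test_law_evaluations_inside_experimental_bands(self):
        law = ExpRateLaw(k0=0.2834, s=0.0435)
        assert 0.7 <= law(37.0) <= 2.7          # hot-incubation band
        assert law(37.0) == pytest.approx(1.42, abs=0.01)
        assert 0.2 <= law(20.0) <= 1.5          # room-temperature band
        assert law(20.0) == pytest.approx(0.68, abs=0.01)

    def test_implied_q10(self):
        law = ExpRateLaw(k0=1.0, s=math.log(2) / 10)
        assert law.q10 == pytest.approx(2.0, rel=1e-12)

    def test_too_few_temperatures_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_rate_temperature([20.0, 20.0, 30.0], [0.5, 0.5, 1.0])


class TestSurfaceFit:
    def test_joint_noise_free_recovery_q10_fixed(self):
        tr = TemperatureResponse(q10=2.0, t_opt=30.0, u_max=30.0)
        mr = MoistureResponse(a=4.84, b=2.35, u_max=30.0)
        t = np.linspace(5, 30, 6)
        w = np.linspace(0.1, 0.95, 10)
        tt, ww = np.meshgrid(t, w, indexing="ij")
        u = combined_rate(tt.ravel(), ww.ravel(), tr, mr)
        fit = fit_response_surface(tt.ravel(), ww.ravel(), u, q10=2.0)
        assert fit.moisture.a == pytest.approx(4.84, rel=1e-4)
        assert fit.moisture.b == pytest.approx(2.35, rel=1e-4)
        assert fit.u_max == pytest.approx(30.0, rel=1e-4)

    def test_joint_recovery_q10_co_fitted(self):
        tr = TemperatureResponse(q10=2.4, t_opt=30.0, u_max=20.0)
        mr = MoistureResponse(a=3.0, b=1.5, u_max=20.0)
        t = np.linspace(5, 30, 6)
        w = np.linspace(0.1, 0.95, 10)
        tt, ww = np.meshgrid(t, w, indexing="ij")
        u = combined_rate(tt.ravel(), ww.ravel(), tr, mr)
        fit = fit_response_surface(tt.ravel(), ww.ravel(), u, q10=None)
        assert fit.temperature.q10 == pytest.approx(2.4, rel=1e-3)
        assert fit.moisture.a == pytest.approx(3.0, rel=1e-3)
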