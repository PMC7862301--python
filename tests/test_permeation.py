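"""Barrier permeation model: analytic limits, fitting, energy mapping."""

import numpy as np
import pytest

from gatekit import (
    PermeationParams,
    barrier_current,
    barrier_energies,
    curve_from_params,
    fit_iv,
    nernst_potential,
    predict_single_occupancy_iv,
)
from gatekit.constants import DEFAULT_CONSTANTS
from gatekit.datatypes import IVCurve, ValidationError

RT = DEFAULT_CONSTANTS.RT


def random_params(rng, **fixed):
    kwargs = dict(
        A=10.0 ** rng.uniform(-1, 1),
        sigma_h=10.0 ** rng.uniform(-2, 1),
        sigma_beta=10.0 ** rng.uniform(-2, 1),
        n=int(rng.integers(3, 6)),
    )
    kwargs.update(fixed)
    return PermeationParams(**kwargs)


class TestBarrierCurrent:
    def test_zero_current_at_zero_volts_symmetric(self):
        p = PermeationParams(1.0, 0.5, 0.05)
        assert barrier_current(0.0, p) == 0.0

    def test_zero_at_nernst_potential_random_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = random_params(
                rng,
                c_i=float(10.0 ** rng.uniform(1, 2.5)),
                c_o=float(10.0 ** rng.uniform(1, 2.5)),
            )
            v_rev = nernst_potential(p)
            scale = np.max(np.abs(barrier_current(np.array([-80.0, 80.0]), p)))
            assert abs(barrier_current(v_rev, p)) < 1e-10 * scale

    def test_v0_matches_analytic_limit(self):
        # at V = 0 the middle-barrier term tends to n − 2 and
        # I = zFA (c_i − c_o) / (1 + (n−2)/σ_h + 1/σ_β)
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = random_params(rng, c_i=150.0, c_o=15.0)
            c = p.constants
            expected = (
                c.z * c.F * p.A * (p.c_i - p.c_o)
                / (1.0 + (p.n - 2) / p.sigma_h + 1.0 / p.sigma_beta)
            )
            assert barrier_current(0.0, p) == pytest.approx(expected, rel=1e-12)

    def test_removable_singularity_is_continuous(self):
        p = PermeationParams(1.0, 0.5, 0.05, c_i=150.0, c_o=50.0)
        i0 = barrier_current(0.0, p)
        for eps in (1e-3, 1e-5, 1e-7):
            assert barrier_current(eps, p) == pytest.approx(i0, rel=1e-4, abs=1e-9)
            assert barrier_current(-eps, p) == pytest.approx(i0, rel=1e-4, abs=1e-9)

    def test_large_sigma_beta_deletes_its_term(self):
        base = PermeationParams(1.0, 0.5, 1e12)
        v = np.arange(-100.0, 101.0, 20.0)
        got = barrier_current(v, base)

        # same expression with the 1/sigma_beta term removed
        c = base.constants
        a = c.z * c.F * (v * 1e-3) / (base.n * c.R * c.T)
        middle = np.where(a == 0, base.n - 2.0,
                          -np.expm1(-(base.n - 2) * np.where(a == 0, 1, a))
                          / np.expm1(np.where(a == 0, 1, a)))
        denom = np.exp(-(base.n - 1) * a) + middle / base.sigma_h
        expected = c.z * c.F * base.A * np.exp(a / 2) * (
            base.c_i - base.c_o * np.exp(-base.n * a)
        ) / denom
        np.testing.assert_allclose(got, expected, rtol=1e-9)

    def test_strictly_increasing_in_voltage(self):
        rng = np.random.default_rng(2)
        v = np.linspace(-100, 100, 81)
        for _ in range(30):
            p = random_params(rng)
            assert np.all(np.diff(barrier_current(v, p)) > 0)

    def test_finite_up_to_200_mV(self):
        p = PermeationParams(1.0, 0.01, 0.01)
        assert np.all(np.isfinite(barrier_current(np.array([-200.0, 200.0]), p)))

    def test_small_inner_rate_gives_outward_rectification(self):
        p = PermeationParams(1.0, 1.0, 0.02)
        i = barrier_current(np.array([-80.0, 80.0]), p)
        assert abs(i[1]) / abs(i[0]) > 1.0


class TestHighPrecisionOracle:
    def test_agrees_with_sympy_to_ten_digits(self):
        sympy = pytest.importorskip("sympy")
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 100:
            p = random_params(rng, c_i=150.0, c_o=float(rng.uniform(15, 300)))
            v_mv = float(rng.uniform(-120, 120))
            if abs(v_mv) < 1e-3:
                continue
            got = barrier_current(v_mv, p)

            c = p.constants
            V, z, F, R, T = [sympy.Float(x, 30) for x in
                             (v_mv * 1e-3, c.z, c.F, c.R, c.T)]
            A, sh, sb, n = [sympy.Float(x, 30) for x in
                            (p.A, p.sigma_h, p.sigma_beta, p.n)]
            ci, co = sympy.Float(p.c_i, 30), sympy.Float(p.c_o, 30)
            e = sympy.exp
            expr = (
                z * F * A * e(z * F * V / (2 * n * R * T))
                * (ci - co * e(-z * F * V / (R * T)))
                / (
                    e(-z * F * V * (n - 1) / (n * R * T))
                    + (1 / sh) * (1 - e(-z * F * V * (n - 2) / (n * R * T)))
                    / (e(z * F * V / (n * R * T)) - 1)
                    + 1 / sb
                )
            )
            expected = float(expr.evalf(30))
            assert got == pytest.approx(expected, rel=1e-10)
            checked += 1


class TestBarrierEnergies:
    def test_unit_rate_is_zero_energy(self):
        e = barrier_energies(1.0, 1.0)
        assert e.dEa_sigma_h == 0.0
        assert e.dEa_sigma_beta == 0.0

    def test_tenth_rate_at_recording_temperature(self):
        e = barrier_energies(1.0, 0.1)
        assert e.dEa_sigma_beta == pytest.approx(1.341, abs=2e-3)

    def test_inverse_e_rate_equals_rt(self):
        e = barrier_energies(np.exp(-1.0), 1.0)
        assert e.dEa_sigma_h == pytest.approx(RT)

    def test_sign_opposite_to_log_rate(self):
        e = barrier_energies(2.0, 0.5)
        assert e.dEa_sigma_h < 0 < e.dEa_sigma_beta

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            barrier_energies(0.0, 1.0)


class TestFitIV:
    def test_noiseless_recovery_four_digits(self):
        truth = PermeationParams(1.0, 0.5, 0.05)
        curve = curve_from_params(truth, np.arange(-100.0, 101.0, 20.0))
        est, fit = fit_iv(curve)
        assert est.A == pytest.approx(truth.A, rel=1e-4)
        assert est.sigma_h == pytest.approx(truth.sigma_h, rel=1e-4)
        assert est.sigma_beta == pytest.approx(truth.sigma_beta, rel=1e-4)

    def test_noisy_truth_inside_ci(self):
        # middle and inner barriers both rate-limiting, so both rates are
        # identified from a single noisy curve
        truth = PermeationParams(2.0, 0.2, 0.5)
        v = np.arange(-100.0, 101.0, 10.0)
        clean = barrier_current(v, truth)
        rng = np.random.default_rng(5)
        noisy = clean + 0.02 * np.max(np.abs(clean)) * rng.standard_normal(len(v))
        est, fit = fit_iv(IVCurve("m", "saturating_ca", v, noisy))
        assert fit.covers("sigma_h", truth.sigma_h)
        assert fit.covers("sigma_beta", truth.sigma_beta)

    def test_rectifying_fit_preserves_rate_ordering(self):
        truth = PermeationParams(1.0, 0.5, 0.02)
        curve = curve_from_params(truth, np.arange(-100.0, 101.0, 20.0))
        est, _ = fit_iv(curve)
        assert est.sigma_beta < est.sigma_h < 1.0

    def test_too_few_points_rejected(self):
        truth = PermeationParams(1.0, 1.0, 1.0)
        curve = curve_from_params(truth, np.array([-40.0, 0.0, 40.0]))
        with pytest.raises(ValidationError):
            fit_iv(curve)

    def test_single_polarity_warns(self):
        truth = PermeationParams(1.0, 0.5, 0.1)
        curve = curve_from_params(truth, np.arange(10.0, 101.0, 10.0))
        with pytest.warns(UserWarning, match="polarity"):
            fit_iv(curve)


class TestSingleOccupancyPrediction:
    def test_identical_fits_are_a_fixed_point(self):
        p = PermeationParams(1.0, 0.5, 0.05)
        v = np.arange(-80.0, 81.0, 20.0)
        curve, pred = predict_single_occupancy_iv(p, p, v)
        np.testing.assert_allclose(curve.currents, barrier_current(v, p), rtol=1e-12)
        assert curve.condition == "predicted_single_occupancy"

    def test_midpoint_energy_maps_to_rate(self):
        # apo ΔE = 2 kcal/mol, saturating ΔE = 0 → σ_single = e^{−1/RT}
        apo = PermeationParams(1.0, 1.0, float(np.exp(-2.0 / RT)))
        sat = PermeationParams(1.0, 1.0, 1.0)
        _, pred = predict_single_occupancy_iv(apo, sat, np.arange(-80.0, 81.0, 40.0))
        assert pred.sigma_beta == pytest.approx(np.exp(-1.0 / RT), rel=1e-12)

    def test_rectification_is_intermediate(self):
        apo = PermeationParams(0.5, 0.8, 0.02)   # strongly outward-rectifying
        sat = PermeationParams(1.0, 1.0, 1.0)    # near-linear
        v = np.arange(-80.0, 81.0, 20.0)
        def ratio(params):
            i = barrier_current(np.array([-80.0, 80.0]), params)
            return abs(i[1]) / abs(i[0])
        _, pred = predict_single_occupancy_iv(apo, sat, v)
        r_apo, r_sat, r_pred = ratio(apo), ratio(sat), ratio(pred)
        assert min(r_apo, r_sat) < r_pred < max(r_apo, r_sat)

    def test_mismatched_fixed_parameters_rejected(self):
        a = PermeationParams(1.0, 1.0, 1.0, c_i=150.0)
        b = PermeationParams(1.0, 1.0, 1.0, c_i=40.0)
        with pytest.raises(ValidationError):
            predict_single_occupancy_iv(a, b, np.arange(-80.0, 81.0, 40.0))
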