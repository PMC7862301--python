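"""Six-state MWC model: occupancies, EC50, chemical maps, estimation."""

import numpy as np
import pytest

from gatekit import (
    ConductanceLevels,
    MWCParams,
    curve_from_params,
    fit_chemical_global,
    fit_mutant_deltaG,
    l0_from_reversibility,
    l2_from_hydration,
    l2_from_methyl,
    l2_from_mutant,
    model_ec50,
    normalized_response,
    state_occupancies,
    subconductance_ratios,
    PermeationParams,
)
from gatekit.constants import DEFAULT_CONSTANTS
from gatekit.datatypes import DoseResponseCurve, DoseResponsePoint
from gatekit.fitting import (
    DegenerateDataError,
    FitResult,
    UnidentifiableParameterError,
    confidence_intervals,
)
from gatekit.mwc import FlatResponseError, _model_ec50_vec
from gatekit.synthetic import SimulationScenario, generate_triad_panel

RT = DEFAULT_CONSTANTS.RT
LEVELS0 = ConductanceLevels(0.0, 0.0)


def random_mwc(rng):
    return MWCParams(
        kd_c=10.0 ** rng.uniform(0, 2),
        kd_o=10.0 ** rng.uniform(-2, 0),
        l2=10.0 ** rng.uniform(-1, 3),
    )


class TestStateOccupancies:
    def test_sum_to_one_on_grid(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            occ = state_occupancies(float(10.0 ** rng.uniform(-4, 4)), random_mwc(rng))
            assert abs(occ.total - 1.0) < 1e-12

    def test_zero_calcium_unbound_states_only(self):
        p = MWCParams(20.0, 0.2, 10.0)
        occ = state_occupancies(0.0, p)
        assert occ.p_o0 == pytest.approx(p.l0 / (1 + p.l0))
        assert occ.p_c1 == occ.p_c2 == occ.p_o1 == occ.p_o2 == 0.0

    def test_saturation_reaches_limiting_open_probability(self):
        # the residual deficit scales as kd_c/ca, so a million-fold excess
        # over kd_o pins the limit for a ten-fold affinity gap
        p = MWCParams(2.0, 0.2, 10.0)
        occ = state_occupancies(1e6 * p.kd_o, p)
        p_open = occ.p_o0 + occ.p_o1 + occ.p_o2
        assert abs(p_open - p.l2 / (1 + p.l2)) < 1e-6

    def test_reversibility_identity(self):
        assert l0_from_reversibility(20.0, 0.1, 1.0) == pytest.approx(0.2)
        assert l0_from_reversibility(5.0, 1.0, 1.0) == pytest.approx(5.0)
        # activating ligand (kd_o < kd_c) closes down the apo equilibrium
        assert l0_from_reversibility(5.0, 0.1, 10.0) < 5.0


class TestNormalizedResponse:
    def test_saturating_limit_is_one(self):
        p = MWCParams(20.0, 0.2, 10.0)
        assert normalized_response(1e8, p, LEVELS0) == pytest.approx(1.0, abs=1e-6)

    def test_silent_apo_channel_starts_at_zero(self):
        p = MWCParams(20.0, 0.2, 10.0)
        assert normalized_response(0.0, p, LEVELS0) == 0.0

    def test_equal_affinities_and_levels_give_flat_unity(self):
        p = MWCParams(1.0, 1.0, 10.0)
        levels = ConductanceLevels(1.0, 1.0)
        ca = np.geomspace(1e-3, 1e3, 20)
        np.testing.assert_allclose(normalized_response(ca, p, levels), 1.0, rtol=1e-12)

    def test_nondecreasing_for_activating_parameters(self):
        rng = np.random.default_rng(1)
        ca = np.geomspace(1e-4, 1e4, 200)
        for _ in range(50):
            p = random_mwc(rng)
            i_k = rng.uniform(0, 1)
            levels = ConductanceLevels(i_k, rng.uniform(i_k, 1))
            r = normalized_response(ca, p, levels)
            assert np.all(np.diff(r) > -1e-10)


class TestModelEC50:
    def test_between_binding_constants_for_strong_gate(self):
        p = MWCParams(kd_c=10.0, kd_o=0.1, l2=100.0)
        ec50 = model_ec50(p, LEVELS0)
        # grid-scan oracle for the half-max crossing
        ca = np.geomspace(1e-4, 1e4, 200001)
        r = normalized_response(ca, p, LEVELS0)
        half = 0.5 * (r[0] + 1.0)
        oracle = ca[np.searchsorted(r, half)]
        assert ec50 == pytest.approx(oracle, rel=1e-3)
        assert p.kd_o < ec50 < p.kd_c

    def test_monotone_decreasing_in_l2(self):
        ec50s = [
            model_ec50(MWCParams(20.0, 0.2, l2), LEVELS0)
            for l2 in np.geomspace(0.5, 5e4, 12)
        ]
        assert np.all(np.diff(ec50s) < 0)

    def test_flat_parameterization_has_no_ec50(self):
        with pytest.raises(FlatResponseError):
            model_ec50(MWCParams(1.0, 1.0, 10.0), ConductanceLevels(1.0, 1.0))

    def test_vectorized_agrees_with_scalar(self):
        rng = np.random.default_rng(2)
        kd_c, kd_o = 15.0, 0.15
        l2 = 10.0 ** rng.uniform(0, 3, size=8)
        vec = _model_ec50_vec(kd_c, kd_o, l2, 0.0, 0.0)
        for l2_i, e in zip(l2, vec):
            assert e == pytest.approx(
                model_ec50(MWCParams(kd_c, kd_o, l2_i), LEVELS0), rel=1e-5
            )


class TestChemicalMaps:
    def test_identity_at_zero_perturbation(self):
        assert l2_from_methyl(0, 0.83, 7.0) == 7.0
        assert l2_from_hydration(0.0, 0.37, 7.0) == 7.0
        assert l2_from_mutant(0.0, 7.0) == 7.0

    def test_three_methyl_removal_hand_value(self):
        # e^{3·0.83/RT} ≈ 71.8
        assert l2_from_methyl(-3, 0.83, 1.0) == pytest.approx(71.8, rel=5e-3)

    def test_hydration_shift_hand_value(self):
        # e^{0.37·2/RT} ≈ 3.56
        assert l2_from_hydration(2.0, 0.37, 1.0) == pytest.approx(3.56, rel=5e-3)

    def test_reversibility_preserved_through_every_map(self):
        kd_c, kd_o, l2_wt = 20.0, 0.2, 10.0
        for l2 in (
            l2_from_methyl(-6, 0.83, l2_wt),
            l2_from_hydration(3.0, 0.37, l2_wt),
            l2_from_mutant(-1.5, l2_wt),
        ):
            p = MWCParams(kd_c, kd_o, l2)
            assert p.l0 / p.l2 == pytest.approx((kd_o / kd_c) ** 2, rel=1e-12)

    def test_ec50_saturates_at_large_methyl_removal(self):
        # log EC50 falls roughly linearly at first, then levels off at the
        # limiting EC50 set by the open-state affinity
        dn = np.arange(0, -16, -1)
        ec = [
            model_ec50(MWCParams(20.0, 0.2, l2_from_methyl(d, 0.83, 10.0)), LEVELS0)
            for d in dn
        ]
        dlog = np.diff(np.log10(ec))
        assert np.all(dlog < 0)
        assert abs(dlog[-1]) < 0.1 * abs(dlog[0])


class TestSubconductanceRatios:
    def test_identical_curves_give_unity(self):
        p = PermeationParams(1.0, 0.5, 0.3)
        v = np.arange(-100.0, 101.0, 20.0)
        c = curve_from_params(p, v)
        levels = subconductance_ratios(c, c, c)
        assert levels.i_over_k == pytest.approx(1.0)

    def test_silent_apo_channel_gives_zero(self):
        from gatekit.datatypes import IVCurve
        v = np.arange(-100.0, 101.0, 20.0)
        sat = curve_from_params(PermeationParams(1.0, 0.5, 0.3), v)
        zero = IVCurve("wt", "zero_ca", v, np.zeros_like(v))
        levels = subconductance_ratios(zero, sat, sat)
        assert levels.i_over_k == 0.0

    def test_ratio_matches_direct_evaluation(self):
        p_zero = PermeationParams(0.3, 0.6, 0.04)
        p_sat = PermeationParams(1.0, 0.8, 0.3)
        v = np.arange(-100.0, 101.0, 20.0)
        from gatekit import barrier_current
        levels = subconductance_ratios(
            curve_from_params(p_zero, v, condition="zero_ca"),
            curve_from_params(p_sat, v),
            curve_from_params(p_sat, v),
        )
        expected = barrier_current(80.0, p_zero) / barrier_current(80.0, p_sat)
        assert levels.i_over_k == pytest.approx(expected, rel=1e-12)

    def test_negative_saturating_current_is_degenerate(self):
        from gatekit.datatypes import IVCurve
        v = np.arange(-100.0, 101.0, 20.0)
        bad = IVCurve("m", "saturating_ca", v, -np.ones_like(v))
        with pytest.raises(DegenerateDataError):
            subconductance_ratios(bad, bad, bad)


class TestChemicalGlobalFit:
    def test_noiseless_panel_exact_recovery(self):
        sc = SimulationScenario(ec50_log10_sd=0.0, seed=1)
        panel = generate_triad_panel(sc)
        fit = fit_chemical_global(
            panel.methyl_pairs(), panel.hydration_pairs(), l2_wt=sc.l2_wt
        )
        assert fit.dg_me == pytest.approx(sc.dg_me, rel=1e-4)
        assert fit.delta == pytest.approx(sc.delta, rel=1e-4)
        assert fit.kd_c == pytest.approx(sc.kd_c, rel=1e-3)
        assert fit.kd_o == pytest.approx(sc.kd_o, rel=1e-3)

    def test_noisy_panel_truth_inside_ci(self):
        sc = SimulationScenario(seed=99)
        panel = generate_triad_panel(sc)
        fit = fit_chemical_global(
            panel.methyl_pairs(), panel.hydration_pairs(), l2_wt=sc.l2_wt
        )
        assert fit.fit.covers("dg_me", sc.dg_me)
        assert fit.fit.covers("delta", sc.delta)

    def test_null_methyl_energy_recovered(self):
        sc = SimulationScenario(dg_me=0.0, seed=7)
        panel = generate_triad_panel(sc)
        fit = fit_chemical_global(
            panel.methyl_pairs(), panel.hydration_pairs(), l2_wt=sc.l2_wt
        )
        assert fit.fit.covers("dg_me", 0.0)

    def test_underdetermined_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            fit_chemical_global([(0, 1.0), (-1, 0.8)], [(0.0, 1.0)] * 4, l2_wt=10.0)


class TestMutantDeltaG:
    @staticmethod
    def _curve(mutant_id, dg, sc, rng=None):
        from gatekit.datatypes import MutantSpec
        spec = MutantSpec()  # WT chemistry: only dg_mut shifts the gate
        sc.dg_mut[spec.mutant_id] = dg
        from gatekit.synthetic import generate_dose_response_panel
        curves, _ = generate_dose_response_panel(sc, panel=[spec], rng=rng)
        curves[0].mutant_id = mutant_id
        return curves[0]

    def test_wild_type_self_consistency(self):
        sc = SimulationScenario(noise_sd_response=0.0, seed=1)
        curve = self._curve("WT", 0.0, sc)
        res = fit_mutant_deltaG([curve], sc.kd_c, sc.kd_o, sc.l2_wt)
        assert abs(res["WT"].param("dg_mut")) < 1e-6

    def test_noisy_recovery_inside_ci(self):
        sc = SimulationScenario(seed=3)
        sc.dg_mut["MUT"] = -2.0
        curve = self._curve("MUT", -2.0, sc)
        res = fit_mutant_deltaG([curve], sc.kd_c, sc.kd_o, sc.l2_wt)
        assert res["MUT"].covers("dg_mut", -2.0)

    def test_flat_curve_flagged_others_proceed(self):
        sc = SimulationScenario(noise_sd_response=0.0, seed=1)
        good = self._curve("GOOD", -1.0, sc)
        flat = DoseResponseCurve(
            "FLAT", [DoseResponsePoint(c, 0.5) for c in (0.1, 1.0, 3.0, 10.0)]
        )
        with pytest.warns(UserWarning, match="FLAT"):
            res = fit_mutant_deltaG([good, flat], sc.kd_c, sc.kd_o, sc.l2_wt)
        assert res["FLAT"] is None
        assert res["GOOD"].param("dg_mut") == pytest.approx(-1.0, abs=1e-8)


class TestConfidenceIntervals:
    def test_zero_residuals_zero_width(self):
        J = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        _, se, ci = confidence_intervals(J, 0.0, 3, np.array([1.0, 2.0]))
        assert np.all(se == 0)
        np.testing.assert_array_equal(ci[:, 0], ci[:, 1])

    def test_diagonal_jtj_closed_form(self):
        # J with orthogonal columns: SE_i = sqrt(SSR/(n−p)) / ||J_i||
        J = np.array([[2.0, 0.0], [0.0, 4.0], [0.0, 0.0], [0.0, 0.0]])
        ssr, n = 0.5, 4
        _, se, _ = confidence_intervals(J, ssr, n, np.zeros(2))
        s = np.sqrt(ssr / (n - 2))
        np.testing.assert_allclose(se, [s / 2.0, s / 4.0], rtol=1e-12)

    def test_duplicated_columns_unidentifiable(self):
        J = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(UnidentifiableParameterError):
            confidence_intervals(J, 1.0, 5, np.zeros(2))

    def test_t_quantile_wider_than_normal(self):
        J = np.arange(1.0, 7.0).reshape(6, 1)
        values = np.array([1.0])
        _, se, ci = confidence_intervals(J, 2.0, 6, values)
        half_width = ci[0, 1] - values[0]
        assert half_width > 1.96 * se[0]

    def test_fitresult_requires_residual_dof(self):
        with pytest.raises(DegenerateDataError):
            FitResult(["a"], np.array([1.0]), 0.0, 1, 1, np.ones((1, 1)))
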