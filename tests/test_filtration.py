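"""Cake filtration: porosity, SCR submodels, deposition kinetics, TMP, cycles."""

import math

import numpy as np
import pytest

from anmbrsim import (CakeCollapseError, CakeParams, CycleSchedule,
                      DepositionParams, MembraneState, OpsPoint, cake_porosity,
                      deposition_rhs, fouling_rate_from_tmp, ims,
                      simulate_cycles, specific_cake_resistance,
                      steady_cycle_cake, tmp)


class TestCakePorosity:
    def test_clean_cake(self, cake_params):
        assert cake_porosity(0.1, 0.0, cake_params) == cake_params.eps_c0

    def test_colloid_filling_arithmetic(self):
        p = CakeParams(eps_c0=0.5, rho_X=1000.0, rho_C=1000.0)
        assert cake_porosity(1.0, 0.5, p) == pytest.approx(0.25)

    def test_floor_binds_for_colloid_rich_cake(self, cake_params):
        eps = cake_porosity(0.01, 10.0, cake_params)
        assert eps == cake_params.eps_c_min

    def test_degenerate_colloid_only_deposit(self, cake_params):
        assert cake_porosity(0.0, 0.1, cake_params) == cake_params.eps_c_min


class TestSpecificCakeResistance:
    def test_carman_kozeny_arithmetic(self):
        p = CakeParams(k_CK=180.0, eps_c0=0.4, rho_X=1000.0)
        alpha = specific_cake_resistance("a1", 0.1, 0.0, 5e-5, 0.0, 1e-3, p)
        assert alpha == pytest.approx(6.75e8, rel=1e-12)

    def test_no_compression_at_zero_flux(self, cake_params):
        a1 = specific_cake_resistance("a1", 0.2, 0.02, 4e-5, 0.0, 1e-3,
                                      cake_params)
        a1p = specific_cake_resistance("a1p", 0.2, 0.02, 4e-5, 0.0, 1e-3,
                                       cake_params)
        assert a1p == pytest.approx(a1, rel=1e-12)

    def test_compression_doubles_at_half_ratio(self):
        # choose Pa so that J*mu*omega_X*alpha/Pa == 0.5 exactly
        p = CakeParams(k_CK=180.0, eps_c0=0.4, rho_X=1000.0)
        J, mu, wX, dp = 1.67e-5, 1e-3, 0.2, 5e-5
        a1 = specific_cake_resistance("a1", wX, 0.0, dp, J, mu, p)
        p2 = CakeParams(k_CK=180.0, eps_c0=0.4, rho_X=1000.0,
                        Pa=2.0 * J * mu * wX * a1)
        a1p = specific_cake_resistance("a1p", wX, 0.0, dp, J, mu, p2)
        assert a1p == pytest.approx(2.0 * a1, rel=1e-12)

    def test_colloid_free_wu_form(self):
        p = CakeParams(k_c=1e15, eps_c0=0.45, rho_X=1000.0)
        alpha = specific_cake_resistance("a2", 0.2, 0.0, 4e-5, 0.0, 1e-3, p)
        expected = 1e15 * (1 - 0.45) / (1000.0 * 0.45**3)
        assert alpha == pytest.approx(expected, rel=1e-12)

    def test_compression_collapse_raises_before_nan(self):
        p = CakeParams(k_CK=180.0, eps_c0=0.4, rho_X=1000.0, Pa=1.0)
        with pytest.raises(CakeCollapseError):
            specific_cake_resistance("a1p", 0.5, 0.0, 5e-5, 1.67e-5, 1e-3, p)

    def test_colloids_raise_scr_for_every_variant(self, cake_params):
        # entrapped colloids reduce porosity and increase resistance
        # (thin, rig-scale deposit so the compressible forms stay physical)
        for v in ("a1", "a1p", "a2", "a2p", "a3"):
            lo = specific_cake_resistance(v, 0.02, 0.0005, 4e-5, 1.9e-6, 7e-4,
                                          cake_params)
            hi = specific_cake_resistance(v, 0.02, 0.002, 4e-5, 1.9e-6, 7e-4,
                                          cake_params)
            assert hi > lo, v

    def test_floc_size_only_affects_carman_kozeny_family(self, cake_params):
        args = (0.02, 0.002, 1.9e-6, 7e-4)
        for v in ("a1", "a1p"):
            small = specific_cake_resistance(v, args[0], args[1], 2e-5,
                                             *args[2:], cake_params)
            large = specific_cake_resistance(v, args[0], args[1], 8e-5,
                                             *args[2:], cake_params)
            assert small > large, v
        for v in ("a2", "a2p", "a3"):
            small = specific_cake_resistance(v, args[0], args[1], 2e-5,
                                             *args[2:], cake_params)
            large = specific_cake_resistance(v, args[0], args[1], 8e-5,
                                             *args[2:], cake_params)
            assert small == pytest.approx(large, rel=1e-12), v


class TestIms:
    def test_simplified_variant_is_unity(self, dep_params):
        assert ims("D1c", 1e-5, 0.003, 1.0, 10.0, 0.4, dep_params) == 1.0

    def test_zero_scale_gives_unity(self):
        p = DepositionParams(K_F=0.0)
        assert ims("D1a", 1e-5, 0.003, 1.0, 10.0, 0.4, p) == 1.0
        assert ims("D1b", 1e-5, 0.003, 1.0, 10.0, 0.4, p) == 1.0

    def test_unit_scale_zero_exponent_gives_half(self):
        p = DepositionParams(K_F=1.0)
        assert ims("D1a", 0.0, 0.0, 1.0, 0.0, 0.0, p) == pytest.approx(0.5)

    def test_colloid_term_only_in_extended_variant(self):
        p = DepositionParams(K_F=1.0, gamma3=2.0)
        a = ims("D1a", 1e-5, 0.003, 1.0, 10.0, 0.4, p)
        b = ims("D1b", 1e-5, 0.003, 1.0, 10.0, 0.4, p)
        assert b < a  # higher colloid load -> more fouling -> lower IMS


class TestDepositionRhs:
    def test_empty_membrane_attaches_only(self, dep_params, reactor_ops):
        st = MembraneState()
        dX, dC = deposition_rhs("D1c", st, 10.0, 0.4, reactor_ops,
                                "filtration", dep_params)
        assert dX == pytest.approx(reactor_ops.J20 * 10.0)
        assert dC == pytest.approx(reactor_ops.J20 * 0.4)

    def test_drag_only_attachment_product(self, dep_params):
        ops = OpsPoint(J=1.5e-5, J20=1.5e-5, uG=0.003)
        dX, _ = deposition_rhs("D1c", MembraneState(), 10.0, 0.0, ops,
                               "filtration", dep_params)
        assert dX == pytest.approx(1.5e-4)

    def test_lift_free_limit_of_force_balance(self, dep_params):
        # G = 0: the lift term vanishes and attachment reduces to J * cX
        ops = OpsPoint(J=1.5e-5, J20=1.5e-5, uG=0.003, G=0.0)
        st = MembraneState(omega_X=0.1, omega_C=0.01, VF=0.005)
        dX, dC = deposition_rhs("D2", st, 10.0, 0.4, ops, "filtration",
                                dep_params)
        assert dX == pytest.approx(1.5e-5 * 10.0)
        assert dC == pytest.approx(dep_params.f_C_c * 1.5e-5 * 0.4)

    def test_relaxation_is_pure_detachment(self, dep_params, reactor_ops):
        st = MembraneState(omega_X=0.3, omega_C=0.03)
        dX, dC = deposition_rhs("D1c", st, 10.0, 0.4, reactor_ops,
                                "relaxation", dep_params)
        assert dX < 0 and dC < 0

    def test_detachment_never_drives_deposits_negative(self, dep_params,
                                                       reactor_ops):
        dX, dC = deposition_rhs("D1c", MembraneState(), 0.0, 0.0, reactor_ops,
                                "relaxation", dep_params)
        assert dX == 0.0 and dC == 0.0


class TestTmp:
    def test_clean_membrane(self, cake_params):
        _, Rt, press = tmp(MembraneState(), 1.67e-5, 1e-3, cake_params, "a1",
                           4.5e-5)
        assert Rt == cake_params.Rm
        assert press == pytest.approx(1.67e-5 * 1e-3 * cake_params.Rm)

    def test_zero_flux_zero_pressure(self, cake_params):
        st = MembraneState(omega_X=0.2, omega_C=0.01)
        _, _, press = tmp(st, 0.0, 1e-3, cake_params, "a1", 4.5e-5)
        assert press == 0.0

    def test_resistance_in_series_closure(self, cake_params):
        st = MembraneState(omega_X=0.2, omega_C=0.01)
        J, mu, dp = 1.67e-5, 1e-3, 4.5e-5
        alpha = specific_cake_resistance("a1", st.omega_X, st.omega_C, dp, J,
                                         mu, cake_params)
        Rc, Rt, press = tmp(st, J, mu, cake_params, "a1", dp)
        assert Rc == pytest.approx(st.omega_X * alpha, rel=1e-12)
        assert Rt == pytest.approx(cake_params.Rm + Rc, rel=1e-12)
        assert press == pytest.approx(J * mu * Rt, rel=1e-12)


class TestCycles:
    def test_zero_bulk_keeps_tmp_at_membrane_baseline(self, cake_params,
                                                      dep_params, reactor_ops):
        times, tmps, phases, final = simulate_cycles(
            MembraneState(), 0.0, 0.0, reactor_ops, CycleSchedule(), 720.0,
            "D1c", "a1", cake_params, dep_params)
        baseline = reactor_ops.J * reactor_ops.mu * cake_params.Rm
        assert np.allclose(tmps[phases == 1], baseline)
        assert final.omega_X == 0.0

    def test_mass_accounting_over_interval(self, cake_params, dep_params,
                                           reactor_ops):
        # integrated attachment - detachment matches the deposit growth
        schedule = CycleSchedule(t_filtration=300.0, t_relaxation=0.0)
        st0 = MembraneState()
        dt = 1.0
        _, _, _, final = simulate_cycles(st0, 10.0, 0.4, reactor_ops, schedule,
                                         300.0, "D1c", "a1", cake_params,
                                         dep_params, dt=dt)
        # reference: dense explicit integration of the same balance
        wX = wC = 0.0
        for _ in range(int(300 / 0.1)):
            dX, dC = deposition_rhs("D1c", MembraneState(max(wX, 0), max(wC, 0)),
                                    10.0, 0.4, reactor_ops, "filtration",
                                    dep_params)
            wX += 0.1 * dX
            wC += 0.1 * dC
        assert final.omega_X == pytest.approx(wX, rel=1e-3)
        assert final.omega_C == pytest.approx(wC, rel=1e-3)

    def test_long_run_approaches_attachment_detachment_fixed_point(
            self, cake_params, dep_params, reactor_ops):
        schedule = CycleSchedule(t_filtration=300.0, t_relaxation=0.0)
        fixed = steady_cycle_cake("D1c", 10.0, 0.4, reactor_ops, schedule,
                                  dep_params)
        _, _, _, final = simulate_cycles(
            MembraneState(), 10.0, 0.4, reactor_ops, schedule, 5.0e5, "D1c",
            "a1", cake_params, dep_params, dt=10.0)
        attach = reactor_ops.J20 * 10.0
        dX, _ = deposition_rhs("D1c", final, 10.0, 0.4, reactor_ops,
                               "filtration", dep_params)
        assert abs(dX) < 1e-6 * attach
        assert final.omega_X == pytest.approx(fixed.omega_X, rel=1e-3)

    def test_shorter_relaxation_grows_the_cake(self, cake_params, dep_params,
                                               reactor_ops):
        def mean_cake(t_relax):
            _, _, _, final = simulate_cycles(
                MembraneState(), 10.0, 0.4, reactor_ops,
                CycleSchedule(t_filtration=300.0, t_relaxation=t_relax),
                3600.0 * 4, "D1c", "a1", cake_params, dep_params)
            return final.omega_X

        assert mean_cake(30.0) > mean_cake(60.0)

    def test_fouling_rate_decreases_with_floc_size(self, cake_params,
                                                   dep_params, reactor_ops):
        # Carman-Kozeny SCR scales as dp^-2
        def fr(dp):
            ops = OpsPoint(**{**reactor_ops.__dict__, "dp": dp})
            st = steady_cycle_cake("D1c", 10.0, 0.4, ops, CycleSchedule(),
                                   dep_params)
            t, p, phase, _ = simulate_cycles(st, 10.0, 0.4, ops,
                                             CycleSchedule(), 300.0, "D1c",
                                             "a1", cake_params, dep_params)
            return fouling_rate_from_tmp(t[phase == 1], p[phase == 1])

        assert fr(6e-5) < fr(3e-5)

    def test_fouling_rate_increases_with_colloids(self, cake_params,
                                                  dep_params, reactor_ops):
        for scr in ("a1", "a2"):
            def fr(cC):
                st = steady_cycle_cake("D1c", 10.0, cC, reactor_ops,
                                       CycleSchedule(), dep_params)
                t, p, phase, _ = simulate_cycles(st, 10.0, cC, reactor_ops,
                                                 CycleSchedule(), 300.0,
                                                 "D1c", scr, cake_params,
                                                 dep_params)
                return fouling_rate_from_tmp(t[phase == 1], p[phase == 1])

            assert fr(0.6) > fr(0.2), scr

    def test_lift_model_more_sensitive_to_gas_velocity(self, cake_params,
                                                       dep_params):
        # gas sparging enters both attachment and detachment of the
        # force-balance submodel, but only detachment of the drag-only one
        from anmbrsim import shear_rate

        def fr(variant, uG):
            # cake growth from a clean membrane over one filtration stage
            G = shear_rate(uG, 10.0, 308.15)
            ops = OpsPoint(J=1.94e-6, J20=1.82e-6, uG=uG, HMT=1.0, G=G,
                           dp=4.5e-5, mu=7.2e-4)
            t, p, phase, _ = simulate_cycles(
                MembraneState(), 10.0, 0.4, ops,
                CycleSchedule(t_filtration=300.0, t_relaxation=0.0), 300.0,
                variant, "a1", cake_params, dep_params)
            return fouling_rate_from_tmp(t[phase == 1], p[phase == 1])

        def rel_sens(variant):
            lo, hi = fr(variant, 0.0025), fr(variant, 0.0035)
            return abs(hi - lo) / ((hi + lo) / 2)

        assert rel_sens("D2") > rel_sens("D1c")


class TestFoulingRateExtraction:
    def test_exact_line(self):
        t = np.linspace(0.0, 100.0, 11)
        assert fouling_rate_from_tmp(t, 5.0 + 2.0 * t) == pytest.approx(2.0)

    def test_constant_tmp(self):
        t = np.linspace(0.0, 100.0, 11)
        assert fouling_rate_from_tmp(t, np.full_like(t, 7.0)) == pytest.approx(
            0.0, abs=1e-12)

    def test_quadratic_against_closed_form_ols(self):
        t = np.linspace(0.0, 10.0, 101)
        y = t**2
        tc = t - t.mean()
        expected = float((tc * (y - y.mean())).sum() / (tc * tc).sum())
        assert fouling_rate_from_tmp(t, y) == pytest.approx(expected, rel=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fouling_rate_from_tmp(np.array([0.0, 1.0]), np.array([0.0, 1.0]))
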