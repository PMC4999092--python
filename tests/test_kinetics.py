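import numpy as np
import pytest
from scipy.integrate import solve_ivp

import petkin as pk


def ode_tissue(topology, p, inputs, t_eval_min, k4=None):
    """Independent oracle: adaptive ODE integration of the compartment
    system with the same piecewise-linear input interpolation."""
    t_min = inputs.time / 60.0
    cp = inputs.cp_parent

    def cp_of(t):
        return np.interp(t, t_min, cp)

    if topology == "1C1i":
        def rhs(t, y):
            return [p.K1 * cp_of(t) - p.k2 * y[0]]
        y0 = [0.0]
    elif topology == "2C1i":
        def rhs(t, y):
            return [p.K1 * cp_of(t) - (p.k2 + p.k3) * y[0] + p.k4 * y[1],
                    p.k3 * y[0] - p.k4 * y[1]]
        y0 = [0.0, 0.0]
    else:
        cm = inputs.cp_metabolite

        def cm_of(t):
            return np.interp(t, t_min, cm)

        def rhs(t, y):
            return [p.K1 * cp_of(t) - (p.k2 + p.k3) * y[0],
                    p.k3 * y[0],
                    p.K1m * cm_of(t) - p.k2m * y[2]]
        y0 = [0.0, 0.0, 0.0]
    sol = solve_ivp(rhs, (0.0, t_min[-1]), y0, t_eval=t_eval_min,
                    rtol=1e-10, atol=1e-12, max_step=0.5)
    return sol.y.sum(axis=0)


class TestSimulator:
    def test_no_uptake_gives_blood_signal_only(self, fdg_inputs, fdg_schedule):
        spec = pk.ModelSpec("2C1i")
        params = pk.KineticParams(K1=0.0, k2=0.1, k3=0.1, vB=0.0)
        tac = pk.simulate_model(spec, params, fdg_inputs, fdg_schedule)
        np.testing.assert_allclose(tac.value, 0.0)
        params_vb = pk.KineticParams(K1=0.0, k2=0.1, vB=0.1)
        tac_vb = pk.simulate_model(spec, params_vb, fdg_inputs, fdg_schedule)
        cwb_mid = np.interp(fdg_schedule.mid, fdg_inputs.time, fdg_inputs.cwb)
        np.testing.assert_allclose(tac_vb.value, 0.1 * cwb_mid)

    def test_one_tissue_constant_input_closed_form(self):
        """1C1i with constant Cp = c: CT = (K1 c / k2)(1 - e^{-k2 t})."""
        sched = pk.FrameSchedule(np.arange(60) * 60.0, np.full(60, 60.0))
        t = np.arange(0.0, sched.total_duration + 1.0)
        c = 10.0
        inputs = pk.InputFunctionSet(t, np.full_like(t, c), np.full_like(t, c))
        K1, k2 = 0.08, 0.12
        tac = pk.simulate_model(pk.ModelSpec("1C1i"),
                                pk.KineticParams(K1=K1, k2=k2), inputs, sched)
        t_mid_min = sched.mid / 60.0
        exact = (K1 * c / k2) * (1.0 - np.exp(-k2 * t_mid_min))
        np.testing.assert_allclose(tac.value, exact, rtol=1e-3)

    def test_irreversible_asymptotic_slope_is_ki(self):
        """2C1i, k4 = 0, constant Cp: late dCT/dt -> K1 k3/(k2+k3) c."""
        sched = pk.FrameSchedule(np.arange(240) * 60.0, np.full(240, 60.0))
        t = np.arange(0.0, sched.total_duration + 1.0)
        c = 5.0
        inputs = pk.InputFunctionSet(t, np.full_like(t, c), np.full_like(t, c))
        K1, k2, k3 = 0.16, 0.19, 0.07
        tac = pk.simulate_model(pk.ModelSpec("2C1i", fixed={"k4": 0.0}),
                                pk.KineticParams(K1=K1, k2=k2, k3=k3),
                                inputs, sched)
        t_min = sched.mid / 60.0
        late = t_min > 200
        slope = np.polyfit(t_min[late], tac.value[late], 1)[0]
        assert slope == pytest.approx(K1 * k3 / (k2 + k3) * c, rel=1e-3)

    def test_matches_ode_oracle_across_random_sweep(self, fdg_inputs,
                                                    fdg_schedule):
        """Analytic exponential convolution vs adaptive ODE integration."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            p = pk.KineticParams(K1=rng.uniform(0.01, 0.5),
                                 k2=rng.uniform(0.01, 1.0),
                                 k3=rng.uniform(0.01, 1.0),
                                 k4=rng.uniform(0.0, 0.2))
            tac = pk.simulate_model(pk.ModelSpec("2C1i"), p, fdg_inputs,
                                    fdg_schedule)
            ref = ode_tissue("2C1i", p, fdg_inputs, fdg_schedule.mid / 60.0)
            err = np.max(np.abs(tac.value - ref)) / np.max(ref)
            assert err < 1e-3

    def test_dual_input_matches_ode_oracle(self):
        sched = pk.build_frame_schedule(pk.FRAMING["FCho"])
        blood = pk.generate_aif(pk.AIFModel(), sched)
        inputs = pk.make_input_set("FCho", blood)
        p = pk.KineticParams(K1=0.11, k2=0.05, k3=0.02, K1m=0.04, k2m=0.03)
        tac = pk.simulate_model(pk.ModelSpec("3C2i"), p, inputs, sched)
        ref = ode_tissue("3C2i", p, inputs, sched.mid / 60.0)
        assert np.max(np.abs(tac.value - ref)) / np.max(ref) < 1e-3

    def test_dual_input_requires_metabolite_curve(self, fdg_inputs,
                                                  fdg_schedule):
        with pytest.raises(ValueError):
            pk.simulate_model(pk.ModelSpec("3C2i"),
                              pk.KineticParams(K1=0.1, k2=0.1),
                              fdg_inputs, fdg_schedule)

    def test_trapping_monotonicity_with_k4_zero(self, fdg_inputs,
                                                fdg_schedule,
                                                irreversible_2c_spec):
        """With k4 = 0 the trapped compartment C2 never decreases for any
        non-negative input (dC2/dt = k3 C1 >= 0), and the total tissue
        activity is non-decreasing for a constant input (the free
        compartment rises monotonically toward its steady state)."""
        K1, k2, k3 = 0.16, 0.19, 0.07
        from petkin.kinetics import expconv
        # trapped compartment under the bolus input: C2 = k3 * conv0(C1)
        t = fdg_inputs.time
        a2 = k2 + k3
        c1 = K1 * expconv(a2, t, fdg_inputs.cp_parent)
        c2 = k3 * expconv(0.0, t, c1)
        assert np.all(np.diff(c2) >= -1e-12 * np.max(c2))
        # total activity under a constant input
        const = pk.InputFunctionSet(t, np.full_like(t, 5.0),
                                    np.full_like(t, 5.0))
        tac = pk.simulate_model(irreversible_2c_spec,
                                pk.KineticParams(K1=K1, k2=k2, k3=k3),
                                const, fdg_schedule)
        assert np.all(np.diff(tac.value) >= -1e-9 * np.max(tac.value))


class TestFitting:
    def test_noiseless_fdg_recovery(self, fdg_inputs, fdg_schedule,
                                    irreversible_2c_spec, fdg_gb_params):
        tac = pk.simulate_model(irreversible_2c_spec, fdg_gb_params,
                                fdg_inputs, fdg_schedule)
        fit = pk.fit_model(tac, fdg_inputs, irreversible_2c_spec)
        assert abs(fit.params.K1 - 0.16) < 1e-3
        assert abs(fit.params.k2 - 0.19) < 1e-3
        assert abs(fit.params.k3 - 0.07) < 1e-3
        assert fit.perfect_fit or fit.ssr < 1e-12

    def test_noiseless_fet_recovery(self, fet_inputs, fet_schedule):
        spec = pk.ModelSpec("1C1i")
        tac = pk.simulate_model(spec, pk.KineticParams(K1=0.06, k2=0.05),
                                fet_inputs, fet_schedule)
        fit = pk.fit_model(tac, fet_inputs, spec)
        assert abs(fit.params.K1 - 0.06) < 1e-3
        assert abs(fit.params.k2 - 0.05) < 1e-3

    def test_all_zero_tac_flags_undefined_se(self, fdg_inputs, fdg_schedule):
        spec = pk.ModelSpec("1C1i")
        tac = pk.TimeActivityCurve(fdg_schedule,
                                   np.zeros(fdg_schedule.n_frames))
        fit = pk.fit_model(tac, fdg_inputs, spec)
        assert fit.params.K1 == pytest.approx(0.0, abs=1e-6)
        assert not fit.se_defined

    def test_scale_consistency_of_rate_constants(self, fdg_inputs,
                                                 fdg_schedule,
                                                 irreversible_2c_spec,
                                                 fdg_gb_params):
        """Scaling Cp and the TAC by a common factor leaves rates unchanged."""
        tac = pk.simulate_model(irreversible_2c_spec, fdg_gb_params,
                                fdg_inputs, fdg_schedule)
        fit1 = pk.fit_model(tac, fdg_inputs, irreversible_2c_spec, n_starts=2)
        scaled_inputs = pk.InputFunctionSet(
            fdg_inputs.time, 3.0 * fdg_inputs.cp_parent, 3.0 * fdg_inputs.cwb)
        tac2 = pk.TimeActivityCurve(fdg_schedule, 3.0 * tac.value)
        fit2 = pk.fit_model(tac2, scaled_inputs, irreversible_2c_spec,
                            n_starts=2)
        for name in ("K1", "k2", "k3"):
            assert getattr(fit1.params, name) == pytest.approx(
                getattr(fit2.params, name), abs=1e-5)

    def test_median_k1_error_under_default_noise(self, fdg_inputs,
                                                 fdg_schedule,
                                                 irreversible_2c_spec,
                                                 fdg_gb_params):
        """Median relative K1 error stays below 10% at the default noise."""
        noise = pk.NoiseModel()
        rng = np.random.default_rng(7)
        errs = []
        for _ in range(25):
            tac = pk.generate_tac(fdg_gb_params, irreversible_2c_spec,
                                  fdg_inputs, fdg_schedule, noise, rng)
            fit = pk.fit_model(tac, fdg_inputs, irreversible_2c_spec,
                               n_starts=3)
            errs.append(abs(fit.params.K1 - 0.16) / 0.16)
        assert np.median(errs) < 0.10

    def test_too_few_frames_raises(self, fdg_inputs):
        sched = pk.build_frame_schedule("2x10s")
        tac = pk.TimeActivityCurve(sched, np.zeros(2))
        with pytest.raises(ValueError):
            pk.fit_model(tac, fdg_inputs, pk.ModelSpec("1C1i"))

    def test_deterministic_given_seed(self, fdg_inputs, fdg_schedule,
                                      irreversible_2c_spec, fdg_gb_params):
        noisy = pk.generate_tac(fdg_gb_params, irreversible_2c_spec,
                                fdg_inputs, fdg_schedule, pk.NoiseModel(), 5)
        f1 = pk.fit_model(noisy, fdg_inputs, irreversible_2c_spec, seed=3)
        f2 = pk.fit_model(noisy, fdg_inputs, irreversible_2c_spec, seed=3)
        assert f1.params.as_dict() == f2.params.as_dict()


class TestMacroParameters:
    @pytest.mark.parametrize("k1, k2, k3, ki_2dp", [
        (0.16, 0.19, 0.07, 0.04),   # glioblastoma FDG group means
        (0.17, 0.28, 0.04, 0.02),   # radiation-necrosis FDG group means
    ])
    def test_influx_rate_matches_reported_group_values(self, k1, k2, k3,
                                                       ki_2dp):
        macro = pk.macro_parameters(pk.KineticParams(K1=k1, k2=k2, k3=k3),
                                    "2C1i")
        assert round(macro.Ki, 2) == ki_2dp
        assert macro.Kp == pytest.approx(k3 / (k2 + k3))
        assert macro.Vd == pytest.approx(k1 / k2)

    def test_no_trapping_means_zero_influx(self):
        macro = pk.macro_parameters(pk.KineticParams(K1=0.1, k2=0.1, k3=0.0),
                                    "2C1i")
        assert macro.Ki == 0.0 and macro.Kp == 0.0

    def test_one_tissue_has_only_vd(self):
        macro = pk.macro_parameters(pk.KineticParams(K1=0.06, k2=0.05),
                                    "1C1i")
        assert macro.Ki is None and macro.Kp is None
        assert macro.Vd == pytest.approx(1.2)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            pk.macro_parameters(pk.KineticParams(K1=0.1, k2=0.0), "2C1i")


class TestMetabolicRate:
    def test_printed_constants_give_expected_rate(self):
        glu = pk.GlucoseInfo(plasma_glucose_mmol_l=3.44, lumped_constant=0.89)
        assert pk.metabolic_rate(0.04, glu) == pytest.approx(0.1546, abs=5e-5)
        assert pk.metabolic_rate(0.0, glu) == 0.0

    def test_zero_lumped_constant_rejected(self):
        with pytest.raises(ValueError):
            pk.GlucoseInfo(lumped_constant=0.0)


class TestModelSelection:
    def _criteria(self, ssr_target, n, p):
        y = np.linspace(1.0, 2.0, n)
        yhat = y + np.sqrt(ssr_target / n)
        return pk.model_selection_criteria(y, yhat, None, p)

    def test_extra_parameter_costs_two_aic_points(self):
        n = 40
        c1 = self._criteria(1.0, n, 3)
        c2 = self._criteria(1.0, n, 4)
        assert c2["aic"] - c1["aic"] == pytest.approx(2.0)

    def test_extra_parameter_costs_log_n_sc_points(self):
        n = 40
        c1 = self._criteria(1.0, n, 3)
        c2 = self._criteria(1.0, n, 4)
        assert c2["sc"] - c1["sc"] == pytest.approx(np.log(n))

    def test_perfect_fit_yields_sentinel(self):
        y = np.linspace(1.0, 2.0, 10)
        crit = pk.model_selection_criteria(y, y, None, 2)
        assert crit["perfect"]
        assert crit["aic"] == -np.inf and crit["msc"] == np.inf

    def test_preference_order_on_real_fits(self, fet_inputs, fet_schedule):
        """A one-tissue tracer is preferred as 1C1i over an overfitted 2C1i
        by SC on noisy data (the simpler model carries less penalty)."""
        truth = pk.KineticParams(K1=0.06, k2=0.05)
        tac = pk.generate_tac(truth, pk.ModelSpec("1C1i"), fet_inputs,
                              fet_schedule, pk.NoiseModel(), 11)
        fit1 = pk.fit_model(tac, fet_inputs, pk.ModelSpec("1C1i"), n_starts=3)
        fit2 = pk.fit_model(tac, fet_inputs,
                            pk.ModelSpec("2C1i", fixed={"k4": 0.0}),
                            n_starts=3)
        comp = pk.compare_models([fit1, fit2])
        assert comp.best_sc == "1C1i"

    def test_identical_fits_declared_tie(self, fet_inputs, fet_schedule):
        spec = pk.ModelSpec("1C1i")
        tac = pk.generate_tac(pk.KineticParams(K1=0.06, k2=0.05), spec,
                              fet_inputs, fet_schedule, pk.NoiseModel(), 2)
        fit = pk.fit_model(tac, fet_inputs, spec, n_starts=2)
        comp = pk.compare_models([fit, fit])
        assert any(name == "aic" for name, _ in comp.ties)

    def test_mismatched_data_raises(self, fet_inputs, fet_schedule,
                                    fdg_inputs, fdg_schedule):
        spec = pk.ModelSpec("1C1i")
        tac_a = pk.simulate_model(spec, pk.KineticParams(K1=0.06, k2=0.05),
                                  fet_inputs, fet_schedule)
        tac_b = pk.simulate_model(spec, pk.KineticParams(K1=0.06, k2=0.05),
                                  fdg_inputs, fdg_schedule)
        fit_a = pk.fit_model(tac_a, fet_inputs, spec, n_starts=1)
        fit_b = pk.fit_model(tac_b, fdg_inputs, spec, n_starts=1)
        with pytest.raises(ValueError):
            pk.compare_models([fit_a, fit_b])
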