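import numpy as np
import pytest

from fructolyse.config import read_timeseries
from fructolyse.diet import scenario_diets, zero_diet
from fructolyse.exchange import BloodState, evaluate_transports
from fructolyse.kinetics import HepaticState, RateVector, evaluate_hepatic_rates
from fructolyse.parameters import load_parameters
from fructolyse.simulator import (
    N_STATES,
    STATE_NAMES,
    FullState,
    SimulationError,
    assemble_derivatives,
    carbon_audit,
    default_initial_state,
    find_equilibrium,
    run_simulation,
    run_to_baseline,
)

FASTED = zero_diet()


def _idx(name):
    return STATE_NAMES.index(name)


def _fasted_equilibrium_guess():
    """Everything drained; glucagon at its fasted ceiling (2x basal)."""
    y = np.zeros(N_STATES)
    y[_idx("Gcg_SHB")] = 2.0
    y[_idx("Gcg_SBC")] = 2.0
    return y


class TestLayout:
    def test_twenty_five_states_in_documented_order(self):
        assert N_STATES == 25
        assert STATE_NAMES[0] == "Fru_SH"
        assert STATE_NAMES[11] == "Fru_SHB"
        assert STATE_NAMES[18] == "Fru_SBC"
        assert STATE_NAMES[16] == "Ins_SHB" and STATE_NAMES[24] == "Gcg_SBC"

    def test_fullstate_array_roundtrip(self, rng):
        y = rng.uniform(0, 100, N_STATES)
        assert np.array_equal(FullState.from_array(y).to_array(), y)


class TestAssembledDerivatives:
    def test_fasted_equilibrium_is_stationary(self, params):
        dy = assemble_derivatives(0.0, _fasted_equilibrium_guess(), params, FASTED)
        assert np.max(np.abs(dy)) < 1e-14

    def test_zero_state_metabolite_derivatives_vanish(self, params):
        """With no substrate anywhere only the hormone relaxation is active."""
        dy = assemble_derivatives(0.0, np.zeros(N_STATES), params, FASTED)
        hormone_rows = {_idx(n) for n in ("Ins_SHB", "Gcg_SHB", "Ins_SBC", "Gcg_SBC")}
        for i in range(N_STATES):
            if i not in hormone_rows:
                assert dy[i] == 0.0, STATE_NAMES[i]

    def test_hepatic_blood_loses_transport_times_rhe(self, params):
        """dFru_SHB = -T_Fru * R_HE when circulation is balanced."""
        y = np.zeros(N_STATES)
        y[_idx("Fru_SHB")] = 500.0
        y[_idx("Fru_SBC")] = 500.0  # no circulation gradient
        dy = assemble_derivatives(0.0, y, params, FASTED)
        t = evaluate_transports(
            BloodState(500.0, 0, 0, 0, 0, 0, 0),
            HepaticState(*[0.0] * 11),
            params,
        )
        assert dy[_idx("Fru_SHB")] == pytest.approx(-4.0 * t.T_Fru, rel=1e-12)

    def test_systemic_fructose_has_only_meal_and_circulation_terms(self, params):
        diet = scenario_diets()["fructose-100g"]
        y = np.zeros(N_STATES)
        y[_idx("Fru_SBC")] = 800.0
        t_mid = 2.0 * 3600.0  # meal peak
        dy = assemble_derivatives(t_mid, y, params, diet)
        from fructolyse.diet import meal_input_rate

        meal_fru, _ = meal_input_rate(diet, 2.0)
        circ_sbc = -params["R_BS"] * (800.0 - 0.0) / params["R_RL"] ** 2
        assert dy[_idx("Fru_SBC")] == pytest.approx(meal_fru + circ_sbc, rel=1e-12)

    def test_nonfinite_state_aborts_with_species_name(self, params):
        y = np.zeros(N_STATES)
        y[_idx("TG_SH")] = np.nan
        with pytest.raises(SimulationError, match="TG_SH"):
            assemble_derivatives(0.0, y, params, FASTED)


class TestCarbonAudit:
    def test_balanced_reactions_have_zero_residual(self, rng):
        rates = RateVector(*rng.uniform(0.1, 10, 16))
        for mode in ("paper-faithful", "carbon-consistent"):
            res = carbon_audit(rates, mode)
            for name in (
                "KHK", "aldB", "TPI_DHAP", "TPI_GA3P", "Tri", "PK", "PEPCK",
                "FAS", "boxi", "TGS", "GK", "G6Pase", "FBP", "PFK",
            ):
                assert res[name] == pytest.approx(0.0, abs=1e-12), (mode, name)

    def test_pyruvate_oxidation_releases_one_carbon(self, rng):
        rates = RateVector(*rng.uniform(0.1, 10, 16))
        for mode in ("paper-faithful", "carbon-consistent"):
            assert carbon_audit(rates, mode)["PDC"] == pytest.approx(
                -rates.R_PDC, rel=1e-12
            )

    def test_lipolysis_residual_is_glycerol_backbone_only_in_faithful_mode(
        self, rng
    ):
        rates = RateVector(*rng.uniform(0.1, 10, 16))
        assert carbon_audit(rates, "paper-faithful")["Lply"] == pytest.approx(
            -3.0 * rates.R_Lply, rel=1e-12
        )
        assert carbon_audit(rates, "carbon-consistent")["Lply"] == pytest.approx(
            0.0, abs=1e-12
        )


class TestIntegration:
    def test_trajectory_times_strictly_increasing(self, params, mixed_diet):
        res = run_simulation(default_initial_state(), params, mixed_diet, 1.0)
        assert np.all(np.diff(res.times_h) > 0)

    def test_determinism_bit_identical(self, params, mixed_diet):
        a = run_simulation(default_initial_state(), params, mixed_diet, 2.0)
        b = run_simulation(default_initial_state(), params, mixed_diet, 2.0)
        assert np.array_equal(a.states, b.states)

    def test_nonnegative_trajectories_all_presets(self, params, baseline_state):
        for name, diet in scenario_diets().items():
            res = run_simulation(baseline_state, params, diet, 12.0)
            col_max = np.maximum(res.states.max(axis=0), 1e-12)
            assert np.all(res.states >= -1e-6 * col_max), name

    def test_rhs_matches_finite_differences_of_trajectory(
        self, params, mixed_diet, baseline_state
    ):
        res = run_simulation(
            baseline_state, params, mixed_diet, 0.5, report_dt_min=1.0 / 30.0
        )
        t_s = res.times_h * 3600.0
        grad = np.gradient(res.states, t_s, axis=0)
        interior = slice(5, -5)
        for j in range(N_STATES):
            rhs = np.array(
                [
                    assemble_derivatives(t, y, params, mixed_diet)[j]
                    for t, y in zip(t_s[interior], res.states[interior])
                ]
            )
            scale = max(np.max(np.abs(rhs)), 1e-9)
            assert np.allclose(grad[interior, j], rhs, atol=0.02 * scale), (
                STATE_NAMES[j]
            )

    def test_csv_roundtrip_exact(self, params, mixed_diet, tmp_path):
        res = run_simulation(default_initial_state(), params, mixed_diet, 0.2)
        path = tmp_path / "traj.csv"
        res.to_csv(path)
        df = read_timeseries(path)
        assert list(df.columns) == ["time_h"] + STATE_NAMES
        assert np.array_equal(df[STATE_NAMES].to_numpy(), res.states)

    def test_circulation_alone_conserves_and_equilibrates(self):
        """With reactions, transports and meals off, circulation conserves
        volume-weighted moles and narrows the SHB/SBC gap monotonically."""
        off = {
            name: 1e-30
            for name in [
                "V_KHK", "V_aldB", "V_TPI_DHAP", "V_TPI_GA3P", "V_Tri", "V_PK",
                "V_PEPCK", "V_PDC", "V_FAS", "V_boxi", "V_TGS", "V_Lply",
                "V_GK", "V_G6Pase", "V_FBP", "V_PFK",
                "V_GLUT2pump", "V_GLUT2ex", "V_GLUT5pump", "V_GLUT5ex",
                "V_GLUTGpump", "V_GLUTGex", "V_Pyrex", "V_FAex", "V_active",
                "V_TGex", "V_out",
                "V_USE_Glu", "V_USE_FA", "V_USE_TG", "V_UP_FA", "V_UP_TG",
            ]
        }
        p = load_parameters(overrides=off)
        y0 = np.zeros(N_STATES)
        pairs = [("Fru", 900.0, 100.0), ("Glu", 50.0, 1500.0), ("TG", 0.0, 800.0)]
        for sp, shb0, sbc0 in pairs:
            y0[_idx(f"{sp}_SHB")] = shb0
            y0[_idx(f"{sp}_SBC")] = sbc0
        res = run_simulation(y0, p, FASTED, 2.0)
        v_l, v_r = p["V_liver"], p["V_body"] - p["V_liver"]
        for sp, shb0, sbc0 in pairs:
            shb = res[f"{sp}_SHB"]
            sbc = res[f"{sp}_SBC"]
            total = v_l * shb + v_r * sbc
            assert np.allclose(total, total[0], rtol=1e-6), sp
            gap = np.abs(shb - sbc)
            assert np.all(np.diff(gap) <= 1e-9 + 1e-6 * gap[0]), sp
            assert gap[-1] < 0.05 * gap[0], sp


class TestBaseline:
    def test_fasted_equilibrium_two_routes_agree(self, params):
        """Damped root-finding and long integration land on the same point."""
        eq_root = find_equilibrium(params)
        res = run_simulation(eq_root, params, FASTED, 12.0)
        floor = np.maximum(np.abs(eq_root), 1.0)
        drift = np.abs(res.final_state() - eq_root) / floor
        assert np.max(drift) < 1e-3

    def test_fasted_equilibrium_matches_analytic_point(self, params):
        eq = find_equilibrium(params)
        expected = _fasted_equilibrium_guess()
        assert np.allclose(eq, expected, atol=1e-6)

    def test_run_to_baseline_is_reproducible(self, params, mixed_diet, baseline_state):
        again = run_to_baseline(params, mixed_diet)
        assert np.array_equal(again, baseline_state)

    def test_daily_cycle_contracts(self, params, mixed_diet):
        """Under identical meal days the day-to-day displacement shrinks."""
        state = default_initial_state()
        dists = []
        for _ in range(3):
            res = run_simulation(state, params, mixed_diet, 24.0, report_dt_min=30.0)
            new = res.final_state()
            dists.append(np.linalg.norm(new - state))
            state = new
        assert dists[1] < dists[0]
        assert dists[2] < dists[1]

    def test_baseline_day_is_periodic(self, params, mixed_diet, baseline_state):
        """One full meal day from the converged 08:00 state returns to it."""
        res = run_simulation(
            baseline_state, params, mixed_diet, 24.0, report_dt_min=30.0
        )
        floor = np.maximum(np.abs(baseline_state), 1.0)
        drift = np.abs(res.final_state() - baseline_state) / floor
        assert np.max(drift) < 2e-3
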