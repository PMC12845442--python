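"""Coupled transport simulator: analytic limits, conservation, convergence."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.special import erfc

from oralpbpk.core import DoseEvent, OralPhysiology, to_canonical
from oralpbpk.pbpk import (
    SimulationGrid,
    biofilm_step,
    flux_saliva_mucosa,
    rhs_pellicle,
    rhs_pocket,
    rhs_saliva,
    rhs_tissue,
    simulate,
)
from oralpbpk.release import ReleaseModel

from conftest import MID_RANGE


@pytest.fixture
def canon(physiology):
    return to_canonical(physiology)


# ---------------------------------------------------------------------------
# single-equation right-hand sides
# ---------------------------------------------------------------------------

class TestSalivaBalance:
    def test_empty_system_is_at_rest(self, canon):
        assert rhs_saliva(0.0, 0.0, 0.0, canon, R_in=0.0) == 0.0

    def test_dilution_reduces_concentration_forty_percent_in_first_minute(self):
        """Resting flow 0.4 mL/min over 0.8 mL empties 50%/min; after one
        minute only e^{-1/2} ≈ 61% of a 2 mg/mL rinse remains."""
        p = OralPhysiology(
            **{**MID_RANGE, "P_SM": 0.0, "k_ads": 0.0, "k_des": 0.0,
               "A_SB": 0.0, "A_SP": 0.0, "Q_GCF": 0.0, "CL_local": 0.0}
        )
        grid = SimulationGrid(t_end=2.0, dt_out=0.25, n_x=20)
        res = simulate(p, grid=grid, initial={"C_S": 2000.0}, far_boundary="sealed")
        ratio = res.C_S[res.t == 1.0][0] / 2000.0
        assert ratio == pytest.approx(np.exp(-0.5), rel=1e-6)
        assert 100 * (1 - ratio) == pytest.approx(39.35, abs=0.05)

    def test_steady_infusion_approaches_rin_over_qs(self, canon):
        p = canon.replace(P_SM=0.0, k_ads=0.0, k_des=0.0, A_SB=0.0, A_SP=0.0,
                          R_in=40.0)
        grid = SimulationGrid(t_end=40.0, dt_out=1.0, n_x=20)
        res = simulate(p, grid=grid, far_boundary="sealed")
        c_ss = p.R_in / p.Q_S
        assert res.C_S[-1] == pytest.approx(c_ss, rel=1e-3)


class TestPellicleKinetics:
    def test_saturated_surface_only_desorbs(self, canon):
        d = rhs_pellicle(5.0, canon.Gamma_max, canon)
        assert d == pytest.approx(-canon.k_des * canon.Gamma_max)
        assert d <= 0.0

    def test_desorption_washout_is_first_order(self, canon):
        assert rhs_pellicle(0.0, 4.0, canon) == pytest.approx(-canon.k_des * 4.0)

    def test_langmuir_equilibrium_reached_in_simulation(self, canon):
        """At clamped C_S the surface settles at the Langmuir isotherm."""
        C_S = 8.0
        eq = canon.Gamma_max * canon.k_ads * C_S / (canon.k_ads * C_S + canon.k_des)
        sol = solve_ivp(
            lambda t, y: [rhs_pellicle(C_S, y[0], canon)], (0.0, 500.0), [0.0],
            rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(eq, rel=1e-6)


class TestInterfacialFlux:
    def test_partition_equilibrium_zeroes_flux(self, canon):
        assert flux_saliva_mucosa(3.0, 3.0 * canon.K_p_T, canon) == pytest.approx(0.0)

    def test_direct_substitution(self, canon):
        p = canon.replace(P_SM=1e-4)
        assert flux_saliva_mucosa(10.0, 0.0, p) == pytest.approx(1e-3)

    def test_antisymmetry_in_driving_gradient(self, canon):
        # states whose driving gradients are equal and opposite give
        # equal and opposite fluxes
        C_S, C_T = 4.0, 2.0
        g = C_S - C_T / canon.K_p_T
        C_S2 = C_T / canon.K_p_T - g  # gradient −g at the same C_T
        j1 = flux_saliva_mucosa(C_S, C_T, canon)
        j2 = flux_saliva_mucosa(C_S2, C_T, canon)
        assert j1 == pytest.approx(-j2, rel=1e-12)


class TestTissue:
    def test_rest_state(self, canon):
        assert rhs_tissue(0.0, 0.0, canon) == 0.0

    def test_fixed_saliva_steady_state(self, canon):
        C_S = 6.0
        c_ss = (
            canon.P_SM * canon.A_SM * C_S
            / (canon.P_SM * canon.A_SM / canon.K_p_T + canon.CL_local)
        )
        sol = solve_ivp(
            lambda t, y: [rhs_tissue(C_S, y[0], canon)], (0.0, 5e4), [0.0],
            rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(c_ss, rel=1e-5)

    def test_infinite_clearance_sink(self, canon):
        p = canon.replace(CL_local=1e6)
        sol = solve_ivp(
            lambda t, y: [rhs_tissue(5.0, y[0], p)], (0.0, 10.0), [0.0],
            method="BDF", rtol=1e-10, atol=1e-14,
        )
        assert sol.y[0, -1] < 1e-6


class TestBiofilm:
    def test_flat_profile_has_no_interior_dynamics(self, canon):
        p = canon.replace(k_bind=0.0)
        grid = SimulationGrid(t_end=10.0, n_x=50)
        C = np.full(50, 7.0)
        dC, J_SB, J_BP = biofilm_step(C, 7.0, p, grid, mode="sealed")
        np.testing.assert_allclose(dC, 0.0, atol=1e-12)
        assert J_SB == pytest.approx(0.0)
        assert J_BP == 0.0

    def test_early_time_profile_matches_semiinfinite_erfc(self, canon):
        """Before the front feels the far wall, the slab behaves as a
        semi-infinite medium: C/C0 = erfc(x / 2√(Dt))."""
        p = canon.replace(k_bind=0.0)
        n_x, C0, t_check = 200, 10.0, 1.0  # t ≪ L²/D ≈ 22 min
        grid = SimulationGrid(t_end=30.0, n_x=n_x)
        sol = solve_ivp(
            lambda t, y: biofilm_step(y, C0, p, grid, mode="sealed")[0],
            (0.0, t_check), np.zeros(n_x), method="BDF", rtol=1e-8, atol=1e-12,
        )
        x = np.linspace(0.0, p.L_B, n_x + 1)[1:]
        analytic = C0 * erfc(x / (2.0 * np.sqrt(p.D_eff * t_check)))
        assert np.max(np.abs(sol.y[:, -1] - analytic)) / C0 < 0.01

    def test_characteristic_diffusion_time_order_of_magnitude(self, canon):
        """L² /D for a 200 µm film at 3e-7 cm²/s is ≈ 1300 s; the simulated
        mid-film 50% rise time has the same order of magnitude."""
        p = canon.replace(k_bind=0.0)
        tau_min = p.L_B**2 / p.D_eff  # canonical: min
        assert tau_min * 60.0 == pytest.approx(1333.3, rel=1e-3)  # seconds
        n_x, C0 = 200, 1.0
        grid = SimulationGrid(t_end=120.0, n_x=n_x)
        sol = solve_ivp(
            lambda t, y: biofilm_step(y, C0, p, grid, mode="sealed")[0],
            (0.0, 120.0), np.zeros(n_x), method="BDF", rtol=1e-8, atol=1e-12,
            dense_output=True,
        )
        tt = np.linspace(0.05, 120.0, 4000)
        mid = sol.sol(tt)[n_x // 2 - 1]  # node at x = L/2
        t50 = tt[np.argmax(mid >= 0.5 * C0)]
        assert tau_min / 10 < t50 < tau_min * 10

    def test_unknown_boundary_mode_rejected(self, canon):
        grid = SimulationGrid(t_end=1.0, n_x=20)
        with pytest.raises(ValueError, match="far-boundary"):
            biofilm_step(np.zeros(20), 1.0, canon, grid, mode="open")


class TestPocket:
    def test_washout_half_life(self):
        """V_P·ln2/Q_GCF with V_P = 1 µL and Q_GCF = 0.3 µL/min is 2.3 min."""
        p = OralPhysiology(
            **{**MID_RANGE, "Q_S": 0.0, "P_SM": 0.0, "k_ads": 0.0, "k_des": 0.0,
               "A_SB": 0.0, "A_SP": 0.0, "CL_local": 0.0, "k_bind": 0.0}
        )
        t_half = 1.0 * np.log(2) / 0.3
        assert t_half == pytest.approx(2.3, abs=0.05)
        grid = SimulationGrid(t_end=10.0, dt_out=0.05, n_x=20)
        res = simulate(p, grid=grid, initial={"C_P": 100.0}, far_boundary="sealed")
        simulated = np.interp(50.0, res.C_P[::-1], res.t[::-1])
        assert simulated == pytest.approx(t_half, rel=0.01)

    def test_constant_source_steady_state(self, canon):
        R = 2.0  # µg/min straight into the pocket
        c_ss = R / canon.Q_GCF
        sol = solve_ivp(
            lambda t, y: [rhs_pocket(y[0], 0.0, R, canon)], (0.0, 60.0), [0.0],
            rtol=1e-10, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(c_ss, rel=1e-3)

    def test_rest_state(self, canon):
        assert rhs_pocket(0.0, 0.0, 0.0, canon) == 0.0


# ---------------------------------------------------------------------------
# full coupled system
# ---------------------------------------------------------------------------

RELEASE = ReleaseModel(
    "biphasic_burst_zero_order",
    {"burst_fraction": 0.4, "burst_rate": 4e-3, "zero_order_rate": 0.6 / 1000.0,
     "t_end": 1000.0},
)


class TestSimulate:
    def test_closed_system_conserves_mass(self, closed_physiology):
        grid = SimulationGrid(t_end=1000.0, dt_out=10.0, n_x=60)
        res = simulate(
            closed_physiology,
            doses=[DoseEvent(amount=500.0, route="saliva_bolus")],
            grid=grid,
            far_boundary="sealed",
        )
        assert res.mass_balance_error().max() < 1e-6
        # everything still resident somewhere
        assert res.stored_mass()[-1] == pytest.approx(500.0, rel=1e-6)

    def test_open_system_ledgers_close_the_balance(self, physiology):
        grid = SimulationGrid(t_end=300.0, dt_out=5.0, n_x=60)
        res = simulate(
            physiology,
            doses=[DoseEvent(amount=800.0, route="pocket_formulation", duration=1000.0)],
            release=RELEASE,
            grid=grid,
        )
        assert res.mass_balance_error().max() < 1e-6
        assert res.ledgers["gcf_washout"][-1] > 0.0
        assert res.ledgers["released"][-1] > 0.0

    def test_states_stay_non_negative(self, physiology):
        grid = SimulationGrid(t_end=120.0, dt_out=1.0, n_x=40)
        res = simulate(
            physiology, doses=[DoseEvent(amount=1000.0)], grid=grid,
            far_boundary="coupled",
        )
        for arr in (res.C_S, res.Gamma, res.C_T, res.C_P):
            assert np.all(arr >= 0.0)
        assert np.all(res.C_B >= 0.0)

    def test_bolus_jump_and_superposition(self, physiology):
        """With Langmuir binding off every term is linear, so doubling the
        dose exactly doubles every trajectory."""
        p = physiology.replace(k_ads=0.0, k_des=0.0)
        grid = SimulationGrid(t_end=60.0, dt_out=1.0, n_x=40, rtol=1e-11, atol=1e-13)
        res1 = simulate(p, doses=[DoseEvent(amount=400.0)], grid=grid,
                        far_boundary="coupled")
        res2 = simulate(p, doses=[DoseEvent(amount=800.0)], grid=grid,
                        far_boundary="coupled")
        for a, b in ((res1.C_S, res2.C_S), (res1.C_T, res2.C_T), (res1.C_P, res2.C_P)):
            scale = max(np.max(np.abs(b)), 1e-300)
            assert np.max(np.abs(2.0 * a - b)) / scale < 1e-8

    def test_pellicle_binding_is_nonlinear(self, physiology):
        """With binding on, superposition must fail (saturable capacity)."""
        grid = SimulationGrid(t_end=60.0, dt_out=1.0, n_x=40)
        res1 = simulate(physiology, doses=[DoseEvent(amount=4000.0)], grid=grid)
        res2 = simulate(physiology, doses=[DoseEvent(amount=8000.0)], grid=grid)
        dev = np.max(np.abs(2 * res1.Gamma - res2.Gamma)) / np.max(res2.Gamma)
        assert dev > 1e-3

    def test_pocket_auc_monotone_decreasing_in_gcf_flow(self, physiology):
        grid = SimulationGrid(t_end=400.0, dt_out=5.0, n_x=40)
        aucs = []
        for q in [0.1, 0.2, 0.3, 0.4, 0.5]:
            res = simulate(
                physiology.replace(Q_GCF=q),
                doses=[DoseEvent(amount=500.0, route="pocket_formulation",
                                 duration=1000.0)],
                release=RELEASE,
                grid=grid,
            )
            aucs.append(res.auc("pocket"))
        assert all(a > b for a, b in zip(aucs, aucs[1:]))

    def test_pocket_auc_monotone_in_dose(self, physiology):
        grid = SimulationGrid(t_end=200.0, dt_out=5.0, n_x=40)
        aucs = [
            simulate(physiology,
                     doses=[DoseEvent(amount=a, route="pocket_formulation",
                                      duration=1000.0)],
                     release=RELEASE, grid=grid).auc("pocket")
            for a in (100.0, 300.0, 900.0)
        ]
        assert aucs[0] < aucs[1] < aucs[2]

    def test_spatial_convergence_of_pocket_auc(self, physiology):
        """Halving the grid spacing moves the pocket AUC by well under 0.5%."""
        aucs = {}
        for n_x in (100, 200):
            grid = SimulationGrid(t_end=200.0, dt_out=5.0, n_x=n_x)
            aucs[n_x] = simulate(
                physiology,
                doses=[DoseEvent(amount=500.0)],
                grid=grid,
                far_boundary="coupled",
            ).auc("pocket")
        assert abs(aucs[200] - aucs[100]) / aucs[200] < 0.005

    def test_formulation_requires_release_model(self, physiology, fast_grid):
        with pytest.raises(ValueError, match="release model"):
            simulate(physiology,
                     doses=[DoseEvent(amount=100.0, route="pocket_formulation")],
                     grid=fast_grid)

    def test_infusion_delivers_exact_amount(self, closed_physiology):
        grid = SimulationGrid(t_end=100.0, dt_out=1.0, n_x=40)
        res = simulate(
            closed_physiology,
            doses=[DoseEvent(amount=300.0, route="saliva_infusion",
                             start=10.0, duration=30.0)],
            grid=grid,
            far_boundary="sealed",
        )
        assert res.ledgers["saliva_input"][-1] == pytest.approx(300.0, rel=1e-6)
        assert res.mass_balance_error().max() < 1e-6

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            SimulationGrid(t_end=0.0)
        with pytest.raises(ValueError):
            SimulationGrid(t_end=10.0, n_x=5)
        with pytest.raises(ValueError):
            SimulationGrid(t_end=10.0, rtol=0.5)
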