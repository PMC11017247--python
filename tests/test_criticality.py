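"""Coexistence fits, IAPWS-E fit, LLCP localisation, melting driver."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

import rwail
from rwail.criticality import (ALPHA_PRIME, CoexistencePoint, GAMMA_S,
                               MU_IAPWS, MeltingPointConfig, antoine_fit,
                               classify_end_state, critical_density_fit,
                               extrapolate_pc, iapws_classical, iapws_e_curve,
                               iapws_e_fit, locate_llcp,
                               melting_point_three_phase, slab_phase_densities,
                               tetrahedral_order, wegner_difference,
                               wegner_fit)
from rwail.fixtures import synth_curves


# ---------------------------------------------------------------- slabs
class TestSlabDensities:
    def make_profile(self, rho_l=950.0, rho_v=5.0, z0=50.0, t=18.0, d=2.5,
                     noise=0.0, seed=0):
        z = np.linspace(0, 100, 200)
        rho = rho_v + 0.5 * (rho_l - rho_v) * (
            np.tanh((z - z0 + t) / d) - np.tanh((z - z0 - t) / d))
        rho += noise * np.random.default_rng(seed).standard_normal(len(z))
        return z, rho

    def test_noiseless_recovery_below_point1_percent(self):
        z, rho = self.make_profile()
        rl, rv = slab_phase_densities(z, rho)
        assert rl == pytest.approx(950.0, rel=1e-3)
        assert rv == pytest.approx(5.0, abs=0.95)

    def test_recovers_bulk_densities_with_noise(self):
        z, rho = self.make_profile(noise=2.0)
        rl, rv = slab_phase_densities(z, rho)
        assert rl == pytest.approx(950.0, rel=3e-3)
        assert rv == pytest.approx(5.0, abs=1.5)

    def test_uniform_profile_signals_lost_coexistence(self):
        z = np.linspace(0, 100, 200)
        rho = np.full_like(z, 400.0)
        with pytest.raises(ValueError, match="coexistence"):
            slab_phase_densities(z, rho)

    def test_vacuum_vapor_region_gives_zero(self):
        """A histogrammed profile with truly empty vacuum bins."""
        z, rho = self.make_profile(rho_v=0.0)
        rho[rho < 1.0] = 0.0          # empty bins away from the slab
        rl, rv = slab_phase_densities(z, rho)
        assert rv == pytest.approx(0.0, abs=1e-6)
        assert rl == pytest.approx(950.0, rel=1e-3)


# ------------------------------------------------------------- Wegner fit
class TestWegnerFit:
    TRUE = {"T_c": 683.0, "B0": 1000.0, "B1": 0.35, "rho_c": 308.0,
            "c1": 450.0, "c2": 120.0}

    def make_points(self, noise=0.0, seed=0, n=8):
        T = np.linspace(325.0, 625.0, n)
        data, gt = synth_curves("coexistence_wegner", self.TRUE, T,
                                noise=noise, seed=seed)
        return [CoexistencePoint(T=t, rho_liquid=l, rho_vapor=v)
                for t, l, v in zip(data["T"], data["rho_liquid"],
                                   data["rho_vapor"])]

    def test_noiseless_recovery(self):
        fit = wegner_fit(self.make_points())
        assert fit["T_c"] == pytest.approx(self.TRUE["T_c"], rel=1e-6)
        assert fit["B0"] == pytest.approx(self.TRUE["B0"], rel=1e-6)
        assert fit["B1"] == pytest.approx(self.TRUE["B1"], rel=1e-4)

    def test_difference_vanishes_at_tc(self):
        assert wegner_difference(683.0, 683.0, 1000.0, [0.35]) == 0.0

    def test_exponents_are_fixed_not_fitted(self):
        fit = wegner_fit(self.make_points())
        assert fit.fixed == {"beta": 0.325, "Delta": 0.5}

    def test_noisy_recovery_unbiased_over_seeds(self):
        """1% noise, 20 seeds: the T_c estimator scatters around truth
        with |bias| below the ensemble confidence interval."""
        tcs = []
        for seed in range(20):
            pts = self.make_points(noise=3.0, seed=seed)   # ~1% of Δρ
            tcs.append(wegner_fit(pts)["T_c"])
        tcs = np.array(tcs)
        bias = tcs.mean() - self.TRUE["T_c"]
        ci = 3 * tcs.std(ddof=1) / math.sqrt(len(tcs))
        assert abs(bias) < max(ci, 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            wegner_fit(self.make_points()[:3])


class TestCriticalDensity:
    def test_symmetric_coexistence_gives_constant_diameter(self):
        T = np.linspace(350, 600, 8)
        pts = [CoexistencePoint(T=t, rho_liquid=400.0 + d, rho_vapor=400.0 - d)
               for t, d in zip(T, np.linspace(300, 80, 8))]
        fit = critical_density_fit(pts, T_c=683.0)
        assert fit["rho_c"] == pytest.approx(400.0, abs=1e-9)

    def test_noiseless_recovery(self):
        pts = TestWegnerFit().make_points()
        fit = critical_density_fit(pts, T_c=683.0)
        assert fit["rho_c"] == pytest.approx(308.0, rel=1e-10)
        assert fit.fixed["alpha_prime"] == ALPHA_PRIME

    def test_noisy_recovery_within_ci(self):
        rcs = []
        for seed in range(20):
            pts = TestWegnerFit().make_points(noise=3.0, seed=100 + seed)
            rcs.append(critical_density_fit(pts, T_c=683.0)["rho_c"])
        rcs = np.array(rcs)
        bias = rcs.mean() - 308.0
        assert abs(bias) < max(3 * rcs.std(ddof=1) / math.sqrt(20), 1.0)

    def test_supercritical_points_rejected(self):
        pts = [CoexistencePoint(T=700.0, rho_liquid=400, rho_vapor=300)]
        with pytest.raises(ValueError):
            critical_density_fit(pts, T_c=683.0)


class TestAntoine:
    TRUE = {"A": 10.83, "B": 3800.0, "C": -40.0}

    def test_three_exact_points_determined_system(self):
        T = np.array([350.0, 450.0, 550.0])
        data, _ = synth_curves("antoine", self.TRUE, T)
        fit = antoine_fit(data["T"], data["P"])
        for k in ("A", "B", "C"):
            assert fit[k] == pytest.approx(self.TRUE[k], rel=1e-6)

    def test_zero_b_constant_pressure(self):
        T = np.linspace(300, 600, 5)
        data, _ = synth_curves("antoine", {"A": 2.0, "B": 0.0, "C": 10.0}, T)
        assert np.allclose(data["P"], math.exp(2.0))

    def test_critical_pressure_closed_form(self):
        T = np.linspace(325, 625, 8)
        data, _ = synth_curves("antoine", self.TRUE, T)
        fit = antoine_fit(data["T"], data["P"])
        pc = extrapolate_pc(fit, 683.0)
        want = math.exp(self.TRUE["A"] - self.TRUE["B"] / (683.0 + self.TRUE["C"]))
        assert pc == pytest.approx(want, rel=1e-6)

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            antoine_fit(np.array([300.0, 400, 500]), np.array([1.0, -2.0, 3.0]))


# ------------------------------------------------------------- IAPWS-E
class TestIapwsE:
    RWAIL_ROW = {"T_c": 683.0, "B": 243.057, "b": -0.727, "c": 0.0872,
                 "T_e": 237.653}

    def make_curve(self, noise=0.0, seed=0):
        T = np.concatenate([np.linspace(242.0, 320.0, 12),
                            np.linspace(340.0, 560.0, 8)])
        data, gt = synth_curves("gamma_iapws_e", self.RWAIL_ROW, T,
                                noise=noise, seed=seed)
        return data, gt

    def test_noiseless_recovery(self):
        data, _ = self.make_curve()
        fit = iapws_e_fit(data["T"], data["gamma"], T_c=683.0)
        assert fit["B"] == pytest.approx(243.057, rel=1e-5)
        assert fit["b"] == pytest.approx(-0.727, rel=1e-4)
        assert fit["c"] == pytest.approx(0.0872, rel=1e-3)
        assert fit["T_e"] == pytest.approx(237.653, abs=0.05)
        assert fit.emergence_detected

    def test_deviation_at_te_is_exactly_gamma_s(self):
        """By the γ_s convention, the fitted curve sits exactly 1 mN/m
        above the classical IAPWS term at T = T_e."""
        data, _ = self.make_curve()
        fit = iapws_e_fit(data["T"], data["gamma"], T_c=683.0)
        te = fit["T_e"]
        full = iapws_e_curve(te, 683.0, fit["B"], fit["b"], fit["c"], te)
        classical = iapws_classical(te, 683.0, fit["B"], fit["b"])
        assert full - classical == pytest.approx(GAMMA_S, rel=1e-12)

    def test_null_emergence_reported_not_detected(self):
        T = np.linspace(250.0, 550.0, 15)
        gamma = iapws_classical(T, 683.0, 243.057, -0.727)
        fit = iapws_e_fit(T, gamma, T_c=683.0)
        assert not fit.emergence_detected
        assert math.isnan(fit["T_e"])

    def test_point_order_invariance(self):
        data, _ = self.make_curve(noise=0.2, seed=3)
        fit1 = iapws_e_fit(data["T"], data["gamma"], T_c=683.0)
        perm = np.random.default_rng(0).permutation(len(data["T"]))
        fit2 = iapws_e_fit(data["T"][perm], data["gamma"][perm], T_c=683.0)
        assert fit1["T_e"] == pytest.approx(fit2["T_e"], rel=1e-8)

    def test_weight_affine_invariance(self):
        data, _ = self.make_curve(noise=0.2, seed=4)
        err = np.full(len(data["T"]), 0.2)
        fit1 = iapws_e_fit(data["T"], data["gamma"], T_c=683.0, stderr=err)
        fit2 = iapws_e_fit(data["T"], data["gamma"], T_c=683.0,
                           stderr=err * 7.5)
        assert fit1["B"] == pytest.approx(fit2["B"], rel=1e-6)

    def test_tc_is_fixed_input(self):
        data, _ = self.make_curve()
        fit = iapws_e_fit(data["T"], data["gamma"], T_c=683.0)
        assert fit.fixed["T_c"] == 683.0
        assert fit.fixed["mu"] == MU_IAPWS

    def test_no_supercooled_points_unidentifiable(self):
        T = np.linspace(330.0, 550.0, 10)
        gamma = iapws_classical(T, 683.0, 243.0, -0.7)
        with pytest.raises(ValueError, match="unidentifiable"):
            iapws_e_fit(T, gamma, T_c=683.0)


# ------------------------------------------------------------------ LLCP
def vdw_density(T, P, Tc, Pc, rhoc):
    """Equilibrium density of a van der Waals fluid (Maxwell built in
    by picking the branch of lower Gibbs energy) — analytic oracle."""
    # reduced: (p + 3/v²)(3v − 1) = 8t  with v = rhoc/rho
    t, p = T / Tc, P / Pc
    # (p + 3/v²)(3v − 1) = 8t  ⇒  3p v³ − (p + 8t) v² + 9v − 3 = 0
    roots = np.roots([3 * p, -(p + 8 * t), 9, -3])
    real = np.array([r.real for r in roots
                     if abs(r.imag) < 1e-9 and r.real > 1.0 / 3.0])
    if len(real) == 1:
        return rhoc / real[0]

    def g_res(v):
        # reduced Gibbs-like potential along the isotherm
        return (-8 * t / 3 * math.log(v - 1 / 3) - 3 / v + p * v)

    v = min(real, key=g_res)
    return rhoc / v


def vdw_kappa(T, P, Tc, Pc, rhoc):
    """κ_T of the vdW fluid at the equilibrium branch (numeric dP/dv)."""
    rho = vdw_density(T, P, Tc, Pc, rhoc)
    v = rhoc / rho
    t = T / Tc
    # p(v) = 8t/(3v−1) − 3/v²  ⇒  dp/dv = −24t/(3v−1)² + 6/v³
    dPdv = Pc * (-24 * t / (3 * v - 1) ** 2 + 6 / v ** 3)
    if dPdv >= 0:
        return 1e9
    return -1.0 / (v * dPdv)


class TestLocateLlcp:
    TC, PC, RHOC = 203.0, 90.0, 980.0

    def make_grids(self, nT=25, nP=9):
        T = np.linspace(185.0, 221.0, nT)
        P = np.linspace(66.0, 114.0, nP)
        rho = np.array([[vdw_density(t, p, self.TC, self.PC, self.RHOC)
                         for p in P] for t in T])
        kap = np.array([[min(vdw_kappa(t, p, self.TC, self.PC, self.RHOC), 50.0)
                         for p in P] for t in T])
        return T, P, kap, rho

    def test_recovers_vdw_critical_point_within_one_cell(self):
        T, P, kap, rho = self.make_grids()
        est = locate_llcp(T, P, kap, rho)
        assert est.bracketed
        dT = T[1] - T[0]
        dP = P[1] - P[0]
        assert abs(est.T - self.TC) <= max(dT, est.dT) + 1e-9
        assert abs(est.P - self.PC) <= max(dP, est.dP) + 1e-9
        assert est.rho == pytest.approx(self.RHOC, rel=0.08)

    def test_featureless_grids_report_no_llcp(self):
        T = np.linspace(185.0, 221.0, 10)
        P = np.linspace(60.0, 120.0, 5)
        rho = 900.0 + np.outer(np.linspace(0, 5, 10), np.ones(5))
        kap = np.full((10, 5), 2.0)
        est = locate_llcp(T, P, kap, rho)
        assert not est.bracketed
        assert est.T is None and est.P is None
        assert "no LLCP" in est.detail["verdict"]

    def test_refining_a_bracketing_grid_narrows_the_bracket(self):
        T1, P1, k1, r1 = self.make_grids(nT=15, nP=5)
        est1 = locate_llcp(T1, P1, k1, r1)
        T2, P2, k2, r2 = self.make_grids(nT=29, nP=13)
        est2 = locate_llcp(T2, P2, k2, r2)
        assert est1.bracketed and est2.bracketed
        assert est2.dP <= est1.dP + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            locate_llcp(np.arange(3.0), np.arange(4.0), np.zeros((3, 3)),
                        np.zeros((3, 3)))


# ------------------------------------------------- melting point driver
class TestMeltingPoint:
    def test_classifier_fires_on_ice_and_liquid(self):
        """Tetrahedral order separates the ice-Ih lattice from a dense
        random (liquid-like) O arrangement."""
        ice = rwail.build_ice_ih((2, 2, 2), seed=0)
        q_ice = tetrahedral_order(ice.o_positions, ice.box).mean()
        assert q_ice > 0.95
        assert classify_end_state(ice.o_positions, ice.box) == "ice"
        rng = np.random.default_rng(1)
        box = np.full(3, 12.4)
        liquidish = rng.uniform(0, 12.4, size=(64, 3))
        assert classify_end_state(liquidish, box) == "liquid"

    def test_bisection_brackets_known_transition(self):
        """Stub propagation melting above 270 K: the driver bisects the
        bracket onto the transition temperature."""
        ice = rwail.build_ice_ih((2, 2, 2), seed=0)
        rng = np.random.default_rng(2)
        liquid = rng.uniform(0, ice.box, size=(len(ice.o_positions), 3))

        def propagate(T):
            return (liquid if T > 270.0 else ice.o_positions), ice.box

        cfg = MeltingPointConfig(T_high=280.0, T_low=260.0,
                                 max_bisections=6, propagate=propagate)
        est = melting_point_three_phase(cfg)
        lo, hi = est.bracket
        assert lo <= 270.0 <= hi + 0.5
        assert hi - lo < 2.0
        assert not est.ambiguous

    def test_ambiguous_end_state_widens_and_flags(self):
        ice = rwail.build_ice_ih((2, 2, 2), seed=0)

        def propagate(T):
            return ice.o_positions, ice.box

        cfg = MeltingPointConfig(T_high=280.0, T_low=260.0, max_bisections=4,
                                 propagate=propagate,
                                 classify=lambda pos, box: "ambiguous")
        est = melting_point_three_phase(cfg)
        assert est.ambiguous
        assert est.bracket == (260.0, 280.0)

    def test_missing_propagate_rejected(self):
        with pytest.raises(ValueError):
            melting_point_three_phase(MeltingPointConfig())
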