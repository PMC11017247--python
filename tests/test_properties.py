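"""Property estimators against generator ground truth and arithmetic
oracles."""

import math

import numpy as np
import pytest

import rwail
from rwail.constants import KB
from rwail.fixtures import synth_series
from rwail.properties import (TimeSeries, block_average, delta_h_vap,
                              dielectric_constant, diffusion_einstein,
                              ensemble_geometry, heat_capacity_fd, kappa_T,
                              model_dipole_debye, rdf,
                              self_polarization_energy, surface_tension)


class TestBlockAverage:
    def test_requires_five_blocks(self):
        with pytest.raises(ValueError):
            block_average(np.arange(100.0), n_blocks=3)

    def test_stderr_positive_for_noisy_series(self):
        rng = np.random.default_rng(0)
        m, s = block_average(rng.normal(size=1000))
        assert s > 0


class TestKappaT:
    def test_constant_volume_gives_zero(self):
        ts = TimeSeries("V", np.full(500, 30000.0), 1.0, "A^3")
        assert kappa_T(ts, 298.0).value == 0.0

    def test_recovers_generator_ground_truth(self):
        ts, gt = synth_series("volume", {"mean_A3": 51000.0, "T_K": 298.0,
                                         "kappa_MPa": 5.74e-4},
                              length=4000, seed=1)
        est = kappa_T(ts, 298.0)
        assert abs(est.value - gt.derived["kappa_MPa"]) < 3 * est.stderr

    def test_linear_in_fluctuation_variance(self):
        ts, _ = synth_series("volume", {"mean_A3": 51000.0, "std_A3": 40.0},
                             length=2000, seed=2)
        v = ts.values
        doubled = TimeSeries("V", v.mean() + (v - v.mean()) * math.sqrt(2),
                             1.0, "A^3")
        k1 = kappa_T(ts, 298.0, discard=0.0).value
        k2 = kappa_T(doubled, 298.0, discard=0.0).value
        assert k2 == pytest.approx(2 * k1, rel=1e-10)

    def test_nonpositive_temperature_rejected(self):
        ts = TimeSeries("V", np.ones(200), 1.0, "A^3")
        with pytest.raises(ValueError):
            kappa_T(ts, -1.0)


class TestHeatCapacity:
    def test_linear_enthalpy_slope(self):
        """H exactly linear in T with slope s per molecule gives C_p = s."""
        n = 64
        s_kcal = 0.018                 # kcal/mol/K per molecule
        h1 = TimeSeries("H", np.full(600, 295.0 * s_kcal * n), 1.0, "kcal/mol")
        h2 = TimeSeries("H", np.full(600, 301.0 * s_kcal * n), 1.0, "kcal/mol")
        est = heat_capacity_fd(h1, 295.0, h2, 301.0, n)
        assert est.value == pytest.approx(s_kcal * 4184.0, rel=1e-12)

    def test_arithmetic_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(-7000.0, 2.0, size=1000)
        b = rng.normal(-6950.0, 2.0, size=1000)
        est = heat_capacity_fd(TimeSeries("H", a), 295.0,
                               TimeSeries("H", b), 301.0, 32)
        m1 = np.mean(a[100:])          # default 10% discard
        m2 = np.mean(b[100:])
        want = (m2 - m1) / 6.0 / 32 * 4184.0
        assert est.value == pytest.approx(want, rel=1e-12)

    def test_argument_order_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.normal(-7000.0, 2.0, size=600)
        b = rng.normal(-6950.0, 2.0, size=600)
        e1 = heat_capacity_fd(TimeSeries("H", a), 295.0,
                              TimeSeries("H", b), 301.0, 32)
        e2 = heat_capacity_fd(TimeSeries("H", b), 301.0,
                              TimeSeries("H", a), 295.0, 32)
        assert e1.value == pytest.approx(e2.value, rel=1e-14)

    def test_equal_temperatures_rejected(self):
        ts = TimeSeries("H", np.ones(200))
        with pytest.raises(ValueError):
            heat_capacity_fd(ts, 298.0, ts, 298.0, 10)


class TestDeltaHVap:
    def test_noninteracting_limit_is_rt(self):
        """⟨V_gas⟩ = ⟨V_liq⟩/N and ΔE_self = 0 leaves only RT."""
        n = 50
        gas = TimeSeries("Vg", np.full(400, -2.0))
        liq = TimeSeries("Vl", np.full(400, -2.0 * n))
        est = delta_h_vap(liq, n, gas, 298.0)
        assert est.value == pytest.approx(KB * 298.0 * 4.184, rel=1e-12)

    def test_arithmetic_oracle(self):
        n = 32
        gas = TimeSeries("Vg", np.full(400, 0.37))
        liq = TimeSeries("Vl", np.full(400, -360.0))
        est = delta_h_vap(liq, n, gas, 298.0, dE_self_kJ=-2.5)
        want = (0.37 + 360.0 / 32 + KB * 298.0) * 4.184 - 2.5
        assert est.value == pytest.approx(want, rel=1e-12)

    def test_self_energy_shifts_linearly(self):
        n = 32
        gas = TimeSeries("Vg", np.full(300, 0.5))
        liq = TimeSeries("Vl", np.full(300, -350.0))
        base = delta_h_vap(liq, n, gas, 298.0, dE_self_kJ=0.0).value
        shifted = delta_h_vap(liq, n, gas, 298.0, dE_self_kJ=-3.0).value
        assert shifted - base == pytest.approx(-3.0, abs=1e-12)

    def test_missing_gas_series_rejected(self):
        liq = TimeSeries("Vl", np.full(300, -350.0))
        with pytest.raises(ValueError):
            delta_h_vap(liq, 32, None, 298.0)

    def test_self_polarization_term_magnitude(self, params_flexible):
        """The self-polarization correction for the model's gas-phase
        dipole (≈2.2 D) is a negative few-kJ/mol term."""
        mu = model_dipole_debye(params_flexible)
        de = self_polarization_energy(mu)
        assert 2.1 < mu < 2.3
        assert -6.0 < de < -0.5


class TestDielectric:
    def test_zero_fluctuation_gives_baseline(self):
        m = np.tile([3.0, -1.0, 0.5], (400, 1))
        est = dielectric_constant(TimeSeries("M", m), 30000.0, 298.0)
        assert est.value == pytest.approx(1.78, abs=1e-12)
        assert est.annotations["epsilon_raw"] == pytest.approx(1.0, abs=1e-12)

    def test_recovers_generator_ground_truth(self):
        ts, gt = synth_series("dipole", {"V_A3": 51000.0, "T_K": 298.0,
                                         "epsilon_raw": 78.0},
                              length=6000, seed=5)
        est = dielectric_constant(ts, 51000.0, 298.0)
        raw = est.annotations["epsilon_raw"]
        assert abs(raw - gt.derived["epsilon_raw"]) < 3 * est.stderr

    def test_volume_scaling(self):
        ts, _ = synth_series("dipole", {"V_A3": 30000.0, "std_eA": 10.0},
                             length=2000, seed=6)
        e1 = dielectric_constant(ts, 30000.0, 298.0).annotations["epsilon_raw"]
        e2 = dielectric_constant(ts, 60000.0, 298.0).annotations["epsilon_raw"]
        assert (e2 - 1.0) == pytest.approx((e1 - 1.0) / 2.0, rel=1e-12)

    def test_invalid_inputs_rejected(self):
        ts = TimeSeries("M", np.zeros((100, 3)))
        with pytest.raises(ValueError):
            dielectric_constant(ts, -1.0, 298.0)


class TestDiffusion:
    def test_frozen_positions_give_zero(self):
        pos = np.tile(np.random.default_rng(0).normal(size=(20, 3)), (50, 1, 1))
        est = diffusion_einstein(pos, dt=1.0)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_recovers_random_walk_ground_truth(self):
        pos, gt = synth_series("msd_walk", {"D_1e5_cm2_s": 1.89,
                                            "n_particles": 60},
                               length=400, seed=7, dt=0.5)
        est = diffusion_einstein(pos, dt=0.5)
        assert abs(est.value - 1.89) < max(3 * est.stderr, 0.15)

    def test_drift_flags_nondiffusive_regime(self):
        t = np.arange(200)[:, None, None]
        pos = np.zeros((200, 5, 3)) + 0.05 * t ** 2 * np.ones((1, 5, 3))
        est = diffusion_einstein(pos, dt=1.0)
        assert est.annotations["nondiffusive_regime_flag"]

    def test_wrapped_input_detected(self):
        pos = np.zeros((50, 4, 3))
        pos[25:, :, 0] += 30.0          # jump > box/2
        with pytest.raises(ValueError, match="unwrapped"):
            diffusion_einstein(pos, dt=1.0,
                               box_for_wrap_check=np.full(3, 20.0))

    def test_quantum_annotation_reported_not_applied(self):
        pos, _ = synth_series("msd_walk", {"D_1e5_cm2_s": 2.0,
                                           "n_particles": 30},
                              length=300, seed=8, dt=0.5)
        est = diffusion_einstein(pos, dt=0.5)
        assert est.annotations["D_quantum_corrected"] == pytest.approx(
            est.value * 1.15, rel=1e-12)


class TestSurfaceTension:
    def test_isotropic_tensor_gives_zero(self):
        iso = TimeSeries("P", np.full(500, -37.0), 1.0, "bar")
        est = surface_tension(iso, iso, iso, L_z=100.0)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_hand_unit_conversion_oracle(self):
        """ΔP = 100 bar at L_z = 100 Å: γ = 50 bar·Å = 50 mN/m... by
        hand: (100/2 Å)·(100 bar)·(10⁻² mN/m per bar·Å)."""
        lat = TimeSeries("P", np.full(500, -80.0), 1.0, "bar")
        nor = TimeSeries("P", np.full(500, 20.0), 1.0, "bar")
        est = surface_tension(lat, lat, nor, L_z=100.0)
        assert est.value == pytest.approx(0.5 * 100.0 * 100.0 * 1e-2,
                                          rel=1e-12)

    def test_linear_in_anisotropy(self):
        comps, gt = synth_series("pressure_tensor",
                                 {"mean_lateral_bar": -120.0,
                                  "mean_normal_bar": 15.0, "std_bar": 0.0,
                                  "L_z_A": 100.0}, length=300, seed=9)
        est = surface_tension(comps["P_xx"], comps["P_yy"], comps["P_zz"],
                              100.0)
        assert est.value == pytest.approx(gt.derived["gamma_mN_m"], rel=1e-12)
        # doubling (P_N − P_lat) doubles gamma
        doubled_pn = TimeSeries("P", -120.0 + 2 * (comps["P_zz"].values + 120.0),
                                1.0, "bar")
        est2 = surface_tension(comps["P_xx"], comps["P_yy"], doubled_pn, 100.0)
        assert est2.value == pytest.approx(2 * est.value, rel=1e-12)

    def test_missing_components_rejected(self):
        ts = TimeSeries("P", np.ones(100))
        with pytest.raises(ValueError):
            surface_tension(ts, None, ts, 100.0)


class TestRdf:
    def test_ideal_gas_is_unity(self):
        rng = np.random.default_rng(10)
        box = np.full(3, 20.0)
        frames = [rng.uniform(0, 20.0, size=(200, 3)) for _ in range(40)]
        idx = np.arange(200)
        r, g = rdf(frames, box, idx, idx, bin_width=0.5, r_max=9.0)
        sel = r > 1.0
        assert np.abs(g[sel] - 1.0).max() < 0.2
        assert g[sel].mean() == pytest.approx(1.0, abs=0.02)

    def test_two_fixed_particles_single_bin(self):
        """Two particles at distance d: one peak whose integral counts
        exactly one neighbor."""
        box = np.full(3, 20.0)
        d = 3.3
        frames = [np.array([[1.0, 1.0, 1.0], [1.0 + d, 1.0, 1.0]])]
        idx = np.arange(2)
        r, g = rdf(frames, box, idx, idx, bin_width=0.2, r_max=9.0)
        nz = np.nonzero(g)[0]
        assert len(nz) == 1
        assert abs(r[nz[0]] - d) < 0.2
        # integral of rho*g over the peak shell = 1 neighbor
        shell = 4 * math.pi * r[nz[0]] ** 2 * 0.2
        rho_pair = 1.0 / box.prod()       # one ordered pair per particle
        assert g[nz[0]] * rho_pair * shell == pytest.approx(1.0, rel=0.05)

    def test_hard_contact_zero(self, liquid32_flexible):
        state, _ = liquid32_flexible
        o_idx = np.arange(state.n_sites)[0::3]
        r, g = rdf([state.positions], state.box, o_idx, o_idx,
                   bin_width=0.1, r_max=4.0)
        assert np.all(g[r < 2.2] == 0.0)

    def test_rmax_beyond_half_box_rejected(self):
        box = np.full(3, 10.0)
        with pytest.raises(ValueError):
            rdf([np.zeros((4, 3))], box, np.arange(4), np.arange(4),
                r_max=6.0)


class TestEnsembleGeometry:
    def test_right_angle_identity(self, params_flexible):
        """⟨OH⟩ = 1 and ⟨HH⟩ = √2 imply a 90° HOH angle."""
        mol = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
        r_e, th = ensemble_geometry([mol], params_flexible)
        assert r_e == pytest.approx(1.0, abs=1e-12)
        assert th == pytest.approx(90.0, abs=1e-10)

    def test_inverse_formula_round_trip(self, params_flexible):
        """A static molecule at the EG298 geometry maps back to its own
        (r_e, θ_e) through the distance-based definition."""
        r_e, th_deg = 0.9706, 105.25
        th = math.radians(th_deg)
        mol = np.array([
            [0.0, 0, 0],
            [r_e * math.sin(th / 2), 0, r_e * math.cos(th / 2)],
            [-r_e * math.sin(th / 2), 0, r_e * math.cos(th / 2)]])
        got_r, got_th = ensemble_geometry([mol], params_flexible)
        assert got_r == pytest.approx(r_e, abs=1e-12)
        assert got_th == pytest.approx(th_deg, abs=1e-10)
        # and the implied HH distance closes the loop
        hh = np.linalg.norm(mol[2] - mol[1])
        assert hh == pytest.approx(2 * r_e * math.sin(th / 2), rel=1e-12)

    def test_rigid_trajectory_rejected(self, params_eg273):
        with pytest.raises(ValueError, match="flexible"):
            ensemble_geometry([np.zeros((3, 3))], params_eg273)
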