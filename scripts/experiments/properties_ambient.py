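#!/usr/bin/env python
"""Ambient liquid properties at the published protocol sizes.

Full protocol: a 1728-molecule box; EG298 for ε (5 ns dipole variance,
NVT), C_p (two 15 ns NPT runs at 295 and 301 K, finite difference) and
κ_T (NPT volume fluctuations at 298 K, 1 bar); the flexible variant at
0.5 fs for D (5 ns NVT, Einstein relation) and ΔH_vap (liquid series
plus a single-molecule gas run at 298 K).  Cutoffs 1.0 nm with
long-range corrections; Nosé–Hoover τ_T = 2 ps (NPT) / 5 ps (NVT);
isotropic barostat τ_P = 5 ps.

Expected wall time at --scale 1: days on one CPU; use a large --scale
divisor for smoke runs.
"""

import argparse
import json

import numpy as np

import rwail
from rwail.ewald import EwaldParams
from rwail.forces import CutoffScheme, ForceField, minimize_energy
from rwail.properties import (TimeSeries, delta_h_vap, dielectric_constant,
                              diffusion_einstein, heat_capacity_fd, kappa_T,
                              model_dipole_debye, self_polarization_energy)


def build(variant, n, seed, r_cut=10.0):
    p = rwail.load_parameters(variant)
    st = rwail.build_water_box(n, 997.0, seed=seed, r_e=p.r_e,
                               theta_e_deg=p.theta_e)
    # headroom below L/2: the box shrinks under the barostat
    rc = min(r_cut, st.box[0] / 2 * 0.85)
    ff = ForceField(p, EwaldParams(r_cut=rc), CutoffScheme(r_cut_vdw=rc))
    return minimize_energy(st, ff), ff


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scale", type=int, default=1,
                    help="divide system size and run length by this")
    ap.add_argument("--out", default="properties_ambient.json")
    args = ap.parse_args()
    s = args.scale
    n = max(27, 1728 // s)
    report = {}

    # --- kappa_T and C_p: EG298 NPT at 295/298/301 K -------------------
    st, ff = build("EG298", n, args.seed)
    series = {}
    for T in (295.0, 298.0, 301.0):
        tr = rwail.run_npt(st, ff, rwail.ThermostatParams(T, tau_t=2.0),
                           rwail.BarostatParams(1.0, tau_p=5.0),
                           n_steps=max(2000, 7_500_000 // s), dt=0.002,
                           seed=args.seed + int(T), sample_every=20)
        series[T] = tr
    kap = kappa_T(TimeSeries("V", series[298.0]["V"], 0.1, "A^3"), 298.0)
    report["kappa_T_1e-4_MPa-1"] = kap.value * 1e4
    # enthalpy H = U + P V (P V in kcal/mol via the bar·Å³ conversion)
    from rwail.constants import P_INTERNAL_TO_BAR
    h = {T: (series[T]["E_pot"] + series[T]["E_kin"]
             + series[T]["P"] * series[T]["V"] / P_INTERNAL_TO_BAR)
         for T in (295.0, 301.0)}
    cp = heat_capacity_fd(TimeSeries("H", h[295.0]), 295.0,
                          TimeSeries("H", h[301.0]), 301.0, n)
    report["cp_J_mol_K"] = cp.value

    # --- dielectric constant: EG298 NVT, 5 ns dipole variance ----------
    tr = rwail.run_nvt(st, ff, rwail.ThermostatParams(298.0, tau_t=5.0),
                       n_steps=max(800, 2_500_000 // s), dt=0.002,
                       seed=args.seed + 7, sample_every=25)
    M = np.column_stack([tr["M_x"], tr["M_y"], tr["M_z"]])
    eps = dielectric_constant(TimeSeries("M", M, 0.05, "e*A"),
                              st.volume, 298.0)
    report["epsilon"] = eps.value
    report["epsilon_raw"] = eps.annotations["epsilon_raw"]

    # --- diffusion + ΔH_vap: flexible model at 0.5 fs ------------------
    stf, fff = build("flexible", n, args.seed + 11)
    trf = rwail.run_nvt(stf, fff, rwail.ThermostatParams(298.0, tau_t=5.0),
                        n_steps=max(1500, 10_000_000 // s), dt=0.0005,
                        seed=args.seed + 13, sample_every=100,
                        track_unwrapped=True)
    d = diffusion_einstein(trf["O_unwrapped"], dt=0.05,
                           box_for_wrap_check=None)
    report["diffusion_1e-5_cm2_s"] = d.value
    report["diffusion_quantum_corrected"] = d.annotations["D_quantum_corrected"]

    gas = stf.copy()
    gas.positions = gas.positions[:3]
    gas.velocities = gas.velocities[:3]
    gas.box = np.full(3, 30.0)
    gff = ForceField(fff.params, EwaldParams(r_cut=8.0),
                     CutoffScheme(r_cut_vdw=8.0, apply_lrc_energy=False,
                                  apply_lrc_pressure=False),
                     enable_coulomb=False, enable_vdw=False, enable_hb=False)
    trg = rwail.run_nvt(gas, gff, rwail.ThermostatParams(298.0, tau_t=0.05),
                        n_steps=max(4000, 2_000_000 // s), dt=0.0005,
                        seed=args.seed + 17, sample_every=20)
    dhv = delta_h_vap(TimeSeries("Vl", trf["E_pot"]), n,
                      TimeSeries("Vg", trg["E_pot"]), 298.0,
                      dE_self_kJ=self_polarization_energy(
                          model_dipole_debye(fff.params)),
                      quantum_correction_kJ=-6.0)
    report["dh_vap_kJ_mol"] = dhv.value
    report["dh_vap_terms"] = dhv.annotations

    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    print(json.dumps(report, indent=2, default=float))


if __name__ == "__main__":
    main()
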