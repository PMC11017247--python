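#!/usr/bin/env python
"""Liquid–liquid critical point scan in the supercooled regime.

Full protocol: NPT simulations of a 343-molecule EG273 box on a (T, P)
grid above 190 K and up to 1000 bar (2 fs steps, Nosé–Hoover τ = 2 ps,
barostat τ = 5 ps, 1.0 nm cutoffs with long-range corrections).  At
each state point the volume series gives κ_T by the fluctuation
formula and the mean density; the grid is classified isobar-by-isobar
(κ_T peak = Widom line vs density discontinuity = first-order) and the
critical point is bracketed between the classifications.

Supercooled equilibration is the wall-clock bottleneck: production
needs tens of nanoseconds per state point near the transition.
"""

import argparse
import json

import numpy as np

import rwail
from rwail.constants import AVOGADRO, WATER_MOLAR_MASS
from rwail.criticality import locate_llcp
from rwail.ewald import EwaldParams
from rwail.forces import CutoffScheme, ForceField, minimize_energy
from rwail.properties import TimeSeries, kappa_T


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scale", type=int, default=1)
    ap.add_argument("--tmin", type=float, default=190.0)
    ap.add_argument("--tmax", type=float, default=230.0)
    ap.add_argument("--nt", type=int, default=9)
    ap.add_argument("--pressures-bar", type=float, nargs="+",
                    default=[1.0, 200.0, 400.0, 600.0, 800.0, 1000.0])
    ap.add_argument("--out", default="llcp_scan.json")
    args = ap.parse_args()
    s = args.scale
    n = max(64, 343 // s)
    p = rwail.load_parameters("EG273")

    T_grid = np.linspace(args.tmin, args.tmax, args.nt)
    P_grid = np.array(args.pressures_bar)
    kappa = np.zeros((len(T_grid), len(P_grid)))
    rho = np.zeros_like(kappa)
    rho_err = np.zeros_like(kappa)
    for j, P in enumerate(P_grid):
        for i, T in enumerate(T_grid):
            st = rwail.build_water_box(n, 1000.0, seed=args.seed + i + 100 * j,
                                       r_e=p.r_e, theta_e_deg=p.theta_e)
            # leave barostat headroom: the box shrinks under pressure
            rc = min(10.0, st.box[0] / 2 * 0.85)
            ff = ForceField(p, EwaldParams(r_cut=rc),
                            CutoffScheme(r_cut_vdw=rc))
            st = minimize_energy(st, ff)
            tr = rwail.run_npt(st, ff,
                               rwail.ThermostatParams(float(T), tau_t=2.0),
                               rwail.BarostatParams(float(P), tau_p=5.0),
                               n_steps=max(1500, 25_000_000 // s), dt=0.002,
                               seed=args.seed + 13 * i + j, sample_every=50)
            V = TimeSeries("V", tr["V"], 0.1, "A^3")
            kap = kappa_T(V, float(T))
            kappa[i, j] = kap.value * 1e4
            v_mean = float(np.mean(tr["V"][len(tr["V"]) // 5:]))
            rho[i, j] = n * WATER_MOLAR_MASS / AVOGADRO / 1e3 / (v_mean * 1e-30)
            rho_err[i, j] = rho[i, j] * kap.stderr / max(kap.value, 1e-12) * 0.1

    est = locate_llcp(T_grid, P_grid / 10.0, kappa, rho, rho_stderr=rho_err)
    report = {"T_K": est.T, "P_MPa": est.P, "rho_kg_m3": est.rho,
              "dT_K": est.dT, "dP_MPa": est.dP, "bracketed": est.bracketed,
              "detail": est.detail,
              "grids": {"T": T_grid.tolist(), "P_MPa": (P_grid / 10).tolist(),
                        "kappa_1e-4_MPa-1": kappa.tolist(),
                        "rho_kg_m3": rho.tolist()}}
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    print(json.dumps({k: report[k] for k in
                      ("T_K", "P_MPa", "rho_kg_m3", "bracketed")}, indent=2))


if __name__ == "__main__":
    main()
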