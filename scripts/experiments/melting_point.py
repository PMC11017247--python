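#!/usr/bin/env python
"""Melting point by the NVE three-phase coexistence method.

Full protocol: an ice-Ih slab joined to a liquid slab with a vacuum
gap (three coexisting phases), propagated at constant energy with
0.5 fs steps from initial temperatures bracketing the melting point —
T_H/T_L = 280/260 K for the flexible model, 275/255 K for EG273.  The
end state (ice grown vs melted) is classified by the mean tetrahedral
order parameter of the oxygen lattice, and the bracket is bisected.

Each NVE leg needs several nanoseconds before the ice front commits,
so a full bisection is an overnight multicore job.
"""

import argparse
import json

import numpy as np

import rwail
from rwail.criticality import MeltingPointConfig, melting_point_three_phase
from rwail.ewald import EwaldParams
from rwail.forces import CutoffScheme, ForceField, minimize_energy
from rwail.integrators import RigidGeometry, constrain_velocities
from rwail.system import SystemState, init_velocities


def three_phase_cell(params, cells, seed):
    """Ice slab + liquid slab + vacuum stacked along z."""
    ice = rwail.build_ice_ih(cells, seed=seed, r_e=params.r_e,
                             theta_e_deg=params.theta_e)
    lx, ly, lz_ice = ice.box
    n_liq = ice.n_molecules
    liq = rwail.build_slab(n_liq, lateral=(float(lx), float(ly)),
                           L_z=float(lz_ice) + 10.0, seed=seed + 1,
                           r_e=params.r_e, theta_e_deg=params.theta_e,
                           cutoff_A=9.0)
    pos = np.concatenate([ice.positions,
                          liq.positions + np.array([0, 0, lz_ice])])
    box = np.array([lx, ly, lz_ice + liq.box[2] + 30.0])
    return SystemState(box=box, positions=pos)


def propagate_factory(params, cells, steps, seed):
    def propagate(T):
        st = three_phase_cell(params, cells, seed)
        rc = min(9.0, st.box[0] / 2 * 0.98)
        ff = ForceField(params, EwaldParams(r_cut=rc),
                        CutoffScheme(r_cut_vdw=rc, apply_lrc_energy=False,
                                     apply_lrc_pressure=False))
        st = minimize_energy(st, ff, max_iter=300)
        init_velocities(st, T, np.random.default_rng(seed + int(T)))
        if params.is_rigid:
            constrain_velocities(st, RigidGeometry.from_params(params))
        tr = rwail.run_md(st, ff, dt=0.0005, n_steps=steps, sample_every=500)
        return tr.state.o_positions, tr.state.box
    return propagate


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--variant", default="EG273",
                    choices=["flexible", "EG273"])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--scale", type=int, default=1)
    ap.add_argument("--cells", type=int, nargs=3, default=[4, 3, 3])
    ap.add_argument("--out", default="melting_point.json")
    args = ap.parse_args()
    p = rwail.load_parameters(args.variant)
    t_high, t_low = (280.0, 260.0) if args.variant == "flexible" \
        else (275.0, 255.0)
    steps = max(1000, 10_000_000 // args.scale)
    cfg = MeltingPointConfig(
        T_high=t_high, T_low=t_low, max_bisections=5,
        propagate=propagate_factory(p, tuple(args.cells), steps, args.seed))
    est = melting_point_three_phase(cfg)
    report = {"variant": args.variant, "T_M_K": est.T_M,
              "bracket_K": list(est.bracket), "ambiguous": est.ambiguous,
              "history": est.history}
    with open(args.out, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    print(json.dumps(report, indent=2, default=float))


if __name__ == "__main__":
    main()
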