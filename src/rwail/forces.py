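"""Assembly of the full rWAIL energy, forces and virial under PBC.

Combines, per force call:

* Ewald electrostatics over the charge sites (M, H1, H2) with all
  intramolecular pairs excluded;
* O–O Born–Mayer repulsion and r⁻⁶ dispersion within the van der Waals
  cutoff, with optional uniform-fluid tail corrections (r⁻⁶ term only;
  the exponential tail decays faster than any power and is neglected);
* the M–H hydrogen-bond shaping term (its own short cutoff r_c);
* intramolecular quartic-bond/harmonic-angle terms (flexible variant).

The force on the massless M site is redistributed onto O, H1, H2 by
the chain rule of the (linear) M-site rule, which preserves the net
force, the torque and the pair virial exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import P_INTERNAL_TO_BAR
from .ewald import EwaldParams, coulomb_ewald
from .forcefield import (INTRA_PREFACTOR, angle_force_mag, bond_force_mag,
                         hb_energy_force, oo_energy_force, R_OO_FLOOR)
from .parameters import ForceFieldParameters
from .system import SystemState, minimum_image


@dataclass(frozen=True)
class CutoffScheme:
    """Van der Waals cutoff and long-range-correction flags (Å)."""

    r_cut_vdw: float = 10.0
    apply_lrc_energy: bool = True
    apply_lrc_pressure: bool = True


@dataclass
class SystemEnergyForces:
    """Result of one force evaluation."""

    coulomb: float
    repulsion: float
    dispersion: float
    hb: float
    intra: float
    lrc: float
    forces: np.ndarray          # (3 n_mol, 3) on physical sites, kcal/mol/Å
    virial: np.ndarray          # (3, 3) kcal/mol

    @property
    def energy(self) -> float:
        return (self.coulomb + self.repulsion + self.dispersion
                + self.hb + self.intra + self.lrc)


@dataclass
class ForceField:
    """Callable bundling parameters, electrostatics and cutoffs.

    Term classes can be toggled independently (used by consistency
    tests and the ideal-gas surrogate).
    """

    params: ForceFieldParameters
    ewald: EwaldParams = field(default_factory=EwaldParams)
    cutoff: CutoffScheme = field(default_factory=CutoffScheme)
    enable_coulomb: bool = True
    enable_vdw: bool = True
    enable_hb: bool = True
    enable_intra: bool = True

    def __call__(self, state: SystemState) -> SystemEnergyForces:
        return system_energy_forces(state, self.params, self.ewald, self.cutoff,
                                    coulomb=self.enable_coulomb,
                                    vdw=self.enable_vdw,
                                    hb=self.enable_hb,
                                    intra=self.enable_intra)

    @property
    def is_null(self) -> bool:
        return not (self.enable_coulomb or self.enable_vdw
                    or self.enable_hb or self.enable_intra)


def _pair_table(pos_a, pos_b, box, rmax, exclude_same=None):
    """Indices, distances and min-image vectors of pairs within rmax.

    pos_a (na,3) vs pos_b (nb,3); ``exclude_same`` is an (na, nb) bool
    mask of pairs to drop.
    """
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d = minimum_image(d, box)
    r = np.linalg.norm(d, axis=-1)
    mask = r < rmax
    if exclude_same is not None:
        mask &= ~exclude_same
    ii, jj = np.nonzero(mask)
    return ii, jj, r[ii, jj], d[ii, jj]


def system_energy_forces(state: SystemState, params: ForceFieldParameters,
                         ewald: EwaldParams, cutoff: CutoffScheme,
                         coulomb: bool = True, vdw: bool = True,
                         hb: bool = True, intra: bool = True
                         ) -> SystemEnergyForces:
    """Full energy/forces/virial of a periodic water system.

    Forces are the exact negative gradient of the returned energy; the
    virial is Σ r_ij ⊗ f_ij over minimum-image pairs plus the analytic
    reciprocal-space term, consistent with the pressure route of the
    engine.
    """
    box = state.box
    n = state.n_molecules
    if vdw and np.any(box < 2.0 * cutoff.r_cut_vdw):
        raise ValueError(
            f"box {box} shorter than twice the vdW cutoff {cutoff.r_cut_vdw} Å"
        )
    mol = state.molecule_view()
    site_forces = np.zeros((4 * n, 3))   # [O,H1,H2,M] per molecule
    virial = np.zeros((3, 3))
    o_idx = np.arange(n) * 4
    h1_idx = o_idx + 1
    h2_idx = o_idx + 2
    m_idx = o_idx + 3

    e_coul = e_rep = e_disp = e_hb = e_intra = e_lrc = 0.0
    msite = state.msites(params.a)
    o_pos = mol[:, 0]

    # ---- electrostatics ------------------------------------------------
    if coulomb:
        # charge site order: [M_0, H1_0, H2_0, M_1, ...]
        cpos = np.empty((3 * n, 3))
        cpos[0::3] = msite
        cpos[1::3] = mol[:, 1]
        cpos[2::3] = mol[:, 2]
        q = np.empty(3 * n)
        q[0::3] = params.q_M
        q[1::3] = params.q_H
        q[2::3] = params.q_H
        base = 3 * np.arange(n)[:, None]
        excl = np.concatenate([base + np.array([[0, 1]]),
                               base + np.array([[0, 2]]),
                               base + np.array([[1, 2]])])
        e_coul, cf, cw = coulomb_ewald(cpos, q, box, ewald, exclusions=excl)
        virial += cw
        site_forces[m_idx] += cf[0::3]
        site_forces[h1_idx] += cf[1::3]
        site_forces[h2_idx] += cf[2::3]

    # ---- O–O repulsion + dispersion ------------------------------------
    if vdw:
        d = o_pos[:, None, :] - o_pos[None, :, :]
        d = minimum_image(d, box)
        r = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(n, k=1)
        rr = r[iu]
        if np.any(rr < R_OO_FLOOR):
            raise ValueError(
                f"unphysical O–O overlap: min r_OO = {rr.min():.3f} Å"
                f" < {R_OO_FLOOR} Å"
            )
        sel = rr < cutoff.r_cut_vdw
        ii, jj = iu[0][sel], iu[1][sel]
        rr = rr[sel]
        dv = d[ii, jj]
        rep, disp, dudr = oo_energy_force(rr, params)
        e_rep = float(rep.sum())
        e_disp = float(disp.sum())
        fpair = -(dudr / rr)[:, None] * dv
        np.add.at(site_forces, o_idx[ii], fpair)
        np.add.at(site_forces, o_idx[jj], -fpair)
        virial += np.einsum("pi,pj->ij", dv, fpair)
        if cutoff.apply_lrc_energy:
            V = state.volume
            e_lrc = -2.0 * np.pi * n * n * params.C_OO / (3.0 * V * cutoff.r_cut_vdw ** 3)
        if cutoff.apply_lrc_pressure:
            V = state.volume
            # ΔP = −4πρ²C/(3 r_c³): each diagonal virial element is V·ΔP
            w_lrc = -4.0 * np.pi * n * n * params.C_OO / (3.0 * V * cutoff.r_cut_vdw ** 3)
            virial += np.eye(3) * w_lrc

    # ---- hydrogen-bond shaping term (intermolecular M–H) ---------------
    if hb:
        hpos = np.empty((2 * n, 3))
        hpos[0::2] = mol[:, 1]
        hpos[1::2] = mol[:, 2]
        same = np.zeros((n, 2 * n), dtype=bool)
        same[np.arange(n), 2 * np.arange(n)] = True
        same[np.arange(n), 2 * np.arange(n) + 1] = True
        ii, jj, rr, dv = _pair_table(msite, hpos, box, params.r_c,
                                     exclude_same=same)
        if len(ii):
            e, dudr = hb_energy_force(rr, params)
            e_hb = float(e.sum())
            fpair = -(dudr / rr)[:, None] * dv   # force on M
            np.add.at(site_forces, m_idx[ii], fpair)
            hsite = np.where(jj % 2 == 0, h1_idx[jj // 2], h2_idx[jj // 2])
            np.add.at(site_forces, hsite, -fpair)
            virial += np.einsum("pi,pj->ij", dv, fpair)

    # ---- intramolecular (flexible only) --------------------------------
    if intra and not params.is_rigid:
        b1 = minimum_image(mol[:, 1] - mol[:, 0], box)
        b2 = minimum_image(mol[:, 2] - mol[:, 0], box)
        r1 = np.linalg.norm(b1, axis=-1)
        r2 = np.linalg.norm(b2, axis=-1)
        u1 = b1 / r1[:, None]
        u2 = b2 / r2[:, None]
        cos_t = np.clip(np.einsum("ij,ij->i", u1, u2), -1.0, 1.0)
        theta = np.arccos(cos_t)
        d1 = r1 - params.r_e
        d2 = r2 - params.r_e
        dth = theta - params.theta_e_rad
        e_intra = float(INTRA_PREFACTOR * np.sum(
            params.k2 * (d1 ** 2 + d2 ** 2)
            + params.k3 * (d1 ** 3 + d2 ** 3)
            + params.k4 * (d1 ** 4 + d2 ** 4)
            + params.k_theta * dth ** 2
        ))
        fb1 = bond_force_mag(r1, params)
        fb2 = bond_force_mag(r2, params)
        f_h1 = -fb1[:, None] * u1
        f_h2 = -fb2[:, None] * u2
        # angle gradient: dθ/dr_H1 = -(1/r1)(u2 - cosθ u1)/sinθ, etc.
        sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 1e-12, None))
        dUdth = angle_force_mag(theta, params)
        g1 = (u2 - cos_t[:, None] * u1) / (r1 * sin_t)[:, None]
        g2 = (u1 - cos_t[:, None] * u2) / (r2 * sin_t)[:, None]
        # F_H = −dU/dθ · ∂θ/∂r_H and ∂θ/∂r_H1 = −g1, so the force is +dU/dθ·g
        f_h1 += dUdth[:, None] * g1
        f_h2 += dUdth[:, None] * g2
        site_forces[h1_idx] += f_h1
        site_forces[h2_idx] += f_h2
        site_forces[o_idx] -= f_h1 + f_h2
        virial += (np.einsum("pi,pj->ij", b1, f_h1)
                   + np.einsum("pi,pj->ij", b2, f_h2))

    # ---- redistribute the M-site force (chain rule of the M rule) ------
    fM = site_forces[m_idx]
    a = params.a
    phys = np.zeros((3 * n, 3))
    phys[0::3] = site_forces[o_idx] + (1.0 - 2.0 * a) * fM
    phys[1::3] = site_forces[h1_idx] + a * fM
    phys[2::3] = site_forces[h2_idx] + a * fM

    return SystemEnergyForces(coulomb=e_coul, repulsion=e_rep, dispersion=e_disp,
                              hb=e_hb, intra=e_intra, lrc=e_lrc,
                              forces=phys, virial=virial)


def minimize_energy(state: SystemState, forcefield: ForceField,
                    max_iter: int = 500, gtol: float = 1.0) -> SystemState:
    """Relax a configuration by L-BFGS on the total energy.

    Used to prepare generated boxes for dynamics: jittered-lattice
    starts contain close contacts whose Born–Mayer/bond forces would
    otherwise demand a much smaller time step during early
    equilibration.  ``gtol`` is the max-force target in kcal/mol/Å.
    """
    from scipy.optimize import minimize as _minimize
    st = state.copy()
    shape = st.positions.shape
    params = forcefield.params
    rigid = params.is_rigid
    if rigid:
        import math
        d_hh = 2.0 * params.r_e * math.sin(params.theta_e_rad / 2.0)
        k_restr = 2000.0    # kcal/mol/Å²: keeps rigid geometry during descent

    def fun(x):
        st.positions = x.reshape(shape)
        ef = forcefield(st)
        e, g = ef.energy, -ef.forces
        if rigid:
            mol = st.molecule_view()
            gm = g.reshape(mol.shape)
            for a, b, d0 in ((0, 1, params.r_e), (0, 2, params.r_e),
                             (1, 2, d_hh)):
                v = mol[:, a] - mol[:, b]
                r = np.linalg.norm(v, axis=-1)
                e += k_restr * float(np.sum((r - d0) ** 2))
                gv = (2.0 * k_restr * (r - d0) / r)[:, None] * v
                gm[:, a] += gv
                gm[:, b] -= gv
        return e, g.ravel()

    res = _minimize(fun, st.positions.ravel(), jac=True, method="L-BFGS-B",
                    options={"maxiter": max_iter, "gtol": gtol})
    st.positions = res.x.reshape(shape)
    if rigid:
        from .integrators import RigidGeometry, constrain_rigid
        st = constrain_rigid(st, RigidGeometry.from_params(params))
    return st


def pressure_tensor(state: SystemState, virial: np.ndarray) -> np.ndarray:
    """Atomic-route pressure tensor (bar): (Σ m v⊗v + W) / V.

    For constrained systems use :func:`molecular_pressure_tensor`,
    which makes constraint forces drop out exactly.
    """
    return (state.kinetic_tensor() + virial) / state.volume * P_INTERNAL_TO_BAR


def molecular_pressure_tensor(state: SystemState, ef: SystemEnergyForces
                              ) -> np.ndarray:
    """Molecular-virial pressure tensor (bar).

    P V = Σ_mol M v_cm⊗v_cm + W_mol with
    W_mol = W_site − Σ_i d_i ⊗ F_i,  d_i = r_i − r_cm(mol(i)).

    Intramolecular forces (bonded terms and SHAKE/RATTLE constraint
    forces alike) cancel identically in W_mol, so this route needs no
    constraint-force bookkeeping and is exact for rigid water.
    """
    from .constants import FORCE_TO_ACC, MASS_WATER
    n = state.n_molecules
    com = state.com()
    d = state.positions - np.repeat(com, 3, axis=0)
    W = ef.virial - np.einsum("ij,ik->jk", d, ef.forces)
    m = state.masses
    vcm = ((m[:, None] * state.velocities).reshape(n, 3, 3).sum(axis=1)
           / MASS_WATER)
    K = MASS_WATER * np.einsum("ij,ik->jk", vcm, vcm) / FORCE_TO_ACC
    return (K + W) / state.volume * P_INTERNAL_TO_BAR
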