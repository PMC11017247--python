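"""The rWAIL energy expressions for a pair of water molecules.

The intermolecular energy of two molecules is

    U = Σ_ij q_i q_j / r_ij            (charge sites: M, H1, H2)
      + A_OO exp(−α r_OO) − C_OO / r_OO⁶
      + Σ_MH U_HB(r_MH)                (intermolecular M–H pairs)

with the hydrogen-bond shaping term

    U_HB(r) = A_4 (1/r² − 1/r_c²)²   for r < r_c,  0 otherwise,

which vanishes with zero slope at the cutoff r_c and diverges as
A_4/r⁴ at short range, keeping the oppositely charged M and H sites
from collapsing.  The massless M site carries the negative charge and
is placed from the two O–H bond vectors,

    r_M = r_O + a [(r_H1 − r_O) + (r_H2 − r_O)].

Flexible molecules additionally carry the intramolecular potential

    U_intra = Σ_{b=1,2} [ ½k2 Δr_b² + ½k3 Δr_b³ + ½k4 Δr_b⁴ ]
            + ½ k_θ (θ − θ_e)²,   Δr_b = r_b − r_e.

The global ½ prefactor is a single named constant (INTRA_PREFACTOR)
locked by tests: with it, the OH-stretch and HOH-bend curvatures land
at physically correct water force constants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import COULOMB
from .parameters import ForceFieldParameters

# Global prefactor of every intramolecular polynomial term (see module
# docstring); changing it silently would change the model.
INTRA_PREFACTOR = 0.5

# Below this O–O separation the Born–Mayer + r⁻⁶ form is attractive and
# divergent; treat as unphysical overlap rather than returning it.
R_OO_FLOOR = 0.5  # Å


@dataclass(frozen=True)
class EnergyBreakdown:
    """Intermolecular pair energy split by physical origin (kcal/mol)."""

    coulomb: float
    repulsion: float
    dispersion: float
    hb: float
    intra: float = 0.0

    @property
    def total(self) -> float:
        return self.coulomb + self.repulsion + self.dispersion + self.hb + self.intra


def msite_position(r_O, r_H1, r_H2, a: float) -> np.ndarray:
    """Position of the massless charge site M.

    M lies at r_O + a[(r_H1 − r_O) + (r_H2 − r_O)]: on the HOH bisector
    for a symmetric molecule, and geometry-responsive for flexible
    molecules.  Accepts single vectors or (..., 3) arrays.
    """
    r_O = np.asarray(r_O, dtype=float)
    r_H1 = np.asarray(r_H1, dtype=float)
    r_H2 = np.asarray(r_H2, dtype=float)
    b1 = r_H1 - r_O
    b2 = r_H2 - r_O
    n1 = np.linalg.norm(b1, axis=-1)
    n2 = np.linalg.norm(b2, axis=-1)
    if np.any(n1 < 1e-10) or np.any(n2 < 1e-10):
        raise ValueError("coincident O/H positions: O–H bond vector has zero length")
    return r_O + a * (b1 + b2)


def hb_term(r_MH: float, params: ForceFieldParameters) -> float:
    """U_HB at one intermolecular M–H distance (kcal/mol).

    Zero at and beyond the cutoff r_c, continuous (C¹) at r_c.
    """
    if r_MH <= 0:
        raise ValueError("r_MH must be positive")
    if r_MH >= params.r_c:
        return 0.0
    x = 1.0 / (r_MH * r_MH) - 1.0 / (params.r_c * params.r_c)
    return params.A_4 * x * x


def hb_energy_force(r: np.ndarray, params: ForceFieldParameters):
    """Vectorized U_HB(r) and its radial derivative dU/dr.

    Used by the system force assembly; r may contain values beyond r_c
    (masked to zero).
    """
    r = np.asarray(r, dtype=float)
    inside = r < params.r_c
    rc2 = params.r_c * params.r_c
    with np.errstate(divide="ignore"):
        inv2 = np.where(r > 0, 1.0 / np.maximum(r, 1e-300) ** 2, np.inf)
    x = inv2 - 1.0 / rc2
    e = np.where(inside, params.A_4 * x * x, 0.0)
    # dU/dr = 2 A4 x * (-2 / r^3)
    dudr = np.where(inside, -4.0 * params.A_4 * x * inv2 / np.maximum(r, 1e-300), 0.0)
    return e, dudr


def oo_energy_force(r: np.ndarray, params: ForceFieldParameters):
    """Born–Mayer repulsion plus r⁻⁶ dispersion on O–O distances.

    Returns (energy, dU/dr) arrays.
    """
    r = np.asarray(r, dtype=float)
    rep = params.A_OO * np.exp(-params.alpha * r)
    r6 = r ** 6
    disp = -params.C_OO / r6
    dudr = -params.alpha * rep + 6.0 * params.C_OO / (r6 * r)
    return rep, disp, dudr


def intramolecular_energy(r1: float, r2: float, theta: float,
                          params: ForceFieldParameters) -> float:
    """Intramolecular energy of one flexible molecule (kcal/mol).

    Parameters are the two O–H bond lengths (Å) and the HOH angle
    (radians).  Zero with zero gradient at (r_e, r_e, θ_e); symmetric
    under r1 ↔ r2.
    """
    if params.is_rigid:
        raise ValueError(
            f"intramolecular energy is undefined for rigid variant {params.variant}"
        )
    if r1 <= 0 or r2 <= 0:
        raise ValueError("bond lengths must be positive")
    if not (0.0 < theta < math.pi):
        raise ValueError("HOH angle must lie in (0, pi)")
    e = 0.0
    for r in (r1, r2):
        d = r - params.r_e
        e += INTRA_PREFACTOR * (params.k2 * d * d + params.k3 * d ** 3
                                + params.k4 * d ** 4)
    dth = theta - params.theta_e_rad
    e += INTRA_PREFACTOR * params.k_theta * dth * dth
    return e


def bond_force_mag(r: np.ndarray, params: ForceFieldParameters) -> np.ndarray:
    """dU/dr of the quartic bond term (vectorized)."""
    d = r - params.r_e
    return INTRA_PREFACTOR * (2.0 * params.k2 * d + 3.0 * params.k3 * d * d
                              + 4.0 * params.k4 * d ** 3)


def angle_force_mag(theta: np.ndarray, params: ForceFieldParameters) -> np.ndarray:
    """dU/dθ of the harmonic angle term (vectorized)."""
    return INTRA_PREFACTOR * 2.0 * params.k_theta * (theta - params.theta_e_rad)


@dataclass
class WaterSiteSet:
    """Site positions of a single water molecule (Å), M derived."""

    r_O: np.ndarray
    r_H1: np.ndarray
    r_H2: np.ndarray
    params: ForceFieldParameters

    def __post_init__(self):
        self.r_O = np.asarray(self.r_O, dtype=float)
        self.r_H1 = np.asarray(self.r_H1, dtype=float)
        self.r_H2 = np.asarray(self.r_H2, dtype=float)

    @property
    def r_M(self) -> np.ndarray:
        return msite_position(self.r_O, self.r_H1, self.r_H2, self.params.a)

    def charge_sites(self):
        """(positions (3,3), charges (3,)) for M, H1, H2."""
        p = self.params
        pos = np.stack([self.r_M, self.r_H1, self.r_H2])
        q = np.array([p.q_M, p.q_H, p.q_H])
        return pos, q


def pair_energy(A: WaterSiteSet, B: WaterSiteSet,
                params: ForceFieldParameters) -> EnergyBreakdown:
    """Open-boundary intermolecular energy of a water dimer.

    coulomb sums over all 3×3 intermolecular charge-site pairs,
    repulsion/dispersion act on r_OO only, hb sums U_HB over the four
    intermolecular M–H pairs.  Symmetric under exchanging A and B.
    """
    r_OO = float(np.linalg.norm(A.r_O - B.r_O))
    if r_OO < R_OO_FLOOR:
        raise ValueError(
            f"unphysical O–O overlap: r_OO = {r_OO:.3f} Å < {R_OO_FLOOR} Å"
        )
    pos_a, q_a = A.charge_sites()
    pos_b, q_b = B.charge_sites()
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    if np.any(d < 1e-10):
        raise ValueError("coincident charge sites across molecules")
    coulomb = COULOMB * float(np.sum(np.outer(q_a, q_b) / d))
    rep = params.A_OO * math.exp(-params.alpha * r_OO)
    disp = -params.C_OO / r_OO ** 6
    hb = 0.0
    for rM, hs in ((A.r_M, (B.r_H1, B.r_H2)), (B.r_M, (A.r_H1, A.r_H2))):
        for rH in hs:
            hb += hb_term(float(np.linalg.norm(rM - rH)), params)
    return EnergyBreakdown(coulomb=coulomb, repulsion=rep, dispersion=disp, hb=hb)
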