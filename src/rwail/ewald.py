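"""Plain Ewald summation for point charges in an orthorhombic box.

This is the reference electrostatics path: exact (to a stated accuracy)
rather than fast.  The total energy is split the standard way,

    E = E_real + E_reciprocal + E_self + E_exclusion,

    E_real = k_e Σ'_{i<j} q_i q_j erfc(α r_ij) / r_ij          (r < r_cut)
    E_rec  = k_e (2π/V) Σ_{k≠0} exp(−k²/4α²)/k² |S(k)|²
    E_self = −k_e α/√π Σ_i q_i²
    E_excl = −k_e Σ_{excluded i<j} q_i q_j erf(α r_ij) / r_ij

where S(k) = Σ_j q_j exp(i k·r_j) and the primed real-space sum skips
excluded (intramolecular) pairs.  The splitting parameter α and the
reciprocal cutoff are chosen together from a single accuracy target so
that the total is independent of α within that target.

Forces are analytic; the virial tensor includes the reciprocal-space
anisotropy term needed for slab pressure profiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, erf

from .constants import COULOMB
from .system import minimum_image

TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)


@dataclass(frozen=True)
class EwaldParams:
    """Splitting/accuracy settings for plain Ewald.

    ``r_cut`` is the real-space cutoff (Å).  If ``alpha`` (Å⁻¹) or
    ``kmax`` (largest integer wave index per dimension) are None they
    are derived from ``accuracy``: erfc(α r_cut) ≤ accuracy and
    exp(−k²/4α²) ≤ accuracy at the reciprocal cutoff.
    """

    r_cut: float = 6.0
    alpha: float | None = None
    kmax: tuple[int, int, int] | None = None
    accuracy: float = 1e-7

    def resolve(self, box: np.ndarray):
        s = math.sqrt(-math.log(self.accuracy))
        alpha = self.alpha if self.alpha is not None else s / self.r_cut
        if self.kmax is not None:
            kmax = self.kmax
        else:
            kcut = 2.0 * alpha * s
            kmax = tuple(int(math.ceil(kcut * L / (2.0 * math.pi))) for L in box)
        return alpha, kmax


def _phase_factors(frac: np.ndarray, kmax: int) -> np.ndarray:
    """exp(2πi n x) for n = −kmax..kmax, shape (N, 2*kmax+1)."""
    n = np.arange(-kmax, kmax + 1)
    return np.exp(2j * math.pi * np.outer(frac, n))


def coulomb_ewald(positions: np.ndarray, charges: np.ndarray, box: np.ndarray,
                  params: EwaldParams, exclusions: np.ndarray | None = None):
    """Ewald energy, forces and virial for point charges.

    Parameters
    ----------
    positions : (N, 3) Å
    charges : (N,) e; must sum to ~0.
    box : (3,) orthorhombic lengths Å; each ≥ 2 r_cut.
    params : EwaldParams
    exclusions : (M, 2) int, optional
        Site-index pairs whose direct Coulomb interaction is excluded
        (intramolecular pairs).  Their reciprocal-space contribution is
        subtracted with the erf complement.

    Returns
    -------
    (energy kcal/mol, forces (N,3) kcal/mol/Å, virial (3,3) kcal/mol)
    """
    positions = np.asarray(positions, dtype=float)
    charges = np.asarray(charges, dtype=float)
    box = np.asarray(box, dtype=float)
    n = len(charges)
    qtot = charges.sum()
    if abs(qtot) > 1e-8 * max(1.0, np.abs(charges).max()):
        raise ValueError(f"Ewald requires a neutral system; net charge {qtot:g} e")
    if np.any(box < 2.0 * params.r_cut):
        raise ValueError(
            f"box {box} shorter than twice the real-space cutoff {params.r_cut} Å"
        )
    alpha, kmax = params.resolve(box)
    V = float(np.prod(box))

    forces = np.zeros_like(positions)
    virial = np.zeros((3, 3))

    # ---- real space (all pairs, minimum image) -------------------------
    d = positions[:, None, :] - positions[None, :, :]
    d = minimum_image(d, box)
    r = np.linalg.norm(d, axis=-1)
    iu = np.triu_indices(n, k=1)
    mask = r[iu] < params.r_cut
    if exclusions is not None and len(exclusions):
        excl_set = np.zeros((n, n), dtype=bool)
        ei, ej = exclusions[:, 0], exclusions[:, 1]
        excl_set[ei, ej] = True
        excl_set[ej, ei] = True
        mask &= ~excl_set[iu]
    ii, jj = iu[0][mask], iu[1][mask]
    rij = r[ii, jj]
    dij = d[ii, jj]
    qq = COULOMB * charges[ii] * charges[jj]
    erfc_term = erfc(alpha * rij)
    e_real = float(np.sum(qq * erfc_term / rij))
    # dU/dr = -qq [erfc(ar)/r^2 + 2a/sqrt(pi) exp(-a^2 r^2)/r]
    dudr = -qq * (erfc_term / rij ** 2
                  + TWO_OVER_SQRT_PI * alpha * np.exp(-(alpha * rij) ** 2) / rij)
    fpair = -(dudr / rij)[:, None] * dij           # force on i from j
    np.add.at(forces, ii, fpair)
    np.add.at(forces, jj, -fpair)
    virial += np.einsum("pi,pj->ij", dij, fpair)

    # ---- reciprocal space ---------------------------------------------
    frac = positions / box
    ex = _phase_factors(frac[:, 0], kmax[0])
    ey = _phase_factors(frac[:, 1], kmax[1])
    ez = _phase_factors(frac[:, 2], kmax[2])
    nx = np.arange(-kmax[0], kmax[0] + 1)
    ny = np.arange(-kmax[1], kmax[1] + 1)
    nz = np.arange(-kmax[2], kmax[2] + 1)
    kx = 2.0 * math.pi * nx / box[0]
    ky = 2.0 * math.pi * ny / box[1]
    kz = 2.0 * math.pi * nz / box[2]
    KX, KY, KZ = np.meshgrid(kx, ky, kz, indexing="ij")
    ksq = KX ** 2 + KY ** 2 + KZ ** 2
    s = math.sqrt(-math.log(params.accuracy))
    kcut2 = (2.0 * alpha * s) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where((ksq > 1e-12) & (ksq <= kcut2),
                     np.exp(-ksq / (4.0 * alpha ** 2)) / ksq, 0.0)
    # structure factor S(k): factorized matmul, O(N·Kx·Ky·Kz / min dim)
    P = ey[:, :, None] * ez[:, None, :]                     # (N, Ky, Kz)
    P2 = P.reshape(n, -1)
    S = ((charges[:, None] * ex).T @ P2).reshape(len(nx), len(ny), len(nz))
    S2 = np.abs(S) ** 2
    pref = COULOMB * 2.0 * math.pi / V
    e_rec = float(pref * np.sum(A * S2))
    # forces: F_i = k_e (4π/V) q_i Σ_k A k Im(conj(S) e^{ik·r_i})
    G = A * np.conj(S)
    for axis, K in enumerate((KX, KY, KZ)):
        Gk = (G * K).reshape(len(nx), -1)
        # contract over (ky,kz) with per-site factors, then over kx
        M = Gk @ P2.T                                        # (Kx, N)
        D = np.einsum("ix,xi->i", ex, M)
        forces[:, axis] += 2.0 * pref * charges * D.imag
    # reciprocal virial
    AS2 = A * S2
    total_AS2 = np.sum(AS2)
    fac = 2.0 * (1.0 / (4.0 * alpha ** 2) + 1.0 / np.where(ksq > 0, ksq, 1.0))
    Ks = (KX, KY, KZ)
    for a_ in range(3):
        for b_ in range(3):
            term = np.sum(AS2 * fac * Ks[a_] * Ks[b_])
            virial[a_, b_] += pref * ((total_AS2 if a_ == b_ else 0.0) - term)

    # ---- self energy ---------------------------------------------------
    e_self = -COULOMB * alpha / math.sqrt(math.pi) * float(np.sum(charges ** 2))

    # ---- exclusion correction (remove erf part of excluded pairs) ------
    e_excl = 0.0
    if exclusions is not None and len(exclusions):
        ei, ej = exclusions[:, 0], exclusions[:, 1]
        dv = minimum_image(positions[ei] - positions[ej], box)
        rv = np.linalg.norm(dv, axis=-1)
        qq = COULOMB * charges[ei] * charges[ej]
        erf_term = erf(alpha * rv)
        e_excl = -float(np.sum(qq * erf_term / rv))
        # d(-qq erf/r)/dr = -qq [2a/sqrt(pi) exp(-a^2r^2)/r - erf(ar)/r^2]
        dudr = -qq * (TWO_OVER_SQRT_PI * alpha * np.exp(-(alpha * rv) ** 2) / rv
                      - erf_term / rv ** 2)
        fpair = -(dudr / rv)[:, None] * dv
        np.add.at(forces, ei, fpair)
        np.add.at(forces, ej, -fpair)
        virial += np.einsum("pi,pj->ij", dv, fpair)

    energy = e_real + e_rec + e_self + e_excl
    return energy, forces, virial


def direct_coulomb(positions: np.ndarray, charges: np.ndarray) -> float:
    """Open-boundary pairwise Coulomb energy (kcal/mol); no periodicity."""
    positions = np.asarray(positions, dtype=float)
    n = len(charges)
    d = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    iu = np.triu_indices(n, k=1)
    return float(COULOMB * np.sum(charges[iu[0]] * charges[iu[1]] / d[iu]))
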