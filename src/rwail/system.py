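"""Periodic simulation state for water systems.

Positions are stored for the three physical sites per molecule in the
fixed order [O, H1, H2]; the massless M site is derived on demand from
the force-field geometry rule.  Boxes are orthorhombic (all systems in
scope are), lengths in Å.  Molecules are kept intact internally: the
minimum-image convention is applied to intermolecular vectors only,
and wrapping moves whole molecules by their O site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MASS_H, MASS_O, KB


@dataclass
class SystemState:
    """Positions/velocities of physical sites in a periodic box.

    Attributes
    ----------
    box : (3,) float
        Orthorhombic box lengths (Å).
    positions : (3*n_molecules, 3) float
        Site positions (Å), molecule-major order [O, H1, H2].
    velocities : (3*n_molecules, 3) float
        Site velocities (Å/ps).
    time : float
        Simulation time (ps).
    wrapped : bool
        Metadata: whether positions have been wrapped into the box.
    """

    box: np.ndarray
    positions: np.ndarray
    velocities: np.ndarray | None = None
    time: float = 0.0
    wrapped: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[0] % 3:
            raise ValueError("positions must be (3*n_molecules, 3)")
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)

    @property
    def n_molecules(self) -> int:
        return self.positions.shape[0] // 3

    @property
    def n_sites(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def masses(self) -> np.ndarray:
        m = np.empty(self.n_sites)
        m[0::3] = MASS_O
        m[1::3] = MASS_H
        m[2::3] = MASS_H
        return m

    @property
    def o_positions(self) -> np.ndarray:
        return self.positions[0::3]

    @property
    def h_positions(self) -> np.ndarray:
        """(2*n, 3) hydrogen positions, molecule-major (H1_0, H2_0, H1_1, ...)."""
        idx = np.arange(self.n_sites).reshape(-1, 3)[:, 1:].ravel()
        return self.positions[idx]

    def molecule_view(self) -> np.ndarray:
        """Positions reshaped to (n_molecules, 3, 3) — a view."""
        return self.positions.reshape(self.n_molecules, 3, 3)

    def msites(self, a: float) -> np.ndarray:
        """M-site positions (n_molecules, 3) for geometry factor *a*."""
        mol = self.molecule_view()
        b1 = mol[:, 1] - mol[:, 0]
        b2 = mol[:, 2] - mol[:, 0]
        return mol[:, 0] + a * (b1 + b2)

    def com(self) -> np.ndarray:
        """Per-molecule centres of mass (n_molecules, 3)."""
        mol = self.molecule_view()
        m = np.array([MASS_O, MASS_H, MASS_H])
        return (mol * m[None, :, None]).sum(axis=1) / m.sum()

    def kinetic_energy(self) -> float:
        """Kinetic energy in kcal/mol (total, not per molecule)."""
        from .constants import FORCE_TO_ACC
        v2 = np.einsum("ij,ij->i", self.velocities, self.velocities)
        return float(0.5 * np.sum(self.masses * v2) / FORCE_TO_ACC)

    def kinetic_tensor(self) -> np.ndarray:
        """Σ m v⊗v in kcal/mol (energy units)."""
        from .constants import FORCE_TO_ACC
        return np.einsum("i,ij,ik->jk", self.masses, self.velocities,
                         self.velocities) / FORCE_TO_ACC

    def temperature(self, n_constraints: int = 0) -> float:
        """Instantaneous kinetic temperature (K), COM motion removed dof."""
        n_dof = 3 * self.n_sites - 3 - n_constraints
        return 2.0 * self.kinetic_energy() / (n_dof * KB)

    def wrap(self) -> None:
        """Translate whole molecules so every O site lies inside the box."""
        mol = self.molecule_view()
        shift = np.floor(mol[:, 0] / self.box) * self.box
        mol -= shift[:, None, :]
        self.wrapped = True

    def copy(self) -> "SystemState":
        return SystemState(
            box=self.box.copy(),
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            time=self.time,
            wrapped=self.wrapped,
            metadata=dict(self.metadata),
        )

    def total_dipole(self, params) -> np.ndarray:
        """Total cell dipole M = Σ q r in e·Å (charge sites M, H)."""
        msite = self.msites(params.a)
        mol = self.molecule_view()
        return (params.q_M * msite.sum(axis=0)
                + params.q_H * (mol[:, 1].sum(axis=0) + mol[:, 2].sum(axis=0)))


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    return d - box * np.round(d / box)


def init_velocities(state: SystemState, T: float, rng: np.random.Generator,
                    remove_com: bool = True) -> None:
    """Draw Maxwell–Boltzmann velocities at temperature T (in place)."""
    from .constants import FORCE_TO_ACC
    sigma = np.sqrt(KB * T * FORCE_TO_ACC / state.masses)
    state.velocities = rng.normal(size=state.positions.shape) * sigma[:, None]
    if remove_com:
        m = state.masses
        p = (m[:, None] * state.velocities).sum(axis=0) / m.sum()
        state.velocities -= p[None, :]
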