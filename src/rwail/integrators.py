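"""Integrators, thermostats, barostat and rigid constraints.

Velocity-Verlet NVE is the base integrator; NVT adds a Nosé–Hoover
thermostat (chain length 1, the plain thermostat); NPT adds isotropic
stochastic cell rescaling (deterministic weak-coupling mode available).
Rigid ensemble-geometry variants are maintained by SHAKE/RATTLE on the
three distance constraints (O–H1, O–H2, H1–H2) to 1e−10, which is
SETTLE-equivalent at that tolerance.

Time in ps; forces in kcal/mol/Å; accelerations via FORCE_TO_ACC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import FORCE_TO_ACC, KB, P_INTERNAL_TO_BAR
from .forces import ForceField, SystemEnergyForces
from .system import SystemState, init_velocities

SHAKE_TOL = 1e-10     # Å², on |r|² − d²  (relative to d²)
SHAKE_MAX_ITER = 500


@dataclass(frozen=True)
class ThermostatParams:
    """Nosé–Hoover target temperature (K) and relaxation time (ps)."""

    T: float
    tau_t: float = 2.0

    def __post_init__(self):
        if self.tau_t <= 0:
            raise ValueError("thermostat relaxation time must be positive")


@dataclass(frozen=True)
class BarostatParams:
    """Isotropic barostat: target pressure (bar), relaxation time (ps).

    ``compressibility`` (1/bar) sets the cell-rescaling gain;
    ``stochastic`` selects stochastic cell rescaling (correct NPT
    volume fluctuations) over deterministic weak coupling.
    """

    P: float
    tau_p: float = 5.0
    compressibility: float = 4.5e-5
    stochastic: bool = True

    def __post_init__(self):
        if self.tau_p <= 0:
            raise ValueError("barostat relaxation time must be positive")


@dataclass
class RigidGeometry:
    """Fixed water geometry (r_e Å, theta_e rad) as three distances."""

    r_e: float
    theta_e: float

    @property
    def d_hh(self) -> float:
        return 2.0 * self.r_e * math.sin(self.theta_e / 2.0)

    @classmethod
    def from_params(cls, params) -> "RigidGeometry":
        return cls(r_e=params.r_e, theta_e=params.theta_e_rad)


def constrain_positions(state: SystemState, ref_positions: np.ndarray,
                        geom: RigidGeometry, dt: float):
    """SHAKE: project positions back onto the constraint manifold.

    ``ref_positions`` are the pre-step positions defining the constraint
    gradients.  Returns the accumulated constraint virial (3,3) in
    kcal/mol (force route −2g/dt² along the reference bonds).
    """
    mol = state.molecule_view()
    ref = ref_positions.reshape(mol.shape)
    masses = np.array([15.999, 1.008, 1.008])
    targets = [(0, 1, geom.r_e ** 2), (0, 2, geom.r_e ** 2),
               (1, 2, geom.d_hh ** 2)]
    gsum = {k: np.zeros(mol.shape[0]) for k in range(3)}
    svec = {}
    for it in range(SHAKE_MAX_ITER):
        worst = 0.0
        for ci, (a, b, d2) in enumerate(targets):
            rab = mol[:, a] - mol[:, b]
            sab = ref[:, a] - ref[:, b]
            svec[ci] = sab
            diff = np.einsum("ij,ij->i", rab, rab) - d2
            worst = max(worst, float(np.max(np.abs(diff)) / d2))
            denom = 2.0 * (1.0 / masses[a] + 1.0 / masses[b]) * np.einsum(
                "ij,ij->i", sab, rab)
            g = diff / denom
            mol[:, a] -= (g / masses[a])[:, None] * sab
            mol[:, b] += (g / masses[b])[:, None] * sab
            gsum[ci] += g
        if worst < SHAKE_TOL:
            break
    else:
        raise RuntimeError(
            f"SHAKE failed to converge after {SHAKE_MAX_ITER} iterations "
            f"(worst residual {worst:.3e})"
        )
    virial = np.zeros((3, 3))
    for ci in range(3):
        # constraint force on atom a: f = -(2 g / dt²) s  (in acceleration
        # units); convert to kcal/mol/Å by dividing by FORCE_TO_ACC
        w = -2.0 * gsum[ci] / (dt * dt) / FORCE_TO_ACC
        virial += np.einsum("p,pi,pj->ij", w, svec[ci], svec[ci])
    return virial


def constrain_velocities(state: SystemState, geom: RigidGeometry):
    """RATTLE: remove velocity components along the constraints."""
    mol = state.molecule_view()
    vel = state.velocities.reshape(mol.shape)
    masses = np.array([15.999, 1.008, 1.008])
    pairs = [(0, 1), (0, 2), (1, 2)]
    for it in range(SHAKE_MAX_ITER):
        worst = 0.0
        for a, b in pairs:
            rab = mol[:, a] - mol[:, b]
            vab = vel[:, a] - vel[:, b]
            r2 = np.einsum("ij,ij->i", rab, rab)
            proj = np.einsum("ij,ij->i", rab, vab)
            worst = max(worst, float(np.max(np.abs(proj) / r2)))
            k = proj / ((1.0 / masses[a] + 1.0 / masses[b]) * r2)
            vel[:, a] -= (k / masses[a])[:, None] * rab
            vel[:, b] += (k / masses[b])[:, None] * rab
        if worst < SHAKE_TOL:
            break
    else:
        raise RuntimeError("RATTLE failed to converge")


def constrain_rigid(state: SystemState, geom: RigidGeometry) -> SystemState:
    """Snap a state exactly onto the rigid geometry (positions+velocities).

    Used to initialise rigid runs; per-step maintenance happens inside
    the integrator.
    """
    st = state.copy()
    constrain_positions(st, st.positions.copy(), geom, dt=1.0)
    constrain_velocities(st, geom)
    return st


def rigid_residuals(state: SystemState, geom: RigidGeometry):
    """Max |OH|−r_e and |HH|−d_hh residuals (Å) — diagnostics."""
    mol = state.molecule_view()
    r1 = np.linalg.norm(mol[:, 1] - mol[:, 0], axis=-1)
    r2 = np.linalg.norm(mol[:, 2] - mol[:, 0], axis=-1)
    hh = np.linalg.norm(mol[:, 2] - mol[:, 1], axis=-1)
    return (float(np.max(np.abs(np.concatenate([r1, r2]) - geom.r_e))),
            float(np.max(np.abs(hh - geom.d_hh))))


class NoseHoover:
    """Single Nosé–Hoover thermostat (chain length 1)."""

    def __init__(self, params: ThermostatParams, n_dof: int):
        self.p = params
        self.n_dof = n_dof
        self.xi = 0.0
        self.Q = n_dof * KB * params.T * params.tau_t ** 2

    def half_step(self, state: SystemState, dt: float):
        kT = self.n_dof * KB * self.p.T
        twoK = 2.0 * state.kinetic_energy()
        self.xi += 0.5 * dt * (twoK - kT) / self.Q
        state.velocities *= math.exp(-self.xi * 0.5 * dt)
        twoK = 2.0 * state.kinetic_energy()
        self.xi += 0.5 * dt * (twoK - kT) / self.Q


def step_nve(state: SystemState, forcefield: ForceField, dt: float,
             cache: SystemEnergyForces | None = None,
             geom: RigidGeometry | None = None,
             thermostat: NoseHoover | None = None):
    """One velocity-Verlet step (optionally thermostatted/constrained).

    Returns (state, SystemEnergyForces at the new positions,
    constraint virial of the step).
    """
    if dt <= 0:
        raise ValueError("time step must be positive")
    ef = cache if cache is not None else forcefield(state)
    if thermostat is not None:
        thermostat.half_step(state, dt)
    m = state.masses[:, None]
    acc = ef.forces * FORCE_TO_ACC / m
    state.velocities += 0.5 * dt * acc
    ref = state.positions.copy()
    state.positions += dt * state.velocities
    cvir = np.zeros((3, 3))
    if geom is not None:
        cvir = constrain_positions(state, ref, geom, dt)
        state.velocities += (state.positions - ref - dt * state.velocities) / dt
    ef2 = forcefield(state)
    acc2 = ef2.forces * FORCE_TO_ACC / m
    state.velocities += 0.5 * dt * acc2
    if geom is not None:
        constrain_velocities(state, geom)
    if thermostat is not None:
        thermostat.half_step(state, dt)
    state.time += dt
    return state, ef2, cvir


@dataclass
class Trajectory:
    """Sampled observables of a run (time series + optional frames)."""

    times: np.ndarray
    series: dict
    frames: list = field(default_factory=list)
    frame_times: list = field(default_factory=list)
    state: SystemState | None = None

    def __getitem__(self, key):
        return np.asarray(self.series[key])


def _sample(series, state, ef, cvir, params, n_constraints):
    from .forces import molecular_pressure_tensor
    P = molecular_pressure_tensor(state, ef)
    series.setdefault("E_pot", []).append(ef.energy)
    series.setdefault("E_kin", []).append(state.kinetic_energy())
    series.setdefault("T", []).append(state.temperature(n_constraints))
    series.setdefault("V", []).append(state.volume)
    series.setdefault("P_xx", []).append(P[0, 0])
    series.setdefault("P_yy", []).append(P[1, 1])
    series.setdefault("P_zz", []).append(P[2, 2])
    series.setdefault("P", []).append(np.trace(P) / 3.0)
    series.setdefault("box_x", []).append(state.box[0])
    mu = state.total_dipole(params)
    series.setdefault("M_x", []).append(mu[0])
    series.setdefault("M_y", []).append(mu[1])
    series.setdefault("M_z", []).append(mu[2])


def run_md(state: SystemState, forcefield: ForceField, dt: float, n_steps: int,
           thermostat: ThermostatParams | None = None,
           barostat: BarostatParams | None = None,
           seed: int | None = None, sample_every: int = 10,
           frame_every: int = 0, track_unwrapped: bool = False) -> Trajectory:
    """Run NVE/NVT/NPT molecular dynamics.

    The ensemble is selected by which coupling parameters are given.
    All randomness (initial velocities if the state has none, barostat
    noise) comes from ``seed``; identical seeds give identical
    trajectories on one platform.
    """
    state = state.copy()
    params = forcefield.params
    rng = np.random.default_rng(seed)
    geom = RigidGeometry.from_params(params) if params.is_rigid else None
    n_constraints = 3 * state.n_molecules if geom else 0
    n_dof = 3 * state.n_sites - 3 - n_constraints
    if np.all(state.velocities == 0.0) and thermostat is not None:
        init_velocities(state, thermostat.T, rng)
        if geom is not None:
            constrain_velocities(state, geom)
    nh = NoseHoover(thermostat, n_dof) if thermostat is not None else None

    if geom is not None:
        state = constrain_rigid(state, geom)

    series: dict = {}
    times = []
    frames, frame_times = [], []
    unwrapped = state.o_positions.copy() if track_unwrapped else None
    prev_o = state.o_positions.copy() if track_unwrapped else None
    uframes = []

    ef = forcefield(state)
    for step in range(n_steps):
        state, ef, cvir = step_nve(state, forcefield, dt, cache=ef, geom=geom,
                                   thermostat=nh)
        if barostat is not None:
            ef = _apply_barostat(state, forcefield, ef, barostat,
                                 thermostat.T if thermostat else 300.0,
                                 dt, rng, cvir)
        if track_unwrapped:
            from .system import minimum_image
            disp = minimum_image(state.o_positions - prev_o, state.box)
            unwrapped = unwrapped + disp
            prev_o = state.o_positions.copy()
        if (step + 1) % sample_every == 0:
            _sample(series, state, ef, cvir, params, n_constraints)
            times.append(state.time)
            if track_unwrapped:
                uframes.append(unwrapped.copy())
        if frame_every and (step + 1) % frame_every == 0:
            frames.append(state.positions.copy())
            frame_times.append(state.time)

    traj = Trajectory(times=np.asarray(times),
                      series={k: np.asarray(v) for k, v in series.items()},
                      frames=frames, frame_times=frame_times, state=state)
    if track_unwrapped:
        traj.series["O_unwrapped"] = np.asarray(uframes)
    traj.series["dt_sample"] = dt * sample_every
    return traj


def _apply_barostat(state, forcefield, ef, baro: BarostatParams, T: float,
                    dt: float, rng, cvir) -> SystemEnergyForces:
    """Isotropic cell rescaling toward the target pressure.

    Whole molecules are translated with their centre of mass so that
    internal geometry (and constraints) are untouched.
    """
    from .forces import molecular_pressure_tensor
    P_int = float(np.trace(molecular_pressure_tensor(state, ef)) / 3.0)
    kappa = baro.compressibility
    dlnv = (kappa / baro.tau_p) * (P_int - baro.P) * dt
    if baro.stochastic:
        # variance of d lnV: 2 kB T κ dt / (V τ); kB T in bar·Å³
        kT_barA3 = KB * T * P_INTERNAL_TO_BAR
        var = 2.0 * kT_barA3 * kappa * dt / (state.volume * baro.tau_p)
        dlnv += math.sqrt(max(var, 0.0)) * rng.standard_normal()
    scale = math.exp(dlnv / 3.0)
    if scale <= 0 or state.box.min() * scale < 1e-3:
        raise RuntimeError("barostat produced a vanishing box")
    com = state.com()
    shift = (scale - 1.0) * com
    mol = state.molecule_view()
    mol += shift[:, None, :]
    state.box *= scale
    return forcefield(state)


def run_nvt(state, forcefield, thermostat: ThermostatParams, n_steps: int,
            dt: float = 0.002, **kw) -> Trajectory:
    """NVT dynamics with the Nosé–Hoover thermostat."""
    return run_md(state, forcefield, dt, n_steps, thermostat=thermostat, **kw)


def run_npt(state, forcefield, thermostat: ThermostatParams,
            barostat: BarostatParams, n_steps: int, dt: float = 0.002,
            **kw) -> Trajectory:
    """NPT dynamics: Nosé–Hoover + isotropic cell rescaling."""
    return run_md(state, forcefield, dt, n_steps, thermostat=thermostat,
                  barostat=barostat, **kw)
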