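"""Deterministic generators for simulation inputs and synthetic data.

Everything the tests and desk-scale experiments need is generated in
code: jittered-lattice water boxes at a target density, liquid slabs
with a vacuum gap, proton-disordered ice Ih satisfying the
Bernal–Fowler rules, and synthetic time series / curves whose ground
truth is known exactly (shipped alongside as :class:`GroundTruth`).
Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AVOGADRO, WATER_MOLAR_MASS, KB_J
from .system import SystemState

MIN_OO_DIST = 2.4      # Å, distance floor for generated liquid configurations

# ice Ih lattice constants (standard hexagonal crystallography values)
ICE_A = 4.5            # Å
ICE_C = 7.32           # Å


@dataclass
class GroundTruth:
    """True parameter values behind a generated fixture."""

    generator: str
    params: dict
    seed: int | None = None
    derived: dict = field(default_factory=dict)


def _water_geometry(r_e: float, theta_e_deg: float):
    """Template molecule [O, H1, H2] centred on O at the origin."""
    th = math.radians(theta_e_deg)
    h1 = np.array([r_e * math.sin(th / 2.0), 0.0, r_e * math.cos(th / 2.0)])
    h2 = np.array([-r_e * math.sin(th / 2.0), 0.0, r_e * math.cos(th / 2.0)])
    return np.stack([np.zeros(3), h1, h2])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def box_edge_for_density(n: int, density_kg_m3: float) -> float:
    """Cubic box edge (Å) holding n water molecules at the given density."""
    v_per_mol = WATER_MOLAR_MASS / AVOGADRO / 1e3 / (density_kg_m3) * 1e30  # Å³
    return (n * v_per_mol) ** (1.0 / 3.0)


def build_water_box(n: int, density_kg_m3: float = 997.0, seed: int = 0,
                    r_e: float = 0.9572, theta_e_deg: float = 104.52,
                    jitter: float = 0.1) -> SystemState:
    """Water molecules on a jittered cubic lattice at a target density.

    Molecules receive random orientations; lattice jitter is capped so
    the minimum intermolecular O–O distance stays ≥ 2.4 Å.  The default
    geometry is overridden by the caller with the model's (r_e, θ_e).
    """
    if n < 2:
        raise ValueError("need at least 2 molecules")
    edge = box_edge_for_density(n, density_kg_m3)
    cells = math.ceil(n ** (1.0 / 3.0))
    spacing = edge / cells
    if spacing < MIN_OO_DIST:
        raise ValueError(
            f"density {density_kg_m3} kg/m³ gives lattice spacing "
            f"{spacing:.2f} Å < O–O floor {MIN_OO_DIST} Å — unattainable")
    rng = np.random.default_rng(seed)
    grid = np.array([(i, j, k) for i in range(cells)
                     for j in range(cells) for k in range(cells)], dtype=float)
    sel = rng.permutation(len(grid))[:n]
    centers = (grid[sel] + 0.5) * spacing
    max_jitter = min(jitter, max(0.0, (spacing - MIN_OO_DIST) / 2.0 - 0.05))
    centers += rng.uniform(-max_jitter, max_jitter, size=centers.shape)
    template = _water_geometry(r_e, theta_e_deg)
    positions = np.empty((3 * n, 3))
    for i, c in enumerate(centers):
        R = _random_rotation(rng)
        positions[3 * i: 3 * i + 3] = c + template @ R.T
    state = SystemState(box=np.full(3, edge), positions=positions)
    state.metadata.update({"generator": "build_water_box", "seed": seed,
                           "density_kg_m3": density_kg_m3})
    return state


def build_slab(n: int, lateral: float, L_z: float, seed: int = 0,
               r_e: float = 0.9572, theta_e_deg: float = 104.52,
               density_kg_m3: float = 997.0,
               cutoff_A: float = 17.5) -> SystemState:
    """Liquid slab centred in Z with vacuum above and below.

    ``lateral`` is the XY box edge (a float for a square footprint or
    an (Lx, Ly) pair) and ``L_z`` the full box height, in Å.  The slab
    thickness follows from n and the target density; the published
    protocols use 1728 molecules in 35.8×35.8×100 ų and 2139 in
    39.99×39.99×100 ų boxes with a ≥ 60 Å vacuum gap.
    """
    lx, ly = (lateral, lateral) if np.isscalar(lateral) else lateral
    v_per_mol = WATER_MOLAR_MASS / AVOGADRO / 1e3 / density_kg_m3 * 1e30
    thickness = n * v_per_mol / (lx * ly)
    vacuum = L_z - thickness
    if vacuum < 0:
        raise ValueError("slab thicker than the box: increase L_z")
    if vacuum < 2.0 * cutoff_A:
        import warnings
        warnings.warn(f"vacuum gap {vacuum:.1f} Å is below twice the vdW "
                      f"cutoff ({cutoff_A} Å): slab images will interact",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    nx = max(1, round(lx / 3.1))
    ny = max(1, round(ly / 3.1))
    nz = math.ceil(n / (nx * ny))
    sx, sy, sz = lx / nx, ly / ny, thickness / nz
    if min(sx, sy, sz) < MIN_OO_DIST:
        raise ValueError(
            f"slab lattice spacing ({sx:.2f}, {sy:.2f}, {sz:.2f}) Å "
            f"violates the O–O floor {MIN_OO_DIST} Å")
    grid = np.array([(i, j, k) for k in range(nz)
                     for i in range(nx) for j in range(ny)], dtype=float)[:n]
    centers = np.empty((n, 3))
    centers[:, 0] = (grid[:, 0] + 0.5) * sx
    centers[:, 1] = (grid[:, 1] + 0.5) * sy
    centers[:, 2] = (grid[:, 2] + 0.5) * sz + (L_z - thickness) / 2.0
    centers += rng.uniform(-0.08, 0.08, size=centers.shape)
    template = _water_geometry(r_e, theta_e_deg)
    positions = np.empty((3 * n, 3))
    for i, c in enumerate(centers):
        R = _random_rotation(rng)
        positions[3 * i: 3 * i + 3] = c + template @ R.T
    state = SystemState(box=np.array([lx, ly, L_z]), positions=positions)
    state.metadata.update({"generator": "build_slab", "seed": seed,
                           "thickness_A": thickness, "vacuum_A": vacuum})
    return state


# --------------------------------------------------------------------------
# proton-disordered ice Ih
# --------------------------------------------------------------------------

def _ih_oxygen_lattice(cells):
    """Oxygen fractional coordinates of an orthorhombic ice-Ih cell.

    8 oxygens per orthorhombic cell (a, a√3, c); the wurtzite-type
    arrangement of the hexagonal lattice.
    """
    # lonsdaleite 4f sites (z = 1/16) mapped onto the orthorhombic cell
    base = np.array([
        [0.0, 1.0 / 3.0, 0.0625],
        [0.5, 5.0 / 6.0, 0.0625],
        [0.0, 1.0 / 3.0, 0.4375],
        [0.5, 5.0 / 6.0, 0.4375],
        [0.5, 1.0 / 6.0, 0.5625],
        [0.0, 2.0 / 3.0, 0.5625],
        [0.5, 1.0 / 6.0, 0.9375],
        [0.0, 2.0 / 3.0, 0.9375],
    ])
    na, nb, nc = cells
    cell = np.array([ICE_A, ICE_A * math.sqrt(3.0), ICE_C])
    box = cell * np.array([na, nb, nc])
    frac = []
    for i in range(na):
        for j in range(nb):
            for k in range(nc):
                frac.append((base + np.array([i, j, k])) / np.array([na, nb, nc]))
    pos = np.concatenate(frac) * box
    return pos, box


def _hb_graph(o_pos, box):
    """Edges (i, j) of the O–O hydrogen-bond network (4 per O)."""
    from .system import minimum_image
    n = len(o_pos)
    d = minimum_image(o_pos[:, None, :] - o_pos[None, :, :], box)
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    edges = set()
    for i in range(n):
        for j in np.argsort(r[i])[:4]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return sorted(edges)


def build_ice_ih(cells=(2, 2, 2), seed: int = 0, r_e: float = 0.9572,
                 theta_e_deg: float = 104.52, max_sweeps: int = 2000
                 ) -> SystemState:
    """Proton-disordered hexagonal ice Ih obeying the ice rules.

    The oxygen lattice is fixed; protons are assigned to the O–O bond
    network by seeded zero-temperature Monte Carlo on the Bernal–Fowler
    defect count (each O donates exactly 2 H; each bond carries exactly
    one H), then the two covalent hydrogens of each molecule are
    snapped to the model geometry about the donated-bond directions.
    """
    if any(c < 1 for c in cells) or any(c % 1 for c in cells):
        raise ValueError("cell counts must be positive integers")
    o_pos, box = _ih_oxygen_lattice(cells)
    n = len(o_pos)
    edges = _hb_graph(o_pos, box)
    if len(edges) != 2 * n:
        raise RuntimeError("malformed O–O network: expected 2 bonds per O")
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        direction = rng.integers(0, 2, size=len(edges))  # 1: i donates to j
        out_deg = np.zeros(n, dtype=int)
        for e, (i, j) in enumerate(edges):
            out_deg[i if direction[e] else j] += 1
        ok = _fix_ice_rules(edges, direction, out_deg, rng, max_sweeps)
        if ok:
            break
    else:
        raise RuntimeError("proton-disorder sampling failed to satisfy the "
                           "ice rules after retries")

    from .system import minimum_image
    donated = [[] for _ in range(n)]
    for e, (i, j) in enumerate(edges):
        donor, acc = (i, j) if direction[e] else (j, i)
        v = minimum_image(o_pos[acc] - o_pos[donor], box)
        donated[donor].append(v / np.linalg.norm(v))
    th = math.radians(theta_e_deg)
    positions = np.empty((3 * n, 3))
    for i in range(n):
        u1, u2 = donated[i]
        # symmetrize the two donated directions to the model angle
        bis = u1 + u2
        bis /= np.linalg.norm(bis)
        perp = u1 - u2
        nrm = np.linalg.norm(perp)
        if nrm < 1e-8:          # degenerate (collinear) — pick any normal
            perp = np.cross(bis, [1.0, 0.0, 0.0])
            if np.linalg.norm(perp) < 1e-8:
                perp = np.cross(bis, [0.0, 1.0, 0.0])
            nrm = np.linalg.norm(perp)
        perp /= nrm
        h1 = bis * math.cos(th / 2.0) + perp * math.sin(th / 2.0)
        h2 = bis * math.cos(th / 2.0) - perp * math.sin(th / 2.0)
        positions[3 * i] = o_pos[i]
        positions[3 * i + 1] = o_pos[i] + r_e * h1
        positions[3 * i + 2] = o_pos[i] + r_e * h2
    state = SystemState(box=box, positions=positions)
    state.metadata.update({"generator": "build_ice_ih", "seed": seed,
                           "cells": tuple(cells),
                           "lattice": {"a": ICE_A, "c": ICE_C}})
    return state


def _fix_ice_rules(edges, direction, out_deg, rng, max_sweeps) -> bool:
    """Zero-temperature MC on Σ(out_deg−2)²: flip bonds that reduce it."""
    n_edges = len(edges)
    cost = int(np.sum((out_deg - 2) ** 2))
    for sweep in range(max_sweeps):
        if cost == 0:
            return True
        order = rng.permutation(n_edges)
        improved = False
        for e in order:
            i, j = edges[e]
            donor, acc = (i, j) if direction[e] else (j, i)
            # flipping moves one donation from donor to acc
            d_old = ((out_deg[donor] - 2) ** 2 + (out_deg[acc] - 2) ** 2)
            d_new = ((out_deg[donor] - 3) ** 2 + (out_deg[acc] - 1) ** 2)
            delta = d_new - d_old
            if delta < 0 or (delta == 0 and rng.random() < 0.1):
                direction[e] ^= 1
                out_deg[donor] -= 1
                out_deg[acc] += 1
                cost += delta
                improved = True
        if not improved and cost > 0:
            # random restart kick: flip a few random bonds
            for e in rng.integers(0, n_edges, size=4):
                i, j = edges[e]
                donor, acc = (i, j) if direction[e] else (j, i)
                d_old = ((out_deg[donor] - 2) ** 2 + (out_deg[acc] - 2) ** 2)
                d_new = ((out_deg[donor] - 3) ** 2 + (out_deg[acc] - 1) ** 2)
                direction[e] ^= 1
                out_deg[donor] -= 1
                out_deg[acc] += 1
                cost += d_new - d_old
    return cost == 0


# --------------------------------------------------------------------------
# synthetic time series
# --------------------------------------------------------------------------

def _ar1(n, mean, std, ac_time, dt, rng):
    """Stationary AR(1) (discrete Ornstein–Uhlenbeck) series."""
    if ac_time <= 0:
        return mean + std * rng.standard_normal(n)
    phi = math.exp(-dt / ac_time)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n) * math.sqrt(1 - phi * phi)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    return mean + std * x


def synth_series(kind: str, true_params: dict, length: int, seed: int = 0,
                 dt: float = 1.0, ac_time: float = 0.0):
    """Synthetic observable stream with exactly known moments.

    kinds and their ground truth:

    - ``volume``: Gaussian V series; params mean_A3, T_K and either
      std_A3 or kappa_MPa (variance chosen to imply that κ_T).
    - ``enthalpy``: Gaussian H series; params mean_kcal, std_kcal.
    - ``dipole``: isotropic Gaussian M(t); params V_A3, T_K and either
      std_eA or epsilon (raw) to imply that dielectric constant.
    - ``pressure_tensor``: anisotropic Gaussian diagonal components;
      params mean_lateral_bar, mean_normal_bar, std_bar, L_z_A (ground
      truth carries the implied γ in mN/m).
    - ``msd_walk``: 3D random walk of n_particles; params D_1e5_cm2_s.

    Returns (TimeSeries or dict of TimeSeries, GroundTruth).
    """
    from .properties import TimeSeries
    from .constants import COULOMB, KB
    if length <= 0:
        raise ValueError("series length must be positive")
    rng = np.random.default_rng(seed)
    p = dict(true_params)
    if kind == "volume":
        mean = p["mean_A3"]
        T = p.get("T_K", 298.0)
        if "kappa_MPa" in p:
            var = p["kappa_MPa"] * 1e-6 * KB_J * T * mean / 1e-30
            std = math.sqrt(var)
        else:
            std = p["std_A3"]
        vals = _ar1(length, mean, std, ac_time, dt, rng)
        kappa = (std * std * 1e-30 / (KB_J * T * mean) * 1e6
                 if mean > 0 else float("nan"))
        gt = GroundTruth("volume", p, seed, {"kappa_MPa": kappa})
        return TimeSeries("V", vals, dt, "A^3"), gt
    if kind == "enthalpy":
        vals = _ar1(length, p["mean_kcal"], p["std_kcal"], ac_time, dt, rng)
        return (TimeSeries("H", vals, dt, "kcal/mol"),
                GroundTruth("enthalpy", p, seed))
    if kind == "dipole":
        V, T = p["V_A3"], p.get("T_K", 298.0)
        pref = 4.0 * math.pi * COULOMB / (3.0 * V * KB * T)
        if "epsilon_raw" in p:
            var_tot = (p["epsilon_raw"] - 1.0) / pref
            std = math.sqrt(var_tot / 3.0)
        else:
            std = p["std_eA"]
        vals = np.column_stack([_ar1(length, 0.0, std, ac_time, dt, rng)
                                for _ in range(3)])
        eps_raw = 1.0 + pref * 3.0 * std * std
        gt = GroundTruth("dipole", p, seed, {"epsilon_raw": eps_raw,
                                             "epsilon_scaled": eps_raw + 0.78})
        return TimeSeries("M", vals, dt, "e*A"), gt
    if kind == "pressure_tensor":
        lat, nor, std = p["mean_lateral_bar"], p["mean_normal_bar"], p["std_bar"]
        comps = {}
        for name, mean in (("P_xx", lat), ("P_yy", lat), ("P_zz", nor)):
            comps[name] = TimeSeries(name,
                                     _ar1(length, mean, std, ac_time, dt, rng),
                                     dt, "bar")
        gamma = 0.5 * p["L_z_A"] * (nor - lat) * 1e-2
        gt = GroundTruth("pressure_tensor", p, seed, {"gamma_mN_m": gamma})
        return comps, gt
    if kind == "msd_walk":
        D = p["D_1e5_cm2_s"] / 10.0       # -> Å²/ps
        npart = p.get("n_particles", 50)
        step_std = math.sqrt(2.0 * D * dt)
        steps = rng.normal(scale=step_std, size=(length, npart, 3))
        pos = np.cumsum(steps, axis=0)
        gt = GroundTruth("msd_walk", p, seed, {"D_1e5_cm2_s": p["D_1e5_cm2_s"]})
        return pos, gt
    raise ValueError(f"unknown series kind {kind!r}")


def synth_curves(kind: str, true_params: dict, T_grid: np.ndarray,
                 noise: float = 0.0, seed: int = 0):
    """Synthetic analysis curves from the closed forms, plus noise.

    kinds: ``gamma_iapws_e`` (params T_c, B, b, c, T_e),
    ``coexistence_wegner`` (params T_c, B0, B1, rho_c, c1, c2),
    ``antoine`` (params A, B, C).
    """
    from .criticality import iapws_e_curve, wegner_difference, ALPHA_PRIME
    T = np.asarray(T_grid, dtype=float)
    rng = np.random.default_rng(seed)
    p = dict(true_params)
    if kind == "gamma_iapws_e":
        g = iapws_e_curve(T, p["T_c"], p["B"], p["b"], p["c"], p["T_e"])
        g = g + noise * rng.standard_normal(len(T))
        return {"T": T, "gamma": g}, GroundTruth(kind, p, seed)
    if kind == "coexistence_wegner":
        if np.any(T >= p["T_c"]):
            raise ValueError("coexistence grid must satisfy T < T_c")
        tau = 1.0 - T / p["T_c"]
        diff = wegner_difference(T, p["T_c"], p["B0"], [p.get("B1", 0.0)])
        diam = (p["rho_c"] + p.get("c1", 0.0) * tau ** (1.0 - ALPHA_PRIME)
                + p.get("c2", 0.0) * tau)
        rho_l = diam + diff / 2.0 + noise * rng.standard_normal(len(T))
        rho_v = diam - diff / 2.0 + noise * rng.standard_normal(len(T))
        return ({"T": T, "rho_liquid": rho_l, "rho_vapor": rho_v},
                GroundTruth(kind, p, seed))
    if kind == "antoine":
        lnP = p["A"] - p["B"] / (T + p["C"])
        P = np.exp(lnP + noise * rng.standard_normal(len(T)))
        return {"T": T, "P": P}, GroundTruth(kind, p, seed)
    raise ValueError(f"unknown curve kind {kind!r}")
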