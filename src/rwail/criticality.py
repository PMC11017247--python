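"""Critical-phenomena analysis for the rWAIL water model.

Liquid–vapor side: bulk phase densities from slab density profiles,
the Wegner expansion for T_c, the singular-diameter law for ρ_c, and
Antoine vapor-pressure extrapolation for P_c.  Supercooled side: the
IAPWS-E surface-tension fit with its exponential emergence component,
and localization of the liquid–liquid critical point from κ_T(T,P)
and ρ(T,P) grids.  A protocol driver for the NVE three-phase
coexistence melting point completes the set.

Fixed critical exponents follow the 3D Ising universality class:
β = 0.325, Δ = 0.5 (Wegner), α′ = 0.11 (diameter), μ = 11/9 (surface
tension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from scipy.stats import qmc

BETA_ISING = 0.325
DELTA_WEGNER = 0.5
ALPHA_PRIME = 0.11
MU_IAPWS = 11.0 / 9.0
GAMMA_S = 1.0          # mN/m: emergence convention defining T_e

N_MULTISTART = 8
FIT_TOL = 1e-10


@dataclass
class FitResult:
    """Fitted + fixed parameters with uncertainties and diagnostics."""

    params: dict
    fixed: dict
    stderr: dict
    residual_rms: float
    settings: dict = field(default_factory=dict)

    def __getitem__(self, key):
        if key in self.params:
            return self.params[key]
        return self.fixed[key]

    def report(self) -> dict:
        return {"free_parameters": self.params, "fixed_parameters": self.fixed,
                "stderr": self.stderr, "residual_rms": self.residual_rms,
                "settings": self.settings}


@dataclass
class CoexistencePoint:
    """One liquid–vapor coexistence state from a slab run."""

    T: float                 # K
    rho_liquid: float        # kg/m³
    rho_vapor: float         # kg/m³
    p_vap: float | None = None   # bar
    source: str = ""


@dataclass
class LlcpEstimate:
    """Bracketed liquid–liquid critical point."""

    T: float | None
    P: float | None          # MPa
    rho: float | None        # kg/m³
    dT: float = 0.0
    dP: float = 0.0
    bracketed: bool = False
    detail: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# slab density profiles
# --------------------------------------------------------------------------

def slab_phase_densities(z: np.ndarray, rho: np.ndarray,
                         interface_exclusion: float = 5.0,
                         min_contrast: float = 5.0):
    """Bulk liquid and vapor densities from a slab density profile.

    Fits the symmetric two-interface profile
        ρ(z) = ρ_v + (ρ_l − ρ_v)/2 [tanh((z−z0+t)/d) − tanh((z−z0−t)/d)]
    and then averages plateau regions at least ``interface_exclusion``
    (Å) away from the fitted interfaces.  Raises if the profile shows
    no coexistence (contrast below ``min_contrast`` × profile noise).
    """
    z = np.asarray(z, dtype=float)
    rho = np.asarray(rho, dtype=float)
    span = rho.max() - rho.min()
    noise = float(np.std(np.diff(rho))) / math.sqrt(2.0)
    if span < min_contrast * max(noise, 1e-12) or span < 1e-9:
        raise ValueError("no identifiable liquid/vapor plateaus: profile is "
                         "uniform (coexistence lost, possibly supercritical)")

    def profile(zz, rv, rl, z0, t, d):
        return rv + 0.5 * (rl - rv) * (np.tanh((zz - z0 + t) / d)
                                       - np.tanh((zz - z0 - t) / d))

    z0_guess = float(np.sum(z * rho) / np.sum(rho))
    t_guess = max((z.max() - z.min()) / 6.0, 1.0)
    p0 = [max(rho.min(), 0.0), rho.max(), z0_guess, t_guess, 2.0]
    try:
        popt, _ = curve_fit(profile, z, rho, p0=p0, maxfev=20000)
        rv, rl, z0, t, d = popt
        t, d = abs(t), abs(d)
    except RuntimeError:
        rv, rl = rho.min(), rho.max()
        z0, t, d = z0_guess, t_guess, 2.0
    lo_if, hi_if = z0 - t, z0 + t
    # keep at least 4 interface widths away so tanh tails bias the
    # plateau means by < 0.1%
    excl = max(interface_exclusion, 4.0 * d)
    liq_mask = (z > lo_if + excl) & (z < hi_if - excl)
    vap_mask = (z < lo_if - excl) | (z > hi_if + excl)
    if liq_mask.sum() < 3 or vap_mask.sum() < 3:
        raise ValueError("interface exclusion leaves no plateau region; "
                         "slab too thin or coexistence lost")
    rho_l = float(np.mean(rho[liq_mask]))
    rho_v = float(np.mean(rho[vap_mask]))
    if rho_l < rho_v:
        rho_l, rho_v = rho_v, rho_l
    return rho_l, max(rho_v, 0.0)


# --------------------------------------------------------------------------
# coexistence-curve fits
# --------------------------------------------------------------------------

def wegner_difference(T, T_c, B0, corrections):
    """ρ_l − ρ_v = B0 τ^β (1 + Σ_m B_m τ^(mΔ)), τ = 1 − T/T_c."""
    tau = 1.0 - np.asarray(T, dtype=float) / T_c
    tau = np.clip(tau, 0.0, None)
    series = np.ones_like(tau)
    for m, Bm in enumerate(corrections, start=1):
        series = series + Bm * tau ** (m * DELTA_WEGNER)
    return B0 * tau ** BETA_ISING * series


def wegner_fit(points: list[CoexistencePoint], n_corrections: int = 1
               ) -> FitResult:
    """Fit the Wegner expansion to ρ_l − ρ_v; exponents fixed, T_c free.

    ``n_corrections`` analytic correction amplitudes beyond leading
    order (default 1).
    """
    pts = sorted(points, key=lambda p: p.T)
    T = np.array([p.T for p in pts])
    dr = np.array([p.rho_liquid - p.rho_vapor for p in pts])
    if len(T) < 4:
        raise ValueError("need at least 4 subcritical coexistence points")
    if np.any(dr <= 0):
        raise ValueError("rho_liquid must exceed rho_vapor below T_c")

    def resid(theta):
        T_c, B0 = theta[0], theta[1]
        if T_c <= T.max():
            return np.full_like(dr, 1e6)
        return wegner_difference(T, T_c, B0, theta[2:]) - dr

    Tc0 = T.max() / (1.0 - (dr[-1] / dr[0]) ** (1.0 / BETA_ISING) *
                     (1.0 - 0.0)) if dr[0] > 0 else T.max() * 1.1
    Tc0 = max(T.max() * 1.02, min(Tc0, T.max() * 2.0))
    x0 = np.r_[Tc0, dr[0] / (1 - T[0] / Tc0) ** BETA_ISING,
               np.zeros(n_corrections)]
    sol = least_squares(resid, x0, xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL)
    if not sol.success or sol.x[0] <= T.max():
        raise RuntimeError(f"Wegner fit failed to converge: {sol.message}; "
                           f"residual {np.abs(sol.fun).max():.3g}")
    stderr = _lsq_stderr(sol)
    names = ["T_c", "B0"] + [f"B{m}" for m in range(1, n_corrections + 1)]
    return FitResult(params=dict(zip(names, map(float, sol.x))),
                     fixed={"beta": BETA_ISING, "Delta": DELTA_WEGNER},
                     stderr=dict(zip(names, stderr)),
                     residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))),
                     settings={"n_corrections": n_corrections})


def critical_density_fit(points: list[CoexistencePoint], T_c: float) -> FitResult:
    """Singular-diameter fit for ρ_c with α′ = 0.11 fixed.

    (ρ_l + ρ_v)/2 = ρ_c + c1 τ^(1−α′) + c2 τ  — linear least squares.
    """
    T = np.array([p.T for p in points])
    diam = np.array([(p.rho_liquid + p.rho_vapor) / 2.0 for p in points])
    tau = 1.0 - T / T_c
    if np.any(tau <= 0):
        raise ValueError("all points must be subcritical (T < T_c)")
    X = np.column_stack([np.ones_like(tau), tau ** (1.0 - ALPHA_PRIME), tau])
    coef, res, rank, _ = np.linalg.lstsq(X, diam, rcond=None)
    fitted = X @ coef
    rms = float(np.sqrt(np.mean((diam - fitted) ** 2)))
    dof = max(len(T) - 3, 1)
    sigma2 = np.sum((diam - fitted) ** 2) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    names = ["rho_c", "c1", "c2"]
    return FitResult(params=dict(zip(names, map(float, coef))),
                     fixed={"T_c": T_c, "alpha_prime": ALPHA_PRIME},
                     stderr=dict(zip(names, np.sqrt(np.diag(cov)))),
                     residual_rms=rms, settings={})


def antoine_fit(T: np.ndarray, P: np.ndarray) -> FitResult:
    """Antoine equation ln P = A − B/(T + C), least squares on ln P."""
    T = np.asarray(T, dtype=float)
    P = np.asarray(P, dtype=float)
    if len(T) < 3:
        raise ValueError("Antoine fit needs at least 3 (T, P) points")
    if np.any(P <= 0):
        raise ValueError("vapor pressures must be positive")
    lnP = np.log(P)

    def resid(theta):
        A, B, C = theta
        return A - B / (T + C) - lnP

    # linearized start: assume C=0
    slope, intercept = np.polyfit(1.0 / T, lnP, 1)
    x0 = np.array([intercept, -slope, 0.0])
    sol = least_squares(resid, x0, xtol=FIT_TOL, ftol=FIT_TOL, gtol=FIT_TOL)
    if not sol.success:
        raise RuntimeError(f"Antoine fit failed: {sol.message}")
    names = ["A", "B", "C"]
    return FitResult(params=dict(zip(names, map(float, sol.x))),
                     fixed={}, stderr=dict(zip(names, _lsq_stderr(sol))),
                     residual_rms=float(np.sqrt(np.mean(sol.fun ** 2))),
                     settings={"objective": "least squares on ln(P)"})


def extrapolate_pc(fit: FitResult, T_c: float) -> float:
    """Critical pressure: the Antoine form evaluated at T_c."""
    return float(math.exp(fit["A"] - fit["B"] / (T_c + fit["C"])))


# --------------------------------------------------------------------------
# IAPWS-E surface-tension fit
# --------------------------------------------------------------------------

def iapws_classical(T, T_c, B, b):
    """Classical IAPWS term B τ^μ (1 + b τ), μ = 11/9."""
    tau = np.clip(1.0 - np.asarray(T, dtype=float) / T_c, 0.0, None)
    return B * tau ** MU_IAPWS * (1.0 + b * tau)


def iapws_e_curve(T, T_c, B, b, c, T_e, gamma_s: float = GAMMA_S):
    """IAPWS-E: classical term plus the exponential emergence component.

    γ(T) = B τ^μ (1 + b τ) + γ_s exp(c (T_e − T)); by construction the
    exponential equals γ_s (1 mN/m) at T = T_e.
    """
    return iapws_classical(T, T_c, B, b) + gamma_s * np.exp(
        c * (T_e - np.asarray(T, dtype=float)))


@dataclass
class IapwsEFit(FitResult):
    """IAPWS-E fit result; T_c fixed, μ = 11/9, γ_s = 1 mN/m convention."""

    emergence_detected: bool = True


def iapws_e_fit(T: np.ndarray, gamma: np.ndarray, T_c: float,
                stderr: np.ndarray | None = None, seed: int = 2016,
                emergence_floor: float = 0.05) -> IapwsEFit:
    """Weighted fit of the IAPWS-E form; returns B, b, c, T_e.

    T_c is supplied (from liquid–vapor coexistence), never fitted.
    Multistart trust-region least squares from a seeded Latin
    hypercube.  If the fitted exponential component stays below
    ``emergence_floor`` mN/m over the data range, the emergence
    temperature is reported as not detected.
    """
    T = np.asarray(T, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if len(T) < 4:
        raise ValueError("need at least 4 points for 4 free parameters")
    w = 1.0 / np.asarray(stderr, dtype=float) if stderr is not None \
        else np.ones_like(T)
    w = w / w.mean()        # invariant to affine weight rescaling
    if T.min() > 320.0:
        raise ValueError("no supercooled/low-temperature points: the "
                         "emergence component (T_e) is unidentifiable")

    order = np.argsort(T)
    T_, g_, w_ = T[order], gamma[order], w[order]

    def resid(theta):
        B, b, c, T_e = theta
        expo = GAMMA_S * np.exp(np.clip(c * (T_e - T_), -700.0, 60.0))
        return w_ * (iapws_classical(T_, T_c, B, b) + expo - g_)

    # seed the multistart around a classical-only fit; clamp so the
    # start window stays ordered even for pathological input
    tau = 1.0 - T_ / T_c
    B0 = float(np.median(g_ / np.clip(tau ** MU_IAPWS, 1e-9, None)))
    B0 = max(abs(B0), 1e-3)
    sampler = qmc.LatinHypercube(d=4, seed=seed)
    unit = sampler.random(N_MULTISTART)
    lo = np.array([0.5 * B0, -1.5, 0.01, T_.min() - 50.0])
    hi = np.array([1.5 * B0, 0.5, 0.5, T_.min() + 80.0])
    starts = lo + unit * (hi - lo)
    bounds = (np.array([0.0, -5.0, 1e-3, T_.min() - 150.0]),
              np.array([np.inf, 5.0, 1.0, T_.max()]))
    best = None
    for x0 in starts:
        try:
            sol = least_squares(resid, x0, xtol=FIT_TOL, ftol=FIT_TOL,
                                gtol=FIT_TOL, max_nfev=4000, bounds=bounds)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise RuntimeError("IAPWS-E fit failed from all multistarts")
    B, b, c, T_e = map(float, best.x)
    expo = GAMMA_S * np.exp(c * (T_e - T_))
    detected = bool(np.max(expo) >= emergence_floor)
    names = ["B", "b", "c", "T_e"]
    err = dict(zip(names, _lsq_stderr(best)))
    fit = IapwsEFit(params={"B": B, "b": b, "c": c,
                            "T_e": T_e if detected else float("nan")},
                    fixed={"T_c": T_c, "mu": MU_IAPWS, "gamma_s": GAMMA_S},
                    stderr=err,
                    residual_rms=float(np.sqrt(np.mean(best.fun ** 2))),
                    settings={"seed": seed, "n_multistart": N_MULTISTART,
                              "parameterization": "B, b, c, T_e free; "
                              "gamma_s=1 pins the exponential amplitude"},
                    emergence_detected=detected)
    return fit


# --------------------------------------------------------------------------
# liquid–liquid critical point
# --------------------------------------------------------------------------

def locate_llcp(T_grid: np.ndarray, P_grid_MPa: np.ndarray,
                kappa: np.ndarray, rho: np.ndarray,
                rho_stderr: np.ndarray | None = None,
                jump_sigma: float = 5.0) -> LlcpEstimate:
    """Bracket the liquid–liquid critical point on a (T, P) grid.

    Each isobar is classified as *continuous* (κ_T shows a finite peak
    — the Widom line) or *discontinuous* (a density jump between
    adjacent temperatures exceeding ``jump_sigma`` × the pooled block
    stderr).  The critical point is bracketed between the highest
    continuous and lowest discontinuous isobar; T comes from the κ_T
    maxima of the bracketing isobars, ρ from the density at the
    estimate.  Uncertainties are at least the grid spacing.  With no
    bracket, returns a "not bracketed" result — never a fabricated
    point.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    P_grid = np.asarray(P_grid_MPa, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    rho = np.asarray(rho, dtype=float)
    if kappa.shape != (len(T_grid), len(P_grid)):
        raise ValueError("kappa grid must be (n_T, n_P)")
    if rho_stderr is None:
        rho_stderr = np.zeros_like(rho)
    pooled = float(np.sqrt(np.mean(np.asarray(rho_stderr) ** 2)))
    classes = []
    peak_T = []
    for j in range(len(P_grid)):
        djump = np.abs(np.diff(rho[:, j]))
        thresh = jump_sigma * max(pooled, 1e-12)
        rho_range = float(rho[:, j].max() - rho[:, j].min())
        # first-order: one adjacent-T jump that both exceeds the error
        # bars and carries most of the isobar's total density change —
        # a steep but continuous Widom crossing spreads its change over
        # several grid cells instead
        discont = bool(djump.max() > max(thresh, 0.45 * rho_range)
                       and rho_range > thresh)
        classes.append("discontinuous" if discont else "continuous")
        k = kappa[:, j]
        peak_idx = int(np.argmax(k))
        interior = 0 < peak_idx < len(T_grid) - 1
        has_peak = interior and k[peak_idx] > 1.5 * np.median(k)
        peak_T.append(T_grid[peak_idx] if has_peak else None)

    dT = float(np.min(np.abs(np.diff(T_grid)))) if len(T_grid) > 1 else 0.0
    dP = float(np.min(np.abs(np.diff(P_grid)))) if len(P_grid) > 1 else 0.0
    cont = [j for j, c in enumerate(classes) if c == "continuous"]
    disc = [j for j, c in enumerate(classes) if c == "discontinuous"]
    detail = {"isobar_class": dict(zip(map(float, P_grid), classes)),
              "kappa_peak_T": dict(zip(map(float, P_grid),
                                       [t if t is None else float(t)
                                        for t in peak_T]))}
    if not cont or not disc:
        if not any(t is not None for t in peak_T) and not disc:
            detail["verdict"] = "no LLCP detected (featureless grids)"
        else:
            detail["verdict"] = "not bracketed by the scanned pressure range"
        return LlcpEstimate(T=None, P=None, rho=None, bracketed=False,
                            detail=detail)
    # bracketing pair: adjacent isobars whose classification changes
    # (works for either orientation of the first-order region in P)
    transitions = [j for j in range(len(P_grid) - 1)
                   if classes[j] != classes[j + 1]]
    j_a, j_b = transitions[0], transitions[0] + 1
    j_cont = j_a if classes[j_a] == "continuous" else j_b
    j_disc = j_b if j_cont == j_a else j_a
    P_c = 0.5 * (float(P_grid[j_a]) + float(P_grid[j_b]))
    Ts = [t for t in (peak_T[j_cont], peak_T[j_disc]) if t is not None]
    if not Ts:
        # fall back to the largest-jump temperature on the
        # discontinuous side of the bracket
        jj = int(np.argmax(np.abs(np.diff(rho[:, j_disc]))))
        Ts = [0.5 * (T_grid[jj] + T_grid[jj + 1])]
    T_c = float(np.mean(Ts))
    i_c = int(np.argmin(np.abs(T_grid - T_c)))
    rho_c = float(0.5 * (rho[i_c, j_a] + rho[i_c, j_b]))
    return LlcpEstimate(T=T_c, P=float(P_c), rho=rho_c,
                        dT=dT,
                        dP=max(dP, float(abs(P_grid[j_b] - P_grid[j_a]) / 2.0)),
                        bracketed=True, detail=detail)


# --------------------------------------------------------------------------
# melting point: NVE three-phase coexistence driver
# --------------------------------------------------------------------------

def tetrahedral_order(o_positions: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Per-molecule tetrahedral order parameter q of the O lattice.

    q = 1 − 3/8 Σ_{j<k} (cos ψ_jk + 1/3)² over the 4 nearest O
    neighbours; q → 1 in ice Ih, ~0.5–0.65 in the liquid.
    """
    from .system import minimum_image
    pos = np.asarray(o_positions, dtype=float)
    n = len(pos)
    d = minimum_image(pos[:, None, :] - pos[None, :, :], np.asarray(box))
    r = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(r, np.inf)
    q = np.empty(n)
    for i in range(n):
        nn = np.argsort(r[i])[:4]
        v = d[nn, i] / r[i][nn][:, None]
        s = 0.0
        for a in range(4):
            for b_ in range(a + 1, 4):
                s += (float(np.dot(v[a], v[b_])) + 1.0 / 3.0) ** 2
        q[i] = 1.0 - 3.0 / 8.0 * s
    return q


def classify_end_state(o_positions: np.ndarray, box: np.ndarray,
                       ice_threshold: float = 0.8,
                       liquid_threshold: float = 0.7) -> str:
    """'ice', 'liquid' or 'ambiguous' from the mean tetrahedral order."""
    qbar = float(np.mean(tetrahedral_order(o_positions, box)))
    if qbar >= ice_threshold:
        return "ice"
    if qbar <= liquid_threshold:
        return "liquid"
    return "ambiguous"


@dataclass
class MeltingPointConfig:
    """Bracketing temperatures (K) and the propagate/classify hooks.

    ``propagate(T) -> (o_positions, box)`` runs the NVE three-phase
    cell initialized at temperature T to its end state (0.5 fs steps in
    the full protocol); ``classify`` maps an end state to
    'ice'/'liquid'/'ambiguous'.  Both are injectable so the driver is
    testable without cluster-scale dynamics.
    """

    T_high: float = 280.0
    T_low: float = 260.0
    max_bisections: int = 6
    propagate: object = None
    classify: object = classify_end_state


@dataclass
class MeltingPointEstimate:
    bracket: tuple[float, float]
    T_M: float
    ambiguous: bool = False
    history: list = field(default_factory=list)


def melting_point_three_phase(config: MeltingPointConfig) -> MeltingPointEstimate:
    """Bisect the melting temperature between T_low and T_high.

    At each trial temperature the three-phase (ice/liquid/vapor) cell
    is propagated at constant energy; ice growth marks T < T_M, ice
    loss marks T > T_M.  Ambiguous end states widen the bracket and
    flag the estimate.
    """
    if config.propagate is None:
        raise ValueError("MeltingPointConfig.propagate must be provided")
    lo, hi = config.T_low, config.T_high
    history = []
    ambiguous = False
    for _ in range(config.max_bisections):
        mid = 0.5 * (lo + hi)
        end_pos, box = config.propagate(mid)
        verdict = config.classify(end_pos, box)
        history.append((mid, verdict))
        if verdict == "ice":
            lo = mid        # ice grew: below the melting point
        elif verdict == "liquid":
            hi = mid
        else:
            ambiguous = True
            break
    return MeltingPointEstimate(bracket=(lo, hi), T_M=0.5 * (lo + hi),
                                ambiguous=ambiguous, history=history)


def _lsq_stderr(sol) -> np.ndarray:
    """Parameter standard errors from a scipy least_squares solution."""
    m, n = sol.jac.shape
    dof = max(m - n, 1)
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * 2.0 * sol.cost / dof
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        return np.full(n, float("nan"))
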