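"""Structure and time-series file IO.

GRO (Gromacs coordinate, nm, fixed-width, 3-decimal) and XYZ (Å) for
structures; CSV for time series.  Round trips are lossless at the
format's stated precision.  GRO/XYZ files written here carry the three
physical sites per molecule (O, HW1, HW2); the virtual M site is a
derived quantity and is regenerated on read.
"""

from __future__ import annotations

import numpy as np

from .properties import TimeSeries
from .system import SystemState

_GRO_NAMES = ("OW", "HW1", "HW2")


def write_gro(state: SystemState, path, title: str = "rWAIL water") -> None:
    """Write a GRO file (positions nm, optional velocities nm/ps)."""
    pos_nm = state.positions / 10.0
    vel = state.velocities / 10.0
    has_vel = np.any(vel != 0.0)
    with open(path, "w") as fh:
        fh.write(f"{title}\n{state.n_sites:d}\n")
        for i in range(state.n_sites):
            mol = i // 3 + 1
            name = _GRO_NAMES[i % 3]
            line = (f"{mol % 100000:5d}{'SOL':<5s}{name:>5s}{(i + 1) % 100000:5d}"
                    f"{pos_nm[i, 0]:8.3f}{pos_nm[i, 1]:8.3f}{pos_nm[i, 2]:8.3f}")
            if has_vel:
                line += f"{vel[i, 0]:8.4f}{vel[i, 1]:8.4f}{vel[i, 2]:8.4f}"
            fh.write(line + "\n")
        b = state.box / 10.0
        fh.write(f"{b[0]:10.5f}{b[1]:10.5f}{b[2]:10.5f}\n")


def read_gro(path) -> SystemState:
    """Parse a GRO file into a SystemState (Å internally)."""
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: truncated GRO file")
    try:
        n = int(lines[1].strip())
    except ValueError as exc:
        raise ValueError(f"{path}, line 2: malformed atom count") from exc
    if n % 3:
        raise ValueError(f"{path}: {n} sites is not a whole number of "
                         "3-site water molecules")
    if len(lines) < n + 3:
        raise ValueError(f"{path}: expected {n + 3} lines, found {len(lines)}")
    pos = np.empty((n, 3))
    vel = np.zeros((n, 3))
    for k in range(n):
        ln = lines[2 + k].rstrip("\n")
        try:
            pos[k] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
            if len(ln) >= 68:
                vel[k] = [float(ln[44:52]), float(ln[52:60]), float(ln[60:68])]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}, line {3 + k}: malformed GRO record "
                             f"{ln!r}") from exc
    try:
        box = np.array([float(x) for x in lines[2 + n].split()[:3]])
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}, line {3 + n}: malformed box record") from exc
    return SystemState(box=box * 10.0, positions=pos * 10.0,
                       velocities=vel * 10.0)


def write_xyz(state: SystemState, path, comment: str = "") -> None:
    """Write an XYZ file (Å); box recorded in the comment line."""
    b = state.box
    with open(path, "w") as fh:
        fh.write(f"{state.n_sites}\n")
        fh.write(f"box {b[0]:.6f} {b[1]:.6f} {b[2]:.6f} {comment}\n")
        for i in range(state.n_sites):
            el = "O" if i % 3 == 0 else "H"
            p = state.positions[i]
            fh.write(f"{el} {p[0]:15.8f} {p[1]:15.8f} {p[2]:15.8f}\n")


def read_xyz(path) -> SystemState:
    """Parse an XYZ file written by :func:`write_xyz`."""
    with open(path) as fh:
        lines = fh.readlines()
    try:
        n = int(lines[0].strip())
    except (ValueError, IndexError) as exc:
        raise ValueError(f"{path}, line 1: malformed atom count") from exc
    parts = lines[1].split()
    if parts and parts[0] == "box":
        box = np.array([float(x) for x in parts[1:4]])
    else:
        raise ValueError(f"{path}, line 2: expected 'box Lx Ly Lz' comment")
    pos = np.empty((n, 3))
    for k in range(n):
        p = lines[2 + k].split()
        try:
            pos[k] = [float(p[1]), float(p[2]), float(p[3])]
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}, line {3 + k}: malformed XYZ record") from exc
    return SystemState(box=box, positions=pos)


def write_timeseries_csv(series: dict[str, TimeSeries] | TimeSeries, path) -> None:
    """Write one or more aligned time series to CSV (documented columns)."""
    import pandas as pd
    if isinstance(series, TimeSeries):
        series = {series.name: series}
    cols = {}
    dt = None
    for name, ts in series.items():
        v = np.asarray(ts.values)
        if v.ndim == 1:
            cols[f"{name} [{ts.units}]"] = v
        else:
            for ax, suffix in zip(range(v.shape[1]), "xyz"):
                cols[f"{name}_{suffix} [{ts.units}]"] = v[:, ax]
        dt = ts.dt
    n = len(next(iter(cols.values())))
    df = pd.DataFrame({"time [ps]": np.arange(n) * (dt or 1.0), **cols})
    df.to_csv(path, index=False)


def read_timeseries_csv(path) -> dict[str, TimeSeries]:
    """Inverse of :func:`write_timeseries_csv`."""
    import pandas as pd
    df = pd.read_csv(path)
    if "time [ps]" not in df.columns:
        raise ValueError(f"{path}: missing 'time [ps]' column")
    t = df["time [ps]"].to_numpy()
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    out = {}
    vector_parts: dict[str, dict] = {}
    for col in df.columns:
        if col == "time [ps]":
            continue
        name, _, unit = col.partition(" [")
        unit = unit.rstrip("]")
        if len(name) > 2 and name[-2] == "_" and name[-1] in "xyz":
            base = name[:-2]
            vector_parts.setdefault(base, {"units": unit, "comps": {}})
            vector_parts[base]["comps"][name[-1]] = df[col].to_numpy()
        else:
            out[name] = TimeSeries(name, df[col].to_numpy(), dt, unit)
    for base, d in vector_parts.items():
        arr = np.column_stack([d["comps"][ax] for ax in "xyz"])
        out[base] = TimeSeries(base, arr, dt, d["units"])
    return out
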