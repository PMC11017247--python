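# Cluster-scale experiment scripts

These scripts encode the full production protocols behind the model's
headline numbers (melting point, surface tension and its supercooled
emergence, dielectric constant, heat capacity, diffusion, liquid–gas
and liquid–liquid critical points).  They are **not** part of the test
suite: each needs hours to days on a multicore node because the
published protocols use 343–2139 molecules and multi-nanosecond
trajectories.  The desk-scale analogues that run in minutes live in
`scripts/acceptance.py` and `tests/`.

| script | protocol | headline quantity |
|---|---|---|
| `properties_ambient.py` | 1728-molecule bulk runs at 298 K | ε, C_p (295/301 K), D, κ_T, ΔH_vap |
| `ensemble_geometry_eg.py` | 5 ns flexible NPT at 273/298 K | EG273/EG298 geometries |
| `surface_tension_scan.py` | 1728/2139-molecule slabs, 325–625 K + supercooled | γ(T), T_c, ρ_c, P_c, T_e |
| `llcp_scan.py` | 343-molecule NPT grid, ≥190 K, ≤1000 bar | LLCP (T, P, ρ) |
| `melting_point.py` | NVE three-phase coexistence, 0.5 fs | T_M (flexible and EG273) |

All scripts accept `--scale` to shrink the system and trajectory for a
smoke run (the defaults are the full published conditions), and
`--seed` for reproducibility.
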