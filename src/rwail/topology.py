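"""Gromacs-dialect topology export/import for the rWAIL variants.

The exponential O–O repulsion does not map onto Lennard-Jones, so the
nonbonded block is written in the Buckingham (exp-6) notation, and the
M–H hydrogen-bond term is declared in the header as a tabulated
interaction — fidelity over convenience.  The virtual site uses the
``virtual_sites3`` funct-1 rule r_M = r_O + a·(r_H1−r_O) + b·(r_H2−r_O)
with a = b, which encodes the model's M-site definition exactly.

Units in the exported blocks follow the Gromacs dialect (kJ/mol, nm);
the canonical model-unit parameters (kcal/mol, Å) additionally ride
along in structured ``;;rwail-param`` comment lines, which the reader
prefers — this makes export → import bit-exact.  Files lacking the
canonical block (e.g. hand-edited ones) are read by back-converting
the kJ·nm values.
"""

from __future__ import annotations

import math
from pathlib import Path

from .parameters import ForceFieldParameters, VARIANTS

KCAL_TO_KJ = 4.184
A_TO_NM = 0.1

# unit conversion factor per parameter, model units -> Gromacs dialect
_CONVERT = {
    "q_M": 1.0,
    "q_H": 1.0,
    "a": 1.0,
    "A_OO": KCAL_TO_KJ,                       # kJ/mol
    "alpha": 10.0,                            # 1/nm
    "C_OO": KCAL_TO_KJ * A_TO_NM ** 6,        # kJ nm^6/mol
    "A_4": KCAL_TO_KJ * A_TO_NM ** 4,         # kJ nm^4/mol
    "r_c": A_TO_NM,
    "r_e": A_TO_NM,
    "k2": KCAL_TO_KJ / A_TO_NM ** 2,          # kJ/(mol nm^2)
    "k3": KCAL_TO_KJ / A_TO_NM ** 3,
    "k4": KCAL_TO_KJ / A_TO_NM ** 4,
    "theta_e": 1.0,                           # deg
    "k_theta": KCAL_TO_KJ,                    # kJ/(mol rad^2)
}


def write_gromacs_topology(params: ForceFieldParameters, directory) -> list[Path]:
    """Write the three-file topology set (.itp, .top, header notes).

    Returns the written paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    itp = directory / f"rwail_{params.variant}.itp"
    top = directory / f"rwail_{params.variant}.top"
    d = params.to_dict()
    canon = "".join(
        ";;rwail-param {} {}\n".format(k, v if isinstance(v, str) else repr(v))
        for k, v in d.items()
    )
    g = {k: (v if k == "variant" else v * _CONVERT[k]) for k, v in d.items()}
    lines = [
        f"; rWAIL water topology, variant {params.variant}",
        "; O-O repulsion is Born-Mayer (exp), NOT Lennard-Jones: the",
        "; [nonbond_params] block below uses the Buckingham (exp-6) form",
        ";   V(r) = A exp(-B r) - C6/r^6",
        "; The M-H hydrogen-bond term V_HB(r) = A4 (1/r^2 - 1/rc^2)^2 for",
        "; r < rc must be supplied as a tabulated nonbonded interaction",
        "; between types MW and HW (energy/table units: kJ/mol, nm).",
        "; Canonical model-unit parameters (kcal/mol, Å, e) follow; a",
        "; conforming reader restores them verbatim:",
        canon.rstrip("\n"),
        "",
        "[ defaults ]",
        "; nbfunc comb-rule",
        "  2      1",
        "",
        "[ atomtypes ]",
        "; name mass      charge   ptype",
        f"  OW   15.99900  0.00000  A",
        f"  HW    1.00800 {g['q_H']:9.5f}  A",
        f"  MW    0.00000 {g['q_M']:9.5f}  V",
        "",
        "[ nonbond_params ]",
        "; i  j  func  A(kJ/mol)        B(1/nm)      C6(kJ nm^6/mol)",
        f"  OW OW 2    {g['A_OO']:.10e}  {g['alpha']:.10e}  {g['C_OO']:.10e}",
        "",
        f"; tabulated HB term: A4 = {g['A_4']:.10e} kJ nm^4/mol,"
        f" rc = {g['r_c']:.10e} nm",
        "",
        "[ moleculetype ]",
        "; name  nrexcl",
        "  SOL   2",
        "",
        "[ atoms ]",
        "; nr type resnr residue atom cgnr charge    mass",
        f"  1  OW   1     SOL     OW   1    0.00000  15.99900",
        f"  2  HW   1     SOL     HW1  1   {g['q_H']:9.5f}   1.00800",
        f"  3  HW   1     SOL     HW2  1   {g['q_H']:9.5f}   1.00800",
        f"  4  MW   1     SOL     MW   1   {g['q_M']:9.5f}   0.00000",
        "",
        "[ virtual_sites3 ]",
        "; site from1 from2 from3 funct a        b",
        f"  4    1     2     3     1     {g['a']:.6f} {g['a']:.6f}",
        "",
        "[ exclusions ]",
        "  1 2 3 4",
        "  2 1 3 4",
        "  3 1 2 4",
        "  4 1 2 3",
        "",
    ]
    if params.is_rigid:
        th = math.radians(g["theta_e"])
        d_oh = g["r_e"]
        d_hh = 2.0 * g["r_e"] * math.sin(th / 2.0)
        lines += [
            "[ settles ]",
            "; OW funct doh      dhh",
            f"  1  1     {d_oh:.10f} {d_hh:.10f}",
            "",
        ]
    else:
        lines += [
            "; quartic bonds V = 1/2 [k2 x^2 + k3 x^3 + k4 x^4], x = r - re",
            "[ bonds ]",
            "; i j funct re(nm)        k2            k3            k4",
            f"  1 2 10   {g['r_e']:.10f}  {g['k2']:.10e}  {g['k3']:.10e}  {g['k4']:.10e}",
            f"  1 3 10   {g['r_e']:.10f}  {g['k2']:.10e}  {g['k3']:.10e}  {g['k4']:.10e}",
            "",
            "; harmonic angle V = 1/2 k_theta (theta - theta_e)^2",
            "[ angles ]",
            "; i j k funct theta_e(deg)  k(kJ/mol/rad^2)",
            f"  2 1 3 1    {g['theta_e']:.6f}  {g['k_theta']:.10e}",
            "",
        ]
    itp.write_text("\n".join(lines))
    top.write_text(
        f'; rWAIL {params.variant} system topology\n'
        f'#include "{itp.name}"\n\n'
        "[ system ]\nrWAIL water\n\n[ molecules ]\n; compound  #mols\n"
        "; SOL       <n>\n"
    )
    return [itp, top]


def read_gromacs_topology(path) -> ForceFieldParameters:
    """Parse a topology written by :func:`write_gromacs_topology`.

    Prefers the canonical ``;;rwail-param`` block (bit-exact); falls
    back to back-converting the kJ·nm dialect values.
    """
    path = Path(path)
    text = path.read_text()
    canon: dict = {}
    for ln_no, line in enumerate(text.splitlines(), start=1):
        if line.startswith(";;rwail-param "):
            try:
                _, key, value = line.split(maxsplit=2)
                canon[key] = value if key == "variant" else float(value)
            except ValueError as exc:
                raise ValueError(
                    f"{path}, line {ln_no}: malformed canonical parameter "
                    f"record {line!r}") from exc
    if canon:
        return ForceFieldParameters.from_dict(canon)
    return _parse_dialect(path, text)


def _parse_dialect(path, text) -> ForceFieldParameters:
    """Best-effort parse of the kJ·nm blocks (Buckingham or tabulated)."""
    import re
    d: dict = {}
    lines = text.splitlines()
    section = None
    for ln_no, raw in enumerate(lines, start=1):
        line = raw.split(";")[0].strip() if not raw.startswith(";") else raw
        m = re.match(r"\[\s*(\w+)\s*\]", line)
        if m:
            section = m.group(1)
            continue
        if raw.startswith("; tabulated HB term"):
            m_hb = re.search(r"A4 = ([-+0-9.eE]+) kJ nm\^4/mol,"
                             r" rc = ([-+0-9.eE]+) nm", raw)
            if m_hb:
                d["A_4"] = float(m_hb.group(1)) / _CONVERT["A_4"]
                d["r_c"] = float(m_hb.group(2)) / _CONVERT["r_c"]
            continue
        if not line or line.startswith(";"):
            continue
        tok = line.split()
        try:
            if section == "nonbond_params" and tok[0] == "OW":
                d["A_OO"] = float(tok[3]) / _CONVERT["A_OO"]
                d["alpha"] = float(tok[4]) / _CONVERT["alpha"]
                d["C_OO"] = float(tok[5]) / _CONVERT["C_OO"]
            elif section == "atoms" and tok[4] == "HW1":
                d["q_H"] = float(tok[6])
            elif section == "atoms" and tok[4] == "MW":
                d["q_M"] = float(tok[6])
            elif section == "virtual_sites3":
                d["a"] = float(tok[5])
            elif section == "settles":
                d_oh = float(tok[2]) / A_TO_NM
                d_hh = float(tok[3]) / A_TO_NM
                d["r_e"] = d_oh
                d["theta_e"] = math.degrees(
                    2.0 * math.asin(d_hh / (2.0 * d_oh)))
            elif section == "bonds":
                d["r_e"] = float(tok[3]) / A_TO_NM
                d["k2"] = float(tok[4]) / _CONVERT["k2"]
                d["k3"] = float(tok[5]) / _CONVERT["k3"]
                d["k4"] = float(tok[6]) / _CONVERT["k4"]
            elif section == "angles":
                d["theta_e"] = float(tok[4])
                d["k_theta"] = float(tok[5]) / _CONVERT["k_theta"]
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"{path}, line {ln_no}: unparseable record {raw!r}") from exc
    rigid = "k2" not in d
    if rigid:
        from .parameters import load_parameters
        # EG variants differ only in geometry: pick the closest r_e
        d["variant"] = min(
            ("EG273", "EG298"),
            key=lambda v: abs(load_parameters(v).r_e - d.get("r_e", 0.0)))
    else:
        d["variant"] = "flexible"
    missing = {"q_M", "q_H", "a", "A_OO", "alpha", "C_OO", "A_4", "r_c",
               "r_e", "theta_e"} - set(d)
    if missing:
        raise ValueError(f"{path}: missing parameters {sorted(missing)}")
    return ForceFieldParameters.from_dict(d)
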