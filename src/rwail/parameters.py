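"""Force-field parameter sets for the rWAIL water model.

The model comes in three published variants:

``flexible``
    Four-site flexible water: point charges on H1, H2 and a massless
    M site, Born–Mayer O–O repulsion, r⁻⁶ O–O dispersion, a short-range
    M–H hydrogen-bond shaping term, and anharmonic (quartic bond /
    harmonic angle) intramolecular terms.
``EG273`` / ``EG298``
    Rigid "ensemble geometry" variants whose fixed bond length and
    angle equal the thermal averages of the flexible model at 273 K
    and 298 K respectively.  They carry no intramolecular terms.

Parameters are shipped as one structured text file per variant under
``rwail/data`` and parsed verbatim — no numerical post-processing, so
loaded values round-trip bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields
from importlib import resources

import yaml

VARIANTS = ("flexible", "EG273", "EG298")

_RIGID_ONLY_NONE = ("k2", "k3", "k4", "k_theta")


@dataclass(frozen=True)
class ForceFieldParameters:
    """All symbols of the rWAIL energy expressions for one variant.

    Units: charges in e, energies kcal/mol, lengths Å, angles deg
    (``theta_e``), bond coefficients kcal/(mol Åⁿ), angle coefficient
    kcal/(mol rad²).  Rigid variants carry ``None`` for the
    intramolecular coefficients.
    """

    variant: str
    q_M: float
    q_H: float
    a: float
    A_OO: float
    alpha: float
    C_OO: float
    A_4: float
    r_c: float
    r_e: float
    theta_e: float
    k2: float | None = None
    k3: float | None = None
    k4: float | None = None
    k_theta: float | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown rWAIL variant {self.variant!r}; "
                f"valid variants are {set(VARIANTS)}"
            )
        if abs(self.q_M + 2.0 * self.q_H) > 1e-12:
            raise ValueError("molecule not neutral: q_M + 2 q_H != 0")
        for name in ("A_OO", "alpha", "C_OO", "A_4", "r_c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.is_rigid:
            if any(getattr(self, n) is not None for n in _RIGID_ONLY_NONE):
                raise ValueError(
                    f"rigid variant {self.variant} must not carry "
                    "intramolecular coefficients"
                )
        else:
            if any(getattr(self, n) is None for n in _RIGID_ONLY_NONE):
                raise ValueError("flexible variant requires k2, k3, k4, k_theta")

    @property
    def is_rigid(self) -> bool:
        return self.variant != "flexible"

    @property
    def theta_e_rad(self) -> float:
        return math.radians(self.theta_e)

    def to_dict(self) -> dict:
        """Canonical parameter dictionary (used by the topology exporter)."""
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)


def load_parameters(variant: str) -> ForceFieldParameters:
    """Load the packaged parameter table for one model variant.

    Parameters
    ----------
    variant : {"flexible", "EG273", "EG298"}

    Returns
    -------
    ForceFieldParameters
        The published values, parsed verbatim from the packaged file.
    """
    if variant not in VARIANTS:
        raise ValueError(
            f"unknown rWAIL variant {variant!r}; "
            f"valid variants are {set(VARIANTS)}"
        )
    text = resources.files("rwail.data").joinpath(f"{variant}.yaml").read_text()
    raw = yaml.safe_load(text)
    return ForceFieldParameters.from_dict(raw)
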