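"""Model parameters for the active-passive lattice gas.

The nondimensional description is fixed by four numbers: the Peclet number
``Pe`` (self-propulsion strength), the rescaled horizontal domain length
``L``, and the active/passive volume fractions ``phi_a``, ``phi_p``.  Time
and space are measured in units of the inverse tumble rate ``1/D_R`` and
the persistence length ``sqrt(D_T/D_R)``; in these units the translational
and rotational diffusivities are both 1 and the self-propulsion speed is
``Pe``.  A microscopic parameter set (``D_T``, ``D_R``, ``v0``, lattice
spacing ``h``, aspect ratio) may be supplied for lattice runs and is
converted to the nondimensional set.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional parameters of the active-passive mixture.

    Parameters
    ----------
    Pe : float
        Peclet number ``v0 / sqrt(D_T * D_R)``.  ``Pe = 0`` is the
        equilibrium three-species symmetric exclusion process.
    L : float
        Horizontal domain length ``l_x * sqrt(D_R / D_T)``.
    phi_a, phi_p : float
        Active and passive volume fractions; ``phi_a + phi_p <= 1``.
    h : float, optional
        Lattice spacing in rescaled units (lattice runs only).
    aspect : float
        Vertical-to-horizontal domain aspect ratio ``l_y / l_x`` for the
        two-dimensional lattice; kymograph runs use 1/4.
    """

    Pe: float
    L: float
    phi_a: float
    phi_p: float
    h: float | None = None
    aspect: float = 0.25

    def __post_init__(self) -> None:
        if self.Pe < 0:
            raise ValueError(f"Pe must be >= 0, got {self.Pe}")
        if self.L <= 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if self.phi_a < 0 or self.phi_p < 0:
            raise ValueError("volume fractions must be non-negative")
        if self.phi_a + self.phi_p > 1.0 + 1e-12:
            raise ValueError(
                f"phi_a + phi_p = {self.phi_a + self.phi_p} exceeds 1 "
                "(excluded-volume constraint)"
            )

    @property
    def phi(self) -> float:
        """Total volume fraction ``phi_a + phi_p``."""
        return self.phi_a + self.phi_p

    @property
    def nu(self) -> float:
        """Passive-to-vacancy ratio ``phi_p / (1 - phi)`` of the mean state."""
        if self.phi >= 1.0:
            raise ValueError("nu undefined at full packing (phi = 1)")
        return self.phi_p / (1.0 - self.phi)

    @classmethod
    def from_microscopic(
        cls,
        *,
        D_T: float,
        D_R: float,
        v0: float,
        l_x: float,
        phi_a: float,
        phi_p: float,
        h: float | None = None,
        aspect: float = 0.25,
    ) -> "ModelParams":
        """Build nondimensional parameters from microscopic rates."""
        if D_T <= 0 or D_R <= 0:
            raise ValueError("diffusivities must be positive")
        pe = v0 / math.sqrt(D_T * D_R)
        L = l_x * math.sqrt(D_R / D_T)
        h_resc = None if h is None else h * math.sqrt(D_R / D_T)
        return cls(Pe=pe, L=L, phi_a=phi_a, phi_p=phi_p, h=h_resc, aspect=aspect)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        names = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in names})


def load_config(path: str | Path) -> dict:
    """Read a plain-text config: JSON, or simple ``key = value`` lines."""
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        pass
    out: dict = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"cannot parse config line: {line!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        try:
            out[key] = json.loads(val)
        except json.JSONDecodeError:
            out[key] = val
    return out
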