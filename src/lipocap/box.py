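"""Periodic simulation box in reduced units, with the physical length mapping."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Default physical size of one cutoff radius, in nm.  This is the common
#: coarse-graining where one water bead represents three water molecules at
#: reduced density 3: r_c = (3 rho V_water)^(1/3) ≈ 0.646 nm.
DEFAULT_LENGTH_SCALE_NM = 0.646

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class BoxSpec:
    """Orthorhombic periodic box.

    Parameters
    ----------
    lengths:
        Edge lengths in reduced units (r_c = 1); periodic in all directions.
    length_scale:
        Physical size of r_c in nm, used only when converting observables
        (diameters, concentrations) to physical units.
    """

    lengths: tuple[float, float, float]
    length_scale: float = DEFAULT_LENGTH_SCALE_NM

    def __post_init__(self) -> None:
        if len(self.lengths) != 3 or any(L <= 0 for L in self.lengths):
            raise ValueError("box lengths must be three positive numbers")
        if self.length_scale <= 0:
            raise ValueError("length_scale must be positive")
        object.__setattr__(self, "lengths", tuple(float(L) for L in self.lengths))

    @classmethod
    def cubic(cls, L: float, length_scale: float = DEFAULT_LENGTH_SCALE_NM) -> "BoxSpec":
        return cls((L, L, L), length_scale)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=np.float64)

    @property
    def volume(self) -> float:
        """Volume in reduced units (r_c^3)."""
        a, b, c = self.lengths
        return a * b * c

    @property
    def volume_nm3(self) -> float:
        return self.volume * self.length_scale**3

    def wrap(self, pos: np.ndarray) -> np.ndarray:
        """Return positions wrapped into [0, L)."""
        return np.mod(pos, self.array)

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Minimum-image displacement(s) for raw difference vectors."""
        L = self.array
        return dr - L * np.rint(dr / L)
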