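"""Equilibrium mass balance of a closed vial with aqueous solution and headspace.

A chemical spiked into the solution of a sealed vial partitions into the
headspace until ``c_hs = Kaw * c_sol``, where ``Kaw`` is the dimensionless
air-water partition coefficient.  Mass balance over the two phases then ties
the equilibrium solution concentration to the initial one through the
headspace/solution volume ratio ``r = V_hs / V_sol``::

    c_sol = c0 / (1 + Kaw * r)

Because an LC-MS peak area is proportional to ``c_sol`` (``area = RF * c_sol``
with an unknown response factor RF), the observable signal follows

    area(r) = A0 / (1 + Kaw * r),     A0 = RF * c0

which is the model fitted by :mod:`kawfit.estimation`.  Only the product
``RF * c0`` is identifiable, never RF or c0 separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Chemical",
    "VialGeometry",
    "EquilibriumState",
    "headspace_ratio",
    "equilibrium_solution_concentration",
    "area_model",
    "water_density",
    "gravimetric_vial_volume",
]


@dataclass(frozen=True)
class Chemical:
    """A test chemical, keyed by a short unique id."""

    id: str
    name: str = ""
    smiles: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("chemical id must be non-empty")


@dataclass(frozen=True)
class VialGeometry:
    """Vial total volume and solution fill volume, both in mL."""

    total_volume: float
    fill_volume: float

    def __post_init__(self) -> None:
        if not self.total_volume > 0:
            raise ValueError(f"total_volume must be > 0, got {self.total_volume}")
        if not 0 < self.fill_volume <= self.total_volume:
            raise ValueError(
                f"fill_volume must satisfy 0 < fill <= total "
                f"(fill={self.fill_volume}, total={self.total_volume})"
            )

    @property
    def ratio(self) -> float:
        """Headspace/solution volume ratio ``(total - fill) / fill``."""
        return (self.total_volume - self.fill_volume) / self.fill_volume


def headspace_ratio(geometry: VialGeometry) -> float:
    """Return the headspace/solution volume ratio of a vial.

    Exactly 0 for a brimful vial; 1 when the phases have equal volume.
    """
    return geometry.ratio


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrated two-phase state of one vial.

    ``c_sol`` and ``c_hs`` are derived from (c0, kaw, ratio) so that the
    partition law ``c_hs = kaw * c_sol`` and the mass balance
    ``c0 = c_sol + c_hs * ratio`` hold by construction.
    """

    c0: float
    kaw: float
    ratio: float
    c_sol: float = field(init=False)
    c_hs: float = field(init=False)

    def __post_init__(self) -> None:
        c_sol = equilibrium_solution_concentration(self.c0, self.kaw, self.ratio)
        object.__setattr__(self, "c_sol", c_sol)
        object.__setattr__(self, "c_hs", self.kaw * c_sol)


def equilibrium_solution_concentration(c0, kaw, ratio):
    """Equilibrium aqueous concentration ``c0 / (1 + kaw * ratio)``.

    Parameters
    ----------
    c0 : float or array
        Initial aqueous concentration (> 0, any consistent unit).
    kaw : float or array
        Dimensionless air-water partition coefficient (>= 0).
    ratio : float or array
        Headspace/solution volume ratio (>= 0).
    """
    c0 = np.asarray(c0, dtype=float)
    kaw = np.asarray(kaw, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if np.any(c0 <= 0):
        raise ValueError("c0 must be > 0")
    if np.any(kaw < 0):
        raise ValueError("kaw must be >= 0")
    if np.any(ratio < 0):
        raise ValueError("ratio must be >= 0")
    out = c0 / (1.0 + kaw * ratio)
    return float(out) if out.ndim == 0 else out


def area_model(amplitude, kaw, ratio):
    """Expected peak area ``A0 / (1 + kaw * ratio)`` with ``A0 = RF * c0``.

    Strictly decreasing in ``ratio`` whenever ``kaw > 0``; equal to the
    amplitude for a vial with no headspace (ratio 0).
    """
    amplitude = np.asarray(amplitude, dtype=float)
    if np.any(amplitude <= 0):
        raise ValueError("amplitude must be > 0")
    return equilibrium_solution_concentration(amplitude, kaw, ratio)


# Kell (1975), J. Chem. Eng. Data 20:97 -- density of air-free liquid water
# at 101.325 kPa, valid 0-150 degC; used here over 0-100 degC.  rho in g/mL:
#   rho(t) = (a0 + a1 t + a2 t^2 + a3 t^3 + a4 t^4 + a5 t^5) / (1 + b t) / 1000
_KELL_NUM = (
    999.83952,
    16.945176,
    -7.9870401e-3,
    -46.170461e-6,
    105.56302e-9,
    -280.54253e-12,
)
_KELL_DEN_B = 16.879850e-3


def water_density(temperature_c: float) -> float:
    """Density of liquid water in g/mL at 1 atm, Kell (1975) correlation.

    Valid for 0 < t < 100 degC.  rho(25 degC) = 0.997045 g/mL.
    """
    t = float(temperature_c)
    if not 0.0 < t < 100.0:
        raise ValueError(f"temperature {t} degC outside correlation validity (0, 100)")
    num = sum(c * t**k for k, c in enumerate(_KELL_NUM))
    return num / (1.0 + _KELL_DEN_B * t) / 1000.0


def gravimetric_vial_volume(mass_empty: float, mass_full: float, temperature_c: float) -> float:
    """Vial volume in mL from empty/full weighing with water.

    ``(mass_full - mass_empty) / rho_water(t)``, the gravimetric calibration
    used when vial nominal volumes are not trusted.
    """
    dm = float(mass_full) - float(mass_empty)
    if dm <= 0:
        raise ValueError("mass_full must exceed mass_empty")
    return dm / water_density(temperature_c)
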