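"""Domain types: guidewire geometry, vessel scenarios, media and conductance bookkeeping.

Units are SI throughout the library (metres, siemens, ohms, hertz).  The
reporting layer (:mod:`condsize.io`, CLI) converts to the conventional
bench units (mm, mS, kHz) at the surface.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import DomainError

INCH = 25.4e-3  # m

#: Shaft diameter of the 0.035-inch peripheral sizing guidewire, m.
D_GW_0035 = 0.035 * INCH
#: Shaft diameter of the 0.014-inch coronary sizing guidewire, m.
D_GW_0014 = 0.014 * INCH


@dataclass(frozen=True)
class GuidewireSpec:
    """Electrode geometry of a tetrapolar sizing guidewire.

    The outer electrode pair injects current, the inner pair senses
    voltage.  A spacing label like ``"5-5-5"`` gives the inter-electrode
    gap in mm; electrode centres are then ``gap + electrode_width`` apart,
    so the effective sensing separation is ``L = gap + electrode_width``
    and the excitation separation ``d = 3 * (gap + electrode_width)``.

    Parameters
    ----------
    label : str
        Spacing label (``"5-5-5"``, ``"2-2-2"`` or free text for custom
        geometries).
    gap : float
        Inter-electrode gap, mm.
    electrode_width : float
        Axial electrode width, mm (1 mm for the stock wires).
    L : float
        Sensing-electrode centre-to-centre separation, m.
    d : float
        Excitation-electrode centre-to-centre separation, m.
    d_gw : float
        Guidewire shaft diameter, m.
    """

    label: str
    gap: float
    electrode_width: float
    L: float
    d: float
    d_gw: float

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise DomainError(f"sensing separation L must be positive, got {self.L}")
        if not self.d > self.L:
            raise DomainError(
                f"excitation separation d={self.d} must exceed sensing separation L={self.L}"
            )
        if not self.d_gw > 0:
            raise DomainError(f"guidewire diameter must be positive, got {self.d_gw}")

    @classmethod
    def from_spacing(
        cls,
        gap_mm: float,
        *,
        electrode_width_mm: float = 1.0,
        d_gw: float = D_GW_0035,
        label: str | None = None,
    ) -> "GuidewireSpec":
        """Build a spec from the spacing convention (gap in mm)."""
        pitch = (gap_mm + electrode_width_mm) * 1e-3
        return cls(
            label=label or f"{gap_mm:g}-{gap_mm:g}-{gap_mm:g}",
            gap=gap_mm,
            electrode_width=electrode_width_mm,
            L=pitch,
            d=3.0 * pitch,
            d_gw=d_gw,
        )

    @classmethod
    def from_label(cls, label: str, *, electrode_width_mm: float = 1.0) -> "GuidewireSpec":
        """Return one of the stock wires by its spacing label."""
        if label == "5-5-5":
            return cls.from_spacing(5.0, electrode_width_mm=electrode_width_mm,
                                    d_gw=D_GW_0035, label=label)
        if label == "2-2-2":
            return cls.from_spacing(2.0, electrode_width_mm=electrode_width_mm,
                                    d_gw=D_GW_0014, label=label)
        raise DomainError(f"unknown guidewire label {label!r}; use from_spacing for custom wires")


#: Stock peripheral wire: 5 mm spacing, 0.035-inch shaft (L = 6 mm, d = 18 mm).
GW_5_5_5 = GuidewireSpec.from_label("5-5-5")
#: Stock coronary wire: 2 mm spacing, 0.014-inch shaft (L = 3 mm, d = 9 mm).
GW_2_2_2 = GuidewireSpec.from_label("2-2-2")


@dataclass(frozen=True)
class VesselScenario:
    """A cylindrical vessel with a conductive wall in a surrounding bath.

    Parameters
    ----------
    d_b : float
        Lumen diameter, m.
    t_w : float
        Wall thickness, m.
    bath_thickness : float
        Radial extent of the surrounding medium beyond the wall outer
        surface, m.
    sigma_bath : float
        Conductivity of the surrounding medium, S/m.
    """

    d_b: float
    t_w: float
    bath_thickness: float = 0.0
    sigma_bath: float = 0.0

    def __post_init__(self) -> None:
        if not self.d_b > 0:
            raise DomainError(f"lumen diameter must be positive, got {self.d_b}")
        if self.t_w < 0:
            raise DomainError(f"wall thickness must be non-negative, got {self.t_w}")
        if self.bath_thickness < 0:
            raise DomainError("bath thickness must be non-negative")
        if self.sigma_bath < 0:
            raise DomainError("bath conductivity must be non-negative")

    @property
    def tr(self) -> float:
        """Wall-thickness to lumen-diameter ratio TR = t_w / d_b."""
        return self.t_w / self.d_b

    @classmethod
    def from_tr(
        cls,
        d_b: float,
        tr: float,
        *,
        bath_thickness: float = 0.0,
        sigma_bath: float = 0.0,
    ) -> "VesselScenario":
        if tr < 0:
            raise DomainError(f"TR must be non-negative, got {tr}")
        return cls(d_b=d_b, t_w=tr * d_b,
                   bath_thickness=bath_thickness, sigma_bath=sigma_bath)

    def with_diameter(self, d_b: float) -> "VesselScenario":
        """Same scenario at a different lumen diameter, TR held fixed."""
        return replace(self, d_b=d_b, t_w=self.tr * d_b)


@dataclass(frozen=True)
class MediumProps:
    """Effective ('ideal') conductivities of lumen fluid and wall tissue, S/m."""

    sigma_b: float
    sigma_t: float

    def __post_init__(self) -> None:
        if self.sigma_b < 0 or self.sigma_t < 0:
            raise DomainError("conductivities must be non-negative")


@dataclass(frozen=True)
class ConductanceDecomposition:
    """Total tetrapolar conductance split into its parallel pathways.

    ``G = G_b + G_t + G_bath`` with ``R = 1/G``: lumen fluid, vessel wall
    and surrounding-bath contributions.
    """

    G_b: float
    G_t: float
    G_bath: float
    G: float = field(init=False)
    R: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("G_b", "G_t", "G_bath"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        total = self.G_b + self.G_t + self.G_bath
        if total <= 0:
            raise DomainError("total conductance must be positive")
        object.__setattr__(self, "G", total)
        object.__setattr__(self, "R", 1.0 / total)

    @property
    def G_p(self) -> float:
        """Parallel conductance: everything outside the lumen."""
        return self.G_t + self.G_bath

    @property
    def parallel_fraction(self) -> float:
        """G_p / G — the share of current lost to wall and surroundings."""
        return self.G_p / self.G


def check_consistency(dec: ConductanceDecomposition, rtol: float = 1e-9) -> bool:
    """Verify G = G_b + G_t + G_bath and R = 1/G to relative tolerance."""
    total = dec.G_b + dec.G_t + dec.G_bath
    return (
        math.isclose(dec.G, total, rel_tol=rtol)
        and math.isclose(dec.R * dec.G, 1.0, rel_tol=rtol)
    )
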