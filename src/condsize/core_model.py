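"""Geometric conductance model of a guidewire in a vessel, and its inverse.

A tetrapolar guidewire in a fluid-filled lumen sees three parallel current
pathways over the sensing separation L: the fluid annulus between shaft and
lumen wall, the vessel-wall annulus, and the surrounding medium.  Each
coaxial annulus of inner/outer diameter (d_i, d_o) contributes an axial
conductance sigma * pi * (d_o^2 - d_i^2) / (4 L).  Summing lumen and wall
terms and solving 1/R = G_b + G_t for the lumen diameter gives the
closed-form inversion used when the surroundings are non-conductive; the
full iterative inversion (with a bath) lives in :mod:`condsize.sizing`.
"""
from __future__ import annotations

import math

from .errors import DomainError
from .geometry import (
    ConductanceDecomposition,
    GuidewireSpec,
    MediumProps,
    VesselScenario,
)
from .parallel_field import FieldKernel, bath_conductance

__all__ = [
    "lumen_conductance",
    "wall_conductance",
    "invert_diameter_closed_form",
    "total_resistance_forward",
    "cylindricity_check",
]


def lumen_conductance(sigma_b: float, d_b: float, gw: GuidewireSpec) -> float:
    """Conductance of the fluid annulus between guidewire shaft and lumen wall.

    G_b = sigma_b * pi * (d_b^2 - d_gw^2) / (4 L)

    Parameters
    ----------
    sigma_b : float
        Lumen-fluid conductivity, S/m.
    d_b : float
        Lumen diameter, m.
    gw : GuidewireSpec
        Guidewire geometry (supplies L and the shaft diameter).

    Returns
    -------
    float
        Lumen conductance, S.
    """
    if sigma_b < 0:
        raise DomainError("fluid conductivity must be non-negative")
    if d_b <= gw.d_gw:
        raise DomainError(
            f"guidewire larger than lumen: d_b={d_b*1e3:.3f} mm <= d_gw={gw.d_gw*1e3:.3f} mm"
        )
    return sigma_b * math.pi * (d_b**2 - gw.d_gw**2) / (4.0 * gw.L)


def wall_conductance(sigma_t: float, d_b: float, tr: float, gw: GuidewireSpec) -> float:
    """Conductance of the vessel-wall annulus of thickness TR * d_b.

    The wall annulus spans diameters d_b to d_b (1 + 2 TR), so

    G_t = sigma_t * pi * d_b^2 * TR * (1 + TR) / L

    Parameters
    ----------
    sigma_t : float
        Wall-tissue conductivity, S/m.
    d_b : float
        Lumen diameter, m.
    tr : float
        Wall-thickness to lumen-diameter ratio.
    gw : GuidewireSpec
        Guidewire geometry (supplies L).

    Returns
    -------
    float
        Wall conductance, S.
    """
    if tr < 0:
        raise DomainError(f"TR must be non-negative, got {tr}")
    if sigma_t < 0:
        raise DomainError("tissue conductivity must be non-negative")
    return sigma_t * math.pi * d_b**2 * tr * (1.0 + tr) / gw.L


def invert_diameter_closed_form(
    R: float, sigma_b: float, sigma_t: float, tr: float, gw: GuidewireSpec
) -> float:
    """Lumen diameter from the system resistance, no surrounding bath.

    Solves 1/R = G_b(d_b) + G_t(d_b) for d_b:

    d_b = sqrt( (4 L + pi R sigma_b d_gw^2)
                / (pi R (sigma_b + 4 sigma_t TR (1 + TR))) )

    Exact inverse of ``lumen_conductance + wall_conductance``.

    Raises
    ------
    DomainError
        If the result falls at or below the guidewire diameter (the
        measurement is inconsistent with the assumed geometry).
    """
    if R <= 0:
        raise DomainError("system resistance must be positive")
    if sigma_b <= 0:
        raise DomainError("fluid conductivity must be positive")
    if tr < 0 or sigma_t < 0:
        raise DomainError("sigma_t and TR must be non-negative")
    num = 4.0 * gw.L + math.pi * R * sigma_b * gw.d_gw**2
    den = math.pi * R * (sigma_b + 4.0 * sigma_t * tr * (1.0 + tr))
    d_b = math.sqrt(num / den)
    if d_b <= gw.d_gw:
        raise DomainError(
            f"inverted diameter {d_b*1e3:.3f} mm does not exceed the guidewire "
            f"shaft ({gw.d_gw*1e3:.3f} mm): measurement inconsistent with geometry"
        )
    return d_b


def total_resistance_forward(
    scn: VesselScenario,
    media: MediumProps,
    gw: GuidewireSpec,
    kernel: FieldKernel | None = None,
) -> ConductanceDecomposition:
    """Forward model: total conductance decomposition for a full scenario.

    G = G_b + G_t + G_bath with R = 1/G.  The bath term uses the radial
    field kernel; with no bath (or zero bath conductivity) it vanishes and
    R reduces to 1/(G_b + G_t).
    """
    if kernel is None:
        kernel = FieldKernel()
    g_b = lumen_conductance(media.sigma_b, scn.d_b, gw)
    g_t = wall_conductance(media.sigma_t, scn.d_b, scn.tr, gw)
    g_bath = bath_conductance(scn, gw, kernel)
    return ConductanceDecomposition(G_b=g_b, G_t=g_t, G_bath=g_bath)


def cylindricity_check(gw: GuidewireSpec, d_b: float, *, min_ratio: float = 2.0) -> str:
    """Check the axial-uniformity (cylindricity) assumption.

    The excitation field is approximately uniform across the sensing
    segment when the excitation separation is at least ``min_ratio`` times
    the lumen diameter.  Returns ``"ok"`` or ``"warning"`` — never an
    error, since marginal geometries still yield usable estimates.
    """
    if d_b <= 0:
        return "ok"
    return "ok" if gw.d / d_b >= min_ratio else "warning"
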