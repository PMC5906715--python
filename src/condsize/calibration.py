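"""Conductivity calibration: phantoms, lookup tables, ex-vivo wall tissue.

The sizing model needs two effective conductivities: the lumen fluid
(frequency- and diameter-dependent 'ideal' conductivity, tabulated from
phantom measurements) and the vessel wall (estimated once from an ex-vivo
measurement with known geometry).  Both calibrations are exact algebraic
inverses of the annular conductance formulas in :mod:`condsize.core_model`.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, InputError
from .geometry import GuidewireSpec

__all__ = [
    "ConductivityTable",
    "phantom_conductivity",
    "conductivity_lookup",
    "tissue_conductivity_from_exvivo",
]


@dataclass(frozen=True)
class ConductivityTable:
    """Ideal lumen-fluid conductivity on a frequency x diameter grid.

    The apparent ('ideal') conductivity back-calculated from phantom
    measurements rises with frequency and falls with phantom diameter;
    both trends are checked at construction and reported as warnings if
    violated (user-supplied tables may be noisy).

    Fields: ``frequencies`` (Hz, ascending), ``diameters`` (m, ascending),
    ``sigma`` (S/m, shape frequencies x diameters).
    """

    frequencies: tuple
    diameters: tuple
    sigma: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        d = np.asarray(self.diameters, dtype=float)
        s = np.asarray(self.sigma, dtype=float)
        if f.size == 0 or d.size == 0:
            raise InputError("empty conductivity table")
        if s.shape != (f.size, d.size):
            raise InputError(
                f"sigma grid shape {s.shape} does not match {f.size} frequencies x {d.size} diameters"
            )
        if np.any(np.diff(f) <= 0) or np.any(np.diff(d) <= 0):
            raise InputError("frequencies and diameters must be strictly ascending")
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            raise InputError("conductivities must be finite and positive (grid must be complete)")
        if np.any(np.diff(s, axis=0) < 0):
            warnings.warn("conductivity not non-decreasing in frequency", stacklevel=2)
        if np.any(np.diff(s, axis=1) > 0):
            warnings.warn("conductivity not non-increasing in diameter", stacklevel=2)
        object.__setattr__(self, "frequencies", tuple(float(x) for x in f))
        object.__setattr__(self, "diameters", tuple(float(x) for x in d))
        object.__setattr__(self, "sigma", s)

    def is_monotonic(self) -> bool:
        """True if sigma is non-decreasing in f and non-increasing in d."""
        s = self.sigma
        return bool(np.all(np.diff(s, axis=0) >= 0) and np.all(np.diff(s, axis=1) <= 0))


def phantom_conductivity(R: float, d_phantom: float, gw: GuidewireSpec) -> float:
    """Fluid conductivity from a phantom of known diameter.

    In a rigid non-conductive tube there is no parallel pathway, so the
    whole measured conductance is the fluid annulus and

        sigma = 4 L / (pi R (d_phantom^2 - d_gw^2))

    Exact inverse of :func:`condsize.core_model.lumen_conductance`.  The
    same formula serves the introducer-catheter calibration in vivo, with
    ``d_phantom`` the catheter inner diameter.
    """
    if d_phantom <= gw.d_gw:
        raise DomainError(
            f"phantom diameter {d_phantom*1e3:.3f} mm must exceed the guidewire "
            f"shaft ({gw.d_gw*1e3:.3f} mm)"
        )
    if R <= 0:
        raise DomainError("system resistance must be positive")
    return 4.0 * gw.L / (math.pi * R * (d_phantom**2 - gw.d_gw**2))


def conductivity_lookup(tbl: ConductivityTable, f: float, d: float) -> float:
    """Bilinear lookup of the fluid conductivity at (frequency, diameter).

    Interpolates linearly in log10(frequency) and linearly in diameter;
    queries outside the grid are clamped to the nearest edge (no
    extrapolation).  Exact at grid nodes.
    """
    from scipy.interpolate import RegularGridInterpolator

    if f <= 0 or d <= 0:
        raise InputError("frequency and diameter must be positive")
    logf = np.log10(np.asarray(tbl.frequencies))
    dd = np.asarray(tbl.diameters)
    interp = RegularGridInterpolator((logf, dd), tbl.sigma, method="linear")
    q_logf = float(np.clip(math.log10(f), logf[0], logf[-1]))
    q_d = float(np.clip(d, dd[0], dd[-1]))
    return float(interp([[q_logf, q_d]])[0])


def tissue_conductivity_from_exvivo(
    g_t: float, d_b: float, tr: float, gw: GuidewireSpec
) -> float:
    """Wall-tissue conductivity from the wall conductance and known geometry.

        sigma_t = G_t * L / (pi * d_b^2 * TR * (1 + TR))

    ``g_t`` is the total conductance minus the lumen conductance of an
    ex-vivo vessel with optically measured diameter and wall thickness.
    Exact inverse of :func:`condsize.core_model.wall_conductance`.
    """
    if g_t < 0:
        raise DomainError("wall conductance must be non-negative")
    if g_t == 0.0:
        return 0.0
    if tr <= 0:
        raise DomainError("positive wall conductance requires TR > 0")
    if d_b <= 0:
        raise DomainError("lumen diameter must be positive")
    return g_t * gw.L / (math.pi * d_b**2 * tr * (1.0 + tr))
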