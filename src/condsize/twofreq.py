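"""Two-frequency extraction of the ohmic system resistance.

The electrode–electrolyte interface adds a polarization capacitance in
series with the tissue resistance, so the measured impedance magnitude is

    |Z(omega)|^2 = R^2 + 1 / (omega C)^2

Measuring |Z| at two frequencies gives a 2x2 linear system in (R^2, 1/C^2);
more frequencies are handled by least squares in the same variables.  R is
the quantity the sizing model consumes (G = 1/R).
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, ModelViolationError

__all__ = [
    "SpectrumMeasurement",
    "TwoFreqFit",
    "impedance_from_voltage",
    "fit_series_rc",
    "fit_series_rc_multi",
]


@dataclass(frozen=True)
class SpectrumMeasurement:
    """One tetrapolar measurement: rms voltage at a known rms current and frequency."""

    frequency: float  # Hz
    current: float    # A rms
    voltage: float    # V rms

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise InputError(f"frequency must be positive, got {self.frequency}")
        if self.current <= 0:
            raise InputError(f"excitation current must be positive, got {self.current}")
        if self.voltage < 0:
            raise InputError("voltage magnitude must be non-negative")

    @property
    def z_mag(self) -> float:
        """Impedance magnitude |Z| = V / I, ohm."""
        return self.voltage / self.current


def impedance_from_voltage(frequency: float, current: float, voltage: float) -> SpectrumMeasurement:
    """Convert a raw (frequency, current, voltage) triple to a measurement.

    The impedance magnitude is the measured voltage divided by the applied
    current; available as ``.z_mag`` on the returned object.
    """
    return SpectrumMeasurement(frequency=frequency, current=current, voltage=voltage)


@dataclass(frozen=True)
class TwoFreqFit:
    """Series-RC fit: system resistance R, polarization capacitance C.

    ``capacitance_unbounded`` flags a purely ohmic spectrum (no dispersion
    between the frequencies), in which case C is +inf.
    """

    R: float
    C: float
    frequencies: tuple
    capacitance_unbounded: bool = False
    rms_residual: float = 0.0  # RMS misfit in |Z|^2, ohm^2 (0 for exact pair fits)

    @property
    def G(self) -> float:
        """System conductance 1/R, S."""
        return 1.0 / self.R


def _solve_pair(f1, z1, f2, z2) -> tuple:
    """Solve |Z|^2 = R^2 + invc2 / omega^2 through two points; returns (R, invc2)."""
    w1 = 2.0 * math.pi * f1
    w2 = 2.0 * math.pi * f2
    num = z1**2 - z2**2
    den = 1.0 / w1**2 - 1.0 / w2**2
    if num < 0:
        raise ModelViolationError(
            f"|Z| increases with frequency ({z1:.6g} ohm @ {f1:g} Hz -> "
            f"{z2:.6g} ohm @ {f2:g} Hz): incompatible with a series-RC model"
        )
    invc2 = num / den
    r_sq = z1**2 - invc2 / w1**2
    if r_sq < 0:
        raise ModelViolationError(
            "negative ohmic term: dispersion too strong for a series-RC model"
        )
    return math.sqrt(r_sq), invc2


def fit_series_rc(m1: SpectrumMeasurement, m2: SpectrumMeasurement) -> TwoFreqFit:
    """Exact series-RC fit through two measurements at distinct frequencies.

    Returns R and C reproducing both measured magnitudes exactly.  R never
    exceeds the smaller of the two |Z|.  Equal magnitudes give a purely
    ohmic fit with unbounded C.
    """
    lo, hi = sorted((m1, m2), key=lambda m: m.frequency)
    if lo.frequency == hi.frequency:
        raise InputError("two-frequency fit needs two distinct frequencies")
    if lo.z_mag <= 0 or hi.z_mag <= 0:
        raise InputError("impedance magnitudes must be positive")
    R, invc2 = _solve_pair(lo.frequency, lo.z_mag, hi.frequency, hi.z_mag)
    if invc2 == 0.0:
        return TwoFreqFit(R=R, C=math.inf, frequencies=(lo.frequency, hi.frequency),
                          capacitance_unbounded=True)
    return TwoFreqFit(R=R, C=1.0 / math.sqrt(invc2),
                      frequencies=(lo.frequency, hi.frequency))


def fit_series_rc_multi(spectrum) -> tuple:
    """Least-squares series-RC fit over a whole spectrum, plus a per-pair table.

    Linear least squares of |Z|^2 against 1/omega^2 gives the pooled
    (R, C).  The second return value is a DataFrame with one row per
    frequency pair (columns f1_hz, f2_hz, R_ohm, C_f) — the grouped
    per-pair diagnostic; pairs violating the model carry NaN.

    Returns
    -------
    (TwoFreqFit, pandas.DataFrame)
    """
    ms = sorted(spectrum, key=lambda m: m.frequency)
    freqs = [m.frequency for m in ms]
    if len(set(freqs)) < 2:
        raise InputError("need measurements at two or more distinct frequencies")
    z = np.array([m.z_mag for m in ms])
    w = 2.0 * math.pi * np.array(freqs)
    x = 1.0 / w**2
    y = z**2
    # slope = 1/C^2, intercept = R^2; x is rescaled for conditioning
    xm = x.max()
    A = np.column_stack([x / xm, np.ones_like(x)])
    (a, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    slope = a / xm
    unbounded = False
    # non-positive or unresolvable dispersion: purely ohmic spectrum
    if a <= 0 or a < 1e-9 * abs(intercept):
        slope, unbounded = 0.0, True
        intercept = float(np.mean(y))
    if intercept < 0:
        raise ModelViolationError("negative ohmic term in pooled fit")
    resid = y - (slope * x + intercept)
    fit = TwoFreqFit(
        R=math.sqrt(intercept),
        C=math.inf if unbounded else 1.0 / math.sqrt(slope),
        frequencies=tuple(freqs),
        capacitance_unbounded=unbounded,
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )
    rows = []
    for (i, mi), (j, mj) in itertools.combinations(enumerate(ms), 2):
        try:
            pair = fit_series_rc(mi, mj)
            rows.append((mi.frequency, mj.frequency, pair.R, pair.C))
        except ModelViolationError:
            rows.append((mi.frequency, mj.frequency, math.nan, math.nan))
    table = pd.DataFrame(rows, columns=["f1_hz", "f2_hz", "R_ohm", "C_f"])
    return fit, table
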