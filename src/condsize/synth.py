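"""Seeded synthetic-measurement simulator.

Forward-simulates the voltage spectra an impedance console would record
for a guidewire in a vessel: the three-pathway conductance model gives the
ohmic system resistance, a series polarization capacitance adds the
electrode-interface dispersion, and multiplicative Gaussian noise stands
in for instrument noise.  Every other module is testable against these
spectra without any instrument data.

The ex-vivo battery generator emulates the bench validation design:
vessels spanning 1.7–8 mm lumen diameter and wall-thickness ratios
0.16–0.9, perfused with 0.45% saline, suspended in a de-ionized water
bath (no conductive surroundings), with the coronary 2-2-2 wire for
vessels under 4 mm and the peripheral 5-5-5 wire above.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import ConductivityTable, conductivity_lookup
from .core_model import total_resistance_forward
from .errors import InputError
from .geometry import GW_2_2_2, GW_5_5_5, GuidewireSpec, MediumProps, VesselScenario
from .parallel_field import FieldKernel
from .twofreq import SpectrumMeasurement

__all__ = ["SimConfig", "simulate_spectrum", "make_exvivo_battery"]

#: Default polarization capacitance, F.  100 nF puts the capacitive term at
#: ~160 ohm at 10 kHz vs ~80 ohm at 20 kHz, so the two working frequencies
#: are well separated in |Z| as the method requires.
DEFAULT_C_POL = 100e-9
DEFAULT_CURRENT = 100e-6  # A rms, the bench excitation
DEFAULT_FREQUENCIES = (10e3, 20e3)


@dataclass(frozen=True)
class SimConfig:
    """One simulated measurement setup (scenario + instrument parameters)."""

    scenario: VesselScenario
    media: MediumProps
    gw: GuidewireSpec
    c_pol: float = DEFAULT_C_POL
    current: float = DEFAULT_CURRENT
    frequencies: tuple = DEFAULT_FREQUENCIES
    noise_cv: float = 0.0
    seed: int = 0
    kernel: FieldKernel = field(default_factory=FieldKernel)

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InputError("noise_cv must be non-negative")
        if len(set(self.frequencies)) != len(self.frequencies):
            raise InputError("frequencies must be distinct")
        if self.c_pol <= 0 or self.current <= 0:
            raise InputError("c_pol and current must be positive")


def simulate_spectrum(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Simulate the rms voltage at each configured frequency.

    V(f) = I * sqrt(R^2 + (1 / (2 pi f C_pol))^2) * (1 + eps_f) with
    eps_f ~ Normal(0, noise_cv), drawn independently per frequency from
    ``rng`` (or a generator seeded with ``cfg.seed``).  Returns a list of
    :class:`SpectrumMeasurement` and is bit-reproducible for a fixed seed.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    dec = total_resistance_forward(cfg.scenario, cfg.media, cfg.gw, cfg.kernel)
    out = []
    for f in cfg.frequencies:
        z = math.sqrt(dec.R**2 + (1.0 / (2.0 * math.pi * f * cfg.c_pol)) ** 2)
        v = cfg.current * z
        if cfg.noise_cv > 0:
            v *= 1.0 + cfg.noise_cv * rng.standard_normal()
        out.append(SpectrumMeasurement(frequency=f, current=cfg.current, voltage=v))
    return out


def _centered_grid(lo: float, hi: float, n: int) -> np.ndarray:
    # n cell midpoints of [lo, hi]; n = 1 gives the interval midpoint
    return lo + (np.arange(n) + 0.5) * (hi - lo) / n


def make_exvivo_battery(
    n: int = 11,
    *,
    d_range_mm: tuple = (1.7, 8.0),
    tr_range: tuple = (0.16, 0.9),
    sigma_table: ConductivityTable | None = None,
    sigma_t: float = 0.4,
    bath_thickness: float = 0.0,
    sigma_bath: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
    duplicates: bool = False,
) -> tuple:
    """Build n ex-vivo-style scenarios plus a truth table.

    Diameters sit on a centred grid covering ``d_range_mm``; TR values on
    a centred grid over ``tr_range``, assigned to diameters by a seeded
    permutation (so size and wall ratio are not artificially correlated).
    The lumen-fluid conductivity is looked up from ``sigma_table`` (the
    packaged 0.45%-saline table by default) at 10 kHz and the true
    diameter.  The guidewire is the 2-2-2 wire below 4 mm, 5-5-5 above.

    With ``duplicates=True`` each scenario appears twice with independent
    noise draws, supporting a repeatability analysis.

    Returns
    -------
    (list of SimConfig, pandas.DataFrame)
        The truth table has one row per config: scenario, replicate,
        d_b_mm, tr, gw label, sigma_b, sigma_t, seed.
    """
    if n < 1:
        raise InputError("need at least one scenario")
    if sigma_table is None:
        from .io import load_saline_conductivity_table

        sigma_table = load_saline_conductivity_table()
    rng = np.random.default_rng(seed)
    diameters = _centered_grid(d_range_mm[0], d_range_mm[1], n) * 1e-3
    trs = _centered_grid(tr_range[0], tr_range[1], n)[rng.permutation(n)]
    seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=2 * n)

    configs, rows = [], []
    k = 0
    for i, (d_b, tr) in enumerate(zip(diameters, trs)):
        gw = GW_2_2_2 if d_b < 4e-3 else GW_5_5_5
        sigma_b = conductivity_lookup(sigma_table, 10e3, d_b)
        scn = VesselScenario.from_tr(d_b, tr, bath_thickness=bath_thickness,
                                     sigma_bath=sigma_bath)
        media = MediumProps(sigma_b=sigma_b, sigma_t=sigma_t)
        for rep in range(2 if duplicates else 1):
            cfg = SimConfig(scenario=scn, media=media, gw=gw,
                            noise_cv=noise_cv, seed=int(seeds[k]))
            configs.append(cfg)
            rows.append({
                "scenario": i, "replicate": rep,
                "d_b_mm": d_b * 1e3, "tr": tr, "guidewire": gw.label,
                "sigma_b_s_per_m": sigma_b, "sigma_t_s_per_m": sigma_t,
                "seed": int(seeds[k]),
            })
            k += 1
    return configs, pd.DataFrame(rows)
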