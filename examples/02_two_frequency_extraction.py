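"""Extracting the ohmic system resistance from a voltage spectrum.

Electrode polarization adds a series capacitance, so the measured |Z|
falls with frequency toward the true tissue resistance R.  Two
frequencies determine (R, C) exactly; a full spectrum is pooled by least
squares and every frequency pair gives the same R on clean data.
"""
import math

from condsize import fit_series_rc_multi, impedance_from_voltage

R_TRUE, C_POL, CURRENT = 500.0, 100e-9, 100e-6  # ohm, F, A rms

spectrum = []
for f in (10e3, 20e3, 40e3, 60e3, 80e3):
    z = math.sqrt(R_TRUE**2 + (1 / (2 * math.pi * f * C_POL)) ** 2)
    spectrum.append(impedance_from_voltage(f, CURRENT, CURRENT * z))
    print(f"{f/1e3:5.0f} kHz: V = {CURRENT * z * 1e3:7.3f} mV  |Z| = {z:7.2f} ohm")

fit, pairs = fit_series_rc_multi(spectrum)
print(f"\npooled fit: R = {fit.R:.3f} ohm, C = {fit.C * 1e9:.2f} nF")
print("per-pair R (ohm):", ", ".join(f"{r:.3f}" for r in pairs["R_ohm"]))
# All ten pairs agree: the series-RC model explains the dispersion, and
# G = 1/R is the conductance the sizing model consumes.
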