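"""Conductivity calibration: phantoms, the packaged saline table, wall tissue.

A rigid phantom of known diameter turns a resistance into a fluid
conductivity; the packaged table maps (frequency, diameter) to the
apparent conductivity of 0.45% saline; an ex-vivo wall conductance turns
into a tissue conductivity through the annular wall geometry.
"""
from condsize import (
    GW_5_5_5,
    conductivity_lookup,
    load_saline_conductivity_table,
    lumen_conductance,
    phantom_conductivity,
    tissue_conductivity_from_exvivo,
)

table = load_saline_conductivity_table()
print("saline table: sigma(10 kHz, 4 mm) =", conductivity_lookup(table, 10e3, 4e-3), "S/m")
print("interpolated  sigma(10 kHz, 5 mm) =", conductivity_lookup(table, 10e3, 5e-3), "S/m")

# phantom calibration round trip: forward-model a 4 mm phantom, invert R
R = 1.0 / lumen_conductance(0.95, 4e-3, GW_5_5_5)
print(f"4 mm phantom at sigma 0.95 S/m -> R = {R:.1f} ohm "
      f"-> recovered sigma = {phantom_conductivity(R, 4e-3, GW_5_5_5):.4f} S/m")

# ex-vivo wall tissue: measured wall conductances at 10 and 40 kHz
for f_khz, g_t_ms in ((10, 2.97), (40, 3.12)):
    sigma_t = tissue_conductivity_from_exvivo(g_t_ms * 1e-3, 3.2e-3, 0.79, GW_5_5_5)
    print(f"wall tissue at {f_khz} kHz: Gt = {g_t_ms} mS -> sigma_t = {sigma_t:.3f} S/m")
# Tissue conductivity is essentially flat over 10-80 kHz (~0.4 S/m), which
# is why a single assumed value suffices for sizing.
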