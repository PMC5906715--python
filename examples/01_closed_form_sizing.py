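"""Closed-form lumen sizing when nothing conducts outside the vessel wall.

Builds the forward conductance model for a 4 mm vessel measured with the
peripheral 5-5-5 guidewire, then inverts the total resistance back to the
diameter.  With no surrounding bath the inversion is exact algebra.
"""
from condsize import (
    GW_5_5_5,
    MediumProps,
    VesselScenario,
    cylindricity_check,
    invert_diameter_closed_form,
    total_resistance_forward,
)

scn = VesselScenario.from_tr(d_b=4e-3, tr=0.5)          # 4 mm lumen, 2 mm wall
media = MediumProps(sigma_b=1.0, sigma_t=0.4)           # S/m: lumen fluid, wall tissue

dec = total_resistance_forward(scn, media, GW_5_5_5)
print(f"lumen conductance  G_b = {dec.G_b * 1e3:.4f} mS")
print(f"wall conductance   G_t = {dec.G_t * 1e3:.4f} mS")
print(f"system resistance  R   = {dec.R:.2f} ohm")

d_hat = invert_diameter_closed_form(dec.R, media.sigma_b, media.sigma_t, scn.tr, GW_5_5_5)
print(f"inverted diameter      = {d_hat * 1e3:.4f} mm (truth 4.0000 mm)")
print(f"cylindricity check     : {cylindricity_check(GW_5_5_5, scn.d_b)}")
# The inversion reproduces the diameter exactly: measured R plus the two
# conductivities and the wall-thickness ratio determine the lumen size.
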