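"""Annular conductance model: forward terms, closed-form inversion, geometry checks."""
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from condsize import (
    DomainError,
    GuidewireSpec,
    MediumProps,
    VesselScenario,
    cylindricity_check,
    invert_diameter_closed_form,
    lumen_conductance,
    total_resistance_forward,
    wall_conductance,
)
from condsize.geometry import check_consistency


class TestGuidewireGeometry:
    def test_stock_wires(self, gw555, gw222):
        # 1 mm electrodes: centre-to-centre sensing gap+width, excitation 3x
        assert gw555.L == pytest.approx(6e-3)
        assert gw555.d == pytest.approx(18e-3)
        assert gw555.d_gw == pytest.approx(0.889e-3)
        assert gw222.L == pytest.approx(3e-3)
        assert gw222.d == pytest.approx(9e-3)
        assert gw222.d_gw == pytest.approx(0.3556e-3)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(DomainError):
            GuidewireSpec(label="bad", gap=5, electrode_width=1, L=-1e-3, d=18e-3, d_gw=1e-3)
        with pytest.raises(DomainError):
            GuidewireSpec(label="bad", gap=5, electrode_width=1, L=6e-3, d=5e-3, d_gw=1e-3)
        with pytest.raises(DomainError):
            GuidewireSpec.from_label("7-7-7")


class TestLumenConductance:
    def test_exvivo_vessel(self, gw555):
        # bovine carotid: sigma_b 1.4 S/m, 3.2 mm lumen -> ~1.75 mS measured
        g = lumen_conductance(1.4, 3.2e-3, gw555)
        assert g == pytest.approx(1.75e-3, rel=0.02)

    def test_hand_evaluated(self, gw555):
        assert lumen_conductance(1.0, 4e-3, gw555) == pytest.approx(1.9910e-3, rel=1e-4)

    def test_zero_conductivity(self, gw555):
        assert lumen_conductance(0.0, 4e-3, gw555) == 0.0

    def test_guidewire_larger_than_lumen(self, gw555):
        with pytest.raises(DomainError):
            lumen_conductance(1.0, 0.5e-3, gw555)

    def test_linear_in_conductivity(self, gw555):
        # Table-2-style consistency: G scales exactly with sigma
        ratio = lumen_conductance(1.5, 3.2e-3, gw555) / lumen_conductance(1.4, 3.2e-3, gw555)
        assert ratio == pytest.approx(1.5 / 1.4, rel=1e-12)


class TestWallConductance:
    def test_exvivo_vessel(self, gw555):
        # TR 0.79, sigma_t 0.39 -> measured wall conductance ~2.97 mS
        g = wall_conductance(0.39, 3.2e-3, 0.79, gw555)
        assert g == pytest.approx(2.97e-3, rel=0.01)

    def test_hand_evaluated(self, gw555):
        assert wall_conductance(0.4, 4e-3, 0.5, gw555) == pytest.approx(2.5133e-3, rel=1e-4)

    def test_zero_wall(self, gw555):
        assert wall_conductance(0.4, 4e-3, 0.0, gw555) == 0.0

    def test_negative_tr_rejected(self, gw555):
        with pytest.raises(DomainError):
            wall_conductance(0.4, 4e-3, -0.1, gw555)


class TestInversion:
    def test_round_trip_reference_case(self, gw555):
        g = lumen_conductance(1.0, 4e-3, gw555) + wall_conductance(0.4, 4e-3, 0.5, gw555)
        assert 1.0 / g == pytest.approx(222.01, rel=1e-4)
        d = invert_diameter_closed_form(1.0 / g, 1.0, 0.4, 0.5, gw555)
        assert d == pytest.approx(4e-3, rel=1e-12)

    def test_bare_cylinder_limit(self):
        # no wall, vanishing shaft: d_b = sqrt(4L / (pi R sigma_b))
        gw = GuidewireSpec(label="thin", gap=5, electrode_width=1, L=6e-3, d=18e-3, d_gw=1e-6)
        R, sigma = 300.0, 1.2
        d = invert_diameter_closed_form(R, sigma, 0.0, 0.0, gw)
        assert d == pytest.approx(math.sqrt(4 * 6e-3 / (math.pi * R * sigma)), rel=1e-6)

    def test_exvivo_total_conductance_gives_optical_diameter(self, gw555):
        # measured zero-bath total 4.6579 mS with bench conductivities
        d = invert_diameter_closed_form(1.0 / 4.6579e-3, 1.4, 0.39, 0.79, gw555)
        assert d * 1e3 == pytest.approx(3.2, rel=0.01)

    def test_inconsistent_measurement_rejected(self, gw555):
        with pytest.raises(DomainError):
            invert_diameter_closed_form(1e9, 1.4, 0.39, 0.79, gw555)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        d_mm=st.floats(1.2, 9.0),
        sigma_b=st.floats(0.3, 2.5),
        sigma_t=st.floats(0.0, 1.0),
        tr=st.floats(0.0, 1.2),
    )
    def test_round_trip_property(self, d_mm, sigma_b, sigma_t, tr):
        gw = GuidewireSpec.from_label("5-5-5")
        d_b = d_mm * 1e-3
        g = lumen_conductance(sigma_b, d_b, gw) + wall_conductance(sigma_t, d_b, tr, gw)
        assert invert_diameter_closed_form(1.0 / g, sigma_b, sigma_t, tr, gw) == pytest.approx(
            d_b, rel=1e-10
        )

    @pytest.mark.parametrize("param", ["sigma_t", "tr"])
    def test_monotone_decreasing_in_wall_terms(self, gw555, param):
        R = 300.0
        values = [0.1, 0.3, 0.5, 0.8]
        kwargs = {"sigma_t": 0.4, "tr": 0.5}
        estimates = []
        for v in values:
            kwargs[param] = v
            estimates.append(invert_diameter_closed_form(R, 1.4, kwargs["sigma_t"], kwargs["tr"], gw555))
        assert all(a > b for a, b in zip(estimates, estimates[1:]))


class TestForwardDecomposition:
    def test_no_bath(self, gw555):
        scn = VesselScenario.from_tr(4e-3, 0.5)
        dec = total_resistance_forward(scn, MediumProps(1.0, 0.4), gw555)
        assert dec.G_bath == 0.0
        assert dec.G == pytest.approx(4.5043e-3, rel=1e-4)
        assert dec.R == pytest.approx(222.01, rel=1e-4)
        assert check_consistency(dec)

    def test_exvivo_zero_bath_total(self, gw555):
        # matches the measured zero-bath total conductance within 3%
        scn = VesselScenario.from_tr(3.2e-3, 0.79)
        dec = total_resistance_forward(scn, MediumProps(1.4, 0.39), gw555)
        assert dec.G == pytest.approx(4.6579e-3, rel=0.03)

    def test_bath_increases_conductance(self, gw555):
        media = MediumProps(1.4, 0.39)
        dry = total_resistance_forward(VesselScenario.from_tr(3.2e-3, 0.79), media, gw555)
        wet = total_resistance_forward(
            VesselScenario.from_tr(3.2e-3, 0.79, bath_thickness=10e-3, sigma_bath=0.18),
            media, gw555)
        assert wet.G > dry.G
        assert wet.G_bath > 0
        assert check_consistency(wet)


class TestCylindricity:
    @pytest.mark.parametrize(
        "label,d_b_mm,expected",
        [
            ("2-2-2", 4.0, "ok"),       # ratio 2.25
            ("5-5-5", 10.0, "warning"),  # ratio 1.8
            ("5-5-5", 1e-6, "ok"),
        ],
    )
    def test_excitation_span_ratio(self, label, d_b_mm, expected):
        gw = GuidewireSpec.from_label(label)
        assert cylindricity_check(gw, d_b_mm * 1e-3) == expected
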