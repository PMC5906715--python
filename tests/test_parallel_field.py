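"""Parallel-conductance field model: kernels, bath fractions, kernel fitting."""
import numpy as np
import pytest

from condsize import (
    BathSeries,
    FieldKernel,
    FitError,
    GW_2_2_2,
    GW_5_5_5,
    InputError,
    VesselScenario,
    bath_conductance,
    bath_fraction_empirical,
    bath_fraction_model,
    fit_kernel_scale,
    parallel_conductance_model,
    wall_conductance,
)

SIGMA_BATH = 0.18  # 0.1% NaCl, room temperature
BATH_GRID = (0.0, 2.118e-3, 4.868e-3, 11.668e-3, 20.868e-3)


def carotid(bath=0.0, sigma_bath=SIGMA_BATH, tr=0.79):
    return VesselScenario.from_tr(3.2e-3, tr, bath_thickness=bath, sigma_bath=sigma_bath)


class TestParallelConductanceModel:
    def test_zero_bath_equals_wall_conductance(self, gw555):
        for kernel in (FieldKernel(), FieldKernel(kind="uniform"),
                       FieldKernel(kind="cylindrical", scale=4e-3)):
            g_p = parallel_conductance_model(carotid(), 0.39, gw555, kernel)
            assert g_p == pytest.approx(wall_conductance(0.39, 3.2e-3, 0.79, gw555), rel=1e-12)

    def test_nonconductive_bath(self, gw555):
        g_p = parallel_conductance_model(carotid(bath=10e-3, sigma_bath=0.0), 0.39,
                                         gw555, FieldKernel())
        assert g_p == pytest.approx(wall_conductance(0.39, 3.2e-3, 0.79, gw555), rel=1e-12)

    def test_quadrature_refinement(self, gw555):
        scn = carotid(bath=20.868e-3)
        coarse = parallel_conductance_model(scn, 0.39, gw555, FieldKernel(), n_steps=1000)
        fine = parallel_conductance_model(scn, 0.39, gw555, FieldKernel(), n_steps=2000)
        assert fine == pytest.approx(coarse, rel=1e-6)

    def test_homogeneous_uniform_limit_is_area_ratio(self, gw555):
        # sigma_bath = sigma_t with full weight: conductances ~ annulus areas
        sigma = 0.39
        scn = carotid(bath=5e-3, sigma_bath=sigma)
        g_bath = bath_conductance(scn, gw555, FieldKernel(kind="uniform"))
        g_wall = wall_conductance(sigma, 3.2e-3, 0.79, gw555)
        r_b, r_w = scn.d_b / 2, scn.d_b / 2 + scn.t_w
        r_o = r_w + scn.bath_thickness
        assert g_bath / g_wall == pytest.approx((r_o**2 - r_w**2) / (r_w**2 - r_b**2), rel=1e-6)

    def test_saturation_with_thickness(self, gw555):
        # integrable kernel: bath conductance approaches an asymptote
        kernel = FieldKernel(scale=5e-3)
        g = [bath_conductance(carotid(bath=t), gw555, kernel)
             for t in (10e-3, 40e-3, 80e-3)]
        assert g[1] < g[2]
        assert (g[2] - g[1]) < 0.01 * g[1]


class TestEmpiricalFractions:
    def test_measured_series_fractions(self, bath_series):
        # largest-bath fractions at 10 and 20 kHz from the packaged series
        frac = bath_fraction_empirical(bath_series) * 100
        assert frac[0, -1] == pytest.approx(63.65, abs=0.01)
        assert frac[1, -1] == pytest.approx(65.38, abs=0.01)
        assert np.all(frac >= 0) and np.all(frac <= 100)
        assert np.all(np.diff(frac, axis=1) >= 0)

    def test_constant_series_gives_zero(self):
        series = BathSeries(bath_thicknesses=(0.0, 1e-3, 2e-3), frequencies=(1e4,),
                            g_total=np.full((1, 3), 5e-3))
        assert np.allclose(bath_fraction_empirical(series), 0.0)

    def test_missing_baseline_rejected(self):
        series = BathSeries(bath_thicknesses=(1e-3, 2e-3), frequencies=(1e4,),
                            g_total=np.array([[5e-3, 6e-3]]))
        with pytest.raises(InputError):
            bath_fraction_empirical(series)


class TestModelFractions:
    def test_zero_bath_column_is_zero(self):
        bf = bath_fraction_model([0.1, 0.3, 0.5, 0.8], BATH_GRID, 3.2e-3, 1.4, 0.39,
                                 SIGMA_BATH, GW_5_5_5, FieldKernel())
        assert np.allclose(bf[:, 0], 0.0)
        assert np.all(bf >= 0) and np.all(bf <= 1)

    def test_thin_wall_loses_more_current_at_max_bath(self):
        # mirrors the printed ordering 87.66% (TR=0.1) > 63.44% (TR=0.8)
        bf = bath_fraction_model([0.1, 0.8], BATH_GRID, 3.2e-3, 1.4, 0.39,
                                 SIGMA_BATH, GW_5_5_5, FieldKernel(scale=7e-3))
        assert bf[0, -1] > bf[1, -1]

    def test_cylindrical_kernel_fully_monotone(self):
        # the cylindrical kernel class guarantees TR-monotonicity everywhere
        for scale in (2e-3, 7e-3, 30e-3):
            bf = bath_fraction_model(np.linspace(0.05, 0.9, 12), BATH_GRID, 3.2e-3,
                                     1.4, 0.39, SIGMA_BATH, GW_5_5_5,
                                     FieldKernel(kind="cylindrical", scale=scale))
            assert np.all(np.diff(bf, axis=0) <= 1e-12)
            assert np.all(np.diff(bf, axis=1) >= -1e-12)

    def test_homogeneous_uniform_kernel_reduces_to_area_ratio(self):
        # sigma_bath = sigma_t, w = 1: fraction = bath annulus area over total
        sigma = 0.39
        bf = bath_fraction_model([0.5], (0.0, 5e-3), 3.2e-3, 1.4, sigma, sigma,
                                 GW_5_5_5, FieldKernel(kind="uniform"))
        scn = VesselScenario.from_tr(3.2e-3, 0.5, bath_thickness=5e-3, sigma_bath=sigma)
        g_bath = bath_conductance(scn, GW_5_5_5, FieldKernel(kind="uniform"))
        from condsize import lumen_conductance

        total = (lumen_conductance(1.4, 3.2e-3, GW_5_5_5)
                 + wall_conductance(sigma, 3.2e-3, 0.5, GW_5_5_5) + g_bath)
        assert bf[0, -1] == pytest.approx(g_bath / total, rel=1e-9)


class TestKernelFit:
    def test_self_consistency_on_synthetic_series(self, gw555):
        true = FieldKernel(scale=6e-3)
        ts = (0.0, 2e-3, 5e-3, 10e-3, 20e-3)
        g0 = 4.7e-3
        g = np.array([[g0 + bath_conductance(carotid(bath=t), gw555, true) if t else g0
                       for t in ts]])
        series = BathSeries(bath_thicknesses=ts, frequencies=(1e4,), g_total=g)
        kernel, resid = fit_kernel_scale(series, carotid(bath=20e-3), gw555)
        assert kernel.scale == pytest.approx(true.scale, rel=0.01)
        assert np.max(np.abs(resid)) < 1e-9

    def test_fit_quality_on_measured_series(self, bath_series, gw555):
        # fitted model reproduces the measured bath-conductance curve well
        kernel, resid = fit_kernel_scale(bath_series, carotid(bath=20.868e-3), gw555)
        g_bath_max = (bath_series.g_total[:, -1] - bath_series.g_total[:, 0]).max()
        rms = float(np.sqrt(np.mean(resid**2)))
        assert rms < 0.15 * g_bath_max

    def test_degenerate_series_rejected(self, gw555):
        series = BathSeries(bath_thicknesses=(0.0, 1e-3, 2e-3), frequencies=(1e4,),
                            g_total=np.full((1, 3), 5e-3))
        with pytest.raises(FitError):
            fit_kernel_scale(series, carotid(bath=2e-3), gw555)

    def test_coronary_wire_sees_smaller_parallel_fraction(self, bath_series, gw555):
        # with the fitted kernel rescaled to the shorter wire, 2-2-2 loses a
        # smaller share of current than 5-5-5 in 2-4 mm vessels
        kernel, _ = fit_kernel_scale(bath_series, carotid(bath=20.868e-3), gw555)
        k222 = kernel.scaled_for_guidewire(GW_2_2_2, gw555)
        assert k222.scale == pytest.approx(kernel.scale / 2)
        for d_mm in (2.0, 3.0, 4.0):
            bf5 = bath_fraction_model([0.3], (0.0, 10e-3), d_mm * 1e-3, 1.2, 0.4,
                                      SIGMA_BATH, gw555, kernel)
            bf2 = bath_fraction_model([0.3], (0.0, 10e-3), d_mm * 1e-3, 1.2, 0.4,
                                      SIGMA_BATH, GW_2_2_2, k222)
            assert bf2[0, -1] < bf5[0, -1]
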