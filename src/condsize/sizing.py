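"""Injection-less lumen-diameter estimation: the iterative inversion.

The procedure mirrors the bench workflow:

1. measure voltages at two frequencies, convert to impedance magnitudes;
2. extract the ohmic system resistance R with the series-RC two-frequency
   model — the total conductance is G = 1/R;
3. for a candidate lumen diameter, compute the lumen conductance G_b with
   the fluid conductivity looked up (frequency, diameter) from the
   calibration table;
4. the measurement-side parallel conductance is G - G_b; the model-side
   parallel conductance is the wall + bath field integral at the same
   candidate diameter;
5. adjust the diameter until the two parallel-conductance estimates agree
   to within the convergence tolerance (2% by default).

Both G_b and the model G_p grow monotonically with the candidate
diameter, so the mismatch (G - G_b) - G_p is strictly decreasing and the
root is unique; it is bracketed on [1.05 d_gw, d/2] and found by
bisection.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibration import ConductivityTable, conductivity_lookup
from .core_model import lumen_conductance
from .errors import InfeasibleMeasurementError, InputError, NoSolutionError
from .geometry import ConductanceDecomposition, GuidewireSpec, VesselScenario
from .parallel_field import FieldKernel, bath_conductance, parallel_conductance_model
from .twofreq import SpectrumMeasurement, fit_series_rc, fit_series_rc_multi

__all__ = ["DiameterEstimate", "estimate_diameter", "sensitivity_analysis"]

#: Default convergence tolerance on the relative parallel-conductance mismatch.
DEFAULT_TOL = 0.02
MAX_ITER = 100


@dataclass(frozen=True)
class DiameterEstimate:
    """Result of the iterative inversion.

    ``mismatch`` is the relative discrepancy between the measurement-side
    and model-side parallel conductances at exit; ``converged`` implies
    mismatch <= tol.  ``decomposition`` carries the conductance split at
    the returned diameter and ``sigma_b_used`` the self-consistent fluid
    conductivity.
    """

    d_b: float
    iterations: int
    converged: bool
    mismatch: float
    decomposition: ConductanceDecomposition
    sigma_b_used: float


def _rel_mismatch(delta: float, g_p_model: float, g_total: float) -> float:
    denom = g_p_model if g_p_model > 0 else g_total
    return abs(delta) / denom


def estimate_diameter(
    spectrum,
    sigma_table: ConductivityTable,
    sigma_t: float,
    tr: float,
    gw: GuidewireSpec,
    *,
    bath_thickness: float = 0.0,
    sigma_bath: float = 0.0,
    kernel: FieldKernel | None = None,
    tol: float = DEFAULT_TOL,
    max_iter: int = MAX_ITER,
) -> DiameterEstimate:
    """Estimate the lumen diameter from a two-frequency voltage spectrum.

    Parameters
    ----------
    spectrum : sequence of SpectrumMeasurement
        Two (or more) measurements at distinct frequencies.  Exactly two
        give the exact pairwise fit; more are pooled by least squares.
    sigma_table : ConductivityTable
        Lumen-fluid conductivity vs (frequency, diameter); looked up at
        the lowest measured frequency and refreshed at every candidate
        diameter, so the returned conductivity is self-consistent with
        the returned diameter.
    sigma_t, tr : float
        Assumed wall conductivity (S/m) and wall-thickness ratio.
    bath_thickness, sigma_bath : float
        Surrounding-medium spec (m, S/m); zero for no parallel bath.
    kernel : FieldKernel, optional
        Radial field kernel for the bath term (default exponential).
    tol : float
        Relative parallel-conductance mismatch accepted as converged.

    Raises
    ------
    InfeasibleMeasurementError
        If G - G_b <= 0 at every admissible diameter.
    NoSolutionError
        If the mismatch does not change sign on the bracket.
    """
    spectrum = list(spectrum)
    if len(spectrum) < 2:
        raise InputError("need at least two measurements at distinct frequencies")
    if not (0.0 < tol < 0.5):
        raise InputError("tolerance must lie in (0, 0.5)")
    if kernel is None:
        kernel = FieldKernel()
    if len(spectrum) == 2:
        fit = fit_series_rc(spectrum[0], spectrum[1])
    else:
        fit, _ = fit_series_rc_multi(spectrum)
    g_total = fit.G
    f_low = min(m.frequency for m in spectrum)

    def pieces(d_b: float):
        sigma_b = conductivity_lookup(sigma_table, f_low, d_b)
        g_b = lumen_conductance(sigma_b, d_b, gw)
        scn = VesselScenario.from_tr(d_b, tr, bath_thickness=bath_thickness,
                                     sigma_bath=sigma_bath)
        g_p_model = parallel_conductance_model(scn, sigma_t, gw, kernel)
        return sigma_b, g_b, g_p_model

    def mismatch(d_b: float) -> float:
        _, g_b, g_p_model = pieces(d_b)
        return (g_total - g_b) - g_p_model

    lo = 1.05 * gw.d_gw
    hi = gw.d / 2.0
    m_lo = mismatch(lo)
    m_hi = mismatch(hi)
    if m_lo < 0 and m_hi < 0:
        # Even the smallest admissible lumen over-explains the measurement.
        grid = np.linspace(lo, hi, 33)
        if all(g_total - pieces(d)[1] <= 0 for d in grid):
            raise InfeasibleMeasurementError(
                "measured conductance is below the lumen conductance at every "
                "admissible diameter; check calibration and geometry"
            )
        raise NoSolutionError("parallel-conductance mismatch has no sign change on the bracket")
    if m_lo * m_hi > 0:
        raise NoSolutionError(
            "parallel-conductance mismatch has no sign change on "
            f"[{lo*1e3:.2f}, {hi*1e3:.2f}] mm"
        )

    iterations = 0
    d_mid = 0.5 * (lo + hi)
    converged = False
    rel = math.inf
    for iterations in range(1, max_iter + 1):
        d_mid = 0.5 * (lo + hi)
        m_mid = mismatch(d_mid)
        _, _, g_p_model = pieces(d_mid)
        rel = _rel_mismatch(m_mid, g_p_model, g_total)
        if rel <= tol and (hi - lo) / d_mid < 1e-3:
            converged = True
            break
        if m_lo * m_mid <= 0:
            hi = d_mid
        else:
            lo, m_lo = d_mid, m_mid

    sigma_b, g_b, g_p_model = pieces(d_mid)
    scn = VesselScenario.from_tr(d_mid, tr, bath_thickness=bath_thickness,
                                 sigma_bath=sigma_bath)
    g_bath = bath_conductance(scn, gw, kernel)
    dec = ConductanceDecomposition(G_b=g_b, G_t=g_p_model - g_bath, G_bath=g_bath)
    return DiameterEstimate(
        d_b=d_mid,
        iterations=iterations,
        converged=converged,
        mismatch=rel,
        decomposition=dec,
        sigma_b_used=sigma_b,
    )


def sensitivity_analysis(
    d_b: float,
    sigma_b: float,
    sigma_t: float,
    tr: float,
    gw: GuidewireSpec,
    *,
    perturb: str = "t_w",
    fraction: float = 0.20,
) -> float:
    """Signed % change of the diameter estimate under an assumption error.

    The measurement is held fixed: the system resistance is what a vessel
    of diameter ``d_b`` with the *true* parameters would produce (no
    bath); the estimate is then re-inverted with the assumed parameter
    perturbed by ``fraction`` (+20% by default).

    Parameters
    ----------
    perturb : {"t_w", "sigma_t"}
        Which model input is mis-assumed: wall thickness (i.e. TR, since
        the true diameter is fixed) or wall conductivity.

    Returns
    -------
    float
        100 * (d_perturbed - d_base) / d_base.
    """
    from .core_model import invert_diameter_closed_form, wall_conductance

    if perturb not in ("t_w", "sigma_t"):
        raise InputError(f"perturb must be 't_w' or 'sigma_t', got {perturb!r}")
    g = lumen_conductance(sigma_b, d_b, gw) + wall_conductance(sigma_t, d_b, tr, gw)
    R = 1.0 / g
    if perturb == "t_w":
        d_pert = invert_diameter_closed_form(R, sigma_b, sigma_t, tr * (1.0 + fraction), gw)
    else:
        d_pert = invert_diameter_closed_form(R, sigma_b, sigma_t * (1.0 + fraction), tr, gw)
    d_base = invert_diameter_closed_form(R, sigma_b, sigma_t, tr, gw)
    return 100.0 * (d_pert - d_base) / d_base
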