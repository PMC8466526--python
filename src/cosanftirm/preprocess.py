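"""Spectral preprocessing operators.

The pipeline uses two documented chains:

* fingerprint / lipids regions: EMSC on the raw spectra, then SNV;
* DNA region: EMSC, Savitzky-Golay second derivative (poly 3, window 9),
  then unit-vector normalization.

EMSC models each raw spectrum as ``a + b*m(nu) + sum_k d_k T_k`` against a
reference ``m`` (default: the set mean) with a low-order polynomial in the
rescaled wavenumber; the corrected spectrum is ``(raw - a - poly)/b``,
removing additive baselines and multiplicative scatter in one least-squares
step.  The rubber-band baseline is the lower convex hull of the spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.signal import savgol_coeffs

from .spectra import Spectrum, SpectrumSet

__all__ = [
    "EMSCModel",
    "emsc_correct",
    "snv_normalize",
    "unit_vector_normalize",
    "rubber_band_correct",
    "linear_baseline_correct",
    "savgol_derivative",
    "sg_edge_width",
    "lower_hull_baseline",
    "apply_recipe",
    "RECIPES",
]

_MIN_GAIN = 1e-6


@dataclass
class EMSCModel:
    """Fitted EMSC coefficients for one spectrum."""

    offset: float          # a
    gain: float            # b
    poly: np.ndarray       # d_1..d_p on Chebyshev-like rescaled axis (degree >= 1 terms)

    def __post_init__(self) -> None:
        if self.gain <= _MIN_GAIN:
            raise ValueError(f"EMSC gain b={self.gain:.3g} <= {_MIN_GAIN}; "
                             "spectrum is unrelated to the reference")


def _emsc_design(wavenumbers: np.ndarray, reference: np.ndarray, poly_order: int) -> np.ndarray:
    nu = (2.0 * (wavenumbers - wavenumbers[0]) / (wavenumbers[-1] - wavenumbers[0])) - 1.0
    cols = [reference, np.ones_like(nu)]
    for k in range(1, poly_order + 1):
        cols.append(nu ** k)
    X = np.column_stack(cols)
    # collinearity guard: a constant reference duplicates the offset column
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "singular EMSC design: reference is collinear with the polynomial "
            "baseline columns (constant reference?)")
    return X


def emsc_correct(sset: SpectrumSet, poly_order: int = 2,
                 reference: Spectrum | None = None) -> tuple[SpectrumSet, list[EMSCModel]]:
    """Extended multiplicative signal correction of a spectrum set.

    Returns the corrected set and the per-spectrum fitted models.  The
    default reference is the set mean, which requires >= 2 spectra.
    """
    if reference is None:
        if len(sset) < 2:
            raise ValueError("EMSC with the set-mean reference needs >= 2 spectra")
        ref = sset.absorbance.mean(axis=0)
    else:
        if not np.array_equal(reference.wavenumbers, sset.wavenumbers):
            raise ValueError("reference must share the set grid")
        ref = reference.absorbance
    X = _emsc_design(sset.wavenumbers, ref, poly_order)
    coefs, *_ = np.linalg.lstsq(X, sset.absorbance.T, rcond=None)
    models: list[EMSCModel] = []
    corrected = np.empty_like(sset.absorbance)
    for i in range(len(sset)):
        b = float(coefs[0, i])
        a = float(coefs[1, i])
        d = coefs[2:, i].copy()
        models.append(EMSCModel(offset=a, gain=b, poly=d))
        baseline = X[:, 1:] @ coefs[1:, i]
        corrected[i] = (sset.absorbance[i] - baseline) / b
    return sset.copy_with(corrected, emsc_poly_order=poly_order), models


def snv_normalize(s: Spectrum) -> Spectrum:
    """Standard normal variate: centre to mean 0, scale to sample sd 1."""
    a = s.absorbance
    if a.size < 2:
        raise ValueError("SNV needs >= 2 points")
    sd = a.std(ddof=1)
    if sd == 0.0:
        raise ValueError("SNV undefined for a constant spectrum (zero variance)")
    return s.copy_with((a - a.mean()) / sd, normalized="snv")


def unit_vector_normalize(s: Spectrum) -> Spectrum:
    """Scale to unit Euclidean norm (direction preserved)."""
    norm = float(np.linalg.norm(s.absorbance))
    if norm == 0.0:
        raise ValueError("cannot unit-normalize the zero spectrum")
    return s.copy_with(s.absorbance / norm, normalized="unit_vector")


def lower_hull_baseline(wavenumbers: np.ndarray, absorbance: np.ndarray) -> np.ndarray:
    """Lower convex hull of the (nu, A) point set, evaluated on the grid.

    Andrew monotone-chain over the ascending grid, keeping only the lower
    chain; the baseline is linear interpolation between hull vertices.
    """
    n = wavenumbers.size
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # drop i1 if it lies on/above the chord i0 -> i
            cross = ((wavenumbers[i1] - wavenumbers[i0]) * (absorbance[i] - absorbance[i0])
                     - (absorbance[i1] - absorbance[i0]) * (wavenumbers[i] - wavenumbers[i0]))
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(wavenumbers, wavenumbers[hull], absorbance[hull])


def rubber_band_correct(s: Spectrum) -> Spectrum:
    """Subtract the rubber-band (lower convex hull) baseline.

    The corrected spectrum is >= 0 everywhere and 0 at the hull vertices,
    in particular at both endpoints.
    """
    if len(s) < 3:
        raise ValueError("rubber-band correction needs >= 3 points")
    base = lower_hull_baseline(s.wavenumbers, s.absorbance)
    out = s.absorbance - base
    np.clip(out, 0.0, None, out=out)  # clear -0.0 / rounding at vertices
    return s.copy_with(out, baseline="rubber_band")


def linear_baseline_correct(s: Spectrum, anchor_lo: float, anchor_hi: float) -> Spectrum:
    """Subtract the straight line through the two anchor-point absorbances.

    Anchors snap to the nearest grid points; the output is exactly 0 at
    both anchors.
    """
    if anchor_lo == anchor_hi:
        raise ValueError("anchors must differ")
    lo, hi = sorted((anchor_lo, anchor_hi))
    w = s.wavenumbers
    if lo < w[0] or hi > w[-1]:
        raise ValueError("anchors outside grid span")
    i_lo = int(np.argmin(np.abs(w - lo)))
    i_hi = int(np.argmin(np.abs(w - hi)))
    slope = (s.absorbance[i_hi] - s.absorbance[i_lo]) / (w[i_hi] - w[i_lo])
    line = s.absorbance[i_lo] + slope * (w - w[i_lo])
    return s.copy_with(s.absorbance - line, baseline="linear")


def sg_edge_width(window: int) -> int:
    """Number of invalid points at each end of a Savitzky-Golay output."""
    return (window - 1) // 2


def savgol_derivative(s: Spectrum, window: int = 9, poly: int = 3,
                      order: int = 2) -> Spectrum:
    """Savitzky-Golay smoothed derivative (default: second derivative,
    third polynomial order, 9 smoothing points).

    Requires an equally spaced grid (1e-6 relative tolerance).  The
    ``(window-1)//2`` points at each edge are computed by the filter's
    one-sided fits but flagged invalid in ``meta['sg_edge']``; peak/minima
    detection must skip them.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if poly >= window:
        raise ValueError("poly must be < window")
    if order not in (0, 1, 2):
        raise ValueError("order must be 0, 1 or 2")
    d = np.diff(s.wavenumbers)
    spacing = d.mean()
    if np.any(np.abs(d - spacing) > 1e-6 * abs(spacing)):
        raise ValueError("grid is not equally spaced; resample_to_grid first")
    if len(s) < window:
        raise ValueError(f"need >= {window} points for window {window}")
    # convolve interior with central SG coefficients; edges via one-sided fits
    from scipy.signal import savgol_filter
    out = savgol_filter(s.absorbance, window_length=window, polyorder=poly,
                        deriv=order, delta=spacing, mode="interp")
    return s.copy_with(out, sg_edge=sg_edge_width(window),
                       sg_window=window, sg_poly=poly, sg_order=order)


# ---------------------------------------------------------------------------
# Named preprocessing recipes (applied per region, EMSC first on the set)

def _per_spectrum(sset: SpectrumSet, fn) -> SpectrumSet:
    rows = np.empty_like(sset.absorbance)
    meta: dict = {}
    for i in range(len(sset)):
        out = fn(sset.spectrum(i))
        rows[i] = out.absorbance
        meta = {k: v for k, v in out.meta.items() if k.startswith(("sg_", "normalized", "baseline"))}
    return sset.copy_with(rows, **meta)


def apply_recipe(sset: SpectrumSet, recipe: str, poly_order: int = 2) -> SpectrumSet:
    """Apply a named preprocessing chain to a (region-restricted) set.

    ``emsc_snv``    : EMSC then per-spectrum SNV (fingerprint / lipids).
    ``emsc_d2_uvn`` : EMSC, SG second derivative (poly 3, window 9), then
                      unit-vector normalization (DNA region).
    ``raw``         : pass-through.
    """
    if recipe == "raw":
        return sset
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; choose from {sorted(RECIPES)}")
    corrected, _ = emsc_correct(sset, poly_order=poly_order)
    if recipe == "emsc_snv":
        return _per_spectrum(corrected, snv_normalize)
    # emsc_d2_uvn
    deriv = _per_spectrum(corrected, savgol_derivative)
    return _per_spectrum(deriv, unit_vector_normalize)


RECIPES = {"emsc_snv", "emsc_d2_uvn", "raw"}
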