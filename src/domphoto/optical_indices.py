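"""CDOM absorption and FDOM fluorescence indices.

Absorption metrics work on decadic absorbance spectra (as measured by the
spectrophotometer):

* a_lambda : Napierian absorption coefficient, 2.303 * A(lambda) / path (m^-1)
* SUVA254  : A(254) / (path_m * DOC), in L mg C^-1 m^-1
* S_275-295, S_350-400 : spectral slopes (nm^-1) from ordinary least squares
  of ln a(lambda) on lambda within each window, reported with positive sign
* S_R      : slope ratio S_275-295 / S_350-400, inversely related to
  molecular weight

Fluorescence metrics work on scatter-corrected EEMs:

* BIX : emission 380 nm over 430 nm at excitation 310 nm (bilinear interp.)
* HIX : integrated emission 435-480 nm over 300-445 nm at excitation 254 nm
  (overlapping-band Zsolnay form, trapezoid integration)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import RegularGridInterpolator

from .core_io import EEM, AbsorbanceSpectrum

__all__ = [
    "NAPIERIAN_FACTOR",
    "OpticalSummary",
    "napierian_a",
    "suva254",
    "spectral_slope",
    "slope_ratio",
    "bix",
    "hix",
    "optical_summary",
]

#: decadic-to-Napierian conversion factor as conventionally printed
NAPIERIAN_FACTOR = 2.303

SLOPE_SHORT = (275.0, 295.0)
SLOPE_LONG = (350.0, 400.0)


class FitError(RuntimeError):
    """A spectral fit could not be performed on the available points."""


def _interp_absorbance(spec: AbsorbanceSpectrum, wavelength: float) -> float:
    wl = spec.wavelength_nm
    if not wl[0] <= wavelength <= wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside measured range "
            f"[{wl[0]}, {wl[-1]}] nm"
        )
    return float(np.interp(wavelength, wl, spec.absorbance))


def napierian_a(spec: AbsorbanceSpectrum, wavelength: float = 300.0) -> float:
    """Napierian absorption coefficient (m^-1) at a wavelength."""
    return NAPIERIAN_FACTOR * _interp_absorbance(spec, wavelength) / spec.path_length_m


def suva254(spec: AbsorbanceSpectrum, doc_mgC_L: float) -> float:
    """Specific UV absorbance at 254 nm (L mg C^-1 m^-1), a DOC-aromaticity proxy."""
    if not doc_mgC_L > 0:
        raise ValueError("DOC concentration must be positive")
    return _interp_absorbance(spec, 254.0) / (spec.path_length_m * doc_mgC_L)


def spectral_slope(spec: AbsorbanceSpectrum, lo: float, hi: float) -> float:
    """Spectral slope S (nm^-1, positive) over [lo, hi].

    Log-linear OLS: regress ln a(lambda) on lambda over grid points with
    positive absorbance inside the window, return the negated slope.  A flat
    spectrum has slope 0; fewer than 5 usable points raise :class:`FitError`.
    """
    wl = spec.wavelength_nm
    mask = (wl >= lo) & (wl <= hi) & (spec.absorbance > 0)
    if mask.sum() < 5:
        raise FitError(
            f"need >= 5 positive-absorbance points in [{lo}, {hi}] nm, "
            f"have {int(mask.sum())}"
        )
    res = stats.linregress(wl[mask], np.log(spec.absorbance[mask]))
    return -float(res.slope)


def slope_ratio(spec: AbsorbanceSpectrum) -> float:
    """S_R = S_275-295 / S_350-400."""
    s_short = spectral_slope(spec, *SLOPE_SHORT)
    s_long = spectral_slope(spec, *SLOPE_LONG)
    if s_long == 0:
        raise FitError("S_350-400 is zero; slope ratio undefined")
    return s_short / s_long


def _eem_interpolator(eem: EEM) -> RegularGridInterpolator:
    return RegularGridInterpolator(
        (eem.excitation_nm, eem.emission_nm), eem.intensity, method="linear",
        bounds_error=True,
    )


def bix(eem: EEM) -> float:
    """Biological index: I(ex 310, em 380) / I(ex 310, em 430)."""
    interp = _eem_interpolator(eem)
    num = float(interp((310.0, 380.0)))
    den = float(interp((310.0, 430.0)))
    if den <= 0:
        raise ValueError("BIX denominator intensity (ex 310, em 430) is <= 0")
    return num / den


def hix(eem: EEM, excitation: float = 254.0, tol_nm: float = 2.0) -> float:
    """Humification index at excitation 254 nm (Zsolnay overlapping bands).

    Trapezoid-integrated emission 435-480 nm divided by 300-445 nm, on the
    nearest measured excitation row within ``tol_nm``.
    """
    ex = eem.excitation_nm
    i = int(np.argmin(np.abs(ex - excitation)))
    if abs(ex[i] - excitation) > tol_nm:
        raise ValueError(
            f"no excitation row within {tol_nm} nm of {excitation} nm "
            f"(nearest: {ex[i]} nm)"
        )
    row_em = eem.emission_nm
    row = eem.intensity[i]

    def band(lo: float, hi: float) -> float:
        if row_em[0] > lo or row_em[-1] < hi:
            raise ValueError(
                f"emission grid [{row_em[0]}, {row_em[-1]}] does not cover "
                f"[{lo}, {hi}] nm"
            )
        inner = row_em[(row_em > lo) & (row_em < hi)]
        grid = np.concatenate(([lo], inner, [hi]))
        vals = np.interp(grid, row_em, row)
        return float(np.trapezoid(vals, grid))

    num = band(435.0, 480.0)
    den = band(300.0, 445.0)
    if den <= 0:
        raise ValueError("HIX denominator band integral is <= 0")
    return num / den


@dataclass
class OpticalSummary:
    """All optical indices for one sample."""

    sample_id: str
    a300_per_m: float
    suva254: float
    s275_295: float
    s350_400: float
    sr: float
    bix: float | None = None
    hix: float | None = None


def optical_summary(
    spec: AbsorbanceSpectrum,
    doc_mgC_L: float,
    eem: EEM | None = None,
) -> OpticalSummary:
    """Compute the full CDOM (and optionally FDOM) index panel for a sample."""
    s_short = spectral_slope(spec, *SLOPE_SHORT)
    s_long = spectral_slope(spec, *SLOPE_LONG)
    return OpticalSummary(
        sample_id=spec.sample_id,
        a300_per_m=napierian_a(spec, 300.0),
        suva254=suva254(spec, doc_mgC_L),
        s275_295=s_short,
        s350_400=s_long,
        sr=s_short / s_long,
        bix=bix(eem) if eem is not None else None,
        hix=hix(eem) if eem is not None else None,
    )
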