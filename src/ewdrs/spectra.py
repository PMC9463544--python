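"""Dual-band diffuse reflectance spectra.

Extended-wavelength DRS acquires two spectra per measurement: a silicon-CCD
band (VIS/NIR, 500-1000 nm) and an InGaAs band (SWIR, 1000-1500 nm).  This
module holds the spectrum container and the preprocessing chain that turns
raw dual-band counts into a single merged reflectance spectrum:

1. referencing against a shuttered background and a white reflectance
   standard, ``S_ref = (M_raw - Bg) / (M_std - Bg)``;
2. Savitzky-Golay smoothing (order 2, frame 41 by default);
3. scaling the SWIR band by the matching factor
   ``M = I_visnir(1000 nm) / I_swir(1000 nm)`` and concatenating the bands
   at the 1000-nm junction without discontinuity.

Referenced intensities are in arbitrary units and may exceed 1 (contact
probe geometry); no upper bound is enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_coeffs

__all__ = [
    "Spectrum",
    "ReferenceTriplet",
    "MatchResult",
    "SpectrumError",
    "GridMismatchError",
    "InvalidReferenceError",
    "DegenerateMatchError",
    "reference_spectrum",
    "savitzky_golay",
    "matching_factor",
    "merge_bands",
    "resample",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "BAND_RANGES",
]

#: Wavelength extent of each spectrometer band, nm.
BAND_RANGES = {
    "visnir": (500.0, 1000.0),
    "swir": (1000.0, 1500.0),
    "merged": (500.0, 1500.0),
}


class SpectrumError(ValueError):
    """Base class for spectral-preprocessing errors."""


class GridMismatchError(SpectrumError):
    """Two spectra that must share a wavelength grid do not."""


class InvalidReferenceError(SpectrumError):
    """Reference triplet with non-positive standard-minus-background."""


class DegenerateMatchError(SpectrumError):
    """Non-positive SWIR intensity at the band-matching wavelength."""


@dataclass(frozen=True)
class Spectrum:
    """Intensity values on a strictly ascending wavelength grid (nm).

    ``band`` tags the originating spectrometer: ``visnir`` grids must lie
    within [500, 1000] nm, ``swir`` within [1000, 1500] nm, and ``merged``
    within [500, 1500] nm.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    band: str = "merged"

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1:
            raise SpectrumError("wavelengths and values must be 1-D")
        if w.size != v.size:
            raise SpectrumError("values length does not match wavelength grid")
        if w.size == 0:
            raise SpectrumError("empty spectrum")
        if not np.all(np.diff(w) > 0):
            raise SpectrumError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(v))):
            raise SpectrumError("non-finite wavelength or intensity value")
        if self.band not in BAND_RANGES:
            raise SpectrumError(f"unknown band tag {self.band!r}")
        lo, hi = BAND_RANGES[self.band]
        if w[0] < lo - 1e-9 or w[-1] > hi + 1e-9:
            raise SpectrumError(
                f"band={self.band} grid [{w[0]:g}, {w[-1]:g}] nm outside [{lo:g}, {hi:g}] nm"
            )
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)
        w.setflags(write=False)
        v.setflags(write=False)

    def __len__(self) -> int:
        return self.wavelengths_nm.size

    def interp(self, nm) -> np.ndarray | float:
        """Linearly interpolated intensity at ``nm`` (must lie in the span)."""
        nm_arr = np.asarray(nm, dtype=float)
        lo, hi = self.wavelengths_nm[0], self.wavelengths_nm[-1]
        if np.any(nm_arr < lo - 1e-9) or np.any(nm_arr > hi + 1e-9):
            raise SpectrumError(
                f"wavelength outside spectrum span [{lo:g}, {hi:g}] nm"
            )
        out = np.interp(nm_arr, self.wavelengths_nm, self.values)
        return float(out) if np.isscalar(nm) or nm_arr.ndim == 0 else out

    def with_values(self, values) -> "Spectrum":
        return Spectrum(self.wavelengths_nm.copy(), values, self.band)


@dataclass(frozen=True)
class ReferenceTriplet:
    """One sample measurement with its background and reflectance standard.

    All three spectra come from the same spectrometer band on an identical
    grid.  ``m_std - bg`` must be strictly positive everywhere, otherwise
    the referencing division is undefined.
    """

    m_raw: Spectrum
    bg: Spectrum
    m_std: Spectrum

    def __post_init__(self) -> None:
        for other in (self.bg, self.m_std):
            if other.band != self.m_raw.band:
                raise GridMismatchError("triplet spectra carry different band tags")
            if not np.array_equal(other.wavelengths_nm, self.m_raw.wavelengths_nm):
                raise GridMismatchError("triplet spectra on different wavelength grids")
        if np.any(self.m_std.values - self.bg.values <= 0):
            raise InvalidReferenceError(
                "reflectance standard does not exceed background at every wavelength"
            )


@dataclass(frozen=True)
class MatchResult:
    """Scalar matching factor joining the two spectrometer bands.

    ``factor`` is exactly ``i_visnir / i_swir`` evaluated at ``match_nm``
    (1000 nm by default).
    """

    factor: float
    i_visnir: float
    i_swir: float
    match_nm: float = 1000.0

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise DegenerateMatchError("matching factor must be positive")
        if self.factor != self.i_visnir / self.i_swir:
            raise DegenerateMatchError("factor != i_visnir / i_swir")


def reference_spectrum(triplet: ReferenceTriplet) -> Spectrum:
    """Reference a raw measurement against background and standard.

    Returns ``(M_raw - Bg) / (M_std - Bg)`` on the triplet's grid.  The
    triplet constructor already guarantees a positive denominator.
    """
    denom = triplet.m_std.values - triplet.bg.values
    vals = (triplet.m_raw.values - triplet.bg.values) / denom
    return Spectrum(triplet.m_raw.wavelengths_nm.copy(), vals, triplet.m_raw.band)


def savitzky_golay(s: Spectrum, poly_order: int = 2, window: int = 41) -> Spectrum:
    """Savitzky-Golay smoothing with truncated-window edge fits.

    Interior points use the standard SG convolution (local least-squares
    polynomial of ``poly_order`` over ``window`` samples, uniform index
    spacing).  Near the ends the polynomial is refit on the available
    (truncated) window rather than padding, so no data are fabricated
    beyond the spectrum span.  Polynomials up to ``poly_order`` are
    reproduced exactly everywhere.
    """
    if window % 2 == 0:
        raise SpectrumError("SG window must be odd")
    if window <= poly_order:
        raise SpectrumError("SG window must exceed polynomial order")
    n = len(s)
    if window > n:
        raise SpectrumError(f"SG window {window} exceeds grid length {n}")
    v = s.values
    half = window // 2
    coeffs = savgol_coeffs(window, poly_order)
    out = np.empty(n)
    # scipy returns coefficients for correlation; SG kernels are symmetric
    # at the central point so convolve works directly.
    out[half : n - half] = np.convolve(v, coeffs, mode="valid")
    idx = np.arange(n, dtype=float)
    for i in range(half):
        for j in (i, n - 1 - i):
            lo = max(0, j - half)
            hi = min(n, j + half + 1)
            x = idx[lo:hi] - idx[j]
            p = np.polynomial.polynomial.polyfit(x, v[lo:hi], poly_order)
            out[j] = p[0]
    return s.with_values(out)


def matching_factor(
    visnir: Spectrum, swir: Spectrum, match_nm: float = 1000.0
) -> MatchResult:
    """Matching factor ``M = I_visnir(match) / I_swir(match)``.

    Intensities at a non-grid match point are obtained by linear
    interpolation, consistent with :func:`resample`.
    """
    i_vis = visnir.interp(match_nm)
    i_swir = swir.interp(match_nm)
    if i_swir <= 0:
        raise DegenerateMatchError(
            f"SWIR intensity at {match_nm:g} nm is {i_swir:g}; matching undefined"
        )
    return MatchResult(factor=i_vis / i_swir, i_visnir=i_vis, i_swir=i_swir, match_nm=match_nm)


def merge_bands(
    visnir: Spectrum, swir: Spectrum, match: MatchResult | None = None
) -> Spectrum:
    """Concatenate the two bands into one continuous spectrum.

    The SWIR band is multiplied by the matching factor (the VIS/NIR band
    keeps its referencing); VIS/NIR points below the match wavelength are
    followed by scaled SWIR points at and above it, so the merged grid is
    single-valued and the junction has zero discontinuity by construction.
    """
    if visnir.band != "visnir":
        raise SpectrumError(f"expected band=visnir, got {visnir.band!r}")
    if swir.band != "swir":
        raise SpectrumError(f"expected band=swir, got {swir.band!r}")
    if match is None:
        match = matching_factor(visnir, swir)
    keep_vis = visnir.wavelengths_nm < match.match_nm
    keep_swir = swir.wavelengths_nm >= match.match_nm
    grid = np.concatenate([visnir.wavelengths_nm[keep_vis], swir.wavelengths_nm[keep_swir]])
    vals = np.concatenate(
        [visnir.values[keep_vis], swir.values[keep_swir] * match.factor]
    )
    return Spectrum(grid, vals, "merged")


def resample(s: Spectrum, new_grid) -> Spectrum:
    """Linear interpolation onto ``new_grid`` (no extrapolation)."""
    new_grid = np.asarray(new_grid, dtype=float)
    if not np.all(np.diff(new_grid) > 0):
        raise SpectrumError("target grid must be strictly increasing")
    if new_grid[0] < s.wavelengths_nm[0] - 1e-9 or new_grid[-1] > s.wavelengths_nm[-1] + 1e-9:
        raise SpectrumError("target grid extends beyond the spectrum span")
    return Spectrum(new_grid, np.interp(new_grid, s.wavelengths_nm, s.values), s.band)


def write_spectrum_csv(s: Spectrum, path) -> None:
    """Two-column CSV ``wavelength_nm,value`` with a ``# band=`` comment."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# band={s.band}\n")
        fh.write("wavelength_nm,value\n")
        for w, v in zip(s.wavelengths_nm, s.values):
            fh.write(f"{w:.6g},{v:.10g}\n")


def read_spectrum_csv(path, band: str | None = None) -> Spectrum:
    """Read the two-column dialect written by :func:`write_spectrum_csv`.

    ``band`` overrides (or supplies, if absent) the ``# band=`` comment.
    """
    file_band = None
    rows_w, rows_v = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("band="):
                    file_band = body.split("=", 1)[1].strip()
                continue
            if line.lower().startswith("wavelength"):
                continue
            w_str, v_str = line.split(",")[:2]
            rows_w.append(float(w_str))
            rows_v.append(float(v_str))
    use_band = band or file_band
    if use_band is None:
        raise SpectrumError(f"{path}: no band= comment and no band override given")
    return Spectrum(np.array(rows_w), np.array(rows_v), use_band)
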