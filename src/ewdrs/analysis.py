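"""Simulation-measurement agreement and spectral characterization.

Simulated and measured spectra live in different units, so both are
normalized to unit area under the curve before comparison.  Repeated
measurements define a pointwise 95% confidence band (mean +/- 1.96 SD);
the difference spectrum (simulation - measurement mean) is flagged
wherever the simulation exits the band, and the out-of-band wavelengths
are reported as contiguous intervals.

Diagnostic peak ratios condense a spectrum to scalars: 575/610 nm tracks
blood/heme content in the VIS/NIR and 1210/1270 nm tracks lipid in the
SWIR.  For phantoms whose heme-mimicking dye absorbs at 630 nm rather
than at the blood doublet, a 630/700 nm variant is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .spectra import Spectrum, SpectrumError, resample

__all__ = [
    "ConfidenceBand",
    "AgreementReport",
    "auc_normalize",
    "confidence_band",
    "agreement",
    "peak_ratio",
    "ratio_trend",
    "RATIO_PRESETS",
]

#: named (numerator, denominator) wavelength pairs, nm
RATIO_PRESETS = {
    "visnir": (575.0, 610.0),       # blood / heme doublet in tissue
    "swir": (1210.0, 1270.0),       # lipid dip vs nearby baseline
    "visnir_phantom": (630.0, 700.0),  # heme-dye stand-in band in phantoms
}


@dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise mean +/- ``z * SD`` envelope of repeated measurements."""

    wavelengths_nm: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    z: float = 1.96

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.z * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.z * self.sd


@dataclass(frozen=True)
class AgreementReport:
    """Difference spectrum (simulation - measurement) and band violations."""

    wavelengths_nm: np.ndarray
    difference: np.ndarray
    out_of_band: np.ndarray  # boolean mask
    intervals: tuple[tuple[float, float], ...]  # contiguous [start, end] nm

    @property
    def in_band_everywhere(self) -> bool:
        return not bool(np.any(self.out_of_band))


def auc_normalize(s: Spectrum) -> Spectrum:
    """Scale so the trapezoidal integral over the nm grid equals 1."""
    area = float(np.trapezoid(s.values, s.wavelengths_nm))
    if area <= 0:
        raise SpectrumError("cannot AUC-normalize a spectrum with non-positive area")
    return s.with_values(s.values / area)


def confidence_band(repeats: list[Spectrum], z: float = 1.96) -> ConfidenceBand:
    """Pointwise mean and sample SD (n-1 denominator) of >= 2 repeats."""
    if len(repeats) < 2:
        raise SpectrumError("need at least two repeats for a confidence band")
    grid = repeats[0].wavelengths_nm
    for r in repeats[1:]:
        if not np.array_equal(r.wavelengths_nm, grid):
            raise SpectrumError("repeats on different grids; resample first")
    stack = np.stack([r.values for r in repeats])
    return ConfidenceBand(
        wavelengths_nm=grid.copy(),
        mean=stack.mean(axis=0),
        sd=stack.std(axis=0, ddof=1),
        z=z,
    )


def agreement(simulated: Spectrum, band: ConfidenceBand) -> AgreementReport:
    """Compare a simulated spectrum against the measurement band.

    Both inputs are expected AUC-normalized on a common grid.  Out-of-band
    points are reported as contiguous ``[start, end]`` nm intervals; the
    mask is not smoothed, so a single in-band grid point splits an
    interval.
    """
    grid = band.wavelengths_nm
    if not np.array_equal(simulated.wavelengths_nm, grid):
        raise SpectrumError("simulation grid differs from band grid; resample first")
    diff = simulated.values - band.mean
    mask = (simulated.values < band.lower) | (simulated.values > band.upper)
    intervals = []
    i = 0
    n = grid.size
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            intervals.append((float(grid[i]), float(grid[j])))
            i = j + 1
        else:
            i += 1
    return AgreementReport(
        wavelengths_nm=grid.copy(),
        difference=diff,
        out_of_band=mask,
        intervals=tuple(intervals),
    )


def peak_ratio(s: Spectrum, numerator_nm: float, denominator_nm: float) -> float:
    """Ratio of linearly interpolated intensities at two wavelengths."""
    num = s.interp(numerator_nm)
    den = s.interp(denominator_nm)
    if den <= 0:
        raise SpectrumError(
            f"denominator intensity at {denominator_nm:g} nm is non-positive"
        )
    return num / den


def ratio_trend(ratios_by_thickness: dict[float, float]) -> dict:
    """Rank trend of a peak ratio across layer thicknesses.

    Returns ``{"direction": -1|0|+1, "is_monotonic": bool, "rho": float}``
    where direction is the sign of the Spearman rank correlation between
    thickness and ratio and ``is_monotonic`` flags strict monotonicity.
    """
    if len(ratios_by_thickness) < 3:
        raise ValueError("need at least three thickness points for a trend")
    thick = np.array(sorted(ratios_by_thickness))
    vals = np.array([ratios_by_thickness[t] for t in thick])
    rho = spearmanr(thick, vals).statistic
    diffs = np.diff(vals)
    mono = bool(np.all(diffs > 0) or np.all(diffs < 0))
    direction = int(np.sign(rho)) if not np.isnan(rho) else 0
    return {"direction": direction, "is_monotonic": mono, "rho": float(rho)}
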