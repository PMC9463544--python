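"""Per-material optical-property spectra.

Tissue and phantom materials are described by an absorption coefficient
``mu_a(lambda)`` and a reduced scattering coefficient ``mu_s'(lambda)``
(both mm^-1) on a wavelength grid, plus a scalar anisotropy ``g`` (default
0.9) and refractive index ``n`` (default 1.34).  Before use in transport
simulations, measured reduced-scattering spectra are condensed to a
first-order exponential decay ``mu_s'(lambda) = a*exp(-lambda/b) + c`` and
absorption spectra are smoothed with a second-order Savitzky-Golay filter.

Because no tabulated extinction spectra ship with the package, synthetic
absorption is built from a small chromophore basis of unit-maximum
Gaussian-mixture line shapes carrying the diagnostic features of soft
tissue in the 500-1500 nm window: a lipid dip complex at 1210 nm with its
1180-nm shoulder, broad water bands near 970 and 1450 nm, a heme-dye
stand-in band at 630 nm, and a blood doublet at 575/610 nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectra import Spectrum, savitzky_golay

__all__ = [
    "OpticalProperties",
    "ScatterDecayFit",
    "ChromophoreBasis",
    "DEFAULT_BASIS",
    "FitFailureError",
    "fit_scattering_decay",
    "smooth_absorption",
    "synth_mu_a",
    "mu_s_from_reduced",
    "read_properties_csv",
    "write_properties_csv",
    "MASTER_GRID",
]

#: 1-nm master wavelength grid over the full EWDRS window, nm.
MASTER_GRID = np.arange(500.0, 1500.0 + 0.5, 1.0)

DEFAULT_G = 0.9
DEFAULT_N = 1.34


class FitFailureError(RuntimeError):
    """Scattering-decay fit did not converge; carries the best iterate."""

    def __init__(self, message: str, best_fit: "ScatterDecayFit"):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption/reduced-scattering spectra with scalar ``g`` and ``n``."""

    wavelengths_nm: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    g: float = DEFAULT_G
    n: float = DEFAULT_N
    name: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        mua = np.asarray(self.mu_a, dtype=float)
        musp = np.asarray(self.mu_s_prime, dtype=float)
        if not (w.size == mua.size == musp.size):
            raise ValueError("property arrays must share the wavelength grid length")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(mua < 0):
            raise ValueError("mu_a must be non-negative")
        if np.any(musp <= 0):
            raise ValueError("mu_s_prime must be strictly positive")
        if not (-1.0 < self.g < 1.0):
            raise ValueError("anisotropy g must lie in (-1, 1)")
        if not self.n >= 1.0:
            raise ValueError("refractive index must be at least 1")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "mu_a", mua)
        object.__setattr__(self, "mu_s_prime", musp)

    @classmethod
    def constant(
        cls,
        mu_a: float,
        mu_s_prime: float,
        g: float = DEFAULT_G,
        n: float = DEFAULT_N,
        name: str = "",
        grid=None,
    ) -> "OpticalProperties":
        """Wavelength-independent properties (useful for validation runs)."""
        w = MASTER_GRID if grid is None else np.asarray(grid, dtype=float)
        return cls(w, np.full(w.size, float(mu_a)), np.full(w.size, float(mu_s_prime)), g, n, name)

    def at(self, nm: float) -> tuple[float, float]:
        """``(mu_a, mu_s_prime)`` linearly interpolated at ``nm``."""
        w = self.wavelengths_nm
        if nm < w[0] - 1e-9 or nm > w[-1] + 1e-9:
            raise ValueError(f"{nm:g} nm outside property grid [{w[0]:g}, {w[-1]:g}]")
        return (
            float(np.interp(nm, w, self.mu_a)),
            float(np.interp(nm, w, self.mu_s_prime)),
        )


@dataclass(frozen=True)
class ScatterDecayFit:
    """Parameters of ``mu_s'(lambda) = a*exp(-lambda/b) + c`` (mm^-1, nm)."""

    a: float
    b: float
    c: float
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.a < 0 or self.b <= 0 or self.c < 0:
            raise ValueError("require a >= 0, b > 0, c >= 0")

    def evaluate(self, wavelengths_nm) -> np.ndarray:
        lam = np.asarray(wavelengths_nm, dtype=float)
        return self.a * np.exp(-lam / self.b) + self.c


def fit_scattering_decay(wavelengths_nm, mu_s_prime_samples) -> ScatterDecayFit:
    """Least-squares fit of a first-order exponential decay to ``mu_s'``.

    Nonlinear least squares on ``a*exp(-lambda/b) + c`` initialized from a
    log-linear regression of ``mu_s' - min`` against wavelength.  Constant
    input degenerates gracefully to the ``a -> 0`` branch with ``c`` equal
    to the sample mean.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    y = np.asarray(mu_s_prime_samples, dtype=float)
    if lam.size < 4:
        raise ValueError("need at least 4 samples to fit the decay")
    if np.any(y <= 0):
        raise ValueError("mu_s_prime samples must be positive")

    span = float(np.ptp(y))
    if span <= 1e-12 * float(np.max(y)):
        c = float(np.mean(y))
        rms = float(np.sqrt(np.mean((y - c) ** 2)))
        return ScatterDecayFit(a=0.0, b=float(np.ptp(lam)) or 1.0, c=c, residual_rms=rms)

    # log-linear initialization: log(y - c0) ~ log(a) - lambda/b
    c0 = max(0.0, float(np.min(y)) - 0.05 * span)
    z = np.log(np.maximum(y - c0, 1e-12))
    slope, intercept = np.polyfit(lam, z, 1)
    if slope >= 0:  # non-decaying samples; fall back to a broad decay guess
        slope = -1.0 / float(np.ptp(lam))
    b0 = -1.0 / slope
    a0 = float(np.exp(intercept))

    def resid(p):
        a, b, c = p
        return a * np.exp(-lam / b) + c - y

    res = least_squares(
        resid,
        x0=[max(a0, 1e-9), max(b0, 1.0), c0],
        bounds=([0.0, 1e-3, 0.0], [np.inf, np.inf, np.inf]),
        max_nfev=2000,
    )
    a, b, c = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    fit = ScatterDecayFit(a=float(a), b=float(b), c=float(c), residual_rms=rms)
    if res.status <= 0:
        raise FitFailureError("scattering-decay fit did not converge", fit)
    return fit


def smooth_absorption(
    props: OpticalProperties, poly_order: int = 2, window: int = 41
) -> OpticalProperties:
    """SG-smooth ``mu_a`` (clamped at zero); scattering, ``g``, ``n`` unchanged."""
    s = Spectrum(props.wavelengths_nm, props.mu_a, "merged")
    smoothed = savitzky_golay(s, poly_order=poly_order, window=window)
    mua = np.maximum(smoothed.values, 0.0)
    return OpticalProperties(
        props.wavelengths_nm.copy(), mua, props.mu_s_prime.copy(), props.g, props.n, props.name
    )


class ChromophoreBasis:
    """Named unit-maximum absorption line shapes on [500, 1500] nm.

    Each basis function is a Gaussian mixture normalized to unit maximum
    over the master grid.  These are synthetic stand-ins engineered to
    carry the feature wavelengths that matter diagnostically, not measured
    extinction spectra.
    """

    def __init__(self, components: dict[str, list[tuple[float, float, float]]]):
        self._components = dict(components)
        self._norms = {}
        for name, mix in self._components.items():
            peak = float(np.max(self._raw(name, MASTER_GRID)))
            if peak <= 0:
                raise ValueError(f"basis function {name!r} has non-positive maximum")
            self._norms[name] = peak

    @property
    def names(self) -> list[str]:
        return sorted(self._components)

    def _raw(self, name: str, grid: np.ndarray) -> np.ndarray:
        out = np.zeros_like(grid, dtype=float)
        for center, sigma, amp in self._components[name]:
            out += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
        return out

    def evaluate(self, name: str, grid) -> np.ndarray:
        """Unit-maximum shape function for ``name`` on ``grid``."""
        if name not in self._components:
            raise KeyError(f"unknown chromophore {name!r}; known: {self.names}")
        grid = np.asarray(grid, dtype=float)
        return self._raw(name, grid) / self._norms[name]


#: Feature placement (center nm, sigma nm, relative amplitude) per chromophore.
DEFAULT_BASIS = ChromophoreBasis(
    {
        # lipid: 1210-nm main band with the 1180-nm shoulder and a weak
        # overtone near 1390 nm
        "lipid": [(1210.0, 14.0, 1.0), (1180.0, 9.0, 0.40), (1390.0, 25.0, 0.12)],
        # water: weak 970-nm band, dominant 1450-nm band with a broad red tail
        "water": [(970.0, 45.0, 0.22), (1450.0, 60.0, 1.0), (1500.0, 90.0, 0.35)],
        # food-dye stand-in for heme pigments: single sharp 630-nm band
        "heme_dye": [(630.0, 18.0, 1.0)],
        # blood doublet producing the characteristic 575/610-nm minima pair
        "blood": [(575.0, 13.0, 1.0), (610.0, 10.0, 0.45), (545.0, 18.0, 0.75)],
        # spectrally flat residual absorption (gelatin matrix, minor
        # pigments); keeps the inter-band floor realistic instead of zero
        "baseline": [(1000.0, 1.0e6, 1.0)],
    }
)


def synth_mu_a(
    concentrations: dict[str, float],
    basis: ChromophoreBasis = DEFAULT_BASIS,
    grid=MASTER_GRID,
) -> np.ndarray:
    """Non-negative linear combination of basis shapes, mm^-1 on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for name, weight in concentrations.items():
        if weight < 0:
            raise ValueError(f"negative weight for chromophore {name!r}")
        out += weight * basis.evaluate(name, grid)
    return out


def mu_s_from_reduced(mu_s_prime, g: float):
    """Similarity relation ``mu_s = mu_s' / (1 - g)``."""
    if g >= 1.0:
        raise ValueError("anisotropy must satisfy g < 1")
    return np.asarray(mu_s_prime, dtype=float) / (1.0 - g) if np.ndim(mu_s_prime) else float(mu_s_prime) / (1.0 - g)


def write_properties_csv(props: OpticalProperties, path) -> None:
    """CSV dialect ``wavelength_nm,mu_a_mm-1,mu_s_prime_mm-1`` + g/n comments."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# g={props.g:g}\n# n={props.n:g}\n")
        if props.name:
            fh.write(f"# name={props.name}\n")
        fh.write("wavelength_nm,mu_a_mm-1,mu_s_prime_mm-1\n")
        for w, a, s in zip(props.wavelengths_nm, props.mu_a, props.mu_s_prime):
            fh.write(f"{w:.6g},{a:.10g},{s:.10g}\n")


def read_properties_csv(path) -> OpticalProperties:
    g, n, name = DEFAULT_G, DEFAULT_N, ""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("g="):
                    g = float(body[2:])
                elif body.startswith("n="):
                    n = float(body[2:])
                elif body.startswith("name="):
                    name = body[5:]
                continue
            if line.lower().startswith("wavelength"):
                continue
            rows.append([float(x) for x in line.split(",")[:3]])
    arr = np.array(rows)
    return OpticalProperties(arr[:, 0], arr[:, 1], arr[:, 2], g, n, name)
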