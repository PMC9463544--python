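"""Synthetic study-condition generator.

No raw spectra or tabulated optical properties ship with the platform, so
this module fabricates the full study: phantom and tissue optical-property
presets (chromophore weights + scattering-decay parameters), raw
measurement triplets that exercise the referencing chain exactly, and
labeled multi-class spectral datasets with repeat-measurement noise for
the classifier and agreement analyses.

The preset roster mirrors the two phantom layers (nerve-mimicking NM:
lipid-rich, high scattering, no blood pigment; muscle-mimicking MM:
630-nm heme-dye band, minimal lipid) and six dissected-tissue classes
(nerve, NVB, skin, muscle, vessel, connective).  Chromophore weights are
fixed once so the qualitative feature set is right - the NM 1210-nm dip
with its 1180-nm shoulder, the MM 630-nm dip, tissue blood doublets at
575/610 nm, and water/collagen structure near 1450 nm - without claiming
any quantitative fidelity to a particular specimen.

Repeat noise defaults to 2% multiplicative gain jitter per repeat plus
additive noise at 0.5% of the band median; repeated-measurement counts
default to five per location.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import auc_normalize
from .mc_engine import ProbeGeometry, TransportSettings, simulate_spectrum
from .optical_props import (
    DEFAULT_BASIS,
    MASTER_GRID,
    ChromophoreBasis,
    OpticalProperties,
    ScatterDecayFit,
    synth_mu_a,
)
from .spectra import (
    ReferenceTriplet,
    Spectrum,
    matching_factor,
    merge_bands,
    reference_spectrum,
    savitzky_golay,
)
from .smlr import LabeledSpectra
from .tissue_models import build_homogeneous, build_two_layer

__all__ = [
    "PhantomRecipe",
    "NoiseModel",
    "PRESETS",
    "make_properties",
    "make_measurement_triplet",
    "make_repeats",
    "make_labeled_dataset",
    "phantom_study",
    "tissue_study",
    "TISSUE_CLASS_COUNTS",
]


@dataclass(frozen=True)
class PhantomRecipe:
    """Chromophore weights (mm^-1 at unit shape maximum) + scattering decay."""

    name: str
    chromophores: dict[str, float]
    scatter: tuple[float, float, float]  # (a mm^-1, b nm, c mm^-1)
    role: str = "homogeneous"

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.chromophores.values()):
            raise ValueError("chromophore weights must be non-negative")


#: fixed preset roster; weights chosen once for qualitative feature fidelity
PRESETS: dict[str, PhantomRecipe] = {
    # lipid-rich, high-scattering nerve-mimicking layer; deliberately free
    # of blood-simulating pigment
    "nm_phantom": PhantomRecipe(
        "nm_phantom",
        {"lipid": 0.55, "water": 0.60, "heme_dye": 0.0, "blood": 0.0, "baseline": 0.02},
        (8.0, 520.0, 0.55),
        role="top layer",
    ),
    # heme-dye (630 nm) muscle-mimicking layer with only traces of lipid
    "mm_phantom": PhantomRecipe(
        "mm_phantom",
        {"lipid": 0.06, "water": 0.80, "heme_dye": 0.90, "blood": 0.0, "baseline": 0.025},
        (5.0, 560.0, 0.40),
        role="bottom layer",
    ),
    # dissected-tissue classes; nerve/skin/connective share blood and
    # scattering and differ mostly in SWIR lipid content
    "nerve": PhantomRecipe(
        "nerve", {"lipid": 0.32, "water": 0.55, "blood": 0.10, "baseline": 0.02}, (6.0, 600.0, 0.40)
    ),
    "nvb": PhantomRecipe(
        "nvb", {"lipid": 0.45, "water": 0.60, "blood": 0.30, "baseline": 0.025}, (6.5, 580.0, 0.45)
    ),
    "skin": PhantomRecipe(
        "skin", {"lipid": 0.62, "water": 0.55, "blood": 0.10, "baseline": 0.03}, (6.0, 600.0, 0.40)
    ),
    "muscle": PhantomRecipe(
        "muscle", {"lipid": 0.04, "water": 0.80, "blood": 0.50, "baseline": 0.03}, (5.5, 650.0, 0.35)
    ),
    "vessel": PhantomRecipe(
        "vessel", {"lipid": 0.06, "water": 0.70, "blood": 0.80, "baseline": 0.035}, (7.0, 560.0, 0.50)
    ),
    "connective": PhantomRecipe(
        "connective", {"lipid": 0.46, "water": 0.55, "blood": 0.10, "baseline": 0.025}, (6.0, 600.0, 0.40)
    ),
}

#: tissue-study class sizes: nerve + NVB margin 25, other tissues 60
TISSUE_CLASS_COUNTS = {
    "nerve": 10,
    "nvb": 15,
    "skin": 15,
    "muscle": 15,
    "vessel": 15,
    "connective": 15,
}


@dataclass(frozen=True)
class NoiseModel:
    """Repeat-measurement noise: per-repeat gain jitter + additive floor."""

    gain_sd: float = 0.02
    additive_sd_frac: float = 0.005  # fraction of the band median
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain_sd < 0 or self.additive_sd_frac < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self, repeat_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(repeat_index,))
        )


def make_properties(
    recipe: PhantomRecipe | str,
    basis: ChromophoreBasis = DEFAULT_BASIS,
    grid=MASTER_GRID,
) -> OpticalProperties:
    """Optical properties from a recipe: synthetic mu_a + decay mu_s'."""
    if isinstance(recipe, str):
        if recipe not in PRESETS:
            raise KeyError(f"unknown preset {recipe!r}; known: {sorted(PRESETS)}")
        recipe = PRESETS[recipe]
    grid = np.asarray(grid, dtype=float)
    mua = synth_mu_a(recipe.chromophores, basis, grid)
    a, b, c = recipe.scatter
    musp = ScatterDecayFit(a, b, c).evaluate(grid)
    return OpticalProperties(grid, mua, musp, name=recipe.name)


def _lamp_profile(grid: np.ndarray) -> np.ndarray:
    """Smooth positive tungsten-halogen-like source shape (arbitrary units)."""
    return 0.2 + np.exp(-0.5 * ((grid - 1100.0) / 420.0) ** 2)


def make_measurement_triplet(
    true_spectrum: Spectrum,
    noise: NoiseModel = NoiseModel(),
    repeat_index: int = 0,
) -> ReferenceTriplet:
    """Construct (Mraw, Bg, Mstd) that reference back to ``true_spectrum``.

    With zero noise the referencing identity is exact by construction:
    ``Bg`` is a small constant offset, ``Mstd = Bg + L(lambda)`` with a
    smooth lamp profile ``L``, and ``Mraw = Bg + L * S_true``.  Noise is
    drawn from the substream ``(noise.seed, repeat_index)``: a scalar gain
    jitter on the raw measurement plus additive noise on every channel.
    """
    grid = true_spectrum.wavelengths_nm
    lamp = _lamp_profile(grid)
    bg_level = 0.05
    bg = np.full(grid.size, bg_level)
    m_std = bg + lamp
    m_raw = bg + lamp * true_spectrum.values
    if noise.gain_sd > 0 or noise.additive_sd_frac > 0:
        rng = noise.rng(repeat_index)
        gain = 1.0 + noise.gain_sd * rng.standard_normal()
        add_sd = noise.additive_sd_frac * float(np.median(m_raw))
        m_raw = bg + gain * lamp * true_spectrum.values
        m_raw = m_raw + add_sd * rng.standard_normal(grid.size)
    band = true_spectrum.band
    return ReferenceTriplet(
        m_raw=Spectrum(grid.copy(), m_raw, band),
        bg=Spectrum(grid.copy(), bg, band),
        m_std=Spectrum(grid.copy(), m_std, band),
    )


def _preprocess_dual_band(truth: Spectrum, noise: NoiseModel, repeat_index: int,
                          sg_window: int = 41, match_nm: float = 1000.0) -> Spectrum:
    """Push one noisy repeat of a merged truth through the full chain.

    The truth spectrum is split at the band junction into the two
    spectrometer ranges, each band is measured as a triplet and
    referenced, the SWIR band is SG-smoothed (window shrunk to the grid if
    needed), and the bands are re-merged with the matching factor.
    """
    grid = truth.wavelengths_nm
    if match_nm not in grid:
        # coarse simulation grids may miss the junction; insert it so the
        # matching factor has a common wavelength in both bands
        aug = np.sort(np.append(grid, match_nm))
        truth = Spectrum(aug, np.interp(aug, grid, truth.values), truth.band)
        grid = truth.wavelengths_nm
    vis_sel = (grid >= 500.0) & (grid <= 1000.0)
    swir_sel = (grid >= 1000.0) & (grid <= 1500.0)
    vis_truth = Spectrum(grid[vis_sel], truth.values[vis_sel], "visnir")
    swir_truth = Spectrum(grid[swir_sel], truth.values[swir_sel], "swir")
    # distinct substreams per band
    vis_trip = make_measurement_triplet(vis_truth, noise, repeat_index * 2)
    swir_trip = make_measurement_triplet(swir_truth, noise, repeat_index * 2 + 1)
    vis = reference_spectrum(vis_trip)
    swir = reference_spectrum(swir_trip)
    # the SG frame of 41 samples is defined on the ~1.3-nm instrument
    # grid (~53 nm span); on coarser simulation grids use the same
    # spectral span, and skip smoothing entirely once the window would
    # span so few samples that it distorts real line shapes
    step = float(np.median(np.diff(swir.wavelengths_nm)))
    span_nm = sg_window * 1.3
    win = int(round(span_nm / step))
    win = min(win if win % 2 == 1 else win - 1, len(swir) if len(swir) % 2 == 1 else len(swir) - 1)
    if win >= 5:
        swir = savitzky_golay(swir, poly_order=2, window=win)
    match = matching_factor(vis, swir, match_nm)
    return merge_bands(vis, swir, match)


def make_repeats(
    truth: Spectrum, n_repeats: int, noise: NoiseModel, first_repeat_index: int = 0
) -> list[Spectrum]:
    """``n_repeats`` preprocessed noisy repeats of one underlying spectrum."""
    return [
        _preprocess_dual_band(truth, noise, first_repeat_index + k)
        for k in range(n_repeats)
    ]


#: default simulation settings for dataset generation.  ``swir_factor``
#: scales the photon budget for wavelengths above the 1000-nm junction,
#: mirroring the instrument's 16x longer SWIR integration (800 ms vs
#: 50 ms acquisition): without it, equal per-wavelength budgets give the
#: SWIR band far more counting noise than any real acquisition.
DEFAULT_MC = {
    "grid": np.arange(500.0, 1500.0 + 1, 20.0),
    "n_photons": 20_000,
    "swir_factor": 16,
}


def _simulate_truth(model, probe, mc: dict, seed: int) -> Spectrum:
    """One merged truth spectrum with the per-band photon budget."""
    grid = np.asarray(mc["grid"], dtype=float)
    n_vis = int(mc["n_photons"])
    n_swir = int(round(n_vis * mc.get("swir_factor", 1)))
    if n_swir == n_vis:
        return simulate_spectrum(model, probe, grid, n_vis, seed=seed).spectrum
    vis_sel = grid <= 1000.0
    sim_v = simulate_spectrum(model, probe, grid[vis_sel], n_vis, seed=seed)
    sim_s = simulate_spectrum(
        model, probe, grid[~vis_sel], n_swir, seed=seed + 499_979
    )
    return Spectrum(
        grid, np.concatenate([sim_v.spectrum.values, sim_s.spectrum.values]), "merged"
    )


def make_labeled_dataset(
    classes: list[str],
    n_per_class: int | dict[str, int] = 5,
    probe: ProbeGeometry | None = None,
    mc_settings: dict | None = None,
    noise: NoiseModel = NoiseModel(),
    seed: int = 0,
    auc: bool = True,
) -> LabeledSpectra:
    """Simulate repeat measurements per class and preprocess them.

    Each class preset becomes a homogeneous half-space probed by the
    Monte Carlo engine at ``mc_settings`` (wavelength grid and photons
    per wavelength).  Every repeat draws an independent photon
    substream, so Monte Carlo counting variance acts as honest
    repeat-to-repeat (site-to-site) variability instead of freezing one
    noise realization into a class fingerprint; instrument noise from
    ``noise`` is layered on top through the dual-band triplet chain.
    Returns rows on the merged grid.
    """
    probe = probe or ProbeGeometry()
    mc = dict(DEFAULT_MC)
    if mc_settings:
        mc.update(mc_settings)
    counts = (
        {c: int(n_per_class) for c in classes}
        if np.isscalar(n_per_class)
        else dict(n_per_class)
    )
    if any(v < 2 for v in counts.values()):
        raise ValueError("need at least two repeats per class")
    rows, labels, grid = [], [], None
    for ci, cls in enumerate(classes):
        model = build_homogeneous(make_properties(cls))
        for k in range(counts[cls]):
            truth = _simulate_truth(model, probe, mc, seed=seed + 1000 * ci + k)
            rep = make_repeats(
                truth, 1, replace(noise, seed=noise.seed + 7919 * ci),
                first_repeat_index=k,
            )[0]
            r2 = auc_normalize(rep) if auc else rep
            if grid is None:
                grid = r2.wavelengths_nm
            rows.append(r2.values)
            labels.append(cls)
    return LabeledSpectra(np.vstack(rows), np.array(labels), wavelengths_nm=grid)


def phantom_study(
    probe: ProbeGeometry | None = None,
    mc_settings: dict | None = None,
    noise: NoiseModel = NoiseModel(),
    n_repeats: int = 5,
    thicknesses_mm: tuple[float, ...] = (1.0, 2.0, 3.0),
    seed: int = 0,
) -> dict:
    """The phantom measurement campaign on synthetic stand-ins.

    Two one-layer phantoms (NM and MM) plus one two-layer NM-over-MM
    phantom per top thickness, each measured ``n_repeats`` times: with
    the defaults that is 5 phantoms x 5 repeats = 25 spectra.  Returns
    ``{phantom_name: {"truth": Spectrum, "repeats": [Spectrum, ...]}}``.
    """
    probe = probe or ProbeGeometry()
    mc = dict(DEFAULT_MC)
    if mc_settings:
        mc.update(mc_settings)
    nm = make_properties("nm_phantom")
    mm = make_properties("mm_phantom")
    models = {"nm_homogeneous": build_homogeneous(nm), "mm_homogeneous": build_homogeneous(mm)}
    for t in thicknesses_mm:
        models[f"two_layer_{t:g}mm"] = build_two_layer(nm, t, mm, 40.0)
    out = {}
    for mi, (name, model) in enumerate(models.items()):
        sim = simulate_spectrum(model, probe, mc["grid"], mc["n_photons"], seed=seed + 100 * mi)
        reps = make_repeats(sim.spectrum, n_repeats, replace(noise, seed=noise.seed + 104729 * mi))
        out[name] = {"truth": sim.spectrum, "repeats": reps}
    return out


def tissue_study(
    probe: ProbeGeometry | None = None,
    mc_settings: dict | None = None,
    noise: NoiseModel = NoiseModel(),
    class_counts: dict[str, int] = None,
    seed: int = 0,
) -> LabeledSpectra:
    """The dissected-tissue dataset: six classes, 85 spectra total.

    Default class sizes put 25 spectra in the nerve + NVB margin and 60
    in the other-tissues margin.
    """
    counts = dict(TISSUE_CLASS_COUNTS if class_counts is None else class_counts)
    return make_labeled_dataset(
        classes=sorted(counts),
        n_per_class=counts,
        probe=probe,
        mc_settings=mc_settings,
        noise=noise,
        seed=seed,
    )
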