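"""JSON run configuration and the end-to-end pipeline.

A run config gathers everything needed to reproduce a simulation +
analysis campaign bit-for-bit: probe geometry, tissue model reference,
wavelength grid, photons per wavelength, the master seed, and the
preprocessing/analysis defaults (SG order 2 / window 41, 1000-nm match
point, z = 1.96, classifier prior 0.1).  Unknown keys are rejected so a
typo cannot silently fall back to a default.  ``run_pipeline`` executes
the requested stages in order and writes a manifest with the sha256 of
every output, which makes rerun identity checkable by hash comparison.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .analysis import RATIO_PRESETS, auc_normalize, peak_ratio
from .mc_engine import ProbeGeometry, simulate_spectrum
from .spectra import write_spectrum_csv
from .synthdata import PRESETS, make_properties
from .tissue_models import build_homogeneous, build_two_layer

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Itemized configuration validation failure."""


_PROBE_KEYS = {"core_radius_mm", "numerical_aperture", "center_spacing_mm"}
_TOP_KEYS = {
    "model",
    "seed",
    "probe",
    "grid_nm",
    "photons_per_wavelength",
    "sg_order",
    "sg_window",
    "match_nm",
    "z",
    "classifier_lambda",
    "stages",
}
_MODEL_KEYS = {"layers"}
_LAYER_KEYS = {"material", "thickness_mm"}


@dataclass(frozen=True)
class RunConfig:
    model: dict
    seed: int
    probe: ProbeGeometry = ProbeGeometry()
    grid_nm: tuple[float, float, float] = (500.0, 1500.0, 20.0)  # start, stop, step
    photons_per_wavelength: int = 100_000
    sg_order: int = 2
    sg_window: int = 41
    match_nm: float = 1000.0
    z: float = 1.96
    classifier_lambda: float = 0.1
    stages: tuple[str, ...] = ("simulate", "ratios")

    def wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.grid_nm
        return np.arange(start, stop + step / 2, step)


def _fail(problems: list[str]):
    raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(problems))


def validate_config(path) -> RunConfig:
    """Load, schema-check and default-fill a JSON run configuration."""
    raw = json.loads(Path(path).read_text())
    problems = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    if "model" not in raw:
        problems.append("missing required key 'model'")
    if "seed" not in raw:
        problems.append("missing required key 'seed' (mandatory for stochastic stages)")
    model = raw.get("model", {})
    if isinstance(model, dict):
        if set(model) - _MODEL_KEYS:
            problems.append(f"model: unknown keys {sorted(set(model) - _MODEL_KEYS)}")
        for i, layer in enumerate(model.get("layers", [])):
            if set(layer) - _LAYER_KEYS:
                problems.append(f"model.layers[{i}]: unknown keys")
            mat = layer.get("material")
            if mat not in PRESETS and not (isinstance(mat, str) and mat.endswith(".csv")):
                problems.append(
                    f"model.layers[{i}].material: {mat!r} is neither a preset "
                    f"({sorted(PRESETS)}) nor a properties CSV path"
                )
        if not model.get("layers"):
            problems.append("model.layers must list at least one layer")
    else:
        problems.append("model must be an object with a 'layers' list")
    photons = raw.get("photons_per_wavelength", 100_000)
    if not (isinstance(photons, int) and photons > 0):
        problems.append("photons_per_wavelength must be a positive integer")
    if "sg_window" in raw and raw["sg_window"] % 2 == 0:
        problems.append("sg_window must be odd")
    probe_raw = raw.get("probe", {})
    if set(probe_raw) - _PROBE_KEYS:
        problems.append(f"probe: unknown keys {sorted(set(probe_raw) - _PROBE_KEYS)}")
    if problems:
        _fail(problems)
    return RunConfig(
        model=model,
        seed=int(raw["seed"]),
        probe=ProbeGeometry(**probe_raw),
        grid_nm=tuple(raw.get("grid_nm", (500.0, 1500.0, 20.0))),
        photons_per_wavelength=photons,
        sg_order=int(raw.get("sg_order", 2)),
        sg_window=int(raw.get("sg_window", 41)),
        match_nm=float(raw.get("match_nm", 1000.0)),
        z=float(raw.get("z", 1.96)),
        classifier_lambda=float(raw.get("classifier_lambda", 0.1)),
        stages=tuple(raw.get("stages", ("simulate", "ratios"))),
    )


def _build_model(cfg: RunConfig):
    from .optical_props import read_properties_csv

    mats = []
    for layer in cfg.model["layers"]:
        mat = layer["material"]
        props = make_properties(mat) if mat in PRESETS else read_properties_csv(mat)
        mats.append((props, layer.get("thickness_mm")))
    if len(mats) == 1:
        return build_homogeneous(mats[0][0])
    if len(mats) == 2:
        return build_two_layer(mats[0][0], mats[0][1], mats[1][0], mats[1][1] or 40.0)
    raise ConfigError("pipeline models support one or two layers")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured stages and write a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "completed": [],
        "outputs": {},
    }
    spectrum = None
    try:
        for stage in config.stages:
            if stage == "simulate":
                model = _build_model(config)
                sim = simulate_spectrum(
                    model,
                    config.probe,
                    config.wavelength_grid(),
                    config.photons_per_wavelength,
                    seed=config.seed,
                )
                spectrum = sim.spectrum
                path = out / "simulated_spectrum.csv"
                write_spectrum_csv(spectrum, path)
                manifest["outputs"]["simulated_spectrum"] = {
                    "path": str(path),
                    "sha256": _sha256(path),
                }
            elif stage == "ratios":
                if spectrum is None:
                    raise ConfigError("'ratios' stage requires 'simulate' before it")
                norm = auc_normalize(spectrum)
                lo = norm.wavelengths_nm[0]
                hi = norm.wavelengths_nm[-1]
                ratios = {
                    name: peak_ratio(norm, *pair)
                    for name, pair in RATIO_PRESETS.items()
                    if lo <= min(pair) and max(pair) <= hi
                }
                path = out / "peak_ratios.json"
                path.write_text(json.dumps(ratios, indent=2, sort_keys=True) + "\n")
                manifest["outputs"]["peak_ratios"] = {
                    "path": str(path),
                    "sha256": _sha256(path),
                }
            else:
                raise ConfigError(f"unknown stage {stage!r}")
            manifest["completed"].append(stage)
    finally:
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return manifest
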