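"""Sample volumes measured by the fiber probe.

Coordinates: the probe rests on the surface plane ``z = 0`` with the
tissue occupying ``z >= 0`` (depth increases into the sample); the probe
axis is ``z``.  Layered models are laterally infinite stacks with
half-open depth intervals ``[top, bottom)`` so an interface depth belongs
to the lower layer.  Voxel models map space onto a 3-D material-index
grid; lateral and bottom lookups outside the grid clamp to the nearest
edge voxel, which extends the boundary material outward.

Three builders cover the study geometries: a homogeneous half-space, a
nerve-mimicking-over-muscle-mimicking two-layer stack (top thickness 1-3
mm over a 40-mm bottom), and a voxelized nerve plexus - a 2-mm-thick
network of nerve cylinders buried under a muscle cover of 0.2-2 mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .optical_props import OpticalProperties

__all__ = [
    "EXTERNAL_MEDIUM",
    "Layer",
    "LayeredModel",
    "VoxelModel",
    "PlexusSpec",
    "build_homogeneous",
    "build_two_layer",
    "build_plexus",
    "material_at",
    "voxelize_layered",
]


class _ExternalMedium:
    """Sentinel for positions above the sample surface (air side)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "<external medium>"


EXTERNAL_MEDIUM = _ExternalMedium()


@dataclass(frozen=True)
class Layer:
    """One horizontal slab: thickness in mm (``inf`` only for the last layer)."""

    thickness_mm: float
    material: OpticalProperties

    def __post_init__(self) -> None:
        if not self.thickness_mm > 0:
            raise ValueError("layer thickness must be positive")


@dataclass(frozen=True)
class LayeredModel:
    """Ordered layers from the surface downward, laterally infinite."""

    layers: tuple[Layer, ...]

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        if not layers:
            raise ValueError("model needs at least one layer")
        for lay in layers[:-1]:
            if math.isinf(lay.thickness_mm):
                raise ValueError("only the terminal layer may be infinite")
        object.__setattr__(self, "layers", layers)

    @property
    def interface_depths(self) -> np.ndarray:
        """Depths of layer tops and bottoms: ``[0, d1, ..., dL]`` mm."""
        depths = [0.0]
        for lay in self.layers:
            depths.append(depths[-1] + lay.thickness_mm)
        return np.array(depths)

    @property
    def total_thickness_mm(self) -> float:
        return float(self.interface_depths[-1])

    def layer_index_at(self, depth_mm: float) -> int:
        """Index of the layer containing ``depth_mm`` (half-open intervals).

        Returns -1 above the surface and -2 below a finite stack.
        """
        if depth_mm < 0:
            return -1
        bounds = self.interface_depths
        for i in range(len(self.layers)):
            if bounds[i] <= depth_mm < bounds[i + 1]:
                return i
        return -2

    def material_at(self, position) -> OpticalProperties | _ExternalMedium:
        z = float(np.asarray(position, dtype=float).reshape(-1)[-1]) if np.ndim(position) else float(position)
        idx = self.layer_index_at(z)
        if idx == -1 or idx == -2:
            return EXTERNAL_MEDIUM
        return self.layers[idx].material


@dataclass(frozen=True)
class PlexusSpec:
    """Geometry of the synthetic nerve-plexus network.

    Three parallel trunk cylinders (axes along y) joined by crossing
    branches (axes along x), all centred at the same depth so the network
    occupies a slab of thickness equal to the trunk diameter.  The
    in-tissue dimensions are configurable because only the 2-mm network
    thickness is anatomically pinned; the rest is a plausible pelvic-plexus
    stand-in.
    """

    trunk_diameter_mm: float = 2.0
    trunk_spacing_mm: float = 3.0
    n_trunks: int = 3
    branch_diameter_mm: float = 1.0
    branch_spacing_mm: float = 6.0
    n_branches: int = 2

    @property
    def thickness_mm(self) -> float:
        return self.trunk_diameter_mm

    def analytic_volume_mm3(self, lateral_extent_mm: float) -> float:
        """Volume of the cylinder union clipped to the lateral extent.

        Branch/trunk intersections are double-counted by the naive sum; an
        inclusion-exclusion correction subtracts the overlap of each
        branch-trunk crossing, approximated as a cylinder-cylinder
        intersection volume (exact for perpendicular equal-axis crossings
        via the Steinmetz-type formula; here radii differ so the smaller
        cylinder is fully absorbed over the crossing length).
        """
        L = lateral_extent_mm
        rt = self.trunk_diameter_mm / 2.0
        rb = self.branch_diameter_mm / 2.0
        vol = self.n_trunks * math.pi * rt**2 * L
        vol += self.n_branches * math.pi * rb**2 * L
        # each branch crosses each trunk; the branch (smaller radius, same
        # centre depth) lies entirely inside the trunk over a chord length
        # 2*sqrt(rt^2 - rb^2) ... conservative estimate: cylinder of radius
        # rb over the trunk diameter.
        overlap = math.pi * rb**2 * (2.0 * rt)
        vol -= self.n_branches * self.n_trunks * overlap
        return vol


@dataclass(frozen=True)
class VoxelModel:
    """Uniform cubic voxel grid: ``grid[iz, iy, ix]`` indexes ``materials``.

    The grid spans ``z in [0, nz*h]`` and is laterally centred on the
    probe axis: ``x in [-nx*h/2, nx*h/2]`` (same for y).  Lookups outside
    the grid clamp to the nearest edge voxel.
    """

    voxel_mm: float
    grid: np.ndarray
    materials: tuple[OpticalProperties, ...]

    def __post_init__(self) -> None:
        if not self.voxel_mm > 0:
            raise ValueError("voxel edge must be positive")
        g = np.asarray(self.grid)
        if g.ndim != 3:
            raise ValueError("grid must be 3-D (z, y, x)")
        if g.max(initial=0) >= len(self.materials) or g.min(initial=0) < 0:
            raise ValueError("grid indexes a material with no table entry")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "materials", tuple(self.materials))

    @property
    def shape(self):
        return self.grid.shape

    def index_of(self, position) -> tuple[int, int, int]:
        x, y, z = (float(v) for v in position)
        nz, ny, nx = self.grid.shape
        h = self.voxel_mm
        ix = min(max(int(math.floor((x + nx * h / 2.0) / h)), 0), nx - 1)
        iy = min(max(int(math.floor((y + ny * h / 2.0) / h)), 0), ny - 1)
        iz = min(max(int(math.floor(z / h)), 0), nz - 1)
        return iz, iy, ix

    def material_at(self, position) -> OpticalProperties | _ExternalMedium:
        x, y, z = (float(v) for v in position)
        if z < 0:
            return EXTERNAL_MEDIUM
        iz, iy, ix = self.index_of(position)
        return self.materials[int(self.grid[iz, iy, ix])]


def material_at(model, position):
    """Material lookup dispatching on the model kind.

    ``position`` is ``(x, y, z)`` in mm, or a bare depth for layered
    models.  Returns :data:`EXTERNAL_MEDIUM` above the surface.
    """
    pos = np.atleast_1d(np.asarray(position, dtype=float))
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    if isinstance(model, LayeredModel):
        z = pos[-1] if pos.size >= 3 else pos[0]
        return model.material_at(z)
    if isinstance(model, VoxelModel):
        if pos.size != 3:
            raise ValueError("voxel lookup requires an (x, y, z) position")
        return model.material_at(pos)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def build_homogeneous(material: OpticalProperties) -> LayeredModel:
    """Semi-infinite half-space of a single material."""
    return LayeredModel((Layer(math.inf, material),))


def build_two_layer(
    top_material: OpticalProperties,
    top_thickness_mm: float,
    bottom_material: OpticalProperties,
    bottom_thickness_mm: float = 40.0,
) -> LayeredModel:
    """Finite top layer over a thick (default 40 mm) bottom layer."""
    if not (top_thickness_mm > 0 and bottom_thickness_mm > 0):
        raise ValueError("layer thicknesses must be positive")
    return LayeredModel(
        (Layer(top_thickness_mm, top_material), Layer(bottom_thickness_mm, bottom_material))
    )


def build_plexus(
    cover_thickness_mm: float,
    nerve_material: OpticalProperties,
    muscle_material: OpticalProperties,
    plexus_spec: PlexusSpec = PlexusSpec(),
    voxel_mm: float = 0.1,
    lateral_extent_mm: float = 20.0,
    below_mm: float = 4.0,
) -> VoxelModel:
    """Voxelize a nerve network under a muscle cover, muscle everywhere else.

    ``cover_thickness_mm`` may be zero (plexus at the surface).  The grid
    depth extends ``below_mm`` past the network; deeper positions clamp to
    the bottom (muscle) voxels.
    """
    if cover_thickness_mm < 0:
        raise ValueError("cover thickness must be non-negative")
    thinnest = plexus_spec.branch_diameter_mm
    if cover_thickness_mm > 0:
        thinnest = min(thinnest, cover_thickness_mm)
    if voxel_mm > thinnest / 2.0 + 1e-12:
        raise ValueError(
            f"voxel edge {voxel_mm:g} mm cannot resolve the thinnest feature "
            f"({thinnest:g} mm); need <= {thinnest / 2.0:g} mm"
        )
    h = voxel_mm
    nx = ny = int(round(lateral_extent_mm / h))
    depth = cover_thickness_mm + plexus_spec.thickness_mm + below_mm
    nz = int(round(depth / h))
    # voxel centres
    xs = (np.arange(nx) + 0.5) * h - nx * h / 2.0
    zs = (np.arange(nz) + 0.5) * h
    zc = cover_thickness_mm + plexus_spec.thickness_mm / 2.0  # network centre depth

    grid = np.zeros((nz, ny, nx), dtype=np.uint8)  # 0 = muscle, 1 = nerve
    dz2 = (zs - zc) ** 2  # (nz,)

    rt = plexus_spec.trunk_diameter_mm / 2.0
    n_t = plexus_spec.n_trunks
    trunk_x = (np.arange(n_t) - (n_t - 1) / 2.0) * plexus_spec.trunk_spacing_mm
    # trunks: axis along y at x = trunk_x -> nerve where (x-x0)^2+(z-zc)^2 <= rt^2
    for x0 in trunk_x:
        mask = dz2[:, None] + (xs[None, :] - x0) ** 2 <= rt**2  # (nz, nx)
        grid |= mask[:, None, :].astype(np.uint8)

    rb = plexus_spec.branch_diameter_mm / 2.0
    n_b = plexus_spec.n_branches
    branch_y = (np.arange(n_b) - (n_b - 1) / 2.0) * plexus_spec.branch_spacing_mm
    ys = (np.arange(ny) + 0.5) * h - ny * h / 2.0
    for y0 in branch_y:
        mask = dz2[:, None] + (ys[None, :] - y0) ** 2 <= rb**2  # (nz, ny)
        grid |= mask[:, :, None].astype(np.uint8)

    return VoxelModel(h, grid, (muscle_material, nerve_material))


def voxelize_layered(
    model: LayeredModel,
    voxel_mm: float = 0.1,
    lateral_extent_mm: float = 20.0,
    depth_mm: float | None = None,
) -> VoxelModel:
    """Render a layered model onto a voxel grid (for cross-checks)."""
    h = voxel_mm
    nx = ny = int(round(lateral_extent_mm / h))
    if depth_mm is None:
        total = model.total_thickness_mm
        depth_mm = min(total, 40.0) if math.isfinite(total) else 10.0
    nz = int(round(depth_mm / h))
    zs = (np.arange(nz) + 0.5) * h
    materials = tuple(lay.material for lay in model.layers)
    idx = np.empty(nz, dtype=np.uint8)
    for k, z in enumerate(zs):
        li = model.layer_index_at(float(z))
        idx[k] = len(materials) - 1 if li == -2 else li
    grid = np.broadcast_to(idx[:, None, None], (nz, ny, nx)).copy()
    return VoxelModel(h, grid, materials)
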