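"""Sampling scalar volumes at the gray-white boundary and at fixed depths.

Two depth conventions coexist, matching standard surface-based practice:

* gray-matter depths are *projection fractions* of local cortical thickness
  along the white-to-pial vertex-correspondence vector (e.g. 30% CT);
* white-matter depths are *absolute distances* in mm along the inward unit
  vertex normal (e.g. -1 mm, -2 mm below the boundary).

Values are interpolated trilinearly in each volume's own voxel space via its
affine; samples falling outside the voxel grid hull are masked invalid, never
clamped or extrapolated.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .core_io import (
    GeometryError,
    ParameterError,
    SurfaceMesh,
    VertexMap,
    VolumeImage,
)


# ---------------------------------------------------------------------------
# Sampling scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Depth:
    """A single sampling depth.

    kind ``"fraction"``: value is a proportion of cortical thickness in [0, 1].
    kind ``"absolute"``: value is a signed distance in mm (negative = into
    white matter, below the boundary).
    """

    kind: str
    value: float
    label: str

    def __post_init__(self):
        if self.kind not in ("fraction", "absolute"):
            raise ParameterError(f"unknown depth kind {self.kind!r}")
        if self.kind == "fraction" and not 0.0 <= self.value <= 1.0:
            raise ParameterError(f"projection fraction {self.value} not in [0, 1]")


def parse_depth(label: str) -> Depth:
    """Parse depth labels like ``"-1mm"``, ``"boundary"``, ``"30CT"``."""
    s = label.strip()
    if s in ("boundary", "0", "0mm"):
        return Depth("absolute", 0.0, "boundary")
    m = re.fullmatch(r"(-?\d+(?:\.\d+)?)\s*mm", s)
    if m:
        return Depth("absolute", float(m.group(1)), s)
    m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*%?CT", s)
    if m:
        return Depth("fraction", float(m.group(1)) / 100.0, s)
    raise ParameterError(f"cannot parse depth label {label!r}")


@dataclass
class SamplingScheme:
    """Ordered list of unique sampling depths."""

    depths: list[Depth] = field(default_factory=lambda: [
        Depth("absolute", -2.0, "-2mm"),
        Depth("absolute", -1.0, "-1mm"),
        Depth("absolute", 0.0, "boundary"),
        Depth("fraction", 0.30, "30CT"),
        Depth("fraction", 0.60, "60CT"),
    ])

    def __post_init__(self):
        labels = [d.label for d in self.depths]
        if len(set(labels)) != len(labels):
            raise ParameterError("duplicate depth labels")

    @classmethod
    def from_labels(cls, labels) -> "SamplingScheme":
        return cls(depths=[parse_depth(s) for s in labels])

    @property
    def labels(self) -> list[str]:
        return [d.label for d in self.depths]


#: The five depths of the default boundary profile.
DEFAULT_SCHEME = SamplingScheme()


# ---------------------------------------------------------------------------
# Normals
# ---------------------------------------------------------------------------

def compute_vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted per-vertex unit normals.

    Orientation follows triangle winding (counter-clockwise from outside,
    so normals point outward, toward the pial surface, for generated
    geometry).  Vertices with no incident face get NaN normals.
    """
    p = mesh.coords[mesh.faces]
    # cross product has magnitude 2*area: area weighting comes for free
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    vn = np.zeros_like(mesh.coords)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    isolated = norms < 1e-300
    with np.errstate(invalid="ignore", divide="ignore"):
        vn = vn / norms[:, None]
    vn[isolated] = np.nan
    return vn


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def trilinear_sample(
    volume: VolumeImage,
    points: np.ndarray,
    nearest: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a volume at world-mm points.

    Returns ``(values, valid)``; points outside the grid hull (continuous
    voxel coordinate outside ``[0, dim-1]`` on any axis) are flagged invalid
    and carry NaN.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    vox = volume.world_to_voxel(pts)
    dims = np.asarray(volume.shape)
    finite = np.all(np.isfinite(vox), axis=1)
    inside = finite & np.all((vox >= 0.0) & (vox <= dims - 1.0), axis=1)
    values = np.full(len(pts), np.nan)
    if inside.any():
        order = 0 if nearest else 1
        values[inside] = map_coordinates(
            volume.data, vox[inside].T, order=order, mode="nearest"
        )
    return values, inside


# ---------------------------------------------------------------------------
# Depth sampling
# ---------------------------------------------------------------------------

def _check_correspondence(white: SurfaceMesh, pial: SurfaceMesh) -> None:
    if white.n_vertices != pial.n_vertices:
        raise GeometryError(
            f"white ({white.n_vertices}) and pial ({pial.n_vertices}) surfaces "
            "are not vertex-corresponding"
        )


def sample_projection_fraction(
    white: SurfaceMesh,
    pial: SurfaceMesh,
    volume: VolumeImage,
    fraction: float,
    modality_tag: str = "t",
    nearest: bool = False,
) -> VertexMap:
    """Sample at ``white + fraction * (pial - white)`` per vertex."""
    _check_correspondence(white, pial)
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction {fraction} not in [0, 1]")
    pts = white.coords + fraction * (pial.coords - white.coords)
    values, valid = trilinear_sample(volume, pts, nearest=nearest)
    return VertexMap(values=values, valid_mask=valid,
                     mesh_id=white.hemisphere, modality_tag=modality_tag)


def sample_absolute_depth(
    white: SurfaceMesh,
    normals: np.ndarray,
    volume: VolumeImage,
    depth_mm: float,
    modality_tag: str = "t",
    nearest: bool = False,
) -> VertexMap:
    """Sample at ``white + depth_mm * outward_normal`` per vertex.

    Negative depths sample inward, into the white matter below the boundary.
    """
    pts = white.coords + depth_mm * normals
    values, valid = trilinear_sample(volume, pts, nearest=nearest)
    valid &= np.all(np.isfinite(normals), axis=1)
    values[~valid] = np.nan
    return VertexMap(values=values, valid_mask=valid,
                     mesh_id=white.hemisphere, modality_tag=modality_tag)


@dataclass
class DepthProfile:
    """One VertexMap per (modality, depth label), on a shared template mesh."""

    maps: dict[tuple[str, str], VertexMap]
    scheme: SamplingScheme
    modalities: list[str]

    def shared_mask(self) -> np.ndarray:
        """Vertices valid at every (modality, depth) they are sampled at."""
        mask = None
        for vm in self.maps.values():
            mask = vm.valid_mask if mask is None else (mask & vm.valid_mask)
        return mask

    def get(self, modality: str, depth_label: str) -> VertexMap:
        return self.maps[(modality, depth_label)]


def build_depth_profile(
    white: SurfaceMesh,
    pial: SurfaceMesh,
    volumes: dict[str, VolumeImage],
    scheme: SamplingScheme = DEFAULT_SCHEME,
    normals: np.ndarray | None = None,
    nearest: bool = False,
) -> DepthProfile:
    """Assemble per-depth VertexMaps for every modality.

    ``volumes`` maps modality tags (``"FA"``, ``"MD"``, ``"T1I"``) to
    coregistered volumes.
    """
    if not volumes:
        raise ParameterError("no volumes supplied")
    _check_correspondence(white, pial)
    if normals is None:
        normals = compute_vertex_normals(white)
    maps: dict[tuple[str, str], VertexMap] = {}
    for modality, vol in volumes.items():
        for depth in scheme.depths:
            if depth.kind == "fraction":
                vm = sample_projection_fraction(
                    white, pial, vol, depth.value, modality, nearest=nearest)
            else:
                vm = sample_absolute_depth(
                    white, normals, vol, depth.value, modality, nearest=nearest)
            maps[(modality, depth.label)] = vm
    return DepthProfile(maps=maps, scheme=scheme, modalities=list(volumes))
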