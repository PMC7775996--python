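"""Shared geometric and tabular data types, plus readers/writers.

All surface and volume coordinates live in a common world RAS frame in
millimetres; voxel indices are 0-based.  Surfaces and volumes are assumed
coregistered on input — an optional 4x4 affine argument lets callers supply
a registration.  Vertex correspondence across subjects is by index on a
shared template mesh.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class FormatError(ValueError):
    """Unreadable or unsupported on-disk format."""


class GeometryError(ValueError):
    """Geometric invariant violated (mesh/volume/affine)."""


class SchemaError(ValueError):
    """Cohort table missing or malformed columns."""


class ParameterError(ValueError):
    """Invalid parameter value."""


class DesignError(ValueError):
    """Statistical design cannot be estimated (rank deficiency etc.)."""


# Required cohort columns and their semantics.
COHORT_REQUIRED = ("subject_id", "group", "sex", "site", "age", "fsiq")
GROUP_LEVELS = ("ASD", "TD")
SEX_LEVELS = ("male", "female")

#: Modalities a VertexMap may carry.
MODALITY_TAGS = ("FA", "MD", "T1I", "GWC", "t", "F", "binary")


# ---------------------------------------------------------------------------
# Surface meshes
# ---------------------------------------------------------------------------

@dataclass
class SurfaceMesh:
    """Triangulated cortical sheet shared across subjects.

    Parameters
    ----------
    coords : (n_vertices, 3) float array
        Vertex coordinates in world mm.
    faces : (n_faces, 3) int array
        Triangle vertex indices, counter-clockwise seen from outside.
    hemisphere : str
        Free-text tag, e.g. ``"lh"`` or ``"slab"``.
    """

    coords: np.ndarray
    faces: np.ndarray
    hemisphere: str = "lh"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise GeometryError("coords must be (n_vertices, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be (n_faces, 3)")
        n = len(self.coords)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise GeometryError(
                f"face index out of range [0, {n})"
            )
        a, b, c = self.faces.T
        if np.any((a == b) | (b == c) | (a == c)):
            raise GeometryError("degenerate triangle (repeated vertex index)")

    @property
    def n_vertices(self) -> int:
        return len(self.coords)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def vertex_adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean vertex adjacency from shared triangle edges."""
        if getattr(self, "_adj", None) is None:
            i = np.concatenate([self.faces[:, 0], self.faces[:, 1], self.faces[:, 2]])
            j = np.concatenate([self.faces[:, 1], self.faces[:, 2], self.faces[:, 0]])
            n = self.n_vertices
            adj = sp.coo_matrix((np.ones_like(i, dtype=np.int8), (i, j)), shape=(n, n))
            adj = adj + adj.T
            adj.data[:] = 1
            self._adj = adj.tocsr()
        return self._adj

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) array with i < j."""
        adj = sp.triu(self.vertex_adjacency(), k=1).tocoo()
        return np.column_stack([adj.row, adj.col])

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        return np.linalg.norm(self.coords[e[:, 0]] - self.coords[e[:, 1]], axis=1)

    def triangle_areas(self) -> np.ndarray:
        p = self.coords[self.faces]
        cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """One third of incident triangle area per vertex (barycentric lumping)."""
        areas = self.triangle_areas()
        va = np.zeros(self.n_vertices)
        for k in range(3):
            np.add.at(va, self.faces[:, k], areas / 3.0)
        return va

    def n_components(self) -> int:
        ncomp, _ = connected_components(self.vertex_adjacency(), directed=False)
        return ncomp


# ---------------------------------------------------------------------------
# Volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeImage:
    """3D scalar grid with an invertible voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise GeometryError("volume data must be 3D")
        if min(self.data.shape) < 2:
            raise GeometryError("volume must have >= 2 voxels along every axis")
        if self.affine.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")

    @property
    def shape(self):
        return self.data.shape

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Map world-mm points (m, 3) to continuous 0-based voxel coordinates."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(np.asarray(ijk, dtype=np.float64))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


# ---------------------------------------------------------------------------
# Vertex maps
# ---------------------------------------------------------------------------

_SENTINEL = np.nan


@dataclass
class VertexMap:
    """One scalar per template-mesh vertex with a validity mask.

    Invalid vertices carry NaN and are excluded from all statistics.
    """

    values: np.ndarray
    valid_mask: np.ndarray | None = None
    mesh_id: str = ""
    modality_tag: str = "t"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).copy()
        if self.valid_mask is None:
            self.valid_mask = np.isfinite(self.values)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool).copy()
        if self.values.shape != self.valid_mask.shape or self.values.ndim != 1:
            raise GeometryError("values and valid_mask must be equal-length 1D")
        self.values[~self.valid_mask] = _SENTINEL

    @property
    def n_vertices(self) -> int:
        return len(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]


def check_same_mesh(*maps: VertexMap) -> None:
    n = {m.n_vertices for m in maps}
    ids = {m.mesh_id for m in maps if m.mesh_id}
    if len(n) > 1 or len(ids) > 1:
        raise GeometryError(f"vertex maps disagree on mesh: sizes {n}, ids {ids}")


# ---------------------------------------------------------------------------
# Cohort table
# ---------------------------------------------------------------------------

@dataclass
class CohortTable:
    """Per-subject covariates and (optionally) input file paths.

    The underlying frame always carries the columns in ``COHORT_REQUIRED``;
    additional columns (clinical scores such as ``aq``/``bdi``/``bai``, path
    columns ending in ``_path``) are passed through untouched.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.reset_index(drop=True).copy()
        missing = [c for c in COHORT_REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns: {missing}")
        for col, levels in (("group", GROUP_LEVELS), ("sex", SEX_LEVELS)):
            bad = set(df[col].unique()) - set(levels)
            if bad:
                raise SchemaError(f"unknown {col} levels: {sorted(bad)}")
        for col in ("age", "fsiq"):
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                rows = list(df.index[vals.isna()] + 2)  # +2: header + 1-based
                raise SchemaError(f"unparseable {col} at line(s) {rows}")
            df[col] = vals.astype(float)
        for col in ("group", "sex", "site"):
            if df[col].nunique() < 2:
                raise SchemaError(
                    f"column {col!r} has a single level; group-by-sex model "
                    "terms are inestimable"
                )
        if df[list(COHORT_REQUIRED)].isna().any().any():
            raise SchemaError("missing values in model covariates")
        self.frame = df

    @property
    def n_subjects(self) -> int:
        return len(self.frame)

    def score_columns(self) -> list[str]:
        skip = set(COHORT_REQUIRED)
        return [
            c for c in self.frame.columns
            if c not in skip and not c.endswith("_path")
            and pd.api.types.is_numeric_dtype(self.frame[c])
        ]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_surface(path: str | Path, hemisphere: str | None = None) -> SurfaceMesh:
    """Read a FreeSurfer binary surface or a GIFTI surface.

    Coordinates are returned in mm in the file's native frame.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such surface file: {path}")
    if path.suffix == ".gii":
        img = nib.load(str(path))
        coords = img.darrays[0].data
        faces = img.darrays[1].data
    else:
        try:
            coords, faces = nib.freesurfer.io.read_geometry(str(path))
        except Exception as exc:  # nibabel raises bare ValueError on bad magic
            size = path.stat().st_size
            raise FormatError(
                f"cannot read {path} as FreeSurfer surface "
                f"(file size {size} bytes): {exc}"
            ) from exc
    hemi = hemisphere or (path.name.split(".")[0] if path.name[:2] in ("lh", "rh") else "unknown")
    return SurfaceMesh(coords=coords, faces=faces, hemisphere=hemi)


def write_surface(mesh: SurfaceMesh, path: str | Path) -> None:
    nib.freesurfer.io.write_geometry(str(path), mesh.coords, mesh.faces)


def read_volume(path: str | Path, affine_override: np.ndarray | None = None) -> VolumeImage:
    """Read an MGH/MGZ or NIfTI-1 scalar volume."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read {path} as MGH/NIfTI: {exc}") from exc
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    affine = np.asarray(img.affine) if affine_override is None else np.asarray(affine_override)
    return VolumeImage(data=data, affine=affine)


def write_volume(vol: VolumeImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".mgh", ".mgz"):
        img = nib.MGHImage(vol.data.astype(np.float32), vol.affine)
    else:
        img = nib.Nifti1Image(vol.data, vol.affine)
    nib.save(img, str(path))


def read_cohort(path: str | Path) -> CohortTable:
    """Read a TSV cohort table with header."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such cohort file: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    return CohortTable(frame=df)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.frame.to_csv(path, sep="\t", index=False)


def write_vertex_map(vmap: VertexMap, path: str | Path) -> None:
    """Write per-vertex values as an MGH overlay (``.mgh``) or TSV."""
    path = Path(path)
    if path.suffix in (".mgh", ".mgz"):
        data = vmap.values.astype(np.float32).reshape(-1, 1, 1)
        nib.save(nib.MGHImage(data, np.eye(4)), str(path))
    else:
        pd.DataFrame({
            "vertex_id": np.arange(vmap.n_vertices),
            "value": vmap.values,
        }).to_csv(path, sep="\t", index=False)


def read_vertex_map(path: str | Path, modality_tag: str = "t") -> VertexMap:
    path = Path(path)
    if path.suffix in (".mgh", ".mgz"):
        vals = np.asarray(nib.load(str(path)).get_fdata()).reshape(-1)
    else:
        vals = pd.read_csv(path, sep="\t")["value"].to_numpy(dtype=float)
    return VertexMap(values=vals, modality_tag=modality_tag)
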