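"""Gray-white tissue contrast (GWC) and surface-based smoothing.

GWC at vertex i is the percentage contrast between the white-matter T1
intensity WMI_i (sampled 1 mm below the boundary) and the gray-matter
intensity GMI_i (sampled at 30% cortical thickness):

    GWC_i = 100 * (WMI_i - GMI_i) / (0.5 * (WMI_i + GMI_i))

i.e. the intensity difference divided by the mean intensity.  A decreased
GWC means less separation between the tissue intensities — a "blurred"
boundary.

Smoothing approximates a Gaussian heat kernel on the mesh by iterating a
symmetric, doubly-stochastic one-ring averaging operator; the iteration
count is calibrated so that the accumulated kernel variance matches the
requested full width at half maximum.  Geodesic distance is approximated by
graph distance with edge lengths, which is accurate at 15 mm FWHM on ~1 mm
meshes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core_io import (
    GeometryError,
    ParameterError,
    SurfaceMesh,
    VertexMap,
    check_same_mesh,
)

GAUSS_VAR_PER_FWHM2 = 1.0 / (8.0 * np.log(2.0))  # sigma^2 = FWHM^2 / (8 ln 2)


@dataclass
class GwcInputs:
    """T1 intensity at 30% CT (gmi) and at -1 mm (wmi), same mesh."""

    gmi: VertexMap
    wmi: VertexMap

    def __post_init__(self):
        check_same_mesh(self.gmi, self.wmi)


def compute_gwc(inputs: GwcInputs) -> VertexMap:
    """Percent gray-white contrast per vertex.

    Defined only where both inputs are valid and WMI + GMI > 0; other
    vertices are masked.
    """
    gmi, wmi = inputs.gmi, inputs.wmi
    valid = gmi.valid_mask & wmi.valid_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = 0.5 * (wmi.values + gmi.values)
        gwc = 100.0 * (wmi.values - gmi.values) / denom
    valid = valid & np.isfinite(gwc) & (denom > 0)
    gwc[~valid] = np.nan
    return VertexMap(values=gwc, valid_mask=valid,
                     mesh_id=gmi.mesh_id, modality_tag="GWC")


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------

def _averaging_operator(
    mesh: SurfaceMesh, valid: np.ndarray, alpha: float = 0.95
) -> tuple[sp.csr_matrix, float]:
    """One-ring diffusion step restricted to valid vertices.

    S = I + (alpha / d_max) (A - D) on the valid-vertex subgraph, where A is
    the 0/1 adjacency and D the degree matrix.  S is symmetric with unit row
    sums, hence doubly stochastic: it conserves constants and the mean
    exactly.  alpha < 1 keeps every diagonal entry positive.

    Returns the operator and the mean per-step 2D kernel variance (mm^2),
    measured as the average over valid vertices of sum_j S_ij |x_j - x_i|^2.
    """
    n = mesh.n_vertices
    adj = mesh.vertex_adjacency().astype(np.float64)
    if not valid.all():
        keep = sp.diags(valid.astype(np.float64))
        adj = keep @ adj @ keep
    deg = np.asarray(adj.sum(axis=1)).ravel()
    dmax = deg.max()
    if dmax == 0:
        return sp.identity(n, format="csr"), 0.0
    S = sp.identity(n, format="csr") + (alpha / dmax) * (adj - sp.diags(deg))
    # per-step added kernel variance: apply S to coordinates and squares
    x = mesh.coords
    x2 = np.einsum("ij,ij->i", x, x)
    var_step = (S @ x2) - x2 - 2.0 * np.einsum("ij,ij->i", (S @ x) - x, x)
    mean_var = float(var_step[valid & (deg > 0)].mean()) if valid.any() else 0.0
    return S.tocsr(), mean_var


def smoothing_iterations(mesh: SurfaceMesh, fwhm_mm: float,
                         valid: np.ndarray | None = None) -> int:
    """Iteration count whose accumulated variance matches ``fwhm_mm``."""
    if fwhm_mm < 0:
        raise ParameterError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return 0
    if valid is None:
        valid = np.ones(mesh.n_vertices, dtype=bool)
    _, var_step = _averaging_operator(mesh, valid)
    if var_step <= 0:
        return 0
    # target is the 2D (in-sheet) kernel variance: 2 axes * sigma^2 each
    target = 2.0 * GAUSS_VAR_PER_FWHM2 * fwhm_mm**2
    return max(1, round(target / var_step))


def smooth_vertex_map(
    mesh: SurfaceMesh,
    vmap: VertexMap,
    fwhm_mm: float,
    n_iter: int | None = None,
) -> VertexMap:
    """Smooth a vertex map along the mesh to a target FWHM.

    Masked vertices are excluded from the averaging (no bleed from invalid
    vertices) and remain masked in the output.
    """
    if fwhm_mm < 0:
        raise ParameterError("fwhm must be >= 0")
    if vmap.n_vertices != mesh.n_vertices:
        raise GeometryError("map length does not match mesh")
    if fwhm_mm == 0 and n_iter is None:
        return VertexMap(values=vmap.values.copy(), valid_mask=vmap.valid_mask.copy(),
                         mesh_id=vmap.mesh_id, modality_tag=vmap.modality_tag)
    valid = vmap.valid_mask
    S, var_step = _averaging_operator(mesh, valid)
    if n_iter is None:
        target = 2.0 * GAUSS_VAR_PER_FWHM2 * fwhm_mm**2
        n_iter = max(1, round(target / var_step)) if var_step > 0 else 0
    x = np.where(valid, vmap.values, 0.0)
    for _ in range(n_iter):
        x = S @ x
    x[~valid] = np.nan
    return VertexMap(values=x, valid_mask=valid.copy(),
                     mesh_id=vmap.mesh_id, modality_tag=vmap.modality_tag)


def smooth_matrix(mesh: SurfaceMesh, Y: np.ndarray, fwhm_mm: float,
                  valid: np.ndarray | None = None) -> np.ndarray:
    """Smooth many maps at once: rows of Y are subjects, columns vertices."""
    if valid is None:
        valid = np.all(np.isfinite(Y), axis=0)
    S, var_step = _averaging_operator(mesh, valid)
    if fwhm_mm == 0 or var_step <= 0:
        return Y.copy()
    target = 2.0 * GAUSS_VAR_PER_FWHM2 * fwhm_mm**2
    n_iter = max(1, round(target / var_step))
    X = np.where(valid[None, :], Y, 0.0).T  # vertices x subjects
    for _ in range(n_iter):
        X = S @ X
    out = X.T.copy()
    out[:, ~valid] = np.nan
    return out


def measure_fwhm_from_delta(mesh: SurfaceMesh, smoothed: VertexMap,
                            source_vertex: int) -> float:
    """Empirical FWHM of a smoothed point source, from kernel variance.

    The kernel after smoothing a delta is the row of the accumulated
    operator; its in-sheet variance v (per axis, mm^2) gives
    FWHM = sqrt(8 ln 2 * v).  Uses distances from the source vertex, so it
    is exact on a flat slab.
    """
    w = np.where(smoothed.valid_mask, smoothed.values, 0.0)
    w = np.clip(w, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ParameterError("smoothed delta has no mass")
    d2 = np.sum((mesh.coords - mesh.coords[source_vertex]) ** 2, axis=1)
    var2d = float((w * d2).sum() / total)  # 2D variance = 2 * per-axis
    return float(np.sqrt(8.0 * np.log(2.0) * var2d / 2.0))
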