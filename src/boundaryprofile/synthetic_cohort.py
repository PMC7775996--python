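"""Synthetic cortical cohorts with known ground truth.

Generates template white/pial geometry, per-subject T1/FA/MD volumes with a
sigmoidal tissue profile across the gray-white boundary, planted regional
group and group-by-sex effects, spatially smooth noise, and a cohort table
whose autism-trait score correlates with each subject's realized effect
magnitude.  Every stage downstream of image acquisition is thereby testable
without any external data.

The default test world is a flat slab (white surface in the z = 0 plane,
pial displaced along +z by per-vertex cortical thickness) because analytic
expectations — normals, sigmoid profiles, kernel FWHM — are exact there.  A
sphere variant exercises curvature.

Default tissue values reflect typical adult T1/DTI contrast: T1 intensity
110 (WM plateau) vs 90 (GM), FA 0.40 vs 0.15, MD 0.70 vs 0.85 in units of
1e-3 mm^2/s; diffusion is more isotropic and slightly faster in gray
matter.  The cohort emulates a two-group, two-sex, two-site adult sample:
ages uniform on 18-52 years, FSIQ normal with mean 115 and SD 11, mean
cortical thickness 2.67 mm (SD 0.09 across vertices).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import trimesh
from scipy.ndimage import gaussian_filter

from .contrast_and_smoothing import smooth_matrix
from .core_io import CohortTable, ParameterError, SurfaceMesh, VolumeImage

SIGMOID_1090 = 2.0 * np.log(9.0)  # 10-90% rise of a logistic = 2 ln 9 scales


@dataclass
class TissueProfile:
    """Plateau values on either side of the boundary and transition width.

    ``transition_width_mm`` is the distance over which the profile rises
    from 10% to 90% of the plateau difference.
    """

    wm_value: float
    gm_value: float
    transition_width_mm: float = 0.5


@dataclass
class PlantedEffect:
    """A disc-shaped regional effect on one modality.

    ``magnitude`` is in units of that modality's vertex noise SD; positive
    magnitudes raise the affected cells.  ``pattern`` is ``"group"`` (added
    for ASD subjects only) or ``"group_x_sex"`` (added with the sign of the
    group*sex effect-code product).  ``depth_range_mm`` bounds the signed
    distance from the boundary over which the effect applies (negative =
    white matter).
    """

    center_xy: tuple[float, float]
    radius_mm: float
    modality: str
    magnitude: float
    pattern: str = "group"
    depth_range_mm: tuple[float, float] = (-3.0, 3.0)

    def cell_coefficient(self, group: str, sex: str) -> float:
        g = 1.0 if group == "ASD" else 0.0
        if self.pattern == "group":
            return g
        if self.pattern == "group_x_sex":
            ge = 1.0 if group == "ASD" else -1.0
            se = 1.0 if sex == "male" else -1.0
            return ge * se
        raise ParameterError(f"unknown effect pattern {self.pattern!r}")


@dataclass
class NoiseModel:
    """Additive noise: spatially smooth vertex noise plus a subject offset.

    ``vertex_sd`` doubles as the per-modality scale reference for planted
    effect magnitudes; ``scale`` multiplies the noise actually applied, so
    ``scale=0`` gives noise-free volumes without zeroing the effects.
    """

    vertex_sd: dict = field(default_factory=lambda: {
        "T1I": 2.0, "FA": 0.03, "MD": 0.03})
    subject_offset_sd: dict = field(default_factory=lambda: {
        "T1I": 0.8, "FA": 0.01, "MD": 0.01})
    fwhm_mm: float = 6.0
    scale: float = 1.0


@dataclass
class ClinicalModel:
    """Autism-trait score generation.

    Within the ASD group the AQ-like score is a linear function of the
    subject's effect-magnitude multiplier plus noise, achieving the target
    Pearson correlation in expectation.
    """

    target_correlation: float = 0.6
    effect_multiplier_sd: float = 0.3
    aq_asd_mean: float = 35.0
    aq_asd_sd: float = 8.0
    aq_td_mean: float = 16.0
    aq_td_sd: float = 6.0


@dataclass
class SyntheticSpec:
    """Full recipe for a synthetic cohort; seed-fixed outputs are bitwise
    reproducible."""

    n_per_cell: int = 5
    mesh_kind: str = "slab"
    mesh_extent_mm: float = 30.0
    vertex_spacing_mm: float = 1.0
    sphere_radius_mm: float = 50.0
    thickness_mean_mm: float = 2.67
    thickness_sd_mm: float = 0.09
    voxel_mm: float = 1.0
    dwi_voxel_mm: float | None = None  # e.g. 2.4 to emulate coarser DTI grids
    tissue_profile: dict = field(default_factory=lambda: {
        "T1I": TissueProfile(110.0, 90.0),
        "FA": TissueProfile(0.40, 0.15),
        "MD": TissueProfile(0.70, 0.85),
    })
    effects: list = field(default_factory=list)
    noise: NoiseModel = field(default_factory=NoiseModel)
    clinical: ClinicalModel = field(default_factory=ClinicalModel)
    age_range: tuple[float, float] = (18.0, 52.0)
    fsiq_mean: float = 115.0
    fsiq_sd: float = 11.0
    seed: int = 0

    def __post_init__(self):
        if self.vertex_spacing_mm <= 0:
            raise ParameterError("vertex spacing must be > 0")
        if self.n_per_cell < 2:
            raise ParameterError("n_per_cell must be >= 2 (variance inestimable)")
        for eff in self.effects:
            if not np.isfinite(eff.magnitude):
                raise ParameterError("effect magnitude must be finite")
            limit = (self.mesh_extent_mm if self.mesh_kind == "slab"
                     else np.pi * self.sphere_radius_mm)
            if eff.radius_mm <= 0 or eff.radius_mm >= limit:
                raise ParameterError("effect radius must be positive and "
                                     "smaller than the mesh extent")


@dataclass
class SyntheticTruth:
    """Ground truth of the planted effects, for recovery tests."""

    effects: list                    # PlantedEffect, as planted
    vertex_sets: list                # np.ndarray of affected vertex indices
    deltas: list                     # absolute effect size in modality units
    subject_multiplier: np.ndarray   # per-subject effect scaling


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def make_template_geometry(spec: SyntheticSpec) -> tuple[SurfaceMesh, SurfaceMesh]:
    """White and pial template surfaces sharing one triangulation."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    if spec.mesh_kind == "slab":
        n_side = int(round(spec.mesh_extent_mm / spec.vertex_spacing_mm)) + 1
        xs = np.arange(n_side) * spec.vertex_spacing_mm
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        coords = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        faces = []
        for i in range(n_side - 1):
            for j in range(n_side - 1):
                v = i * n_side + j
                # counter-clockwise seen from +z so normals point outward
                faces.append([v, v + n_side, v + 1])
                faces.append([v + 1, v + n_side, v + n_side + 1])
        faces = np.asarray(faces)
        normals = np.tile([0.0, 0.0, 1.0], (len(coords), 1))
        tag = "slab"
    elif spec.mesh_kind == "sphere":
        subdiv = max(2, int(np.ceil(np.log2(
            spec.sphere_radius_mm / spec.vertex_spacing_mm))) - 1)
        ico = trimesh.creation.icosphere(subdivisions=subdiv,
                                         radius=spec.sphere_radius_mm)
        coords = np.asarray(ico.vertices)
        faces = np.asarray(ico.faces)
        normals = coords / np.linalg.norm(coords, axis=1, keepdims=True)
        tag = "sphere"
    else:
        raise ParameterError(f"unknown mesh kind {spec.mesh_kind!r}")
    thickness = rng.normal(spec.thickness_mean_mm, spec.thickness_sd_mm,
                           len(coords))
    thickness = np.clip(thickness, 0.5, None)
    white = SurfaceMesh(coords=coords, faces=faces, hemisphere=tag)
    pial = SurfaceMesh(coords=coords + thickness[:, None] * normals,
                       faces=faces.copy(), hemisphere=tag)
    return white, pial


def _signed_distance(spec: SyntheticSpec, X, Y, Z):
    """Signed distance from the boundary; positive into gray matter."""
    if spec.mesh_kind == "slab":
        return Z
    r = np.sqrt(X**2 + Y**2 + Z**2)
    return r - spec.sphere_radius_mm


def _volume_grid(spec: SyntheticSpec, white: SurfaceMesh, pial: SurfaceMesh,
                 voxel: float, margin: float = 5.0):
    lo = np.minimum(white.coords.min(axis=0), pial.coords.min(axis=0)) - margin
    hi = np.maximum(white.coords.max(axis=0), pial.coords.max(axis=0)) + margin
    shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 2)
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = lo
    axes = [lo[k] + voxel * np.arange(shape[k]) for k in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return X, Y, Z, affine


def _region_mask(spec: SyntheticSpec, eff: PlantedEffect, X, Y, Z, s):
    if spec.mesh_kind == "slab":
        d = np.sqrt((X - eff.center_xy[0])**2 + (Y - eff.center_xy[1])**2)
    else:
        # geodesic distance on the sphere from the point above center_xy
        cx, cy = eff.center_xy
        c = np.array([cx, cy, np.sqrt(max(spec.sphere_radius_mm**2
                                          - cx**2 - cy**2, 0.0))])
        c /= np.linalg.norm(c)
        r = np.sqrt(X**2 + Y**2 + Z**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = (X * c[0] + Y * c[1] + Z * c[2]) / r
        d = spec.sphere_radius_mm * np.arccos(np.clip(cosang, -1, 1))
    lo, hi = eff.depth_range_mm
    return (d <= eff.radius_mm) & (s >= lo) & (s <= hi)


def simulate_subject_volumes(
    geometry: tuple[SurfaceMesh, SurfaceMesh],
    spec: SyntheticSpec,
    subject_cell: tuple[str, str, str],
    seed: int,
    effect_multiplier: float = 1.0,
) -> dict[str, VolumeImage]:
    """One subject's T1I/FA/MD volumes; deterministic under ``seed``.

    ``subject_cell`` is (group, sex, site).  T1 is generated on the
    structural grid (``voxel_mm``); FA and MD on the diffusion grid when
    ``dwi_voxel_mm`` is set, reproducing a structural/diffusion resolution
    mismatch.
    """
    white, pial = geometry
    group, sex, _site = subject_cell
    rng = np.random.default_rng(seed)
    out: dict[str, VolumeImage] = {}
    for modality, prof in spec.tissue_profile.items():
        voxel = spec.voxel_mm
        if modality in ("FA", "MD") and spec.dwi_voxel_mm:
            voxel = spec.dwi_voxel_mm
        X, Y, Z, affine = _volume_grid(spec, white, pial, voxel)
        s = _signed_distance(spec, X, Y, Z)
        scale = prof.transition_width_mm / SIGMOID_1090
        data = prof.gm_value + (prof.wm_value - prof.gm_value) / (
            1.0 + np.exp(s / scale))
        noise_sd = spec.noise.vertex_sd.get(modality, 0.0)
        for eff in spec.effects:
            if eff.modality != modality:
                continue
            coeff = eff.cell_coefficient(group, sex)
            if coeff == 0.0:
                continue
            mask = _region_mask(spec, eff, X, Y, Z, s)
            data = data + (mask * (coeff * eff.magnitude * noise_sd
                                   * effect_multiplier))
        applied_sd = noise_sd * spec.noise.scale
        if applied_sd > 0:
            white_noise = rng.standard_normal(data.shape)
            sigma_vox = spec.noise.fwhm_mm / (np.sqrt(8 * np.log(2)) * voxel)
            if sigma_vox > 0.05:
                field_ = gaussian_filter(white_noise, sigma_vox, mode="reflect")
                field_ /= field_.std()
            else:
                field_ = white_noise
            data = data + applied_sd * field_
        offset_sd = spec.noise.subject_offset_sd.get(modality, 0.0) * spec.noise.scale
        if offset_sd > 0:
            data = data + rng.normal(0.0, offset_sd)
        out[modality] = VolumeImage(data=data, affine=affine)
    return out


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _truth_vertex_sets(spec: SyntheticSpec, white: SurfaceMesh):
    sets, deltas = [], []
    for eff in spec.effects:
        if spec.mesh_kind == "slab":
            d = np.sqrt((white.coords[:, 0] - eff.center_xy[0])**2
                        + (white.coords[:, 1] - eff.center_xy[1])**2)
        else:
            cx, cy = eff.center_xy
            c = np.array([cx, cy, np.sqrt(max(spec.sphere_radius_mm**2
                                              - cx**2 - cy**2, 0.0))])
            c /= np.linalg.norm(c)
            unit = white.coords / np.linalg.norm(white.coords, axis=1,
                                                 keepdims=True)
            d = spec.sphere_radius_mm * np.arccos(np.clip(unit @ c, -1, 1))
        verts = np.flatnonzero(d <= eff.radius_mm)
        if verts.size == 0:
            raise ParameterError("planted effect region contains no vertices "
                                 "(outside mesh?)")
        sets.append(verts)
        deltas.append(eff.magnitude * spec.noise.vertex_sd.get(eff.modality, 0.0))
    return sets, deltas


def simulate_cohort(spec: SyntheticSpec) -> tuple[CohortTable, SyntheticTruth]:
    """Cohort table plus ground truth; group/sex/site cells filled equally."""
    ss = np.random.SeedSequence([spec.seed, 2])
    rng = np.random.default_rng(ss)
    cells = list(itertools.product(("ASD", "TD"), ("male", "female"), ("A", "B")))
    rows = []
    k = 0
    for group, sex, site in cells:
        for _ in range(spec.n_per_cell):
            rows.append({
                "subject_id": f"S{k:04d}", "group": group, "sex": sex,
                "site": site,
                "age": rng.uniform(*spec.age_range),
                "fsiq": rng.normal(spec.fsiq_mean, spec.fsiq_sd),
            })
            k += 1
    df = pd.DataFrame(rows)
    n = len(df)
    cm = spec.clinical
    mult = rng.normal(1.0, cm.effect_multiplier_sd, n)
    asd = (df["group"] == "ASD").to_numpy()
    rho = float(np.clip(cm.target_correlation, -1.0, 1.0))
    z_noise = rng.standard_normal(n)
    aq = np.empty(n)
    # standardize the multiplier within ASD so the correlation target is exact
    z_mult = np.zeros(n)
    if asd.sum() >= 2 and mult[asd].std() > 0:
        z_mult[asd] = (mult[asd] - mult[asd].mean()) / mult[asd].std()
    aq[asd] = cm.aq_asd_mean + cm.aq_asd_sd * (
        rho * z_mult[asd] + np.sqrt(1 - rho**2) * z_noise[asd])
    aq[~asd] = cm.aq_td_mean + cm.aq_td_sd * z_noise[~asd]
    df["aq"] = aq
    df["bdi"] = np.clip(rng.normal(8.0, 6.0, n) + 4.0 * asd, 0.0, None)
    df["bai"] = np.clip(rng.normal(7.0, 6.0, n) + 3.0 * asd, 0.0, None)
    white, _ = make_template_geometry(spec)
    sets, deltas = _truth_vertex_sets(spec, white)
    truth = SyntheticTruth(effects=list(spec.effects), vertex_sets=sets,
                           deltas=deltas, subject_multiplier=mult)
    return CohortTable(frame=df), truth


def subject_seeds(spec: SyntheticSpec, n_subjects: int) -> list[int]:
    """Per-subject volume seeds, derived from the spec seed."""
    ss = np.random.SeedSequence([spec.seed, 3])
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_subjects)]


def simulate_dataset(spec: SyntheticSpec):
    """Geometry, cohort, truth, and all per-subject volumes in one call."""
    geometry = make_template_geometry(spec)
    cohort, truth = simulate_cohort(spec)
    seeds = subject_seeds(spec, cohort.n_subjects)
    volumes = []
    for i, row in cohort.frame.iterrows():
        volumes.append(simulate_subject_volumes(
            geometry, spec, (row["group"], row["sex"], row["site"]),
            seeds[i], effect_multiplier=truth.subject_multiplier[i]))
    return geometry, cohort, truth, volumes


# ---------------------------------------------------------------------------
# Vertex-level shortcut for inference calibration studies
# ---------------------------------------------------------------------------

def simulate_smooth_vertex_data(
    mesh: SurfaceMesh,
    n_subjects: int,
    fwhm_mm: float,
    rng: np.random.Generator,
    effect: np.ndarray | None = None,
    effect_rows: np.ndarray | None = None,
) -> np.ndarray:
    """Spatially smooth unit-variance Gaussian vertex data, optionally with
    a per-vertex effect added to selected subjects.

    Used for null-calibration and power studies where generating full
    volumes per subject would add nothing: the noise is white across
    subjects and smoothed along the mesh to ``fwhm_mm``, matching the
    smoothness assumption random-field theory requires.
    """
    Y = rng.standard_normal((n_subjects, mesh.n_vertices))
    if fwhm_mm > 0:
        Y = smooth_matrix(mesh, Y, fwhm_mm)
        sd = Y.std(axis=0).mean()
        Y /= sd
    if effect is not None:
        rows = (np.ones(n_subjects, dtype=bool)
                if effect_rows is None else effect_rows)
        Y[rows] += effect[None, :]
    return Y
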