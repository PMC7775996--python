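"""Vertex-wise general linear model with group, sex, and their interaction.

The model at each vertex i is

    Y_i = b0 + b1*Group + b2*Sex + b3*Group-by-Sex + b4*Site
             + b5*Age + b6*Age^2 + b7*FSIQ + e_i

with categorical factors effect-coded (-1/+1) so that b1 is half the group
difference and b3 the interaction, and continuous covariates mean-centered
across the full sample.  Age^2 is the square of centered age, itself
centered, to limit collinearity with the linear term.

Between-group t-maps divide a coefficient by its standard error; model terms
are assessed by step-up nested-model F-tests at each vertex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import CohortTable, DesignError, ParameterError, VertexMap

EFFECT_CODES = {
    "group": {"ASD": 1.0, "TD": -1.0},
    "sex": {"male": 1.0, "female": -1.0},
}

FULL_COLUMNS = ("intercept", "group", "sex", "group_x_sex",
                "site", "age", "age2", "fsiq")


@dataclass
class DesignMatrix:
    """Per-subject design with a centering record for continuous columns."""

    X: np.ndarray
    columns: list[str]
    centering: dict[str, float] = field(default_factory=dict)
    check_rank: bool = True

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise DesignError("X shape does not match column names")
        if not self.check_rank:
            return
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            # name the collinear columns via the QR diagonal
            _, R = np.linalg.qr(self.X)
            diag = np.abs(np.diag(R))
            bad = [c for c, d in zip(self.columns, diag)
                   if d < 1e-8 * diag.max()]
            raise DesignError(f"design is rank deficient; collinear columns: {bad}")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def contrast_for(self, name: str) -> np.ndarray:
        c = np.zeros(len(self.columns))
        c[self.column_index(name)] = 1.0
        return c

    def drop(self, *names: str) -> "DesignMatrix":
        keep = [i for i, c in enumerate(self.columns) if c not in names]
        return DesignMatrix(X=self.X[:, keep],
                            columns=[self.columns[i] for i in keep],
                            centering=dict(self.centering))


def build_design(
    cohort: CohortTable,
    include_interaction: bool = True,
    extra_covariates: tuple[str, ...] = (),
) -> DesignMatrix:
    """Build the 8-column design from a cohort table.

    ``extra_covariates`` names additional numeric cohort columns (e.g.
    ``"bdi"`` or total brain measures for robustness reruns); each is
    mean-centered and appended.
    """
    df = cohort.frame
    n = len(df)
    group = df["group"].map(EFFECT_CODES["group"]).to_numpy()
    sex = df["sex"].map(EFFECT_CODES["sex"]).to_numpy()
    sites = sorted(df["site"].unique())
    if len(sites) != 2:
        raise DesignError(f"expected 2 sites, got {sites}")
    site = df["site"].map({sites[0]: 1.0, sites[1]: -1.0}).to_numpy()

    centering: dict[str, float] = {}
    age_mean = float(df["age"].mean())
    age_c = df["age"].to_numpy(dtype=float) - age_mean
    centering["age"] = age_mean
    age2 = age_c**2
    age2_mean = float(age2.mean())
    age2_c = age2 - age2_mean
    centering["age2"] = age2_mean
    fsiq_mean = float(df["fsiq"].mean())
    fsiq_c = df["fsiq"].to_numpy(dtype=float) - fsiq_mean
    centering["fsiq"] = fsiq_mean

    cols = {
        "intercept": np.ones(n),
        "group": group,
        "sex": sex,
        "group_x_sex": group * sex,
        "site": site,
        "age": age_c,
        "age2": age2_c,
        "fsiq": fsiq_c,
    }
    if not include_interaction:
        del cols["group_x_sex"]
    for name in extra_covariates:
        v = df[name].to_numpy(dtype=float)
        centering[name] = float(v.mean())
        cols[name] = v - centering[name]
    X = np.column_stack(list(cols.values()))
    return DesignMatrix(X=X, columns=list(cols), centering=centering)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    """Per-vertex OLS fit with residuals retained for smoothness estimation."""

    beta: np.ndarray          # (p, n_vertices)
    residuals: np.ndarray     # (n_subjects, n_vertices)
    sigma2: np.ndarray        # (n_vertices,) residual variance (RSS / df)
    df: int
    design: DesignMatrix
    valid: np.ndarray         # (n_vertices,) vertices actually fitted

    @property
    def n_vertices(self) -> int:
        return self.beta.shape[1]


@dataclass
class StatMap:
    """A t- or F-statistic VertexMap with its degrees of freedom."""

    vmap: VertexMap
    df: tuple[int, ...]
    contrast: str = ""


def fit_glm(Y: np.ndarray, design: DesignMatrix) -> GlmFit:
    """Ordinary least squares at every vertex (columns of Y).

    Vertices with any non-finite observation are masked, not fatal.
    """
    Y = np.asarray(Y, dtype=np.float64)
    X = design.X
    if Y.shape[0] != X.shape[0]:
        raise DesignError(
            f"Y has {Y.shape[0]} rows but design has {X.shape[0]} subjects")
    n, p = X.shape
    df = n - p
    if df <= 0:
        raise DesignError("no residual degrees of freedom")
    valid = np.all(np.isfinite(Y), axis=0)
    beta = np.full((p, Y.shape[1]), np.nan)
    resid = np.full_like(Y, np.nan)
    pinv = np.linalg.pinv(X)
    beta[:, valid] = pinv @ Y[:, valid]
    resid[:, valid] = Y[:, valid] - X @ beta[:, valid]
    sigma2 = np.full(Y.shape[1], np.nan)
    sigma2[valid] = np.einsum("ij,ij->j", resid[:, valid], resid[:, valid]) / df
    return GlmFit(beta=beta, residuals=resid, sigma2=sigma2, df=df,
                  design=design, valid=valid)


def contrast_t(fit: GlmFit, contrast: np.ndarray | str) -> StatMap:
    """t = c'beta / se(c'beta) per vertex, df = residual df."""
    if isinstance(contrast, str):
        name = contrast
        c = fit.design.contrast_for(contrast)
    else:
        c = np.asarray(contrast, dtype=np.float64)
        name = "custom"
    if c.shape != (fit.design.X.shape[1],):
        raise DesignError("contrast length does not match design columns")
    XtX_inv = np.linalg.inv(fit.design.X.T @ fit.design.X)
    cvar = float(c @ XtX_inv @ c)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(fit.sigma2 * cvar)
        t = (c @ fit.beta) / se
    valid = fit.valid & np.isfinite(t)
    t[~valid] = np.nan
    vm = VertexMap(values=t, valid_mask=valid, modality_tag="t")
    return StatMap(vmap=vm, df=(fit.df,), contrast=name)


def nested_f_test(Y: np.ndarray, reduced: DesignMatrix,
                  full: DesignMatrix) -> StatMap:
    """Step-up nested-model comparison F-test at each vertex.

    F = ((RSS_r - RSS_f) / dp) / (RSS_f / df_f), df = (dp, df_f).
    """
    _check_nested(reduced, full)
    fit_r = fit_glm(Y, reduced)
    fit_f = fit_glm(Y, full)
    dp = full.X.shape[1] - reduced.X.shape[1]
    if dp == 0:
        raise ParameterError("full and reduced designs have equal size")
    df_f = fit_f.df
    rss_r = fit_r.sigma2 * fit_r.df
    rss_f = fit_f.sigma2 * df_f
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ((rss_r - rss_f) / dp) / (rss_f / df_f)
    F = np.clip(F, 0.0, None)  # guard tiny negative round-off
    valid = fit_f.valid & np.isfinite(F)
    F[~valid] = np.nan
    vm = VertexMap(values=F, valid_mask=valid, modality_tag="F")
    return StatMap(vmap=vm, df=(dp, df_f), contrast="nested")


def _check_nested(reduced: DesignMatrix, full: DesignMatrix) -> None:
    """Every reduced column must appear (exactly) among the full columns."""
    for name in reduced.columns:
        if name not in full.columns:
            raise ParameterError(
                f"designs are not nested: column {name!r} absent from full model")
        jr = reduced.column_index(name)
        jf = full.column_index(name)
        if not np.allclose(reduced.X[:, jr], full.X[:, jf]):
            raise ParameterError(
                f"designs are not nested: column {name!r} differs between models")


def t_pvalues(stat: StatMap) -> np.ndarray:
    """Two-tailed p-values for a t StatMap."""
    return 2.0 * stats.t.sf(np.abs(stat.vmap.values), df=stat.df[0])


def f_pvalues(stat: StatMap) -> np.ndarray:
    return stats.f.sf(stat.vmap.values, stat.df[0], stat.df[1])
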