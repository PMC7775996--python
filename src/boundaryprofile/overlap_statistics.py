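"""Spatial overlap of thresholded difference maps.

Quantifies how much two binary maps of significant vertices overlap
(counts, percent relative to an explicit denominator map), tests whether
two measures' alterations are equally prevalent with a continuity-corrected
2x2 chi-square, and estimates the chance probability of the observed
percent overlap from random difference maps.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .core_io import GeometryError, ParameterError, VertexMap, check_same_mesh
from .rft_cluster_inference import ClusterTable


@dataclass
class BinaryMap:
    """0/1 vertex map with provenance (measure name, threshold rule)."""

    vmap: VertexMap
    measure: str = ""
    threshold_rule: str = ""

    @property
    def count(self) -> int:
        return int(np.sum(self.vmap.values[self.vmap.valid_mask] == 1.0))

    @property
    def indicator(self) -> np.ndarray:
        return (self.vmap.values == 1.0) & self.vmap.valid_mask


@dataclass
class OverlapResult:
    n_vertices_total: int
    count_A: int
    count_B: int
    count_intersection: int
    percent_overlap: float
    denominator: str
    chi2_value: float | None = None
    chi2_df: int = 1
    chi2_p: float | None = None
    sim_n: int | None = None
    sim_p: float | None = None
    sim_mode: str | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def binarize_significant(
    clusters: ClusterTable, alpha: float = 0.05,
    measure: str = "",
) -> BinaryMap:
    """1 at vertices inside clusters with corrected p < alpha, else 0."""
    sig = clusters.significant_vertices(alpha)
    vm = VertexMap(values=sig.astype(float), valid_mask=np.ones_like(sig),
                   modality_tag="binary")
    return BinaryMap(vmap=vm, measure=measure,
                     threshold_rule=f"cluster-corrected p<{alpha}")


def overlap_summary(
    map_A: BinaryMap, map_B: BinaryMap, denominator: str = "B",
) -> OverlapResult:
    """Intersection count and percent overlap.

    ``denominator`` selects which map's count the percentage is relative to
    (the convention here is the diffusion-measure map as B).
    """
    check_same_mesh(map_A.vmap, map_B.vmap)
    if denominator not in ("A", "B"):
        raise ParameterError("denominator must be 'A' or 'B'")
    a, b = map_A.indicator, map_B.indicator
    inter = int(np.sum(a & b))
    count_A, count_B = int(a.sum()), int(b.sum())
    denom = count_A if denominator == "A" else count_B
    if denom == 0:
        raise GeometryError("denominator map has no suprathreshold vertices")
    return OverlapResult(
        n_vertices_total=map_A.vmap.n_vertices,
        count_A=count_A, count_B=count_B, count_intersection=inter,
        percent_overlap=100.0 * inter / denom, denominator=denominator)


def prevalence_chi2(
    count_A: int, count_B: int, n_vertices: int, correction: bool = True,
) -> tuple[float, float]:
    """Chi-square test that two alterations are equally prevalent.

    2x2 table [[count_A, n - count_A], [count_B, n - count_B]], df = 1,
    with Yates continuity correction by default.
    """
    if not (0 <= count_A <= n_vertices and 0 <= count_B <= n_vertices):
        raise ParameterError("counts must be within [0, n_vertices]")
    table = np.array([[count_A, n_vertices - count_A],
                      [count_B, n_vertices - count_B]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("chi-square undefined: zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def simulate_overlap_null(
    n_vertices: int,
    observed_percent: float | None = None,
    n_sims: int = 5000,
    seed: int = 0,
    mode: str = "iid",
    threshold_p: float = 0.05,
    df: int | None = None,
    counts: tuple[int, int] | None = None,
    denominator: str = "B",
) -> dict:
    """Null distribution of percent overlap between random difference maps.

    ``iid`` mode draws a fresh pair of vertex-wise random t-values per
    simulation (standard normal, or Student t when ``df`` is given),
    thresholds each at two-tailed ``threshold_p``, and measures the percent
    overlap relative to the denominator map.  ``prevalence_matched`` mode
    conditions on the observed suprathreshold counts: the intersection of
    two uniformly random vertex subsets of those sizes is hypergeometric,
    and is drawn as such.

    Returns the simulated percent distribution and, when an observed
    percentage is supplied, the one-sided exceedance probability
    ``(1 + #{sims >= observed}) / (n_sims + 1)``.
    """
    if n_sims < 1:
        raise ParameterError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    percents = np.empty(n_sims)
    if mode == "iid":
        crit = (stats.norm.isf(threshold_p / 2.0) if df is None
                else stats.t.isf(threshold_p / 2.0, df))
        for s in range(n_sims):
            if df is None:
                ta = rng.standard_normal(n_vertices)
                tb = rng.standard_normal(n_vertices)
            else:
                ta = rng.standard_t(df, n_vertices)
                tb = rng.standard_t(df, n_vertices)
            a = np.abs(ta) >= crit
            b = np.abs(tb) >= crit
            denom = a.sum() if denominator == "A" else b.sum()
            percents[s] = 100.0 * np.sum(a & b) / denom if denom else 0.0
    elif mode == "prevalence_matched":
        if counts is None:
            raise ParameterError("prevalence_matched mode needs observed counts")
        count_A, count_B = counts
        inter = rng.hypergeometric(count_A, n_vertices - count_A,
                                   count_B, size=n_sims)
        denom = count_A if denominator == "A" else count_B
        percents = 100.0 * inter / denom
    else:
        raise ParameterError(f"unknown simulation mode {mode!r}")
    out = {
        "mode": mode, "n_sims": n_sims, "seed": seed,
        "n_vertices": n_vertices,
        "percents": percents,
        "mean_percent": float(percents.mean()),
    }
    if observed_percent is not None:
        exceed = int(np.sum(percents >= observed_percent))
        out["sim_p"] = (1.0 + exceed) / (n_sims + 1.0)
        out["observed_percent"] = observed_percent
    return out
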