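"""Demographic group comparisons and cluster-wise clinical correlations.

Continuous demographics are compared with Welch's unequal-variance t-test
(fractional Welch-Satterthwaite df); categorical 2x2 tables use the
continuity-corrected chi-square.  Clinical associations are Pearson
correlations between per-subject cluster means of a measure and
questionnaire scores, reported uncorrected (exploratory) with an optional
Benjamini-Hochberg column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CohortTable, ParameterError


@dataclass
class GroupSummary:
    """n, mean, SD of one continuous variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ParameterError("group summary needs n >= 2")
        if self.sd < 0:
            raise ParameterError("SD must be >= 0")

    @classmethod
    def from_values(cls, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        return cls(n=len(v), mean=float(v.mean()), sd=float(v.std(ddof=1)))


def welch_t(a: GroupSummary, b: GroupSummary) -> tuple[float, float, float]:
    """Welch's t, Welch-Satterthwaite df, and two-tailed p from summaries."""
    if a.sd <= 0 or b.sd <= 0:
        raise ParameterError("Welch t needs positive SDs")
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    t = (a.mean - b.mean) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def chi2_2x2(counts, correction: bool = True) -> tuple[float, float]:
    """Continuity-corrected chi-square on a 2x2 count table, df = 1."""
    table = np.asarray(counts, dtype=float)
    if table.shape != (2, 2):
        raise ParameterError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ParameterError("chi-square undefined: zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(chi2), float(p)


def demographics_table(cohort: CohortTable) -> pd.DataFrame:
    """Group comparison of age, FSIQ (Welch t) and sex, site (chi-square)."""
    df = cohort.frame
    asd = df[df["group"] == "ASD"]
    td = df[df["group"] == "TD"]
    rows = []
    for var in ("age", "fsiq"):
        sa = GroupSummary.from_values(asd[var])
        sb = GroupSummary.from_values(td[var])
        t, wdf, p = welch_t(sa, sb)
        rows.append({
            "variable": var, "test": "welch_t",
            "ASD": f"{sa.mean:.2f} ± {sa.sd:.2f}",
            "TD": f"{sb.mean:.2f} ± {sb.sd:.2f}",
            "statistic": t, "df": wdf, "p": p,
        })
    for var in ("sex", "site"):
        levels = sorted(df[var].unique())
        table = [[int((asd[var] == lv).sum()) for lv in levels],
                 [int((td[var] == lv).sum()) for lv in levels]]
        if len(levels) != 2:
            raise ParameterError(f"{var} must have exactly 2 levels for a 2x2 test")
        chi2, p = chi2_2x2(table)
        rows.append({
            "variable": var, "test": "chi2",
            "ASD": "/".join(str(v) for v in table[0]),
            "TD": "/".join(str(v) for v in table[1]),
            "statistic": chi2, "df": 1, "p": p,
        })
    return pd.DataFrame(rows)


def cluster_clinical_correlations(
    cluster_means: pd.DataFrame,
    scores: pd.DataFrame,
    group: str | None = "ASD",
    cohort: CohortTable | None = None,
    bh_column: bool = True,
) -> pd.DataFrame:
    """Pearson r between per-subject cluster means and clinical scores.

    ``cluster_means``: one row per subject, one column per (cluster,
    measure); ``scores``: one row per subject, one column per questionnaire.
    Rows align by index (subject order).  Missing scores are dropped
    pairwise; pairs with < 3 complete observations or zero variance are
    reported as undefined (NaN).  When ``group`` and ``cohort`` are given,
    rows are restricted to that group (scores are condition-specific).
    """
    if len(cluster_means) != len(scores):
        raise ParameterError("cluster_means and scores must have equal rows")
    keep = np.ones(len(scores), dtype=bool)
    if group is not None and cohort is not None:
        keep = (cohort.frame["group"] == group).to_numpy()
    rows = []
    for mcol in cluster_means.columns:
        x_all = cluster_means[mcol].to_numpy(dtype=float)[keep]
        for scol in scores.columns:
            y_all = scores[scol].to_numpy(dtype=float)[keep]
            ok = np.isfinite(x_all) & np.isfinite(y_all)
            x, y = x_all[ok], y_all[ok]
            tiny_x = np.std(x) <= 1e-12 * max(1.0, np.abs(x).max(initial=0.0))
            tiny_y = np.std(y) <= 1e-12 * max(1.0, np.abs(y).max(initial=0.0))
            if len(x) < 3 or tiny_x or tiny_y:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            rows.append({"cluster_measure": mcol, "score": scol,
                         "n": int(ok.sum()), "r": r, "p": p})
    out = pd.DataFrame(rows)
    if bh_column:
        out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values, NaNs passed through."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps)
    ranked = ps[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(ranked, 1.0)
    q[ok] = adj
    return q
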