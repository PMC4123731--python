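"""Spatial variability statistics of parameter maps across three scales.

Within-mat variability is quantified three ways on each parameter image:
the SD over all layer pixels (total), the SD of the mean vertical profile
and the SD of the mean horizontal profile. Within-site variability is the
SD of the mat-level layer means per site; global variability is the SD of
the site means. A two-factor variance decomposition with depth (row) and
horizontal position (column) as factors splits the within-mat sum of
squares into vertical, horizontal and interaction components. Site-level
differences in the mat means are tested by one-way ANOVA with a
Shapiro-Wilk normality check and Tukey-style rank groups.

All SDs use the n - 1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    LayerMask,
    ProfileStats,
    StudyDesign,
    ValidationError,
    VarianceDecomposition,
)

__all__ = [
    "average_profile",
    "within_mat_variability",
    "largest_rectangle",
    "variance_decomposition",
    "multiscale_report",
    "site_anova",
    "SiteANOVA",
]


def _masked(map_: np.ndarray, layer: LayerMask) -> np.ndarray:
    m = np.asarray(map_, dtype=float)
    if m.shape != layer.shape:
        raise ValidationError("map and mask shapes differ")
    vals = np.where(layer.mask, m, np.nan)
    if not np.isfinite(vals[layer.mask]).any():
        raise ValidationError("no finite masked value")
    return vals


def average_profile(map_, layer: LayerMask, axis: str) -> ProfileStats:
    """Mean vertical (per-row) or horizontal (per-column) profile.

    The mean at each position is taken over the masked pixels of that row
    (vertical) or column (horizontal); the SD is across the orthogonal
    direction at that position.
    """
    vals = _masked(map_, layer)
    if axis == "vertical":
        data = vals
    elif axis == "horizontal":
        data = vals.T
    else:
        raise ValidationError("axis must be 'vertical' or 'horizontal'")
    n = np.isfinite(data).sum(axis=1)
    mean = np.full(len(n), np.nan)
    sd = np.full(len(n), np.nan)
    some, multi = n > 0, n > 1
    mean[some] = np.nansum(np.where(np.isfinite(data[some]), data[some], 0.0),
                           axis=1) / n[some]
    if multi.any():
        sd[multi] = np.nanstd(data[multi], axis=1, ddof=1)
    keep = n > 0
    return ProfileStats(
        axis=axis,
        positions=np.flatnonzero(keep).astype(float),
        mean=mean[keep],
        sd=sd[keep],
        n=n[keep],
    )


def within_mat_variability(map_, layer: LayerMask) -> dict[str, float]:
    """Total, vertical and horizontal SD plus the CV of one parameter map.

    total: SD over all masked pixels; vertical: SD of the mean vertical
    profile; horizontal: SD of the mean horizontal profile; CV = total SD
    divided by the masked mean (NaN when the mean is 0).
    """
    vals = _masked(map_, layer)
    finite = vals[np.isfinite(vals)]
    if finite.size < 2:
        raise ValidationError("need at least 2 masked pixels")
    total = float(finite.std(ddof=1))
    mean = float(finite.mean())
    vert = average_profile(map_, layer, "vertical").mean
    horiz = average_profile(map_, layer, "horizontal").mean
    return {
        "total_sd": total,
        "vertical_sd": float(vert.std(ddof=1)) if len(vert) > 1 else 0.0,
        "horizontal_sd": float(horiz.std(ddof=1)) if len(horiz) > 1 else 0.0,
        "cv": total / mean if mean != 0 else float("nan"),
        "mean": mean,
    }


def largest_rectangle(mask: np.ndarray) -> tuple[slice, slice]:
    """Largest full rectangle of True cells (histogram-stack algorithm)."""
    mask = np.asarray(mask, dtype=bool)
    nr, nc = mask.shape
    heights = np.zeros(nc + 1, dtype=int)  # sentinel column of height 0
    best = (0, slice(0, 0), slice(0, 0))
    for r in range(nr):
        heights[:nc] = np.where(mask[r], heights[:nc] + 1, 0)
        stack: list[int] = []
        for c in range(nc + 1):
            while stack and heights[stack[-1]] > heights[c]:
                h = int(heights[stack.pop()])
                left = stack[-1] + 1 if stack else 0
                area = h * (c - left)
                if area > best[0]:
                    best = (area, slice(r - h + 1, r + 1), slice(left, c))
            stack.append(c)
    if best[0] == 0:
        raise ValidationError("mask has no True cell")
    return best[1], best[2]


def variance_decomposition(
    map_, layer: LayerMask, balanced: bool = True
) -> VarianceDecomposition:
    """Two-factor variance split of one image: depth x horizontal position.

    One observation per cell, so the interaction is the residual:
    SS_interaction = SS_total - SS_row - SS_col. By default the largest
    full rectangle inscribed in the mask is used (balanced design; the
    irregular layer boundary would otherwise unbalance the factors). The
    ``balanced=False`` variant uses count-weighted marginal means over all
    masked cells; its interaction term is a residual that can go negative.
    """
    vals = _masked(map_, layer)
    if balanced:
        rs, cs = largest_rectangle(layer.mask & np.isfinite(vals))
        sub = vals[rs, cs]
        if sub.shape[0] < 2 or sub.shape[1] < 2:
            raise ValidationError("mask must span >= 2 rows and >= 2 columns")
        grand = sub.mean()
        ss_total = float(((sub - grand) ** 2).sum())
        ss_row = float(sub.shape[1] * ((sub.mean(axis=1) - grand) ** 2).sum())
        ss_col = float(sub.shape[0] * ((sub.mean(axis=0) - grand) ** 2).sum())
    else:
        finite = np.isfinite(vals)
        if (finite.any(axis=1).sum() < 2) or (finite.any(axis=0).sum() < 2):
            raise ValidationError("mask must span >= 2 rows and >= 2 columns")
        grand = np.nanmean(vals)
        ss_total = float(np.nansum((vals - grand) ** 2))
        n_r = finite.sum(axis=1)
        n_c = finite.sum(axis=0)
        with np.errstate(invalid="ignore"):
            rm = np.nanmean(vals, axis=1)
            cm = np.nanmean(vals, axis=0)
        ss_row = float(np.nansum(n_r * (rm - grand) ** 2))
        ss_col = float(np.nansum(n_c * (cm - grand) ** 2))
    ss_int = ss_total - ss_row - ss_col
    if ss_total == 0:
        return VarianceDecomposition(0.0, 0.0, 0.0, 0.0, defined=False)
    return VarianceDecomposition(ss_row, ss_col, ss_int, ss_total)


def multiscale_report(
    mat_stats: pd.DataFrame, design: StudyDesign, parameter: str = ""
) -> pd.DataFrame:
    """Three-scale variability table from per-mat layer statistics.

    ``mat_stats`` has one row per mat: columns mat_id, mean, total_sd,
    vertical_sd, horizontal_sd (the within-mat quantities). The report
    stacks: one within_mat row per mat; one within_site row per site (SD
    of the mat means; NaN-flagged for single-mat sites); one global row
    (SD of the site means, each site mean being the mean of its mats'
    layer means). Mat ordering does not affect the result.
    """
    if "mat_id" not in mat_stats.columns:
        raise ValidationError("mat_stats needs a mat_id column")
    t = mat_stats.merge(design.table[["mat_id", "site_id"]], on="mat_id")
    rows = []
    for _, r in t.sort_values("mat_id").iterrows():
        rows.append({
            "scale": "within_mat", "unit": r["mat_id"], "sd": r["total_sd"],
            "vertical_sd": r.get("vertical_sd", np.nan),
            "horizontal_sd": r.get("horizontal_sd", np.nan),
            "cv": r["total_sd"] / r["mean"] if r["mean"] else np.nan,
            "n": 1, "flag": "",
        })
    site_means = {}
    for site in dict.fromkeys(design.table["site_id"]):
        grp = t[t["site_id"] == site]
        means = grp["mean"].to_numpy(dtype=float)
        site_means[site] = means.mean()
        single = len(means) < 2
        sd = np.nan if single else float(means.std(ddof=1))
        rows.append({
            "scale": "within_site", "unit": site, "sd": sd,
            "vertical_sd": np.nan, "horizontal_sd": np.nan,
            "cv": sd / means.mean() if (not single and means.mean()) else np.nan,
            "n": len(means), "flag": "single_mat" if single else "",
        })
    if len(site_means) >= 2:
        sm = np.array(list(site_means.values()))
        rows.append({
            "scale": "global", "unit": "all_sites", "sd": float(sm.std(ddof=1)),
            "vertical_sd": np.nan, "horizontal_sd": np.nan,
            "cv": float(sm.std(ddof=1) / sm.mean()) if sm.mean() else np.nan,
            "n": len(sm), "flag": "",
        })
    out = pd.DataFrame(rows)
    out.insert(0, "parameter", parameter)
    return out


@dataclass
class SiteANOVA:
    parameter: str
    site_means: dict[str, float]
    site_sds: dict[str, float]
    shapiro_p: float
    anova_f: float
    anova_p: float
    rank_groups: dict[str, str]
    log_transformed: bool


def _rank_groups(order: list[str], different) -> dict[str, str]:
    """Compact rank labels from pairwise significance.

    Sites are ordered by decreasing mean. Rank clusters are the maximal
    cliques of the "not significantly different" graph, numbered from the
    cluster containing the highest mean downward; a site belonging to
    clusters 1 and 2 is labelled "1-2".
    """
    from itertools import combinations

    n = len(order)
    cliques: list[tuple[int, ...]] = []
    for size in range(n, 0, -1):
        for combo in combinations(range(n), size):
            if any(set(combo) <= set(c) for c in cliques):
                continue
            if all(not different(order[i], order[j])
                   for i, j in combinations(combo, 2)):
                cliques.append(combo)
    cliques.sort(key=lambda c: c[0])  # by position of the best member
    labels = {}
    for i, s in enumerate(order):
        ids = sorted(k + 1 for k, c in enumerate(cliques) if i in c)
        labels[s] = f"{ids[0]}-{ids[-1]}" if len(ids) > 1 else str(ids[0])
    return labels


def site_anova(
    values_by_site: dict[str, np.ndarray],
    parameter: str = "",
    log_transform: bool = False,
    alpha: float = 0.05,
) -> SiteANOVA:
    """One-way ANOVA of mat-level means across sites with rank groups.

    Normality of the residuals is checked by Shapiro-Wilk at p = 0.05
    (reported, not enforced). Rank groups come from pairwise Tukey HSD
    comparisons at the same alpha, rendered in bracket notation: sites
    ranked [1] are significantly larger than those ranked [2]; [1-2] sits
    in both. With log_transform the test runs on log values (variance
    homogenisation for right-skewed parameters); reported means/SDs stay
    on the original scale.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_site.items()}
    if len(groups) < 2:
        raise ValidationError("need >= 2 sites")
    testable = {k: v for k, v in groups.items() if len(v) >= 2}
    data = [np.log(v) if log_transform else v for v in testable.values()]
    names = list(testable.keys())
    site_means = {k: float(v.mean()) for k, v in groups.items()}
    site_sds = {k: float(v.std(ddof=1)) if len(v) > 1 else np.nan
                for k, v in groups.items()}
    pooled_resid = np.concatenate([d - d.mean() for d in data])
    if np.allclose(pooled_resid, 0):
        # zero within-group variance: F undefined
        order = sorted(names, key=lambda s: -site_means[s])
        return SiteANOVA(parameter, site_means, site_sds, np.nan, np.nan,
                         np.nan, {s: "" for s in names}, log_transform)
    shapiro_p = float(stats.shapiro(pooled_resid).pvalue)
    f, p = stats.f_oneway(*data)
    tuk = stats.tukey_hsd(*data)

    def different(a: str, b: str) -> bool:
        ia, ib = names.index(a), names.index(b)
        return bool(tuk.pvalue[ia, ib] < alpha)

    order = sorted(names, key=lambda s: -np.mean(data[names.index(s)]))
    ranks = _rank_groups(order, different)
    return SiteANOVA(parameter, site_means, site_sds, shapiro_p,
                     float(f), float(p), ranks, log_transform)
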