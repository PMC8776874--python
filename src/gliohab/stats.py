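"""Nonparametric group statistics and label categorization.

Covers the statistical toolkit of the habitat analysis: Mann-Whitney U with
an exact small-sample path, Benjamini-Hochberg FDR adjustment, label
categorization into M/N/W (log-ratio significantly higher in IDH-mutant /
no difference / higher in wild-type), majority-category assignment of
spherical biopsy targets, Kruskal-Wallis with Dunn's post-hoc z tests, and
one-way ANOVA with Tukey HSD.

Mann-Whitney two-sided p values follow the convention
p = min(1, 2 * min(P(U <= u), P(U >= u))).  For combined sample sizes up to
``EXACT_N_MAX`` the null distribution of U is obtained by full enumeration
of all group assignments of the pooled midranks (exact, and well defined
under ties); above that, the normal approximation with tie and continuity
corrections is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .features import IDH_MUTANT, IDH_WILDTYPE

logger = logging.getLogger(__name__)

EXACT_N_MAX = 12

CATEGORY_MUTANT = "M"
CATEGORY_NEITHER = "N"
CATEGORY_WILDTYPE = "W"
#: Tie precedence for majority-category assignment of biopsy spheres.
CATEGORY_PRECEDENCE = {CATEGORY_WILDTYPE: 2, CATEGORY_MUTANT: 1, CATEGORY_NEITHER: 0}


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of sample x against y, from midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    nx = len(x)
    return float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of x, two-sided p).

    Exact by full enumeration of all C(n, n_x) group assignments when the
    combined sample size is <= 12 (midranks make this well defined with
    ties); otherwise the normal approximation with tie correction and a
    0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = len(x), len(y)
    n = nx + ny
    u = _u_statistic(x, y)

    if n <= EXACT_N_MAX:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        const = nx * (nx + 1) / 2.0
        us = np.fromiter(
            (ranks[list(idx)].sum() - const for idx in combinations(range(n), nx)),
            dtype=float, count=comb(n, nx))
        eps = 1e-9
        lo = np.mean(us <= u + eps)
        hi = np.mean(us >= u - eps)
        p = min(1.0, 2.0 * min(lo, hi))
        return u, float(p)

    mu = nx * ny / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return u, float(p)


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (original order)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Label categorization


@dataclass
class CategoryMap:
    """M/N/W category per habitat label, with the underlying statistics."""

    categories: dict[int, str]
    raw_p: dict[int, float]
    adjusted_p: dict[int, float]
    direction: dict[int, str]  # which class had the higher median
    alpha: float = 0.05

    def labels_in(self, category: str) -> list[int]:
        return sorted(k for k, c in self.categories.items() if c == category)

    def to_frame(self) -> pd.DataFrame:
        labels = sorted(self.categories)
        return pd.DataFrame({
            "label": labels,
            "category": [self.categories[k] for k in labels],
            "p_raw": [self.raw_p[k] for k in labels],
            "p_adjusted": [self.adjusted_p[k] for k in labels],
            "higher_in": [self.direction[k] for k in labels],
        })


def categorize_labels(compositions, alpha: float = 0.05) -> CategoryMap:
    """Categorize each habitat label as M, N or W from the cohort log-ratios.

    Per label, the log-ratio values are compared between IDH-mutant and
    wild-type subjects by Mann-Whitney U; p values are BH-adjusted across
    the K labels.  A label is M if its adjusted p < alpha with the mutant
    median higher, W if adjusted p < alpha with the wild-type median higher,
    and N otherwise.

    Parameters
    ----------
    compositions : sequence of LabelComposition
        Per-subject label compositions (see :mod:`gliohab.classify`), each
        carrying ``logratio`` and ``idh_status``.
    """
    comps = list(compositions)
    mut = [c for c in comps if c.idh_status == IDH_MUTANT]
    wt = [c for c in comps if c.idh_status == IDH_WILDTYPE]
    if len(mut) < 2 or len(wt) < 2:
        raise ValueError("need >= 2 subjects in each IDH class")
    K = len(comps[0].logratio)
    if any(len(c.logratio) != K for c in comps):
        raise ValueError("compositions disagree on K")

    raw = np.empty(K)
    direction = {}
    for k in range(K):
        xm = np.array([c.logratio[k] for c in mut])
        xw = np.array([c.logratio[k] for c in wt])
        _, raw[k] = mann_whitney_u(xm, xw)
        direction[k + 1] = (IDH_MUTANT if np.median(xm) > np.median(xw)
                            else IDH_WILDTYPE)
    adj = benjamini_hochberg(raw)

    categories = {}
    for k in range(K):
        if adj[k] < alpha:
            categories[k + 1] = (CATEGORY_MUTANT
                                 if direction[k + 1] == IDH_MUTANT
                                 else CATEGORY_WILDTYPE)
        else:
            categories[k + 1] = CATEGORY_NEITHER
    return CategoryMap(
        categories=categories,
        raw_p={k + 1: float(raw[k]) for k in range(K)},
        adjusted_p={k + 1: float(adj[k]) for k in range(K)},
        direction=direction,
        alpha=alpha,
    )


def majority_category(labeled, catmap: CategoryMap, center, radius: float) -> str:
    """Category occupying the majority of a spherical target ROI.

    ``center`` is a voxel index triple and ``radius`` is in voxel units
    (isotropic spacing assumed); a voxel belongs to the sphere when its
    center lies within the Euclidean radius.  Exact ties between categories
    break by the precedence W > M > N — a wild-type signal is the clinically
    salient call for a biopsy target.
    """
    labels = labeled.labels
    center = np.asarray(center, dtype=float)
    grids = np.meshgrid(*[np.arange(s) for s in labels.shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    inside = (d2 <= radius**2) & labeled.defined_mask
    if not inside.any():
        raise ValueError("target sphere contains no labeled tumor voxels")
    shares: dict[str, int] = {}
    vals, counts = np.unique(labels[inside], return_counts=True)
    for v, c in zip(vals, counts):
        cat = catmap.categories[int(v)]
        shares[cat] = shares.get(cat, 0) + int(c)
    return max(shares, key=lambda cat: (shares[cat], CATEGORY_PRECEDENCE[cat]))


# ---------------------------------------------------------------------------
# K-sample tests


def kruskal_wallis_dunn(groups) -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis H (tie-corrected, chi-square p) plus Dunn's post hoc.

    Dunn's pairwise z statistics use the pooled midranks and the
    tie-corrected variance; pairwise p values are Bonferroni-corrected over
    the number of pairs.  Returns (H, p, pairwise table).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("need >= 3 groups; use mann_whitney_u for two")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")

    try:
        h, p = sps.kruskal(*groups)
        if not np.isfinite(h):  # all values identical: zero rank variance
            h, p = 0.0, 1.0
    except ValueError:
        h, p = 0.0, 1.0

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = (counts**3 - counts).sum() / (12.0 * (n - 1))
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]

    pairs = list(combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        se = sqrt((n * (n + 1) / 12.0 - tie_corr) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_i": i, "group_j": j, "z": z,
                     "p_raw": p_raw, "p_adjusted": min(1.0, p_raw * len(pairs))})
    return float(h), float(p), pd.DataFrame(rows)


def anova_tukey(groups) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA F test plus Tukey HSD pairwise comparisons.

    Returns (F, p, Tukey table with columns group_i, group_j, meandiff,
    p_adjusted, reject).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 values")
    within_var = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    means = [g.mean() for g in groups]
    if within_var == 0 and max(means) - min(means) == 0:
        raise ValueError("all groups identical and constant: F undefined")

    f, p = sps.f_oneway(*groups)
    data = np.concatenate(groups)
    labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    res = pairwise_tukeyhsd(data, labels)
    pairs = list(combinations(range(len(groups)), 2))
    tbl = pd.DataFrame({
        "group_i": [pair[0] for pair in pairs],
        "group_j": [pair[1] for pair in pairs],
        "meandiff": res.meandiffs,
        "p_adjusted": res.pvalues,
        "reject": res.reject,
    })
    return float(f), float(p), tbl


# ---------------------------------------------------------------------------
# Histology comparisons


def compare_histology(records: pd.DataFrame, markers, statuses: dict[str, str]) -> dict:
    """Group comparisons of biopsy-marker measurements.

    Parameters
    ----------
    records : DataFrame
        One row per biopsy; columns ``subject_id``, ``category`` (M/N/W)
        and one column per marker (positive-cell percentages).
    markers : sequence of str
        Marker column names.
    statuses : mapping subject_id -> IDH status.

    Returns a dict with three result sets:

    - ``across_categories``: per marker, Kruskal-Wallis + Dunn across the
      M/N/W categories (categories with < 2 records are excluded, logged);
    - ``within_category``: per category, Mann-Whitney mutant vs wild-type
      per marker with BH adjustment across markers;
    - ``overall``: per marker, Mann-Whitney mutant vs wild-type ignoring
      categories;
    - ``summary``: mean +/- sd per (category, marker) and (status, marker).
    """
    records = records.copy()
    if records["category"].nunique() < 2:
        raise ValueError("need >= 2 categories represented")
    records["idh_status"] = records["subject_id"].map(statuses)

    cat_counts = records["category"].value_counts()
    usable = [c for c in (CATEGORY_MUTANT, CATEGORY_NEITHER, CATEGORY_WILDTYPE)
              if cat_counts.get(c, 0) >= 2]
    dropped = [c for c in cat_counts.index if c not in usable]
    if dropped:
        logger.warning("compare_histology: categories %s have < 2 records and "
                       "are excluded from the across-category tests", dropped)

    across = {}
    if len(usable) >= 3:
        for m in markers:
            groups = [records.loc[records["category"] == c, m].to_numpy()
                      for c in usable]
            h, p, dunn = kruskal_wallis_dunn(groups)
            dunn = dunn.assign(
                group_i=[usable[i] for i in dunn["group_i"]],
                group_j=[usable[j] for j in dunn["group_j"]],
            )
            across[m] = {"H": h, "p": p, "dunn": dunn}
    elif len(usable) == 2:
        for m in markers:
            u, p = mann_whitney_u(
                records.loc[records["category"] == usable[0], m],
                records.loc[records["category"] == usable[1], m])
            across[m] = {"U": u, "p": p, "pair": tuple(usable)}

    within = {}
    for c in usable:
        sub = records[records["category"] == c]
        xm = sub[sub["idh_status"] == IDH_MUTANT]
        xw = sub[sub["idh_status"] == IDH_WILDTYPE]
        if len(xm) < 1 or len(xw) < 1:
            logger.info("category %s lacks one IDH class; within-category "
                        "comparison skipped", c)
            continue
        raws = [mann_whitney_u(xm[m], xw[m])[1] for m in markers]
        adj = benjamini_hochberg(raws)
        within[c] = pd.DataFrame({"marker": list(markers),
                                  "p_raw": raws, "p_adjusted": adj})

    overall_rows = []
    xm = records[records["idh_status"] == IDH_MUTANT]
    xw = records[records["idh_status"] == IDH_WILDTYPE]
    for m in markers:
        if len(xm) and len(xw):
            u, p = mann_whitney_u(xm[m], xw[m])
            overall_rows.append({"marker": m, "U": u, "p": p})
    overall = pd.DataFrame(overall_rows)

    summary = pd.concat([
        records.groupby("category")[list(markers)].agg(["mean", "std"]),
        records.groupby("idh_status")[list(markers)].agg(["mean", "std"]),
    ])
    return {"across_categories": across, "within_category": within,
            "overall": overall, "summary": summary}
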