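"""Diagnostics asking whether fluorescence responses need a detection limit.

If a genuine lower limit of detection (LOD) existed on the fluorescence
scale, point scatter just below it should collapse relative to scatter just
above it, rank-to-rank response differences should shrink toward zero at low
rank, and pairwise tests among low-abundance analytes should yield uniform
p-values (pure noise).  These diagnostics quantify each of those signatures:

* balanced above/below-LOD coefficient-of-variation comparisons with an
  F-test on log2 variances (per analyte x tissue), aggregated across rows by
  a Mann-Whitney rank-sum test and a paired t-test;
* the log2 rank-difference profile, whose level reveals the instrument's
  fluorescence quantization step (a flat profile at -1 = half-unit steps,
  with no approach to zero at low rank);
* a p-value uniformity scan over tissue pairs with a Kolmogorov-Smirnov
  statistic against Uniform(0,1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .plate_data import PlateDataset

logger = logging.getLogger(__name__)


@dataclass
class CVComparisonRow:
    analyte: str
    tissue: str
    lod_fl: float
    n_selected: int
    n_above: int
    n_below: int
    cv_above: float
    cv_below: float
    ratio: float
    f_pvalue: float | None


@dataclass
class CVAggregate:
    w_statistic: float
    p_mw: float
    t_statistic: float
    df: int
    p_t: float


@dataclass
class RankDiffProfile:
    ranks: np.ndarray      # 1 .. n-1
    log2_diffs: np.ndarray
    head_mean: float       # mean over the first 50% of ranks


def balanced_neighborhood(responses, lod_fl: float):
    """Select the N nearest points above and below an LOD.

    N is the minimum of the above/below counts, so the selection is balanced
    (2N points).  A value exactly at the LOD counts as "above".  Ties in
    distance are broken by the smaller value, then by input order, making
    the selection deterministic and order-invariant.
    """
    x = np.asarray(responses, dtype=float)
    above_idx = np.flatnonzero(x >= lod_fl)
    below_idx = np.flatnonzero(x < lod_fl)
    n = min(len(above_idx), len(below_idx))
    if n == 0:
        return np.array([]), np.array([]), 0

    def nearest(idx):
        vals = x[idx]
        order = np.lexsort((idx, vals, np.abs(vals - lod_fl)))
        return np.sort(vals[order[:n]])

    return nearest(above_idx), nearest(below_idx), n


def coefficient_of_variation(values) -> float:
    """Sample CV: sd (n-1 denominator) over mean, raw scale."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m = v.mean()
    if m <= 0:
        raise ValueError("mean must be positive for a CV")
    return float(v.std(ddof=1) / m)


def cv_ratio_test(above, below):
    """F-test of equal scatter above vs below an LOD.

    Equality of two CVs is tested as equality of variances of the log2
    transformed data: F = var(log2 above) / var(log2 below) with
    (n_above - 1, n_below - 1) degrees of freedom and a two-sided p-value
    equal to twice the smaller tail, capped at 1.

    Returns (cv_above, cv_below, ratio, f_pvalue); f_pvalue is None when
    either side has zero variance (degenerate).
    """
    a = np.asarray(above, dtype=float)
    b = np.asarray(below, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each side needs at least 2 values")
    cv_a = coefficient_of_variation(a)
    cv_b = coefficient_of_variation(b)
    ratio = cv_a / cv_b if cv_b > 0 else np.inf
    va = np.var(np.log2(a), ddof=1)
    vb = np.var(np.log2(b), ddof=1)
    if va == 0 or vb == 0:
        return cv_a, cv_b, ratio, None
    f = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2 * min(dist.cdf(f), dist.sf(f))
    return cv_a, cv_b, ratio, float(min(p, 1.0))


def mann_whitney(x, y):
    """Two-sided Mann-Whitney rank-sum test.

    Tie-corrected normal approximation with continuity correction when
    either sample exceeds 8 points, exact enumeration otherwise (the
    behaviour of the classical statistical packages this field uses).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "asymptotic" if (len(x) > 8 or len(y) > 8) else "exact"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                                 use_continuity=True)
    except ValueError:  # exact method refuses ties
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def aggregate_cv_comparison(rows) -> CVAggregate:
    """Aggregate a CV-comparison table across analyte x tissue rows.

    Two views are reported, mirroring common practice: a Mann-Whitney
    rank-sum test treating the log2 CVs above and below the LOD as
    independent samples, and a paired two-sided t-test on the row-wise
    log2 differences (df = rows - 1).

    ``rows`` may be a list of :class:`CVComparisonRow` or a DataFrame with
    ``cv_above`` / ``cv_below`` columns.  Rows with non-positive CVs are
    excluded with a warning.
    """
    if isinstance(rows, pd.DataFrame):
        cva = rows["cv_above"].to_numpy(dtype=float)
        cvb = rows["cv_below"].to_numpy(dtype=float)
    else:
        cva = np.array([r.cv_above for r in rows], dtype=float)
        cvb = np.array([r.cv_below for r in rows], dtype=float)
    ok = (cva > 0) & (cvb > 0) & np.isfinite(cva) & np.isfinite(cvb)
    if ok.sum() < len(cva):
        logger.warning("excluding %d rows with non-positive CVs",
                       int(len(cva) - ok.sum()))
    cva, cvb = cva[ok], cvb[ok]
    if len(cva) < 2:
        raise ValueError("need at least 2 rows with positive CVs")
    la, lb = np.log2(cva), np.log2(cvb)
    w, p_mw = mann_whitney(la, lb)
    if np.allclose(la, lb):
        t, p_t = 0.0, 1.0
    else:
        t, p_t = stats.ttest_rel(la, lb)
    return CVAggregate(w_statistic=w, p_mw=p_mw, t_statistic=float(t),
                       df=len(la) - 1, p_t=float(p_t))


def rank_difference_profile(responses) -> RankDiffProfile:
    """log2 of successive differences of the unique sorted responses.

    ``rank.diff(r) = Fl(r+1) - Fl(r)`` over the ascending unique values;
    ``head_mean`` averages the log2 differences over the first half of the
    ranks (1 .. floor((n-1)/2)), where a detection limit would pull the
    profile toward -inf and pure quantization at step s pins it at log2(s).
    """
    u = np.unique(np.asarray(responses, dtype=float))
    if u.size < 3:
        raise ValueError("need at least 3 unique responses")
    diffs = np.diff(u)
    log2_diffs = np.log2(diffs)
    n_d = len(diffs)
    head = max(n_d // 2, 1)
    return RankDiffProfile(
        ranks=np.arange(1, n_d + 1),
        log2_diffs=log2_diffs,
        head_mean=float(log2_diffs[:head].mean()),
    )


def cv_comparison_table(ds: PlateDataset, lods: dict, min_side: int = 5) -> pd.DataFrame:
    """Build a point-scatter comparison table from a mapped dataset.

    ``lods`` maps analyte -> fluorescence LOD.  For every analyte x tissue
    with at least ``min_side`` responses on each side of the LOD, the
    balanced neighborhood is selected and the CV ratio F-test run.
    """
    rows = []
    samples = ds.samples()
    for (analyte, tissue), grp in samples.groupby(["analyte", "tissue"],
                                                  observed=True):
        if analyte not in lods:
            continue
        lod = lods[analyte]
        fl = grp["fluorescence"].to_numpy(dtype=float)
        n_above = int((fl >= lod).sum())
        n_below = int((fl < lod).sum())
        if min(n_above, n_below) < min_side:
            continue
        above, below, n = balanced_neighborhood(fl, lod)
        cv_a, cv_b, ratio, p = cv_ratio_test(above, below)
        rows.append(CVComparisonRow(analyte, tissue, lod, n, n_above,
                                    n_below, cv_a, cv_b, ratio, p))
    return pd.DataFrame([r.__dict__ for r in rows])


def pvalue_uniformity_scan(ds: PlateDataset, analytes, group_factor: str = "tissue"):
    """Mann-Whitney scan across group pairs for the selected analytes.

    One two-sided Mann-Whitney p-value per analyte x unordered pair of
    ``group_factor`` levels (each side needing >= 3 samples) on log2
    fluorescence.  Under the hypothesis that low-abundance responses are
    pure noise these p-values are Uniform(0,1); returned alongside are a
    one-sample Kolmogorov-Smirnov statistic/p against that uniform and the
    fraction of p-values below 0.05.
    """
    samples = ds.samples()
    pvals = []
    detail = []
    for analyte in analytes:
        sub = samples[samples["analyte"] == analyte]
        levels = sorted(sub[group_factor].unique())
        for g1, g2 in combinations(levels, 2):
            x = sub.loc[sub[group_factor] == g1, "fluorescence"].to_numpy(float)
            y = sub.loc[sub[group_factor] == g2, "fluorescence"].to_numpy(float)
            if len(x) < 3 or len(y) < 3:
                logger.info("skipping %s %s vs %s: too few samples",
                            analyte, g1, g2)
                continue
            _, p = mann_whitney(np.log2(x), np.log2(y))
            pvals.append(p)
            detail.append((analyte, g1, g2, p))
    pvals = np.asarray(pvals)
    if pvals.size:
        ks_stat, ks_p = stats.kstest(pvals, "uniform")
        frac = float((pvals < 0.05).mean())
    else:
        ks_stat = ks_p = frac = float("nan")
    return {
        "pvalues": pvals,
        "detail": pd.DataFrame(detail, columns=["analyte", "group1", "group2", "p"]),
        "ks_statistic": float(ks_stat),
        "ks_pvalue": float(ks_p),
        "frac_below_0.05": frac,
    }


# -- printed-table fixtures -------------------------------------------------

def load_printed_point_scatter() -> pd.DataFrame:
    """Published above/below-LOD point-scatter comparison table.

    17 analyte x tissue rows with columns: analyte, tissue, lod_fl,
    n_selected, n_above, n_below, cv_above, cv_below, ratio, f_pvalue.
    The CVs are reported to 3 decimals; aggregate statistics recomputed from
    them can differ slightly from values computed on unrounded CVs.
    """
    with resources.files("fluorplex.data").joinpath(
            "printed_point_scatter.csv").open() as fh:
        return pd.read_csv(fh)


def load_printed_contrasts() -> pd.DataFrame:
    """Published significant pairwise condition-contrast table.

    56 analyte x contrast rows; fluorescence and concentration estimates,
    Wald chi-squares and Holm-adjusted p-values as printed (3 decimals).
    Missing concentration entries mark contrasts that could not be analysed
    because of censored concentration values.
    """
    with resources.files("fluorplex.data").joinpath(
            "printed_condition_contrasts.csv").open() as fh:
        return pd.read_csv(fh)
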