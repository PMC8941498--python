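"""Cross-group statistics: surface association, niche-overlap D and I,
randomization significance, categorical chi-square, and Welch t-tests.

Schoener's D and the Hellinger-based I compare two spatial surfaces after
each is min-max normalized to [0, 1] and rescaled to sum to one over the
jointly non-missing cells:

    D = 1 - 0.5 * sum_i |p_ai - p_bi|
    I = 1 - 0.5 * sum_i (sqrt(p_ai) - sqrt(p_bi))^2

Both lie in [0, 1], are symmetric, and equal 1 iff the proportion vectors are
identical.  Significance uses a permutation null: the cell values of one
surface are shuffled across its non-missing cells (destroying spatial
co-structure while preserving the value distribution) and the observed
statistic is compared to the null distribution with a one-sample t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .dispersion import DispersionClassification
from .grid_assembly import MetricSurface, normalize_surface

__all__ = [
    "AssociationResult",
    "OverlapResult",
    "CrossTab",
    "surface_association",
    "schoener_d",
    "hellinger_i",
    "overlap_null",
    "category_chisq",
    "welch_t",
]


@dataclass(frozen=True)
class AssociationResult:
    slope: float
    intercept: float
    adj_r2: float
    pearson_r: float
    p_value: float
    n: int


def surface_association(a: MetricSurface, b: MetricSurface) -> AssociationResult:
    """OLS fit b ~ a and Pearson correlation over jointly non-missing cells."""
    mask = a.mask & b.mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 jointly non-missing cells")
    x = a.values[mask]
    y = b.values[mask]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance in one of the surfaces")
    res = scipy.stats.linregress(x, y)
    n = int(mask.sum())
    r2 = res.rvalue**2
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return AssociationResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        adj_r2=float(adj_r2),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=n,
    )


def _proportions(a: MetricSurface, b: MetricSurface) -> tuple[np.ndarray, np.ndarray]:
    """[0,1]-normalized surfaces rescaled to sum 1 over jointly present cells."""
    an = normalize_surface(a)
    bn = normalize_surface(b)
    mask = an.mask & bn.mask
    if not mask.any():
        raise ValueError("surfaces share no non-missing cells")
    pa = an.values[mask]
    pb = bn.values[mask]
    if pa.sum() == 0 or pb.sum() == 0:
        raise ValueError("all-zero surface after normalization")
    return pa / pa.sum(), pb / pb.sum()


def _d_from_p(pa: np.ndarray, pb: np.ndarray) -> float:
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def _i_from_p(pa: np.ndarray, pb: np.ndarray) -> float:
    return float(1.0 - 0.5 * ((np.sqrt(pa) - np.sqrt(pb)) ** 2).sum())


def schoener_d(a: MetricSurface, b: MetricSurface) -> float:
    pa, pb = _proportions(a, b)
    return _d_from_p(pa, pb)


def hellinger_i(a: MetricSurface, b: MetricSurface) -> float:
    pa, pb = _proportions(a, b)
    return _i_from_p(pa, pb)


@dataclass
class OverlapResult:
    """Observed D and I with their permutation-null distributions.

    t/df/p compare each null distribution to the observed statistic with a
    two-sided one-sample t-test (df = n_null - 1).  ``zero_variance`` flags a
    degenerate null where the t-test is undefined.
    """

    d: float
    i: float
    null_d: np.ndarray
    null_i: np.ndarray
    t_d: float | None
    p_d: float | None
    t_i: float | None
    p_i: float | None
    df: int
    zero_variance: bool = False


def overlap_null(
    a: MetricSurface, b: MetricSurface, n_null: int = 99, seed: int = 0
) -> OverlapResult:
    """Permutation test of surface overlap.

    Surface ``b``'s values are permuted across its non-missing cells
    ``n_null`` times; D and I are recomputed each time.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    rng = np.random.default_rng([seed, 0x0E1])
    d_obs = schoener_d(a, b)
    i_obs = hellinger_i(a, b)
    null_d = np.empty(n_null)
    null_i = np.empty(n_null)
    bvals = b.values.copy()
    bmask = b.mask
    for k in range(n_null):
        perm = bvals.copy()
        perm[bmask] = rng.permutation(bvals[bmask])
        bperm = MetricSurface(grid=b.grid, values=perm, name=b.name, group=b.group)
        null_d[k] = schoener_d(a, bperm)
        null_i[k] = hellinger_i(a, bperm)
    zero_var = null_d.std(ddof=1) == 0 or null_i.std(ddof=1) == 0
    if zero_var:
        t_d = p_d = t_i = p_i = None
    else:
        rd = scipy.stats.ttest_1samp(null_d, d_obs)
        ri = scipy.stats.ttest_1samp(null_i, i_obs)
        t_d, p_d = float(rd.statistic), float(rd.pvalue)
        t_i, p_i = float(ri.statistic), float(ri.pvalue)
    return OverlapResult(
        d=d_obs,
        i=i_obs,
        null_d=null_d,
        null_i=null_i,
        t_d=t_d,
        p_d=p_d,
        t_i=t_i,
        p_i=p_i,
        df=n_null - 1,
        zero_variance=zero_var,
    )


@dataclass
class CrossTab:
    """Joint per-cell category table for two groups with its chi-square test."""

    table: np.ndarray  # 3x3 counts, rows = group A category, cols = group B
    chi2: float
    df: int
    p: float


def category_chisq(
    class_a: DispersionClassification, class_b: DispersionClassification
) -> CrossTab:
    """Pearson chi-square (no continuity correction) on the 3x3 contingency of
    per-cell joint dispersion categories; empty rows/columns are dropped
    (with a warning) before testing, so a full table has df = 4."""
    if class_a.grid != class_b.grid:
        raise ValueError("classifications are on different grids")
    mask = class_a.mask & class_b.mask
    if not mask.any():
        raise ValueError("no jointly classified cells")
    ca = class_a.category[mask].astype(int)
    cb = class_b.category[mask].astype(int)
    table = np.zeros((3, 3), dtype=int)
    np.add.at(table, (ca, cb), 1)
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("empty category rows/columns dropped before chi-square")
    sub = table[np.ix_(rows, cols)]
    res = scipy.stats.chi2_contingency(sub, correction=False)
    return CrossTab(table=table, chi2=float(res.statistic), df=int(res.dof), p=float(res.pvalue))


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, Welch-Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples: t undefined")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
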