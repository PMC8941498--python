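"""Dispersion relative to the PD ~ richness regression.

Phylogenetic dispersion is operationalised against an ordinary least-squares
regression of (across-tree mean) Faith's PD on species richness over grid
cells: a 95% band is placed around the fitted line and each cell is assigned
category 0 (below the band: underdispersed), 1 (within), or 2 (above:
overdispersed).  Categories are averaged within ecoregions and rescaled to
[-1, 1] (mean - 1), and the two taxon groups can be combined cell-wise.

Two band types are supported.  The default, ``prediction``, is the 95%
prediction interval for a new observation; with many cells it classifies
roughly 5% of on-model cells as non-neutral.  The mean-response confidence
band (``mean``) shrinks with the cell count and, at realistic grid sizes,
classifies nearly every cell as 0 or 2; it is provided for completeness.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .grid_assembly import GridSpec, MetricSurface
from .synthetic_data import EcoregionMap

__all__ = [
    "DispersionFit",
    "DispersionClassification",
    "fit_pd_richness",
    "classify_cells",
    "ecoregion_scores",
    "combine_groups",
]


@dataclass(frozen=True)
class DispersionFit:
    """OLS fit of PD on richness plus what the 95% bands need."""

    slope: float
    intercept: float
    resid_var: float  # s^2, residual mean square
    adj_r2: float
    n: int
    x_mean: float
    sxx: float  # sum of squared deviations of richness
    level: float = 0.95

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def band_halfwidth(self, x: np.ndarray, band: str = "prediction") -> np.ndarray:
        """Half-width of the confidence band at richness ``x``.

        mean:       t* s sqrt(1/n + (x - x̄)²/Sxx)
        prediction: t* s sqrt(1 + 1/n + (x - x̄)²/Sxx)
        """
        x = np.asarray(x, dtype=float)
        tcrit = scipy.stats.t.ppf(0.5 + self.level / 2, df=self.n - 2)
        leverage = 1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx
        if band == "mean":
            var = leverage
        elif band == "prediction":
            var = 1.0 + leverage
        else:
            raise ValueError(f"unknown band type {band!r}")
        return tcrit * np.sqrt(self.resid_var * var)


def fit_pd_richness(
    pd_surface: MetricSurface,
    richness_surface: MetricSurface,
    level: float = 0.95,
) -> DispersionFit:
    """OLS regression PD = b0 + b1 * richness over jointly non-missing cells."""
    mask = pd_surface.mask & richness_surface.mask
    if mask.sum() < 3:
        raise ValueError("need at least 3 cells with both PD and richness")
    y = pd_surface.values[mask]
    x = richness_surface.values[mask]
    if np.ptp(x) == 0:
        raise ValueError("richness is constant: regression undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return DispersionFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        resid_var=float(res.mse_resid),
        adj_r2=float(res.rsquared_adj),
        n=int(res.nobs),
        x_mean=float(x.mean()),
        sxx=float(((x - x.mean()) ** 2).sum()),
        level=level,
    )


@dataclass
class DispersionClassification:
    """Per-cell dispersion category: 0 under, 1 within band, 2 over.

    ``category`` is a float array with NaN for unclassified cells (missing
    PD or richness).
    """

    grid: GridSpec
    category: np.ndarray
    band: str
    level: float

    def __post_init__(self) -> None:
        self.category = np.asarray(self.category, dtype=float)
        vals = self.category[~np.isnan(self.category)]
        if not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("categories must be 0, 1 or 2")

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.category)

    def counts(self) -> np.ndarray:
        """Counts of categories [0, 1, 2] over classified cells."""
        return np.array([(self.category == c).sum() for c in (0.0, 1.0, 2.0)])

    def to_frame(self) -> pd.DataFrame:
        x, y = self.grid.cell_xy()
        return pd.DataFrame(
            {
                "cell_index": np.arange(self.grid.n_cells),
                "x": x,
                "y": y,
                "category": self.category,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="")


def classify_cells(
    fit: DispersionFit,
    pd_surface: MetricSurface,
    richness_surface: MetricSurface,
    band: str = "prediction",
) -> DispersionClassification:
    """Assign each cell 0/1/2 against the fitted band at its richness."""
    if band not in ("prediction", "mean"):
        raise ValueError(f"unknown band type {band!r}")
    mask = pd_surface.mask & richness_surface.mask
    cat = np.full(pd_surface.grid.n_cells, np.nan)
    x = richness_surface.values[mask]
    y = pd_surface.values[mask]
    center = fit.predict(x)
    half = fit.band_halfwidth(x, band=band)
    c = np.ones(mask.sum())
    c[y < center - half] = 0.0
    c[y > center + half] = 2.0
    cat[mask] = c
    return DispersionClassification(
        grid=pd_surface.grid, category=cat, band=band, level=fit.level
    )


def ecoregion_scores(
    classification: DispersionClassification, ecoregions: EcoregionMap
) -> pd.DataFrame:
    """Mean category and rescaled score (mean - 1, in [-1, 1]) per ecoregion.

    Ecoregions with no classified cells get missing scores.
    """
    if len(ecoregions.region_of) != classification.grid.n_cells:
        raise ValueError("ecoregion map does not match the classification grid")
    df = pd.DataFrame(
        {"ecoregion_id": ecoregions.region_of, "category": classification.category}
    )
    grouped = df.groupby("ecoregion_id")["category"].agg(
        n_cells="count", mean_category="mean"
    )
    grouped = grouped.reset_index()
    grouped["rescaled_score"] = grouped["mean_category"] - 1.0
    return grouped


def combine_groups(
    class_a: DispersionClassification,
    class_b: DispersionClassification,
    ecoregions: EcoregionMap | None = None,
) -> tuple[np.ndarray, pd.DataFrame | None]:
    """Combine two groups' dispersion patterns.

    Per cell: the mean of the two categories (range [0, 2]; 0 = most
    underdispersed in both groups), missing wherever either group is
    unclassified.  If an ecoregion map is given, also returns a per-ecoregion
    table whose combined rescaled score is the mean of the two groups'
    rescaled scores.
    """
    if class_a.grid != class_b.grid:
        raise ValueError("classifications are on different grids")
    combined = np.where(
        class_a.mask & class_b.mask,
        (class_a.category + class_b.category) / 2.0,
        np.nan,
    )
    table = None
    if ecoregions is not None:
        ta = ecoregion_scores(class_a, ecoregions).set_index("ecoregion_id")
        tb = ecoregion_scores(class_b, ecoregions).set_index("ecoregion_id")
        table = pd.DataFrame(
            {
                "rescaled_score_a": ta["rescaled_score"],
                "rescaled_score_b": tb["rescaled_score"],
            }
        )
        table["combined_rescaled_score"] = (
            table["rescaled_score_a"] + table["rescaled_score_b"]
        ) / 2.0
        table = table.reset_index()
    return combined, table
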