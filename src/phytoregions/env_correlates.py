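"""Environmental profiling of regions with the Getis-Ord Gi* statistic.

Environmental point values (or fine-lattice raster samples) are averaged
to the analysis grid cells; each (region, variable) pair is then scored
with the standardized Getis-Ord Gi* statistic using binary membership
weights over the whole region:

    z = (sum_{j in region} x_j - m * xbar) / (S * sqrt((n*m - m^2) / (n - 1)))

with n the number of cells with values, m the region size, xbar the global
mean and S the global *population* standard deviation.  z measures how
far the region's summed values sit above or below what a random set of m
cells would give; |z| > 2 is treated as significant (alpha < 0.05).  No
multiple-testing correction is applied by default (a Bonferroni option
exists).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clustering import RegionClassification
from .occurrence_grid import GridSpec

__all__ = ["EnvCellTable", "GiResult", "aggregate_env", "gi_star",
           "region_env_profile", "read_env_table", "write_env_table",
           "write_profile"]

logger = logging.getLogger(__name__)

SIGNIFICANCE_Z = 2.0


class DegenerateStatisticError(ValueError):
    """Gi* denominator is zero (no variance, or the region is the whole grid)."""


@dataclass
class EnvCellTable:
    """Cell-mean environmental values: a DataFrame indexed by (row, col) cells.

    Columns are variables in their native units; missing cells are NaN and
    are excluded from all statistics (the global support shrinks).
    """

    values: pd.DataFrame

    def __post_init__(self):
        if not isinstance(self.values.index, pd.MultiIndex):
            raise ValueError("values must be indexed by (row, col) cell tuples")

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def column(self, variable: str) -> pd.Series:
        s = self.values[variable]
        n_missing = int(s.isna().sum())
        if n_missing:
            logger.info("variable %s: %d cells missing, excluded", variable, n_missing)
        return s.dropna()


@dataclass(frozen=True)
class GiResult:
    region: object
    variable: str
    z: float
    significant: bool
    n_cells: int


def aggregate_env(points: pd.DataFrame, grid: GridSpec) -> EnvCellTable:
    """Cell means of point-sampled environmental variables.

    ``points`` has projected ``x``/``y`` columns plus one column per
    variable; every source value whose location falls in a cell
    contributes to that cell's arithmetic mean.  Cells with no source
    values are flagged missing (all-NaN rows over the grid extent).
    """
    if not {"x", "y"}.issubset(points.columns):
        raise ValueError("points table needs projected x and y columns")
    row, col = grid.cell_index(points["x"].to_numpy(), points["y"].to_numpy())
    in_extent = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    if not in_extent.any():
        raise ValueError("no environmental values fall inside the grid extent "
                         "(extent or CRS mismatch?)")
    var_cols = [c for c in points.columns if c not in ("x", "y")]
    df = points.loc[in_extent, var_cols].copy()
    df["_row"] = row[in_extent]
    df["_col"] = col[in_extent]
    means = df.groupby(["_row", "_col"]).mean()
    full_index = pd.MultiIndex.from_product(
        [range(grid.n_rows), range(grid.n_cols)], names=["_row", "_col"])
    means = means.reindex(full_index)
    n_missing = int(means.isna().all(axis=1).sum())
    if n_missing:
        logger.info("%d grid cells have no environmental samples", n_missing)
    return EnvCellTable(values=means)


def gi_star(env: EnvCellTable, region_cells, variable: str) -> GiResult:
    """Getis-Ord Gi* z-score of one region for one variable.

    The "neighborhood" is the region itself (binary weights), and the
    null reference is the global distribution of cell values.  Raises
    :class:`DegenerateStatisticError` when the global variance is zero or
    the region covers every cell with data.
    """
    col = env.column(variable)
    x = col.to_numpy(dtype=float)
    n = len(x)
    if n < 2:
        raise DegenerateStatisticError("need at least 2 cells with values")
    region = set(tuple(c) for c in region_cells)
    member = np.array([tuple(c) in region for c in col.index])
    m = int(member.sum())
    if m == 0:
        raise ValueError(f"region has no cells with values for {variable}")
    if m == n:
        raise DegenerateStatisticError("region covers the entire support (m = n)")
    xbar = x.mean()
    S = x.std()  # population standard deviation
    if S <= 0:
        raise DegenerateStatisticError(f"zero variance in {variable}")
    num = x[member].sum() - xbar * m
    den = S * np.sqrt((n * m - m**2) / (n - 1))
    z = float(num / den)
    return GiResult(region=None, variable=variable, z=z,
                    significant=abs(z) > SIGNIFICANCE_Z, n_cells=m)


def region_env_profile(env: EnvCellTable, classification: RegionClassification,
                       bonferroni: bool = False) -> pd.DataFrame:
    """Gi* score of every (region, variable) pair.

    Returns a tidy table with columns region, variable, z, significant,
    n_cells, most_extreme (flagging, per region, the variable with the
    largest |z|).  Degenerate pairs are kept with NaN z and an ``error``
    note rather than aborting the rest.  With ``bonferroni=True`` the
    significance flag uses the two-sided normal cutoff for 0.05 divided
    by the number of scored pairs.
    """
    regions = sorted(set(classification.labels.values()) - {-1}, key=str)
    cells_by_region = {g: [c for c, lab in classification.labels.items() if lab == g]
                       for g in regions}
    rows = []
    for g in regions:
        for var in env.variables:
            try:
                res = gi_star(env, cells_by_region[g], var)
                rows.append({"region": g, "variable": var, "z": res.z,
                             "n_cells": res.n_cells, "error": ""})
            except (DegenerateStatisticError, ValueError) as exc:
                rows.append({"region": g, "variable": var, "z": np.nan,
                             "n_cells": len(cells_by_region[g]), "error": str(exc)})
    out = pd.DataFrame(rows)
    cutoff = SIGNIFICANCE_Z
    if bonferroni:
        from scipy.stats import norm
        n_tests = int(out["z"].notna().sum())
        cutoff = float(norm.isf(0.05 / n_tests / 2.0)) if n_tests else np.inf
    out["significant"] = out["z"].abs() > cutoff
    out["most_extreme"] = False
    for g in regions:
        sub = out[(out["region"] == g) & out["z"].notna()]
        if len(sub):
            out.loc[sub["z"].abs().idxmax(), "most_extreme"] = True
    return out


def read_env_table(path) -> EnvCellTable:
    """Read a cell-value table (cell_row, cell_col, one column per variable)."""
    df = pd.read_csv(path)
    if not {"cell_row", "cell_col"}.issubset(df.columns):
        raise ValueError("env table needs cell_row and cell_col columns")
    df = df.set_index(["cell_row", "cell_col"])
    df.index.names = ["_row", "_col"]
    return EnvCellTable(values=df)


def write_env_table(env: EnvCellTable, path) -> None:
    """Write a cell-value table readable by :func:`read_env_table`."""
    out = env.values.copy()
    out.index.names = ["cell_row", "cell_col"]
    out.reset_index().to_csv(path, index=False)


def write_profile(profile: pd.DataFrame, path) -> None:
    """Write the regions-x-variables z-score matrix, significance starred."""
    wide = profile.pivot(index="variable", columns="region", values="z")
    sig = profile.pivot(index="variable", columns="region", values="significant")
    starred = wide.round(2).astype(str)
    starred = starred.where(~sig, starred + "*")
    starred.to_csv(path)
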