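"""Occurrence-record ingest, cleaning, equal-area projection and gridding.

The unit of analysis downstream is the grid cell: point records of species
observations are cleaned, projected onto an equal-area plane and aggregated
into square cells (default 100 km x 100 km), producing a binary
site-by-species incidence matrix.  Sampling completeness per cell is
summarised by redundancy, 1 - richness/records: a cell where every record
is a new species (redundancy 0) is badly undersampled, while repeated
recording of the same species (redundancy near 1) indicates the species
list is close to complete.

Records are handled as a pandas DataFrame with columns
``raw_name, species, lon, lat`` and, after projection, ``x, y`` — one row
per occurrence record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .projection import AlbersEqualArea, AUSTRALIAN_ALBERS

__all__ = [
    "GridSpec",
    "SiteBySpeciesMatrix",
    "RedundancyReport",
    "normalize_name",
    "read_occurrences",
    "read_mask",
    "clean_records",
    "project_records",
    "grid_records",
    "redundancy",
    "write_matrix",
    "read_matrix",
]

# Rank markers at or below which a name stops being a binomial.
_INFRASPECIFIC_MARKERS = {
    "subsp.", "subsp", "ssp.", "ssp", "var.", "var", "f.", "forma",
    "subvar.", "subvar", "cv.", "cv", "x",
}
_EPITHET_RE = re.compile(r"^[a-z][a-z-]+$")

REASON_INVALID_NAME = "invalid_name"
REASON_MISSING_COORDINATES = "missing_coordinates"
REASON_OUTSIDE_MASK = "outside_mask"
REASON_SPATIAL_OUTLIER = "spatial_outlier"


class DegenerateCellError(ValueError):
    """A grid cell with no species presence reached a computation that forbids it."""


class GridExtentError(ValueError):
    """Records fall outside the declared grid extent."""


def normalize_name(raw_name: str) -> str | None:
    """Reduce a taxon name to a normalized species binomial.

    Infraspecific qualifiers (``subsp.``, ``var.``, ``f.`` ...) and anything
    after them are dropped, the genus is capitalised and the epithet
    lower-cased.  Returns ``None`` (a rejection signal) for names that do
    not resolve to two tokens — e.g. bare genera or epithets like ``sp.``.

    Raises ``ValueError`` on empty input.
    """
    if raw_name is None or not str(raw_name).strip():
        raise ValueError("empty taxon name")
    tokens = str(raw_name).split()
    kept: list[str] = []
    for tok in tokens:
        if tok.lower() in _INFRASPECIFIC_MARKERS:
            break
        kept.append(tok)
        if len(kept) == 2:
            break
    if len(kept) < 2:
        return None
    genus = kept[0].capitalize()
    epithet = kept[1].lower()
    if not genus[0].isalpha() or not _EPITHET_RE.match(epithet):
        return None
    return f"{genus} {epithet}"


@dataclass(frozen=True)
class GridSpec:
    """Square-cell grid on an equal-area plane.

    Cells are half-open squares ``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s,
    y0 + (i+1)*s)`` identified by 0-based ``(row, col)`` with row indexing
    y; ordering is row-major.
    """

    cell_size: float = 100_000.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    n_rows: int = 0
    n_cols: int = 0
    projection: AlbersEqualArea = field(default_factory=lambda: AUSTRALIAN_ALBERS)

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @classmethod
    def from_points(cls, x, y, cell_size: float = 100_000.0,
                    projection: AlbersEqualArea = AUSTRALIAN_ALBERS) -> "GridSpec":
        """Smallest grid (origin snapped to cell_size multiples) covering the points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ox = np.floor(x.min() / cell_size) * cell_size
        oy = np.floor(y.min() / cell_size) * cell_size
        n_cols = int(np.floor((x.max() - ox) / cell_size)) + 1
        n_rows = int(np.floor((y.max() - oy) / cell_size)) + 1
        return cls(cell_size=cell_size, origin_x=float(ox), origin_y=float(oy),
                   n_rows=n_rows, n_cols=n_cols, projection=projection)

    def cell_index(self, x, y):
        """Half-open cell assignment: boundary points go to the higher cell."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y, dtype=float) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def cell_center(self, row, col):
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y + (np.asarray(row) + 0.5) * self.cell_size
        return x, y


@dataclass
class SiteBySpeciesMatrix:
    """Binary incidence of species across grid cells.

    ``presence`` is a dense boolean array, cells x species; only cells
    with at least one record are retained.  ``records_per_cell`` keeps the
    raw record counts (duplicates included) for redundancy computation.
    """

    cells: list[tuple[int, int]]
    species: list[str]
    presence: np.ndarray
    records_per_cell: np.ndarray

    def __post_init__(self):
        self.presence = np.asarray(self.presence, dtype=bool)
        self.records_per_cell = np.asarray(self.records_per_cell, dtype=int)
        n_cells, n_species = self.presence.shape
        if n_cells != len(self.cells) or n_species != len(self.species):
            raise ValueError("presence shape does not match cell/species labels")
        if n_cells and not self.presence.any(axis=1).all():
            empty = [self.cells[i] for i in np.flatnonzero(~self.presence.any(axis=1))]
            raise DegenerateCellError(f"cells with no species presence: {empty[:5]}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def richness_per_cell(self) -> np.ndarray:
        return self.presence.sum(axis=1)

    def species_set(self, cell: tuple[int, int]) -> frozenset[str]:
        i = self.cells.index(cell)
        return frozenset(np.asarray(self.species)[self.presence[i]])

    def cell_order(self) -> list[int]:
        """Indices that sort cells row-major."""
        return sorted(range(self.n_cells), key=lambda i: self.cells[i])


@dataclass(frozen=True)
class RedundancyReport:
    """Per-cell sampling redundancy and the fraction of well-sampled cells."""

    per_cell: pd.Series
    threshold: float
    fraction_at_or_above: float


def read_occurrences(path, species_col: str = "species", lon_col: str = "longitude",
                     lat_col: str = "latitude", delimiter: str = ",",
                     coords: str = "lonlat") -> pd.DataFrame:
    """Read a delimited occurrence file into the record DataFrame.

    ``coords='lonlat'`` expects geographic coordinates (to be projected);
    ``coords='projected'`` expects planar meters already in the analysis
    projection, stored straight into ``x``/``y``.
    """
    if coords not in ("lonlat", "projected"):
        raise ValueError("coords must be 'lonlat' or 'projected'")
    raw = pd.read_csv(path, delimiter=delimiter, dtype={species_col: str})
    for c in (species_col, lon_col, lat_col):
        if c not in raw.columns:
            raise ValueError(f"missing column {c!r} in {path}")
    out = pd.DataFrame({
        "raw_name": raw[species_col].astype(str),
        "lon": pd.to_numeric(raw[lon_col], errors="coerce"),
        "lat": pd.to_numeric(raw[lat_col], errors="coerce"),
    })
    if coords == "projected":
        out = out.rename(columns={"lon": "x", "lat": "y"})
        out["lon"] = np.nan
        out["lat"] = np.nan
    return out


def read_mask(path):
    """Read a land mask as WKT text (one geometry per line; blank lines ignored)."""
    geoms = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                geoms.append(shapely.from_wkt(line))
    if not geoms:
        raise ValueError(f"no geometries in mask file {path}")
    return shapely.unary_union(geoms)


def clean_records(records: pd.DataFrame, mask=None, outlier_sd: float | None = None,
                  projection: AlbersEqualArea = AUSTRALIAN_ALBERS
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate names and coordinates; return (survivors, rejection log).

    Applied in order: name normalization (rows whose name does not reduce
    to a binomial are rejected), coordinate presence/range, the optional
    geographic mask, and the optional per-species spatial-outlier rule.
    The outlier rule drops records whose distance from their species'
    centroid (in projected meters) exceeds ``outlier_sd`` times the
    population standard deviation of those distances; species with fewer
    than 3 records, or with zero distance spread, are left untouched.

    Survivor order follows input order; survivors + rejects partition the
    input exactly, and the log carries a ``reason`` column.
    """
    if outlier_sd is not None and outlier_sd <= 0:
        raise ValueError("outlier_sd must be positive")
    df = records.copy()
    reason = pd.Series(pd.NA, index=df.index, dtype="object")

    species = df["raw_name"].map(lambda s: normalize_name(s) if str(s).strip() else None)
    reason[species.isna()] = REASON_INVALID_NAME
    df["species"] = species

    has_projected = "x" in df.columns and df["x"].notna().all()
    if has_projected:
        coord_ok = df["x"].notna() & df["y"].notna() & np.isfinite(df["x"]) & np.isfinite(df["y"])
    else:
        coord_ok = (
            df["lon"].notna() & df["lat"].notna()
            & df["lon"].between(-180, 180) & df["lat"].between(-90, 90)
        )
    reason[reason.isna() & ~coord_ok] = REASON_MISSING_COORDINATES

    if mask is not None:
        cand = reason.isna()
        if has_projected:
            lon, lat = projection.inverse(df.loc[cand, "x"].to_numpy(),
                                          df.loc[cand, "y"].to_numpy())
        else:
            lon = df.loc[cand, "lon"].to_numpy()
            lat = df.loc[cand, "lat"].to_numpy()
        inside = shapely.intersects_xy(mask, lon, lat)
        reason.loc[cand[cand].index[~inside]] = REASON_OUTSIDE_MASK

    if outlier_sd is not None:
        cand = reason.isna()
        sub = df.loc[cand]
        if has_projected:
            px, py = sub["x"].to_numpy(), sub["y"].to_numpy()
        else:
            px, py = projection.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
        pos = pd.DataFrame({"species": sub["species"].to_numpy(), "px": px, "py": py},
                           index=sub.index)
        for _, grp in pos.groupby("species", sort=False):
            if len(grp) < 3:
                continue
            cx, cy = grp["px"].mean(), grp["py"].mean()
            d = np.hypot(grp["px"] - cx, grp["py"] - cy)
            sd = float(np.std(d))  # population SD of centroid distances
            if sd <= 0:
                continue
            out = d > outlier_sd * sd
            reason.loc[grp.index[out]] = REASON_SPATIAL_OUTLIER

    rejects = df.loc[reason.notna()].copy()
    rejects["reason"] = reason[reason.notna()]
    survivors = df.loc[reason.isna()].copy()
    return survivors, rejects


def project_records(records: pd.DataFrame,
                    projection: AlbersEqualArea = AUSTRALIAN_ALBERS) -> pd.DataFrame:
    """Fill ``x``/``y`` with the forward equal-area projection of lon/lat."""
    out = records.copy()
    if "x" in out.columns and out["x"].notna().all() and len(out):
        return out
    x, y = projection.forward(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["x"] = x
    out["y"] = y
    return out


def grid_records(records: pd.DataFrame, grid: GridSpec) -> SiteBySpeciesMatrix:
    """Aggregate projected records into the binary site-by-species matrix.

    Duplicate (cell, species) records collapse to a single presence but
    still count toward ``records_per_cell``.  Cells without records are
    simply absent from the matrix.  Records outside the grid extent raise
    :class:`GridExtentError`.
    """
    if "x" not in records.columns or records["x"].isna().any():
        raise ValueError("records must be projected before gridding")
    if "species" not in records.columns:
        raise ValueError("records must carry normalized species names")
    row, col = grid.cell_index(records["x"].to_numpy(), records["y"].to_numpy())
    if grid.n_rows and grid.n_cols:
        bad = (row < 0) | (row >= grid.n_rows) | (col < 0) | (col >= grid.n_cols)
        if bad.any():
            offenders = records.index[bad][:10].tolist()
            raise GridExtentError(f"records outside grid extent at rows {offenders}")
    df = pd.DataFrame({"row": row, "col": col, "species": records["species"].to_numpy()})
    cells = sorted(set(zip(df["row"], df["col"])))
    cell_idx = {c: i for i, c in enumerate(cells)}
    species = sorted(df["species"].unique())
    sp_idx = {s: j for j, s in enumerate(species)}
    presence = np.zeros((len(cells), len(species)), dtype=bool)
    counts = np.zeros(len(cells), dtype=int)
    ci = np.array([cell_idx[c] for c in zip(df["row"], df["col"])])
    sj = np.array([sp_idx[s] for s in df["species"]])
    presence[ci, sj] = True
    np.add.at(counts, ci, 1)
    return SiteBySpeciesMatrix(cells=cells, species=species,
                               presence=presence, records_per_cell=counts)


def redundancy(matrix: SiteBySpeciesMatrix, threshold: float = 0.6) -> RedundancyReport:
    """Per-cell redundancy 1 - richness/records and the well-sampled fraction.

    Redundancy 0 means every record added a new species (no evidence the
    inventory is complete); values near 1 mean heavy resampling of a known
    flora.  The report's headline number is the fraction of cells at or
    above ``threshold``.
    """
    rich = matrix.richness_per_cell
    recs = matrix.records_per_cell
    if np.any(recs < rich) or np.any(rich < 1):
        raise ValueError("inconsistent matrix: need records >= richness >= 1 per cell")
    red = 1.0 - rich / recs
    index = pd.MultiIndex.from_tuples(matrix.cells, names=["cell_row", "cell_col"]) \
        if matrix.cells and isinstance(matrix.cells[0], tuple) \
        else pd.Index(matrix.cells, name="cell")
    per_cell = pd.Series(red, index=index, name="redundancy")
    frac = float(np.mean(red >= threshold)) if len(red) else 0.0
    return RedundancyReport(per_cell=per_cell, threshold=threshold, fraction_at_or_above=frac)


def write_matrix(matrix: SiteBySpeciesMatrix, path) -> None:
    """Write the incidence matrix as a sparse triplet table (one presence per line)."""
    rows = []
    for i, (r, c) in enumerate(matrix.cells):
        for j in np.flatnonzero(matrix.presence[i]):
            rows.append((r, c, matrix.species[j], matrix.records_per_cell[i]))
    pd.DataFrame(rows, columns=["cell_row", "cell_col", "species", "cell_records"]) \
        .to_csv(path, index=False)


def read_matrix(path) -> SiteBySpeciesMatrix:
    df = pd.read_csv(path)
    cells = sorted(set(zip(df["cell_row"].astype(int), df["cell_col"].astype(int))))
    species = sorted(df["species"].unique())
    cell_idx = {c: i for i, c in enumerate(cells)}
    sp_idx = {s: j for j, s in enumerate(species)}
    presence = np.zeros((len(cells), len(species)), dtype=bool)
    counts = np.zeros(len(cells), dtype=int)
    for row in df.itertuples(index=False):
        i = cell_idx[(int(row.cell_row), int(row.cell_col))]
        presence[i, sp_idx[row.species]] = True
        counts[i] = int(row.cell_records)
    return SiteBySpeciesMatrix(cells=cells, species=species,
                               presence=presence, records_per_cell=counts)
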