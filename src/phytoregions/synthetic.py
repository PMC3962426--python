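"""Synthetic occurrence data with planted regional structure.

Every pipeline stage needs ground truth to be testable: this module
generates point occurrence records whose species pools are organised into
planted, (near-)contiguous regions, together with distorted reference
classifications and environmental layers with known per-region offsets.
The generative model:

* the grid is partitioned into ``n_regions`` contiguous rectangular blocks
  (or Voronoi cells of random seeds, for irregular layouts);
* each region owns a pool of ``pool_size_per_region`` species; a fraction
  ``shared_fraction`` of each pool is also planted into one adjacent
  region's pool (emulating range overlap at region boundaries);
* each pool species occurs in each cell of its region(s) independently
  with probability ``occupancy_prob`` (the planted incidence);
* each cell yields a Poisson(``records_per_cell_mean``) number of records;
  each record is a uniform draw from the species actually present in the
  cell, except with probability ``noise_record_prob`` it is drawn from the
  global pool regardless (mis-identifications, vagrants, georeferencing
  blunders);
* record coordinates are the cell center plus uniform jitter, emitted in
  the projected plane directly or inverse-projected to longitude/latitude
  so the full ingest path can be exercised.

All randomness derives from ``scenario.seed`` through independent named
streams, so identical parameters reproduce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from string import ascii_lowercase

import numpy as np
import pandas as pd

from .clustering import RegionClassification
from .env_correlates import EnvCellTable
from .occurrence_grid import GridSpec, SiteBySpeciesMatrix
from .projection import AlbersEqualArea, AUSTRALIAN_ALBERS

__all__ = [
    "SyntheticScenario", "SyntheticEnvironment",
    "region_layout", "species_pools", "planted_incidence",
    "planted_classification", "generate_occurrences",
    "generate_reference_classification", "generate_environment",
    "write_occurrences",
]

# independent substreams of scenario.seed
_STREAM_INCIDENCE = 0
_STREAM_RECORDS = 1
_STREAM_REFERENCE = 2
_STREAM_ENVIRONMENT = 3
_STREAM_LAYOUT = 4
_STREAM_POOLS = 5


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of the planted-region sampling model.

    Defaults are the package's standard study conditions: a 20 x 25 grid
    of 100 km cells (500 cells, the same order of magnitude as a
    continental analysis), six regions, 100 species per regional pool,
    occupancy 0.8, 10% pool sharing with neighbours, 5% noise records and
    a mean of 200 records per cell (which puts per-cell sampling
    redundancy near 0.6).
    """

    grid_rows: int = 20
    grid_cols: int = 25
    n_regions: int = 6
    pool_size_per_region: int = 100
    shared_fraction: float = 0.1
    occupancy_prob: float = 0.8
    records_per_cell_mean: float = 200.0
    noise_record_prob: float = 0.05
    seed: int = 0
    layout: str = "blocks"  # or "voronoi"
    cell_size: float = 100_000.0
    projection: AlbersEqualArea = field(default_factory=lambda: AUSTRALIAN_ALBERS)

    def __post_init__(self):
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if not 1 <= self.n_regions <= self.grid_rows * self.grid_cols:
            raise ValueError("n_regions must be in [1, n_cells]")
        if self.pool_size_per_region < 1:
            raise ValueError("pool_size_per_region must be positive")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ValueError("shared_fraction must be in [0, 1]")
        if not 0.0 < self.occupancy_prob <= 1.0:
            raise ValueError("occupancy_prob must be in (0, 1]")
        if self.records_per_cell_mean <= 0:
            raise ValueError("records_per_cell_mean must be positive")
        if not 0.0 <= self.noise_record_prob < 1.0:
            raise ValueError("noise_record_prob must be in [0, 1)")
        if self.layout not in ("blocks", "voronoi"):
            raise ValueError("layout must be 'blocks' or 'voronoi'")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))

    def grid_spec(self) -> GridSpec:
        return GridSpec(cell_size=self.cell_size, origin_x=0.0, origin_y=0.0,
                        n_rows=self.grid_rows, n_cols=self.grid_cols,
                        projection=self.projection)


@dataclass(frozen=True)
class SyntheticEnvironment:
    """Generated environmental layers plus the planted offsets behind them.

    ``offsets`` records, per variable, the per-region additive offset, so
    tests know the expected sign of every region's Gi* score in advance.
    """

    table: EnvCellTable
    offsets: dict
    gradient_slope: dict
    noise_sd: float


def _species_name(region: int, index: int) -> str:
    """Deterministic binomial-shaped name, letters only (survives name cleaning)."""
    genus = "Pool" + ascii_lowercase[region % 26] + ascii_lowercase[region // 26]
    digits = []
    i = index
    for _ in range(4):
        digits.append(ascii_lowercase[i % 26])
        i //= 26
    return f"{genus.capitalize()} {''.join(reversed(digits))}"


def region_layout(scenario: SyntheticScenario) -> np.ndarray:
    """Region index of every cell, as a (rows, cols) integer array.

    Block layout partitions the grid into near-square contiguous
    rectangles; the Voronoi layout assigns each cell to its nearest of
    ``n_regions`` random seed cells (ties to the lower region index).
    """
    R, C, k = scenario.grid_rows, scenario.grid_cols, scenario.n_regions
    if scenario.layout == "voronoi":
        rng = scenario.rng(_STREAM_LAYOUT)
        flat = rng.choice(R * C, size=k, replace=False)
        seeds = np.stack([flat // C, flat % C], axis=1)
        rr, cc = np.meshgrid(np.arange(R), np.arange(C), indexing="ij")
        d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
        return d2.argmin(axis=2).astype(int)
    # most-square factorisation p x q = k relative to the grid aspect
    best = None
    for p in range(1, k + 1):
        if k % p:
            continue
        q = k // p
        if p > R or q > C:
            continue
        score = abs(np.log((R / p) / (C / q)))
        if best is None or score < best[0]:
            best = (score, p, q)
    if best is None:
        raise ValueError("cannot lay out this many rectangular regions on the grid")
    _, p, q = best
    row_edges = np.linspace(0, R, p + 1).round().astype(int)
    col_edges = np.linspace(0, C, q + 1).round().astype(int)
    out = np.empty((R, C), dtype=int)
    for bi in range(p):
        for bj in range(q):
            out[row_edges[bi]:row_edges[bi + 1],
                col_edges[bj]:col_edges[bj + 1]] = bi * q + bj
    return out


def _region_adjacency(layout: np.ndarray) -> dict:
    adj: dict = {g: set() for g in np.unique(layout)}
    R, C = layout.shape
    for r in range(R):
        for c in range(C):
            g = layout[r, c]
            if r + 1 < R and layout[r + 1, c] != g:
                adj[g].add(layout[r + 1, c])
                adj[layout[r + 1, c]].add(g)
            if c + 1 < C and layout[r, c + 1] != g:
                adj[g].add(layout[r, c + 1])
                adj[layout[r, c + 1]].add(g)
    return adj


def species_pools(scenario: SyntheticScenario) -> dict:
    """Species pool of each region: its own species plus shared incomers.

    Each region owns ``pool_size_per_region`` species; the first
    ``round(shared_fraction * pool_size)`` of them are additionally planted
    into one uniformly chosen adjacent region's pool (endemic + shared
    fractions of each pool sum to 1 by construction).
    """
    layout = region_layout(scenario)
    adj = _region_adjacency(layout)
    rng = scenario.rng(_STREAM_POOLS)
    pools = {g: [_species_name(g, i) for i in range(scenario.pool_size_per_region)]
             for g in range(scenario.n_regions)}
    n_shared = int(round(scenario.shared_fraction * scenario.pool_size_per_region))
    for g in range(scenario.n_regions):
        neighbours = sorted(adj.get(g, ()))
        if not neighbours:
            continue
        for sp in pools[g][:n_shared]:
            target = int(neighbours[rng.integers(len(neighbours))])
            pools[target].append(sp)
    return {g: sorted(set(pool)) for g, pool in pools.items()}


def planted_incidence(scenario: SyntheticScenario) -> SiteBySpeciesMatrix:
    """The planted presence/absence ground truth over all grid cells.

    Each cell's candidate species are its region's pool; each is present
    with probability ``occupancy_prob``.  A cell left empty by sampling
    (possible only at low occupancy x small pools) gets one uniformly
    chosen pool species so the incidence matrix stays valid.
    """
    layout = region_layout(scenario)
    pools = species_pools(scenario)
    species = sorted({sp for pool in pools.values() for sp in pool})
    sp_idx = {s: j for j, s in enumerate(species)}
    cells = [(r, c) for r in range(scenario.grid_rows) for c in range(scenario.grid_cols)]
    rng = scenario.rng(_STREAM_INCIDENCE)
    presence = np.zeros((len(cells), len(species)), dtype=bool)
    for i, (r, c) in enumerate(cells):
        pool = pools[int(layout[r, c])]
        draws = rng.random(len(pool)) < scenario.occupancy_prob
        if not draws.any():
            draws[rng.integers(len(pool))] = True
        for sp, hit in zip(pool, draws):
            if hit:
                presence[i, sp_idx[sp]] = True
    return SiteBySpeciesMatrix(cells=cells, species=species, presence=presence,
                               records_per_cell=presence.sum(axis=1))


def planted_classification(scenario: SyntheticScenario) -> RegionClassification:
    layout = region_layout(scenario)
    labels = {(r, c): int(layout[r, c])
              for r in range(scenario.grid_rows) for c in range(scenario.grid_cols)}
    return RegionClassification(labels=labels, k=scenario.n_regions,
                                provenance="planted")


def generate_occurrences(scenario: SyntheticScenario, emit: str = "projected",
                         ensure_coverage: bool = False) -> pd.DataFrame:
    """Sample occurrence records from the planted model.

    Returns a record DataFrame with ``species``, projected ``x``/``y``
    and — with ``emit='lonlat'`` — inverse-projected ``lon``/``lat``
    columns.  ``ensure_coverage=True`` appends one record per present
    species missing from a cell's sample, making the gridded incidence
    reproduce the planted incidence exactly (at the cost of record counts
    exceeding the Poisson law).
    """
    if emit not in ("projected", "lonlat"):
        raise ValueError("emit must be 'projected' or 'lonlat'")
    truth = planted_incidence(scenario)
    species_arr = np.asarray(truth.species)
    rng = scenario.rng(_STREAM_RECORDS)
    cs = scenario.cell_size
    rows = []
    for i, (r, c) in enumerate(truth.cells):
        present = np.flatnonzero(truth.presence[i])
        n_rec = int(rng.poisson(scenario.records_per_cell_mean))
        if n_rec:
            noise = rng.random(n_rec) < scenario.noise_record_prob
            picks = np.empty(n_rec, dtype=int)
            n_noise = int(noise.sum())
            if n_noise:
                picks[noise] = rng.integers(len(species_arr), size=n_noise)
            if n_rec - n_noise:
                picks[~noise] = present[rng.integers(len(present), size=n_rec - n_noise)]
        else:
            picks = np.empty(0, dtype=int)
        if ensure_coverage:
            missing = np.setdiff1d(present, picks)
            picks = np.concatenate([picks, missing])
        if not len(picks):
            continue
        u = rng.uniform(0.05, 0.95, size=(len(picks), 2))
        x = (c + u[:, 0]) * cs
        y = (r + u[:, 1]) * cs
        rows.append(pd.DataFrame({"species": species_arr[picks], "x": x, "y": y}))
    records = pd.concat(rows, ignore_index=True)
    if emit == "lonlat":
        lon, lat = scenario.projection.inverse(records["x"].to_numpy(),
                                               records["y"].to_numpy())
        records["lon"] = lon
        records["lat"] = lat
    return records


def generate_reference_classification(scenario: SyntheticScenario,
                                      distortion_fraction: float = 0.0
                                      ) -> RegionClassification:
    """The planted layout with a fraction of cells flipped to a neighbour's label.

    Exactly ``round(distortion_fraction * n_cells)`` cells, chosen without
    replacement, are relabelled to the label of one of their region's
    adjacent regions (uniformly); with a single region the layout is
    returned unchanged.  Emulates an independently drawn historical
    reference scheme that broadly agrees with the planted structure.
    """
    if not 0.0 <= distortion_fraction <= 1.0:
        raise ValueError("distortion_fraction must be in [0, 1]")
    layout = region_layout(scenario)
    adj = _region_adjacency(layout)
    labels = {(r, c): int(layout[r, c])
              for r in range(scenario.grid_rows) for c in range(scenario.grid_cols)}
    n_cells = len(labels)
    n_flip = int(round(distortion_fraction * n_cells))
    rng = scenario.rng(_STREAM_REFERENCE)
    cells = sorted(labels)
    chosen = rng.choice(n_cells, size=n_flip, replace=False)
    for idx in chosen:
        cell = cells[int(idx)]
        neighbours = sorted(adj.get(labels[cell], ()))
        if neighbours:
            labels[cell] = int(neighbours[rng.integers(len(neighbours))])
    return RegionClassification(labels=labels, k=scenario.n_regions,
                                provenance=f"reference:distortion={distortion_fraction}")


def generate_environment(scenario: SyntheticScenario, offsets,
                         noise_sd: float = 0.0,
                         gradient_slope=1.0) -> SyntheticEnvironment:
    """Environmental layers: linear row gradient + per-region offset + noise.

    ``offsets`` is either one sequence of ``n_regions`` per-region offsets
    (a single variable named ``var1``) or a mapping of variable name to
    such a sequence; ``gradient_slope`` (scalar or per-variable mapping)
    is the value increment per grid row.  Noise is i.i.d. normal with the
    stated standard deviation.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if not isinstance(offsets, dict):
        offsets = {"var1": offsets}
    offsets = {v: np.asarray(o, dtype=float) for v, o in offsets.items()}
    for v, o in offsets.items():
        if o.shape != (scenario.n_regions,):
            raise ValueError(
                f"variable {v!r}: expected {scenario.n_regions} per-region offsets, "
                f"got {o.shape}")
    if not isinstance(gradient_slope, dict):
        gradient_slope = {v: float(gradient_slope) for v in offsets}
    layout = region_layout(scenario)
    rng = scenario.rng(_STREAM_ENVIRONMENT)
    index = pd.MultiIndex.from_product(
        [range(scenario.grid_rows), range(scenario.grid_cols)],
        names=["_row", "_col"])
    rows = index.get_level_values(0).to_numpy()
    cols = index.get_level_values(1).to_numpy()
    data = {}
    for v in sorted(offsets):
        vals = gradient_slope.get(v, 0.0) * rows + offsets[v][layout[rows, cols]]
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=len(vals))
        data[v] = vals
    table = EnvCellTable(values=pd.DataFrame(data, index=index))
    return SyntheticEnvironment(table=table,
                                offsets={v: o.tolist() for v, o in offsets.items()},
                                gradient_slope=gradient_slope, noise_sd=noise_sd)


def write_occurrences(records: pd.DataFrame, path, emit: str = "projected") -> None:
    """Write records in the ingest module's delimited format.

    Projected emission uses columns ``species,x,y`` (read back with
    ``coords='projected'``); geographic emission uses
    ``species,longitude,latitude``.
    """
    if emit == "projected":
        records[["species", "x", "y"]].to_csv(path, index=False)
    elif emit == "lonlat":
        out = records.rename(columns={"lon": "longitude", "lat": "latitude"})
        out[["species", "longitude", "latitude"]].to_csv(path, index=False)
    else:
        raise ValueError("emit must be 'projected' or 'lonlat'")
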