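"""Record cleaning, gridding and redundancy."""

import numpy as np
import pandas as pd
import pytest

from phytoregions import (
    GridSpec, SiteBySpeciesMatrix, clean_records, grid_records,
    normalize_name, project_records, read_matrix, redundancy, write_matrix,
)
from phytoregions.occurrence_grid import (
    DegenerateCellError, GridExtentError,
    REASON_INVALID_NAME, REASON_MISSING_COORDINATES, REASON_OUTSIDE_MASK,
    REASON_SPATIAL_OUTLIER,
)
from phytoregions.synthetic import SyntheticScenario, generate_occurrences, \
    planted_incidence


@pytest.mark.parametrize("raw,expected", [
    ("Acacia dealbata subsp. dealbata", "Acacia dealbata"),
    ("Eucalyptus regnans", "Eucalyptus regnans"),
    ("EUCALYPTUS REGNANS", "Eucalyptus regnans"),
    ("Acacia dealbata var. mollis", "Acacia dealbata"),
    ("Banksia spinulosa   f.  collina", "Banksia spinulosa"),
    ("Acacia", None),            # rank above species
    ("Acacia sp.", None),        # undetermined epithet
    ("Acacia 123", None),
])
def test_normalize_name(raw, expected):
    assert normalize_name(raw) == expected


def test_normalize_name_rejects_empty():
    with pytest.raises(ValueError):
        normalize_name("   ")


def _records(rows):
    return pd.DataFrame(rows, columns=["raw_name", "lon", "lat"])


def test_clean_records_reason_codes():
    df = _records([
        ("Acacia dealbata", 135.0, -25.0),
        ("Acacia dealbata", np.nan, -25.0),     # missing coordinate
        ("Acacia", 135.0, -25.0),               # bare genus
        ("Acacia dealbata", 200.0, -25.0),      # longitude out of range
    ])
    survivors, rejects = clean_records(df)
    assert len(survivors) == 1 and len(rejects) == 3
    assert set(rejects["reason"]) == {REASON_MISSING_COORDINATES, REASON_INVALID_NAME}
    # survivors + rejects partition the input exactly, order preserved
    assert sorted(survivors.index.tolist() + rejects.index.tolist()) \
        == df.index.tolist()


def test_clean_records_identity_when_everything_valid():
    df = _records([("Acacia dealbata", 135.0 + i * 0.01, -25.0) for i in range(5)])
    survivors, rejects = clean_records(df)
    assert len(rejects) == 0
    assert survivors.index.tolist() == df.index.tolist()


def test_clean_records_mask():
    import shapely
    mask = shapely.box(130.0, -30.0, 140.0, -20.0)
    df = _records([
        ("Acacia dealbata", 135.0, -25.0),
        ("Acacia dealbata", 150.0, -25.0),  # east of the mask
    ])
    survivors, rejects = clean_records(df, mask=mask)
    assert len(survivors) == 1
    assert rejects["reason"].tolist() == [REASON_OUTSIDE_MASK]


def test_clean_records_outlier_rule_hand_example():
    """10 collinear points at x=0..9 plus one at x=1000: only the distant
    one exceeds 3 population-SDs of distance from the species centroid."""
    xs = list(range(10)) + [1000]
    df = pd.DataFrame({"raw_name": ["Acacia dealbata"] * 11,
                       "lon": [np.nan] * 11, "lat": [np.nan] * 11,
                       "x": [float(v) for v in xs], "y": [0.0] * 11})
    survivors, rejects = clean_records(df, outlier_sd=3.0)
    assert rejects["reason"].tolist() == [REASON_SPATIAL_OUTLIER]
    assert rejects["x"].tolist() == [1000.0]
    assert len(survivors) == 10


def test_grid_boundary_record_goes_to_higher_cell():
    spec = GridSpec(cell_size=10.0, n_rows=2, n_cols=2)
    df = pd.DataFrame({"species": ["Acacia dealbata", "Acacia mearnsii"],
                       "x": [10.0, 5.0], "y": [5.0, 5.0]})
    m = grid_records(df, spec)
    assert (0, 1) in m.cells and (0, 0) in m.cells
    assert m.species_set((0, 1)) == {"Acacia dealbata"}


def test_grid_counts_and_richness():
    spec = GridSpec(cell_size=10.0, n_rows=1, n_cols=1)
    df = pd.DataFrame({"species": ["A b", "A b", "A b", "C d", "C d"],
                       "x": [1.0] * 5, "y": [2.0] * 5})
    m = grid_records(df, spec)
    assert m.richness_per_cell.tolist() == [2]
    assert m.records_per_cell.tolist() == [5]


def test_grid_extent_error():
    spec = GridSpec(cell_size=10.0, n_rows=1, n_cols=1)
    df = pd.DataFrame({"species": ["A b"], "x": [25.0], "y": [5.0]})
    with pytest.raises(GridExtentError):
        grid_records(df, spec)


def test_gridding_matches_planted_incidence_exactly():
    """With full occupancy, no noise and guaranteed coverage, the gridded
    matrix must equal the generator's planted incidence."""
    sc = SyntheticScenario(grid_rows=4, grid_cols=5, n_regions=2,
                           pool_size_per_region=12, shared_fraction=0.0,
                           occupancy_prob=1.0, noise_record_prob=0.0,
                           records_per_cell_mean=30.0, seed=3)
    rec = generate_occurrences(sc, ensure_coverage=True)
    m = grid_records(rec, sc.grid_spec())
    truth = planted_incidence(sc)
    assert m.cells == truth.cells
    assert m.species == truth.species
    assert np.array_equal(m.presence, truth.presence)


def test_gridding_idempotent_on_cell_centers():
    sc = SyntheticScenario(grid_rows=4, grid_cols=4, n_regions=2,
                           pool_size_per_region=10, seed=5)
    rec = generate_occurrences(sc)
    spec = sc.grid_spec()
    m1 = grid_records(rec, spec)
    rows = []
    for i, (r, c) in enumerate(m1.cells):
        x, y = spec.cell_center(r, c)
        for j in np.flatnonzero(m1.presence[i]):
            rows.append({"species": m1.species[j], "x": float(x), "y": float(y)})
    m2 = grid_records(pd.DataFrame(rows), spec)
    assert m2.cells == m1.cells and m2.species == m1.species
    assert np.array_equal(m2.presence, m1.presence)


def test_projection_fills_xy():
    df = _records([("Acacia dealbata", 135.0, -25.0)])
    out = project_records(df)
    assert {"x", "y"}.issubset(out.columns)
    assert np.isfinite(out[["x", "y"]]).all().all()


def test_empty_cell_rejected_by_matrix():
    with pytest.raises(DegenerateCellError):
        SiteBySpeciesMatrix(cells=[(0, 0), (0, 1)], species=["A b"],
                            presence=np.array([[True], [False]]),
                            records_per_cell=np.array([1, 0]))


@pytest.mark.parametrize("records,richness,expected", [
    (10, 4, 0.6),   # the "good level" example
    (7, 7, 0.0),    # every record a distinct species
])
def test_redundancy_per_cell(records, richness, expected):
    presence = np.zeros((1, richness), dtype=bool)
    presence[0, :] = True
    m = SiteBySpeciesMatrix(cells=[(0, 0)], species=[f"G s{chr(97 + i)}" for i in range(richness)],
                            presence=presence, records_per_cell=np.array([records]))
    rep = redundancy(m)
    assert rep.per_cell.iloc[0] == pytest.approx(expected)


def test_redundancy_fraction_counts_cells():
    # 10 cells; 7 have redundancy >= 0.6 (10 records, 4 species), 3 have 0
    n = 10
    presence = np.zeros((n, 4), dtype=bool)
    presence[:7, :] = True
    presence[7:, :] = [True, True, True, True]
    records = np.array([10] * 7 + [4] * 3)
    m = SiteBySpeciesMatrix(cells=[(0, i) for i in range(n)],
                            species=["G sa", "G sb", "G sc", "G sd"],
                            presence=presence, records_per_cell=records)
    rep = redundancy(m, threshold=0.6)
    assert rep.fraction_at_or_above == pytest.approx(0.7)


def test_redundancy_rejects_inconsistent_counts():
    presence = np.ones((1, 3), dtype=bool)
    m = SiteBySpeciesMatrix(cells=[(0, 0)], species=["G sa", "G sb", "G sc"],
                            presence=presence, records_per_cell=np.array([2]))
    with pytest.raises(ValueError):
        redundancy(m)


def test_matrix_io_round_trip(tmp_path, small_scenario):
    rec = generate_occurrences(small_scenario)
    m = grid_records(rec, small_scenario.grid_spec())
    path = tmp_path / "matrix.csv"
    write_matrix(m, path)
    m2 = read_matrix(path)
    assert m2.cells == m.cells and m2.species == m.species
    assert np.array_equal(m2.presence, m.presence)
    assert np.array_equal(m2.records_per_cell, m.records_per_cell)
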