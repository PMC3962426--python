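"""The planted-region generator: determinism, structure, degradation."""

import numpy as np
import pytest

from phytoregions import grid_records, overlap_agreement, turnover_matrix, wpgma, \
    cut_regions
from phytoregions.synthetic import (
    SyntheticScenario, generate_environment, generate_occurrences,
    generate_reference_classification, planted_classification,
    planted_incidence, region_layout, species_pools,
)
from tests.conftest import label_agreement


def test_invalid_parameters_rejected():
    with pytest.raises(ValueError):
        SyntheticScenario(grid_rows=0)
    with pytest.raises(ValueError):
        SyntheticScenario(noise_record_prob=1.0)
    with pytest.raises(ValueError):
        SyntheticScenario(occupancy_prob=0.0)
    with pytest.raises(ValueError):
        SyntheticScenario(shared_fraction=1.5)
    with pytest.raises(ValueError):
        SyntheticScenario(records_per_cell_mean=0.0)


def test_layout_partitions_grid_into_contiguous_blocks():
    sc = SyntheticScenario(grid_rows=20, grid_cols=25, n_regions=6)
    layout = region_layout(sc)
    assert layout.shape == (20, 25)
    assert set(np.unique(layout)) == set(range(6))
    # blocks are contiguous rectangles: each region's bounding box is full
    for g in range(6):
        rows, cols = np.nonzero(layout == g)
        assert (layout[rows.min():rows.max() + 1, cols.min():cols.max() + 1] == g).all()


def test_voronoi_layout_covers_all_regions():
    sc = SyntheticScenario(grid_rows=12, grid_cols=12, n_regions=5, layout="voronoi",
                           seed=2)
    layout = region_layout(sc)
    assert set(np.unique(layout)) == set(range(5))


def test_determinism_same_seed_same_records():
    sc = SyntheticScenario(grid_rows=6, grid_cols=6, n_regions=2, seed=42)
    r1 = generate_occurrences(sc)
    r2 = generate_occurrences(SyntheticScenario(grid_rows=6, grid_cols=6,
                                                n_regions=2, seed=42))
    assert r1.equals(r2)
    r3 = generate_occurrences(SyntheticScenario(grid_rows=6, grid_cols=6,
                                                n_regions=2, seed=43))
    assert not r1.equals(r3)


def test_shared_plus_endemic_fractions_sum_to_one():
    sc = SyntheticScenario(grid_rows=8, grid_cols=8, n_regions=4,
                           pool_size_per_region=20, shared_fraction=0.25, seed=1)
    pools = species_pools(sc)
    total_names = {sp for pool in pools.values() for sp in pool}
    # sharing reuses owned species rather than minting new ones, so each
    # pool's endemic + shared-out fractions sum to 1
    assert len(total_names) == 4 * 20
    for g, pool in pools.items():
        owned = [sp for sp in pool if sp.startswith(f"Pool{'abcd'[g]}")]
        assert len(owned) == 20


def test_disjoint_pools_force_maximal_turnover():
    """shared=0, noise=0, occupancy=1: species never cross regions, so
    between-region turnover is exactly 1."""
    sc = SyntheticScenario(grid_rows=4, grid_cols=4, n_regions=2,
                           pool_size_per_region=15, shared_fraction=0.0,
                           occupancy_prob=1.0, noise_record_prob=0.0,
                           records_per_cell_mean=60.0, seed=7)
    rec = generate_occurrences(sc)
    m = grid_records(rec, sc.grid_spec())
    tm = turnover_matrix(m)
    layout = region_layout(sc)
    for i, ci in enumerate(m.cells):
        for j, cj in enumerate(m.cells):
            if i < j and layout[ci] != layout[cj]:
                assert tm.beta[i, j] == 1.0


def test_expected_turnover_single_region_matches_monte_carlo_oracle():
    """One region: the expected beta_sim between two cells under the
    sampling model, estimated by an independent brute-force simulation
    (>= 10,000 replicates), must match the generator + pipeline estimate."""
    pool, occ, lam = 6, 0.9, 8.0

    def oracle(rng, reps=10_000):
        vals = []
        while len(vals) < reps:
            obs = []
            for _ in range(2):
                present = np.flatnonzero(rng.random(pool) < occ)
                if len(present) == 0:
                    present = np.array([rng.integers(pool)])
                n = rng.poisson(lam)
                obs.append(set(present[rng.integers(len(present), size=n)])
                           if n else set())
            if not obs[0] or not obs[1]:
                continue
            a = len(obs[0] & obs[1])
            bb = len(obs[0] - obs[1])
            cc = len(obs[1] - obs[0])
            vals.append(1.0 if a == 0 else min(bb, cc) / (min(bb, cc) + a))
        return np.array(vals)

    expect = oracle(np.random.default_rng(123)).mean()
    got = []
    for seed in range(400):
        sc = SyntheticScenario(grid_rows=1, grid_cols=2, n_regions=1,
                               pool_size_per_region=pool, shared_fraction=0.0,
                               occupancy_prob=occ, noise_record_prob=0.0,
                               records_per_cell_mean=lam, seed=seed)
        m = grid_records(generate_occurrences(sc), sc.grid_spec())
        if m.n_cells == 2:
            got.append(turnover_matrix(m).beta[0, 1])
    assert np.mean(got) == pytest.approx(expect, abs=0.03)


def test_reference_distortion_zero_is_planted_layout():
    sc = SyntheticScenario(grid_rows=5, grid_cols=5, n_regions=2, seed=3)
    assert generate_reference_classification(sc, 0.0).labels == \
        planted_classification(sc).labels


def test_reference_distortion_relabels_exact_count():
    sc = SyntheticScenario(grid_rows=4, grid_cols=4, n_regions=2, seed=9)
    ref = generate_reference_classification(sc, 0.25)
    planted = planted_classification(sc)
    flipped = sum(ref.labels[c] != planted.labels[c] for c in planted.labels)
    assert flipped == 4  # round(0.25 * 16)


def test_full_distortion_two_regions_swaps_labels():
    """With 2 regions every relabelled cell takes the other label, so full
    distortion inverts the partition: cell-wise agreement with the planted
    layout is 0, yet plurality overlap after matching is 100 (each
    sub-region sits wholly inside one derived region) — the hand-enumerated
    base rates."""
    sc = SyntheticScenario(grid_rows=4, grid_cols=4, n_regions=2, seed=5)
    ref = generate_reference_classification(sc, 1.0)
    planted = planted_classification(sc)
    assert all(ref.labels[c] != planted.labels[c] for c in planted.labels)
    rep = overlap_agreement(planted, ref)
    assert rep.overall_agreement == pytest.approx(100.0)


def test_environment_offsets_and_gradient():
    sc = SyntheticScenario(grid_rows=4, grid_cols=4, n_regions=2, seed=0)
    envo = generate_environment(sc, [0.0, 0.0], noise_sd=0.0, gradient_slope=2.0)
    vals = envo.table.values["var1"]
    for (r, _), v in vals.items():
        assert v == pytest.approx(2.0 * r)
    with pytest.raises(ValueError):
        generate_environment(sc, [0.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        generate_environment(sc, [0.0, 0.0], noise_sd=-1.0)


def test_gi_star_zero_for_region_matching_row_distribution():
    """The 2-region block layout on a square grid splits by columns, so
    each region sees every row equally: under a pure row gradient its mean
    equals the global mean and Gi* is exactly 0."""
    from phytoregions import gi_star
    sc = SyntheticScenario(grid_rows=4, grid_cols=4, n_regions=2, seed=0)
    envo = generate_environment(sc, [0.0, 0.0], noise_sd=0.0, gradient_slope=1.0)
    rc = planted_classification(sc)
    region = [c for c, g in rc.labels.items() if g == 0]
    layout = region_layout(sc)
    assert set(np.unique(layout[:, :2])) == {layout[0, 0]}  # column split
    assert gi_star(envo.table, region, "var1").z == pytest.approx(0.0, abs=1e-12)


def test_planted_incidence_has_no_empty_cells():
    sc = SyntheticScenario(grid_rows=6, grid_cols=6, n_regions=4,
                           pool_size_per_region=3, occupancy_prob=0.05, seed=8)
    truth = planted_incidence(sc)
    assert truth.presence.any(axis=1).all()


def _recovery(sc):
    m = grid_records(generate_occurrences(sc), sc.grid_spec())
    rc, _ = cut_regions(wpgma(turnover_matrix(m), m), k=sc.n_regions)
    return label_agreement(planted_classification(sc), rc)


def test_recovery_degrades_monotonically_with_pool_sharing():
    """Mean planted-region recovery over a seed ensemble never increases
    as shared_fraction grows."""
    means = []
    for sf in (0.0, 0.5, 1.0):
        vals = [_recovery(SyntheticScenario(
            grid_rows=8, grid_cols=8, n_regions=4, pool_size_per_region=30,
            shared_fraction=sf, occupancy_prob=0.8, noise_record_prob=0.05,
            records_per_cell_mean=60.0, seed=seed)) for seed in range(8)]
        means.append(np.mean(vals))
    assert means[0] >= means[1] - 0.02
    assert means[1] >= means[2] - 0.02
    assert means[0] >= 0.95
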