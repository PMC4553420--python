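import numpy as np
import pytest

from pollendep import (
    DESIGN_NAMES,
    LeafGeometry,
    PilotScan,
    cluster_design,
    full_transect_design,
    make_design,
    random_raster_design,
    repeated_transects_design,
    spot_mean_intensity,
    structured_design,
)
from pollendep.errors import InfeasibleDesignError, InvalidParameterError

MIDRIB_Y = 8.75 / 2


class TestRandomRaster:
    def test_default_spot_count(self, geometry):
        assert len(random_raster_design(geometry, seed=1)) == 35

    def test_exhaustive_case_selects_every_cell(self, geometry):
        design = random_raster_design(geometry, n_points=95, seed=1)
        assert sorted(design.provenance["cells"]) == list(range(95))

    def test_too_many_points_rejected(self, geometry):
        with pytest.raises(InfeasibleDesignError):
            random_raster_design(geometry, n_points=96, seed=1)

    def test_cells_distinct_and_spots_in_their_cells(self, geometry):
        design = random_raster_design(geometry, seed=5)
        cells = design.provenance["cells"]
        assert len(set(cells)) == 35
        for flat, spot in zip(cells, design.spots):
            x0, x1, y0, y1 = geometry.cell_bounds(*geometry.cell_of(flat))
            assert x0 <= spot.x_cm <= x1 and y0 <= spot.y_cm <= y1

    def test_cell_selection_frequencies_binomial(self, geometry):
        # each of the 95 cells selected with frequency 35/95 +- 3 SE over 1,000 seeds
        n_seeds = 1000
        hits = np.zeros(95)
        for seed in range(n_seeds):
            hits[random_raster_design(geometry, seed=seed).provenance["cells"]] += 1
        p = 35 / 95
        se = np.sqrt(p * (1 - p) / n_seeds)
        freq = hits / n_seeds
        # simultaneous check across 95 cells: allow the multiplicity-adjusted band
        z = 3.9  # two-sided 95% familywise for 95 binomial checks
        assert np.all(np.abs(freq - p) < z * se)


class TestFullTransect:
    def test_default_spot_count(self, geometry):
        assert len(full_transect_design(geometry)) == 38

    def test_all_spots_at_mid_length(self, geometry):
        design = full_transect_design(geometry)
        assert all(s.x_cm == pytest.approx(23.75) for s in design.spots)

    def test_even_spacing_across_width(self, geometry):
        design = full_transect_design(geometry)
        ys = np.array([s.y_cm for s in design.spots])
        spacing = 8.75 / 38
        assert np.allclose(np.diff(ys), spacing)
        assert ys[0] == pytest.approx(spacing / 2)

    def test_circular_footprint_overlap_warning(self, geometry):
        # circular 5 mm^2 fields (diameter 2.52 mm) overlap at 2.30 mm spacing
        design = full_transect_design(geometry, footprint="circle")
        assert any("overlap" in w for w in design.provenance["warnings"])

    def test_square_footprint_tiles_without_overlap(self, geometry):
        design = full_transect_design(geometry, footprint="square")
        assert design.provenance["warnings"] == []


class TestRepeatedTransects:
    def test_default_spot_count(self, geometry):
        assert len(repeated_transects_design(geometry)) == 25

    def test_transect_x_positions_evenly_spread(self, geometry):
        design = repeated_transects_design(geometry)
        xs = sorted({s.x_cm for s in design.spots})
        assert xs == pytest.approx([47.5 * f for f in (0.1, 0.3, 0.5, 0.7, 0.9)])

    def test_one_midrib_spot_per_transect(self, geometry):
        design = repeated_transects_design(geometry)
        for x in {s.x_cm for s in design.spots}:
            on_midrib = [s for s in design.spots
                         if s.x_cm == x and abs(s.y_cm - MIDRIB_Y) <= 0.4]
            assert len(on_midrib) == 1

    def test_edge_spots_inset_by_half_diameter(self, geometry):
        design = repeated_transects_design(geometry)
        r = design.spots[0].radius_cm
        ys = sorted({s.y_cm for s in design.spots})
        assert ys[0] == pytest.approx(r)
        assert ys[-1] == pytest.approx(8.75 - r)


class TestClusters:
    def test_default_spot_count(self, geometry, default_pilot):
        assert len(cluster_design(geometry, default_pilot, seed=2)) == 30

    def test_zero_points_per_cluster_gives_empty_design(self, geometry, default_pilot):
        design = cluster_design(geometry, default_pilot, points_per_cluster=0, seed=2)
        assert len(design) == 0

    def test_high_low_cells_from_extreme_deciles(self, geometry, default_pilot):
        design = cluster_design(geometry, default_pilot, seed=3)
        ranking = list(default_pilot.ranking)
        decile = 10  # ceil(0.1 * 95)
        for cell in design.provenance["high_cells"]:
            assert ranking.index(cell) < decile
        for cell in design.provenance["low_cells"]:
            assert ranking.index(cell) >= 95 - decile

    def test_two_level_field_cluster_intensities(self, two_level_field):
        # pilot ranking on the deterministic field puts high clusters on the
        # 1000-band row; low-cluster spots all sit on the 100 background
        pilot = PilotScan.from_field(two_level_field)
        design = cluster_design(two_level_field.geometry, pilot, seed=4)
        kinds = design.provenance["cluster_kind"]
        high = [spot_mean_intensity(two_level_field, s)
                for s, k in zip(design.spots, kinds) if k == "high"]
        low = [spot_mean_intensity(two_level_field, s)
               for s, k in zip(design.spots, kinds) if k == "low"]
        assert all(v == pytest.approx(100.0) for v in low)
        assert all(100.0 <= v <= 1000.0 + 1e-6 for v in high)
        assert max(high) == pytest.approx(1000.0)
        assert np.mean(high) > np.mean(low)

    def test_mean_pilot_rank_high_above_low(self, geometry, default_pilot):
        design = cluster_design(geometry, default_pilot, seed=6)
        rank = {cell: i for i, cell in enumerate(default_pilot.ranking)}
        mean_high = np.mean([rank[c] for c in design.provenance["high_cells"]])
        mean_low = np.mean([rank[c] for c in design.provenance["low_cells"]])
        assert mean_high < mean_low  # rank 0 = highest density

    def test_missing_pilot_rejected(self, geometry):
        with pytest.raises(InfeasibleDesignError):
            cluster_design(geometry, None, seed=1)

    def test_insufficient_extreme_cells_rejected(self, geometry, default_pilot):
        with pytest.raises(InfeasibleDesignError):
            cluster_design(geometry, default_pilot, n_high=11, seed=1)


class TestStructured:
    def test_total_and_composition(self, geometry, default_pilot):
        design = structured_design(geometry, default_pilot, seed=1)
        assert len(design) == 27
        assert design.provenance["n_transect_spots"] == 15  # 3 transects x 5
        assert design.provenance["n_cluster_spots"] == 12   # 4 clusters x 3

    def test_no_coincident_spots_over_seeds(self, geometry, default_pilot):
        for seed in range(100):
            design = structured_design(geometry, default_pilot, seed=seed)
            pts = np.array([(s.x_cm, s.y_cm) for s in design.spots])
            d = np.hypot(pts[:, None, 0] - pts[None, :, 0],
                         pts[:, None, 1] - pts[None, :, 1])
            np.fill_diagonal(d, np.inf)
            assert d.min() > 0.0


class TestCrossDesign:
    def test_default_design_sizes(self, geometry, default_pilot):
        sizes = {name: len(make_design(name, geometry, pilot=default_pilot, seed=0))
                 for name in DESIGN_NAMES}
        assert sizes == {
            "random_raster": 35, "full_transect": 38,
            "repeated_transects": 25, "clusters": 30, "structured": 27,
        }

    @pytest.mark.parametrize("name", DESIGN_NAMES)
    def test_spots_inside_leaf(self, name, geometry, default_pilot):
        # full transect uses the square footprint that tiles the width exactly;
        # the circular variant is allowed to overhang marginally (recorded).
        kwargs = {"footprint": "square"} if name == "full_transect" else {}
        design = make_design(name, geometry, pilot=default_pilot, seed=3, **kwargs)
        for spot in design.spots:
            spot.validate_inside(geometry, tol_cm=1e-6)

    @pytest.mark.parametrize("name", DESIGN_NAMES)
    def test_determinism(self, name, geometry, default_pilot):
        a = make_design(name, geometry, pilot=default_pilot, seed=9)
        b = make_design(name, geometry, pilot=default_pilot, seed=9)
        assert [(s.x_cm, s.y_cm) for s in a.spots] == [(s.x_cm, s.y_cm) for s in b.spots]

    def test_unknown_design_rejected(self, geometry):
        with pytest.raises(InvalidParameterError):
            make_design("spiral", geometry)


class TestPilotScan:
    def test_one_value_per_cell_and_ranking_is_permutation(self, default_pilot):
        assert default_pilot.densities.shape == (95,)
        assert sorted(default_pilot.ranking) == list(range(95))

    def test_ranking_orders_densities(self, default_pilot):
        d = default_pilot.densities[default_pilot.ranking]
        assert np.all(np.diff(d) <= 0)

    def test_truth_and_measured_modes_agree_on_ordering(self, two_level_field):
        measured = PilotScan.from_field(two_level_field, mode="measured")
        truth = PilotScan.from_field(two_level_field, mode="truth")
        # both modes put the band row cells first
        assert set(measured.ranking[:10]) == set(truth.ranking[:10])
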