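import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pollendep import (
    FieldParams,
    LeafGeometry,
    Spot,
    draw_spot_count,
    generate_field,
    spot_mean_intensity,
    true_summary,
)
from pollendep.errors import GeometryError, InvalidParameterError
from pollendep.rng import substream

MIDRIB_Y = 8.75 / 2  # midrib centre on the default leaf


def homogeneous(gm=100.0, seed=0):
    return generate_field(FieldParams(
        background_gm=gm, background_gsd=1.0,
        midrib_multiplier=1.0, vein_multiplier=1.0, edge_multiplier=1.0,
        seed=seed,
    ))


class TestGenerateField:
    def test_noise_free_homogeneous_limit(self):
        field = homogeneous(gm=100.0)
        xx = np.linspace(0, 47.5, 23)
        yy = np.linspace(0, 8.75, 17)
        lam = field.intensity(*np.meshgrid(xx, yy, indexing="ij"))
        assert np.allclose(lam, 100.0)

    def test_deterministic_midrib_multiplier(self, two_level_field):
        # lambda = 1000 inside the midrib band, 100 outside
        assert two_level_field.intensity(10.0, MIDRIB_Y) == pytest.approx(1000.0)
        assert two_level_field.intensity(10.0, MIDRIB_Y + 0.39) == pytest.approx(1000.0)
        assert two_level_field.intensity(10.0, 1.0) == pytest.approx(100.0)
        assert two_level_field.intensity(40.0, 7.0) == pytest.approx(100.0)

    def test_multiplier_algebra_noise_free(self):
        # with zero spatial noise, lambda = gm x product of applicable multipliers
        params = FieldParams(background_gm=50.0, background_gsd=1.0, seed=0)
        field = generate_field(params)
        assert field.intensity(5.0, MIDRIB_Y) == pytest.approx(50.0 * 10.0)
        # vein band one spacing from the midrib
        assert field.intensity(5.0, MIDRIB_Y + 1.0) == pytest.approx(50.0 * 3.0)
        # edge band
        assert field.intensity(5.0, 0.1) == pytest.approx(50.0 * 3.0)
        # plain background between structures
        assert field.intensity(5.0, MIDRIB_Y + 1.5) == pytest.approx(50.0)

    def test_reproducible_given_seed(self):
        a = generate_field(FieldParams(seed=42))
        b = generate_field(FieldParams(seed=42))
        c = generate_field(FieldParams(seed=43))
        xx, yy = np.meshgrid(np.linspace(0, 47.5, 31), np.linspace(0, 8.75, 13),
                             indexing="ij")
        assert np.array_equal(a.intensity(xx, yy), b.intensity(xx, yy))
        assert not np.array_equal(a.intensity(xx, yy), c.intensity(xx, yy))

    def test_positivity(self):
        field = generate_field(FieldParams(seed=7))
        _, _, lam = field.grid(0.25)
        assert np.all(lam > 0)

    def test_gaussian_component_marginal_sd(self):
        # pooled grid values of G across fields match sd = ln(gsd); pooling
        # across independent fields avoids the within-field small-domain bias
        pooled = np.concatenate([
            generate_field(FieldParams(background_gsd=2.0, seed=seed))._g.ravel()
            for seed in range(12)
        ])
        assert pooled.std() == pytest.approx(np.log(2.0), rel=0.05)

    @pytest.mark.parametrize("kwargs", [
        {"background_gm": 0.0}, {"background_gm": -5.0},
        {"background_gsd": 0.5}, {"midrib_multiplier": 0.9},
        {"correlation_length_cm": 0.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            FieldParams(**kwargs)


class TestTrueSummary:
    def test_homogeneous_field_collapses(self):
        ts = true_summary(homogeneous(gm=100.0))
        for v in (ts.gm, ts.q05, ts.q95, ts.max):
            assert v == pytest.approx(100.0)

    def test_two_level_closed_form(self, two_level_field):
        # gm = exp((1-f) ln 100 + f ln 1000) for band area fraction f
        f = (2 * 0.4) / 8.75
        expected = np.exp((1 - f) * np.log(100.0) + f * np.log(1000.0))
        ts = true_summary(two_level_field)
        assert ts.gm == pytest.approx(expected, rel=0.01)
        assert ts.max == pytest.approx(1000.0)
        assert ts.q05 == pytest.approx(100.0)

    def test_grid_refinement_converges(self, default_field):
        coarse = true_summary(default_field, grid_step_cm=0.1)
        fine = true_summary(default_field, grid_step_cm=0.05)
        assert fine.gm == pytest.approx(coarse.gm, rel=0.01)

    def test_quantile_ordering(self, default_field):
        ts = true_summary(default_field)
        assert ts.q05 <= ts.gm <= ts.q95 <= ts.max

    def test_grid_step_coarser_than_structures_rejected(self, default_field):
        with pytest.raises(InvalidParameterError):
            true_summary(default_field, grid_step_cm=0.2)


class TestSpotMeanIntensity:
    def test_homogeneous_any_spot(self):
        field = homogeneous(gm=540.0)
        for x, y in [(5.0, 2.0), (23.75, MIDRIB_Y), (40.0, 8.0)]:
            assert spot_mean_intensity(field, Spot(x, y)) == pytest.approx(540.0)

    def test_spot_fully_inside_band(self, two_level_field):
        assert spot_mean_intensity(
            two_level_field, Spot(10.0, MIDRIB_Y)
        ) == pytest.approx(1000.0)

    def test_spot_half_covering_band_edge(self, two_level_field):
        # centred on the band boundary: area-weighted mean of 100 and 1000
        spot = Spot(10.0, MIDRIB_Y + 0.4)
        value = spot_mean_intensity(two_level_field, spot)
        assert 100.0 < value < 1000.0
        assert value == pytest.approx(0.5 * (100.0 + 1000.0), rel=0.01)

    def test_spot_off_leaf_rejected(self, default_field):
        with pytest.raises(GeometryError):
            spot_mean_intensity(default_field, Spot(-1.0, 2.0))


class TestDrawSpotCount:
    def test_deterministic_mode_rounds_mean(self):
        field = homogeneous(gm=540.0)
        assert draw_spot_count(field, Spot(10.0, 4.0), deterministic=True) == 27

    def test_zero_intensity_limit(self):
        field = homogeneous(gm=1e-9)
        rng = substream(0, "t")
        counts = [draw_spot_count(field, Spot(10.0, 4.0), seed=rng) for _ in range(50)]
        assert counts == [0] * 50

    def test_poisson_mean(self):
        field = homogeneous(gm=540.0)
        rng = substream(123, "poisson-mean")
        draws = np.array([
            draw_spot_count(field, Spot(10.0, 4.0), seed=rng) for _ in range(10_000)
        ])
        se = np.sqrt(27.0 / len(draws))
        assert abs(draws.mean() - 27.0) < 3 * se

    def test_poisson_variance_to_mean(self):
        field = homogeneous(gm=540.0)
        rng = substream(99, "poisson-var")
        draws = np.array([
            draw_spot_count(field, Spot(10.0, 4.0), seed=rng) for _ in range(10_000)
        ])
        assert 0.9 < draws.var() / draws.mean() < 1.1


@settings(deadline=None, max_examples=25)
@given(
    gm=st.floats(10.0, 1000.0),
    midrib=st.floats(1.0, 20.0),
    vein=st.floats(1.0, 5.0),
    edge=st.floats(1.0, 5.0),
)
def test_multiplier_algebra_property(gm, midrib, vein, edge):
    """Noise-free lambda equals gm times the product of applicable multipliers."""
    params = FieldParams(
        background_gm=gm, background_gsd=1.0,
        midrib_multiplier=midrib, vein_multiplier=vein, edge_multiplier=edge,
        seed=0,
    )
    field = generate_field(params)
    assert field.intensity(12.0, MIDRIB_Y) == pytest.approx(gm * midrib)
    assert field.intensity(12.0, 0.05) == pytest.approx(gm * edge)
    assert field.intensity(12.0, MIDRIB_Y - 2.0) == pytest.approx(gm * vein)
    assert field.intensity(12.0, MIDRIB_Y - 1.5) == pytest.approx(gm)
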