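import numpy as np
import pytest
from scipy import stats

from admkit.errors import (
    DegenerateNicheError,
    ParameterError,
    SamplingError,
    StratificationError,
)
from admkit.grids import GridGeometry
from admkit.synthetic import (
    VirtualSpecies,
    gen_env_stack,
    gen_landcover,
    gen_virtual_species,
    sample_occurrences,
    simulate_field_survey,
)


def lag1_autocorr(field: np.ndarray) -> float:
    """Brute-force Moran-like statistic: correlation with the right neighbor."""
    a, b = field[:, :-1].ravel(), field[:, 1:].ravel()
    return float(np.corrcoef(a, b)[0, 1])


class TestGenEnvStack:
    def test_standardized_to_machine_precision(self, stack60):
        for i in range(stack60.n_layers):
            v = stack60.values[i][stack60.valid_mask]
            assert abs(v.mean()) < 1e-9 and abs(v.std() - 1.0) < 1e-9

    def test_no_spatial_autocorrelation_without_smoothing(self):
        stack = gen_env_stack(seed=3, n_layers=3, n_rows=100, n_cols=100, autocorr_range=0.0)
        for i in range(3):
            assert abs(lag1_autocorr(stack.values[i])) < 0.05

    def test_smoothing_induces_autocorrelation(self, stack60):
        assert lag1_autocorr(stack60.values[0]) > 0.5

    def test_layers_are_correlated(self, stack60):
        corr = np.corrcoef(stack60.valid_values().T)
        off = np.abs(corr[np.triu_indices_from(corr, k=1)])
        assert off.max() > 0.5  # latent-factor mixing mimics bioclim collinearity

    def test_same_seed_identical(self):
        a = gen_env_stack(seed=5, n_layers=3, n_rows=20, n_cols=25)
        b = gen_env_stack(seed=5, n_layers=3, n_rows=20, n_cols=25)
        assert np.array_equal(a.values, b.values)

    @pytest.mark.parametrize("kw", [{"n_rows": 0}, {"n_layers": 1}, {"autocorr_range": -1}])
    def test_bad_parameters_rejected(self, kw):
        with pytest.raises(ParameterError):
            gen_env_stack(seed=0, **{"n_layers": 3, "n_rows": 20, "n_cols": 20, **kw})


class TestGenVirtualSpecies:
    def test_zero_marginality_centers_niche_at_centroid(self, stack60):
        vs = gen_virtual_species(stack60, seed=1, marginality_target=0.0)
        assert np.allclose(vs.niche_center, 0.0)
        # the truth peak sits at the environmental centroid, not a map corner
        Z = stack60.valid_values()
        peak = np.argmax(vs.truth_suitability[stack60.valid_mask])
        assert np.linalg.norm(Z[peak]) < np.percentile(np.linalg.norm(Z, axis=1), 10)

    def test_center_norm_is_1_96_times_target(self, stack60):
        vs = gen_virtual_species(stack60, seed=2, marginality_target=1.5)
        assert np.isclose(np.linalg.norm(vs.niche_center), 2.94)

    def test_truth_matches_gaussian_formula(self, stack60):
        vs = gen_virtual_species(stack60, seed=3, marginality_target=1.0)
        Z = stack60.valid_values()
        expect = np.exp(-0.5 * (((Z - vs.niche_center) / vs.niche_width) ** 2).sum(axis=1))
        assert np.allclose(vs.truth_suitability[stack60.valid_mask], expect)

    def test_width_calibration_hits_tolerance_target(self, stack60):
        vs = gen_virtual_species(stack60, seed=4, marginality_target=0.5, tolerance_target=0.5)
        Z = stack60.valid_values()
        w = vs.truth_suitability[stack60.valid_mask]
        wm = (w[:, None] * Z).sum(0) / w.sum()
        wsd = np.sqrt((w[:, None] * (Z - wm) ** 2).sum(0) / w.sum())
        assert np.all(np.abs(wsd - 0.5) < 0.15)

    def test_impossible_niche_raises_degenerate_error(self, stack60):
        with pytest.raises(DegenerateNicheError):
            gen_virtual_species(stack60, seed=5, marginality_target=3.0, tolerance_target=0.02)

    def test_seeded_determinism(self, stack60):
        a = gen_virtual_species(stack60, seed=6)
        b = gen_virtual_species(stack60, seed=6)
        assert np.array_equal(a.truth_suitability, b.truth_suitability)


def _uniform_species(n=10, cell=1000.0):
    geo = GridGeometry(n, n, 0.0, n * cell, cell)
    return VirtualSpecies(
        "flat", np.zeros(2), np.ones(2), np.ones((n, n)), frozenset({1}), geo,
        np.ones((n, n), bool),
    )


class TestSampleOccurrences:
    def test_uniform_truth_gives_uniform_cell_frequencies(self):
        vs = _uniform_species(10)
        occ = sample_occurrences(vs, n=10_000, seed=8)
        cells = occ.cells(vs.geometry)
        counts = np.bincount(cells[:, 0] * 10 + cells[:, 1], minlength=100)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_points_fall_inside_their_cells(self, stack60, planted60):
        vs, occ = planted60
        cells = occ.cells(vs.geometry)
        assert (vs.truth_suitability[cells[:, 0], cells[:, 1]] > 0).all()

    def test_n_zero_rejected(self):
        with pytest.raises(ParameterError):
            sample_occurrences(_uniform_species(), 0, seed=0)

    def test_without_replacement_capacity_enforced(self):
        with pytest.raises(SamplingError):
            sample_occurrences(_uniform_species(3), n=10, seed=0, replace=False)

    def test_same_seed_identical_even_with_clustering(self):
        vs = _uniform_species()
        a = sample_occurrences(vs, 50, seed=4, clustering=1.0)
        b = sample_occurrences(vs, 50, seed=4, clustering=1.0)
        assert np.array_equal(a.points, b.points)


class TestGenLandcover:
    def test_fine_grid_dimensions(self, stack60):
        lc = gen_landcover(stack60, seed=9, n_classes=3, subcell_ratio=4)
        assert lc.class_grid.shape == (240, 240)
        assert lc.subcell_ratio(stack60.geometry) == 4

    def test_classes_partition_valid_area(self, stack60):
        lc = gen_landcover(stack60, seed=9, n_classes=4)
        codes = lc.class_grid[lc.valid_mask]
        assert set(np.unique(codes)) == {1, 2, 3, 4}
        assert len(codes) == int(lc.valid_mask.sum())

    def test_two_classes_with_large_patches_are_contiguous_blobs(self, stack60):
        from scipy.ndimage import label

        lc = gen_landcover(stack60, seed=10, n_classes=2, patch_scale=30.0, subcell_ratio=1)
        n_components = sum(
            label(lc.class_grid == c)[1] for c in (1, 2)
        )
        assert n_components <= 4

    def test_seeded_determinism(self, stack60):
        a = gen_landcover(stack60, seed=11)
        b = gen_landcover(stack60, seed=11)
        assert np.array_equal(a.class_grid, b.class_grid)


class TestFieldSurvey:
    @pytest.fixture()
    def flat_world(self):
        from admkit.grids import LandCover

        vs = _uniform_species(12)
        geo = vs.geometry
        fine = GridGeometry(24, 24, geo.origin_x, geo.origin_y, geo.cell_size / 2)
        lc = LandCover(np.ones((24, 24), int), {1: "dry_forest"}, fine, np.ones((24, 24), bool))
        return vs, lc

    def test_perfect_detection_in_perfect_habitat_detects_every_point(self, flat_world):
        vs, lc = flat_world
        occ = simulate_field_survey(vs, lc, n_sites=5, points_per_site=4,
                                    min_point_spacing=10.0, detection_prob=1.0, seed=1)
        assert len(occ) == 20  # every packed point is a detection

    def test_wide_spacing_packs_at_most_one_point_per_site(self, flat_world):
        vs, lc = flat_world
        occ = simulate_field_survey(vs, lc, n_sites=6, points_per_site=8,
                                    min_point_spacing=5000.0, detection_prob=1.0, seed=2)
        assert len(occ) == 6
        assert len(np.unique(occ.site_ids)) == 6

    def test_detection_rate_matches_binomial_oracle(self, flat_world):
        vs, lc = flat_world
        n_pts = 0
        detected = 0
        for seed in range(5):
            occ = simulate_field_survey(vs, lc, n_sites=20, points_per_site=10,
                                        min_point_spacing=1.0, detection_prob=0.5, seed=seed)
            detected += len(occ)
            n_pts += 20 * 10
        p = 0.5  # truth is 1 everywhere, so detection ~ Bernoulli(0.5)
        sd = np.sqrt(n_pts * p * (1 - p))
        assert abs(detected - p * n_pts) < 3 * sd

    def test_sites_respect_habitat_stratification(self, stack60, planted60):
        vs, _ = planted60
        lc = gen_landcover(stack60, seed=12, n_classes=4, subcell_ratio=2)
        occ = simulate_field_survey(vs, lc, n_sites=10, points_per_site=5, seed=3)
        dom = lc.dominant_classes(vs.geometry)
        cells = occ.cells(vs.geometry)
        assert np.all(dom[cells[:, 0], cells[:, 1]] == 1)

    def test_too_few_eligible_cells_is_stratification_error(self, flat_world):
        vs, lc = flat_world
        vs2 = VirtualSpecies(vs.species, vs.niche_center, vs.niche_width,
                             vs.truth_suitability, frozenset({7}), vs.geometry, vs.valid_mask)
        with pytest.raises(StratificationError):
            simulate_field_survey(vs2, lc, n_sites=3, seed=0)
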