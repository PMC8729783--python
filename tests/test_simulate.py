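"""Hard-disc placement, labelling and rendering of synthetic NPC fields."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from npcmorph import simulate as sim


def brute_force_min_distance(centers: np.ndarray) -> float:
    """All-pairs minimum distance without spatial indexing (chunked)."""
    n = len(centers)
    if n < 2:
        return np.inf
    best = np.inf
    for start in range(0, n, 500):
        block = cdist(centers[start : start + 500], centers)
        ii = np.arange(block.shape[0])
        block[ii, start + ii] = np.inf  # self-distances
        best = min(best, block.min())
    return float(best)


class TestPlacePores:
    def test_zero_coverage_gives_empty_field(self):
        field = sim.place_pores(100, 100, 0.0, seed=0)
        assert field.n_pores == 0
        assert field.achieved_coverage == 0.0

    def test_small_region_fits_exactly_one_pore(self):
        # pi * 25 / 400 ~ 0.196: only one non-clipped disc fits a 20x20 patch
        field = sim.place_pores(20, 20, 0.196, pore_radius_px=5, seed=3)
        assert field.n_pores == 1
        assert field.achieved_coverage == pytest.approx(np.pi * 25 / 400, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_target_coverage_and_nonoverlap(self, seed):
        field = sim.place_pores(1000, 1000, 0.30, pore_radius_px=5, seed=seed)
        assert 0.295 <= field.achieved_coverage <= 0.305
        assert brute_force_min_distance(field.centers) >= 10.0

    def test_border_margin_respected(self):
        field = sim.place_pores(256, 256, 0.40, pore_radius_px=5, seed=7)
        r = field.pore_radius_px
        assert field.centers[:, 0].min() >= r
        assert field.centers[:, 1].min() >= r
        assert field.centers[:, 0].max() <= 256 - r
        assert field.centers[:, 1].max() <= 256 - r

    def test_high_coverage_beyond_jamming_still_placed(self):
        field = sim.place_pores(256, 256, 0.60, seed=11)
        assert abs(field.achieved_coverage - 0.60) <= 0.005
        assert brute_force_min_distance(field.centers) >= 10.0

    def test_coverage_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sim.place_pores(256, 256, 0.7, seed=0)

    def test_stored_coverage_matches_centers(self):
        field = sim.place_pores(512, 512, 0.25, seed=5)
        assert field.achieved_coverage == pytest.approx(
            field.coverage_from_centers(), abs=0
        )

    def test_deterministic_for_fixed_seed(self):
        a = sim.place_pores(256, 256, 0.3, seed=9)
        b = sim.place_pores(256, 256, 0.3, seed=9)
        assert np.array_equal(a.centers, b.centers)

    def test_json_round_trip(self):
        a = sim.place_pores(128, 128, 0.2, seed=4)
        b = sim.PoreField.from_json(a.to_json())
        assert np.array_equal(a.centers, b.centers)
        assert b.achieved_coverage == a.achieved_coverage


class TestClusteredPlacement:
    def test_nonoverlap_and_coverage(self):
        field = sim.place_pores_clustered(512, 512, 0.10, seed=2)
        assert brute_force_min_distance(field.centers) >= 10.0
        assert field.achieved_coverage == pytest.approx(0.10, abs=0.01)

    def test_too_dense_for_ribbons_fails(self):
        with pytest.raises(sim.PlacementError):
            sim.place_pores_clustered(512, 512, 0.30, ribbon_fraction=0.3, seed=0)


def _lattice_field(n_side=100, spacing=12.0, radius=5.0, seed=0):
    """Direct PoreField construction on a square lattice (no placement)."""
    g = (np.arange(n_side) + 0.5) * spacing + radius
    xx, yy = np.meshgrid(g, g)
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    side = int(n_side * spacing + 2 * radius + 1)
    return sim.PoreField(
        region_width_px=side,
        region_height_px=side,
        pore_radius_px=radius,
        centers=centers,
        target_coverage=0.0,
        achieved_coverage=len(centers) * np.pi * radius**2 / side**2,
        seed=seed,
    )


class TestLabelling:
    def test_full_efficiency_keeps_every_site(self):
        field = sim.place_pores(128, 128, 0.2, seed=1)
        lab = sim.apply_labelling(field, 1.0, copies_per_pore=32)
        assert len(lab.sites) == field.n_pores * 32

    def test_zero_efficiency_keeps_nothing(self):
        field = sim.place_pores(128, 128, 0.2, seed=1)
        lab = sim.apply_labelling(field, 0.0)
        assert len(lab.sites) == 0

    @pytest.mark.parametrize("eff", [0.2, 0.5, 0.8])
    def test_retention_is_binomial(self, eff):
        # 10,000 pores x 32 copies: empirical retention within 3 binomial SE
        field = _lattice_field()
        lab = sim.apply_labelling(field, eff, copies_per_pore=32, seed=21)
        n_sites = field.n_pores * 32
        se = np.sqrt(eff * (1 - eff) / n_sites)
        assert abs(len(lab.sites) / n_sites - eff) <= 3 * se

    def test_sites_lie_on_pore_rings(self):
        field = sim.place_pores(128, 128, 0.15, seed=6)
        lab = sim.apply_labelling(field, 0.7, seed=6)
        centers_nm = field.centers[lab.pore_index] * sim.PIXEL_NM
        r = np.linalg.norm(lab.sites - centers_nm, axis=1)
        assert np.allclose(r, field.pore_radius_px * sim.PIXEL_NM)

    def test_invalid_efficiency_rejected(self):
        field = sim.place_pores(64, 64, 0.1, seed=0)
        with pytest.raises(ValueError):
            sim.apply_labelling(field, 1.5)


def _single_site_field(x_nm=500.0, y_nm=500.0):
    """One pore of zero ring radius with a single copy: a point source."""
    pores = sim.PoreField(
        region_width_px=100,
        region_height_px=100,
        pore_radius_px=0.0,
        centers=np.array([[x_nm / sim.PIXEL_NM, y_nm / sim.PIXEL_NM]]),
        target_coverage=0.0,
        achieved_coverage=0.0,
        seed=0,
    )
    return sim.apply_labelling(pores, 1.0, copies_per_pore=1, seed=0)


class TestRenderLocalizations:
    def test_no_sites_gives_empty_table(self):
        field = sim.place_pores(64, 64, 0.1, seed=0)
        lab = sim.apply_labelling(field, 0.0)
        locs = sim.render_localizations(lab)
        assert len(locs) == 0
        assert set(sim.LOC_COLUMNS) <= set(locs.columns)

    def test_localization_mean_converges_to_site(self):
        lab = _single_site_field()
        locs = sim.render_localizations(lab, mean_blinks_per_site=1000,
                                        precision_nm=10.0, seed=8)
        n = len(locs)
        bound = 3 * 10.0 / np.sqrt(n)
        assert abs(locs["x_nm"].mean() - 500.0) <= bound
        assert abs(locs["y_nm"].mean() - 500.0) <= bound

    def test_zero_precision_reproduces_sites_exactly(self):
        lab = _single_site_field()
        locs = sim.render_localizations(lab, mean_blinks_per_site=50,
                                        precision_nm=0.0, seed=8)
        assert np.all(locs["x_nm"] == 500.0)
        assert np.all(locs["y_nm"] == 500.0)

    def test_table_and_coords_paths_agree(self):
        field = sim.place_pores(128, 128, 0.2, seed=3)
        lab = sim.apply_labelling(field, 0.5, seed=3)
        locs = sim.render_localizations(lab, 5, 10, seed=3)
        pts = sim.draw_localization_coords(lab, 5, 10, seed=3)
        assert np.array_equal(locs[["x_nm", "y_nm"]].to_numpy(), pts)


class TestRenderImage:
    def test_empty_table_gives_zero_image(self):
        img = sim.render_image(np.empty((0, 2)), 32, 32)
        assert img.pixels.sum() == 0

    def test_pixel_sum_equals_in_bounds_count(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-50, 400, size=(1000, 2))
        img = sim.render_image(pts, 32, 32)
        in_bounds = np.sum(
            (pts[:, 0] >= 0) & (pts[:, 0] < 320) & (pts[:, 1] >= 0) & (pts[:, 1] < 320)
        )
        assert img.pixels.sum() == in_bounds
        assert img.n_out_of_bounds == 1000 - in_bounds

    def test_floor_binning_convention(self):
        img = sim.render_image(np.array([[25.0, 25.0]]), 4, 4)
        assert img.pixels[2, 2] == 1
        assert img.pixels.sum() == 1


class TestFilamentFixture:
    def test_zero_noise_points_lie_on_segment(self):
        locs = sim.make_filament_fixture((0, 0), (1000, 0), sigma_nm=0.0,
                                         n_locs=200, seed=0)
        assert np.all(locs["y_nm"] == 0.0)
        assert locs["x_nm"].between(0, 1000).all()

    def test_degenerate_line_rejected(self):
        with pytest.raises(ValueError):
            sim.make_filament_fixture((5, 5), (5, 5), 10.0, 100)

    def test_two_line_fixture_has_two_offset_populations(self):
        locs = sim.make_filament_fixture((0, 0), (1000, 0), sigma_nm=0.0,
                                         n_locs=400, second_line_offset_nm=111.0,
                                         seed=0)
        ys = np.sort(locs["y_nm"].unique())
        assert np.allclose(ys, [0.0, 111.0])
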