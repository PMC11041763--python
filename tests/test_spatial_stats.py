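"""Radial profiles, expression peaks, chemistry depth translation."""

import numpy as np
import pandas as pd
import pytest

import aggrescope as ag
from aggrescope.segmentation import ColonyObservation
from aggrescope.tracking import ColonyTrack


def _tracks_at_distances(distances, areas=None):
    areas = areas if areas is not None else [100.0] * len(distances)
    tracks = []
    for i, (d, a) in enumerate(zip(distances, areas)):
        obs = [ColonyObservation(0, 0.0, i + 1, float(a), (0.0, 0.0), float(d))]
        tracks.append(ColonyTrack(i, 0, obs, float(d)))
    return tracks


class TestRadialBiomassProfile:
    def test_all_colonies_in_one_bin(self, disk_geometry):
        tracks = _tracks_at_distances([250.0, 255.0, 260.0],
                                      [100.0, 200.0, 300.0])
        prof = ag.radial_biomass_profile(tracks, disk_geometry, bins=5)
        tab = prof.table
        nonzero = tab[tab["count"] > 0]
        assert len(nonzero) == 1
        assert nonzero["total_area_um2"].iloc[0] == 600.0

    def test_bin_conservation(self, disk_geometry, scene_pipeline):
        tracks = scene_pipeline["tracks"]
        geom = scene_pipeline["geometry"]
        prof = ag.radial_biomass_profile(tracks, geom, bins=8)
        total = sum(t.observations[-1].area_um2 for t in tracks)
        assert prof.table["total_area_um2"].sum() == pytest.approx(total)
        # mean size x count summed over bins equals the total area too
        tab = prof.table.dropna(subset=["mean_area_um2"])
        assert (tab["mean_area_um2"] * tab["count"]).sum() == pytest.approx(total)

    def test_generator_binning_matches_recount(self, scene_pipeline):
        tracks = scene_pipeline["tracks"]
        geom = scene_pipeline["geometry"]
        edges = np.linspace(0, geom.equivalent_radius_um, 7)
        prof = ag.radial_biomass_profile(tracks, geom, bins=edges)
        dist = [t.observations[-1].distance_to_edge_um for t in tracks]
        area = [t.observations[-1].area_um2 for t in tracks]
        for b in range(6):
            sel = [(edges[b] <= d < edges[b + 1]) or
                   (b == 5 and d == edges[6]) for d in dist]
            assert prof.table["count"].iloc[b] == sum(sel)
            assert prof.table["total_area_um2"].iloc[b] == pytest.approx(
                sum(a for a, s in zip(area, sel) if s))


class TestColonyRadialPdf:
    def test_density_integrates_to_one(self, disk_geometry):
        rng = np.random.default_rng(0)
        tracks = _tracks_at_distances(rng.uniform(0, 1500, 200))
        prof = ag.colony_radial_pdf(tracks, disk_geometry)
        x = prof.table["distance_um"].to_numpy()
        d = prof.table["density"].to_numpy()
        assert np.trapezoid(d, x) == pytest.approx(1.0, abs=1e-6)

    def test_uniform_placement_gives_flat_density(self, disk_geometry):
        rng = np.random.default_rng(1)
        tracks = _tracks_at_distances(rng.uniform(0, 1500, 4000))
        prof = ag.colony_radial_pdf(tracks, disk_geometry, bandwidth=0.1)
        x = prof.table["distance_um"].to_numpy()
        d = prof.table["density"].to_numpy()
        interior = (x > 150) & (x < 1350)
        assert np.all(np.abs(d[interior] * 1500 - 1.0) < 0.25)

    def test_mode_at_cluster(self, disk_geometry):
        tracks = _tracks_at_distances([100.0, 101.0, 99.0, 100.5])
        prof = ag.colony_radial_pdf(tracks, disk_geometry)
        x = prof.table["distance_um"].to_numpy()
        d = prof.table["density"].to_numpy()
        assert abs(x[np.argmax(d)] - 100.0) < 25.0

    def test_single_colony_degenerate(self, disk_geometry):
        with pytest.raises(ValueError):
            ag.colony_radial_pdf(_tracks_at_distances([100.0]), disk_geometry)


class TestExpressionRadialProfile:
    @pytest.mark.parametrize("center,sigma,tol", [(204.0, 34.0, 5.0),
                                                  (489.0, 146.0, 10.0)])
    def test_gaussian_ring_peak_recovered(self, disk_geometry, center, sigma, tol):
        img = ag.render_expression_ring(disk_geometry, center, sigma,
                                        rng=np.random.default_rng(2))
        prof = ag.expression_radial_profile(img, disk_geometry)
        assert abs(prof.peak_mean_um - center) < tol

    def test_density_normalized(self, disk_geometry):
        img = ag.render_expression_ring(disk_geometry, 204.0, 34.0,
                                        rng=np.random.default_rng(3))
        prof = ag.expression_radial_profile(img, disk_geometry)
        widths = np.diff(np.append(prof.distance_um - 5.0,
                                   prof.distance_um[-1] + 5.0))
        assert (prof.density * widths).sum() == pytest.approx(1.0, abs=1e-6)

    def test_uniform_signal_weighted_median_matches_cumsum(self, disk_geometry):
        img = np.where(disk_geometry.particle_mask, 50.0, 0.0)
        prof = ag.expression_radial_profile(img, disk_geometry)
        # brute-force cumulative sum over the per-bin weights
        w = prof.density
        centers = prof.distance_um
        cum = np.cumsum(w) / w.sum()
        expected = float(np.interp(0.5, cum, centers))
        assert prof.peak_median_um == pytest.approx(expected, abs=10.0)

    def test_all_zero_channel_rejected(self, disk_geometry):
        with pytest.raises(ValueError, match="empty"):
            ag.expression_radial_profile(
                np.zeros(disk_geometry.particle_mask.shape), disk_geometry)

    def test_diatom_pixels_excluded(self, disk_geometry):
        img = ag.render_expression_ring(disk_geometry, 204.0, 34.0,
                                        noise_sd=0.0)
        diatoms = np.zeros(img.shape, bool)
        diatoms[160:180, 150:220] = True
        hot = img.copy()
        hot[diatoms] = 1e4   # chlorophyll bleed-through
        prof = ag.expression_radial_profile(hot, disk_geometry,
                                            diatom_mask=diatoms)
        assert abs(prof.peak_mean_um - 204.0) < 5.0


class TestChemistryDepthProfile:
    def test_sample_at_100h_maps_to_20m(self):
        df = pd.DataFrame({"time_h": [0.0, 100.0], "doc_mg_L": [28.0, 5.0]})
        out = ag.chemistry_depth_profile(df)
        assert out["depth_m"].iloc[1] == pytest.approx(20.0)

    def test_constant_series_flat_profile(self):
        df = pd.DataFrame({"time_h": np.arange(0, 100, 24.0),
                           "no3_umol_L": 10.0})
        out = ag.chemistry_depth_profile(df)
        assert out["no3_umol_L"].nunique() == 1

    def test_generator_broken_series_initial_doc(self):
        series = ag.simulate_bulk_chemistry("broken")
        out = ag.chemistry_depth_profile(series)
        assert out["doc_mg_L"].iloc[0] == pytest.approx(28.0)

    def test_non_monotone_time_rejected(self):
        df = pd.DataFrame({"time_h": [0.0, 48.0, 24.0], "doc_mg_L": 1.0})
        with pytest.raises(ValueError, match="strictly increasing"):
            ag.chemistry_depth_profile(df)

    def test_depth_mapping_commutes_with_unit_conversion(self):
        t_h = np.array([0.0, 50.0, 100.0])
        direct = ag.depth_from_time(t_h, 4.8)
        via_days = 4.8 * (t_h / 24.0)
        assert np.allclose(direct, via_days)


class TestCompareConditions:
    def test_identical_samples(self):
        res = ag.compare_conditions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_separated_samples_small_p(self):
        rng = np.random.default_rng(0)
        a = 1.0 + rng.normal(0, 1e-3, 3)
        b = 2.0 + rng.normal(0, 1e-3, 3)
        assert ag.compare_conditions(a, b).p < 0.01

    def test_hand_computed_welch_statistic(self):
        # A = {1,2,3}, B = {2,4,6}: t = -2 / sqrt(1/3 + 4/3) = -1.5492,
        # Welch-Satterthwaite df = (5/3)^2 / (1/18 + 16/18) = 50/17
        res = ag.compare_conditions([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert res.t == pytest.approx(-1.549193, abs=1e-5)
        assert res.df == pytest.approx(50.0 / 17.0, abs=1e-6)

    def test_swap_negates_t_preserves_p(self):
        a, b = [1.0, 1.2, 0.9], [2.0, 2.2, 1.8]
        r1 = ag.compare_conditions(a, b)
        r2 = ag.compare_conditions(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            ag.compare_conditions([1.0], [2.0, 3.0])
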