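"""Generator: oxygen solver oracle checks, rendering contracts, chemistry."""

import numpy as np
import pytest

import aggrescope as ag
from aggrescope.synthetic_scene import uniform_consumption_closed_form

from conftest import small_scene_config


def _disk(shape, radius_px):
    yy, xx = np.indices(shape)
    c = (shape[0] - 1) / 2
    r = np.hypot(yy - c, xx - c)
    return r <= radius_px, r


class TestOxygenSolver:
    def test_no_sinks_returns_boundary_everywhere(self):
        mask, _ = _disk((64, 64), 25)
        c = ag.simulate_oxygen_field(mask, np.zeros(mask.shape), 210.0,
                                     pixel_size_um=10.0)
        assert np.allclose(c, 210.0)

    def test_uniform_consumption_matches_closed_form(self):
        # D lap C = q on a disk has C(r) = boundary - q (R^2 - r^2) / (4 D);
        # the discrete Dirichlet layer sits half a pixel beyond the mask.
        h, D, boundary, q0 = 12.5, 1900.0, 210.0, 0.135
        mask, r = _disk((128, 128), 55.0)
        c = ag.simulate_oxygen_field(mask, np.where(mask, q0, 0.0), boundary,
                                     D, pixel_size_um=h, tol=1e-8)
        r_eff = (np.sqrt(mask.sum() / np.pi) + 0.5) * h
        expected = uniform_consumption_closed_form(r * h, r_eff, boundary, q0, D)
        center = r < 1
        mid = np.abs(r * h - r_eff / 2) < h
        for sel in (center, mid & mask):
            err = np.abs(c[sel] - expected[sel]).max() / boundary
            assert err < 1e-3

    def test_single_central_sink_concentration_increases_outward(self):
        # Maximum principle: with one interior sink, C is non-decreasing
        # along every radius, scanned brute-force.
        mask, r = _disk((96, 96), 40.0)
        q = np.zeros(mask.shape)
        q[44:52, 44:52] = 80.0
        c = ag.simulate_oxygen_field(mask, q, 210.0, pixel_size_um=10.0)
        center = (mask.shape[0] - 1) / 2
        for theta in np.linspace(0, 2 * np.pi, 16, endpoint=False):
            rr = np.arange(5, 39)
            rows = np.round(center + rr * np.sin(theta)).astype(int)
            cols = np.round(center + rr * np.cos(theta)).astype(int)
            prof = c[rows, cols]
            # rasterized rays wobble tangentially between grid cells; allow
            # that discretization jitter but no genuine interior maximum
            assert np.all(np.diff(prof) >= -1e-3)
        # and the shell means are strictly monotone outward
        ri = np.round(r).astype(int)
        shell_means = [c[mask & (ri == k)].mean() for k in range(4, 39)]
        assert np.all(np.diff(shell_means) > 0)

    def test_sink_outside_particle_rejected(self):
        mask, _ = _disk((32, 32), 10)
        q = np.zeros(mask.shape)
        q[1, 1] = 5.0
        with pytest.raises(ValueError, match="inside the particle"):
            ag.simulate_oxygen_field(mask, q, 210.0)

    def test_non_convergence_is_an_explicit_failure(self):
        mask, _ = _disk((64, 64), 25)
        with pytest.raises(ag.SolverConvergenceError):
            ag.simulate_oxygen_field(mask, np.where(mask, 10.0, 0.0), 210.0,
                                     pixel_size_um=10.0, max_iter=3)


class TestRendering:
    def test_no_colonies_sensor_equals_air_endmember(self):
        config = small_scene_config(n_colonies=0, n_frames=2, n_diatoms=2,
                                    particle_radius_um=500.0)
        stack, cal, _ = ag.render_frames(config)
        for frame in stack.sensor:
            assert np.allclose(frame, cal.air)

    def test_same_seed_bit_identical_different_seed_not(self):
        config = small_scene_config(n_frames=2, particle_radius_um=500.0,
                                    n_colonies=3, noise_sd=10.0)
        a = ag.render_frames(config)
        b = ag.render_frames(config)
        assert np.array_equal(a[0].sensor, b[0].sensor)
        assert np.array_equal(a[0].brightfield, b[0].brightfield)
        c = ag.render_frames(small_scene_config(
            n_frames=2, particle_radius_um=500.0, n_colonies=3,
            noise_sd=10.0, rng_seed=4))
        assert not np.array_equal(a[0].sensor, c[0].sensor)

    def test_exponential_growth_doubles_at_ln2_over_mu(self):
        params = ag.DiauxicGrowthParams(mu1=0.05, lag_start_h=1e9,
                                        lag_duration_h=0.0, mu2=0.0,
                                        area0_um2=100.0)
        t_double = np.log(2) / 0.05  # ~13.9 h
        assert params.area_at(t_double) == pytest.approx(200.0)
        assert params.area_at(2 * t_double) == pytest.approx(400.0)

    def test_ground_truth_areas_match_label_maps(self, scene):
        config, _, _, truth = scene
        px = config.pixel_size_um ** 2
        for cid, areas in truth.areas_um2.items():
            counted = [(truth.labels[t] == cid).sum() * px
                       for t in range(config.n_frames)]
            assert np.array_equal(np.asarray(counted), areas)

    def test_colony_masks_inside_particle(self, scene):
        _, _, _, truth = scene
        assert not np.any((truth.labels > 0) & ~truth.particle_mask[None])

    def test_explicit_colony_position_outside_particle_rejected(self):
        config = small_scene_config(
            particle_radius_um=500.0, n_frames=3,
            colony_seed_positions=[(495.0, 0.0)])
        with pytest.raises(ValueError, match="outside the particle"):
            ag.render_frames(config)

    def test_sensor_transform_strictly_decreasing_in_oxygen(self):
        ksv, f0 = 0.01, 1000.0
        c = np.linspace(0, 300, 100)
        f = f0 / (1 + ksv * c)
        assert np.all(np.diff(f) < 0)


class TestBulkChemistry:
    @pytest.mark.parametrize("scenario,doc0", [("broken", 28.0), ("intact", 14.0)])
    def test_initial_doc_matches_scenario(self, scenario, doc0):
        df = ag.simulate_bulk_chemistry(scenario)
        assert df["doc_mg_L"].iloc[0] == pytest.approx(doc0)

    def test_series_non_negative_and_scenario_shapes(self):
        broken = ag.simulate_bulk_chemistry("broken")
        intact = ag.simulate_bulk_chemistry("intact")
        for df in (broken, intact):
            assert (df[["doc_mg_L", "no3_umol_L", "no2_umol_L"]] >= 0).all().all()
        # broken leak twice the intact initial efflux; pulse decays faster
        assert broken["doc_mg_L"].iloc[0] == pytest.approx(
            2 * intact["doc_mg_L"].iloc[0])
        drop_broken = broken["doc_mg_L"].iloc[0] - broken["doc_mg_L"].iloc[5]
        drop_intact = intact["doc_mg_L"].iloc[0] - intact["doc_mg_L"].iloc[5]
        assert drop_broken > drop_intact
        # broken nitrite leaks immediately; intact peaks mid-series
        assert broken["no2_umol_L"].iloc[0] > intact["no2_umol_L"].iloc[0]
        assert intact["no2_umol_L"].idxmax() > 2

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            ag.simulate_bulk_chemistry("pulverized")
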