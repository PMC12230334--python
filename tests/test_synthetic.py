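"""Generator fidelity: shapes, undulations, edge memory, dropouts, noise."""

import math

import numpy as np
import pytest

import sicmorph as sm
from sicmorph.synthetic import cap_surface_area, cap_volume

from conftest import flat_topography


class TestCaps:
    def test_centre_height_and_substrate(self):
        t = sm.make_cap(101, 101, 10.0, 400.0, 300.0)
        assert t.heights[50, 50] == pytest.approx(300.0)
        assert t.heights[0, 0] == 0.0
        footprint_r = math.sqrt(300.0 * (2 * 400.0 - 300.0))
        yy, xx = np.mgrid[0:101, 0:101]
        rho = np.hypot((xx - 50) * 10.0, (yy - 50) * 10.0)
        assert np.all(t.heights[rho > footprint_r + 15.0] == 0.0)

    def test_shallow_cap_volume_closed_form(self):
        r, h = 400.0, 300.0
        t = sm.make_cap(301, 301, 3.0, r, h)
        v = t.pitch_x * t.pitch_y * t.heights.sum()
        assert v == pytest.approx(math.pi * h**2 * (3 * r - h) / 3.0, rel=0.01)

    def test_tall_cap_matches_closed_forms(self):
        # h > r: upper hemisphere over a vertical shadow wall
        r, h = 500.0, 900.0
        t = sm.make_cap(251, 251, 5.0, r, h)
        mask = sm.segment_object(t, rel_threshold=0.01)
        assert sm.volume(t, mask) == pytest.approx(cap_volume(r, h), rel=0.01)
        # a vertical cylindrical wall rendered on a square grid is a
        # staircase of facets: its triangulated area lies between the true
        # cylinder (factor 1) and the axis-aligned bound (factor 4/pi)
        zone = 2 * math.pi * r * r
        wall = 2 * math.pi * r * (h - r)
        sa = sm.surface_area(t, mask)
        assert zone + wall < sa < zone + (4 / math.pi) * wall

    def test_height_cannot_exceed_diameter(self):
        with pytest.raises(ValueError):
            sm.make_cap(32, 32, 10.0, 100.0, 201.0)

    def test_ledger_closes_loop_with_shape_metrics(self, default_study):
        """Analytic ideal V/SA in the ground-truth ledger agree with the
        analyzer run on the noiseless grid (spherical records)."""
        _, ledger = default_study
        checked = 0
        for entry in ledger["records"]:
            if entry["ideal_method"] != "analytic" or not entry["complete"]:
                continue
            cfg = sm.SynthConfig(
                n_rows=128, n_cols=128, pitch_nm=entry["pitch_nm"],
                cap_radius_nm=entry["cap_radius_nm"],
                cap_height_nm=entry["cap_height_nm"],
            )
            ideal = sm.make_cap(
                cfg.n_rows, cfg.n_cols, cfg.pitch_nm, cfg.cap_radius_nm, cfg.cap_height_nm
            )
            mask = sm.segment_object(ideal, rel_threshold=0.01)
            assert sm.volume(ideal, mask) == pytest.approx(entry["ideal_volume_nm3"], rel=0.03)
            # triangulated SA of the shadow wall carries the staircase
            # factor (up to 4/pi on the wall term); see the tall-cap test
            ratio = sm.surface_area(ideal, mask) / entry["ideal_sa_nm2"]
            assert 0.99 < ratio < 1.15
            checked += 1
        assert checked >= 3


class TestIrregular:
    def test_single_lobe_falls_back_with_warning(self):
        with pytest.warns(UserWarning):
            t = sm.make_irregular(64, 64, 25.0, 500.0, 900.0, n_lobes=1, seed=0)
        ref = sm.make_cap(64, 64, 25.0, 500.0, 900.0)
        np.testing.assert_array_equal(t.heights, ref.heights)

    def test_deterministic_per_seed(self):
        a = sm.make_irregular(96, 96, 25.0, 800.0, 1400.0, seed=9)
        b = sm.make_irregular(96, 96, 25.0, 800.0, 1400.0, seed=9)
        np.testing.assert_array_equal(a.heights, b.heights)
        c = sm.make_irregular(96, 96, 25.0, 800.0, 1400.0, seed=10)
        assert not np.array_equal(a.heights, c.heights)


class TestUndulations:
    def test_zero_amplitude_is_identity(self):
        t = sm.make_cap(64, 64, 25.0, 700.0, 1300.0)
        out = sm.add_undulations(t, 0.0, 100.0, seed=1)
        np.testing.assert_array_equal(out.heights, t.heights)

    def test_substrate_untouched(self):
        t = sm.make_cap(64, 64, 25.0, 500.0, 900.0)
        out = sm.add_undulations(t, 100.0, 100.0, seed=2)
        np.testing.assert_array_equal(out.heights[t.heights == 0.0], 0.0)

    def test_rms_hits_target_within_15_percent(self):
        t = sm.make_cap(128, 128, 25.0, 950.0, 1800.0)
        inside = t.heights > 200.0
        rms_values = []
        for seed in range(10):
            out = sm.add_undulations(t, 100.0, 100.0, seed=seed)
            rms_values.append(np.sqrt(np.mean((out.heights - t.heights)[inside] ** 2)))
        assert np.mean(rms_values) == pytest.approx(50.0, rel=0.15)


class TestEdgeMemory:
    def test_expired_memory_means_identical_scans(self):
        t = sm.make_cap(96, 96, 25.0, 800.0, 1500.0)
        pair = sm.apply_edge_memory(t, delta0_nm=150.0, t_prep_h=20.0, t_zero_h=18.8, seed=0)
        np.testing.assert_array_equal(pair.forward.heights, pair.backward.heights)
        assert sm.total_edge_volume(pair) == 0.0

    def test_forward_scan_is_the_input(self):
        t = sm.make_cap(96, 96, 25.0, 800.0, 1500.0)
        pair = sm.apply_edge_memory(t, 150.0, 2.0, 18.8, seed=0)
        np.testing.assert_array_equal(pair.forward.heights, t.heights)

    def test_tev_non_increasing_with_time(self):
        t = sm.make_cap(96, 96, 25.0, 800.0, 1500.0)
        tevs = []
        for tp in (1.0, 5.0, 9.0, 13.0, 17.0):
            pair = sm.apply_edge_memory(t, 150.0, tp, 18.8, seed=3)
            tevs.append(sm.total_edge_volume(pair))
        assert all(a >= b for a, b in zip(tevs, tevs[1:]))
        assert tevs[0] > 0

    def test_boundary_moves_outward_by_delta(self):
        # with zero anisotropy the footprint radius grows by ~delta everywhere
        t = sm.make_cap(128, 128, 25.0, 800.0, 1500.0)
        pair = sm.apply_edge_memory(t, 100.0, 0.0, 18.8, anisotropy=0.0, seed=1)
        row = 64
        fwd_w = np.count_nonzero(pair.forward.heights[row] > 1.0) * 25.0
        bwd_w = np.count_nonzero(pair.backward.heights[row] > 1.0) * 25.0
        assert bwd_w - fwd_w == pytest.approx(2 * 100.0, abs=50.0)


class TestDropouts:
    @staticmethod
    def _steep_pair():
        t = sm.make_cap(64, 64, 25.0, 700.0, 1300.0)
        return sm.ScanPair(
            t,
            sm.Topography(t.heights.copy(), 25.0, 25.0, direction="backward"),
        )

    def test_q_zero_is_identity(self):
        pair = self._steep_pair()
        out, truth = sm.apply_dropouts(pair, q=0.0, seed=0)
        np.testing.assert_array_equal(out.forward.heights, pair.forward.heights)
        assert truth["forward"].sum() == 0 and truth["backward"].sum() == 0

    def test_q_one_single_eligible_pixel(self):
        z = np.array([[0.0, 0.0, 10.0, 2000.0, 2000.0, 2000.0, 2000.0, 2000.0]])
        pair = sm.ScanPair(
            flat_topography(z, pitch=10.0),
            sm.Topography(z.copy() * 0, 10.0, 10.0, direction="backward"),
        )
        out, truth = sm.apply_dropouts(pair, q=1.0, slope_threshold=50.0, max_run=3, seed=1)
        # exactly one trigger (the 10 -> 2000 on-object climb); the run starts
        # at the next pixel along the scan
        rows, cols = np.nonzero(truth["forward"])
        assert len(rows) >= 1 and cols.min() == 4
        assert np.all(out.forward.heights[truth["forward"]] == 0.0)

    def test_trigger_rate_is_binomial(self):
        """Observed run starts match Binomial(n_eligible, q) within 3 sigma."""
        q = 0.2
        t = sm.make_cap(64, 64, 25.0, 700.0, 1300.0)
        z = t.heights
        climb = (z[:, 1:] - z[:, :-1]) / 25.0
        on_obj = (z[:, 1:] > 0) & (z[:, :-1] > 0)
        n_eligible = int(((climb > 1.0) & on_obj).sum())
        total = 0
        n_rep = 20
        for seed in range(n_rep):
            pair = self._steep_pair()
            out, truth = sm.apply_dropouts(pair, q=q, slope_threshold=1.0, max_run=1, seed=seed)
            total += int(truth["forward"].sum())
        mean, var = n_rep * n_eligible * q, n_rep * n_eligible * q * (1 - q)
        assert abs(total - mean) <= 3 * math.sqrt(var) + 0.05 * mean

    def test_dropped_pixels_rest_at_substrate(self):
        pair = self._steep_pair()
        out, truth = sm.apply_dropouts(pair, q=0.3, seed=2)
        assert truth["forward"].any()
        np.testing.assert_array_equal(out.forward.heights[truth["forward"]], 0.0)


class TestNoise:
    def test_zero_sigma_identity(self):
        t = flat_topography(np.zeros((8, 8)))
        np.testing.assert_array_equal(sm.add_noise(t, 0.0, seed=0).heights, t.heights)

    def test_sample_sd_matches_sigma(self):
        t = flat_topography(np.zeros((256, 256)))
        out = sm.add_noise(t, 1.0, seed=3)
        assert np.std(out.heights - t.heights) == pytest.approx(1.0, rel=0.05)

    def test_same_seed_reproduces(self):
        t = flat_topography(np.zeros((32, 32)))
        a = sm.add_noise(t, 1.0, seed=7).heights
        b = sm.add_noise(t, 1.0, seed=7).heights
        np.testing.assert_array_equal(a, b)


class TestStudy:
    def test_same_master_seed_is_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            records, ledger = sm.simulate_study(n_records=3, master_seed=21, grid=48)
            sm.write_study(records, ledger, tmp_path / sub)
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_invalid_schedule_rejected(self):
        with pytest.raises(ValueError):
            sm.simulate_study(n_records=3, t_prep_h=[1.0, 2.0])
        with pytest.raises(ValueError):
            sm.simulate_study(n_records=0)

    def test_noise_only_tev_matches_folded_gaussian(self):
        """Without edge memory or dropouts, TEV is pure noise: the mean
        absolute difference of two sigma-noisy scans is 2*sigma/sqrt(pi)."""
        sigma = 1.0
        cfg = sm.SynthConfig(seed=13, delta0_nm=0.0, dropout_q=0.0, noise_sigma_nm=sigma)
        pair, _ = sm.synthesize_pair(cfg)
        n_px = pair.forward.heights.size
        expected = pair.pitch_x * pair.pitch_y * n_px * 2 * sigma / math.sqrt(math.pi)
        assert sm.total_edge_volume(pair) == pytest.approx(expected, rel=0.03)
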