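"""Projection, kernel UDs, isopleths and Bhattacharyya overlap."""

import numpy as np
import pandas as pd
import pytest

import kittitrack as kt
from kittitrack.space_use import (
    IsoplethUD,
    UDGrid,
    ba_bootstrap,
    colony_ud_pair,
    isopleth,
    kernel_ud,
    reference_bandwidth,
)

CENTER = (50.0, 170.0)


class TestProjection:
    def test_center_maps_to_origin(self):
        x, y = kt.project_points(CENTER[0], CENTER[1], CENTER)
        assert float(x) == pytest.approx(0.0, abs=1e-9)
        assert float(y) == pytest.approx(0.0, abs=1e-9)

    def test_round_trip(self, rng):
        lat = rng.uniform(30, 65, 50)
        lon = rng.uniform(140, 220, 50)  # crosses the antimeridian
        x, y = kt.project_points(lat, lon, CENTER)
        lat2, lon2 = kt.unproject_points(x, y, CENTER)
        assert np.allclose(lat, lat2, atol=1e-6)
        dlon = (np.asarray(lon2) - lon + 180.0) % 360.0 - 180.0
        assert np.allclose(dlon, 0.0, atol=1e-6)

    def test_meridian_arc_scale(self):
        # one degree of latitude near the center spans ~111.2 km
        x0, y0 = kt.project_points(50.0, 170.0, CENTER)
        x1, y1 = kt.project_points(51.0, 170.0, CENTER)
        assert abs(float(y1) - float(y0)) == pytest.approx(111.195, abs=0.1)

    def test_antipode_rejected(self):
        with pytest.raises(ValueError, match="antipode"):
            kt.project_points(-50.0, -10.0, CENTER)


class TestKernelUD:
    def test_mass_normalized(self, rng):
        lat = rng.normal(50, 2, 40)
        lon = rng.normal(170, 3, 40)
        ud = kernel_ud(lat, lon, cell_size_km=50.0)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)
        assert (ud.density >= 0).all()

    def test_tight_cluster_mode_location(self):
        lat = np.array([50.0, 50.01, 49.99, 50.0, 50.0])
        lon = np.array([170.0, 170.0, 170.0, 170.01, 169.99])
        ud = kernel_ud(lat, lon, center=CENTER, cell_size_km=10.0, bandwidth_km=20.0)
        iy, ix = np.unravel_index(np.argmax(ud.density), ud.density.shape)
        x_c, y_c = kt.project_points(50.0, 170.0, CENTER)
        assert abs(ud.x[ix] - float(x_c)) <= ud.cell_size_km
        assert abs(ud.y[iy] - float(y_c)) <= ud.cell_size_km

    def test_matches_direct_gaussian_sum_oracle(self, rng):
        # independent brute-force kernel sum on a 10-point set
        lat = rng.uniform(48, 52, 10)
        lon = rng.uniform(168, 172, 10)
        h = 75.0
        ud = kernel_ud(lat, lon, center=CENTER, cell_size_km=50.0, bandwidth_km=h)
        x, y = kt.project_points(lat, lon, CENTER)
        x, y = np.asarray(x), np.asarray(y)
        oracle = np.zeros_like(ud.density)
        for iy, gy in enumerate(ud.y):
            for ix, gx in enumerate(ud.x):
                oracle[iy, ix] = np.sum(
                    np.exp(-((gx - x) ** 2 + (gy - y) ** 2) / (2 * h * h))
                ) / (2 * np.pi * h * h)
        oracle /= oracle.sum() * ud.cell_area
        assert np.allclose(ud.density, oracle, atol=1e-8)

    def test_degenerate_points_need_explicit_bandwidth(self):
        lat = np.full(6, 50.0)
        lon = np.full(6, 170.0)
        with pytest.raises(ValueError, match="bandwidth"):
            kernel_ud(lat, lon, center=CENTER)
        ud = kernel_ud(lat, lon, center=CENTER, bandwidth_km=50.0)
        assert ud.total_mass() == pytest.approx(1.0, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 5"):
            kernel_ud([50.0] * 4, [170.0] * 4, center=CENTER, bandwidth_km=10.0)


@pytest.fixture(scope="module")
def smooth_ud():
    rng = np.random.default_rng(7)
    lat = rng.normal(50, 2.5, 120)
    lon = rng.normal(170, 4, 120)
    return kernel_ud(lat, lon, center=CENTER, cell_size_km=25.0)


class TestIsopleth:
    def test_level_one_is_all_positive_cells(self, smooth_ud):
        iso = isopleth(smooth_ud, 1.0)
        assert (iso.mask == (smooth_ud.density > 0)).all()

    def test_mask_is_density_threshold_set(self, smooth_ud):
        iso = isopleth(smooth_ud, 0.5)
        thr = smooth_ud.density[iso.mask].min()
        assert (smooth_ud.density[iso.mask] >= thr).all()
        assert (smooth_ud.density[~iso.mask] <= thr).all()

    def test_mass_quantization_bound(self, smooth_ud):
        iso = isopleth(smooth_ud, 0.5)
        max_cell = smooth_ud.density.max() * smooth_ud.cell_area
        assert 0.5 <= iso.mass() < 0.5 + max_cell

    def test_mode_inside_core(self, smooth_ud):
        iso = isopleth(smooth_ud, 0.5)
        assert iso.mask.ravel()[np.argmax(smooth_ud.density)]

    def test_invalid_level(self, smooth_ud):
        for lv in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                isopleth(smooth_ud, lv)


class TestBhattacharyya:
    @pytest.mark.parametrize("level", [0.5, 0.95])
    def test_self_overlap_attains_level(self, smooth_ud, level):
        iso = isopleth(smooth_ud, level)
        ba = kt.bhattacharyya(iso, iso)
        assert ba == pytest.approx(level, abs=0.005)

    def test_disjoint_masks_zero(self, smooth_ud):
        iso = isopleth(smooth_ud, 0.5)
        other = IsoplethUD(
            parent=smooth_ud,
            level=0.5,
            mask=~iso.mask,
            truncated_density=np.where(~iso.mask, smooth_ud.density, 0.0),
        )
        assert kt.bhattacharyya(iso, other) == 0.0

    def test_symmetry_and_bounds(self, smooth_ud, rng):
        lat = rng.normal(51, 3, 80)
        lon = rng.normal(172, 3, 80)
        other = kernel_ud(lat, lon, center=CENTER, cell_size_km=25.0,
                          grid=(smooth_ud.x, smooth_ud.y), bandwidth_km=smooth_ud.bandwidth_km)
        for level in (0.5, 0.95):
            a, b = isopleth(smooth_ud, level), isopleth(other, level)
            ba = kt.bhattacharyya(a, b)
            assert ba == pytest.approx(kt.bhattacharyya(b, a), abs=1e-12)
            max_cell = max(smooth_ud.density.max(), other.density.max()) * smooth_ud.cell_area
            assert 0.0 <= ba <= level + max_cell

    def test_mismatched_grids_rejected(self, smooth_ud, rng):
        other = kernel_ud(rng.normal(50, 2, 30), rng.normal(170, 2, 30),
                          center=CENTER, cell_size_km=50.0)
        with pytest.raises(ValueError, match="grid"):
            kt.bhattacharyya(isopleth(smooth_ud, 0.5), isopleth(other, 0.5))

    def test_resolution_stability(self, rng):
        # halving the cell size changes BA by < 0.01 on smooth synthetic UDs
        lat_a, lon_a = rng.normal(50, 2, 100), rng.normal(169, 3, 100)
        lat_b, lon_b = rng.normal(51, 2, 100), rng.normal(171, 3, 100)
        bas = []
        for cell in (50.0, 25.0):
            ud_a = kernel_ud(lat_a, lon_a, center=CENTER, cell_size_km=cell, bandwidth_km=150.0)
            ud_b = kernel_ud(lat_b, lon_b, center=CENTER, cell_size_km=cell,
                             grid=(ud_a.x, ud_a.y), bandwidth_km=150.0)
            bas.append(kt.bhattacharyya(isopleth(ud_a, 0.95), isopleth(ud_b, 0.95)))
        assert abs(bas[0] - bas[1]) < 0.01


def _two_colony_positions(rng, n_birds=5, n_days=30, shift=(0.0, 0.0)):
    rows = []
    for colony, (dlat, dlon) in (("A", (0.0, 0.0)), ("B", shift)):
        for b in range(n_birds):
            lat = rng.normal(50 + dlat, 1.5, n_days)
            lon = rng.normal(170 + dlon, 2.0, n_days)
            for d in range(n_days):
                rows.append((f"{colony}{b}", colony, d, lat[d], lon[d]))
    return pd.DataFrame(rows, columns=["bird_id", "colony", "date", "lat", "lon"])


class TestBABootstrap:
    def test_identical_shared_track_zero_se(self):
        # every bird in each group carries one identical track: no resampling variance
        days = list(range(10))
        rows = []
        for colony in ("A", "B"):
            for b in range(3):
                for d in days:
                    rows.append((f"{colony}{b}", colony, d, 50.0 + 0.3 * d, 170.0 + 0.5 * d))
        df = pd.DataFrame(rows, columns=["bird_id", "colony", "date", "lat", "lon"])
        res = ba_bootstrap(df[df.colony == "A"], df[df.colony == "B"], 0.5,
                           n_boot=20, seed=3, cell_size_km=25.0, bandwidth_km=100.0)
        assert res.ba_se == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        df = _two_colony_positions(rng, shift=(1.0, 2.0))
        args = (df[df.colony == "A"], df[df.colony == "B"], 0.5)
        r1 = ba_bootstrap(*args, n_boot=15, seed=42, cell_size_km=50.0)
        r2 = ba_bootstrap(*args, n_boot=15, seed=42, cell_size_km=50.0)
        assert r1 == r2

    def test_se_same_order_as_jackknife(self, rng):
        df = _two_colony_positions(rng, n_birds=10, shift=(0.5, 1.0))
        pos_a, pos_b = df[df.colony == "A"], df[df.colony == "B"]
        boot = ba_bootstrap(pos_a, pos_b, 0.95, n_boot=60, seed=5, cell_size_km=50.0)
        # leave-one-out jackknife over birds of group A as an independent scale check
        from kittitrack.space_use import ba_overlap

        birds = sorted(pos_a.bird_id.unique())
        loo = np.array(
            [ba_overlap(pos_a[pos_a.bird_id != b], pos_b, 0.95, cell_size_km=50.0) for b in birds]
        )
        n = len(birds)
        jack_se = np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2))
        assert 0.1 <= boot.ba_se / max(jack_se, 1e-12) <= 10.0

    def test_colony_relabeling_invariance(self, rng):
        df = _two_colony_positions(rng, shift=(1.0, 1.5))
        pos_a, pos_b = df[df.colony == "A"], df[df.colony == "B"]
        ud_a, ud_b = colony_ud_pair(pos_a, pos_b, cell_size_km=50.0)
        ba_ab = kt.bhattacharyya(isopleth(ud_a, 0.5), isopleth(ud_b, 0.5))
        ud_b2, ud_a2 = colony_ud_pair(pos_b, pos_a, cell_size_km=50.0)
        ba_ba = kt.bhattacharyya(isopleth(ud_b2, 0.5), isopleth(ud_a2, 0.5))
        assert ba_ab == pytest.approx(ba_ba, abs=1e-12)

    def test_needs_two_birds_per_group(self, rng):
        df = _two_colony_positions(rng, n_birds=1)
        with pytest.raises(ValueError, match="2 birds"):
            ba_bootstrap(df[df.colony == "A"], df[df.colony == "B"], 0.5, n_boot=5, seed=0)
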