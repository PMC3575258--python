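"""Coordinate normalisation, resampling, averaging and projection oracles."""

import numpy as np
import pytest

from hdemgmap import (
    ActivationBlob,
    ActivationMap,
    ElectrodeGrid,
    NormalizedMap,
    Projection,
    average_maps,
    bipolar_rms,
    common_coordinates,
    generate_from_gains,
    normalize_map_coords,
    project_map,
    projection_median,
    region_mean_intensity,
    resample_common_grid,
    segment_map,
    variability_summary,
)

from conftest import FS, sine_recording


def make_map(values, pitch=10.0):
    values = np.asarray(values, dtype=float)
    return ActivationMap(values, np.arange(values.shape[1]) * pitch,
                         np.arange(values.shape[0]) * pitch)


class TestNormalization:
    def test_known_arithmetic(self):
        grid = ElectrodeGrid(6, 17, pitch_mm=10.0, origin_row=2, origin_col=7,
                             circumference_mm=250.0, segment_length_mm=200.0)
        nmap = normalize_map_coords(make_map(np.ones((6, 17))), grid)
        assert nmap.x[12] == pytest.approx((12 - 7) * 10.0 / 250.0)  # = 0.2
        assert nmap.x[7] == 0.0 and nmap.y[2] == 0.0

    def test_round_trip_recovers_mm_positions(self):
        grid = ElectrodeGrid(6, 17, origin_row=2, origin_col=8)
        nmap = normalize_map_coords(make_map(np.ones((6, 17))), grid)
        x_mm = nmap.x * grid.circumference_mm + grid.origin_col * grid.pitch_mm
        assert np.allclose(x_mm, np.arange(17) * 10.0)


class TestResampling:
    def test_identity_on_source_coordinates(self):
        rng = np.random.default_rng(0)
        nmap = NormalizedMap(rng.uniform(0.1, 1, (6, 17)),
                             np.linspace(-0.3, 0.3, 17), np.linspace(-0.1, 0.1, 6))
        out = resample_common_grid(nmap, nmap.x, nmap.y)
        assert np.allclose(out.intensity, nmap.intensity, atol=1e-9)

    def test_linear_field_reproduced_exactly(self):
        x = np.linspace(0, 1, 17)
        y = np.linspace(0, 1, 6)
        xx, yy = np.meshgrid(x, y)
        plane = 1.0 + 2.0 * xx + 3.0 * yy
        nmap = NormalizedMap(plane, x, y)
        xt = np.linspace(0.05, 0.95, 31)
        yt = np.linspace(0.05, 0.95, 11)
        out = resample_common_grid(nmap, xt, yt)
        xx2, yy2 = np.meshgrid(xt, yt)
        assert np.allclose(out.intensity, 1.0 + 2.0 * xx2 + 3.0 * yy2, atol=1e-9)

    def test_gaussian_two_fold_upsampling_error_below_one_percent(self):
        x = np.linspace(-1, 1, 17)
        y = np.linspace(-1, 1, 9)
        xx, yy = np.meshgrid(x, y)
        blob = np.exp(-(xx**2 + yy**2) / 0.3)
        nmap = NormalizedMap(blob, x, y)
        xt = np.linspace(-1, 1, 33)
        yt = np.linspace(-1, 1, 17)
        out = resample_common_grid(nmap, xt, yt)
        xx2, yy2 = np.meshgrid(xt, yt)
        exact = np.exp(-(xx2**2 + yy2**2) / 0.3)
        assert np.abs(out.intensity - exact).max() <= 0.01 * exact.max()

    def test_extrapolation_rejected(self):
        nmap = NormalizedMap(np.ones((6, 17)), np.linspace(0, 1, 17), np.linspace(0, 1, 6))
        with pytest.raises(ValueError):
            resample_common_grid(nmap, np.linspace(-0.5, 1, 5), nmap.y)


class TestAveraging:
    def grid_maps(self, intensities):
        x = np.linspace(-0.3, 0.3, 17)
        y = np.linspace(-0.1, 0.1, 6)
        return [NormalizedMap(i, x, y) for i in intensities]

    def test_identical_maps_have_zero_variability(self):
        base = np.full((6, 17), 2.0)
        mean, var = average_maps(self.grid_maps([base, base, base]))
        assert np.allclose(mean.intensity, 2.0)
        assert np.allclose(var, 0.0)

    def test_two_map_closed_form(self):
        base = np.full((6, 17), 1.0)
        delta = 0.2
        mean, var = average_maps(self.grid_maps([base * (1 + delta), base * (1 - delta)]))
        assert np.allclose(var, delta * np.sqrt(2))  # n-1 std convention

    def test_lognormal_subject_gains_give_table_scale_variability(self):
        rng = np.random.default_rng(1)
        base = np.full((6, 17), 1.0)
        summaries = []
        for _ in range(30):
            maps = self.grid_maps([base * rng.lognormal(0.0, 0.25) for _ in range(12)])
            _, var = average_maps(maps)
            summaries.append(variability_summary(var)[0])
        assert 0.2 <= np.mean(summaries) <= 0.3

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(2)
        mats = [rng.uniform(0.5, 1.5, (6, 17)) for _ in range(5)]
        m1, v1 = average_maps(self.grid_maps(mats))
        m2, v2 = average_maps(self.grid_maps(mats[::-1]))
        assert np.allclose(m1.intensity, m2.intensity)
        assert np.allclose(v1, v2)

    def test_grid_mismatch_rejected(self):
        a = NormalizedMap(np.ones((6, 17)), np.linspace(0, 1, 17), np.linspace(0, 1, 6))
        b = NormalizedMap(np.ones((6, 17)), np.linspace(0, 2, 17), np.linspace(0, 1, 6))
        with pytest.raises(ValueError):
            average_maps([a, b])


class TestProjections:
    def segmented_blob(self, cx=11):
        ii, jj = np.meshgrid(np.arange(6), np.arange(17), indexing="ij")
        blob = np.exp(-((jj - cx) ** 2 / 18.0 + (ii - 2.5) ** 2 / 18.0))
        return segment_map(make_map(blob + 0.02))

    def test_single_peak_projection_centred_on_blob(self):
        seg = self.segmented_blob(cx=11)
        proj = project_map(seg, "x")
        # the dome top is a plateau; its median sits on the blob centre
        assert projection_median(proj) == pytest.approx(110.0, abs=5.0)
        assert abs(proj.coords[np.argmax(proj.values)] - 110.0) <= 10.0

    def test_translation_moves_projection(self):
        p1 = project_map(self.segmented_blob(cx=8), "x")
        p2 = project_map(self.segmented_blob(cx=10), "x")
        assert np.argmax(p2.values) - np.argmax(p1.values) == 2

    def test_matches_per_column_max_oracle(self):
        seg = self.segmented_blob()
        proj = project_map(seg, "x", restrict_to_selected=False)
        assert np.array_equal(proj.values, seg.dome.max(axis=0))

    def test_projection_median_symmetric_profile(self):
        proj = Projection("x", np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 2.0, 1.0]))
        assert projection_median(proj) == pytest.approx(2.5)

    def test_projection_median_delta(self):
        proj = Projection("x", np.arange(1.0, 6.0), np.array([0, 0, 7.0, 0, 0]))
        assert projection_median(proj) == pytest.approx(3.0)

    def test_projection_median_brackets_half_mass(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            q = rng.uniform(0, 1, 12)
            q[rng.integers(0, 12)] += 2.0
            proj = Projection("x", np.arange(12.0), q)
            mu = projection_median(proj)
            # piecewise-constant mass left of mu equals half the total
            edges = np.concatenate([[-0.5], np.arange(0.5, 12.0), [11.5]])
            mass = 0.0
            for k in range(12):
                lo, hi = k - 0.5, k + 0.5
                mass += q[k] * max(0.0, (min(mu, hi) - lo)) / (hi - lo) if mu > lo else 0.0
            assert mass == pytest.approx(q.sum() / 2, rel=1e-9)

    def test_zero_projection_rejected(self):
        with pytest.raises(ValueError):
            projection_median(Projection("x", np.arange(3.0), np.zeros(3)))


class TestIntensityFeatures:
    def test_uniform_map_region_mean_is_constant(self):
        ii, jj = np.meshgrid(np.arange(6), np.arange(17), indexing="ij")
        blob = np.exp(-((jj - 8) ** 2 / 18.0 + (ii - 2.5) ** 2 / 18.0))
        amap = make_map(blob + 0.02)
        seg = segment_map(amap)
        mask = seg.selected_mask()
        assert region_mean_intensity(amap, seg) == pytest.approx(amap.intensity[mask].mean())

    def test_bipolar_common_mode_cancels(self, small_grid):
        rec = sine_recording(small_grid, 100.0, 1.0)
        assert bipolar_rms(rec, (2, 8), (3, 8)) == pytest.approx(0.0, abs=1e-9)

    def test_bipolar_single_sided_sine(self, small_grid):
        rec = sine_recording(small_grid, 100.0, 0.9)
        rec.samples[small_grid.channel_index(3, 8)] = 0.0
        assert bipolar_rms(rec, (2, 8), (3, 8)) == pytest.approx(0.9 / np.sqrt(2), rel=0.02)

    def test_bipolar_partially_correlated_noise_matches_analytic(self, small_grid):
        """With shared fraction 1-b of power, the difference RMS is
        sqrt(2 b) times the channel RMS."""
        beta = 0.4
        gains = [np.ones((6, 17))]
        rec = generate_from_gains(small_grid, gains, duration_s=3.0, seed=9, beta=beta)
        r = bipolar_rms(rec, (2, 8), (3, 8))
        assert r == pytest.approx(np.sqrt(2 * beta), rel=0.08)

    def test_identical_electrodes_rejected(self, small_grid):
        rec = sine_recording(small_grid, 100.0)
        with pytest.raises(ValueError):
            bipolar_rms(rec, (2, 8), (2, 8))


def test_common_coordinates_cover_intersection_only():
    a = NormalizedMap(np.ones((6, 17)), np.linspace(-0.4, 0.4, 17), np.linspace(-0.1, 0.2, 6))
    b = NormalizedMap(np.ones((6, 17)), np.linspace(-0.3, 0.5, 17), np.linspace(-0.2, 0.1, 6))
    x, y = common_coordinates([a, b])
    assert x.min() == pytest.approx(-0.3) and x.max() == pytest.approx(0.4)
    assert y.min() == pytest.approx(-0.1) and y.max() == pytest.approx(0.1)
    assert x.size == 34 and y.size == 12
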