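"""Peak detection, symmetry estimation, ring metrology and aggregation."""

import math

import numpy as np
import pytest
from scipy import ndimage

from oligoscope.afm import FilterSpec, HeightMap, ScanGrid, TipModel, simulate_topograph
from oligoscope.errors import AnalysisError, DegenerateFitError
from oligoscope.rings import (
    RingMeasurement,
    SubunitPeak,
    aggregate_patch_calls,
    analyze_heightmap,
    classify_oligomer,
    detect_subunit_peaks,
    estimate_symmetry_order,
    fit_ring,
)
from oligoscope.synthetic import NoiseSpec, SyntheticOligomerSpec, corrupt_heightmap, make_ring_oligomer


def _flat_map(n=32, pixel=0.1, value=0.0):
    g = ScanGrid(pixel_size=pixel, nx=n, ny=n)
    return HeightMap(grid=g, heights=np.full((n, n), value), provenance="synthetic")


def _gauss_bumps(centers, heights, sigma=0.3, n=64, pixel=0.1):
    g = ScanGrid.centered(pixel, n, n)
    xx, yy = np.meshgrid(g.x, g.y)
    h = np.zeros((n, n))
    for (cx, cy), a in zip(centers, heights):
        h += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
    return HeightMap(grid=g, heights=h, provenance="synthetic")


def _ring_map(n_fold, diameter, seed=0, noise=0.05, central="none", npix=101):
    spec = SyntheticOligomerSpec(
        n=n_fold, ring_radius=diameter / 2, central_feature=central, seed=seed
    )
    structure, _, truth = make_ring_oligomer(spec)
    grid = ScanGrid.centered(0.1, npix, npix)
    hm = simulate_topograph(structure, TipModel(), grid)
    if noise:
        hm = corrupt_heightmap(hm, NoiseSpec(sigma=noise, seed=seed + 1))
    return hm, truth


class TestDetectPeaks:
    def test_flat_map_no_peaks(self):
        assert detect_subunit_peaks(_flat_map()) == []

    def test_two_close_bumps_yield_one_peak(self):
        hm = _gauss_bumps([(-0.15, 0.0), (0.15, 0.0)], [1.0, 0.8], sigma=0.2)
        peaks = detect_subunit_peaks(hm, min_prominence=0.05, min_separation=0.5)
        assert len(peaks) == 1
        assert peaks[0].position[0] < 0  # the higher bump wins

    def test_synthetic_ring_peaks_near_ground_truth(self):
        hm, truth = _ring_map(5, 4.3, seed=12)
        peaks = detect_subunit_peaks(hm, presmooth=FilterSpec(2.0))
        assert len(peaks) == 5
        found = np.array([p.position for p in peaks])
        for apex in truth.peak_positions:
            assert np.min(np.linalg.norm(found - apex, axis=1)) <= 0.15

    def test_min_separation_must_cover_pixel(self):
        with pytest.raises(AnalysisError):
            detect_subunit_peaks(_flat_map(pixel=0.2), min_separation=0.1)

    def test_prominence_values_are_saddle_depths(self):
        # two well-separated bumps: smaller peak's prominence is its height
        # above the connecting saddle (~0 here), bigger gets the global range
        hm = _gauss_bumps([(-1.5, 0.0), (1.5, 0.0)], [1.0, 0.6], sigma=0.3)
        peaks = detect_subunit_peaks(hm, min_prominence=0.1, min_separation=0.5)
        assert len(peaks) == 2
        proms = sorted(p.prominence for p in peaks)
        assert proms[0] == pytest.approx(0.6, abs=0.03)  # pixel-sampling sag
        assert proms[1] == pytest.approx(1.0, abs=0.04)


class TestSymmetry:
    @pytest.mark.parametrize("n_fold", [3, 5, 6])
    def test_recovers_generator_order(self, n_fold):
        diameter = {3: 3.4, 5: 4.3, 6: 4.6}[n_fold]
        hm, truth = _ring_map(n_fold, diameter, seed=5)
        res = estimate_symmetry_order(hm, truth.center, orders=(3, 4, 5, 6))
        assert res.order == n_fold
        assert not res.low_confidence

    def test_uniform_torus_flagged_degenerate(self):
        g = ScanGrid.centered(0.1, 81, 81)
        xx, yy = np.meshgrid(g.x, g.y)
        r = np.hypot(xx, yy)
        h = 2.0 * np.exp(-((r - 2.0) ** 2) / (2 * 0.4**2))
        hm = HeightMap(grid=g, heights=h, provenance="synthetic")
        res = estimate_symmetry_order(hm, (0.0, 0.0), orders=(3, 4, 5, 6))
        vals = list(res.scores.values())
        assert max(vals) - min(vals) < 1e-4
        assert res.low_confidence
        assert res.confidence == 0.0

    def test_annulus_outside_map_rejected(self):
        hm = _flat_map(n=32, pixel=0.1)
        with pytest.raises(AnalysisError):
            estimate_symmetry_order(hm, (1.55, 1.55), annulus=(0.5, 5.0))


class TestFitRing:
    def _peaks_on_circle(self, n, radius, center=(0.0, 0.0), phase=0.1):
        pts = []
        for i in range(n):
            a = 2 * math.pi * i / n + phase
            pts.append(SubunitPeak(
                position=np.array([center[0] + radius * math.cos(a),
                                   center[1] + radius * math.sin(a)]),
                height=2.0, prominence=0.5,
            ))
        return pts

    def test_exact_circle_recovered(self):
        hm = _flat_map(n=96, pixel=0.1)
        hm.grid = ScanGrid.centered(0.1, 96, 96)
        peaks = self._peaks_on_circle(5, 2.15)
        m = fit_ring(peaks, hm)
        assert m.diameter == pytest.approx(4.30, abs=1e-9)
        assert np.linalg.norm(m.center) < 1e-9
        assert m.n_subunits == 5

    def test_collinear_points_degenerate(self):
        hm = _flat_map()
        pts = [SubunitPeak(np.array([0.1 * i, 0.2 * i]), 1.0, 0.5) for i in range(3)]
        with pytest.raises(DegenerateFitError):
            fit_ring(pts, hm)

    def test_too_few_peaks(self):
        hm = _flat_map()
        pts = self._peaks_on_circle(2, 1.0)
        with pytest.raises(AnalysisError):
            fit_ring(pts, hm)

    def test_simulated_pentamer_diameter_and_pore(self):
        hm, truth = _ring_map(5, 4.3, seed=3, central="pore")
        call = analyze_heightmap(hm, presmooth=FilterSpec(2.0))
        assert call.measurement.diameter == pytest.approx(4.3, abs=0.15)
        assert call.measurement.central_feature < -0.2
        assert call.measurement.outer_diameter > call.measurement.diameter

    def test_rotation_invariance(self):
        hm, truth = _ring_map(5, 4.3, seed=8, noise=0.0)
        call = analyze_heightmap(hm, presmooth=FilterSpec(2.0))
        rot = ndimage.rotate(hm.heights, 360.0 / 5, reshape=False, order=3)
        hm_rot = HeightMap(grid=hm.grid, heights=rot, provenance="synthetic")
        call_rot = analyze_heightmap(hm_rot, presmooth=FilterSpec(2.0))
        tol = hm.grid.pixel_size
        assert abs(call.measurement.diameter - call_rot.measurement.diameter) < tol
        assert abs(call.measurement.central_feature
                   - call_rot.measurement.central_feature) < tol

    def test_scale_covariance(self):
        """Scaling all lateral coordinates by s scales both diameters by s."""
        hm, _ = _ring_map(5, 4.3, seed=4, noise=0.0)
        call = analyze_heightmap(hm, presmooth=FilterSpec(2.0))
        s = 1.5
        g = hm.grid
        scaled_grid = ScanGrid.centered(g.pixel_size * s, g.nx, g.ny)
        hm_scaled = HeightMap(grid=scaled_grid, heights=hm.heights.copy(),
                              provenance="synthetic")
        call_s = analyze_heightmap(
            hm_scaled, min_separation=0.8 * s, presmooth=FilterSpec(2.0 * s)
        )
        assert call_s.measurement.diameter == pytest.approx(
            s * call.measurement.diameter, rel=1e-9
        )
        assert call_s.measurement.outer_diameter == pytest.approx(
            s * call.measurement.outer_diameter, rel=1e-9
        )


class TestClassify:
    def _m(self, order, central):
        return RingMeasurement(
            center=np.zeros(2), n_subunits=order, symmetry_order=order,
            diameter=4.3, outer_diameter=6.0, central_feature=central,
        )

    @pytest.mark.parametrize(
        "order,central,cls,face",
        [
            (5, +0.4, "pentamer", "C-side"),
            (5, -0.3, "pentamer", "N-side"),
            (3, +0.05, "trimer", "unknown"),
            (6, -0.5, "hexamer", "N-side"),
            (4, 0.0, "tetramer", "unknown"),
            (7, 0.0, "other", "unknown"),
        ],
    )
    def test_rules(self, order, central, cls, face):
        call = classify_oligomer(self._m(order, central), protrusion_threshold=0.2)
        assert call.cls == cls
        assert call.face == face

    def test_deterministic(self):
        m = self._m(5, 0.3)
        a = classify_oligomer(m, 0.2)
        b = classify_oligomer(m, 0.2)
        assert (a.cls, a.face, a.confidence) == (b.cls, b.face, b.confidence)


class TestAggregate:
    def _call(self, cls, patch):
        return classify_oligomer(
            RingMeasurement(np.zeros(2), 5, {"pentamer": 5, "hexamer": 6,
                                             "trimer": 3}[cls], 4.3, 6.0, 0.0),
            patch_id=patch,
        )

    def test_mean_and_sd(self):
        calls = (
            [self._call("pentamer", "A")] * 3
            + [self._call("pentamer", "B")] * 5
            + [self._call("pentamer", "C")] * 7
        )
        s = aggregate_patch_calls(calls)
        assert s.mean == pytest.approx(5.0)
        assert s.sd == pytest.approx(2.0)  # n-1 denominator
        assert s.n_patches == 3

    def test_class_fractions(self):
        calls = [self._call("pentamer", "P")] * 76 + [self._call("hexamer", "P")] * 24
        s = aggregate_patch_calls(calls)
        assert s.class_fractions == {"pentamer": 0.76, "hexamer": 0.24}
        assert sum(s.class_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_single_patch_flagged(self):
        s = aggregate_patch_calls([self._call("trimer", "solo")])
        assert s.single_patch
        assert s.sd == 0.0
        assert s.mean == 1.0

    def test_empty_rejected(self):
        with pytest.raises(AnalysisError):
            aggregate_patch_calls([])


class TestRecovery:
    def test_seeded_rings_recovered(self):
        """Symmetry order and diameter recovery across the realistic range."""
        rng = np.random.default_rng(77)
        ranges = {3: (2.8, 4.8), 5: (4.1, 4.9), 6: (4.5, 4.9)}
        n_ok_sym = n_ok_d = 0
        trials = 24
        for _ in range(trials):
            n = int(rng.choice([3, 5, 6]))
            d = float(rng.uniform(*ranges[n]))
            hm, _ = _ring_map(n, d, seed=int(rng.integers(2**31)))
            call = analyze_heightmap(hm, presmooth=FilterSpec(2.0))
            n_ok_sym += call.measurement.symmetry_order == n
            n_ok_d += abs(call.measurement.diameter - d) <= 0.15
        assert n_ok_sym >= 0.95 * trials
        assert n_ok_d >= 0.90 * trials
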