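import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anisokernel import (
    KernelConfig,
    VolumeGrid,
    combine_peak_maps,
    deformed_step,
    fwhm_from_sigma,
    gaussian_value,
    propagate,
    recreate_from_peak,
    sigma_from_fwhm,
)
from anisokernel.meta import Peak

from conftest import make_random_template, make_uniform_template


def oracle_distances(template, seed, config):
    """Independent brute-force oracle: Bellman-Ford on explicit edges.

    Edge weights are recomputed from the deformed-distance formula with
    plain Python math; distances beyond the cutoff are set to +inf
    afterwards (strict > comparison).
    """
    shape = template.shape
    sigma = config.fwhm_mm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    lin = template.affine[:3, :3]
    thr = config.tissue_threshold

    def factor(v):
        if thr == 0:
            return 1.0
        return min(template.tissue_prob.data[v] / thr, 1.0)

    edges = []
    for v in product(*(range(s) for s in shape)):
        for off in template.offsets.offsets:
            w = tuple(np.add(v, off))
            if not all(0 <= c < s for c, s in zip(w, shape)):
                continue
            rho = template.correlation(v, off) * min(factor(v), factor(w))
            d_real = float(np.linalg.norm(lin @ np.asarray(off, float)))
            if config.alpha == 0.0:
                dist = d_real
            elif math.isnan(rho) or rho <= 0:
                continue
            else:
                rho = min(rho, 1.0)
                dist = math.sqrt(
                    (1 - config.alpha) * d_real**2
                    + config.alpha * 2 * sigma**2 * math.log(1 / rho)
                )
            edges.append((v, w, dist))

    dist = {v: math.inf for v in product(*(range(s) for s in shape))}
    dist[tuple(seed)] = 0.0
    for _ in range(len(dist)):
        changed = False
        for u, w, d in edges:
            if dist[u] + d < dist[w] - 1e-15:
                dist[w] = dist[u] + d
                changed = True
        if not changed:
            break
    out = np.full(shape, math.inf)
    for v, d in dist.items():
        out[v] = d if d <= config.cutoff else math.inf
    return out


class TestSigmaFwhm:
    def test_fwhm20_gives_sigma_8p5(self):
        assert round(sigma_from_fwhm(20.0), 1) == 8.5

    def test_sigma4_gives_fwhm_9p4(self):
        assert round(fwhm_from_sigma(4.0), 1) == 9.4

    def test_unit_fwhm(self):
        assert sigma_from_fwhm(1.0) == pytest.approx(
            1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        )

    def test_ratio_is_0425(self):
        assert round(sigma_from_fwhm(1.0), 3) == 0.425

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(ValueError):
            sigma_from_fwhm(bad)
        with pytest.raises(ValueError):
            fwhm_from_sigma(bad)

    @given(st.floats(0.1, 1e3))
    def test_roundtrip(self, fwhm):
        assert fwhm_from_sigma(sigma_from_fwhm(fwhm)) == pytest.approx(fwhm)


class TestGaussianValue:
    def test_zero_distance_gives_peak(self):
        assert gaussian_value(0.0, 8.5, 1.7) == 1.7

    def test_value_at_fwhm_is_peak_over_16(self):
        fwhm = 20.0
        val = gaussian_value(fwhm, sigma_from_fwhm(fwhm), 1.0)
        assert val == pytest.approx(1.0 / 16.0, rel=1e-12)

    def test_at_one_sigma(self):
        assert gaussian_value(4.0, 4.0, 1.0) == pytest.approx(
            math.exp(-0.5)
        )

    def test_infinite_distance_gives_zero(self):
        assert gaussian_value(math.inf, 8.5, 2.0) == 0.0

    def test_sign_preserved(self):
        assert gaussian_value(5.0, 8.5, -2.0) < 0

    @given(st.floats(0.0, 100.0), st.floats(0.1, 50.0))
    def test_magnitude_bounded_by_peak(self, d, sigma):
        assert abs(gaussian_value(d, sigma, 3.0)) <= 3.0


class TestDeformedStep:
    def test_rho_one_full_anisotropy_is_zero(self):
        assert deformed_step(1.0, 8.5, 1.0, 2.0) == 0.0

    def test_alpha_zero_is_euclidean(self):
        for rho in (0.0, 0.5, 1.0, float("nan")):
            assert deformed_step(rho, 8.5, 0.0, 2.0) == 2.0

    def test_half_correlation_full_anisotropy(self):
        # sqrt(2 * 8.5^2 * ln 2) = 10.01 mm
        assert deformed_step(0.5, 8.5, 1.0, 2.0) == pytest.approx(
            10.01, abs=5e-3
        )

    def test_nonpositive_rho_unreachable(self):
        assert deformed_step(0.0, 8.5, 1.0, 2.0) == math.inf
        assert deformed_step(-0.3, 8.5, 0.5, 2.0) == math.inf
        assert deformed_step(float("nan"), 8.5, 1.0, 2.0) == math.inf

    def test_rho_above_one_rejected(self):
        with pytest.raises(ValueError):
            deformed_step(1.1, 8.5, 1.0, 2.0)

    def test_rho_near_one_clamped(self):
        assert deformed_step(1.0 - 1e-13, 8.5, 1.0, 2.0) == 0.0

    @given(
        rho=st.floats(1e-6, 1.0),
        alpha=st.floats(0.0, 1.0),
        sigma=st.floats(0.5, 50.0),
        d_real=st.floats(0.1, 10.0),
    )
    @settings(max_examples=200)
    def test_eq5_eq7_consistency(self, rho, alpha, sigma, d_real):
        """exp(-D^2/2s^2) == rho_iso^(1-a) * rho^a per step."""
        d = deformed_step(rho, sigma, alpha, d_real)
        lhs = math.exp(-(d**2) / (2 * sigma**2))
        rho_iso = math.exp(-(d_real**2) / (2 * sigma**2))
        rhs = rho_iso ** (1 - alpha) * rho**alpha
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


class TestPropagate:
    def test_distance_zero_at_seed(self, uniform_template):
        field = propagate(uniform_template, (3, 3, 3), KernelConfig(20.0, 1.0))
        assert field.distance[3, 3, 3] == 0.0

    def test_uniform_rho_adjacent_equals_single_step(self, uniform_template):
        cfg = KernelConfig(fwhm_mm=20.0, alpha=0.7)
        field = propagate(uniform_template, (3, 3, 3), cfg)
        for off in uniform_template.offsets.offsets:
            d_real = 2.0 * math.sqrt(sum(c * c for c in off))
            expected = deformed_step(0.8, cfg.sigma_mm, 0.7, d_real)
            v = tuple(np.add((3, 3, 3), off))
            if expected <= cfg.cutoff:
                assert field.distance[v] == pytest.approx(expected)

    def test_detour_beats_direct_edge(self):
        """3x3x1 grid: low-rho direct edge vs high-rho two-step detour."""
        tmpl = make_uniform_template((3, 3, 1), rho=0.9, voxel_mm=2.0)
        k, _ = tmpl.offsets.half_index((1, 0, 0))
        tmpl.rho[k, 0, 0, 0] = 0.01  # direct (0,0,0)->(1,0,0) is bad
        cfg = KernelConfig(fwhm_mm=30.0, alpha=1.0)
        field = propagate(tmpl, (0, 0, 0), cfg)
        oracle = oracle_distances(tmpl, (0, 0, 0), cfg)
        np.testing.assert_allclose(field.distance, oracle, rtol=1e-9)
        # the detour must genuinely beat the direct edge
        direct = deformed_step(0.01, cfg.sigma_mm, 1.0, 2.0)
        assert field.distance[1, 0, 0] < direct

    def test_zero_rho_isolates_seed(self):
        tmpl = make_uniform_template((3, 3, 3), rho=0.9)
        tmpl.rho[:, :, :, :] = 0.9
        # kill every edge touching the center voxel
        seed = (1, 1, 1)
        for kk, off in enumerate(tmpl.offsets.unique_half):
            tmpl.rho[(kk, *seed)] = 0.0
            prev = tuple(np.subtract(seed, off))
            tmpl.rho[(kk, *prev)] = 0.0
        field = propagate(tmpl, seed, KernelConfig(20.0, 1.0))
        finite = np.isfinite(field.distance)
        assert finite.sum() == 1 and finite[seed]

    def test_seed_outside_rejected(self, uniform_template):
        with pytest.raises(ValueError, match="outside"):
            propagate(uniform_template, (9, 0, 0), KernelConfig(20.0, 1.0))

    def test_triangle_property(self, rng):
        tmpl = make_random_template((5, 5, 5), rng)
        cfg = KernelConfig(fwhm_mm=25.0, alpha=0.6)
        field = propagate(tmpl, (2, 2, 2), cfg)
        dist = field.distance
        sigma = cfg.sigma_mm
        for v in product(range(5), repeat=3):
            if not np.isfinite(dist[v]):
                continue
            for off in tmpl.offsets.offsets:
                w = tuple(np.add(v, off))
                if not all(0 <= c < 5 for c in w):
                    continue
                d_real = 2.0 * math.sqrt(sum(c * c for c in off))
                step = deformed_step(tmpl.correlation(v, off), sigma,
                                     cfg.alpha, d_real)
                if np.isfinite(dist[w]):
                    assert dist[w] <= dist[v] + step + 1e-9

    @pytest.mark.parametrize("case", range(12))
    def test_oracle_equivalence_random_fields(self, case):
        rng = np.random.default_rng(1000 + case)
        shape = tuple(rng.integers(2, 5, size=3))
        lo = 0.02 if case % 3 else 0.3
        tmpl = make_random_template(shape, rng, lo=lo)
        if case % 4 == 0:  # sprinkle missing / non-positive correlations
            m = rng.random(tmpl.rho.shape) < 0.15
            tmpl.rho[m] = np.nan
        alpha = float(rng.uniform(0, 1))
        if case % 5 == 0:
            alpha = 1.0
        cfg = KernelConfig(fwhm_mm=float(rng.uniform(10, 60)), alpha=alpha)
        seed = tuple(int(rng.integers(0, s)) for s in shape)
        field = propagate(tmpl, seed, cfg)
        oracle = oracle_distances(tmpl, seed, cfg)
        np.testing.assert_allclose(field.distance, oracle, rtol=1e-9)

    def test_monotone_in_rho(self, rng):
        """Raising one edge's correlation never increases any distance."""
        tmpl = make_random_template((4, 4, 4), rng, lo=0.1, hi=0.9)
        cfg = KernelConfig(fwhm_mm=40.0, alpha=0.8)
        base = propagate(tmpl, (0, 0, 0), cfg).distance
        k = 3
        tmpl.rho[k, 2, 2, 2] = min(1.0, tmpl.rho[k, 2, 2, 2] + 0.09)
        bumped = propagate(tmpl, (0, 0, 0), cfg).distance
        assert np.all(bumped <= base + 1e-12)


class TestRecreate:
    def _peak(self, template, voxel, value=1.0):
        grid = VolumeGrid(np.zeros(template.shape), template.affine)
        return Peak(coord_mm=tuple(grid.voxel_to_world(voxel)), value=value)

    def test_peak_voxel_gets_peak_value(self, uniform_template):
        peak = self._peak(uniform_template, (3, 3, 3), value=1.3)
        rec = recreate_from_peak(uniform_template, peak,
                                 KernelConfig(20.0, 1.0))
        assert rec.data[3, 3, 3] == 1.3

    def test_fwhm_invariance_at_full_anisotropy(self, demo_ds):
        tmpl = demo_ds.template
        peak = self._peak(tmpl, (14, 14, 14), value=2.0)
        maps = [
            recreate_from_peak(tmpl, peak, KernelConfig(f, 1.0)).data
            for f in (10.0, 20.0, 100.0)
        ]
        np.testing.assert_allclose(maps[0], maps[1], rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(maps[0], maps[2], rtol=1e-9, atol=1e-12)

    def test_cutoff_floor(self, uniform_template):
        cfg = KernelConfig(fwhm_mm=20.0, alpha=1.0)
        peak = self._peak(uniform_template, (3, 3, 3), value=1.0)
        rec = recreate_from_peak(uniform_template, peak, cfg)
        nz = rec.data[rec.data != 0]
        assert np.all(np.abs(nz) >= 1.0 / 16.0 - 1e-12)

    def test_magnitude_bounded_by_peak(self, uniform_template):
        peak = self._peak(uniform_template, (2, 2, 2), value=-1.8)
        rec = recreate_from_peak(uniform_template, peak,
                                 KernelConfig(25.0, 0.5))
        assert np.all(np.abs(rec.data) <= 1.8 + 1e-12)

    def test_alpha_zero_matches_straight_line_kernel_on_axis(self):
        """On a uniform open grid the axis profile is the closed form."""
        tmpl = make_uniform_template((9, 9, 9), rho=0.42, voxel_mm=2.0)
        cfg = KernelConfig(fwhm_mm=20.0, alpha=0.0)
        peak = self._peak(tmpl, (4, 4, 4), value=1.0)
        rec = recreate_from_peak(tmpl, peak, cfg)
        sigma = cfg.sigma_mm
        for step_vox in range(0, 5):
            d_mm = 2.0 * step_vox
            expected = (math.exp(-(d_mm**2) / (2 * sigma**2))
                        if d_mm <= cfg.cutoff else 0.0)
            assert rec.data[4 + step_vox, 4, 4] == pytest.approx(expected)
            assert rec.data[4, 4 - step_vox, 4] == pytest.approx(expected)

    def test_coordinate_outside_rejected(self, uniform_template):
        peak = Peak(coord_mm=(500.0, 0.0, 0.0), value=1.0)
        with pytest.raises(ValueError, match="500"):
            recreate_from_peak(uniform_template, peak, KernelConfig())


class TestCombinePeakMaps:
    def _grids(self, *arrays):
        return [VolumeGrid(np.asarray(a, dtype=float).reshape(1, 1, -1))
                for a in arrays]

    def test_single_map_unchanged(self):
        (m,) = self._grids([0.4, 0.2, 0.0])
        (w,) = self._grids([0.8, 0.4, 0.0])
        out = combine_peak_maps([m], [w])
        np.testing.assert_allclose(out.data.ravel(), [0.4, 0.2, 0.0])

    def test_coincident_equal_peaks(self):
        m1, m2 = self._grids([1.0, 0.5], [1.0, 0.5])
        w1, w2 = self._grids([1.0, 0.5], [1.0, 0.5])
        out = combine_peak_maps([m1, m2], [w1, w2])
        np.testing.assert_allclose(out.data.ravel(), [1.0, 0.5])

    def test_hand_weighted_average(self):
        # w1=0.5, v1=0.5; w2=0.25, v2=0.5 -> (0.25+0.125)/0.75 = 0.5
        m1, m2 = self._grids([0.5 * 1.0], [0.25 * 2.0])
        w1, w2 = self._grids([0.5], [0.25])
        out = combine_peak_maps([m1, m2], [w1, w2])
        assert out.data.ravel()[0] == pytest.approx(0.5)

    def test_all_zero_weights_give_zero(self):
        m1, m2 = self._grids([0.3], [0.7])
        w1, w2 = self._grids([0.0], [0.0])
        out = combine_peak_maps([m1, m2], [w1, w2])
        assert out.data.ravel()[0] == 0.0

    def test_bounded_by_contributions(self, rng):
        vals = rng.uniform(-1, 1, size=(3, 1, 1, 8))
        ws = rng.uniform(0, 1, size=(3, 1, 1, 8))
        maps = [VolumeGrid(v) for v in vals]
        weights = [VolumeGrid(w) for w in ws]
        out = combine_peak_maps(maps, weights).data
        assert np.all(out <= vals.max(axis=0) + 1e-12)
        assert np.all(out >= vals.min(axis=0) - 1e-12)

    def test_geometry_mismatch_rejected(self):
        m1 = VolumeGrid(np.zeros((2, 2, 2)))
        m2 = VolumeGrid(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError):
            combine_peak_maps([m1, m2], [m1, m2])
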