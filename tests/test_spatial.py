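import math

import numpy as np
import pytest

from condensate_spt.maps import DensityMap
from condensate_spt.spatial import (
    PairCorrelationCurve,
    aggregate_and_bootstrap,
    bootstrap_radial,
    fit_exponential,
    nanodomain_centers,
    pair_correlation,
    radial_profile,
    ring_area_in_mask,
)

PX = 0.117


def disk_mask(radius_um, pad_px=2):
    r_px = radius_um / PX
    n = int(2 * (r_px + pad_px)) + 1
    c = n / 2
    ys, xs = np.mgrid[:n, :n]
    mask = ((ys + 0.5 - c) ** 2 + (xs + 0.5 - c) ** 2) <= r_px**2
    center_um = (c * PX, c * PX)
    return mask, center_um


def uniform_in_disk(rng, center, radius, n):
    r = radius * np.sqrt(rng.uniform(size=n))
    th = rng.uniform(0, 2 * math.pi, n)
    return np.stack(
        [center[0] + r * np.cos(th), center[1] + r * np.sin(th)], axis=1
    )


class TestRingArea:
    def test_interior_annulus_matches_analytic(self):
        mask, center = disk_mask(2.0)
        r, dr = 0.4, 0.1
        expected = math.pi * ((r + dr) ** 2 - r**2)
        got = ring_area_in_mask(center, r, dr, mask)
        assert got == pytest.approx(expected, rel=0.02)

    def test_half_plane_center_half_area(self):
        mask = np.zeros((80, 160), bool)
        mask[:, 80:] = True  # half plane x >= 80 px
        center = (80 * PX, 40 * PX)  # on the boundary
        r, dr = 0.5, 0.1
        expected = 0.5 * math.pi * ((r + dr) ** 2 - r**2)
        got = ring_area_in_mask(center, r, dr, mask)
        assert got == pytest.approx(expected, rel=0.03)

    def test_matches_monte_carlo_on_arbitrary_mask(self):
        # oracle: 10^6-sample Monte-Carlo estimate of the annulus-mask overlap
        rng = np.random.default_rng(0)
        mask, center = disk_mask(1.0)
        mask[:, : mask.shape[1] // 3] = False  # carve the mask asymmetric
        p = (center[0] - 0.3, center[1] + 0.2)
        r, dr = 0.5, 0.1
        n_mc = 10**6
        rr = np.sqrt(rng.uniform(r**2, (r + dr) ** 2, n_mc))
        th = rng.uniform(0, 2 * math.pi, n_mc)
        xs = p[0] + rr * np.cos(th)
        ys = p[1] + rr * np.sin(th)
        ix = np.floor(xs / PX).astype(int)
        iy = np.floor(ys / PX).astype(int)
        ok = (
            (ix >= 0) & (ix < mask.shape[1]) & (iy >= 0) & (iy < mask.shape[0])
        )
        inside = np.zeros(n_mc, bool)
        inside[ok] = mask[iy[ok], ix[ok]]
        mc_area = inside.mean() * math.pi * ((r + dr) ** 2 - r**2)
        got = ring_area_in_mask(p, r, dr, mask, subdivide=16)
        assert got == pytest.approx(mc_area, rel=0.01)

    def test_negative_r_rejected(self):
        mask, center = disk_mask(1.0)
        with pytest.raises(ValueError):
            ring_area_in_mask(center, -0.1, 0.1, mask)


class TestPairCorrelation:
    def test_csr_uniform_disk_near_one(self):
        rng = np.random.default_rng(1)
        mask, center = disk_mask(3.0)
        pts = uniform_in_disk(rng, center, 3.0, 10**4)
        curve = pair_correlation(pts, pts, mask, mode="auto", subdivide=2)
        assert np.nanmean(curve.g) == pytest.approx(1.0, abs=0.05)
        interior = curve.r > 0.1
        assert np.all(np.abs(curve.g[interior] - 1.0) < 0.1)

    def test_tight_cluster_large_g_at_small_r(self):
        rng = np.random.default_rng(2)
        mask, center = disk_mask(2.0)
        pts = center + rng.normal(0, 0.05, size=(300, 2))
        curve = pair_correlation(pts, pts, mask, mode="auto")
        assert curve.g[0] > 10
        assert curve.g[0] > curve.g[len(curve.g) // 2]

    def test_matches_brute_force_double_loop(self):
        # oracle: explicit double loop with Monte-Carlo edge-corrected areas
        rng = np.random.default_rng(3)
        mask, center = disk_mask(1.0)
        pts = uniform_in_disk(rng, center, 0.95, 25)
        curve = pair_correlation(pts, pts, mask, mode="auto", subdivide=16)
        area_roi = mask.sum() * PX**2
        rho = len(pts) / area_roi
        r_grid = curve.r
        dr = curve.dr
        g_oracle = np.zeros_like(r_grid)
        mc = 200_000
        for k, r in enumerate(r_grid):
            tot_count, tot_area = 0.0, 0.0
            for i, p in enumerate(pts):
                for j, q in enumerate(pts):
                    if i == j:
                        continue
                    d = math.hypot(p[0] - q[0], p[1] - q[1])
                    if r <= d < r + dr:
                        tot_count += 1
                rr = np.sqrt(rng.uniform(r**2, (r + dr) ** 2, mc))
                th = rng.uniform(0, 2 * math.pi, mc)
                ix = np.floor((p[0] + rr * np.cos(th)) / PX).astype(int)
                iy = np.floor((p[1] + rr * np.sin(th)) / PX).astype(int)
                ok = (
                    (ix >= 0) & (ix < mask.shape[1])
                    & (iy >= 0) & (iy < mask.shape[0])
                )
                frac = np.zeros(mc, bool)
                frac[ok] = mask[iy[ok], ix[ok]]
                tot_area += frac.mean() * math.pi * ((r + dr) ** 2 - r**2)
            g_oracle[k] = tot_count / (rho * tot_area) if tot_area > 0 else np.nan
        ok = np.isfinite(g_oracle) & np.isfinite(curve.g) & (g_oracle > 0)
        assert np.allclose(curve.g[ok], g_oracle[ok], rtol=0.02, atol=0.02)

    def test_edge_correction_removes_boundary_drop(self):
        rng = np.random.default_rng(4)
        mask, center = disk_mask(1.5)
        pts = uniform_in_disk(rng, center, 1.5, 3000)
        corrected = pair_correlation(pts, pts, mask, mode="auto", subdivide=2)
        uncorrected = pair_correlation(
            pts, pts, mask, mode="auto", edge_correction=False
        )
        # uncorrected G decays with r (rings leave the disk); corrected flat
        slope_c = np.polyfit(corrected.r, corrected.g, 1)[0]
        slope_u = np.polyfit(uncorrected.r, uncorrected.g, 1)[0]
        assert slope_u < -0.3
        assert abs(slope_c) < 0.15

    def test_cross_symmetric_for_equal_densities(self):
        rng = np.random.default_rng(5)
        mask, center = disk_mask(2.0)
        a = uniform_in_disk(rng, center, 2.0, 400)
        b = uniform_in_disk(rng, center, 2.0, 400)
        gab = pair_correlation(a, b, mask, mode="cross", subdivide=2)
        gba = pair_correlation(b, a, mask, mode="cross", subdivide=2)
        ok = np.isfinite(gab.g) & np.isfinite(gba.g)
        assert np.corrcoef(gab.g[ok], gba.g[ok])[0, 1] > 0.9
        assert np.nanmean(gab.g) == pytest.approx(np.nanmean(gba.g), abs=0.05)

    def test_empty_interest_flagged(self):
        mask, center = disk_mask(1.0)
        curve = pair_correlation(
            np.array([center, (center[0] + 0.1, center[1])]),
            np.empty((0, 2)), mask, mode="cross",
        )
        assert "empty_interest_set" in curve.flags
        assert np.all(np.isnan(curve.g))


class TestExponentialFit:
    def test_recovers_study_scale_parameters(self):
        # ground truth at the guest-free condensate scale: A=1.0, R=0.289 um
        r = np.arange(0.0, 1.01, 0.02)
        g = 1.0 + 1.0 * np.exp(-r / 0.289)
        fit = fit_exponential((r, g))
        assert fit.amplitude == pytest.approx(1.0, rel=0.01)
        assert fit.radius == pytest.approx(0.289, rel=0.01)

    def test_flat_curve_zero_amplitude(self):
        r = np.arange(0.0, 1.01, 0.02)
        fit = fit_exponential((r, np.ones_like(r)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)

    def test_noisy_curve_within_tolerance(self):
        rng = np.random.default_rng(6)
        r = np.arange(0.0, 1.01, 0.02)
        g = 1.0 + 0.8 * np.exp(-r / 0.25) + rng.normal(0, 0.02, len(r))
        fit = fit_exponential((r, g))
        assert fit.amplitude == pytest.approx(0.8, abs=0.1)
        assert fit.radius == pytest.approx(0.25, abs=0.05)

    def test_too_few_bins_flagged(self):
        fit = fit_exponential((np.arange(3.0), np.ones(3)))
        assert not fit.success


def synth_curve(rng, a=1.0, R=0.289, noise=0.05, n_pts=200):
    r = np.round(np.arange(0.0, 1.0 + 0.01, 0.02), 10)
    g = 1.0 + a * np.exp(-r / R) + rng.normal(0, noise, len(r))
    return PairCorrelationCurve(r, g, 0.1, n_pts, n_pts)


class TestAggregateBootstrap:
    def test_identical_curves_zero_width_ci(self):
        rng = np.random.default_rng(7)
        c = synth_curve(rng, noise=0.0)
        res = aggregate_and_bootstrap([c, c, c], n_boot=100, seed=1)
        assert res.a_ci[0] == pytest.approx(res.a_ci[1], abs=1e-12)
        assert np.allclose(res.pooled_g, c.g)

    def test_equal_weights_arithmetic_mean(self):
        rng = np.random.default_rng(8)
        c1, c2 = synth_curve(rng), synth_curve(rng)
        res = aggregate_and_bootstrap([c1, c2], weights=[1, 1], n_boot=10, seed=1)
        assert np.allclose(res.pooled_g, 0.5 * (c1.g + c2.g))

    def test_generator_inside_ci(self):
        rng = np.random.default_rng(9)
        curves = [synth_curve(rng, noise=0.05) for _ in range(12)]
        res = aggregate_and_bootstrap(curves, n_boot=300, seed=2)
        assert res.a_ci[0] <= 1.0 <= res.a_ci[1]
        assert res.r_ci[0] <= 0.289 <= res.r_ci[1]

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(10)
        curves = [synth_curve(rng) for _ in range(5)]
        r1 = aggregate_and_bootstrap(curves, n_boot=50, seed=3)
        r2 = aggregate_and_bootstrap(curves, n_boot=50, seed=3)
        assert np.array_equal(r1.a_samples, r2.a_samples)


class TestNanodomainCenters:
    def _punctate_map(self):
        counts = np.zeros((40, 40))
        true_px = [(10, 12), (25, 8), (30, 30)]
        ys, xs = np.mgrid[:40, :40]
        for cy, cx in true_px:
            counts += 40 * np.exp(-((ys - cy) ** 2 + (xs - cx) ** 2) / (2 * 1.5**2))
        return DensityMap(np.round(counts).astype(int)), true_px

    def test_three_puncta_recovered_within_one_pixel(self):
        dmap, true_px = self._punctate_map()
        centers = nanodomain_centers(dmap, method="puncta")
        assert len(centers) == 3
        for cy, cx in true_px:
            truth = np.array([(cx + 0.5) * PX, (cy + 0.5) * PX])
            d = np.linalg.norm(centers - truth, axis=1).min()
            assert d <= PX

    def test_no_confined_trajectories_empty(self):
        centers = nanodomain_centers(classified=[], method="confined-centroid")
        assert centers.shape == (0, 2)

    def test_methods_agree_on_strong_trap_simulation(self):
        from condensate_spt.diffusion import classify_trajectories
        from condensate_spt.maps import density_map, subsample_pool
        from condensate_spt.simulate import (
            Nanodomain, Scene, SimParams, simulate_trajectories,
        )

        scene = Scene(
            (2.0, 2.0), 1.8,
            [Nanodomain((1.3, 1.3), 0.12), Nanodomain((2.7, 2.6), 0.12)],
        )
        params = SimParams(
            p_confined=0.8, D_confined=0.2, D_free=1.0,
            n_trajectories=300, mean_length=30, min_length=20, seed=11,
        )
        sims = simulate_trajectories(scene, params)
        trajs = [s.trajectory for s in sims]
        pool = subsample_pool(trajs, seed=1)
        dmap = density_map(pool, shape=(40, 40))
        by_puncta = nanodomain_centers(dmap, method="puncta", threshold=3.0)
        by_centroid = nanodomain_centers(
            classified=classify_trajectories(trajs), method="confined-centroid"
        )
        assert len(by_puncta) >= 2
        # every detected punctum near some true domain center
        true_centers = np.array([nd.center for nd in scene.nanodomains])
        for p in by_puncta:
            assert np.linalg.norm(true_centers - p, axis=1).min() < 2 * PX
        # confined centroids cluster around the same true centers
        d = np.linalg.norm(
            by_centroid[:, None, :] - true_centers[None, :, :], axis=2
        ).min(axis=1)
        assert np.median(d) < 2 * PX


class TestRadialProfile:
    def test_uniform_points_flat_at_one(self):
        rng = np.random.default_rng(12)
        pts = uniform_in_disk(rng, (0.0, 0.0), 1.0, 10**4)
        prof = radial_profile(pts, (0.0, 0.0), 1.0)
        interior = prof.bin_centers < 0.95
        assert np.allclose(prof.p_norm[interior], 1.0, atol=0.15)
        assert np.mean(prof.p_norm[interior]) == pytest.approx(1.0, abs=0.05)

    def test_peripheral_points_single_peak(self):
        rng = np.random.default_rng(13)
        th = rng.uniform(0, 2 * math.pi, 500)
        pts = np.stack([0.9 * np.cos(th), 0.9 * np.sin(th)], axis=1)
        prof = radial_profile(pts, (0.0, 0.0), 1.0)
        assert prof.bin_centers[np.argmax(prof.p_norm)] == pytest.approx(
            0.9, abs=0.05
        )

    def test_annular_process_matches_closed_form(self):
        # uniform density restricted to the annulus [0.5, 0.8]: P_norm is
        # 1/(0.8^2-0.5^2) inside the annulus and 0 outside
        rng = np.random.default_rng(14)
        n = 10**4
        rr = np.sqrt(rng.uniform(0.5**2, 0.8**2, n))
        th = rng.uniform(0, 2 * math.pi, n)
        pts = np.stack([rr * np.cos(th), rr * np.sin(th)], axis=1)
        prof = radial_profile(pts, (0.0, 0.0), 1.0)
        expected = 1.0 / (0.8**2 - 0.5**2)
        inside = (prof.bin_edges[:-1] >= 0.5) & (prof.bin_edges[1:] <= 0.8)
        assert np.allclose(prof.p_norm[inside], expected, rtol=0.05)
        outside = prof.bin_edges[1:] <= 0.45
        assert np.allclose(prof.p_norm[outside], 0.0)

    def test_outside_points_flagged(self):
        prof = radial_profile(np.array([[1.3, 0.0]]), (0, 0), 1.0)
        assert "points_outside_range" in prof.flags


class TestBootstrapRadial:
    def _profiles(self, rng, k=6, jitter=0.0):
        out = []
        for _ in range(k):
            pts = uniform_in_disk(rng, (0, 0), 1.0, 400)
            if jitter:
                pts *= 1 + rng.normal(0, jitter)
            out.append(radial_profile(pts, (0, 0), 1.0))
        return out

    def test_identical_profiles_zero_band(self):
        rng = np.random.default_rng(15)
        p = self._profiles(rng, k=1)[0]
        mean, lo, hi = bootstrap_radial([p, p, p], n_boot=100, seed=1)
        assert np.allclose(lo, hi)
        assert np.allclose(mean, p.p_norm)

    def test_mean_between_two_distinct(self):
        e = np.arange(0, 1.25, 0.05)
        from condensate_spt.spatial import RadialProfile

        p1 = RadialProfile(e, np.full(len(e) - 1, 0.5), 100)
        p2 = RadialProfile(e, np.full(len(e) - 1, 1.5), 100)
        mean, lo, hi = bootstrap_radial([p1, p2], n_boot=500, seed=2)
        assert np.all((mean > 0.5) & (mean < 1.5))

    def test_reproducible(self):
        rng = np.random.default_rng(16)
        ps = self._profiles(rng, k=4, jitter=0.05)
        a = bootstrap_radial(ps, n_boot=200, seed=3)
        b = bootstrap_radial(ps, n_boot=200, seed=3)
        assert np.array_equal(a[0], b[0])
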