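import numpy as np
import pytest

from sxfh import detector_sim as ds
from sxfh import processing as pr
from sxfh import structure_io as sio
from sxfh.grid import HologramGrid, spherical_smooth
from sxfh.hologram_model import GridSpec, cluster_hologram, \
    superpose_holograms

from conftest import rot_x, rot_z, rotate_cluster


@pytest.fixture(scope="module")
def geom():
    return ds.DetectorGeometry(n_pixels=(64, 64), pixel_pitch_um=440.0,
                               distance_mm=30.0)


def ramp_frame(geometry, base=200.0):
    rows, cols = geometry.n_pixels
    ii, jj = np.mgrid[0:rows, 0:cols]
    return ds.DetectorFrame(base + 2.0 * ii + 3.0 * jj, geometry)


def smooth_chi(theta_max=90.0, step=1.0, amplitude=0.2, m=4):
    """Band-limited test hologram with zero azimuthal mean."""
    g = HologramGrid.empty(2.99, theta_max, step, step)
    t = np.deg2rad(g.thetas_deg)[:, None]
    p = np.deg2rad(g.phis_deg)[None, :]
    g.values = amplitude * (np.sin(2 * t) * np.cos(m * p)
                            + 0.5 * np.sin(3 * t) * np.sin((m + 1) * p))
    return g


class TestOutlierRemoval:
    def test_constant_frame_unchanged(self, geom):
        f = ds.DetectorFrame(np.full(geom.n_pixels, 500), geom)
        out = pr.remove_outlier_pixels(f)
        np.testing.assert_array_equal(out.counts, f.counts)

    def test_single_saturated_pixel_restored(self, geom):
        counts = np.full(geom.n_pixels, 500)
        counts[20, 30] = ds.MAX_COUNT
        out = pr.remove_outlier_pixels(ds.DetectorFrame(counts, geom))
        assert out.counts[20, 30] == 500

    def test_seeded_hot_and_dead_on_ramp_restored(self, geom):
        clean = ramp_frame(geom)
        counts = clean.counts.copy()
        rng = np.random.default_rng(3)
        spots = []
        while len(spots) < 20:   # keep outliers non-adjacent
            i, j = rng.integers(1, 63, 2)
            if all(abs(i - a) > 1 or abs(j - b) > 1 for a, b in spots):
                spots.append((int(i), int(j)))
        for n, (i, j) in enumerate(spots):
            counts[i, j] = 0 if n % 2 else ds.MAX_COUNT
        out = pr.remove_outlier_pixels(ds.DetectorFrame(counts, geom))
        for i, j in spots:
            assert abs(out.counts[i, j] - clean.counts[i, j]) <= 1.0


class TestIntegrateFrames:
    def test_single_frame_identity(self, geom):
        f = ramp_frame(geom)
        out = pr.integrate_frames(ds.ScanSet([f]))
        np.testing.assert_array_equal(out.counts, f.counts)

    def test_n_copies_scale(self, geom):
        f = ramp_frame(geom)
        out = pr.integrate_frames(ds.ScanSet([f] * 5))
        np.testing.assert_allclose(out.counts, 5.0 * np.asarray(f.counts))

    def test_photon_conservation_231_positions(self):
        """Total photons of the integrated frame equal the sum of the
        per-frame totals across a 231-position scan."""
        tiny = ds.DetectorGeometry(n_pixels=(8, 8))
        rng = np.random.default_rng(0)
        frames = [ds.DetectorFrame(rng.poisson(50.0, (8, 8)), tiny)
                  for _ in range(231)]
        out = pr.integrate_frames(ds.ScanSet(frames))
        assert out.total_photons == sum(f.counts.sum() for f in frames)

    def test_mixed_geometry_rejected(self, geom):
        other = ds.DetectorGeometry(n_pixels=(64, 64), pixel_pitch_um=100.0)
        with pytest.raises(ValueError):
            ds.ScanSet([ramp_frame(geom), ramp_frame(other)])


class TestNormalize:
    def test_identity_and_scaling(self, geom):
        P = ds.make_background(geom, ds.BackgroundParams(amplitude=1.0,
                                                         offset=2.0))
        one = pr.normalize_frame(ds.DetectorFrame(P, geom), P)
        np.testing.assert_allclose(one.values, 1.0)
        two = pr.normalize_frame(ds.DetectorFrame(2 * P, geom), P)
        np.testing.assert_allclose(two.values, 2.0)

    def test_noiseless_render_recovers_chi_at_pixels(self, geom):
        chi = smooth_chi()
        P = ds.make_background(geom, ds.BackgroundParams(amplitude=0.8,
                                                         offset=1.0))
        frame = ds.render_frame(chi, P, 700.0, geom, noise=False)
        H = pr.normalize_frame(frame, 700.0 * P)
        ii, jj = np.mgrid[0:64, 0:64]
        t, p = ds.pixel_to_direction(ii, jj, geom)
        expected, _ = chi.sample(t, p)
        np.testing.assert_allclose(H.values - 1.0, expected, atol=1e-10)

    def test_nonpositive_background_masked(self, geom):
        P = np.ones(geom.n_pixels)
        P[5, 5] = 0.0
        with pytest.warns(UserWarning):
            H = pr.normalize_frame(ramp_frame(geom), P)
        assert not H.mask[5, 5] and H.mask[0, 0]


class TestNormalizingPattern:
    def test_identical_chi_free_frames_give_that_frame(self, geom):
        f = ramp_frame(geom)
        P = pr.estimate_normalizing_pattern([f] * 12)
        np.testing.assert_allclose(P, np.asarray(f.counts, float))

    def test_too_few_frames_warns(self, geom):
        with pytest.warns(UserWarning):
            pr.estimate_normalizing_pattern([ramp_frame(geom)] * 4)

    def test_rotation_series_suppresses_modulation(self, geom):
        chi = smooth_chi()
        P = ds.make_background(geom, ds.BackgroundParams(amplitude=0.5,
                                                         offset=1.0))
        frames = ds.render_rotation_series(chi, P, 300.0, geom, n_frames=36,
                                           noise=False)
        est = pr.estimate_normalizing_pattern(frames)
        single = frames[0].counts / (300.0 * P) - 1.0
        residual = est / (300.0 * P) - 1.0
        assert np.sqrt(np.mean(residual**2)) < \
            np.sqrt(np.mean(single**2)) / 6.0

    def test_masked_pixels_propagate(self, geom):
        f = ramp_frame(geom)
        bad = ramp_frame(geom)
        bad.mask[7, 9] = False
        P = pr.estimate_normalizing_pattern([f] * 10 + [bad] * 2)
        with pytest.warns(UserWarning):
            H = pr.normalize_frame(f, P)
        assert not H.mask[7, 9]


class TestToSpherical:
    def test_constant_image_gives_constant_grid(self, geom):
        img = pr.NormalizedImage(np.full(geom.n_pixels, 1.3),
                                 np.ones(geom.n_pixels, bool), geom)
        g = pr.to_spherical(img, k=2.99)
        assert g.mask.any()
        np.testing.assert_allclose(g.values[g.mask], 1.3, atol=1e-12)

    def test_band_limited_chi_recovered_under_1pct(self):
        # pixel pitch fine enough (0.4 deg) to resolve the band limit
        fine = ds.DetectorGeometry(n_pixels=(128, 128), pixel_pitch_um=220.0)
        chi = smooth_chi()
        P = ds.make_background(fine, ds.BackgroundParams(offset=1.0))
        frame = ds.render_frame(chi, P, 100.0, fine, noise=False)
        H = pr.normalize_frame(frame, 100.0 * P)
        g = pr.to_spherical(H, k=chi.k)
        m = g.mask
        err = np.sqrt(np.mean((g.values[m] - 1.0 - chi.values[m]) ** 2))
        assert err < 0.01 * np.sqrt(np.mean(chi.values[m] ** 2))

    def test_coverage_boundary_matches_edge_angle(self, geom):
        img = pr.NormalizedImage(np.ones(geom.n_pixels),
                                 np.ones(geom.n_pixels, bool), geom)
        g = pr.to_spherical(img, k=2.99)
        edge = geom.edge_angle_deg()
        corner = np.rad2deg(np.arctan(
            np.sqrt(2) * np.tan(np.deg2rad(edge))))
        covered_thetas = g.thetas_deg[g.mask.any(axis=1)]
        full_rows = g.thetas_deg[g.mask.all(axis=1)]
        assert full_rows.max() <= edge + g.theta_step
        assert covered_thetas.max() <= corner + g.theta_step


class TestFlatten:
    def test_constant_grid_becomes_ones(self):
        g = HologramGrid.empty(2.99, 90.0, 2.0, 2.0)
        g.values[:] = 4.2
        out = pr.flatten(g, 20.0)
        np.testing.assert_allclose(out.values[out.mask], 1.0, atol=1e-9)

    def test_scale_separation_recovers_oscillation(self):
        # full sphere: the only grid boundaries are the zero-weight poles
        chi = smooth_chi(theta_max=180.0, step=2.0, amplitude=0.05, m=8)
        t = np.deg2rad(chi.thetas_deg)[:, None]
        background = 1.0 + 0.02 * np.cos(t)
        g = chi.copy()
        g.values = background * (1.0 + chi.values)
        out = pr.flatten(g, 20.0)
        err = out.values - 1.0 - chi.values
        w = out.solid_angle_weights()
        rms = lambda x: np.sqrt((w * x**2).sum() / w.sum())
        assert rms(err) < 0.05 * rms(chi.values)

    def test_idempotent_on_flat_grid(self):
        chi = smooth_chi(step=2.0, amplitude=0.05, m=8)
        flat = chi.copy()
        flat.values = 1.0 + chi.values
        once = pr.flatten(flat, 20.0)
        diff = np.abs(once.values[once.mask] - flat.values[once.mask])
        assert diff.max() < 1e-3


class TestOrient:
    def test_identity_rotation_unchanged(self):
        g = smooth_chi(step=2.0)
        out = pr.orient(g, np.eye(3))
        np.testing.assert_allclose(out.values, g.values, atol=1e-12)

    def test_full_turn_about_pole_unchanged(self):
        g = smooth_chi(step=2.0)
        out = pr.orient(g, rot_z(360.0))
        np.testing.assert_allclose(out.values, g.values, atol=1e-9)

    def test_composition_law(self):
        g = smooth_chi(step=2.0)
        r1, r2 = rot_z(33.0), rot_x(11.0)
        a = pr.orient(pr.orient(g, r1), r2)
        b = pr.orient(g, r2 @ r1)
        m = a.mask & b.mask
        w = np.sin(np.deg2rad(a.thetas_deg))[:, None] * m
        err = np.sqrt((w * (a.values - b.values) ** 2).sum() / w.sum())
        assert err < 0.02 * g.weighted_rms()

    def test_improper_matrix_rejected(self):
        g = smooth_chi(step=2.0)
        with pytest.raises(ValueError):
            pr.orient(g, np.diag([1.0, 1.0, -1.0]))


class TestCompose:
    def test_single_fragment_identity(self):
        g = smooth_chi(step=2.0)
        out = pr.compose_fragments([g])
        np.testing.assert_array_equal(out.values, g.values)

    def test_disjoint_coverage_union(self):
        g = smooth_chi(step=2.0)
        a, b = g.copy(), g.copy()
        a.mask[:, 90:] = False
        b.mask[:, :90] = False
        out = pr.compose_fragments([a, b], weights=[3.0, 1.0])
        assert out.mask.all()
        np.testing.assert_allclose(out.values, g.values, atol=1e-12)

    def test_nine_wedges_grow_coverage_monotonically(self):
        g = smooth_chi(step=2.0)
        frags = []
        for n in range(9):
            f = g.copy()
            f.mask[:] = False
            f.mask[:, 18 * n:18 * (n + 1) + 4] = True
            frags.append(f)
        cover = [pr.compose_fragments(frags[:n + 1]).mask.mean()
                 for n in range(9)]
        assert all(np.diff(cover) > 0)
        assert cover[-1] > max(f.mask.mean() for f in frags)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            pr.compose_fragments([])


class TestFinalize:
    def test_all_ones_become_zeros(self):
        g = HologramGrid.empty(2.99, 90.0, 2.0, 2.0)
        g.values[:] = 1.0
        out = pr.finalize(g, 10.0)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)

    def test_zero_mean_after_finalize(self):
        g = smooth_chi(step=2.0)
        g.values += 1.03
        out = pr.finalize(g, 10.0)
        assert abs(out.weighted_mean()) < 1e-3 * max(out.weighted_rms(),
                                                     1e-12)

    @pytest.mark.parametrize("ell,keep_min,keep_max",
                             [(1, 0.90, 1.0), (40, 0.0, 0.5)])
    def test_harmonic_transfer(self, ell, keep_min, keep_max):
        """The 10-degree low-pass keeps low-degree structure and kills
        degree ~40 structure by more than half."""
        from scipy.special import eval_legendre
        g = HologramGrid.empty(2.99, 180.0, 2.0, 2.0)
        ct = np.cos(np.deg2rad(g.thetas_deg))[:, None]
        g.values = 1.0 + 0.1 * np.broadcast_to(eval_legendre(ell, ct),
                                               g.values.shape)
        out = pr.finalize(g, 10.0)
        harmonic = eval_legendre(ell, ct) * np.ones_like(g.values)
        harmonic -= (harmonic * g.solid_angle_weights()).sum() / \
            g.solid_angle_weights().sum()
        w = g.solid_angle_weights()
        coeff = (w * out.values * harmonic).sum() / (w * harmonic**2).sum()
        assert keep_min <= coeff / 0.1 <= keep_max

    def test_masked_hole_stays_masked(self):
        g = smooth_chi(step=2.0)
        g.values += 1.0
        g.mask[10:14, 30:40] = False
        out = pr.finalize(g, 10.0)
        assert not out.mask[11, 33]
        assert np.isfinite(out.values[out.mask]).all()


class TestApplySymmetry:
    def test_identity_only_unchanged(self):
        g = smooth_chi(step=2.0)
        out = pr.apply_symmetry(g, [np.eye(3)])
        np.testing.assert_allclose(out.values, g.values, atol=1e-12)

    def test_c2_about_pole_output_invariant(self):
        g = smooth_chi(step=2.0, m=3)   # asymmetric under C2
        out = pr.apply_symmetry(g, [np.eye(3), rot_z(180.0)])
        np.testing.assert_allclose(out.values,
                                   np.roll(out.values, 90, axis=1),
                                   atol=1e-9)

    def test_222_orbit_of_wedge_covers_sphere(self):
        g = smooth_chi(theta_max=180.0, step=2.0)
        g.mask[:] = False
        g.mask[:46, :92] = True   # theta <= 90, phi < 182 wedge
        out = pr.apply_symmetry(g, pr.point_group_222())
        assert out.mask.mean() > 0.999

    def test_invariant_under_own_operators(self):
        g = smooth_chi(theta_max=180.0, step=2.0)
        ops = pr.point_group_222()
        sym = pr.apply_symmetry(g, ops)
        for op in ops[1:]:
            back = pr.orient(sym, op)
            m = sym.mask & back.mask
            w = np.sin(np.deg2rad(sym.thetas_deg))[:, None] * m
            err = np.sqrt((w * (sym.values - back.values) ** 2).sum()
                          / w.sum())
            assert err < 0.02 * max(sym.weighted_rms(), 1e-12)


def _oec_chi_and_scansets(oec_clusters, k_mn, orientations, geometry, P,
                          exposure, noise=False, n_frames=1, seed=0):
    """Render scan sets plus the exact lab-frame reference fragments."""
    spec = GridSpec()
    chi = superpose_holograms([cluster_hologram(c, k_mn, spec)
                               for c in oec_clusters])
    scale = 0.2 / np.abs(chi.values).max()
    chi.values *= scale
    scan_sets, refs = [], []
    root = np.random.SeedSequence(seed)
    for n, R in enumerate(orientations):
        seeds = root.spawn(n_frames)
        frames = [ds.render_frame(chi, P, exposure, geometry, R,
                                  rng_seed=s, noise=noise)
                  for s in seeds]
        scan_sets.append(ds.ScanSet(frames, R, "H", f"{n:03d}"))
        lab_clusters = [rotate_cluster(c, R) for c in oec_clusters]
        lab = superpose_holograms([cluster_hologram(c, k_mn, spec)
                                   for c in lab_clusters])
        lab.values = 1.0 + scale * lab.values
        refs.append(lab)
    return chi, scan_sets, refs


def _reference_reduction(refs, geometry, scan_sets, config):
    """Apply the spherical-domain part of the chain to the exact truth,
    so the comparison isolates detector-mapping errors from the intended
    filter response."""
    frags = []
    for lab, ss in zip(refs, scan_sets):
        g = lab.copy()
        t, p = np.meshgrid(g.thetas_deg, g.phis_deg, indexing="ij")
        fi, fj = ds.direction_to_pixel(t, p, geometry)
        rows, cols = geometry.n_pixels
        inside = (np.isfinite(fi) & np.isfinite(fj) & (fi >= 0)
                  & (fi <= rows - 1) & (fj >= 0) & (fj <= cols - 1))
        g.mask = inside
        g.values = np.where(inside, g.values, 0.0)
        g = pr.flatten(g, config.flatten_sigma)
        g = pr.orient(g, ss.orientation.T)
        frags.append(g)
    composed = pr.compose_fragments(
        frags, [s.total_photons() for s in scan_sets])
    return pr.finalize(composed, config.lowpass_sigma)


class TestEndToEnd:
    def test_noiseless_reduction_recovers_hologram(self, oec_clusters, k_mn):
        geometry = ds.DetectorGeometry(n_pixels=(128, 128),
                                       pixel_pitch_um=220.0)
        P = ds.make_background(geometry,
                               ds.BackgroundParams(amplitude=0.5, offset=1.0))
        orientations = [np.eye(3), rot_x(15.0), rot_z(40.0) @ rot_x(8.0)]
        chi, scan_sets, refs = _oec_chi_and_scansets(
            oec_clusters, k_mn, orientations, geometry, P, 1000.0)
        config = pr.ReductionConfig(theta_max=90.0)
        holo, report = pr.reduce_scan_sets(scan_sets, [P] * 3, config, k_mn)
        ref = _reference_reduction(refs, geometry, scan_sets, config)
        m = holo.mask & ref.mask
        assert m.any()
        w = np.sin(np.deg2rad(holo.thetas_deg))[:, None] * m
        err = np.sqrt((w * (holo.values - ref.values) ** 2).sum() / w.sum())
        rms = np.sqrt((w * ref.values**2).sum() / w.sum())
        assert err < 0.05 * rms
        assert report["n_scans"] == 3

    def test_noisy_reduction_correlates_with_truth(self, oec_clusters, k_mn):
        geometry = ds.DetectorGeometry(n_pixels=(64, 64),
                                       pixel_pitch_um=440.0)
        P = ds.make_background(geometry, ds.BackgroundParams(offset=1.0))
        chi, scan_sets, refs = _oec_chi_and_scansets(
            oec_clusters, k_mn, [np.eye(3)], geometry, P, 30.0,
            noise=True, n_frames=100, seed=11)
        config = pr.ReductionConfig(theta_max=90.0)
        holo, _ = pr.reduce_scan_sets(scan_sets, [P], config, k_mn)
        ref = _reference_reduction(refs, geometry, scan_sets, config)
        m = holo.mask & ref.mask
        a = holo.values[m] - holo.values[m].mean()
        b = ref.values[m] - ref.values[m].mean()
        corr = (a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum())
        assert corr > 0.9

    def test_every_stage_is_mask_monotone(self, oec_clusters, k_mn):
        geometry = ds.DetectorGeometry(n_pixels=(64, 64),
                                       pixel_pitch_um=440.0)
        P = ds.make_background(geometry, ds.BackgroundParams(offset=1.0))
        chi, scan_sets, _ = _oec_chi_and_scansets(
            oec_clusters, k_mn, [rot_x(5.0)], geometry, P, 500.0)
        frame = pr.integrate_frames(scan_sets[0])
        frame = pr.remove_outlier_pixels(frame)
        H = pr.normalize_frame(frame, P)
        g = pr.to_spherical(H, k_mn)
        masks = [g.mask.copy()]
        g = pr.flatten(g, 20.0)
        masks.append(g.mask.copy())
        g = pr.orient(g, scan_sets[0].orientation.T)
        g2 = pr.finalize(g, 10.0)
        for before, after in zip(masks, masks[1:]):
            assert not np.any(after & ~before)
        assert not np.any(g2.mask & ~g.mask)
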