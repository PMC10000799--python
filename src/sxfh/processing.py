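"""Detector-frame reduction: raw scans -> composed spherical hologram.

The chain, applied per crystal and then across crystals:

1. integrate all frames of a scan (pixelwise sum),
2. repair hot/dead pixels (3x3 median, selectively on histogram outliers),
3. normalize by the rotation-averaged pattern P:  H = I / P,
4. project the gnomonic detector image onto the (theta, phi) sphere,
5. flatten: divide by a wide Gaussian-smoothed copy so the signal
   oscillates around 1,
6. rotate into the common crystal frame (from diffraction indexing),
7. compose fragments from all crystals (photon-weighted mean),
8. finalize: subtract 1 and low-pass with a spherical Gaussian
   (sigma = 10 degrees by default),
9. optionally average over the crystal point-group rotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .detector_sim import (DetectorFrame, DetectorGeometry, ScanSet,
                           direction_to_pixel)
from .grid import HologramGrid, check_rotation, rotate_grid, spherical_smooth

__all__ = ["ReductionConfig", "NormalizedImage", "remove_outlier_pixels",
           "integrate_frames", "normalize_frame",
           "estimate_normalizing_pattern", "to_spherical", "flatten",
           "orient", "compose_fragments", "finalize", "apply_symmetry",
           "reduce_scan_sets", "point_group_222"]


@dataclass
class ReductionConfig:
    median_kernel: int = 3
    histogram_clip: float = 5.0      # MAD multiples
    flatten_sigma: float = 20.0      # degrees; unstated upstream, free choice
    lowpass_sigma: float = 10.0      # degrees
    symmetry_ops: list = field(default_factory=lambda: [np.eye(3)])
    composition_weighting: str = "counts"   # or "equal"
    # full sphere: arbitrarily oriented crystals cover either hemisphere
    theta_max: float = 180.0
    theta_step: float = 1.0
    phi_step: float = 1.0

    def __post_init__(self):
        if self.median_kernel % 2 == 0 or self.median_kernel < 1:
            raise ValueError("median kernel must be odd")
        if self.flatten_sigma is not None and self.flatten_sigma <= 0:
            raise ValueError("flatten sigma must be positive")
        if self.lowpass_sigma <= 0:
            raise ValueError("lowpass sigma must be positive")


@dataclass
class NormalizedImage:
    """Detector-frame image after normalization (float, maskable)."""

    values: np.ndarray
    mask: np.ndarray
    geometry: DetectorGeometry


def remove_outlier_pixels(frame: DetectorFrame, kernel: int = 3,
                          clip: float = 5.0) -> DetectorFrame:
    """Repair hot/dead pixels by selective median replacement.

    A pixel is an outlier when its residual against the ``kernel x kernel``
    median image falls outside median +- ``clip`` * scale of the residual
    histogram, where the scale is the MAD floored at the Poisson level
    sqrt(median count); only outliers are replaced (the hologram is not
    blurred by a global median).
    """
    counts = np.asarray(frame.counts, dtype=float)
    med_img = ndi.median_filter(counts, size=kernel, mode="nearest")
    resid = counts - med_img
    center = np.median(resid)
    mad = np.median(np.abs(resid - center))
    scale = max(mad, np.sqrt(max(np.median(counts), 1.0)))
    bad = np.abs(resid - center) > clip * scale
    repaired = counts.copy()
    repaired[bad] = med_img[bad]
    return DetectorFrame(repaired, frame.geometry,
                         frame.incident_energy_kev, frame.scan_position_um,
                         frame.crystal_id, frame.mask.copy(),
                         check_depth=frame.check_depth)


def integrate_frames(scan: ScanSet) -> DetectorFrame:
    """Pixelwise sum over all frames of a scan (one crystal, one energy)."""
    if not scan.frames:
        raise ValueError("scan contains no frames")
    total = np.sum([np.asarray(f.counts, dtype=float) for f in scan.frames],
                   axis=0)
    out = DetectorFrame(total, scan.frames[0].geometry,
                        scan.frames[0].incident_energy_kev,
                        crystal_id=scan.crystal_id, check_depth=False)
    out.total_photons = float(total.sum())
    return out


def normalize_frame(frame: DetectorFrame, P) -> NormalizedImage:
    """H = I / P pixelwise; pixels with nonpositive P are masked."""
    P = np.asarray(P, dtype=float)
    good = P > 0
    if not np.all(good):
        warnings.warn("nonpositive normalizing-pattern pixels masked")
    vals = np.where(good, np.asarray(frame.counts, float)
                    / np.where(good, P, 1.0), 0.0)
    return NormalizedImage(vals, good & frame.mask, frame.geometry)


def estimate_normalizing_pattern(frames) -> np.ndarray:
    """Pixelwise mean of an in-plane rotation series.

    Rotation averages the holographic modulation out, leaving the
    geometry-fixed background.  Fewer than 8 frames triggers a warning but
    still returns the mean.  Pixels masked in any input frame are zeroed,
    so they propagate into the mask of every frame normalized with this P.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames")
    if len(frames) < 8:
        warnings.warn("fewer than 8 rotation frames; holographic signal "
                      "may not be fully averaged out of P")
    P = np.mean([np.asarray(f.counts, dtype=float) for f in frames], axis=0)
    good = np.logical_and.reduce([f.mask for f in frames])
    return np.where(good, P, 0.0)


def to_spherical(image: NormalizedImage, k: float, theta_max: float = 90.0,
                 theta_step: float = 1.0, phi_step: float = 1.0
                 ) -> HologramGrid:
    """Resample the gnomonic detector image onto the spherical grid.

    Each grid node is back-projected to its fractional pixel and bilinearly
    interpolated; nodes outside detector coverage (or touching masked
    pixels) are masked.
    """
    grid = HologramGrid.empty(k, theta_max, theta_step, phi_step)
    t, p = np.meshgrid(grid.thetas_deg, grid.phis_deg, indexing="ij")
    fi, fj = direction_to_pixel(t, p, image.geometry)
    rows, cols = image.geometry.n_pixels
    inside = (np.isfinite(fi) & np.isfinite(fj)
              & (fi >= 0) & (fi <= rows - 1) & (fj >= 0) & (fj <= cols - 1))
    fi = np.where(inside, fi, 0.0)
    fj = np.where(inside, fj, 0.0)
    i0 = np.floor(fi).astype(int)
    j0 = np.floor(fj).astype(int)
    i1 = np.minimum(i0 + 1, rows - 1)
    j1 = np.minimum(j0 + 1, cols - 1)
    wi = fi - i0
    wj = fj - j0
    vals = np.zeros(t.shape)
    ok = inside.copy()
    for ii, jj, w in ((i0, j0, (1 - wi) * (1 - wj)),
                      (i0, j1, (1 - wi) * wj),
                      (i1, j0, wi * (1 - wj)), (i1, j1, wi * wj)):
        vals += w * image.values[ii, jj]
        ok &= (w <= 1e-12) | image.mask[ii, jj]
    grid.values = np.where(ok, vals, 0.0)
    grid.mask = ok
    return grid


def flatten(grid: HologramGrid, flatten_sigma: float) -> HologramGrid:
    """Divide by the Gaussian-smoothed copy; the result oscillates around 1.

    Removes residual low-frequency background on the sphere.  Nodes whose
    smoothed background is nonpositive are masked.
    """
    G = spherical_smooth(grid, flatten_sigma)
    good = grid.mask & G.mask & (G.values > 0)
    out = grid.copy()
    out.values = np.where(good, grid.values / np.where(good, G.values, 1.0),
                          0.0)
    out.mask = good
    return out


def orient(grid: HologramGrid, rotation) -> HologramGrid:
    """Rotate a fragment: node n receives the value formerly at R^-1 n."""
    return rotate_grid(grid, np.asarray(rotation, dtype=float))


def compose_fragments(grids, weights=None) -> HologramGrid:
    """Per-node weighted mean over the fragments valid there (union
    coverage); default photon-count weights must be passed explicitly."""
    grids = list(grids)
    if not grids:
        raise ValueError("no fragments to compose")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_spec(g):
            raise ValueError("fragment grid specs differ")
    if weights is None:
        weights = np.ones(len(grids))
    weights = np.asarray(weights, dtype=float)
    num = np.zeros(first.values.shape)
    den = np.zeros(first.values.shape)
    for g, w in zip(grids, weights):
        num += w * np.where(g.mask, g.values, 0.0)
        den += w * g.mask
    out = first.copy()
    out.mask = den > 0
    out.values = np.where(out.mask, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def finalize(grid: HologramGrid, lowpass_sigma: float = 10.0,
             subtract: float = 1.0) -> HologramGrid:
    """Subtract the baseline, low-pass, and enforce a zero mean.

    The low-pass is a spherical Gaussian of the stated angular sigma using
    great-circle distances and sin(theta) solid-angle weights.  The tiny
    residual weighted mean left after subtracting the constant baseline is
    removed so chi is exactly mean-zero.
    """
    out = grid.copy()
    out.values = np.where(out.mask, out.values - subtract, 0.0)
    out = spherical_smooth(out, lowpass_sigma)
    if out.mask.any():
        out.values = np.where(out.mask, out.values - out.weighted_mean(), 0.0)
    return out


def apply_symmetry(grid: HologramGrid, symmetry_ops) -> HologramGrid:
    """Average the hologram over a set of rotations (the crystal point
    group); output nodes are the mean of all valid symmetry images, so
    coverage grows to the union of the rotated fragments."""
    images = []
    for op in symmetry_ops:
        op = np.asarray(op, dtype=float)
        check_rotation(op)
        images.append(rotate_grid(grid, op))
    return compose_fragments(images)


def point_group_222(include_inversion: bool = False):
    """Rotation operators of point group 222 (optionally plus inversion
    partners for Friedel-type averaging)."""
    ops = [np.diag([1.0, 1.0, 1.0]), np.diag([1.0, -1.0, -1.0]),
           np.diag([-1.0, 1.0, -1.0]), np.diag([-1.0, -1.0, 1.0])]
    if include_inversion:
        ops = ops + [-o for o in ops]
    return ops


def reduce_scan_sets(scan_sets, P, config: ReductionConfig, k: float):
    """Full reduction of a list of ScanSets into one composed hologram.

    ``P`` is either one normalizing pattern or a per-scan list.  Returns
    ``(hologram, report)`` where the report carries per-stage counters.
    """
    scan_sets = list(scan_sets)
    if not scan_sets:
        raise ValueError("no scan sets")
    if isinstance(P, np.ndarray):
        P = [P] * len(scan_sets)
    fragments, weights = [], []
    report = {"n_scans": len(scan_sets), "per_scan": []}
    for ss, Pn in zip(scan_sets, P):
        frame = integrate_frames(ss)
        total = frame.total_photons
        frame = remove_outlier_pixels(frame, config.median_kernel,
                                      config.histogram_clip)
        H = normalize_frame(frame, Pn)
        frag = to_spherical(H, k, config.theta_max, config.theta_step,
                            config.phi_step)
        if config.flatten_sigma is not None:
            frag = flatten(frag, config.flatten_sigma)
        frag = orient(frag, ss.orientation.T)   # lab -> crystal frame
        fragments.append(frag)
        weights.append(total if config.composition_weighting == "counts"
                       else 1.0)
        report["per_scan"].append({
            "crystal_id": ss.crystal_id, "energy_label": ss.energy_label,
            "n_frames": len(ss.frames), "total_photons": total,
            "coverage_fraction": float(frag.mask.mean())})
    composed = compose_fragments(fragments, weights)
    final = finalize(composed, config.lowpass_sigma)
    if len(config.symmetry_ops) > 1 or not np.allclose(
            config.symmetry_ops[0], np.eye(3)):
        final = apply_symmetry(final, config.symmetry_ops)
    report["coverage_fraction"] = float(final.mask.mean())
    report["rms"] = final.weighted_rms() if final.mask.any() else 0.0
    return final, report
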