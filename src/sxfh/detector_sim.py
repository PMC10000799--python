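"""Flat 2D detector model and synthetic scan generation.

A flat detector at distance D from the sample records a gnomonic (central)
projection of the spherical hologram.  This module maps pixels to emission
directions and back, builds smooth fluorescence backgrounds, and renders
Poisson-noisy frames from a known hologram so the full reduction chain can
be exercised without beamtime data.

The default geometry mirrors a Medipix3 quad chip: 256 x 256 pixels of
110 um pitch, 30 mm from the sample, 24-bit counters.  The detector axis
defaults to the hologram pole; the physical two-theta arm is reduced to a
single configurable rotation.  Energy windowing and filter transmission are
folded into one exposure scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

from .grid import HologramGrid, check_rotation

__all__ = ["DetectorGeometry", "DetectorFrame", "ScanSet", "BackgroundParams",
           "pixel_to_direction", "direction_to_pixel", "make_background",
           "render_frame", "render_rotation_series", "synth_scan",
           "save_scan_sets", "load_scan_sets", "MAX_COUNT"]

#: 24-bit counter depth
MAX_COUNT = 2**24 - 1


@dataclass
class DetectorGeometry:
    n_pixels: tuple[int, int] = (256, 256)
    pixel_pitch_um: float = 110.0
    distance_mm: float = 30.0
    detector_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    inplane_rotation_deg: float = 0.0

    def __post_init__(self):
        if self.distance_mm <= 0 or self.pixel_pitch_um <= 0:
            raise ValueError("distance and pixel pitch must be positive")

    def basis(self) -> np.ndarray:
        """Lab-frame basis whose columns are (detector-x, detector-y, axis),
        including the in-plane rotation."""
        z = np.asarray(self.detector_axis, dtype=float)
        z = z / np.linalg.norm(z)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(z @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x = ref - (ref @ z) * z
        x /= np.linalg.norm(x)
        if np.allclose(self.detector_axis, (0.0, 0.0, 1.0)):
            x = np.array([1.0, 0.0, 0.0])
        y = np.cross(z, x)
        a = np.deg2rad(self.inplane_rotation_deg)
        rot = np.array([[np.cos(a), -np.sin(a), 0.0],
                        [np.sin(a), np.cos(a), 0.0],
                        [0.0, 0.0, 1.0]])
        return np.column_stack([x, y, z]) @ rot

    def pixel_offsets_mm(self, i, j):
        rows, cols = self.n_pixels
        pitch = self.pixel_pitch_um * 1e-3
        x = (np.asarray(j, dtype=float) - (cols - 1) / 2.0) * pitch
        y = (np.asarray(i, dtype=float) - (rows - 1) / 2.0) * pitch
        return x, y

    def edge_angle_deg(self) -> float:
        """Polar angle of an edge-center pixel (coverage boundary)."""
        rows, cols = self.n_pixels
        half = min(rows, cols) / 2.0 * self.pixel_pitch_um * 1e-3
        return float(np.rad2deg(np.arctan2(half, self.distance_mm)))


@dataclass
class DetectorFrame:
    counts: np.ndarray
    geometry: DetectorGeometry
    incident_energy_kev: float = 6.565
    scan_position_um: tuple[float, float] = (0.0, 0.0)
    crystal_id: str = "001"
    mask: np.ndarray | None = None
    #: raw frames respect the 24-bit counter; sums of frames need not
    check_depth: bool = True

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != tuple(self.geometry.n_pixels):
            raise ValueError("counts shape does not match detector geometry")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.check_depth and np.any(self.counts > MAX_COUNT):
            raise ValueError("counts exceed 24-bit depth")
        if self.mask is None:
            self.mask = np.ones(self.counts.shape, bool)


@dataclass
class ScanSet:
    """Frames from one crystal at one incident energy."""

    frames: list[DetectorFrame]
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))
    energy_label: str = "H"
    crystal_id: str = "001"

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float)
        check_rotation(self.orientation)
        if self.frames:
            g0 = self.frames[0].geometry
            e0 = self.frames[0].incident_energy_kev
            for f in self.frames:
                if f.geometry is not g0 and f.geometry != g0:
                    raise ValueError("frames in a scan must share geometry")
                if not np.isclose(f.incident_energy_kev, e0):
                    raise ValueError("frames in a scan must share energy")

    def total_photons(self) -> float:
        return float(sum(f.counts.sum() for f in self.frames))


def pixel_to_direction(i, j, geometry: DetectorGeometry):
    """(theta, phi) in degrees of the unit direction through pixel center.

    Accepts scalars or arrays; raises for out-of-range scalar pixels.
    """
    rows, cols = geometry.n_pixels
    i_arr = np.asarray(i, dtype=float)
    j_arr = np.asarray(j, dtype=float)
    if np.any(i_arr < 0) or np.any(i_arr > rows - 1) \
            or np.any(j_arr < 0) or np.any(j_arr > cols - 1):
        raise ValueError("pixel index outside detector")
    x, y = geometry.pixel_offsets_mm(i_arr, j_arr)
    v = np.stack(np.broadcast_arrays(x, y, np.full(np.broadcast(x, y).shape,
                                                   geometry.distance_mm)),
                 axis=-1)
    v = v @ geometry.basis().T
    v /= np.linalg.norm(v, axis=-1, keepdims=True)
    theta = np.rad2deg(np.arccos(np.clip(v[..., 2], -1.0, 1.0)))
    phi = np.rad2deg(np.arctan2(v[..., 1], v[..., 0])) % 360.0
    return theta, phi


def direction_to_pixel(theta_deg, phi_deg, geometry: DetectorGeometry):
    """Fractional (i, j) of the gnomonic image of a direction.

    Directions behind or parallel to the detector plane give NaN.
    """
    t = np.deg2rad(np.asarray(theta_deg, dtype=float))
    p = np.deg2rad(np.asarray(phi_deg, dtype=float))
    v = np.stack(np.broadcast_arrays(np.sin(t) * np.cos(p),
                                     np.sin(t) * np.sin(p), np.cos(t)),
                 axis=-1)
    vd = v @ geometry.basis()   # into detector frame
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(vd[..., 2] > 1e-9,
                         geometry.distance_mm / vd[..., 2], np.nan)
    x = vd[..., 0] * scale
    y = vd[..., 1] * scale
    rows, cols = geometry.n_pixels
    pitch = geometry.pixel_pitch_um * 1e-3
    j = x / pitch + (cols - 1) / 2.0
    i = y / pitch + (rows - 1) / 2.0
    return i, j


@dataclass
class BackgroundParams:
    """Smooth sample-detector fluorescence background profile.

    amplitude * exp(-rho^2 / 2 sigma_px^2) + offset + gradient . (i, j),
    with rho the pixel distance from ``center`` (defaults to the detector
    center, the projection of the beam axis).
    """

    amplitude: float = 0.0
    sigma_px: float = 80.0
    offset: float = 1.0
    gradient: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] | None = None


def make_background(geometry: DetectorGeometry,
                    params: BackgroundParams) -> np.ndarray:
    """Strictly positive smooth normalizing pattern P on the detector."""
    rows, cols = geometry.n_pixels
    ii, jj = np.mgrid[0:rows, 0:cols]
    ci, cj = params.center if params.center is not None \
        else ((rows - 1) / 2.0, (cols - 1) / 2.0)
    rho2 = (ii - ci) ** 2 + (jj - cj) ** 2
    P = (params.offset + params.gradient[0] * (ii - ci)
         + params.gradient[1] * (jj - cj)
         + params.amplitude * np.exp(-0.5 * rho2 / params.sigma_px**2))
    if np.any(P <= 0):
        raise ValueError("background profile must be strictly positive")
    return P


def _expected_counts(hologram: HologramGrid, P, exposure_scale, geometry,
                     orientation):
    """exposure * P * (1 + chi) at each pixel; chi = 0 outside hologram
    coverage (no signal information there, background only)."""
    orientation = np.asarray(orientation, dtype=float)
    check_rotation(orientation)
    rows, cols = geometry.n_pixels
    ii, jj = np.mgrid[0:rows, 0:cols]
    theta, phi = pixel_to_direction(ii, jj, geometry)
    t = np.deg2rad(theta)
    p = np.deg2rad(phi)
    d_lab = np.stack([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p),
                      np.cos(t)], axis=-1)
    d_cry = d_lab @ orientation     # R^T d: lab -> crystal frame
    tc = np.rad2deg(np.arccos(np.clip(d_cry[..., 2], -1.0, 1.0)))
    pc = np.rad2deg(np.arctan2(d_cry[..., 1], d_cry[..., 0])) % 360.0
    chi, valid = hologram.sample(tc, pc)
    chi = np.where(valid, chi, 0.0)
    if np.any(np.abs(chi) >= 1.0):
        raise ValueError("|chi| must stay below 1 for a positive intensity")
    expected = exposure_scale * P * (1.0 + chi)
    if np.any(expected > MAX_COUNT):
        raise ValueError("expected counts exceed 24-bit detector depth")
    return expected


def render_frame(hologram: HologramGrid, P, exposure_scale: float,
                 geometry: DetectorGeometry, orientation=np.eye(3),
                 rng_seed=None, hot_pixels=(), dead_pixels=(),
                 noise: bool = True, **frame_kwargs) -> DetectorFrame:
    """One synthetic detector frame.

    Expected counts are exposure * P * (1 + chi(direction)); with
    ``noise=True`` counts are Poisson-drawn from the given seed (bitwise
    reproducible), otherwise the real-valued expectation is returned
    (infinite-exposure limit).  Hot pixels are overwritten with saturation,
    dead pixels with 0.
    """
    expected = _expected_counts(hologram, P, exposure_scale, geometry,
                                orientation)
    if noise:
        rng = np.random.default_rng(rng_seed)
        counts = rng.poisson(expected).astype(np.int64)
    else:
        counts = expected
    for (i, j) in hot_pixels:
        counts[i, j] = MAX_COUNT
    for (i, j) in dead_pixels:
        counts[i, j] = 0
    return DetectorFrame(counts, geometry, **frame_kwargs)


def render_rotation_series(hologram: HologramGrid, P, exposure_scale,
                           geometry: DetectorGeometry, n_frames: int = 36,
                           span_deg: float = 360.0, orientation=np.eye(3),
                           rng_seed=None, noise: bool = True):
    """Frames at n in-plane sample rotations spanning ``span_deg``.

    Emulates the acquisition of the normalizing pattern: rotating the sample
    averages the holographic modulation out of the frame mean while the
    geometry-fixed background stays put.
    """
    orientation = np.asarray(orientation, dtype=float)
    seeds = np.random.SeedSequence(rng_seed).spawn(n_frames)
    frames = []
    for n in range(n_frames):
        a = np.deg2rad(span_deg * n / n_frames)
        rz = np.array([[np.cos(a), -np.sin(a), 0.0],
                       [np.sin(a), np.cos(a), 0.0],
                       [0.0, 0.0, 1.0]])
        frames.append(render_frame(hologram, P, exposure_scale, geometry,
                                   rz @ orientation,
                                   rng_seed=seeds[n], noise=noise))
    return frames


def synth_scan(chi_by_valence: dict, geometry: DetectorGeometry,
               n_positions: int, orientations, alpha: float, beta: float,
               seed=None, P=None, exposure_scale: float = 1000.0,
               fractions=(0.5, 0.5), n_hot: int = 20, noise: bool = True,
               step_um=(30.0, 40.0)) -> list[ScanSet]:
    """Two-energy multi-crystal synthetic acquisition.

    ``chi_by_valence`` maps "III"/"IV" to crystal-frame holograms; per
    crystal one high-energy set with chi_H = (chi_III + chi_IV)/2 and one
    low-energy set with chi_L = (alpha chi_III + beta chi_IV)/2 are rendered
    (site-count fractions configurable).  Hot/dead pixels are injected at
    seeded random positions.  Returns ScanSets ordered [H, L] per crystal.
    """
    if not (0.0 < alpha <= 1.0 and 0.0 < beta <= 1.0):
        raise ValueError("alpha and beta must lie in (0, 1]")
    if alpha == beta:
        raise ValueError("alpha must differ from beta "
                         "(two-energy decomposition is singular otherwise)")
    from .valence import compose_valence  # local import, avoids cycle
    chi_h, chi_l = compose_valence(chi_by_valence["III"], chi_by_valence["IV"],
                                   alpha, beta, fractions)
    if P is None:
        P = make_background(geometry, BackgroundParams(amplitude=0.3,
                                                       offset=1.0))
    root = np.random.SeedSequence(seed)
    out = []
    for ic, R in enumerate(orientations):
        crystal = f"{ic + 1:03d}"
        for label, chi in (("H", chi_h), ("L", chi_l)):
            sub = root.spawn(1)[0]
            rng = np.random.default_rng(sub)
            rows, cols = geometry.n_pixels
            hot = [tuple(x) for x in
                   rng.integers(0, [rows, cols], size=(n_hot // 2, 2))]
            dead = [tuple(x) for x in
                    rng.integers(0, [rows, cols], size=(n_hot - n_hot // 2, 2))]
            frames = []
            for n in range(n_positions):
                pos = ((n % 16) * step_um[0], (n // 16) * step_um[1])
                frames.append(render_frame(
                    chi, P, exposure_scale, geometry, R,
                    rng_seed=rng.integers(2**31), hot_pixels=hot,
                    dead_pixels=dead, noise=noise,
                    incident_energy_kev=6.565 if label == "H" else 6.551,
                    scan_position_um=pos, crystal_id=crystal))
            out.append(ScanSet(frames, R, label, crystal))
    return out


def save_scan_sets(scan_sets, path) -> None:
    """HDF5 stack: one group per scan set with a counts cube and metadata."""
    with h5py.File(path, "w") as f:
        for n, ss in enumerate(scan_sets):
            g = f.create_group(f"scan_{n:03d}")
            g.create_dataset("counts",
                             data=np.stack([fr.counts for fr in ss.frames]),
                             track_times=False)
            g.create_dataset("orientation", data=ss.orientation,
                             track_times=False)
            g.attrs["energy_label"] = ss.energy_label
            g.attrs["crystal_id"] = ss.crystal_id
            geo = ss.frames[0].geometry
            g.attrs["n_pixels"] = geo.n_pixels
            g.attrs["pixel_pitch_um"] = geo.pixel_pitch_um
            g.attrs["distance_mm"] = geo.distance_mm
            g.attrs["incident_energy_kev"] = ss.frames[0].incident_energy_kev


def load_scan_sets(path) -> list[ScanSet]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            geo = DetectorGeometry(tuple(int(x) for x in g.attrs["n_pixels"]),
                                   float(g.attrs["pixel_pitch_um"]),
                                   float(g.attrs["distance_mm"]))
            energy = float(g.attrs["incident_energy_kev"])
            frames = [DetectorFrame(c, geo, incident_energy_kev=energy,
                                    crystal_id=str(g.attrs["crystal_id"]))
                      for c in g["counts"][...]]
            out.append(ScanSet(frames, g["orientation"][...],
                               str(g.attrs["energy_label"]),
                               str(g.attrs["crystal_id"])))
    return out
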