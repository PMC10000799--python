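"""Spherical hologram grids.

A hologram is the dimensionless oscillation chi sampled on a regular
(theta, phi) grid at a fixed fluorescence wavenumber k.  Theta is the polar
angle from the grid pole (+z), phi the azimuth from +x toward +y,
right-handed, both in degrees.  A boolean mask marks valid nodes; reduction
steps only ever *shrink* validity except where composition/symmetry union
semantics apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

CONVENTION = "theta: polar from +z pole; phi: from +x toward +y; degrees"

_KERNEL_CACHE: dict = {}


@dataclass
class HologramGrid:
    """chi on a regular spherical grid at fixed wavenumber.

    Parameters
    ----------
    values : (ntheta, nphi) float array
        chi at nodes theta_i = i*theta_step, phi_j = j*phi_step.
    mask : (ntheta, nphi) bool array
        True where the node is valid.
    k : float
        Fluorescence wavenumber in 1/Angstrom.
    theta_step, phi_step : float
        Grid steps in degrees.  phi covers [0, 360) with nphi*phi_step == 360.
    """

    values: np.ndarray
    mask: np.ndarray
    k: float
    theta_step: float = 1.0
    phi_step: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must be matching 2D arrays")
        if not np.isclose(self.nphi * self.phi_step, 360.0):
            raise ValueError("phi axis must tile [0, 360) exactly")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values on valid nodes")

    # -- construction -----------------------------------------------------
    @classmethod
    def empty(cls, k: float, theta_max: float = 90.0, theta_step: float = 1.0,
              phi_step: float = 1.0) -> "HologramGrid":
        nt = int(round(theta_max / theta_step)) + 1
        nphi = int(round(360.0 / phi_step))
        return cls(np.zeros((nt, nphi)), np.ones((nt, nphi), bool), k,
                   theta_step, phi_step)

    def copy(self) -> "HologramGrid":
        return replace(self, values=self.values.copy(), mask=self.mask.copy(),
                       meta=dict(self.meta))

    # -- geometry ---------------------------------------------------------
    @property
    def ntheta(self) -> int:
        return self.values.shape[0]

    @property
    def nphi(self) -> int:
        return self.values.shape[1]

    @property
    def thetas_deg(self) -> np.ndarray:
        return np.arange(self.ntheta) * self.theta_step

    @property
    def phis_deg(self) -> np.ndarray:
        return np.arange(self.nphi) * self.phi_step

    @property
    def theta_max(self) -> float:
        return (self.ntheta - 1) * self.theta_step

    def directions(self) -> np.ndarray:
        """Unit vectors of all nodes, shape (ntheta, nphi, 3)."""
        t = np.deg2rad(self.thetas_deg)[:, None]
        p = np.deg2rad(self.phis_deg)[None, :]
        st = np.broadcast_to(np.sin(t), self.values.shape)
        return np.stack([st * np.cos(p), st * np.sin(p),
                         np.broadcast_to(np.cos(t), self.values.shape)], axis=-1)

    def solid_angle_weights(self) -> np.ndarray:
        """sin(theta) node weights, zeroed on masked nodes."""
        w = np.broadcast_to(np.sin(np.deg2rad(self.thetas_deg))[:, None],
                            self.values.shape).copy()
        w[~self.mask] = 0.0
        return w

    def same_spec(self, other: "HologramGrid", check_k: bool = True) -> bool:
        return (self.values.shape == other.values.shape
                and np.isclose(self.theta_step, other.theta_step)
                and np.isclose(self.phi_step, other.phi_step)
                and (not check_k or np.isclose(self.k, other.k)))

    # -- statistics -------------------------------------------------------
    def weighted_mean(self) -> float:
        w = self.solid_angle_weights()
        tot = w.sum()
        if tot == 0:
            raise ValueError("no valid nodes with nonzero weight")
        return float((w * self.values).sum() / tot)

    def weighted_rms(self) -> float:
        w = self.solid_angle_weights()
        tot = w.sum()
        if tot == 0:
            raise ValueError("no valid nodes with nonzero weight")
        return float(np.sqrt((w * self.values**2).sum() / tot))

    # -- sampling ---------------------------------------------------------
    def sample(self, theta_deg, phi_deg):
        """Bilinear interpolation at arbitrary angles.

        phi wraps periodically; theta outside [0, theta_max] is invalid.
        A sample is valid only if every contributing corner node is valid
        (masked nodes never leak).

        Returns ``(values, valid)`` arrays of the broadcast shape.
        """
        theta = np.asarray(theta_deg, dtype=float)
        phi = np.asarray(phi_deg, dtype=float)
        theta, phi = np.broadcast_arrays(theta, phi)

        ft = theta / self.theta_step
        fp = np.mod(phi, 360.0) / self.phi_step
        i0 = np.floor(ft).astype(int)
        j0 = np.floor(fp).astype(int) % self.nphi
        wt = ft - np.floor(ft)
        wp = fp - np.floor(fp)

        in_range = (theta >= -1e-9) & (ft <= self.ntheta - 1 + 1e-9)
        i0c = np.clip(i0, 0, self.ntheta - 1)
        i1c = np.clip(i0 + 1, 0, self.ntheta - 1)
        j1 = (j0 + 1) % self.nphi

        out = np.zeros(theta.shape)
        valid = in_range.copy()
        corners = ((i0c, j0, (1 - wt) * (1 - wp)), (i0c, j1, (1 - wt) * wp),
                   (i1c, j0, wt * (1 - wp)), (i1c, j1, wt * wp))
        for ii, jj, w in corners:
            contributes = w > 1e-12
            out += w * self.values[ii, jj]
            valid &= ~contributes | self.mask[ii, jj]
        out[~valid] = 0.0
        return out, valid

    # -- persistence ------------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=self.values, track_times=False)
            f.create_dataset("mask", data=self.mask, track_times=False)
            f.attrs["k"] = self.k
            f.attrs["theta_step"] = self.theta_step
            f.attrs["phi_step"] = self.phi_step
            f.attrs["convention"] = CONVENTION

    @classmethod
    def from_hdf5(cls, path) -> "HologramGrid":
        with h5py.File(path, "r") as f:
            return cls(f["values"][...], f["mask"][...], float(f.attrs["k"]),
                       float(f.attrs["theta_step"]), float(f.attrs["phi_step"]))

    def to_csv(self, path) -> None:
        t, p = np.meshgrid(self.thetas_deg, self.phis_deg, indexing="ij")
        chi = np.where(self.mask, self.values, np.nan)
        df = pd.DataFrame({"theta_deg": t.ravel(), "phi_deg": p.ravel(),
                           "chi": chi.ravel()})
        with open(path, "w") as fh:
            fh.write(f"# k = {self.k!r}\n# theta_step = {self.theta_step!r}\n"
                     f"# phi_step = {self.phi_step!r}\n# {CONVENTION}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "HologramGrid":
        attrs = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                parts = line[1:].split("=")
                if len(parts) == 2:
                    attrs[parts[0].strip()] = float(parts[1])
        df = pd.read_csv(path, comment="#")
        nt = df["theta_deg"].nunique()
        nphi = df["phi_deg"].nunique()
        values = df["chi"].to_numpy().reshape(nt, nphi)
        mask = np.isfinite(values)
        values = np.where(mask, values, 0.0)
        return cls(values, mask, attrs.get("k", 0.0),
                   attrs.get("theta_step", 1.0), attrs.get("phi_step", 1.0))


def rotate_grid(grid: HologramGrid, rotation: np.ndarray) -> HologramGrid:
    """Resample so node n holds the value formerly at R^-1 * n.

    A feature at direction d moves to R*d.  The mask is transported the same
    way; source directions outside grid coverage come out masked.
    """
    rotation = np.asarray(rotation, dtype=float)
    check_rotation(rotation)
    dirs = grid.directions()
    src = dirs @ rotation  # row-vector form of R^T @ n
    z = np.clip(src[..., 2], -1.0, 1.0)
    theta = np.rad2deg(np.arccos(z))
    phi = np.rad2deg(np.arctan2(src[..., 1], src[..., 0]))
    vals, valid = grid.sample(theta, phi)
    out = grid.copy()
    out.values, out.mask = vals, valid
    return out


def check_rotation(rotation: np.ndarray, tol: float = 1e-6) -> None:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if not np.allclose(rotation @ rotation.T, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthogonal")
    if abs(np.linalg.det(rotation) - 1.0) > tol:
        raise ValueError("matrix is not a proper rotation (det != +1)")


def _smoothing_kernel(ntheta, nphi, theta_step, phi_step, sigma_deg):
    """Per-row-pair azimuthal FFTs of the great-circle Gaussian kernel.

    Returns (row_lo, row_hi, kernel_fft) where kernel_fft[i] holds the rfft
    over delta-phi of exp(-Delta^2 / 2 sigma^2) * sin(theta_j) for source rows
    j in [row_lo[i], row_hi[i]).
    """
    key = (ntheta, nphi, round(theta_step, 9), round(phi_step, 9),
           round(sigma_deg, 9))
    if key in _KERNEL_CACHE:
        return _KERNEL_CACHE[key]
    sigma = np.deg2rad(sigma_deg)
    thetas = np.deg2rad(np.arange(ntheta) * theta_step)
    dphi = np.deg2rad(np.arange(nphi) * phi_step)
    cos_dphi = np.cos(dphi)
    window = max(1, int(np.ceil(4.0 * sigma_deg / theta_step)))
    row_lo = np.maximum(np.arange(ntheta) - window, 0)
    row_hi = np.minimum(np.arange(ntheta) + window + 1, ntheta)
    ker = []
    for i in range(ntheta):
        js = np.arange(row_lo[i], row_hi[i])
        cosd = (np.cos(thetas[i]) * np.cos(thetas[js])[:, None]
                + np.sin(thetas[i]) * np.sin(thetas[js])[:, None]
                * cos_dphi[None, :])
        delta = np.arccos(np.clip(cosd, -1.0, 1.0))
        w = np.exp(-0.5 * (delta / sigma) ** 2) * np.sin(thetas[js])[:, None]
        ker.append(np.fft.rfft(w, axis=1))
    _KERNEL_CACHE[key] = (row_lo, row_hi, ker)
    return _KERNEL_CACHE[key]


def spherical_smooth(grid: HologramGrid, sigma_deg: float) -> HologramGrid:
    """Gaussian smoothing with great-circle distances and sin(theta) weights.

    Masked nodes contribute nothing; remaining weights are renormalized, so
    the filter is exact near mask boundaries.  The output mask equals the
    input mask (smoothing never unmasks).
    """
    if sigma_deg <= 0:
        raise ValueError("sigma must be positive")
    row_lo, row_hi, ker = _smoothing_kernel(
        grid.ntheta, grid.nphi, grid.theta_step, grid.phi_step, sigma_deg)
    m = grid.mask.astype(float)
    vm_fft = np.fft.rfft(grid.values * m, axis=1)
    m_fft = np.fft.rfft(m, axis=1)
    num = np.zeros_like(grid.values)
    den = np.zeros_like(grid.values)
    for i in range(grid.ntheta):
        kf = ker[i]
        sl = slice(row_lo[i], row_hi[i])
        num[i] = np.fft.irfft((kf * vm_fft[sl]).sum(axis=0), n=grid.nphi)
        den[i] = np.fft.irfft((kf * m_fft[sl]).sum(axis=0), n=grid.nphi)
    out = grid.copy()
    good = grid.mask & (den > 1e-12)
    out.values = np.where(good, num / np.where(den > 1e-12, den, 1.0), 0.0)
    out.mask = good
    return out
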