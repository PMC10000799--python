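"""Forward hologram model (normal mode, single scattering).

The holographic oscillation recorded along the emission direction k-hat is

    chi(k_hat) = -r_e * sum_j occ_j * f_j(theta_rj) / r_j
                 * exp(-sigma^2 k^2 (1 - cos theta_rj))
                 * cos(k r_j (1 - cos theta_rj))

with r_j the emitter->scatterer vector, theta_rj the angle between k_hat and
r_j, f_j the atomic form factor evaluated at momentum transfer
q = 2 k sin(theta_rj / 2), and sigma^2 = <u^2>_Rel / 3 the Gaussian width of
the relative displacement of the scatterer about its mean position (from the
isotropic relation <u^2>/6 = sigma^2/2 per Cartesian component pair).

The sign is chosen so that the forward-scattering (theta_rj = 0) feature is
an intensity *dip*; at theta_rj = 0 the damping term is identically 1, which
is why forward dips survive arbitrarily large disorder while backscattering
rings wash out.  The overall r_e prefactor is configurable
(`constants.CHI_SIGN`, `physical_scale`); all analyses here are invariant
under it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import constants
from .grid import HologramGrid, check_rotation
from .structure_io import AtomSite, EmitterCluster, form_factor

__all__ = ["FSDirection", "damping_factor", "dimer_hologram",
           "cluster_hologram", "superpose_holograms", "fs_directions",
           "cluster_terms", "GridSpec"]


@dataclass
class GridSpec:
    """Angular grid layout for computed holograms (degrees)."""

    theta_max: float = 90.0
    theta_step: float = 1.0
    phi_step: float = 1.0

    def empty(self, k: float) -> HologramGrid:
        return HologramGrid.empty(k, self.theta_max, self.theta_step,
                                  self.phi_step)


@dataclass
class FSDirection:
    """Forward-scattering dip position: the real-space projection of one
    scatterer as seen from its emitter."""

    emitter_label: str
    scatterer_label: str
    theta: float       # degrees, in hologram frame
    phi: float         # degrees
    distance: float    # Angstrom

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180] degrees")

    @property
    def marker_weight(self) -> float:
        """Plot-marker weight proportional to 1/distance."""
        return 1.0 / self.distance


def damping_factor(k: float, theta_rj, u2rel: float):
    """Disorder damping exp(-sigma^2 k^2 (1 - cos theta_rj)).

    ``theta_rj`` is in radians; ``u2rel`` is <u^2>_Rel in A^2 and
    sigma^2 = u2rel / 3.  Equals 1 exactly at theta_rj = 0 for any disorder.
    """
    if u2rel < 0:
        raise ValueError("u2rel must be >= 0")
    sigma2 = u2rel / 3.0
    return np.exp(-sigma2 * k**2 * (1.0 - np.cos(theta_rj)))


def _scatterer_field(emitter: AtomSite, scatterer: AtomSite, k: float,
                     dirs: np.ndarray, physical_scale: bool):
    """(amplitude*cos term without damping, damping exponent coefficient).

    chi_j(u2) = amp * exp(-u2 * coef) nodewise, with
    coef = k^2 (1 - cos theta_rj) / 3.
    """
    rvec = scatterer.position - emitter.position
    r = np.linalg.norm(rvec)
    if r == 0:
        raise ValueError("emitter and scatterer coincide")
    cos_t = np.clip(dirs @ (rvec / r), -1.0, 1.0)
    one_m = 1.0 - cos_t
    q = 2.0 * k * np.sin(0.5 * np.arccos(cos_t))
    f = form_factor(scatterer.element, q)
    re = constants.R_E_ANGSTROM if physical_scale else 1.0
    amp = (constants.CHI_SIGN * re * scatterer.occupancy * f / r
           * np.cos(k * r * one_m))
    coef = (k**2 / 3.0) * one_m
    return amp, coef


def dimer_hologram(emitter: AtomSite, scatterer: AtomSite, k: float,
                   u2rel: float = 0.0, grid_spec: GridSpec | None = None,
                   physical_scale: bool = False) -> HologramGrid:
    """Hologram of a single emitter-scatterer pair.

    The global minimum sits at the grid node nearest the emitter->scatterer
    direction (the FS dip), surrounded by concentric interference rings whose
    amplitude the disorder term suppresses.
    """
    if u2rel < 0:
        raise ValueError("u2rel must be >= 0")
    grid = (grid_spec or GridSpec()).empty(k)
    amp, coef = _scatterer_field(emitter, scatterer, k, grid.directions(),
                                 physical_scale)
    grid.values = amp * np.exp(-u2rel * coef)
    return grid


def cluster_hologram(cluster: EmitterCluster, k: float,
                     grid_spec: GridSpec | None = None,
                     physical_scale: bool = False) -> HologramGrid:
    """Sum of single-scatterer holograms over the cluster; zero for an
    empty cluster.  Linear in scatterer occupancy."""
    grid = (grid_spec or GridSpec()).empty(k)
    dirs = grid.directions()
    total = np.zeros(grid.values.shape)
    for s in cluster.scatterers:
        amp, coef = _scatterer_field(cluster.emitter, s, k, dirs,
                                     physical_scale)
        total += amp * np.exp(-cluster.u2rel * coef)
    grid.values = total
    return grid


def cluster_terms(clusters, k: float, grid_spec: GridSpec | None = None,
                  physical_scale: bool = False):
    """Precompute per-scatterer fields so the superposed hologram can be
    re-evaluated cheaply at many disorder values.

    Returns ``(amps, coefs, template)``; the equal-weight superposition at a
    given u2 is ``mean_over_clusters(sum_j amps_j * exp(-u2 * coefs_j))`` and
    is produced by :func:`evaluate_terms`.
    """
    clusters = list(clusters)
    template = (grid_spec or GridSpec()).empty(k)
    dirs = template.directions()
    amps, coefs = [], []
    for cl in clusters:
        for s in cl.scatterers:
            a, c = _scatterer_field(cl.emitter, s, k, dirs, physical_scale)
            amps.append(a)
            coefs.append(c)
    n = max(len(clusters), 1)
    return (np.array(amps), np.array(coefs), n, template)


def evaluate_terms(terms, u2rel: float) -> HologramGrid:
    """Equal-weight superposed hologram at one disorder value from
    :func:`cluster_terms` output."""
    amps, coefs, n_clusters, template = terms
    out = template.copy()
    if len(amps):
        out.values = (amps * np.exp(-u2rel * coefs)).sum(axis=0) / n_clusters
    return out


def superpose_holograms(grids, weights=None) -> HologramGrid:
    """Weighted mean of holograms on identical grids (default equal weights).

    Per node, the mean runs over the grids valid there; nodes valid in no
    grid are masked.
    """
    grids = list(grids)
    if not grids:
        raise ValueError("no holograms to superpose")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_spec(g):
            raise ValueError("hologram grid specs (shape/steps/k) differ")
    if weights is None:
        weights = np.ones(len(grids))
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (len(grids),):
        raise ValueError("one weight per hologram required")
    num = np.zeros(first.values.shape)
    den = np.zeros(first.values.shape)
    for g, w in zip(grids, weights):
        num += w * np.where(g.mask, g.values, 0.0)
        den += w * g.mask
    out = first.copy()
    out.mask = den > 0
    out.values = np.where(out.mask, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def fs_directions(cluster: EmitterCluster, orientation=None,
                  element_filter=("Mn", "Ca")) -> list[FSDirection]:
    """Forward-scattering dip directions for the filtered scatterers.

    ``orientation`` (crystal->hologram frame rotation) is applied to each
    emitter->scatterer unit vector; marker weight is 1/distance, mirroring
    the convention that closer scatterers get larger overlay circles.
    """
    if orientation is None:
        orientation = np.eye(3)
    orientation = np.asarray(orientation, dtype=float)
    check_rotation(orientation)
    wanted = set(element_filter) if element_filter else None
    out = []
    for s in cluster.scatterers:
        if wanted is not None and s.element not in wanted:
            continue
        v = s.position - cluster.emitter.position
        d = float(np.linalg.norm(v))
        u = orientation @ (v / d)
        theta = float(np.rad2deg(np.arccos(np.clip(u[2], -1.0, 1.0))))
        phi = float(np.rad2deg(np.arctan2(u[1], u[0])) % 360.0)
        out.append(FSDirection(cluster.emitter.label, s.label, theta, phi, d))
    return out
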