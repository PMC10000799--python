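"""R-factor comparison and grid-scan estimation of <u^2>_Rel.

The agreement between an experimental and a calculated hologram is scored
with a scale-factored R-factor (the photoelectron-diffraction convention):

    R = sum_w (chi_exp - s * chi_calc)^2 / sum_w chi_exp^2

with solid-angle weights w = sin(theta) over the joint valid nodes and s the
least-squares scale, so R is invariant under rescaling of either pattern and
R = 0 iff the patterns are proportional.  A symmetric alternative
sum_w (e - c)^2 / sum_w (e^2 + c^2) is available for sensitivity checks.

The disorder parameter is estimated by recomputing the superposed cluster
hologram on a grid of <u^2>_Rel values (each low-passed like the
experimental hologram) and taking the R-factor argmin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import HologramGrid
from .hologram_model import GridSpec, cluster_terms, evaluate_terms
from .processing import finalize

__all__ = ["RFactorScan", "r_factor", "scan_u2rel", "u2_to_bfactor",
           "DEFAULT_U2_GRID"]

#: default scan grid in A^2, covering the physically illustrated range
DEFAULT_U2_GRID = np.round(np.arange(0.05, 2.0001, 0.05), 10)


@dataclass
class RFactorScan:
    u2rel_values: np.ndarray
    r_values: np.ndarray
    argmin: float

    def __post_init__(self):
        self.u2rel_values = np.asarray(self.u2rel_values, dtype=float)
        self.r_values = np.asarray(self.r_values, dtype=float)
        if np.any(self.r_values < 0):
            raise ValueError("R-factors must be >= 0")
        if self.argmin not in self.u2rel_values:
            raise ValueError("argmin must be attained on the grid")


def r_factor(chi_exp: HologramGrid, chi_calc: HologramGrid,
             form: str = "scaled") -> float:
    """Weighted R-factor between two holograms on the same grid spec."""
    if not chi_exp.same_spec(chi_calc, check_k=False):
        raise ValueError("hologram grid specs differ")
    mask = chi_exp.mask & chi_calc.mask
    w = np.broadcast_to(
        np.sin(np.deg2rad(chi_exp.thetas_deg))[:, None], mask.shape).copy()
    w[~mask] = 0.0
    if w.sum() == 0:
        raise ValueError("empty joint mask")
    e = chi_exp.values
    c = chi_calc.values
    norm_e = (w * e**2).sum()
    if norm_e == 0:
        raise ValueError("experimental hologram has zero norm")
    if form == "scaled":
        norm_c = (w * c**2).sum()
        s = (w * e * c).sum() / norm_c if norm_c > 0 else 0.0
        return float((w * (e - s * c) ** 2).sum() / norm_e)
    if form == "symmetric":
        norm_c = (w * c**2).sum()
        return float((w * (e - c) ** 2).sum() / (norm_e + norm_c))
    raise ValueError(f"unknown R-factor form {form!r}")


def scan_u2rel(chi_exp: HologramGrid, clusters, k: float,
               grid_spec: GridSpec | None = None, u2_grid=DEFAULT_U2_GRID,
               lowpass_sigma: float = 10.0, form: str = "scaled"
               ) -> RFactorScan:
    """R-factor curve over a grid of disorder values and its argmin.

    Each candidate hologram is the equal-weight superposition over the
    clusters, low-passed and de-meaned exactly like the experimental
    hologram, then scored against it.  Ties break toward smaller u2.
    """
    u2_grid = np.asarray(u2_grid, dtype=float)
    if u2_grid.size == 0:
        raise ValueError("empty u2 grid")
    if np.any(np.diff(u2_grid) <= 0):
        raise ValueError("u2 grid must be ascending")
    if grid_spec is None:
        grid_spec = GridSpec(theta_max=chi_exp.theta_max,
                             theta_step=chi_exp.theta_step,
                             phi_step=chi_exp.phi_step)
    terms = cluster_terms(clusters, k, grid_spec)
    rs = np.empty(u2_grid.size)
    for n, u2 in enumerate(u2_grid):
        calc = evaluate_terms(terms, u2)
        calc.mask = calc.mask & chi_exp.mask
        calc = finalize(calc, lowpass_sigma, subtract=0.0)
        rs[n] = r_factor(chi_exp, calc, form=form)
    best = int(np.argmin(rs))   # first minimum = smaller u2 on ties
    return RFactorScan(u2_grid, rs, float(u2_grid[best]))


def u2_to_bfactor(u2) -> float:
    """Crystallographic displacement parameter B = 8 pi^2 <u^2> (A^2)."""
    u2 = np.asarray(u2, dtype=float)
    if np.any(u2 < 0):
        raise ValueError("mean-square displacement must be >= 0")
    out = 8.0 * np.pi**2 * u2
    return float(out) if out.ndim == 0 else out
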