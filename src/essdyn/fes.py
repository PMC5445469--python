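"""Free-energy surfaces over pairs of principal components.

The density of the trajectory projected onto two user-selected PC axes is
estimated by Gaussian kernel density estimation with a diagonal bandwidth
(Silverman's rule per axis by default) and converted to a relative free
energy

    dG(x) = -k_B T ln[ p(x) / p_max ],

which is zero at the density maximum by construction.  Grid cells whose
density falls below 1e-12 of the maximum are masked (infinite dG).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FESGrid", "silverman_bandwidths", "kde2d", "free_energy_surface"]

KB_KCAL_PER_MOL_K = 0.0019872041  # Boltzmann constant, kcal/(mol K)
DENSITY_FLOOR_RTOL = 1e-12


@dataclass
class FESGrid:
    """2D free-energy grid over two PC axes.

    ``free_energy`` is in units of k_B T; multiply by
    ``kcal_per_mol_per_kbt`` for kcal/mol.  ``min_location`` indexes the
    dG = 0 cell (density maximum).
    """

    axis1: np.ndarray  # grid coordinates along PC axis 1 (G,)
    axis2: np.ndarray  # (G,)
    free_energy: np.ndarray  # (G, G) in k_B T; masked cells are +inf
    bandwidths: tuple[float, float]
    temperature: float  # K
    min_location: tuple[int, int]
    density: np.ndarray | None = None

    @property
    def kcal_per_mol_per_kbt(self) -> float:
        return KB_KCAL_PER_MOL_K * self.temperature

    def to_text(self, path: str | Path) -> None:
        """Write a 3-column table (pc1, pc2, dG in k_B T and kcal/mol)."""
        with open(path, "w") as fh:
            fh.write(
                f"# free energy surface; T = {self.temperature} K; "
                f"bandwidths = {self.bandwidths[0]:.6g}, {self.bandwidths[1]:.6g} "
                "(Silverman per axis unless overridden)\n"
                "# pc1 pc2 dG_kBT dG_kcal_per_mol\n"
            )
            conv = self.kcal_per_mol_per_kbt
            for i, x in enumerate(self.axis1):
                for j, y in enumerate(self.axis2):
                    g = self.free_energy[i, j]
                    fh.write(f"{x:.6e} {y:.6e} {g:.6e} {g * conv:.6e}\n")


def silverman_bandwidths(points: np.ndarray) -> tuple[float, float]:
    """Per-axis Silverman bandwidth h = sigma * n^(-1/6) for 2-D data."""
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    sd = points.std(axis=0, ddof=1)
    return tuple(float(s) * n ** (-1.0 / 6.0) for s in sd)


def kde2d(
    points: np.ndarray,
    grid_size: int = 100,
    bandwidths: tuple[float, float] | None = None,
    padding: float = 3.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian KDE of n x 2 points on a grid padded by ``padding``
    bandwidths beyond the data range.

    Returns ``(axis1, axis2, density)`` with density (G, G), normalised so
    that its Riemann sum over the plane is ~1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be n x 2")
    n = points.shape[0]
    if n < 10:
        raise ValueError("KDE requires at least 10 points")
    if bandwidths is None:
        bandwidths = silverman_bandwidths(points)
    hx, hy = bandwidths
    if hx <= 0 or hy <= 0:
        raise ValueError("zero-variance axis: bandwidth must be positive")
    x, y = points[:, 0], points[:, 1]
    ax1 = np.linspace(x.min() - padding * hx, x.max() + padding * hx, grid_size)
    ax2 = np.linspace(y.min() - padding * hy, y.max() + padding * hy, grid_size)
    # separable Gaussian kernels: density = Gx @ Gy^T / n
    gx = np.exp(-0.5 * ((ax1[:, None] - x[None, :]) / hx) ** 2) / (
        hx * np.sqrt(2 * np.pi)
    )
    gy = np.exp(-0.5 * ((ax2[:, None] - y[None, :]) / hy) ** 2) / (
        hy * np.sqrt(2 * np.pi)
    )
    density = gx @ gy.T / n
    return ax1, ax2, density


def free_energy_surface(
    pc_pair: np.ndarray,
    temperature: float = 300.0,
    grid_size: int = 100,
    bandwidths: tuple[float, float] | None = None,
) -> FESGrid:
    """Relative free energy -k_B T ln(p / p_max) over two PC projections.

    The surface minimum is exactly 0 at the density maximum; cells with
    density below 1e-12 of the maximum are masked to +inf.
    """
    ax1, ax2, density = kde2d(pc_pair, grid_size, bandwidths)
    if bandwidths is None:
        bandwidths = silverman_bandwidths(np.asarray(pc_pair, dtype=float))
    p_max = density.max()
    imax = np.unravel_index(int(np.argmax(density)), density.shape)
    floor = DENSITY_FLOOR_RTOL * p_max
    with np.errstate(divide="ignore"):
        dg = np.where(density >= floor, -np.log(density / p_max), np.inf)
    dg[imax] = 0.0
    return FESGrid(
        axis1=ax1,
        axis2=ax2,
        free_energy=dg,
        bandwidths=(float(bandwidths[0]), float(bandwidths[1])),
        temperature=float(temperature),
        min_location=(int(imax[0]), int(imax[1])),
        density=density,
    )
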