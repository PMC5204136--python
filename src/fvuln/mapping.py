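"""Kernel-density maps of redundancy, sensitivity and vulnerability in trait space.

Each index is mapped over a pair of functional axes as a weighted 2-D
Gaussian kernel density: FE points carry mass proportional to their
index value, so the surface shows where in the trait space the index
concentrates. The bandwidth follows the bivariate normal-reference
("ad hoc") rule

    h = sigma * n^(-1/6),   sigma^2 = (var(x) + var(y)) / 2

with n the number of FEs and var the per-axis sample variances.
Surface agreement is quantified with the Pearson product-moment
correlation, either across grid cells or across FE-level index values.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError


def adhoc_bandwidth(points: np.ndarray) -> float:
    """Normal-reference bandwidth for a 2-D point cloud.

    sigma pools the two per-axis sample variances (mean of the variance
    estimates); the n^(-1/6) rate is the bivariate normal-optimal decay.
    Doubling all coordinates doubles h; h decreases monotonically in n.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected n x 2 coordinates, got shape {pts.shape}")
    n = pts.shape[0]
    if n < 2:
        raise ValidationError("bandwidth requires at least 2 points")
    var = pts.var(axis=0, ddof=1)
    sigma2 = float(var.mean())
    if sigma2 <= 0:
        raise ValidationError("zero variance point cloud: bandwidth undefined")
    return float(np.sqrt(sigma2) * n ** (-1.0 / 6.0))


@dataclasses.dataclass(frozen=True)
class DensitySurface:
    """Gridded weighted KDE of one index over two functional axes."""

    axis_pair: tuple[str, str]
    x: np.ndarray  # grid cell centres, shape (g,)
    y: np.ndarray
    values: np.ndarray  # shape (g, g), rows follow y, columns follow x
    bandwidth: float
    weight_field: str = "density"

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def integral(self) -> float:
        return float(self.values.sum() * self.cell_area)


def kde_surface(
    points: np.ndarray,
    weights: np.ndarray | None = None,
    h: float | None = None,
    grid_size: int = 100,
    padding: float | None = None,
    axis_pair: tuple[str, str] = ("PC1", "PC2"),
    weight_field: str = "density",
) -> DensitySurface:
    """Weighted isotropic Gaussian KDE of FE points on a regular grid.

    Weights (the index values) are normalised to sum to 1, so two
    coincident unit-weight points and one point of weight 2 produce the
    same surface, and equal weights reduce to an ordinary KDE. The grid
    spans the point extents padded by 3h per side (configurable) and the
    discretised surface is renormalised so that its Riemann sum is
    exactly 1.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError(f"expected n x 2 coordinates, got shape {pts.shape}")
    if h is None:
        h = adhoc_bandwidth(pts)
    if h <= 0:
        raise ValidationError(f"bandwidth must be positive, got {h}")
    if weights is None:
        w = np.ones(len(pts))
    else:
        w = np.asarray(weights, float)
        if len(w) != len(pts):
            raise ValidationError("weights and points length mismatch")
        if (w < 0).any():
            raise ValidationError("KDE weights must be non-negative")
        if w.sum() <= 0:
            raise ValidationError("all KDE weights are zero")
    w = w / w.sum()
    if padding is None:
        padding = 3.0 * h
    lo = pts.min(axis=0) - padding
    hi = pts.max(axis=0) + padding
    gx = np.linspace(lo[0], hi[0], grid_size)
    gy = np.linspace(lo[1], hi[1], grid_size)
    # evaluate sum_i w_i N((x,y); p_i, h^2 I) on the grid, separably per point
    dx = (gx[None, :] - pts[:, 0][:, None]) / h  # (n, g)
    dy = (gy[None, :] - pts[:, 1][:, None]) / h
    kx = np.exp(-0.5 * dx**2)
    ky = np.exp(-0.5 * dy**2)
    dens = np.einsum("i,iy,ix->yx", w, ky, kx) / (2.0 * np.pi * h**2)
    surf = DensitySurface(
        axis_pair=axis_pair, x=gx, y=gy, values=dens, bandwidth=float(h),
        weight_field=weight_field,
    )
    # renormalise the Riemann sum to 1 (tail mass outside the grid and
    # discretisation would otherwise leave the integral slightly off)
    total = surf.integral()
    if total <= 0:
        raise ValidationError("KDE surface integrates to zero")
    return dataclasses.replace(surf, values=dens / total)


def surface_correlation(sa: DensitySurface, sb: DensitySurface) -> tuple[float, float]:
    """Pearson r (and p-value) between two surfaces over shared grid cells."""
    if sa.values.shape != sb.values.shape:
        raise ValidationError("surfaces are on different grids")
    if not (np.allclose(sa.x, sb.x) and np.allclose(sa.y, sb.y)):
        raise ValidationError("surfaces are on different grid extents")
    va, vb = sa.values.ravel(), sb.values.ravel()
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValidationError("constant surface: Pearson correlation undefined")
    r, p = stats.pearsonr(va, vb)
    return float(r), float(p)


def index_correlation(x, y) -> tuple[float, float]:
    """FE-level Pearson correlation between two per-FE index vectors."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if len(xa) != len(ya):
        raise ValidationError("index vectors differ in length")
    if len(xa) < 3:
        raise ValidationError("need at least 3 FEs to correlate")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValidationError("constant index vector: Pearson correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


def surface_frame(surf: DensitySurface) -> pd.DataFrame:
    """Long-format frame (x, y, density) of a surface, for CSV output."""
    xx, yy = np.meshgrid(surf.x, surf.y)
    return pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "density": surf.values.ravel()}
    )
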