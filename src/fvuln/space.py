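"""Functional trait space: Gower distances, PCoA ordination, convex-hull richness.

The trait space is built by ordinating the species x species Gower
distance matrix with principal coordinates analysis (PCoA) and retaining
the first four axes. Functional richness (FRic) of an assemblage is the
volume of the convex hull of its points in that space, usually reported
relative to the hull volume of the global species pool.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .entities import ORDERED_TRAITS, TRAIT_CATEGORIES, TRAIT_COLUMNS, validate_traits
from .errors import DegenerateHullError, ValidationError


def gower_distance(traits: pd.DataFrame) -> DistanceMatrix:
    """Pairwise Gower distances between species from the six traits.

    Each trait contributes with equal weight 1/6. Ordered traits are
    encoded as equally spaced ranks scaled to [0, 1] and contribute the
    absolute rank difference; diet (nominal) contributes simple matching
    (0 if equal, 1 otherwise). Distances therefore lie in [0, 1], with 0
    for identical trait vectors and 1 for species differing maximally in
    every trait.
    """
    df = validate_traits(traits)
    n = len(df)
    if n < 2:
        raise ValidationError("gower_distance requires at least 2 species")
    total = np.zeros((n, n))
    for col in TRAIT_COLUMNS:
        cats = TRAIT_CATEGORIES[col]
        codes = df[col].map({c: i for i, c in enumerate(cats)}).to_numpy(float)
        if col in ORDERED_TRAITS:
            ranks = codes / (len(cats) - 1)  # range-normalised to [0,1]
            contrib = np.abs(ranks[:, None] - ranks[None, :])
        else:
            contrib = (codes[:, None] != codes[None, :]).astype(float)
        total += contrib
    d = total / len(TRAIT_COLUMNS)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=list(df.index))


@dataclasses.dataclass(frozen=True)
class FunctionalSpace:
    """Point coordinates on the retained PCoA axes.

    Attributes
    ----------
    coordinates
        Species (or FE) x axis frame, columns ``PC1..PCk``; column means
        are ~0 (PCoA centres the configuration).
    eigenvalues
        Eigenvalues of the retained axes, non-negative and decreasing.
    corrected
        Whether an additive (Lingoes) correction was applied to remove
        negative eigenvalues before extracting axes.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    corrected: bool = False

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def points(self, ids: list[str] | None = None) -> np.ndarray:
        if ids is None:
            return self.coordinates.to_numpy()
        missing = [i for i in ids if i not in self.coordinates.index]
        if missing:
            raise ValidationError(f"ids not present in functional space: {missing[:5]}")
        return self.coordinates.loc[list(ids)].to_numpy()


def _gram_eigenvalues(d: np.ndarray) -> np.ndarray:
    """Eigenvalues of the double-centred -0.5 * D^2 matrix, descending."""
    d2 = d**2
    j = np.eye(len(d)) - np.ones_like(d) / len(d)
    g = -0.5 * j @ d2 @ j
    return np.sort(np.linalg.eigvalsh(g))[::-1]


def pcoa(
    dist: DistanceMatrix,
    n_axes: int = 4,
    negative_policy: str = "auto",
) -> FunctionalSpace:
    """Principal coordinates analysis of a distance matrix.

    Parameters
    ----------
    dist
        Symmetric distance matrix (e.g. Gower).
    n_axes
        Number of leading axes to retain (default 4).
    negative_policy
        How to treat negative eigenvalues, which arise because Gower
        matrices are generally non-Euclidean:

        - ``"drop"``: ignore negative axes, keep the leading positive ones;
        - ``"correct"``: always apply the Lingoes additive correction
          (d'^2 = d^2 + 2|lambda_min| off-diagonal) so the matrix embeds
          exactly;
        - ``"auto"`` (default): correct only when the most negative
          eigenvalue is comparable in magnitude to the smallest retained
          one (|lambda_min| >= lambda_(n_axes)), i.e. when the retained
          axes would be distorted; otherwise drop.

    Axis signs are fixed so that each axis' largest-magnitude coordinate
    is positive, making ordinations reproducible across platforms.
    """
    if negative_policy not in ("auto", "correct", "drop"):
        raise ValidationError(f"unknown negative_policy: {negative_policy!r}")
    d = dist.data.astype(float)
    n = len(d)
    if n < n_axes + 1:
        raise ValidationError(
            f"pcoa requires at least {n_axes + 1} points for {n_axes} axes, got {n}"
        )
    if not np.any(d > 0):
        raise ValidationError("all pairwise distances are zero; no ordination exists")

    eig = _gram_eigenvalues(d)
    lam_min = eig[-1]
    corrected = False
    if lam_min < -1e-12:
        if negative_policy == "correct" or (
            negative_policy == "auto" and abs(lam_min) >= eig[n_axes - 1]
        ):
            # Lingoes: adding 2*c to off-diagonal squared distances shifts all
            # non-trivial eigenvalues up by c, removing negatives exactly.
            c = abs(lam_min)
            d2 = d**2 + 2.0 * c
            np.fill_diagonal(d2, 0.0)
            d = np.sqrt(d2)
            corrected = True

    with warnings.catch_warnings():
        # negative eigenvalues are handled by the policy above; skbio's
        # advisory warnings about them are redundant here
        warnings.simplefilter("ignore", RuntimeWarning)
        res = _skbio_pcoa(DistanceMatrix(d, ids=dist.ids), method="eigh")
    eigvals = res.eigvals.to_numpy()
    coords = res.samples.to_numpy()
    k = min(n_axes, coords.shape[1])
    coords = coords[:, :k].copy()
    eigvals = eigvals[:k].copy()
    # sign convention: largest-|coordinate| entry of each axis is positive
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    frame = pd.DataFrame(
        coords,
        index=pd.Index(dist.ids, name="id"),
        columns=[f"PC{j + 1}" for j in range(coords.shape[1])],
    )
    return FunctionalSpace(coordinates=frame, eigenvalues=eigvals, corrected=corrected)


def hull_volume(points: np.ndarray) -> float:
    """Exact convex-hull volume of a point cloud (Qhull facet decomposition)."""
    points = np.asarray(points, float)
    try:
        return float(ConvexHull(points).volume)
    except QhullError as exc:
        raise DegenerateHullError(
            f"degenerate point set ({points.shape[0]} points in "
            f"{points.shape[1]}-D): {str(exc).splitlines()[0]}"
        ) from exc


@dataclasses.dataclass(frozen=True)
class FRicResult:
    """Functional richness of a region relative to the global pool."""

    region_id: str
    hull_volume: float
    global_volume: float

    @property
    def ratio(self) -> float:
        return self.hull_volume / self.global_volume


def fric(
    space: FunctionalSpace,
    region_members: list[str],
    global_members: list[str],
    region_id: str = "region",
) -> FRicResult:
    """Convex-hull functional richness of a region as a fraction of the pool.

    ``region_members`` must be a subset of ``global_members``; both hulls
    are built on species points in the retained-axis space. The ratio lies
    in (0, 1]: it equals 1 when the region holds the whole pool (or all of
    its hull vertices, since interior points do not change a hull).
    """
    region_set, global_set = set(region_members), set(global_members)
    extra = region_set - global_set
    if extra:
        raise ValidationError(
            f"region members not in global pool: {sorted(extra)[:5]}"
        )
    vol_r = hull_volume(space.points(sorted(region_set)))
    vol_g = hull_volume(space.points(sorted(global_set)))
    return FRicResult(region_id=region_id, hull_volume=vol_r, global_volume=vol_g)
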