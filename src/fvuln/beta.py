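"""Pairwise beta-diversity partitioned into turnover and nestedness (Jaccard family).

Taxonomic beta-diversity works on species incidence between two regions,
summarised by the triple (a, b, c): shared, unique-to-A, unique-to-B
counts. The Jaccard dissimilarity splits additively into a turnover
(replacement) component and a nestedness-resultant component:

    beta_jac = (b + c) / (a + b + c)
    beta_jtu = 2 min(b, c) / (a + 2 min(b, c))
    beta_jne = beta_jac - beta_jtu

Functional beta-diversity applies the same partition to convex-hull
volumes in trait space: the shared hull volume plays the role of a, the
volumes unique to each region play b and c. Intersection volumes in 4-D
are estimated by seeded rejection sampling.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .errors import DegenerateHullError, ValidationError
from .space import FunctionalSpace


@dataclasses.dataclass(frozen=True)
class BetaResult:
    pair: tuple[str, str]
    beta_jac: float
    beta_jtu: float
    beta_jne: float
    mode: str  # "taxonomic" | "functional"
    se: float | None = None  # Monte-Carlo standard error of beta_jac (functional)


def jaccard_partition(a: float, b: float, c: float, pair=("A", "B"), mode="taxonomic") -> BetaResult:
    """Partition Jaccard dissimilarity from an incidence (or volume) triple.

    ``a`` is the quantity shared by both assemblages, ``b`` and ``c`` the
    quantities unique to each. All must be non-negative with a positive
    sum. Identical assemblages (b = c = 0) give all components 0;
    disjoint assemblages (a = 0) give beta_jac = beta_jtu = 1, the
    maximum, and beta_jne = 0.
    """
    if min(a, b, c) < 0:
        raise ValidationError(f"incidence triple must be non-negative, got {(a, b, c)}")
    if a + b + c == 0:
        raise ValidationError("a = b = c = 0: Jaccard dissimilarity is undefined")
    beta_jac = (b + c) / (a + b + c)
    m = min(b, c)
    beta_jtu = 2 * m / (a + 2 * m) if m > 0 else 0.0
    return BetaResult(
        pair=tuple(pair),
        beta_jac=float(beta_jac),
        beta_jtu=float(beta_jtu),
        beta_jne=float(beta_jac - beta_jtu),
        mode=mode,
    )


def taxonomic_beta(regions: dict[str, set]) -> list[BetaResult]:
    """Jaccard partition for every unordered pair of regional species sets."""
    if len(regions) < 2:
        raise ValidationError("taxonomic_beta requires at least 2 regions")
    for rid, sp in regions.items():
        if not sp:
            raise ValidationError(f"region '{rid}' has an empty species set")
    out = []
    for ra, rb in itertools.combinations(sorted(regions), 2):
        sa, sb = set(regions[ra]), set(regions[rb])
        a = len(sa & sb)
        b = len(sa - sb)
        c = len(sb - sa)
        out.append(jaccard_partition(a, b, c, pair=(ra, rb), mode="taxonomic"))
    return out


def _hull(points: np.ndarray, label: str) -> ConvexHull:
    try:
        return ConvexHull(points)
    except QhullError as exc:
        raise DegenerateHullError(
            f"region '{label}': degenerate hull ({points.shape[0]} points in "
            f"{points.shape[1]}-D): {str(exc).splitlines()[0]}"
        ) from exc


def _inside(hull: ConvexHull, pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    # facet half-space test: A x + b <= 0 for all facets
    eq = hull.equations
    return np.all(pts @ eq[:, :-1].T + eq[:, -1] <= tol, axis=1)


def hull_overlap_volumes(
    points_a: np.ndarray,
    points_b: np.ndarray,
    n_samples: int = 100_000,
    seed: int = 0,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[float, float, float, float]:
    """Shared and unique hull volumes of two point clouds, by rejection sampling.

    Returns ``(shared, only_a, only_b, se_union_fraction)`` where volumes
    are absolute and the last entry is the binomial standard error of the
    shared-given-union fraction that drives beta_jac.
    """
    hull_a = _hull(np.asarray(points_a, float), labels[0])
    hull_b = _hull(np.asarray(points_b, float), labels[1])
    lo = np.minimum(points_a.min(axis=0), points_b.min(axis=0))
    hi = np.maximum(points_a.max(axis=0), points_b.max(axis=0))
    box_vol = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(int(n_samples), len(lo)))
    in_a = _inside(hull_a, pts)
    in_b = _inside(hull_b, pts)
    n_union = int((in_a | in_b).sum())
    n_shared = int((in_a & in_b).sum())
    if n_union == 0:
        raise DegenerateHullError("no samples fell inside either hull")
    a = box_vol * n_shared / len(pts)
    b = box_vol * int((in_a & ~in_b).sum()) / len(pts)
    c = box_vol * int((~in_a & in_b).sum()) / len(pts)
    p = n_shared / n_union
    se = float(np.sqrt(p * (1 - p) / n_union))
    return a, b, c, se


def functional_beta(
    space: FunctionalSpace,
    regions: dict[str, set],
    n_samples: int = 100_000,
    seed: int = 0,
) -> list[BetaResult]:
    """Hull-overlap analogue of the Jaccard partition between regional FE sets.

    Each region is represented by the convex hull of its members' points
    in the functional space. Regions with identical member sets share the
    hull exactly and get all components 0 without sampling.
    """
    if len(regions) < 2:
        raise ValidationError("functional_beta requires at least 2 regions")
    out = []
    for i, (ra, rb) in enumerate(itertools.combinations(sorted(regions), 2)):
        ids_a, ids_b = set(regions[ra]), set(regions[rb])
        if ids_a == ids_b:
            out.append(BetaResult((ra, rb), 0.0, 0.0, 0.0, "functional", 0.0))
            continue
        pa = space.points(sorted(ids_a))
        pb = space.points(sorted(ids_b))
        a, b, c, se = hull_overlap_volumes(
            pa, pb, n_samples=n_samples, seed=seed + i, labels=(ra, rb)
        )
        res = jaccard_partition(a, b, c, pair=(ra, rb), mode="functional")
        out.append(dataclasses.replace(res, se=se))
    return out


def beta_frame(results: list[BetaResult]) -> pd.DataFrame:
    """Tidy frame of beta-diversity results (one row per pair)."""
    rows = [
        {
            "region_a": r.pair[0],
            "region_b": r.pair[1],
            "mode": r.mode,
            "beta_jac": r.beta_jac,
            "beta_jtu": r.beta_jtu,
            "beta_jne": r.beta_jne,
            "se": np.nan if r.se is None else r.se,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
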