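"""Per-FE functional redundancy indices within a region.

Three complementary indices describe how buffered a functional entity is
against species loss in a given region:

- ``FR_S``: number of member species observed in the region;
- ``FR_ab``: summed mean abundance (individuals per standard transect
  area) of the member species;
- ``FR_Shannon``: equivalent number of species, exp(H) with H the Shannon
  entropy of the member species' abundance proportions. It ranges from 1
  (a single effective species) to FR_S (all members equally abundant) and
  obeys Hill's doubling property.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclasses.dataclass
class CommunityMatrix:
    """Transect x species abundance counts for one region.

    ``counts`` is indexed by transect_id with one integer column per
    species; ``area_m2`` is the sampled area of every transect (a single
    common value per matrix).
    """

    region_id: str
    counts: pd.DataFrame
    area_m2: float

    def __post_init__(self):
        if self.area_m2 <= 0:
            raise ValidationError(f"area_m2 must be positive, got {self.area_m2}")
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate species columns in community matrix")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("abundance counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("abundance counts must be integers")

    @property
    def n_transects(self) -> int:
        return len(self.counts)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)


def aggregate_transects(
    cm: CommunityMatrix, target_area: float, seed: int = 0
) -> CommunityMatrix:
    """Randomly group transects so each pooled unit covers ``target_area``.

    Surveys recorded at a smaller per-transect area are made comparable
    across regions by summing counts over random disjoint groups of
    k = target_area / area transects. Transects already at the target
    area are returned unchanged. A leftover transect that cannot complete
    a group is dropped with a warning; with an exact multiple the total
    individual count is conserved.
    """
    if target_area <= 0:
        raise ValidationError(f"target_area must be positive, got {target_area}")
    ratio = target_area / cm.area_m2
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValidationError(
            f"transect area {cm.area_m2} m2 does not divide target {target_area} m2"
        )
    if k == 1:
        return cm
    rng = np.random.default_rng(seed)
    order = rng.permutation(cm.n_transects)
    n_groups, leftover = divmod(cm.n_transects, k)
    if leftover:
        warnings.warn(
            f"region '{cm.region_id}': dropping {leftover} leftover transect(s) "
            f"when aggregating {cm.n_transects} x {cm.area_m2} m2 into {target_area} m2 units",
            stacklevel=2,
        )
    if n_groups == 0:
        raise ValidationError(
            f"region '{cm.region_id}': fewer than {k} transects to aggregate"
        )
    rows = []
    index = []
    arr = cm.counts.to_numpy()
    for g in range(n_groups):
        members = order[g * k : (g + 1) * k]
        rows.append(arr[members].sum(axis=0))
        index.append(f"{cm.region_id}_agg{g + 1}")
    pooled = pd.DataFrame(rows, index=pd.Index(index, name="transect_id"),
                          columns=cm.counts.columns)
    return CommunityMatrix(region_id=cm.region_id, counts=pooled, area_m2=target_area)


def mean_abundance(cm: CommunityMatrix) -> pd.Series:
    """Per-species mean count per transect area, zeros included.

    The mean is taken over all N transects of the region, so species
    absent from some transects are averaged over the full survey effort.
    """
    if cm.n_transects < 1:
        raise ValidationError("community matrix has no transects")
    means = cm.counts.mean(axis=0)
    means.name = "mean_abundance"
    return means


def fr_ab(means: pd.Series, members: dict[str, list[str]]) -> pd.Series:
    """Summed mean abundance per FE (abundance-based redundancy)."""
    out = {}
    for fe, sps in members.items():
        missing = [s for s in sps if s not in means.index]
        if missing:
            raise ValidationError(
                f"FE '{fe}': species missing from abundance means: {missing[:5]}"
            )
        out[fe] = float(means[sps].sum())
    s = pd.Series(out, name="FR_ab")
    s.index.name = "fe_id"
    return s.sort_index()


def fr_shannon(member_means) -> float:
    """Equivalent number of species from member abundance proportions.

    p_i = mean_i / sum(means) over members with positive mean; zero-mean
    members are excluded from the entropy sum (0 ln 0 := 0). Returns
    exp(-sum p_i ln p_i), in [1, number of positive members].
    """
    m = np.asarray(member_means, float)
    if (m < 0).any():
        raise ValidationError("abundance means must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValidationError("fr_shannon requires at least one positive mean")
    p = m[m > 0] / total
    p = p[p > 0]  # proportions that underflow to 0 carry no entropy (0 ln 0 := 0)
    h = float(-(p * np.log(p)).sum())
    return float(np.exp(h))


def redundancy_profile(
    cm: CommunityMatrix, members: dict[str, list[str]]
) -> pd.DataFrame:
    """All three redundancy indices for every FE, for one region.

    FEs whose member species were never observed in the region keep
    FR_S = 0 and NaN Shannon redundancy; they are flagged absent so the
    vulnerability ranking can exclude them rather than treat missing
    functions as redundant.
    """
    means = mean_abundance(cm)
    rows = []
    for fe, sps in sorted(members.items()):
        m = np.array([means.get(s, 0.0) for s in sps], float)
        present = m > 0
        fr_s = int(present.sum())
        row = {
            "fe_id": fe,
            "FR_S": fr_s,
            "FR_ab": float(m.sum()),
            "FR_Shannon": fr_shannon(m[present]) if fr_s else np.nan,
            "present": fr_s > 0,
        }
        rows.append(row)
    out = pd.DataFrame(rows).set_index("fe_id")
    out.insert(0, "region_id", cm.region_id)
    return out
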