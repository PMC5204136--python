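"""Synthetic reef-fish communities with the structure the analysis assumes.

The generator emulates the statistical shape of an Indo-Pacific outer-reef
fish survey: a few hundred species collapsing onto far fewer functional
entities, with most entities holding a single species (right-skewed,
power-law-like species-per-FE multiplicities), right-skewed abundances,
and fishing-sensitivity scores that rise with body size but are
independent of how many species share an entity. It exists so that every
downstream stage can be exercised end-to-end without survey data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .entities import TRAIT_CATEGORIES, TRAIT_COLUMNS
from .errors import ValidationError
from .redundancy import CommunityMatrix

#: Hard cap on species per functional entity; the most packed entities
#: observed on unfished reefs hold on this order of 15-17 species.
MAX_FE_SIZE = 17


@dataclasses.dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic community generator.

    Defaults describe the survey regime the pipeline targets: ~400
    species over 3 regions of 500 m2 transects, with >60% of functional
    entities holding a single species and log-normal species abundances.
    """

    n_species: int = 400
    n_regions: int = 3
    n_transects_per_region: int = 20
    transect_area_m2: float = 500.0
    packing: float = 1.0  # fraction of MAX_FE_SIZE usable as largest FE
    singleton_target: float = 0.62  # desired fraction of single-species FEs
    abundance_dispersion: float = 1.2  # log-normal sigma of species mean abundance
    mean_abundance: float = 8.0  # median individuals per transect for a typical species
    region_occupancy: float = 0.45  # probability a species occurs in a given region
    sensitivity_range: tuple[float, float] = (0.0, 100.0)
    seed: int = 0

    def __post_init__(self):
        def _positive_int(name):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise ValidationError(f"{name} must be a positive integer, got {v!r}")

        for f in ("n_species", "n_regions", "n_transects_per_region"):
            _positive_int(f)
        if self.transect_area_m2 <= 0:
            raise ValidationError(
                f"transect_area_m2 must be positive, got {self.transect_area_m2}"
            )
        if not 0 < self.packing <= 1:
            raise ValidationError(f"packing must be in (0, 1], got {self.packing}")
        if not 0 < self.singleton_target < 1:
            raise ValidationError(
                f"singleton_target must be in (0, 1), got {self.singleton_target}"
            )
        if self.abundance_dispersion < 0:
            raise ValidationError(
                f"abundance_dispersion must be non-negative, got {self.abundance_dispersion}"
            )
        if self.mean_abundance <= 0:
            raise ValidationError(
                f"mean_abundance must be positive, got {self.mean_abundance}"
            )
        if not 0 < self.region_occupancy <= 1:
            raise ValidationError(
                f"region_occupancy must be in (0, 1], got {self.region_occupancy}"
            )
        lo, hi = self.sensitivity_range
        if not (0 <= lo <= hi <= 100):
            raise ValidationError(
                f"sensitivity_range must satisfy 0 <= lo <= hi <= 100, got {self.sensitivity_range}"
            )
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError(f"seed must be an integer, got {self.seed!r}")


def _rng(cfg: SynthConfig, stage: int) -> np.random.Generator:
    # per-stage substream: traits=0, abundances=1, sensitivity=2
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def _size_pmf(cfg: SynthConfig) -> np.ndarray:
    """Truncated power-law pmf over FE sizes 1..kmax with P(1) = singleton_target."""
    kmax = max(1, int(round(MAX_FE_SIZE * cfg.packing)))
    if kmax == 1:
        return np.array([1.0])
    k = np.arange(1, kmax + 1, dtype=float)

    def p1(s):
        return 1.0 / np.sum(k**-s) - cfg.singleton_target

    # P(1) ranges over (1/kmax, ~1) as the exponent grows
    lo, hi = 1e-6, 50.0
    if p1(lo) >= 0:  # target below the flat-distribution floor
        s = lo
    else:
        s = brentq(p1, lo, hi)
    pmf = k**-s
    return pmf / pmf.sum()


def generate_traits(cfg: SynthConfig) -> pd.DataFrame:
    """Species x trait table whose FE multiplicities follow a skewed law.

    Functional entities are drawn first: sizes come from a power law over
    1..17 species (exponent solved so the expected singleton fraction
    equals ``singleton_target``), each entity gets a distinct random
    trait combination, and member species inherit the entity's traits.
    """
    rng = _rng(cfg, 0)
    pmf = _size_pmf(cfg)
    sizes: list[int] = []
    remaining = cfg.n_species
    while remaining > 0:
        s = int(rng.choice(len(pmf), p=pmf)) + 1
        s = min(s, remaining)
        sizes.append(s)
        remaining -= s

    # distinct trait combinations, one per FE
    combos: set[tuple[int, ...]] = set()
    combo_list: list[tuple[int, ...]] = []
    n_combos = int(np.prod([len(TRAIT_CATEGORIES[c]) for c in TRAIT_COLUMNS]))
    if len(sizes) > n_combos:
        raise ValidationError(
            f"cannot place {len(sizes)} FEs into {n_combos} trait combinations"
        )
    while len(combo_list) < len(sizes):
        combo = tuple(
            int(rng.integers(len(TRAIT_CATEGORIES[c]))) for c in TRAIT_COLUMNS
        )
        if combo not in combos:
            combos.add(combo)
            combo_list.append(combo)

    rows = []
    sp = 0
    for fe_idx, (size, combo) in enumerate(zip(sizes, combo_list)):
        for _ in range(size):
            sp += 1
            rows.append(
                {
                    "species_id": f"sp{sp:04d}",
                    **{
                        col: TRAIT_CATEGORIES[col][code]
                        for col, code in zip(TRAIT_COLUMNS, combo)
                    },
                }
            )
    return pd.DataFrame(rows).set_index("species_id")


def generate_abundances(
    cfg: SynthConfig, traits: pd.DataFrame
) -> list[CommunityMatrix]:
    """One transect x species count matrix per region.

    Species i gets a latent mean abundance lambda_i from a log-normal
    (median ``mean_abundance``, log-sd ``abundance_dispersion``); counts
    on each transect where the species occurs are Poisson(lambda_i).
    Regional occupancy is Bernoulli per species and region, with every
    species forced into at least one region; a species whose sampled
    counts are all zero gets one sentinel individual so the pool and the
    surveys agree on the species list.
    """
    if traits.empty:
        raise ValidationError("trait table is empty")
    rng = _rng(cfg, 1)
    species = list(traits.index)
    n_sp = len(species)
    lam = cfg.mean_abundance * np.exp(
        rng.normal(0.0, cfg.abundance_dispersion, size=n_sp)
    )
    occ = rng.random((n_sp, cfg.n_regions)) < cfg.region_occupancy
    none = ~occ.any(axis=1)
    occ[none, rng.integers(cfg.n_regions, size=int(none.sum()))] = True

    matrices = []
    counts_by_region = []
    for r in range(cfg.n_regions):
        counts = rng.poisson(
            lam[None, :] * occ[None, :, r], size=(cfg.n_transects_per_region, n_sp)
        )
        counts_by_region.append(counts)
    total = sum(c.sum(axis=0) for c in counts_by_region)
    for i in np.flatnonzero(total == 0):
        r = int(np.flatnonzero(occ[i])[0])
        t = int(rng.integers(cfg.n_transects_per_region))
        counts_by_region[r][t, i] = 1

    for r, counts in enumerate(counts_by_region):
        region_id = f"region{r + 1}"
        frame = pd.DataFrame(
            counts,
            index=pd.Index(
                [f"{region_id}_t{t + 1}" for t in range(cfg.n_transects_per_region)],
                name="transect_id",
            ),
            columns=pd.Index(species, name="species_id"),
        )
        matrices.append(
            CommunityMatrix(region_id=region_id, counts=frame, area_m2=cfg.transect_area_m2)
        )
    return matrices


def generate_sensitivity(cfg: SynthConfig, traits: pd.DataFrame) -> pd.Series:
    """Per-species sensitivity-to-fishing scores on the 0-100 scale.

    Expected score rises linearly with body-size class (larger species
    are more sensitive to fishing), with Gaussian noise, clipped to
    ``sensitivity_range``. Because trait combinations are assigned to
    entities independently of entity size, scores are independent of FE
    species counts by construction.
    """
    if traits.empty:
        raise ValidationError("trait table is empty")
    rng = _rng(cfg, 2)
    lo, hi = cfg.sensitivity_range
    span = hi - lo
    size_cats = TRAIT_CATEGORIES["size_class"]
    k = traits["size_class"].map({c: i for i, c in enumerate(size_cats)}).to_numpy()
    mean = lo + span * (0.15 + 0.6 * k / (len(size_cats) - 1))
    noise = rng.normal(0.0, 0.15 * span, size=len(traits))
    scores = np.clip(mean + noise, lo, hi)
    s = pd.Series(scores, index=traits.index, name="sensitivity")
    s.index.name = "species_id"
    return s


@dataclasses.dataclass(frozen=True)
class SyntheticDataset:
    traits: pd.DataFrame
    communities: list[CommunityMatrix]
    sensitivity: pd.Series


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Traits, regional abundance matrices and sensitivity scores in one call."""
    traits = generate_traits(cfg)
    return SyntheticDataset(
        traits=traits,
        communities=generate_abundances(cfg, traits),
        sensitivity=generate_sensitivity(cfg, traits),
    )


def write_dataset(data: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the three standard input files (traits, abundances, sensitivity).

    Abundance files use the long format (transect_id, species_id, count,
    area_m2) with zero counts omitted. Returns logical name -> path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    traits_path = outdir / "traits.csv"
    data.traits.to_csv(traits_path)
    paths["traits"] = traits_path
    for cm in data.communities:
        counts = cm.counts.copy()
        counts.columns.name = "species_id"
        long = counts.stack().rename("count").reset_index()
        long = long[long["count"] > 0].copy()
        long["area_m2"] = cm.area_m2
        p = outdir / f"abundance_{cm.region_id}.csv"
        long.to_csv(p, index=False)
        paths[f"abundance_{cm.region_id}"] = p
    sens_path = outdir / "sensitivity.csv"
    data.sensitivity.to_frame().to_csv(sens_path)
    paths["sensitivity"] = sens_path
    return paths
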