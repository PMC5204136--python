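"""Functional entities (FEs) from categorical trait tables.

A functional entity is a group of species sharing identical categories on
all six traits (maximum body size, diet, home range, water-column
position, activity period, schooling behaviour). Five traits are ordered;
diet is nominal. The FE is the unit at which redundancy and vulnerability
are assessed downstream.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Canonical category labels per trait, in rank order for ordered traits.
TRAIT_CATEGORIES: dict[str, tuple[str, ...]] = {
    "size_class": ("0-7", "7.1-15", "15.1-30", "30.1-50", "50.1-80", ">80"),
    "diet": (
        "herbivorous-detritivorous",
        "macroalgal-herbivorous",
        "sessile-invertivore",
        "mobile-invertivore",
        "planktivore",
        "piscivore",
        "omnivore",
    ),
    "home_range": ("sedentary", "mobile-within-reef", "mobile-between-reefs"),
    "position": ("benthic", "bentho-pelagic", "pelagic"),
    "activity": ("diurnal", "both", "nocturnal"),
    "schooling": ("solitary", "pairing", "small-3-20", "medium-20-50", "large-gt50"),
}

TRAIT_COLUMNS: tuple[str, ...] = tuple(TRAIT_CATEGORIES)

#: Ordered traits contribute range-normalised rank differences to Gower
#: distance; the nominal trait (diet) contributes simple matching.
ORDERED_TRAITS: tuple[str, ...] = (
    "size_class",
    "home_range",
    "position",
    "activity",
    "schooling",
)

_FE_CODE_PREFIX = {
    "size_class": "S",
    "diet": "D",
    "home_range": "H",
    "position": "P",
    "activity": "A",
    "schooling": "G",
}


def trait_codes(traits: pd.DataFrame) -> pd.DataFrame:
    """Integer category codes (1-based) for a validated trait table."""
    out = {}
    for col in TRAIT_COLUMNS:
        cats = TRAIT_CATEGORIES[col]
        out[col] = traits[col].map({c: i + 1 for i, c in enumerate(cats)})
    return pd.DataFrame(out, index=traits.index)


def validate_traits(traits: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a species x trait table.

    Accepts either canonical category strings or 1-based integer codes
    (both dialects may be mixed across columns, not within a cell).
    Returns a copy indexed by ``species_id`` with canonical string
    categories. Missing or unknown categories are rejected, never imputed.
    """
    df = traits.copy()
    if "species_id" in df.columns:
        df = df.set_index("species_id")
    if df.index.name != "species_id":
        df.index.name = "species_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicated species_id: {dupes}")
    missing_cols = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"missing trait columns: {missing_cols}")
    df = df[list(TRAIT_COLUMNS)]

    for col in TRAIT_COLUMNS:
        cats = TRAIT_CATEGORIES[col]
        mapping: dict[object, str] = {c: c for c in cats}
        # integer-code dialect: 1-based rank within the category set
        for i, c in enumerate(cats):
            mapping[i + 1] = c
            mapping[str(i + 1)] = c
        canon = df[col].map(mapping)
        bad = df.index[canon.isna()]
        if len(bad):
            sp = bad[0]
            raise ValidationError(
                f"species '{sp}': invalid category {df.loc[sp, col]!r} "
                f"for trait '{col}' (expected one of {list(cats)} or codes 1..{len(cats)})"
            )
        df[col] = canon
    return df


def entity_id(row: Mapping[str, str]) -> str:
    """Deterministic FE identifier from the six category codes.

    Built from 1-based integer codes (e.g. ``S2.D5.H1.P1.A1.G3``) so the
    identifier is stable across platforms and label spellings.
    """
    parts = []
    for col in TRAIT_COLUMNS:
        code = TRAIT_CATEGORIES[col].index(row[col]) + 1
        parts.append(f"{_FE_CODE_PREFIX[col]}{code}")
    return ".".join(parts)


def assign_entities(traits: pd.DataFrame) -> pd.Series:
    """Partition species into functional entities.

    Parameters
    ----------
    traits
        Species x trait table (validated or raw; validation is applied).

    Returns
    -------
    pandas.Series
        ``fe_id`` indexed by ``species_id``. The mapping is a partition:
        every species belongs to exactly one FE, and two species share an
        FE iff they share all six trait categories. Row order of the
        input is irrelevant to the FE identifiers.
    """
    df = validate_traits(traits)
    fe = df.apply(entity_id, axis=1)
    fe.name = "fe_id"
    return fe


def entity_members(entities: pd.Series) -> dict[str, list[str]]:
    """FE id -> sorted list of member species ids."""
    members: dict[str, list[str]] = {}
    for sp, fe in entities.items():
        members.setdefault(fe, []).append(sp)
    return {fe: sorted(sps) for fe, sps in sorted(members.items())}


def species_per_entity(entities: pd.Series) -> pd.DataFrame:
    """Histogram of species-count per FE.

    Returns a frame indexed by FE size (number of member species) with
    columns ``n_fe`` (how many FEs have that size) and ``pct_fe``
    (percentage of FEs). ``sum(size * n_fe)`` equals the number of
    species and ``pct_fe`` sums to 100.
    """
    sizes = entities.value_counts()
    hist = sizes.value_counts().sort_index()
    out = pd.DataFrame({"n_fe": hist})
    out.index.name = "fe_size"
    out["pct_fe"] = 100.0 * out["n_fe"] / out["n_fe"].sum()
    return out


def singleton_fraction(entities: pd.Series) -> float:
    """Fraction of FEs represented by exactly one species."""
    sizes = entities.value_counts()
    return float((sizes == 1).mean())
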