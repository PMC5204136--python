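"""Plain-CSV readers and writers for the pipeline's tabular interfaces."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import ValidationError
from .redundancy import CommunityMatrix


def read_traits(path: str | Path) -> pd.DataFrame:
    """Trait table CSV: species_id plus the six trait columns.

    Categories may be canonical strings or 1-based integer codes; both
    dialects are validated downstream by ``entities.validate_traits``.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"traits file not found: {path}")
    return pd.read_csv(path)


def read_sensitivity(path: str | Path) -> pd.Series:
    """Sensitivity CSV: species_id, sensitivity (0-100)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"sensitivity file not found: {path}")
    df = pd.read_csv(path)
    for col in ("species_id", "sensitivity"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column '{col}'")
    if df["species_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated species_id")
    s = df.set_index("species_id")["sensitivity"].astype(float)
    if ((s < 0) | (s > 100)).any():
        bad = s[(s < 0) | (s > 100)].index[:5].tolist()
        raise ValidationError(f"{path}: sensitivity outside [0, 100] for {bad}")
    return s


def read_abundance(path: str | Path, region_id: str | None = None) -> CommunityMatrix:
    """Abundance CSV for one region, long or wide dialect.

    Long: columns transect_id, species_id, count, area_m2 (zero counts
    may be omitted). Wide: transect_id, area_m2, then one column per
    species. The region id defaults to the file stem (minus an
    ``abundance_`` prefix).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"abundance file not found: {path}")
    if region_id is None:
        region_id = path.stem.removeprefix("abundance_")
    df = pd.read_csv(path)
    if "transect_id" not in df.columns or "area_m2" not in df.columns:
        raise ValidationError(f"{path}: needs 'transect_id' and 'area_m2' columns")
    areas = df["area_m2"].unique()
    if len(areas) != 1:
        raise ValidationError(f"{path}: transects must share one area, got {areas}")
    if {"species_id", "count"} <= set(df.columns):  # long dialect
        wide = (
            df.pivot_table(
                index="transect_id", columns="species_id", values="count",
                aggfunc="sum", fill_value=0,
            )
            .sort_index()
        )
    else:  # wide dialect
        wide = df.drop(columns=["area_m2"]).set_index("transect_id").sort_index()
    wide = wide.astype(int)
    return CommunityMatrix(region_id=region_id, counts=wide, area_m2=float(areas[0]))
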