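"""TOPSIS vulnerability ranking of functional entities.

An FE is vulnerable when its member species are sensitive to fishing and
the entity has little redundancy to absorb their loss. Sensitivity
(0-100, higher = more prone to decline under fishing) is a cost
criterion; the redundancy indices are benefit criteria. After min-max
normalisation of each criterion over the FE set, two reference points
are defined: the positive ideal solution A+ (minimum sensitivity,
maximum redundancy) and the negative ideal A- (maximum sensitivity,
minimum redundancy). Vulnerability is the relative distance

    V = d+ / (d+ + d-)

with d+/d- the Euclidean distances to A+/A- in normalised criteria
space, so V = 0 exactly at A+ and V = 1 exactly at A-.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Default criteria: sensitivity (cost) plus the Shannon-equivalent
#: redundancy, which already reflects both species counts and abundances.
DEFAULT_COST = ("sensitivity",)
DEFAULT_BENEFIT = ("FR_Shannon",)


def fe_sensitivity(members: dict[str, list[str]], scores: pd.Series) -> pd.Series:
    """Mean member-species sensitivity per FE, on the species' 0-100 scale."""
    out = {}
    for fe, sps in members.items():
        missing = [s for s in sps if s not in scores.index]
        if missing:
            raise ValidationError(
                f"FE '{fe}': species without a sensitivity score: {missing[:5]}"
            )
        out[fe] = float(scores[sps].mean())
    s = pd.Series(out, name="sensitivity")
    s.index.name = "fe_id"
    return s.sort_index()


def _minmax(col: np.ndarray) -> np.ndarray:
    lo, hi = col.min(), col.max()
    if hi - lo == 0:
        # constant criterion: carries no information, pin mid-scale so it
        # contributes symmetrically to d+ and d-
        return np.full_like(col, 0.5, dtype=float)
    return (col - lo) / (hi - lo)


def topsis_vulnerability(
    criteria: pd.DataFrame,
    cost: tuple[str, ...] = DEFAULT_COST,
    benefit: tuple[str, ...] = DEFAULT_BENEFIT,
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Vulnerability V in [0, 1] for every FE in a criteria matrix.

    Parameters
    ----------
    criteria
        FE-indexed frame holding every column named in ``cost`` and
        ``benefit`` (finite values).
    cost, benefit
        Criterion columns to minimise / maximise. Defaults: sensitivity
        as cost, FR_Shannon as benefit.
    weights
        Optional per-criterion weights (normalised internally); equal by
        default.

    Returns the input columns plus ``d_plus``, ``d_minus`` and ``V``,
    indexed like ``criteria``. Normalisation is min-max over the FE set
    handed in, so rankings are relative to the assemblage analysed.
    """
    cols = list(cost) + list(benefit)
    if len(criteria) < 2:
        raise ValidationError("TOPSIS requires at least 2 FEs")
    missing = [c for c in cols if c not in criteria.columns]
    if missing:
        raise ValidationError(f"criteria matrix lacks columns: {missing}")
    x = criteria[cols].to_numpy(float)
    if not np.isfinite(x).all():
        bad = criteria.index[~np.isfinite(x).all(axis=1)][:5].tolist()
        raise ValidationError(f"non-finite criteria for FEs: {bad}")

    norm = np.column_stack([_minmax(x[:, j]) for j in range(x.shape[1])])
    # ideal solutions in normalised space: best = 0 for cost, 1 for benefit
    a_plus = np.array([0.0] * len(cost) + [1.0] * len(benefit))
    a_minus = 1.0 - a_plus
    if weights is None:
        w = np.ones(len(cols))
    else:
        unknown = set(weights) - set(cols)
        if unknown:
            raise ValidationError(f"weights for unknown criteria: {sorted(unknown)}")
        w = np.array([weights.get(c, 1.0) for c in cols], float)
        if (w < 0).any() or w.sum() == 0:
            raise ValidationError("criterion weights must be non-negative, not all zero")
    w = w / w.sum()

    d_plus = np.sqrt(((norm - a_plus) ** 2 * w).sum(axis=1))
    d_minus = np.sqrt(((norm - a_minus) ** 2 * w).sum(axis=1))
    denom = d_plus + d_minus
    if (denom == 0).any():
        raise ValidationError(
            "d+ + d- = 0 for some FE (all criteria constant?); V is undefined"
        )
    out = criteria.copy()
    out["d_plus"] = d_plus
    out["d_minus"] = d_minus
    out["V"] = d_plus / denom
    return out


def rank_entities(results: pd.DataFrame) -> pd.DataFrame:
    """Order FEs by descending vulnerability, ties broken by fe_id.

    Adds a 1-based ``rank`` column; the ordering is deterministic and
    invariant to the input row order.
    """
    if "V" not in results.columns:
        raise ValidationError("results lack a 'V' column; run topsis_vulnerability first")
    out = results.copy()
    fe = out["fe_id"] if "fe_id" in out.columns else out.index.to_series()
    order = np.lexsort((fe.to_numpy(), -out["V"].to_numpy()))
    out = out.iloc[order]
    out["rank"] = np.arange(1, len(out) + 1)
    return out
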