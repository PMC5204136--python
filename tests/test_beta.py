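import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fvuln.beta import (
    functional_beta,
    hull_overlap_volumes,
    jaccard_partition,
    taxonomic_beta,
)
from fvuln.errors import DegenerateHullError, ValidationError
from fvuln.space import FunctionalSpace


@pytest.mark.parametrize(
    "a,b,c,expected",
    [
        (5, 0, 0, (0.0, 0.0, 0.0)),  # identical assemblages
        (0, 3, 4, (1.0, 1.0, 0.0)),  # disjoint: turnover at its maximum
        (2, 1, 3, (4 / 6, 1 / 2, 4 / 6 - 1 / 2)),
    ],
)
def test_jaccard_partition_known_triples(a, b, c, expected):
    res = jaccard_partition(a, b, c)
    assert res.beta_jac == pytest.approx(expected[0])
    assert res.beta_jtu == pytest.approx(expected[1])
    assert res.beta_jne == pytest.approx(expected[2])


def test_jaccard_partition_undefined_for_empty_triple():
    with pytest.raises(ValidationError, match="undefined"):
        jaccard_partition(0, 0, 0)


@settings(derandomize=True, max_examples=300)
@given(
    a=st.integers(min_value=0, max_value=500),
    b=st.integers(min_value=0, max_value=500),
    c=st.integers(min_value=0, max_value=500),
)
def test_jaccard_partition_additive_symmetric_bounded(a, b, c):
    if a + b + c == 0:
        return
    res = jaccard_partition(a, b, c)
    assert abs(res.beta_jac - (res.beta_jtu + res.beta_jne)) < 1e-12
    swapped = jaccard_partition(a, c, b)
    assert swapped.beta_jac == pytest.approx(res.beta_jac)
    assert swapped.beta_jtu == pytest.approx(res.beta_jtu)
    for v in (res.beta_jac, res.beta_jtu, res.beta_jne):
        assert -1e-12 <= v <= 1 + 1e-12


def test_taxonomic_beta_identical_regions_zero():
    res = taxonomic_beta({"A": {"x", "y"}, "B": {"x", "y"}})
    assert res[0].beta_jac == 0.0


def test_taxonomic_beta_three_regions_three_pairs():
    res = taxonomic_beta({"A": {"x"}, "B": {"y"}, "C": {"x", "y"}})
    assert len(res) == 3
    assert all(r.mode == "taxonomic" for r in res)


def test_taxonomic_beta_low_sharing_gives_high_dissimilarity():
    # two regions sharing ~13% of a 200-species pool
    pool = [f"s{i}" for i in range(200)]
    shared = set(pool[:26])
    a = shared | set(pool[26:110])
    b = shared | set(pool[110:])
    res = taxonomic_beta({"A": a, "B": b})[0]
    assert res.beta_jac > 0.6


def test_taxonomic_beta_rejects_empty_region():
    with pytest.raises(ValidationError, match="empty"):
        taxonomic_beta({"A": {"x"}, "B": set()})


def _space(points_by_id):
    ids = list(points_by_id)
    pts = np.array([points_by_id[i] for i in ids], float)
    frame = pd.DataFrame(pts, index=ids, columns=[f"PC{j+1}" for j in range(pts.shape[1])])
    return FunctionalSpace(coordinates=frame, eigenvalues=np.ones(pts.shape[1]))


def test_functional_beta_identical_sets_all_zero():
    corners = list(itertools.product([0.0, 1.0], repeat=4))
    space = _space({f"fe{i}": c for i, c in enumerate(corners)})
    ids = set(space.coordinates.index)
    res = functional_beta(space, {"A": ids, "B": ids})[0]
    assert (res.beta_jac, res.beta_jtu, res.beta_jne) == (0.0, 0.0, 0.0)


def test_functional_beta_nested_hulls_pure_nestedness():
    outer = {f"o{i}": c for i, c in enumerate(itertools.product([0.0, 1.0], repeat=4))}
    inner = {
        f"i{i}": tuple(0.25 + 0.5 * x for x in c)
        for i, c in enumerate(itertools.product([0.0, 1.0], repeat=4))
    }
    space = _space({**outer, **inner})
    res = functional_beta(
        space, {"IN": set(inner), "OUT": set(outer)}, n_samples=50_000, seed=4
    )[0]
    assert res.beta_jtu == 0.0
    assert res.beta_jne == pytest.approx(res.beta_jac)
    assert res.beta_jac > 0


def test_hull_overlap_half_shifted_hypercubes_match_exact_values():
    """Two unit 4-D hypercubes offset by half an edge share half their volume:
    a = b = c = 0.5 exactly, so beta_jac = beta_jtu = 2/3 and beta_jne = 0."""
    cube = np.array(list(itertools.product([0.0, 1.0], repeat=4)))
    shifted = cube + np.array([0.5, 0, 0, 0])
    a, b, c, se = hull_overlap_volumes(cube, shifted, n_samples=200_000, seed=9)
    assert a == pytest.approx(0.5, abs=0.02)
    assert b == pytest.approx(0.5, abs=0.02)
    assert c == pytest.approx(0.5, abs=0.02)
    res = jaccard_partition(a, b, c, mode="functional")
    assert res.beta_jac == pytest.approx(2 / 3, abs=0.02)
    assert res.beta_jtu == pytest.approx(2 / 3, abs=0.02)
    assert res.beta_jne == pytest.approx(0.0, abs=0.02)


def test_functional_beta_names_degenerate_region():
    pts = {f"fe{i}": (float(i), 0.0, 0.0, 0.0) for i in range(6)}  # collinear
    space = _space(pts)
    with pytest.raises(DegenerateHullError, match="A"):
        functional_beta(space, {"A": set(pts), "B": set(pts) - {"fe0"}})
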