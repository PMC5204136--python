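import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from fvuln.entities import TRAIT_CATEGORIES
from fvuln.errors import DegenerateHullError, ValidationError
from fvuln.space import FunctionalSpace, fric, gower_distance, hull_volume, pcoa
from fvuln.synthetic import SynthConfig, generate_traits

from conftest import mc_hull_volume


def _traits(rows):
    cols = ["size_class", "diet", "home_range", "position", "activity", "schooling"]
    df = pd.DataFrame(rows, columns=["species_id"] + cols).set_index("species_id")
    return df


def test_gower_identical_and_maximal_pairs():
    rows = [
        ("a", "0-7", "planktivore", "sedentary", "benthic", "diurnal", "solitary"),
        ("b", "0-7", "planktivore", "sedentary", "benthic", "diurnal", "solitary"),
        # opposite extreme of every ordered trait, different diet
        ("c", ">80", "piscivore", "mobile-between-reefs", "pelagic", "nocturnal", "large-gt50"),
    ]
    d = gower_distance(_traits(rows))
    assert d["a", "b"] == 0.0
    assert d["a", "c"] == pytest.approx(1.0)


def test_gower_single_trait_difference_weights_one_sixth():
    rows = [
        ("a", "0-7", "planktivore", "sedentary", "benthic", "diurnal", "solitary"),
        ("b", ">80", "planktivore", "sedentary", "benthic", "diurnal", "solitary"),
    ]
    d = gower_distance(_traits(rows))
    assert d["a", "b"] == pytest.approx(1 / 6)


def test_gower_range_and_symmetry(dataset):
    d = gower_distance(dataset.traits).data
    assert d.min() >= 0 and d.max() <= 1
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0)


def test_gower_triangle_inequality_on_random_triples(dataset):
    d = gower_distance(dataset.traits).data
    rng = np.random.default_rng(0)
    n = d.shape[0]
    for _ in range(300):
        i, j, k = rng.choice(n, size=3, replace=False)
        assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def test_gower_requires_two_species(small_traits):
    with pytest.raises(ValidationError):
        gower_distance(small_traits.iloc[[0]])


def test_pcoa_recovers_euclidean_configuration():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(12, 4))
    dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"p{i}" for i in range(12)])
    sp = pcoa(dm, n_axes=4)
    rec = squareform(pdist(sp.coordinates.to_numpy()))
    assert np.allclose(rec, dm.data, atol=1e-8)
    assert np.allclose(sp.coordinates.mean(axis=0), 0, atol=1e-9)
    assert np.all(np.diff(sp.eigenvalues) <= 1e-9)


def test_pcoa_duplicated_points_coincide():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(8, 4))
    pts[3] = pts[0]
    dm = DistanceMatrix(squareform(pdist(pts)), ids=[f"p{i}" for i in range(8)])
    sp = pcoa(dm)
    coords = sp.coordinates.to_numpy()
    assert np.allclose(coords[3], coords[0], atol=1e-8)


def test_pcoa_rejects_degenerate_inputs():
    ids = list("abcd")
    with pytest.raises(ValidationError, match="at least 5"):
        pcoa(DistanceMatrix(1 - np.eye(4), ids=ids))
    with pytest.raises(ValidationError, match="zero"):
        pcoa(DistanceMatrix(np.zeros((6, 6)), ids=list("abcdef")))


def test_pcoa_on_gower_matrix_gives_positive_decreasing_axes(dataset):
    sp = pcoa(gower_distance(dataset.traits), n_axes=4)
    eig = sp.eigenvalues
    assert len(eig) == 4
    assert np.all(eig > 0)
    assert np.all(np.diff(eig) <= 0)


def test_pcoa_lingoes_correction_removes_negative_eigenvalues(dataset):
    dm = gower_distance(dataset.traits)
    sp = pcoa(dm, negative_policy="correct")
    assert sp.corrected
    assert np.all(sp.eigenvalues > 0)


def _space_from_points(pts):
    ids = [f"p{i}" for i in range(len(pts))]
    frame = pd.DataFrame(pts, index=ids, columns=[f"PC{j+1}" for j in range(pts.shape[1])])
    return FunctionalSpace(coordinates=frame, eigenvalues=np.ones(pts.shape[1])), ids


def test_fric_identity_and_interior_point_removal():
    # 4-D hypercube corners plus one interior point
    corners = np.array(list(itertools.product([0.0, 1.0], repeat=4)))
    pts = np.vstack([corners, [[0.5, 0.5, 0.5, 0.5]]])
    space, ids = _space_from_points(pts)
    full = fric(space, ids, ids)
    assert full.ratio == pytest.approx(1.0)
    assert full.global_volume == pytest.approx(1.0)
    no_interior = fric(space, ids[:-1], ids)
    assert no_interior.ratio == pytest.approx(1.0)


def test_fric_monotone_in_members():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(30, 4))
    space, ids = _space_from_points(pts)
    vols = [
        fric(space, ids[:k], ids).hull_volume for k in (10, 15, 20, 30)
    ]
    assert all(a <= b + 1e-12 for a, b in zip(vols, vols[1:]))


def test_fric_rejects_region_outside_pool():
    pts = np.random.default_rng(0).normal(size=(10, 4))
    space, ids = _space_from_points(pts)
    with pytest.raises(ValidationError, match="not in global pool"):
        fric(space, ["zzz"], ids[:8])


def test_hull_volume_matches_monte_carlo_oracle():
    rng = np.random.default_rng(11)
    for trial in range(5):
        pts = rng.normal(size=(25, 4))
        exact = hull_volume(pts)
        est, se = mc_hull_volume(pts, n_samples=150_000, seed=trial)
        assert abs(exact - est) <= 3 * se


def test_degenerate_hull_raises():
    pts = np.zeros((8, 4))
    pts[:, 0] = np.arange(8)  # collinear in 4-D
    with pytest.raises(DegenerateHullError):
        hull_volume(pts)
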