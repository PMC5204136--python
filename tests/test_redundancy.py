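import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fvuln.errors import ValidationError
from fvuln.redundancy import (
    CommunityMatrix,
    aggregate_transects,
    fr_ab,
    fr_shannon,
    mean_abundance,
    redundancy_profile,
)


def _cm(counts, area=500.0, region="R"):
    frame = pd.DataFrame(
        counts,
        index=pd.Index([f"t{i}" for i in range(len(counts))], name="transect_id"),
        columns=pd.Index([f"s{j}" for j in range(len(counts[0]))], name="species_id"),
    )
    return CommunityMatrix(region_id=region, counts=frame, area_m2=area)


def test_community_matrix_validation():
    with pytest.raises(ValidationError, match="non-negative"):
        _cm([[1, -1]])
    with pytest.raises(ValidationError, match="positive"):
        _cm([[1, 2]], area=0)


def test_aggregate_two_250m2_transects_into_500m2():
    cm = _cm([[1, 0], [2, 3], [4, 5], [0, 7]], area=250.0)
    agg = aggregate_transects(cm, 500.0, seed=0)
    assert agg.n_transects == 2
    assert agg.area_m2 == 500.0
    # total individuals conserved with an even transect count
    assert agg.counts.sum().sum() == cm.counts.sum().sum()
    assert (agg.counts.sum(axis=0) == cm.counts.sum(axis=0)).all()


def test_aggregate_identity_at_target_area():
    cm = _cm([[1, 2], [3, 4]])
    assert aggregate_transects(cm, 500.0, seed=1) is cm


def test_aggregate_seeded_pairing_is_reproducible():
    cm = _cm([[i, i + 1] for i in range(8)], area=250.0)
    a1 = aggregate_transects(cm, 500.0, seed=5)
    a2 = aggregate_transects(cm, 500.0, seed=5)
    assert a1.counts.equals(a2.counts)


def test_aggregate_drops_odd_leftover_with_warning():
    cm = _cm([[1, 1], [2, 2], [3, 3]], area=250.0)
    with pytest.warns(UserWarning, match="leftover"):
        agg = aggregate_transects(cm, 500.0, seed=0)
    assert agg.n_transects == 1


def test_aggregate_rejects_non_dividing_area():
    cm = _cm([[1]], area=300.0)
    with pytest.raises(ValidationError, match="divide"):
        aggregate_transects(cm, 500.0)


def test_mean_abundance_over_all_transects_including_zeros():
    cm = _cm([[0, 3], [10, 4], [0, 5]])
    means = mean_abundance(cm)
    assert means["s0"] == pytest.approx(10 / 3)
    assert means["s1"] == pytest.approx(4.0)
    absent = _cm([[0], [0]])
    assert mean_abundance(absent)["s0"] == 0.0


def test_fr_ab_sums_member_means():
    means = pd.Series({"s0": 3.0, "s1": 5.0, "s2": 2.0})
    out = fr_ab(means, {"FE1": ["s0", "s1"], "FE2": ["s2"]})
    assert out["FE1"] == 8.0
    assert out["FE2"] == 2.0
    with pytest.raises(ValidationError, match="missing"):
        fr_ab(means, {"FE1": ["s0", "zzz"]})


@pytest.mark.parametrize(
    "means,expected",
    [
        ([7.0], 1.0),  # singleton
        ([2.0, 2.0, 2.0, 2.0], 4.0),  # equal proportions: maximum entropy
        ([8.0, 2.0], np.exp(-(0.8 * np.log(0.8) + 0.2 * np.log(0.2)))),
    ],
)
def test_fr_shannon_equivalent_species(means, expected):
    assert fr_shannon(means) == pytest.approx(expected)
    # hand-computed reference for the (8, 2) split
    if means == [8.0, 2.0]:
        assert fr_shannon(means) == pytest.approx(1.6494, abs=1e-4)


def test_fr_shannon_hill_doubling():
    means = [5.0, 1.0, 3.0]
    doubled = means + means  # disjoint equal-abundance copy
    assert fr_shannon(doubled) == pytest.approx(2 * fr_shannon(means))


def test_fr_shannon_requires_positive_mass():
    with pytest.raises(ValidationError):
        fr_shannon([0.0, 0.0])


@settings(derandomize=True, max_examples=200)
@given(
    means=st.lists(
        st.floats(min_value=0.0, max_value=1e4, allow_nan=False), min_size=1, max_size=12
    )
)
def test_fr_shannon_bounded_by_species_count_and_scale_free(means):
    positive = [m for m in means if m > 0]
    if not positive:
        return
    val = fr_shannon(means)
    assert 1 - 1e-9 <= val <= len(positive) + 1e-9
    assert fr_shannon([3.7 * m for m in means]) == pytest.approx(val)


def test_redundancy_profile_flags_absent_entities():
    cm = _cm([[2, 0, 0], [4, 0, 0]])
    members = {"FE1": ["s0", "s1"], "FE2": ["s2"]}
    prof = redundancy_profile(cm, members)
    assert prof.loc["FE1", "FR_S"] == 1  # s1 never observed
    assert prof.loc["FE1", "FR_ab"] == pytest.approx(3.0)
    assert prof.loc["FE1", "FR_Shannon"] == pytest.approx(1.0)
    assert not prof.loc["FE2", "present"]
    assert prof.loc["FE2", "FR_S"] == 0
    assert np.isnan(prof.loc["FE2", "FR_Shannon"])
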