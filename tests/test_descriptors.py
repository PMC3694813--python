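"""Flexibility descriptor, B-factor extraction, normalization, agreement."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecdyn
from ecdyn import ECDError
from ecdyn.descriptors import BFactorProfile, FlexibilityProfile, segment_flexibility

from conftest import make_structure


def profile_from(values, start_resid=1):
    values = np.asarray(values, dtype=float)
    residues = [("A", start_resid + i, "ALA") for i in range(len(values))]
    return FlexibilityProfile(residues, values, np.zeros_like(values), 1, len(values))


# ---------------------------------------------------------------------------
# Flexibility descriptor identities
# ---------------------------------------------------------------------------

def test_flexibility_is_zero_for_coincident_images():
    images = np.tile([0.3, 0.1, 0.7], (6, 1))
    np.testing.assert_allclose(segment_flexibility(images), 0.0, atol=1e-14)


@given(st.integers(0, 1000))
def test_two_point_flexibility_is_half_the_pair_distance(seed):
    rng = np.random.default_rng(seed)
    images = rng.uniform(0, 1, size=(2, 4))
    pair = np.linalg.norm(images[0] - images[1])
    np.testing.assert_allclose(segment_flexibility(images), pair / 2, atol=1e-12)


def test_across_segment_sd_zero_for_replicated_segments():
    rng = np.random.default_rng(2)
    seg = rng.normal(scale=0.5, size=(12, 5, 3)) + rng.uniform(-4, 4, size=(1, 5, 3))
    coords = np.concatenate([seg] * 4, axis=0)
    atoms = [ecdyn.AtomRecord("A", i + 1, "ALA", "CA", "C", None) for i in range(5)]
    traj = ecdyn.Trajectory(coords, atoms)
    ens = ecdyn.segment_trajectory(traj, 4, 12, take="all")
    profile = ecdyn.flexibility_profile(ens, ecdyn.select_atoms(traj, "all"))
    np.testing.assert_allclose(profile.sd_flex, 0.0, atol=1e-12)
    assert profile.n_segments == 4


def test_single_segment_reports_zero_sd_with_warning(caplog):
    rng = np.random.default_rng(3)
    coords = rng.normal(size=(10, 4, 3))
    atoms = [ecdyn.AtomRecord("A", i + 1, "ALA", "CA", "C", None) for i in range(4)]
    traj = ecdyn.Trajectory(coords, atoms)
    ens = ecdyn.segment_trajectory(traj, 1, 10)
    with caplog.at_level("WARNING"):
        profile = ecdyn.flexibility_profile(ens, ecdyn.select_atoms(traj, "all"))
    np.testing.assert_array_equal(profile.sd_flex, 0.0)
    assert any("single segment" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# B-factor extraction
# ---------------------------------------------------------------------------

@pytest.fixture
def bfactor_structure():
    rows = []
    for r in range(3):
        for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            rows.append(("A", r + 1, name, element, 10.0 * (r + 1) + {"N": 0, "CA": 1, "C": 2, "O": 9}[name]))
    chains, resids, names, elements, bfac = zip(*rows)
    coords = np.arange(len(rows) * 3, dtype=float).reshape(-1, 3)
    return make_structure(coords, chains, resids, names, elements, bfactors=bfac)


def test_extract_bfactors_ca_only(bfactor_structure):
    profile = ecdyn.extract_bfactors(bfactor_structure, "CA-only")
    np.testing.assert_allclose(profile.values, [11.0, 21.0, 31.0])
    assert profile.residues == [("A", 1), ("A", 2), ("A", 3)]


def test_extract_bfactors_backbone_mean(bfactor_structure):
    profile = ecdyn.extract_bfactors(bfactor_structure, "backbone-mean")
    np.testing.assert_allclose(profile.values, [11.0, 21.0, 31.0])  # mean of r+0, r+1, r+2


def test_extract_bfactors_requires_values():
    structure = make_structure(
        np.zeros((1, 3)), ["A"], [1], ["CA"], ["C"], bfactors=[None]
    )
    with pytest.raises(ECDError, match="missing B-factor"):
        ecdyn.extract_bfactors(structure)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def ref_profile(values, start_resid=1):
    values = np.asarray(values, dtype=float)
    return BFactorProfile([("A", start_resid + i) for i in range(len(values))], values, "CA-only")


def test_minmax_normalization_maps_onto_reference_range():
    profile = profile_from([0.0, 0.5, 1.0, 0.25])
    ref = ref_profile([10.0, 30.0, 20.0, 12.0])
    out = ecdyn.normalize_profile(profile, ref, method="minmax")
    assert out.mean_flex.min() == pytest.approx(10.0)
    assert out.mean_flex.max() == pytest.approx(30.0)


@given(scale=st.floats(0.1, 50.0), offset=st.floats(0.0, 100.0))
def test_normalization_is_affine_invariant(scale, offset):
    base = np.array([0.2, 0.9, 0.4, 0.7, 0.1])
    ref = ref_profile([5.0, 9.0, 7.0, 8.0, 6.0])
    out_a = ecdyn.normalize_profile(profile_from(base), ref, method="minmax")
    out_b = ecdyn.normalize_profile(profile_from(base * scale + offset), ref, method="minmax")
    np.testing.assert_allclose(out_a.mean_flex, out_b.mean_flex, atol=1e-8)
    out_az = ecdyn.normalize_profile(profile_from(base), ref, method="zscore")
    out_bz = ecdyn.normalize_profile(profile_from(base * scale + offset), ref, method="zscore")
    np.testing.assert_allclose(out_az.mean_flex, out_bz.mean_flex, atol=1e-8)


def test_zscore_normalization_matches_reference_moments():
    profile = profile_from([1.0, 2.0, 5.0, 4.0])
    ref = ref_profile([10.0, 40.0, 20.0, 30.0])
    out = ecdyn.normalize_profile(profile, ref, method="zscore")
    assert out.mean_flex.mean() == pytest.approx(25.0)
    assert out.mean_flex.std(ddof=0) == pytest.approx(np.std([10, 40, 20, 30]))


def test_normalization_restricted_to_common_residues_in_reference_order():
    profile = profile_from([0.0, 1.0, 2.0, 3.0], start_resid=1)  # resids 1..4
    ref = ref_profile([7.0, 5.0, 6.0], start_resid=2)  # resids 2..4
    out = ecdyn.normalize_profile(profile, ref)
    assert [r[1] for r in out.residues] == [2, 3, 4]
    assert out.mean_flex.min() == pytest.approx(5.0)
    assert out.mean_flex.max() == pytest.approx(7.0)


def test_constant_profile_rejected():
    with pytest.raises(ECDError, match="constant"):
        ecdyn.normalize_profile(profile_from([2.0, 2.0, 2.0]), ref_profile([1.0, 2.0, 3.0]))


def test_too_few_common_residues_rejected():
    with pytest.raises(ECDError, match="share only"):
        ecdyn.normalize_profile(profile_from([1.0, 2.0, 3.0]), ref_profile([1.0], start_resid=1))


# ---------------------------------------------------------------------------
# Agreement
# ---------------------------------------------------------------------------

def test_profile_agreement_is_one_for_identical_profiles():
    profile = profile_from([0.4, 0.2, 0.9, 0.5])
    result = ecdyn.profile_agreement(profile, profile)
    assert result["pearson"] == pytest.approx(1.0)
    assert result["spearman"] == pytest.approx(1.0)
    assert result["n_common"] == 4


def test_profile_agreement_mixes_profile_types():
    profile = profile_from([1.0, 2.0, 3.0])
    ref = ref_profile([10.0, 20.0, 30.0])
    result = ecdyn.profile_agreement(profile, ref)
    assert result["pearson"] == pytest.approx(1.0)


def test_profile_tsv_round_trip(tmp_path):
    import pandas as pd

    profile = profile_from([0.4, 0.2, 0.9])
    path = tmp_path / "flex.tsv"
    profile.to_tsv(str(path))
    frame = pd.read_csv(path, sep="\t")
    np.testing.assert_allclose(frame["mean_flex"], profile.mean_flex, atol=1e-7)
    assert list(frame["resid"]) == [1, 2, 3]
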