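"""Essential-space eigendecomposition, atom images, correlation maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ecdyn
from ecdyn import ECDError
from ecdyn.core import CovarianceResult, atom_label, build_images


# ---------------------------------------------------------------------------
# Independent oracle: cyclic Jacobi eigensolver (no numpy.linalg involved)
# ---------------------------------------------------------------------------

def jacobi_eigh(matrix, sweeps=60, tol=1e-14):
    """Brute-force symmetric eigendecomposition via cyclic Jacobi rotations."""
    a = np.array(matrix, dtype=float)
    n = a.shape[0]
    vecs = np.eye(n)
    for _ in range(sweeps):
        off = np.sqrt(np.sum(np.tril(a, -1) ** 2))
        if off < tol:
            break
        for p in range(n - 1):
            for q in range(p + 1, n):
                if abs(a[p, q]) < tol:
                    continue
                theta = 0.5 * np.arctan2(2 * a[p, q], a[q, q] - a[p, p])
                c, s = np.cos(theta), np.sin(theta)
                rot = np.eye(n)
                rot[p, p] = rot[q, q] = c
                rot[p, q] = s
                rot[q, p] = -s
                a = rot.T @ a @ rot
                vecs = vecs @ rot
    order = np.argsort(-np.diag(a))
    return np.diag(a)[order], vecs[:, order]


def cov_result(matrix):
    dim = matrix.shape[0]
    return CovarianceResult(matrix, mean_structure=np.zeros(dim), n_frames_used=1)


def random_psd(dim, seed):
    rng = np.random.default_rng(seed)
    root = rng.normal(size=(dim, dim))
    return root @ root.T


@pytest.mark.parametrize("seed", range(5))
def test_essential_space_matches_jacobi_oracle(seed):
    matrix = random_psd(12, seed)
    space = ecdyn.essential_space(cov_result(matrix), fixed_m=12)
    values, vectors = jacobi_eigh(matrix)
    np.testing.assert_allclose(space.eigenvalues, values, atol=1e-8)
    # eigenvectors match up to sign
    for k in range(12):
        dot = abs(float(space.eigenvectors[:, k] @ vectors[:, k]))
        assert dot == pytest.approx(1.0, abs=1e-8)


def test_covariance_of_toy_trajectory_matches_jacobi_oracle():
    rng = np.random.default_rng(11)
    coords = rng.normal(scale=0.4, size=(60, 3, 3)) + np.array(
        [[0.0, 0, 0], [3, 0, 0], [6, 0, 0]]
    )
    traj = ecdyn.Trajectory(coords, [ecdyn.AtomRecord("A", i + 1, "ALA", "CA", "C", None) for i in range(3)])
    sel = ecdyn.select_atoms(traj, "all")
    cov = ecdyn.compute_covariance(traj, sel)
    values, _ = jacobi_eigh(cov.matrix)
    space = ecdyn.essential_space(cov, fixed_m=9)
    np.testing.assert_allclose(space.eigenvalues, values, atol=1e-8)


# ---------------------------------------------------------------------------
# Covariance contract
# ---------------------------------------------------------------------------

def test_covariance_is_symmetric_psd_and_matches_numpy_cov():
    rng = np.random.default_rng(5)
    coords = rng.normal(size=(200, 4, 3))
    traj = ecdyn.Trajectory(coords, [ecdyn.AtomRecord("A", i + 1, "ALA", "CA", "C", None) for i in range(4)])
    cov = ecdyn.compute_covariance(traj, ecdyn.select_atoms(traj, "all"))
    flat = coords.reshape(200, -1)
    expected = np.cov(flat.T, ddof=0)
    np.testing.assert_allclose(cov.matrix, expected, atol=1e-10)
    np.testing.assert_allclose(cov.matrix, cov.matrix.T)
    assert np.linalg.eigvalsh(cov.matrix)[0] >= -1e-10


def test_asymmetric_matrix_rejected():
    matrix = np.eye(6)
    matrix[0, 1] = 0.5
    with pytest.raises(ECDError, match="symmetric"):
        ecdyn.essential_space(cov_result(matrix))


# ---------------------------------------------------------------------------
# Images and m selection
# ---------------------------------------------------------------------------

def test_images_are_unsigned_block_norms():
    vecs = np.zeros((6, 2))
    vecs[:, 0] = [1, 0, 0, -1, 0, 0] / np.sqrt(2)
    vecs[:, 1] = [0, 0.6, 0, 0, 0, -0.8]
    images = build_images(vecs, m=2, weights=None)
    np.testing.assert_allclose(
        images, [[1 / np.sqrt(2), 0.6], [1 / np.sqrt(2), 0.8]], atol=1e-12
    )


def test_m_is_smallest_count_reaching_fraction():
    matrix = np.diag([4.0, 3.0, 2.0, 1.0, 0.0, 0.0])
    cov = cov_result(matrix)
    # cumulative fractions: 0.4, 0.7, 0.9, 1.0
    assert ecdyn.essential_space(cov, fraction=0.90).m == 3
    assert ecdyn.essential_space(cov, fraction=0.95).m == 4
    assert ecdyn.essential_space(cov, fraction=0.40).m == 1
    assert ecdyn.essential_space(cov, fixed_m=2).m == 2
    assert ecdyn.essential_space(cov, fraction=0.90).variance_fraction == pytest.approx(0.9)


def test_mode_weighting_scales_components():
    matrix = np.diag([4.0, 1.0, 0.0])
    cov = cov_result(matrix)
    plain = ecdyn.essential_space(cov, fixed_m=2)
    weighted = ecdyn.essential_space(cov, fixed_m=2, mode_weighting="sqrt_eigenvalue")
    np.testing.assert_allclose(weighted.images[:, 0], plain.images[:, 0])
    np.testing.assert_allclose(weighted.images[:, 1], 0.5 * plain.images[:, 1])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@given(seed=st.integers(0, 10_000))
def test_pair_distance_matches_matrix(seed):
    rng = np.random.default_rng(seed)
    matrix = random_psd(9, seed)
    space = ecdyn.essential_space(cov_result(matrix), fixed_m=4)
    dmat = ecdyn.image_distance_matrix(space)
    i, j = rng.integers(0, 3, size=2)
    assert ecdyn.pair_distance(space, int(i), int(j)) == pytest.approx(dmat[i, j])


# ---------------------------------------------------------------------------
# Correlation maps
# ---------------------------------------------------------------------------

def _tiny_ensemble(n_copies):
    rng = np.random.default_rng(8)
    seg_coords = rng.normal(scale=0.5, size=(10, 5, 3)) + rng.uniform(-5, 5, size=(1, 5, 3))
    coords = np.concatenate([seg_coords] * n_copies, axis=0)
    atoms = [ecdyn.AtomRecord("A", i + 1, "ALA", "CA", "C", None) for i in range(5)]
    traj = ecdyn.Trajectory(coords, atoms)
    return ecdyn.segment_trajectory(traj, n_copies, 10, take="all")


def test_correlation_map_of_identical_segments_equals_single_segment_map():
    single = _tiny_ensemble(1)
    triple = _tiny_ensemble(3)
    sel1 = ecdyn.select_atoms(single.segments[0], "all")
    sel3 = ecdyn.select_atoms(triple.segments[0], "all")
    m1 = ecdyn.correlation_map(single, sel1, sel1)
    m3 = ecdyn.correlation_map(triple, sel3, sel3)
    np.testing.assert_allclose(m3.values, m1.values, atol=1e-10)
    assert m3.metadata["m_per_segment"] == m3.metadata["m_per_segment"][:1] * 3


def test_correlation_map_tsv_round_trip(tmp_path):
    import pandas as pd

    ens = _tiny_ensemble(2)
    sel = ecdyn.select_atoms(ens.segments[0], "all")
    cmap = ecdyn.correlation_map(ens, sel, sel)
    path = tmp_path / "map.tsv"
    cmap.to_tsv(str(path))
    frame = pd.read_csv(path, sep="\t", index_col=0)
    np.testing.assert_allclose(frame.values, cmap.values, atol=1e-6)
    assert list(frame.columns) == cmap.col_labels


def test_atom_label_format():
    assert atom_label(ecdyn.AtomRecord("A", 42, "GLY", "CA", "C", None)) == "A:42:CA"
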