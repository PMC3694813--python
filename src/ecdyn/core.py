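"""Essential collective dynamics core: covariance, essential space, atom images,
pair-correlation descriptors.

The analysis follows the ECD construction: PCA of the Cartesian fluctuation
covariance of a (superposed) trajectory segment yields orthonormal eigenvectors;
the leading ``m`` of them — the essential collective coordinates — sample a set
fraction (default 90%) of the total displacement.  Each atom is mapped to a
point in the m-dimensional essential space whose component ``k`` is the norm of
the atom's 3-entry block of eigenvector ``k`` (an unsigned direction-cosine
magnitude).  Euclidean distances ``d_ij`` between image points are dimensionless
pair-correlation descriptors: small distances mean strongly coupled motion.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .trajectory import AtomSelection, SegmentEnsemble, Trajectory, superpose_frames

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-10
PSD_TOL = 1e-8


class ECDError(ValueError):
    """Raised for invalid inputs to the essential-dynamics computations."""


@dataclass
class CovarianceResult:
    """3N x 3N fluctuation covariance (Angstrom^2) with the mean structure."""

    matrix: np.ndarray
    mean_structure: np.ndarray
    n_frames_used: int


@dataclass
class EssentialSpace:
    """Eigen-decomposition of a fluctuation covariance plus the atom-image matrix."""

    eigenvalues: np.ndarray  # (3N,), non-increasing, Angstrom^2
    eigenvectors: np.ndarray  # (3N, 3N), orthonormal columns
    m: int
    variance_fraction: float
    images: np.ndarray  # (N, m), dimensionless

    @property
    def n_atoms(self) -> int:
        return self.eigenvectors.shape[0] // 3


@dataclass
class CorrelationMap:
    """Segment-averaged pair-correlation descriptors d_ij between two selections."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray
    n_segments_averaged: int
    metadata: dict | None = None

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        frame = pd.DataFrame(self.values, index=self.row_labels, columns=self.col_labels)
        frame.to_csv(path, sep="\t", float_format="%.8g")
        if self.metadata is not None:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.metadata, fh, indent=2, sort_keys=True)


def atom_label(atom) -> str:
    return f"{atom.chain_id}:{atom.residue_number}:{atom.atom_name}"


# ---------------------------------------------------------------------------
# Covariance
# ---------------------------------------------------------------------------

def compute_covariance(
    segment: Trajectory, sel: AtomSelection, ddof: int = 0
) -> CovarianceResult:
    """Fluctuation covariance C = <dx dx^T> over the frames of a segment.

    Coordinates are ordered (atom0.x, atom0.y, atom0.z, atom1.x, ...).  The
    default divisor is the population convention (``ddof=0``); the segment is
    assumed to be already superposed.
    """
    if segment.n_frames < 2:
        raise ECDError("covariance requires at least 2 frames")
    xyz = segment.coords[:, sel.indices, :]
    if not np.all(np.isfinite(xyz)):
        raise ECDError("non-finite coordinates in covariance input")
    n_frames = xyz.shape[0]
    flat = xyz.reshape(n_frames, -1)
    mean = flat.mean(axis=0)
    delta = flat - mean
    matrix = (delta.T @ delta) / (n_frames - ddof)
    matrix = 0.5 * (matrix + matrix.T)  # enforce exact symmetry
    return CovarianceResult(matrix, mean.reshape(-1, 3), n_frames)


# ---------------------------------------------------------------------------
# Essential space
# ---------------------------------------------------------------------------

def build_images(
    eigenvectors: np.ndarray, m: int, weights: np.ndarray | None = None
) -> np.ndarray:
    """Atom-image matrix: component k of atom i is the norm of eigenvector k's
    3-entry block for atom i, optionally scaled by a per-mode weight."""
    if m < 1:
        raise ECDError("m must be >= 1")
    vecs = np.asarray(eigenvectors)[:, :m]
    n_atoms = vecs.shape[0] // 3
    blocks = vecs.reshape(n_atoms, 3, m)
    images = np.linalg.norm(blocks, axis=1)
    if weights is not None:
        images = images * np.asarray(weights)[:m]
    return images


def essential_space(
    cov: CovarianceResult,
    fraction: float | None = 0.90,
    fixed_m: int | None = None,
    mode_weighting: str = "none",
) -> EssentialSpace:
    """Diagonalize a fluctuation covariance and build the atom-image matrix.

    ``m`` is the smallest eigenvalue count whose cumulative variance fraction
    reaches ``fraction`` (default 0.90), unless ``fixed_m`` is given.
    ``mode_weighting='sqrt_eigenvalue'`` scales image component k by
    sqrt(lambda_k) normalized to the leading mode.
    """
    matrix = np.asarray(cov.matrix, dtype=float)
    dim = matrix.shape[0]
    if matrix.shape != (dim, dim):
        raise ECDError("covariance matrix must be square")
    asym = np.max(np.abs(matrix - matrix.T))
    scale = max(np.max(np.abs(matrix)), 1.0)
    if asym > SYMMETRY_TOL * scale:
        raise ECDError(f"covariance not symmetric (max asymmetry {asym:.3g})")
    eigenvalues, eigenvectors = np.linalg.eigh(matrix)
    trace = float(np.sum(eigenvalues))
    if eigenvalues[0] < -PSD_TOL * max(trace, 1.0):
        raise ECDError(
            f"covariance not positive semi-definite (min eigenvalue {eigenvalues[0]:.3g})"
        )
    order = np.argsort(-eigenvalues, kind="stable")
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = eigenvectors[:, order]

    total = float(eigenvalues.sum())
    if fixed_m is not None:
        if not 1 <= fixed_m <= dim:
            raise ECDError(f"fixed_m must lie in [1, {dim}]")
        m = int(fixed_m)
    else:
        if fraction is None or not 0.0 < fraction <= 1.0:
            raise ECDError("fraction must lie in (0, 1]")
        if total <= 0.0:
            m = 1
        else:
            cumulative = np.cumsum(eigenvalues) / total
            m = int(np.searchsorted(cumulative, fraction - 1e-12) + 1)
            m = min(m, dim)
    variance_fraction = float(eigenvalues[:m].sum() / total) if total > 0 else 0.0

    weights = None
    if mode_weighting == "sqrt_eigenvalue":
        lead = np.sqrt(eigenvalues[0]) if eigenvalues[0] > 0 else 1.0
        weights = np.sqrt(eigenvalues) / lead
    elif mode_weighting != "none":
        raise ECDError(f"unknown mode_weighting {mode_weighting!r}")

    images = build_images(eigenvectors, m, weights)

    return EssentialSpace(eigenvalues, eigenvectors, m, variance_fraction, images)


def pair_distance(space: EssentialSpace, i: int, j: int) -> float:
    """Dimensionless correlation descriptor d_ij between atoms i and j."""
    n = space.images.shape[0]
    if not (0 <= i < n and 0 <= j < n):
        raise ECDError(f"atom index out of range for {n}-atom space")
    return float(np.linalg.norm(space.images[i] - space.images[j]))


def image_distance_matrix(
    space: EssentialSpace, rows: np.ndarray | None = None, cols: np.ndarray | None = None
) -> np.ndarray:
    """Pairwise Euclidean distances between image points (rows x cols)."""
    from scipy.spatial.distance import cdist

    imgs = space.images
    r = imgs if rows is None else imgs[np.asarray(rows)]
    c = imgs if cols is None else imgs[np.asarray(cols)]
    return cdist(r, c)


# ---------------------------------------------------------------------------
# Segment-averaged correlation maps
# ---------------------------------------------------------------------------

def essential_space_of_segment(
    segment: Trajectory,
    sel: AtomSelection,
    fraction: float | None = 0.90,
    fixed_m: int | None = None,
    superpose: bool = True,
    mode_weighting: str = "none",
    ddof: int = 0,
) -> EssentialSpace:
    """Superpose a segment on the selection, then covariance -> essential space."""
    seg = superpose_frames(segment, sel, reference="mean") if superpose else segment
    cov = compute_covariance(seg, sel, ddof=ddof)
    return essential_space(cov, fraction=fraction, fixed_m=fixed_m, mode_weighting=mode_weighting)


def correlation_map(
    ensemble: SegmentEnsemble,
    sel_rows: AtomSelection,
    sel_cols: AtomSelection,
    fraction: float | None = 0.90,
    fixed_m: int | None = None,
    superpose: bool = True,
    mode_weighting: str = "none",
) -> CorrelationMap:
    """Segment-averaged map of pair descriptors d_ij between two selections.

    Each segment is independently superposed and decomposed over the union of
    the two selections; the returned values are arithmetic means of the
    per-segment distance matrices.
    """
    union = np.union1d(sel_rows.indices, sel_cols.indices)
    row_pos = np.searchsorted(union, sel_rows.indices)
    col_pos = np.searchsorted(union, sel_cols.indices)
    accum = None
    m_used = []
    var_used = []
    for k, segment in enumerate(ensemble.segments):
        try:
            union_sel = AtomSelection(segment, union, label="union")
            space = essential_space_of_segment(
                segment,
                union_sel,
                fraction=fraction,
                fixed_m=fixed_m,
                superpose=superpose,
                mode_weighting=mode_weighting,
            )
        except Exception as exc:
            raise ECDError(f"correlation map failed on segment {k}: {exc}") from exc
        dist = image_distance_matrix(space, row_pos, col_pos)
        accum = dist if accum is None else accum + dist
        m_used.append(space.m)
        var_used.append(space.variance_fraction)
    values = accum / ensemble.n_segments
    atoms = ensemble.atoms
    metadata = {
        "rows": sel_rows.label,
        "cols": sel_cols.label,
        "n_segments": ensemble.n_segments,
        "m_per_segment": m_used,
        "variance_fraction_per_segment": var_used,
    }
    logger.info(
        "correlation map %s x %s: %d segments, m in [%d, %d]",
        sel_rows.label, sel_cols.label, ensemble.n_segments, min(m_used), max(m_used),
    )
    return CorrelationMap(
        row_labels=[atom_label(atoms[i]) for i in sel_rows.indices],
        col_labels=[atom_label(atoms[i]) for i in sel_cols.indices],
        values=values,
        n_segments_averaged=ensemble.n_segments,
        metadata=metadata,
    )
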