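"""Per-residue flexibility profiles and comparison with crystallographic B-factors.

The flexibility descriptor of a C-alpha atom is the Euclidean distance in the
m-dimensional essential space between the atom's image point and the centroid of
all selected C-alpha images.  It measures how strongly the atom's motion is
coupled to the collective motion of the whole molecule: flexible loops sit far
from the centroid, rigid secondary-structure elements close to it.  Profiles
are averaged across trajectory segments, with the across-segment standard
deviation reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ECDError, essential_space_of_segment
from .trajectory import AtomSelection, SegmentEnsemble, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class FlexibilityProfile:
    """Mean and across-segment SD of the per-residue flexibility descriptor."""

    residues: list[tuple[str, int, str]]  # (chain, resid, resname)
    mean_flex: np.ndarray
    sd_flex: np.ndarray
    n_segments: int
    n_calpha: int

    def __post_init__(self) -> None:
        self.mean_flex = np.asarray(self.mean_flex, dtype=float)
        self.sd_flex = np.asarray(self.sd_flex, dtype=float)
        if not (len(self.residues) == len(self.mean_flex) == len(self.sd_flex)):
            raise ECDError("profile fields have inconsistent lengths")
        if np.any(self.mean_flex < 0):
            raise ECDError("flexibility values must be non-negative")

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "chain": [r[0] for r in self.residues],
                "resid": [r[1] for r in self.residues],
                "resname": [r[2] for r in self.residues],
                "mean_flex": self.mean_flex,
                "sd_flex": self.sd_flex,
            }
        ).to_csv(path, sep="\t", index=False, float_format="%.8g")


@dataclass
class BFactorProfile:
    """Per-residue crystallographic B-factors (Angstrom^2)."""

    residues: list[tuple[str, int]]  # (chain, resid)
    values: np.ndarray
    aggregation: str  # "CA-only" | "backbone-mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residues) != len(self.values):
            raise ECDError("B-factor profile fields have inconsistent lengths")


def segment_flexibility(images: np.ndarray) -> np.ndarray:
    """Single-segment flexibility: distance of each image from the image centroid."""
    centroid = images.mean(axis=0)
    return np.linalg.norm(images - centroid, axis=1)


def flexibility_profile(
    ensemble: SegmentEnsemble,
    sel: AtomSelection,
    fraction: float | None = 0.90,
    fixed_m: int | None = None,
    superpose: bool = True,
    mode_weighting: str = "none",
) -> FlexibilityProfile:
    """Across-segment mean and SD of the per-residue flexibility descriptor.

    The selection is expected to hold exactly one C-alpha (or representative
    atom) per residue of interest.
    """
    per_segment = []
    for k, segment in enumerate(ensemble.segments):
        try:
            seg_sel = AtomSelection(segment, sel.indices, label=sel.label)
            space = essential_space_of_segment(
                segment,
                seg_sel,
                fraction=fraction,
                fixed_m=fixed_m,
                superpose=superpose,
                mode_weighting=mode_weighting,
            )
        except Exception as exc:
            raise ECDError(f"flexibility failed on segment {k}: {exc}") from exc
        per_segment.append(segment_flexibility(space.images))
    values = np.array(per_segment)  # (n_segments, n_atoms)
    mean_flex = values.mean(axis=0)
    if ensemble.n_segments < 2:
        logger.warning("single segment: across-segment SD reported as 0")
        sd_flex = np.zeros_like(mean_flex)
    else:
        sd_flex = values.std(axis=0, ddof=0)
    atoms = [ensemble.atoms[i] for i in sel.indices]
    residues = [(a.chain_id, a.residue_number, a.residue_name) for a in atoms]
    return FlexibilityProfile(residues, mean_flex, sd_flex, ensemble.n_segments, len(atoms))


# ---------------------------------------------------------------------------
# B-factor extraction and profile comparison
# ---------------------------------------------------------------------------

BACKBONE_ATOMS = ("N", "CA", "C")


def extract_bfactors(structure: Trajectory, aggregation: str = "CA-only") -> BFactorProfile:
    """Per-residue B-factor profile from a single-frame structure.

    ``aggregation='CA-only'`` takes the C-alpha value; ``'backbone-mean'``
    averages over N, CA, C (warning and partial mean if some are missing).
    """
    if aggregation not in ("CA-only", "backbone-mean"):
        raise ECDError(f"aggregation must be 'CA-only' or 'backbone-mean', got {aggregation!r}")
    if any(a.bfactor is None for a in structure.atoms):
        raise ECDError("structure is missing B-factor values")
    wanted = ("CA",) if aggregation == "CA-only" else BACKBONE_ATOMS
    groups: dict[tuple[str, int], list[float]] = {}
    order: list[tuple[str, int]] = []
    for atom in structure.atoms:
        if atom.atom_name not in wanted:
            continue
        key = (atom.chain_id, atom.residue_number)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(atom.bfactor)
    if not order:
        raise ECDError("no backbone atoms found for B-factor extraction")
    if aggregation == "backbone-mean":
        short = [k for k, v in groups.items() if len(v) < len(BACKBONE_ATOMS)]
        if short:
            logger.warning(
                "%d residues missing backbone atoms; using available atoms", len(short)
            )
    values = np.array([float(np.mean(groups[k])) for k in order])
    return BFactorProfile(order, values, aggregation)


def normalize_profile(
    profile: FlexibilityProfile, reference: BFactorProfile, method: str = "minmax"
) -> FlexibilityProfile:
    """Map a flexibility profile onto the range of a reference B-factor profile.

    ``method='minmax'`` applies the affine map sending [min, max] of the profile
    (over the common residues) onto [min, max] of the reference; ``'zscore'``
    matches mean and SD instead.  The returned profile is restricted to the
    residue intersection in reference order, with SDs scaled by the same factor.
    """
    prof_keys = {(c, r): i for i, (c, r, _n) in enumerate(profile.residues)}
    common = [(key, prof_keys[key]) for key in reference.residues if key in prof_keys]
    if len(common) < 3:
        raise ECDError(f"profiles share only {len(common)} residues; need >= 3")
    prof_idx = np.array([i for _k, i in common])
    ref_idx = np.array(
        [j for j, key in enumerate(reference.residues) if key in prof_keys]
    )
    x = profile.mean_flex[prof_idx]
    y = reference.values[ref_idx]
    if method == "minmax":
        span = x.max() - x.min()
        if span <= 0:
            raise ECDError("constant flexibility profile: min-max normalization undefined")
        scale = (y.max() - y.min()) / span
        offset = y.min() - x.min() * scale
    elif method == "zscore":
        sd = x.std(ddof=0)
        if sd <= 0:
            raise ECDError("constant flexibility profile: z-score normalization undefined")
        scale = y.std(ddof=0) / sd
        offset = y.mean() - x.mean() * scale
    else:
        raise ECDError(f"unknown normalization method {method!r}")
    residues = [profile.residues[i] for _k, i in common]
    return FlexibilityProfile(
        residues,
        x * scale + offset,
        profile.sd_flex[prof_idx] * abs(scale),
        profile.n_segments,
        profile.n_calpha,
    )


def profile_agreement(a, b) -> dict:
    """Pearson and Spearman correlation between two per-residue profiles.

    Accepts FlexibilityProfile or BFactorProfile for either argument; pairing is
    by (chain, resid).
    """

    def keyed(profile):
        if isinstance(profile, BFactorProfile):
            return {(c, r): v for (c, r), v in zip(profile.residues, profile.values)}
        return {
            (c, r): v for (c, r, _n), v in zip(profile.residues, profile.mean_flex)
        }

    map_a, map_b = keyed(a), keyed(b)
    common = [k for k in map_a if k in map_b]
    if len(common) < 3:
        raise ECDError(f"profiles share only {len(common)} residues; need >= 3")
    xs = np.array([map_a[k] for k in common])
    ys = np.array([map_b[k] for k in common])
    pearson = float(stats.pearsonr(xs, ys).statistic)
    spearman = float(stats.spearmanr(xs, ys).statistic)
    return {"pearson": pearson, "spearman": spearman, "n_common": len(common)}


def plot_flexibility(profiles: dict[str, FlexibilityProfile], path: str) -> None:
    """Line plot of flexibility profiles with SD error bars, written as SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    for name, profile in profiles.items():
        resids = [r[1] for r in profile.residues]
        ax.errorbar(resids, profile.mean_flex, yerr=profile.sd_flex, label=name, capsize=2)
    ax.set_xlabel("residue")
    ax.set_ylabel("flexibility (dimensionless)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
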