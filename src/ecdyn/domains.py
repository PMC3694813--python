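"""Dynamic domains of correlated motion.

Atoms whose image points lie within an interdomain distance ``d_c`` of a chain
of neighbours move coherently; single-linkage clustering (connected components
of the <= d_c adjacency graph) of the protein's image therefore partitions the
structure into dynamic domains.  The threshold-selection heuristic scans a grid
of candidate d_c values and picks the one that maximizes the number of domains
and the atom count outside the largest domain, subject to the largest domain
holding a reasonable (> 10%) share of the atoms.

The default interdomain distance, 0.0015, is the established optimum for
C-alpha-level analyses of single-protein images built from unweighted
direction-cosine block norms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import CorrelationMap, ECDError, EssentialSpace, image_distance_matrix
from .trajectory import AtomRecord

logger = logging.getLogger(__name__)

DEFAULT_INTERDOMAIN_DISTANCE = 0.0015
DEFAULT_MIN_DOMAIN_SIZE = 3


@dataclass
class DomainPartition:
    """Disjoint atom clusters ordered by decreasing size, plus unassigned atoms."""

    threshold: float
    domains: list[np.ndarray]  # positions into the analyzed selection
    unassigned: np.ndarray
    largest_fraction: float

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def labels(self, n_atoms: int) -> np.ndarray:
        """Per-atom domain rank (0 = largest); -1 for unassigned."""
        out = np.full(n_atoms, -1, dtype=int)
        for rank, members in enumerate(self.domains):
            out[members] = rank
        return out


def _distance_matrix(space_or_map, sel=None) -> np.ndarray:
    if isinstance(space_or_map, EssentialSpace):
        idx = None if sel is None else np.asarray(sel.indices)
        return image_distance_matrix(space_or_map, idx, idx)
    if isinstance(space_or_map, CorrelationMap):
        if space_or_map.row_labels != space_or_map.col_labels:
            raise ECDError("domain clustering needs a square intra-selection map")
        return np.asarray(space_or_map.values)
    matrix = np.asarray(space_or_map, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ECDError("distance matrix must be square")
    return matrix


def cluster_domains(
    space_or_map,
    sel=None,
    threshold: float = DEFAULT_INTERDOMAIN_DISTANCE,
    min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE,
) -> DomainPartition:
    """Single-linkage clustering of atom images at an interdomain distance.

    Accepts an EssentialSpace (distances computed from images, optionally over a
    selection) or a precomputed square distance matrix / intra CorrelationMap.
    Components smaller than ``min_domain_size`` are reported as unassigned.
    Domains are sorted by size, ties broken by smallest member index.
    """
    if threshold <= 0:
        raise ECDError("threshold must be positive")
    if min_domain_size < 1:
        raise ECDError("min_domain_size must be >= 1")
    dist = _distance_matrix(space_or_map, sel)
    n = dist.shape[0]
    adjacency = csr_matrix(dist <= threshold)
    n_comp, labels = connected_components(adjacency, directed=False)
    components = [np.flatnonzero(labels == c) for c in range(n_comp)]
    components.sort(key=lambda members: (-members.size, members[0]))
    domains = [c for c in components if c.size >= min_domain_size]
    small = [c for c in components if c.size < min_domain_size]
    unassigned = (
        np.sort(np.concatenate(small)) if small else np.array([], dtype=int)
    )
    largest_fraction = domains[0].size / n if domains else 0.0
    return DomainPartition(threshold, domains, unassigned, largest_fraction)


def select_threshold(
    space_or_map,
    sel=None,
    grid=None,
    min_largest_fraction: float = 0.10,
    min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE,
) -> dict:
    """Pick the interdomain distance from a grid of candidates.

    For each grid value the diagnostics (n_domains, atoms outside the largest
    domain, largest-domain fraction) are computed; among grid points whose
    largest-domain fraction exceeds ``min_largest_fraction``, the one maximizing
    the lexicographic pair (n_domains, total_in_domains - largest_size) is
    returned, ties resolved toward the smallest threshold.  The full diagnostics
    table is always included so other selection rules can be applied.

    When no grid is given, candidates are quantiles of the observed positive
    pair distances, so the scan covers the data's own scale regardless of
    system size or units.
    """
    dist = _distance_matrix(space_or_map, sel)
    if grid is None:
        positive = dist[np.triu_indices_from(dist, k=1)]
        positive = positive[positive > 0]
        if positive.size == 0:
            raise ECDError("all pair distances are zero; threshold scan undefined")
        grid = np.unique(np.quantile(positive, np.linspace(0.02, 0.98, 40)))
    grid = np.asarray(sorted(grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ECDError("threshold grid must be non-empty and positive")
    diagnostics = []
    for threshold in grid:
        part = cluster_domains(dist, threshold=threshold, min_domain_size=min_domain_size)
        total_in_domains = int(sum(d.size for d in part.domains))
        largest = part.domains[0].size if part.domains else 0
        diagnostics.append(
            {
                "threshold": float(threshold),
                "n_domains": part.n_domains,
                "atoms_outside_largest": total_in_domains - largest,
                "largest_fraction": part.largest_fraction,
            }
        )
    feasible = [d for d in diagnostics if d["largest_fraction"] > min_largest_fraction]
    if not feasible:
        raise ECDError(
            "no grid threshold yields a largest domain above "
            f"{min_largest_fraction:.0%} of atoms; diagnostics: {json.dumps(diagnostics)}"
        )
    best = max(
        feasible,
        key=lambda d: (d["n_domains"], d["atoms_outside_largest"], -d["threshold"]),
    )
    keys = [(d["n_domains"], d["atoms_outside_largest"], d["largest_fraction"]) for d in diagnostics]
    degenerate = len(set(keys)) == 1
    if degenerate:
        logger.warning("all grid thresholds give identical partitions; grid uninformative")
    logger.info(
        "selected interdomain distance %.4g (%d domains, largest fraction %.2f)",
        best["threshold"], best["n_domains"], best["largest_fraction"],
    )
    return {
        "threshold": best["threshold"],
        "diagnostics": diagnostics,
        "degenerate": degenerate,
    }


def domain_summary(
    partition: DomainPartition, atoms: list[AtomRecord], k: int = 6
) -> list[dict]:
    """Residue-range report for the k largest domains.

    Each entry lists contiguous author-numbered residue ranges per chain as
    strings like ``A:10-20 (11 residues)``, with the domain's atom count and
    fraction of the analyzed atoms.
    """
    n_total = sum(d.size for d in partition.domains) + partition.unassigned.size
    report = []
    for rank, members in enumerate(partition.domains[:k]):
        by_chain: dict[str, set[int]] = {}
        for pos in members:
            atom = atoms[pos]
            by_chain.setdefault(atom.chain_id, set()).add(atom.residue_number)
        ranges = []
        for chain in sorted(by_chain):
            resids = sorted(by_chain[chain])
            start = prev = resids[0]
            for r in resids[1:]:
                if r != prev + 1:
                    ranges.append(_format_range(chain, start, prev))
                    start = r
                prev = r
            ranges.append(_format_range(chain, start, prev))
        report.append(
            {
                "rank": rank,
                "size": int(members.size),
                "fraction": members.size / n_total if n_total else 0.0,
                "ranges": ranges,
            }
        )
    return report


def _format_range(chain: str, start: int, stop: int) -> str:
    count = stop - start + 1
    span = f"{start}-{stop}" if stop > start else f"{start}"
    return f"{chain}:{span} ({count} residue{'s' if count != 1 else ''})"


def partition_to_tsv(
    partition: DomainPartition, atoms: list[AtomRecord], sel_indices: np.ndarray, path: str
) -> None:
    """Serialize a partition as TSV: chain, resid, atom, domain_rank (-1 unassigned)."""
    import pandas as pd

    labels = partition.labels(len(sel_indices))
    pd.DataFrame(
        {
            "chain": [atoms[i].chain_id for i in sel_indices],
            "resid": [atoms[i].residue_number for i in sel_indices],
            "atom": [atoms[i].atom_name for i in sel_indices],
            "domain_rank": labels,
        }
    ).to_csv(path, sep="\t", index=False)
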