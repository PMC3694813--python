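"""Distance-cutoff classification of inter-molecular residue contacts.

Residue pairs across a binding interface are classified by the chemistry of
their closest atom pairs:

- ``hbond_range``: a nitrogen/oxygen pair (donor/acceptor-capable) within 4.0 A
- ``polar``:       an N/O/S pair within 3.5 A
- ``nonpolar``:    a carbon-carbon pair within 4.5 A
- ``neighbor``:    any heavy-atom pair within 5.0 A

A residue pair may satisfy several classes; the reported class is the most
specific (smallest satisfied cutoff) and all satisfied classes are listed.
Chemistry perception is by element only — a deliberate, reproducible
approximation of full donor/acceptor typing.  Hydrogens are ignored; X-H...Y
interactions are assessed on the heavy-atom pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .trajectory import AtomSelection, Trajectory, TrajectoryError

DEFAULT_CUTOFFS = {"hbond": 4.0, "polar": 3.5, "nonpolar": 4.5, "neighbor": 5.0}

POLAR_ELEMENTS = frozenset({"N", "O", "S"})
HBOND_ELEMENTS = frozenset({"N", "O"})

ResidueKey = tuple[str, int, str]  # (chain, resid, resname)


@dataclass
class ContactRecord:
    """One inter-molecular residue contact with its realizing atom pair."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_distance: float
    contact_class: str
    atoms: tuple[str, str]  # atom names of the closest pair
    classes: list[str] = field(default_factory=list)

    @property
    def pair_key(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return (self.residue_a[:2], self.residue_b[:2])


def _classify_pairs(elem_a, elem_b, dist, cutoffs) -> list[str]:
    """All contact classes satisfied by a single atom pair, most specific first."""
    satisfied = []
    if elem_a in POLAR_ELEMENTS and elem_b in POLAR_ELEMENTS and dist <= cutoffs["polar"]:
        satisfied.append("polar")
    if elem_a in HBOND_ELEMENTS and elem_b in HBOND_ELEMENTS and dist <= cutoffs["hbond"]:
        satisfied.append("hbond_range")
    if elem_a == "C" and elem_b == "C" and dist <= cutoffs["nonpolar"]:
        satisfied.append("nonpolar")
    return satisfied


def interface_contacts(
    structure: Trajectory,
    group_a: AtomSelection,
    group_b: AtomSelection,
    cutoffs: dict | None = None,
    frame: int = 0,
) -> list[ContactRecord]:
    """Residue-pair contacts between two disjoint atom groups of one structure.

    Emits one record per residue pair with any inter-group heavy-atom pair
    within the neighbor cutoff, carrying the minimal distance, the realizing
    atoms, the most specific satisfied class, and all satisfied classes.
    """
    cutoffs = {**DEFAULT_CUTOFFS, **(cutoffs or {})}
    if np.intersect1d(group_a.indices, group_b.indices).size:
        raise TrajectoryError("contact groups must be disjoint")
    coords = structure.coords[frame]
    atoms = structure.atoms

    def heavy(indices):
        return np.array([i for i in indices if atoms[i].element.upper() != "H"], dtype=int)

    idx_a = heavy(group_a.indices)
    idx_b = heavy(group_b.indices)
    if idx_a.size == 0 or idx_b.size == 0:
        return []
    tree_b = cKDTree(coords[idx_b])
    pairs = tree_b.query_ball_point(coords[idx_a], r=cutoffs["neighbor"])

    per_residue: dict[tuple[ResidueKey, ResidueKey], dict] = {}
    class_rank = {"polar": 0, "hbond_range": 1, "nonpolar": 2, "neighbor": 3}
    for ai_pos, neighbors in enumerate(pairs):
        ia = idx_a[ai_pos]
        atom_a = atoms[ia]
        key_a = (atom_a.chain_id, atom_a.residue_number, atom_a.residue_name)
        for bj_pos in neighbors:
            ib = idx_b[bj_pos]
            atom_b = atoms[ib]
            dist = float(np.linalg.norm(coords[ia] - coords[ib]))
            if dist > cutoffs["neighbor"]:
                continue
            key_b = (atom_b.chain_id, atom_b.residue_number, atom_b.residue_name)
            key = (key_a, key_b)
            entry = per_residue.setdefault(
                key, {"min": np.inf, "atoms": None, "classes": set()}
            )
            if dist < entry["min"]:
                entry["min"] = dist
                entry["atoms"] = (atom_a.atom_name, atom_b.atom_name)
            entry["classes"].update(
                _classify_pairs(atom_a.element.upper(), atom_b.element.upper(), dist, cutoffs)
            )

    records = []
    for (key_a, key_b), entry in sorted(per_residue.items()):
        classes = sorted(entry["classes"] | {"neighbor"}, key=class_rank.__getitem__)
        records.append(
            ContactRecord(
                residue_a=key_a,
                residue_b=key_b,
                min_distance=entry["min"],
                contact_class=classes[0],
                atoms=entry["atoms"],
                classes=classes,
            )
        )
    return records


def compare_interfaces(contacts_a: list[ContactRecord], contacts_b: list[ContactRecord]) -> dict:
    """Set comparison of two interfaces keyed by residue pair, classes carried along."""

    def keyed(records):
        return {r.pair_key: r for r in records}

    map_a, map_b = keyed(contacts_a), keyed(contacts_b)
    shared = sorted(set(map_a) & set(map_b))
    only_a = sorted(set(map_a) - set(map_b))
    only_b = sorted(set(map_b) - set(map_a))
    return {
        "shared": [(k, map_a[k].contact_class, map_b[k].contact_class) for k in shared],
        "unique_to_a": [(k, map_a[k].contact_class) for k in only_a],
        "unique_to_b": [(k, map_b[k].contact_class) for k in only_b],
    }


def contacts_to_tsv(records: list[ContactRecord], path: str) -> None:
    """Serialize contacts as TSV: residue pair, class, all classes, distance, atoms."""
    import pandas as pd

    pd.DataFrame(
        {
            "chain_a": [r.residue_a[0] for r in records],
            "resid_a": [r.residue_a[1] for r in records],
            "resname_a": [r.residue_a[2] for r in records],
            "chain_b": [r.residue_b[0] for r in records],
            "resid_b": [r.residue_b[1] for r in records],
            "resname_b": [r.residue_b[2] for r in records],
            "class": [r.contact_class for r in records],
            "all_classes": [",".join(r.classes) for r in records],
            "min_distance": [round(r.min_distance, 4) for r in records],
            "atom_a": [r.atoms[0] for r in records],
            "atom_b": [r.atoms[1] for r in records],
        }
    ).to_csv(path, sep="\t", index=False)
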