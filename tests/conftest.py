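"""Shared fixtures: synthetic systems, analyzed ensembles, tiny PDB builders."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ecdyn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: analysis protocol used for all synthetic block-system studies
N_SEGMENTS = 50
SEGMENT_LENGTH = 40
SEEDS = (0, 1, 2, 3, 4)


@pytest.fixture(scope="session")
def block_analyses():
    """Per-(n_blocks, seed) analysis products of the default block systems.

    Computed once per test session: spec, trajectory, segment ensemble,
    correlation map, flexibility profile, analytic MSF.
    """
    cache: dict[tuple[int, int], dict] = {}

    def get(n_blocks: int, seed: int) -> dict:
        key = (n_blocks, seed)
        if key not in cache:
            spec = ecdyn.make_block_system(n_blocks=n_blocks, seed=seed)
            traj = ecdyn.generate_enm_trajectory(spec)
            ensemble = ecdyn.segment_trajectory(traj, N_SEGMENTS, SEGMENT_LENGTH, take="tail")
            sel = ecdyn.select_atoms(traj, "name CA")
            cmap = ecdyn.correlation_map(ensemble, sel, sel)
            profile = ecdyn.flexibility_profile(ensemble, sel)
            cache[key] = {
                "spec": spec,
                "trajectory": traj,
                "ensemble": ensemble,
                "selection": sel,
                "correlation_map": cmap,
                "flexibility": profile,
                "analytic_msf": ecdyn.analytic_msf(spec),
                "labels": np.array(spec.block_labels),
            }
        return cache[key]

    return get


def make_structure(coords, chains, resids, names, elements, bfactors=None, resnames=None):
    """Single-frame Trajectory from parallel per-atom lists."""
    n = len(chains)
    if resnames is None:
        resnames = ["ALA"] * n
    if bfactors is None:
        bfactors = [None] * n
    atoms = [
        ecdyn.AtomRecord(chains[i], int(resids[i]), resnames[i], names[i], elements[i],
                         None if bfactors[i] is None else float(bfactors[i]))
        for i in range(n)
    ]
    return ecdyn.Trajectory(np.asarray(coords, dtype=float)[None, :, :], atoms)


@pytest.fixture
def two_chain_structure():
    """Two 3-residue chains facing each other across a narrow interface."""
    rows = []
    coords = []
    for c, chain in enumerate("AB"):
        for r in range(3):
            base = np.array([c * 6.0, r * 3.0, 0.0])
            for name, element, offset in (
                ("N", "N", [0.0, 0.0, 0.0]),
                ("CA", "C", [0.8, 0.6, 0.0]),
                ("C", "C", [1.6, 0.0, 0.0]),
                ("O", "O", [1.6, -1.2, 0.0]),
            ):
                rows.append((chain, r + 1, name, element))
                coords.append(base + np.array(offset) + (0 if c == 0 else np.array([-2.0, 0, 0])))
    chains, resids, names, elements = zip(*rows)
    return make_structure(np.array(coords), chains, resids, names, elements)
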