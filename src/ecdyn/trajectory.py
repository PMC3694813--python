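"""Trajectory containers, readers/writers, atom selection, superposition, segmentation.

Coordinates are stored in Angstrom throughout; formats with nm-native payloads
(XTC) are converted on read.  Residue numbers follow author (PDB) numbering and
ranges are inclusive at both ends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

SUPPORTED_TRAJ_FORMATS = (".dcd", ".xtc", ".pdb")


class TrajectoryError(ValueError):
    """Raised for malformed or inconsistent trajectory/structure input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology: identity plus optional crystallographic B-factor."""

    chain_id: str
    residue_number: int
    residue_name: str
    atom_name: str
    element: str
    bfactor: float | None = None


@dataclass
class Trajectory:
    """Frames x atoms x 3 Cartesian coordinates (Angstrom) with an atom table."""

    coords: np.ndarray
    atoms: list[AtomRecord]
    frame_interval: float | None = None  # ps between frames, metadata only

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        if self.coords.shape[0] < 1:
            raise TrajectoryError("trajectory must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("trajectory coordinates contain non-finite values")
        if len(self.atoms) != self.coords.shape[1]:
            raise TrajectoryError(
                f"atom table length {len(self.atoms)} does not match "
                f"coordinate atom count {self.coords.shape[1]}"
            )

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        return Trajectory(self.coords[start:stop].copy(), self.atoms, self.frame_interval)


@dataclass
class AtomSelection:
    """Ordered, strictly increasing 0-based atom indices into a trajectory."""

    source: Trajectory
    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise TrajectoryError(f"selection {self.label!r} is empty")
        if np.any(np.diff(self.indices) <= 0):
            raise TrajectoryError("selection indices must be strictly increasing")
        if self.indices[0] < 0 or self.indices[-1] >= self.source.n_atoms:
            raise TrajectoryError("selection index out of range")

    def __len__(self) -> int:
        return int(self.indices.size)

    @property
    def atoms(self) -> list[AtomRecord]:
        return [self.source.atoms[i] for i in self.indices]


@dataclass
class SegmentEnsemble:
    """Contiguous, non-overlapping, equal-length trajectory segments sharing one atom table."""

    segments: list[Trajectory]
    n_segments: int = field(init=False)
    segment_length_frames: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise TrajectoryError("segment ensemble is empty")
        lengths = {s.n_frames for s in self.segments}
        if len(lengths) != 1:
            raise TrajectoryError(f"segments have unequal lengths: {sorted(lengths)}")
        first = self.segments[0]
        for s in self.segments[1:]:
            if s.atoms is not first.atoms and s.atoms != first.atoms:
                raise TrajectoryError("segments do not share an atom table")
        self.n_segments = len(self.segments)
        self.segment_length_frames = first.n_frames

    @property
    def atoms(self) -> list[AtomRecord]:
        return self.segments[0].atoms


# ---------------------------------------------------------------------------
# PDB reading / writing (fixed-column, multi-MODEL) via biotite
# ---------------------------------------------------------------------------

def read_pdb(path: str, model_policy: str = "all") -> Trajectory:
    """Read a (possibly multi-MODEL) PDB file into a Trajectory.

    ``model_policy='all'`` yields one frame per MODEL; ``'first'`` keeps only
    the first model.  The B-factor column (61-66, 1-based) populates
    ``AtomRecord.bfactor``.
    """
    import biotite.structure.io.pdb as pdb

    if model_policy not in ("first", "all"):
        raise TrajectoryError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    _validate_pdb_lines(path)
    pdb_file = pdb.PDBFile.read(path)
    try:
        stack = pdb_file.get_structure(extra_fields=["b_factor"])
    except Exception as exc:  # biotite raises assorted parse errors
        raise TrajectoryError(f"failed to parse PDB {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise TrajectoryError(f"PDB file {path} contains no atoms")
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    if model_policy == "first":
        coords = coords[:1]
    first = stack[0] if coords.shape[0] >= 1 else stack
    atoms = [
        AtomRecord(
            chain_id=str(first.chain_id[i]),
            residue_number=int(first.res_id[i]),
            residue_name=str(first.res_name[i]),
            atom_name=str(first.atom_name[i]),
            element=str(first.element[i]),
            bfactor=float(first.b_factor[i]),
        )
        for i in range(first.array_length())
    ]
    logger.info("read %s: %d frames, %d atoms", path, coords.shape[0], coords.shape[1])
    return Trajectory(coords, atoms)


def _validate_pdb_lines(path: str) -> None:
    """Pre-scan ATOM/HETATM records so parse errors can name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise TrajectoryError(
                    f"{path}:{lineno}: ATOM record shorter than coordinate fields"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                int(line[22:26])
            except ValueError as exc:
                raise TrajectoryError(
                    f"{path}:{lineno}: malformed ATOM record: {exc}"
                ) from exc


def write_pdb(traj: Trajectory, path: str) -> None:
    """Write a Trajectory as a multi-MODEL PDB (one MODEL per frame)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = traj.coords.astype(np.float32)
    stack.chain_id = np.array([a.chain_id for a in traj.atoms])
    stack.res_id = np.array([a.residue_number for a in traj.atoms])
    stack.res_name = np.array([a.residue_name for a in traj.atoms])
    stack.atom_name = np.array([a.atom_name for a in traj.atoms])
    stack.element = np.array([a.element for a in traj.atoms])
    stack.set_annotation(
        "b_factor",
        np.array([a.bfactor if a.bfactor is not None else 0.0 for a in traj.atoms]),
    )
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(path)
    logger.info("wrote %s: %d frames, %d atoms", path, traj.n_frames, n)


# ---------------------------------------------------------------------------
# Binary trajectory formats via MDAnalysis
# ---------------------------------------------------------------------------

def read_trajectory(topology: str, traj: str) -> Trajectory:
    """Read a binary trajectory (DCD/XTC) with a companion topology (e.g. PDB).

    MDAnalysis converts native units to Angstrom on read.
    """
    import MDAnalysis as mda

    ext = "." + traj.rsplit(".", 1)[-1].lower()
    if ext not in SUPPORTED_TRAJ_FORMATS:
        raise TrajectoryError(
            f"unsupported trajectory format {ext!r}; supported: "
            + ", ".join(SUPPORTED_TRAJ_FORMATS)
        )
    try:
        universe = mda.Universe(topology, traj)
    except Exception as exc:
        msg = str(exc)
        if "atoms" in msg.lower():
            raise TrajectoryError(
                f"topology {topology} and trajectory {traj} disagree on atom count: {msg}"
            ) from exc
        raise TrajectoryError(f"failed to read {traj} with topology {topology}: {msg}") from exc
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = np.array([universe.atoms.positions.copy() for _ in universe.trajectory])
    atoms = _atoms_from_universe(universe)
    logger.info("read %s: %d frames, %d atoms", traj, coords.shape[0], coords.shape[1])
    return Trajectory(coords.astype(float), atoms)


def _atoms_from_universe(universe) -> list[AtomRecord]:
    ag = universe.atoms

    def ann(name, default):
        try:
            return getattr(ag, name)
        except Exception:
            return [default] * len(ag)

    chains = ann("chainIDs", "A")
    resids = ann("resids", 1)
    resnames = ann("resnames", "UNK")
    names = ann("names", "X")
    elements = ann("elements", "")
    bfactors = ann("tempfactors", None)
    records = []
    for i in range(len(ag)):
        elem = str(elements[i]) if str(elements[i]).strip() else _guess_element(str(names[i]))
        bf = bfactors[i]
        records.append(
            AtomRecord(
                chain_id=str(chains[i]),
                residue_number=int(resids[i]),
                residue_name=str(resnames[i]),
                atom_name=str(names[i]),
                element=elem,
                bfactor=float(bf) if bf is not None else None,
            )
        )
    return records


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def write_trajectory(traj: Trajectory, topology_path: str, traj_path: str) -> None:
    """Write the trajectory to DCD or XTC (plus a single-frame PDB topology)."""
    import MDAnalysis as mda

    first_frame = Trajectory(traj.coords[:1], traj.atoms)
    write_pdb(first_frame, topology_path)
    universe = mda.Universe(topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(traj_path, n_atoms=traj.n_atoms) as writer:
            for frame in traj.coords:
                universe.atoms.positions = frame
                writer.write(universe.atoms)
    logger.info("wrote %s: %d frames", traj_path, traj.n_frames)


# ---------------------------------------------------------------------------
# Atom selection mini-grammar
# ---------------------------------------------------------------------------

def select_atoms(traj: Trajectory, expr: str, label: str | None = None) -> AtomSelection:
    """Select atoms with a minimal expression grammar.

    Clauses joined by ``and``:

    - ``name CA`` or ``name C,CA,N`` - atom names
    - ``chain A`` or ``chain A,B``   - chain identifiers
    - ``resid 85-89`` or ``resid 12,30-35`` - inclusive author-numbered ranges
    - ``all`` - every atom
    """
    mask = np.ones(traj.n_atoms, dtype=bool)
    for clause in [c.strip() for c in expr.split(" and ")]:
        if not clause:
            raise TrajectoryError(f"empty clause in selection expression {expr!r}")
        parts = clause.split(None, 1)
        keyword = parts[0].lower()
        if keyword == "all":
            continue
        if len(parts) != 2:
            raise TrajectoryError(f"clause {clause!r} missing an argument")
        arg = parts[1]
        if keyword == "name":
            names = {n.strip() for n in arg.split(",")}
            mask &= np.array([a.atom_name in names for a in traj.atoms])
        elif keyword == "chain":
            chains = {c.strip() for c in arg.split(",")}
            mask &= np.array([a.chain_id in chains for a in traj.atoms])
        elif keyword == "resid":
            ok = np.zeros(traj.n_atoms, dtype=bool)
            for token in arg.split(","):
                token = token.strip()
                if "-" in token[1:]:  # allow negative lower bound
                    lo_s, hi_s = token.rsplit("-", 1)
                    lo, hi = int(lo_s), int(hi_s)
                else:
                    lo = hi = int(token)
                ok |= np.array(
                    [lo <= a.residue_number <= hi for a in traj.atoms]
                )
            mask &= ok
        else:
            raise TrajectoryError(
                f"unknown selection keyword {keyword!r} (expected name/chain/resid/all)"
            )
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise TrajectoryError(f"selection {expr!r} matched no atoms")
    return AtomSelection(traj, indices, label=label if label is not None else expr)


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def _kabsch_transform(mobile: np.ndarray, target: np.ndarray):
    """Proper-rotation least-squares fit of mobile onto target.

    Returns (R, t) with fitted = mobile @ R.T + t and det(R) = +1.
    """
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tgt_center, mobile - mob_center)
    R = rot.as_matrix()
    t = tgt_center - mob_center @ R.T
    return R, t


def _check_reference_geometry(ref: np.ndarray) -> None:
    if ref.shape[0] < 3:
        raise TrajectoryError("superposition requires at least 3 reference atoms")
    centered = ref - ref.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] < 1e-8 * max(svals[0], 1.0):
        raise TrajectoryError("reference atoms are collinear or coincident")


def superpose_frames(
    traj: Trajectory, sel: AtomSelection, reference: str = "mean", n_iterations: int = 2
) -> Trajectory:
    """Rigid-body superpose every frame onto a reference over the selection.

    ``reference='mean'`` aligns to the mean structure, recomputing the mean and
    realigning ``n_iterations`` times; ``'first'`` aligns to frame 0.  The fitted
    transform is applied to all atoms of each frame.
    """
    if reference not in ("mean", "first"):
        raise TrajectoryError(f"reference must be 'mean' or 'first', got {reference!r}")
    idx = sel.indices
    coords = traj.coords.copy()
    if reference == "first":
        ref = coords[0, idx]
        _check_reference_geometry(ref)
        for f in range(traj.n_frames):
            R, t = _kabsch_transform(coords[f, idx], ref)
            coords[f] = coords[f] @ R.T + t
    else:
        for _ in range(max(1, n_iterations)):
            ref = coords[:, idx].mean(axis=0)
            _check_reference_geometry(ref)
            for f in range(traj.n_frames):
                R, t = _kabsch_transform(coords[f, idx], ref)
                coords[f] = coords[f] @ R.T + t
    return Trajectory(coords, traj.atoms, traj.frame_interval)


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    sel: AtomSelection | None = None,
    superpose: bool = False,
) -> float:
    """Root-mean-square deviation (Angstrom) between two coordinate sets.

    With ``superpose=True`` the deviation is computed after a Kabsch fit of
    ``b`` onto ``a`` over the (optionally selected) atoms.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise TrajectoryError(f"coordinate shape mismatch: {a.shape} vs {b.shape}")
    if sel is not None:
        a = a[sel.indices]
        b = b[sel.indices]
    if superpose:
        R, t = _kabsch_transform(b, a)
        b = b @ R.T + t
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_trajectory(
    traj: Trajectory,
    n_segments: int,
    segment_length_frames: int,
    take: str = "tail",
) -> SegmentEnsemble:
    """Cut the trajectory into contiguous, non-overlapping, equal-length segments.

    ``take='tail'`` slices the required frames from the end of the trajectory,
    ``'head'`` from the start; ``'all'`` requires the trajectory length to equal
    the requested region exactly.
    """
    if take not in ("tail", "head", "all"):
        raise TrajectoryError(f"take must be tail/head/all, got {take!r}")
    if n_segments < 1 or segment_length_frames < 2:
        raise TrajectoryError("need n_segments >= 1 and segment_length_frames >= 2")
    needed = n_segments * segment_length_frames
    if needed > traj.n_frames:
        raise TrajectoryError(
            f"segmenting requires {needed} frames "
            f"({n_segments} segments x {segment_length_frames}); only {traj.n_frames} available"
        )
    if take == "all" and needed != traj.n_frames:
        raise TrajectoryError(
            f"take='all' requires exactly {needed} frames, trajectory has {traj.n_frames}"
        )
    start = traj.n_frames - needed if take == "tail" else 0
    segments = [
        traj.slice_frames(start + k * segment_length_frames, start + (k + 1) * segment_length_frames)
        for k in range(n_segments)
    ]
    # share the atom table object so SegmentEnsemble's identity check is cheap
    segments = [replace(s, atoms=traj.atoms) for s in segments]
    return SegmentEnsemble(segments)
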