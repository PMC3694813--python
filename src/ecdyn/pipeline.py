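"""End-to-end analysis pipeline: configuration, orchestration, provenance.

`run_analyze` ties the stages together: read trajectory, slice into segments,
per-segment essential spaces, averaged correlation map, flexibility profile,
domain partition — writing TSV/JSON artifacts plus a resolved-config copy into
a single run directory so every run is reproducible from its own outputs.
`run_simulate` materializes a synthetic elastic-network trajectory with its
ground-truth sidecar from a JSON specification.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contacts import DEFAULT_CUTOFFS
from .core import correlation_map
from .descriptors import flexibility_profile
from .domains import (
    DEFAULT_INTERDOMAIN_DISTANCE,
    DEFAULT_MIN_DOMAIN_SIZE,
    cluster_domains,
    domain_summary,
    partition_to_tsv,
    select_threshold,
)
from .synthetic import ENMError, ENMSpec, generate_enm_trajectory, make_block_system, write_ground_truth
from .trajectory import (
    Trajectory,
    TrajectoryError,
    read_pdb,
    read_trajectory,
    segment_trajectory,
    select_atoms,
    write_pdb,
    write_trajectory,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    """Resolved configuration of one analysis run.

    Defaults: 100 segments, 90% essential variance fraction, contact cutoffs
    4.0/3.5/4.5/5.0 A, single-linkage interdomain distance chosen by grid scan
    unless ``domain_threshold`` is set.  Every run writes this object (resolved)
    as JSON next to its outputs.
    """

    topology: str
    trajectory: str | None = None
    selection: str = "name CA"
    n_segments: int = 100
    segment_length: int | None = None
    take: str = "tail"
    fraction: float = 0.90
    fixed_m: int | None = None
    mode_weighting: str = "none"
    superpose: bool = True
    domain_threshold: float | None = None
    threshold_grid: list[float] | None = None
    min_domain_size: int = DEFAULT_MIN_DOMAIN_SIZE
    contact_cutoffs: dict = field(default_factory=lambda: dict(DEFAULT_CUTOFFS))
    outdir: str = "ecdyn_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_segments < 1:
            raise ConfigError("n_segments must be >= 1")
        if self.segment_length is not None and self.segment_length < 2:
            raise ConfigError("segment_length must be >= 2 frames")
        if not (self.fraction is None or 0.0 < self.fraction <= 1.0):
            raise ConfigError("fraction must lie in (0, 1]")
        if self.fixed_m is not None and self.fixed_m < 1:
            raise ConfigError("fixed_m must be >= 1")
        if self.domain_threshold is not None and self.domain_threshold <= 0:
            raise ConfigError("domain_threshold must be positive")
        if self.take not in ("tail", "head", "all"):
            raise ConfigError(f"take must be 'tail', 'head' or 'all', got {self.take!r}")
        missing = set(DEFAULT_CUTOFFS) - set(self.contact_cutoffs)
        if missing:
            raise ConfigError(f"contact_cutoffs missing keys: {sorted(missing)}")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "AnalysisConfig":
        """Load a flat JSON config document; keyword overrides win."""
        try:
            with open(path) as fh:
                data = json.load(fh)
        except FileNotFoundError as exc:
            raise FileNotFoundError(f"config file not found: {path}") from exc
        except json.JSONDecodeError as exc:
            raise ConfigError(f"config file {path} is not valid JSON: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config document must be a JSON object")
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def write_resolved(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _load_trajectory(config: AnalysisConfig) -> Trajectory:
    if config.trajectory is None:
        return read_pdb(config.topology)
    return read_trajectory(config.topology, config.trajectory)


def _segment(traj: Trajectory, config: AnalysisConfig):
    n_frames = traj.n_frames
    length = config.segment_length
    if length is None:
        length = n_frames // config.n_segments
        if length < 2:
            raise ConfigError(
                f"{n_frames} frames cannot hold {config.n_segments} segments of >= 2 frames"
            )
    return segment_trajectory(traj, config.n_segments, length, take=config.take)


def run_analyze(config: AnalysisConfig) -> dict:
    """Full analysis: correlation map, flexibility profile, domain partition.

    Returns a dict of artifact paths.  Deterministic for fixed inputs/config.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.write_resolved(str(outdir / "config.resolved.json"))

    traj = _load_trajectory(config)
    logger.info("loaded trajectory: %d frames, %d atoms", traj.n_frames, traj.n_atoms)
    sel = select_atoms(traj, config.selection)
    ensemble = _segment(traj, config)
    logger.info(
        "segmented into %d segments of %d frames (%s)",
        ensemble.n_segments, ensemble.segment_length_frames, config.take,
    )

    cmap = correlation_map(
        ensemble, sel, sel,
        fraction=config.fraction, fixed_m=config.fixed_m,
        superpose=config.superpose, mode_weighting=config.mode_weighting,
    )
    m_per_seg = cmap.metadata["m_per_segment"]
    logger.info(
        "essential modes per segment: min %d, median %.0f, max %d; variance fractions %.3f-%.3f",
        min(m_per_seg), float(np.median(m_per_seg)), max(m_per_seg),
        min(cmap.metadata["variance_fraction_per_segment"]),
        max(cmap.metadata["variance_fraction_per_segment"]),
    )
    cmap_path = outdir / "correlation_map.tsv"
    cmap.to_tsv(str(cmap_path))

    profile = flexibility_profile(
        ensemble, sel,
        fraction=config.fraction, fixed_m=config.fixed_m,
        superpose=config.superpose, mode_weighting=config.mode_weighting,
    )
    flex_path = outdir / "flexibility.tsv"
    profile.to_tsv(str(flex_path))

    if config.domain_threshold is not None:
        threshold = config.domain_threshold
        selection_info = {"threshold": threshold, "source": "config"}
    else:
        scan = select_threshold(
            cmap, grid=config.threshold_grid, min_domain_size=config.min_domain_size
        )
        threshold = scan["threshold"]
        selection_info = {
            "threshold": threshold,
            "source": "grid_scan",
            "diagnostics": scan["diagnostics"],
            "degenerate": scan["degenerate"],
        }
    partition = cluster_domains(cmap, threshold=threshold, min_domain_size=config.min_domain_size)
    logger.info(
        "domain partition at d_c=%.4g: %d domains, largest fraction %.2f, %d unassigned",
        threshold, partition.n_domains, partition.largest_fraction, partition.unassigned.size,
    )
    dom_tsv = outdir / "domains.tsv"
    partition_to_tsv(partition, traj.atoms, np.asarray(sel.indices), str(dom_tsv))
    dom_json = outdir / "domains.json"
    with open(dom_json, "w") as fh:
        json.dump(
            {
                "selection": selection_info,
                "n_domains": partition.n_domains,
                "largest_fraction": partition.largest_fraction,
                "n_unassigned": int(partition.unassigned.size),
                "summary": domain_summary(partition, [traj.atoms[i] for i in sel.indices]),
            },
            fh, indent=2,
        )
    return {
        "config": str(outdir / "config.resolved.json"),
        "correlation_map": str(cmap_path),
        "flexibility": str(flex_path),
        "domains_tsv": str(dom_tsv),
        "domains_json": str(dom_json),
    }


# ---------------------------------------------------------------------------
# Simulation entry point
# ---------------------------------------------------------------------------

def load_enm_spec(path: str) -> ENMSpec:
    """ENMSpec from a JSON document.

    Either a ``block_system`` object with :func:`make_block_system` keyword
    arguments, or the explicit ENMSpec fields (positions0 and springs as
    nested lists).
    """
    try:
        with open(path) as fh:
            data = json.load(fh)
    except FileNotFoundError as exc:
        raise FileNotFoundError(f"spec file not found: {path}") from exc
    except json.JSONDecodeError as exc:
        raise ENMError(f"spec file {path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ENMError("spec document must be a JSON object")
    if "block_system" in data:
        kwargs = data["block_system"]
        if not isinstance(kwargs, dict):
            raise ENMError("'block_system' must be an object of keyword arguments")
        try:
            return make_block_system(**kwargs)
        except TypeError as exc:
            raise ENMError(f"invalid block_system arguments: {exc}") from exc
    fields = {f.name for f in dataclasses.fields(ENMSpec)} - {"atoms"}
    unknown = set(data) - fields
    if unknown:
        raise ENMError(f"unknown spec fields: {sorted(unknown)}")
    if "springs" in data:
        data["springs"] = [tuple(s) for s in data["springs"]]
    try:
        return ENMSpec(**data)
    except TypeError as exc:
        raise ENMError(f"incomplete spec: {exc}") from exc


def run_simulate(spec_path: str, outdir: str, traj_format: str = "pdb") -> dict:
    """Generate a synthetic trajectory plus ground-truth and provenance sidecars."""
    spec = load_enm_spec(spec_path)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    traj = generate_enm_trajectory(spec)
    if traj_format == "pdb":
        traj_path = out / "trajectory.pdb"
        write_pdb(traj, str(traj_path))
    elif traj_format == "dcd":
        topo_path = out / "topology.pdb"
        traj_path = out / "trajectory.dcd"
        write_trajectory(traj, str(topo_path), str(traj_path))
    else:
        raise ConfigError(f"unsupported trajectory format {traj_format!r}")
    truth_path = out / "ground_truth.json"
    write_ground_truth(spec, str(truth_path))
    spec_copy = out / "spec.resolved.json"
    payload = dataclasses.asdict(spec)
    payload["positions0"] = spec.positions0.tolist()
    payload.pop("atoms", None)
    with open(spec_copy, "w") as fh:
        json.dump(payload, fh, indent=2)
    logger.info("simulated %d frames of %d atoms -> %s", traj.n_frames, traj.n_atoms, traj_path)
    return {
        "trajectory": str(traj_path),
        "ground_truth": str(truth_path),
        "spec": str(spec_copy),
    }
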