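"""Formats, configuration and result plumbing.

GRO coordinate files (fixed-width, nm) are read and written through
MDAnalysis behind a thin species-aware layer; multi-frame trajectories use
either one GRO per frame or the internal columnar store
(:meth:`raftkit.bilayer.Trajectory.save`, a single ``.npz``).  Species
names longer than the 5-character GRO residue field are mapped to stable
short residue names and back.

Analysis outputs are tidy CSV tables plus a JSON summary; every output
embeds the run seed and a hash of the fully serialized configuration so a
result file is regenerable from its own header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import yaml

from .bilayer import Frame, Trajectory
from .cg_model import MoleculeSpec, build_all_species

__all__ = [
    "SPECIES_TO_RESNAME",
    "RESNAME_TO_SPECIES",
    "RunConfig",
    "read_gro",
    "read_frames",
    "write_gro",
    "write_frames",
    "write_outputs",
    "series_to_dict",
]

log = logging.getLogger("raftkit")

#: GRO residue names are at most 5 characters; variant species get stable
#: short aliases.
SPECIES_TO_RESNAME = {
    "DPPC": "DPPC", "DUPC": "DUPC", "CHOL": "CHOL",
    "DUa": "DUA", "DUs": "DUS", "DUas": "DUAS",
    "DUb2": "DUB2", "DUb3": "DUB3", "DUb23": "DUB23", "DUasb23": "DUASB",
    "DPPC_soft": "DPPCS", "DPPC_3b": "DPPC3",
    "CHOL_300": "CHO30", "CHOL_+1HB": "CHO1H", "DPPC_3b_plus1": "DPP31",
}
RESNAME_TO_SPECIES = {v: k for k, v in SPECIES_TO_RESNAME.items()}


def _mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


# --------------------------------------------------------------------------
# GRO
# --------------------------------------------------------------------------


def write_gro(frame: Frame, path) -> Path:
    """Write one frame as a GRO coordinate file (nm -> the GRO dialect's
    fixed 3-decimal columns; round-trips bit-exactly through read_gro)."""
    mda = _mda()
    path = Path(path)
    n_mols = frame.n_molecules
    resnames = [SPECIES_TO_RESNAME.get(s, s[:5]) for s in frame.species]
    u = mda.Universe.empty(
        frame.n_beads, n_residues=n_mols,
        atom_resindex=frame.mol_index, trajectory=True,
    )
    names = []
    for m in range(n_mols):
        spec = frame.registry[frame.species[m]]
        names.extend(b.name or b.bead_type for b in spec.beads)
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_mols + 1))
    u.atoms.positions = frame.pos * 10.0  # nm -> Angstrom
    z_span = frame.pos[:, 2].max() - frame.pos[:, 2].min() + 2.0
    u.dimensions = [frame.box[0] * 10, frame.box[1] * 10, z_span * 10, 90, 90, 90]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(path))
    return path


def read_gro(path, registry: dict[str, MoleculeSpec] | None = None) -> Frame:
    """Read a GRO file into a Frame (wrapped coordinates only).

    Molecules are grouped by residue; species come from the residue-name
    alias table; leaflets are assigned from head-bead z versus the global
    midplane.  Malformed records surface MDAnalysis' line diagnostics.
    """
    mda = _mda()
    registry = registry or build_all_species()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
    if u.dimensions is None or not np.all(u.dimensions[:2] > 0):
        raise ValueError(f"{path}: GRO file lacks a box record")
    species = []
    mol_index = []
    bead_index = []
    for r_i, res in enumerate(u.residues):
        resname = res.resname
        sp = RESNAME_TO_SPECIES.get(resname, resname)
        if sp not in registry:
            raise ValueError(f"{path}: unknown residue/species {resname!r}")
        if len(res.atoms) != registry[sp].n_beads:
            raise ValueError(
                f"{path}: residue {r_i + 1} ({resname}) has {len(res.atoms)} "
                f"atoms, expected {registry[sp].n_beads}"
            )
        species.append(sp)
        mol_index.extend([r_i] * len(res.atoms))
        bead_index.extend(range(1, len(res.atoms) + 1))
    frame = Frame(
        pos=u.atoms.positions.astype(float) / 10.0,
        box=u.dimensions[:2].astype(float) / 10.0,
        time=0.0,
        mol_index=np.array(mol_index),
        bead_index=np.array(bead_index),
        species=np.array(species, dtype="U16"),
        leaflet=np.zeros(len(species), dtype=int),
        registry=registry,
        upos=None,
    )
    from .observables import assign_leaflets

    frame.leaflet = assign_leaflets(frame).labels
    return frame


def write_frames(traj: Trajectory | Frame, path_or_dir) -> list[Path]:
    """Write a Frame to one GRO file, or a Trajectory to one GRO per frame
    inside a directory (frame_0000.gro, ...)."""
    if isinstance(traj, Frame):
        return [write_gro(traj, path_or_dir)]
    outdir = Path(path_or_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    return [
        write_gro(f, outdir / f"frame_{i:04d}.gro") for i, f in enumerate(traj)
    ]


def read_frames(paths, registry=None, dt: float = 1.0) -> Trajectory:
    """Read a sorted list of GRO files as a wrapped-only Trajectory."""
    frames = []
    for i, p in enumerate(sorted(Path(p) for p in paths)):
        f = read_gro(p, registry)
        f.time = i * dt
        frames.append(f)
    return Trajectory(frames)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Fully serializable description of a generator/analysis run."""

    scenario: str = "mixed"
    seed: int = 0
    counts: dict[str, int] | None = None
    box_xy: float | None = None
    n_frames: int = 21
    dt: float = 1.0
    registration: float = 1.0
    domain_geometry: str = "stripe"
    asymmetric: bool = False
    cell_size: float = 1.5
    s_gel: float = 0.8
    s_lo: float = 0.45
    out: str = "."

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# --------------------------------------------------------------------------
# Outputs
# --------------------------------------------------------------------------


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if dataclasses.is_dataclass(x) and not isinstance(x, type):
        return _jsonable(dataclasses.asdict(x))
    if isinstance(x, float) and (np.isnan(x) or np.isinf(x)):
        return None
    return x


def write_outputs(tables: dict, summaries: dict, outdir, config: RunConfig) -> dict:
    """Write tidy CSV tables and a JSON summary; both carry the seed and
    the config hash so any result is regenerable."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = {"seed": config.seed, "config_hash": config.config_hash,
              "config": config.to_dict()}
    paths = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    summary = {**header, "results": _jsonable(summaries), "tables": paths}
    sp = outdir / "summary.json"
    sp.write_text(json.dumps(summary, indent=2))
    log.info("wrote %s (seed=%d, config=%s)", sp, config.seed, config.config_hash)
    return summary


def series_to_dict(series) -> dict:
    """JSON-ready view of an ObservableSeries."""
    return _jsonable({
        "time": series.time,
        "S": series.S,
        "E": series.E,
        "dE": series.dE,
        "corr": series.corr,
        "corr_species": series.corr_species,
        "largest_domain_fraction": series.largest_domain_fraction,
        "n_replicates": series.n_replicates,
        "S_se": series.S_se,
        "E_se": series.E_se,
        "notes": series.notes,
    })
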