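"""Synthetic bilayer configurations and trajectories.

Desk-scale stand-ins for microsecond coarse-grained MD of a ~20 nm
DPPC/DUPC/CHOL bilayer.  The generator does not integrate forces; it
constructs configurations and kinematic trajectories carrying the
statistical signatures the analysis layer consumes:

* a two-leaflet composition (default 510 DPPC : 810 DUPC : 238 CHOL over
  both leaflets, i.e. mole fractions 0.34 : 0.51 : 0.15),
* mixed, phase-separated, or gel lateral layouts, with a controllable
  cross-leaflet registration of the saturated-lipid/cholesterol domain,
* per-species, per-phase chain order parameters realized exactly through
  the chain-construction geometry,
* per-species head/tail z placement with a tunable tail-tail gap across
  the midplane (negative gap = interdigitated),
* per-phase lateral Brownian diffusion with optional gel arrest,
* optional leaflet asymmetry (one leaflet pure DUPC).

Chain geometry: each chain bond makes a fixed polar angle theta* with the
bilayer normal, cos^2(theta*) = (2*S + 1)/3, so the P2 order parameter of
the chain bonds equals the target S exactly; azimuths advance by a fixed
increment along the chain (keeping beads self-avoiding) with a random
per-chain offset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cg_model import MoleculeSpec, build_all_species

__all__ = [
    "CompositionSpec",
    "PhaseLayout",
    "DynamicsParams",
    "OrderTargets",
    "Frame",
    "Trajectory",
    "OverfullBoxError",
    "build_bilayer",
    "sample_chain_orientation",
    "simulate_lateral_dynamics",
    "generate_timecourse",
    "TimecourseParams",
    "write_frames",
    "species_family",
]

BOND_LENGTH_NM = 0.47
#: Spacing between consecutive beads along a sterol body.
STEROL_BEAD_SPACING_NM = 0.30
#: Azimuth increment along a chain (degrees); keeps successive beads from
#: overlapping even for fully in-plane chains.
CHAIN_AZIMUTH_STEP_DEG = 100.0

#: Default projected area per placed molecule (nm^2).
AREA_LIPID_NM2 = 0.64
AREA_STEROL_NM2 = 0.32


class OverfullBoxError(ValueError):
    """Raised when a leaflet's molecules cannot fit the box at the
    configured molecular areas."""


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------


def _default_counts() -> dict[str, int]:
    return {"DPPC": 255, "DUPC": 405, "CHOL": 119}


@dataclass
class CompositionSpec:
    """Per-leaflet species counts plus box geometry.

    ``box_xy=None`` sizes the (square) box to the smallest side that holds
    the composition at the configured per-molecule areas; the default
    composition then yields a box of ~21.5 nm, the ~20 nm class of system
    the analyses are designed around.  ``temperature_label`` is metadata
    only (no thermostat exists here).
    """

    counts: dict[str, int] = field(default_factory=_default_counts)
    box_xy: float | None = None
    temperature_label: float = 295.0
    area_per_molecule: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("species counts must be non-negative")

    def area_of(self, species: str, registry: dict[str, MoleculeSpec]) -> float:
        if species in self.area_per_molecule:
            return self.area_per_molecule[species]
        return AREA_STEROL_NM2 if registry[species].is_sterol else AREA_LIPID_NM2

    def required_area(self, registry: dict[str, MoleculeSpec]) -> float:
        return sum(n * self.area_of(s, registry) for s, n in self.counts.items())

    def resolve_box(self, registry: dict[str, MoleculeSpec]) -> float:
        need = self.required_area(registry)
        if self.box_xy is None:
            return math.sqrt(need) if need > 0 else 1.0
        if need > self.box_xy**2 * (1 + 1e-9):
            raise OverfullBoxError(
                f"composition needs {need:.1f} nm^2 but box offers "
                f"{self.box_xy**2:.1f} nm^2"
            )
        return self.box_xy


@dataclass
class PhaseLayout:
    """Lateral organization of the bilayer.

    ``registration`` is the target cross-leaflet correlation of the
    ordered-domain placement (ignored for mixed layouts).  The ordered
    domain collects ``domain_species`` (default: every non-DU species,
    i.e. the saturated lipid plus the sterol or its mimic).
    """

    state: str = "mixed"  # mixed | separated | gel
    registration: float = 1.0
    domain_geometry: str = "stripe"  # stripe | disc
    domain_species: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.state not in ("mixed", "separated", "gel"):
            raise ValueError(f"unknown layout state {self.state!r}")
        if self.domain_geometry not in ("stripe", "disc"):
            raise ValueError(f"unknown domain geometry {self.domain_geometry!r}")
        if not -1.0 <= self.registration <= 1.0:
            raise ValueError("registration target must lie in [-1, 1]")

    def is_domain_species(self, species: str) -> bool:
        if self.domain_species is not None:
            return species in self.domain_species
        return not species.startswith("DU")

    def phase_of(self, species: str) -> str:
        """Phase label assigned to a species under this layout."""
        if self.state == "mixed":
            return "Ld"
        if self.state == "gel":
            return "gel"
        return "Lo" if self.is_domain_species(species) else "Ld"


@dataclass
class DynamicsParams:
    """Per-species, per-phase lateral diffusion constants (nm^2/ns).

    Lookup order: ``D[species][phase]``, then ``D[species]["*"]``, then
    ``default_D``.  With ``gel_arrest`` molecules in gel domains are
    frozen outright.
    """

    D: dict[str, dict[str, float]] = field(default_factory=dict)
    default_D: float = 0.1
    n_frames: int = 100
    dt: float = 1.0  # ns between saved frames
    seed: int = 0
    gel_arrest: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for per_phase in self.D.values():
            if any(d < 0 for d in per_phase.values()):
                raise ValueError("diffusion constants must be non-negative")
        if self.default_D < 0:
            raise ValueError("diffusion constants must be non-negative")

    def d_of(self, species: str, phase: str) -> float:
        if self.gel_arrest and phase == "gel":
            return 0.0
        per_phase = self.D.get(species, {})
        return per_phase.get(phase, per_phase.get("*", self.default_D))


def _default_s_targets() -> dict[str, dict[str, float]]:
    # Phase-typical chain order: unsaturated lipid near 0.3 throughout,
    # disordered saturated lipid below the liquid-ordered boundary,
    # ordered-domain values near 0.7-0.8, gel around 0.9.
    return {
        "DPPC": {"Ld": 0.40, "Lo": 0.70, "gel": 0.90},
        "DUPC": {"Ld": 0.30, "Lo": 0.35, "gel": 0.90},
        "CHOL": {"Ld": 0.60, "Lo": 0.80, "gel": 0.92},
    }


def species_family(species: str) -> str:
    """Map a variant species onto the standard family whose targets it
    inherits (DU* -> DUPC; the CHOL-mimic DPPC_3b* -> CHOL; DPPC* -> DPPC;
    CHOL* -> CHOL)."""
    if species.startswith("DU"):
        return "DUPC"
    if "3b" in species:
        return "CHOL"
    if species.startswith("DPPC"):
        return "DPPC"
    if species.startswith("CHOL"):
        return "CHOL"
    raise KeyError(f"no target family for species {species!r}")


@dataclass
class OrderTargets:
    """Target chain order and z placement per species.

    ``S`` maps species -> phase -> target order parameter in [-0.5, 1].
    ``head_z`` / ``tail_z`` are distances (nm) of head and terminal tail
    beads from the local midplane; unset tail heights default to half the
    ``interdigitation_gap``, the signed z separation between opposing
    terminal tail beads (negative = interdigitated).
    """

    S: dict[str, dict[str, float]] = field(default_factory=_default_s_targets)
    head_z: dict[str, float] = field(default_factory=dict)
    tail_z: dict[str, float] = field(default_factory=dict)
    interdigitation_gap: float = 0.4
    #: In the gel the straightened tails withdraw from the midplane; the
    #: cross-leaflet gap widens to ~2 x 0.35 nm.
    gel_interdigitation_gap: float = 0.7

    def __post_init__(self) -> None:
        for per_phase in self.S.values():
            for s in per_phase.values():
                if not -0.5 <= s <= 1.0:
                    raise ValueError(f"order target {s} outside [-0.5, 1]")

    def s_for(self, species: str, phase: str) -> float:
        table = self.S.get(species) or self.S[species_family(species)]
        return table[phase]

    def head_z_for(self, species: str, registry: dict[str, MoleculeSpec]) -> float:
        if species in self.head_z:
            return self.head_z[species]
        return 1.6 if registry[species].is_sterol else 2.0

    def tail_z_for(self, species: str, phase: str = "Ld") -> float:
        if species in self.tail_z:
            return self.tail_z[species]
        gap = self.gel_interdigitation_gap if phase == "gel" else self.interdigitation_gap
        return gap / 2.0


# --------------------------------------------------------------------------
# Frame / Trajectory containers
# --------------------------------------------------------------------------


@dataclass
class Frame:
    """One configuration: per-bead coordinates plus molecule metadata.

    Beads of a molecule are stored contiguously in topology order, so the
    bead with 1-based index ``i`` of molecule ``m`` sits at flat position
    ``mol_start[m] + i - 1``.  ``upos`` carries unwrapped coordinates
    (identical to ``pos`` for freshly built frames); frames read from
    wrapped-only files have ``upos=None``.
    """

    pos: np.ndarray  # (n_beads, 3) nm, wrapped into the box in x/y
    box: np.ndarray  # (2,) nm
    time: float  # ns
    mol_index: np.ndarray  # (n_beads,) molecule id per bead
    bead_index: np.ndarray  # (n_beads,) 1-based index within molecule
    species: np.ndarray  # (n_molecules,) species name per molecule
    leaflet: np.ndarray  # (n_molecules,) +1 upper / -1 lower
    registry: dict[str, MoleculeSpec]
    upos: np.ndarray | None = None
    mol_phase: np.ndarray | None = None  # generator metadata (Ld/Lo/gel)
    mol_slots: list | None = None  # lattice slots per molecule (not serialized)

    @property
    def n_beads(self) -> int:
        return len(self.pos)

    @property
    def n_molecules(self) -> int:
        return len(self.species)

    @property
    def mol_start(self) -> np.ndarray:
        start = getattr(self, "_mol_start", None)
        if start is None:
            counts = np.bincount(self.mol_index, minlength=self.n_molecules)
            start = np.concatenate(([0], np.cumsum(counts)))
            self._mol_start = start
        return start

    def molecules_of(self, species: str | None = None,
                     leaflet: int | None = None) -> np.ndarray:
        """Molecule ids filtered by species and/or leaflet."""
        mask = np.ones(self.n_molecules, dtype=bool)
        if species is not None:
            mask &= self.species == species
        if leaflet is not None:
            mask &= self.leaflet == leaflet
        return np.flatnonzero(mask)

    def bead_positions(self, mols: np.ndarray, bead_index: int,
                       unwrapped: bool = False) -> np.ndarray:
        arr = self.upos if unwrapped else self.pos
        return arr[self.mol_start[mols] + bead_index - 1]

    def head_positions(self, mols: np.ndarray) -> np.ndarray:
        heads = np.array([self.registry[s].head_index for s in self.species[mols]])
        return self.pos[self.mol_start[mols] + heads - 1]

    def tail_flat_indices(self, mols: np.ndarray) -> np.ndarray:
        """Flat bead indices of every terminal tail bead of the molecules."""
        out = []
        for m in mols:
            for t in self.registry[self.species[m]].tail_indices:
                out.append(self.mol_start[m] + t - 1)
        return np.array(out, dtype=int)

    def mol_centroids(self, unwrapped: bool = False) -> np.ndarray:
        """Per-molecule centroid of bead coordinates, (n_molecules, 3)."""
        arr = self.upos if unwrapped else self.pos
        if arr is None:
            raise ValueError("frame carries no unwrapped coordinates")
        sums = np.zeros((self.n_molecules, 3))
        np.add.at(sums, self.mol_index, arr)
        counts = np.bincount(self.mol_index, minlength=self.n_molecules)
        return sums / counts[:, None]

    def copy(self) -> "Frame":
        return Frame(
            pos=self.pos.copy(),
            box=self.box.copy(),
            time=self.time,
            mol_index=self.mol_index,
            bead_index=self.bead_index,
            species=self.species,
            leaflet=self.leaflet,
            registry=self.registry,
            upos=None if self.upos is None else self.upos.copy(),
            mol_phase=self.mol_phase,
            mol_slots=self.mol_slots,
        )


@dataclass
class Trajectory:
    """A time-ordered sequence of frames sharing one topology."""

    frames: list[Frame]

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def has_unwrapped(self) -> bool:
        return all(f.upos is not None for f in self.frames)

    def save(self, path) -> None:
        """Persist to the internal columnar store (single .npz file)."""
        f0 = self.frames[0]
        np.savez_compressed(
            path,
            times=self.times,
            pos=np.stack([f.pos for f in self.frames]),
            upos=(np.stack([f.upos for f in self.frames])
                  if self.has_unwrapped else np.zeros(0)),
            box=f0.box,
            mol_index=f0.mol_index,
            bead_index=f0.bead_index,
            species=f0.species.astype("U"),
            leaflet=f0.leaflet,
            mol_phase=(f0.mol_phase.astype("U") if f0.mol_phase is not None
                       else np.zeros(0)),
        )

    @classmethod
    def load(cls, path, registry: dict[str, MoleculeSpec] | None = None) -> "Trajectory":
        data = np.load(path, allow_pickle=False)
        registry = registry or build_all_species()
        upos = data["upos"] if data["upos"].size else None
        phase = data["mol_phase"] if data["mol_phase"].size else None
        frames = []
        for i, t in enumerate(data["times"]):
            frames.append(Frame(
                pos=data["pos"][i],
                box=data["box"],
                time=float(t),
                mol_index=data["mol_index"],
                bead_index=data["bead_index"],
                species=data["species"],
                leaflet=data["leaflet"],
                registry=registry,
                upos=None if upos is None else upos[i],
                mol_phase=phase,
            ))
        return cls(frames)


# --------------------------------------------------------------------------
# Chain geometry
# --------------------------------------------------------------------------


def polar_angle_for_order(s_target: float) -> float:
    """Polar angle theta* (rad) whose P2 statistic equals ``s_target``."""
    if not -0.5 <= s_target <= 1.0:
        raise ValueError(f"order target {s_target} outside [-0.5, 1]")
    cos2 = (2.0 * s_target + 1.0) / 3.0
    return math.acos(math.sqrt(cos2))


def sample_chain_orientation(
    s_target: float,
    n_chains: int = 1,
    n_bonds: int = 3,
    seed: int | np.random.Generator = 0,
    phi0: float | None = None,
) -> np.ndarray:
    """Unit bond vectors realizing a target P2 order parameter.

    Every bond makes the deterministic polar angle theta* with z
    (cos^2 theta* = (2*S+1)/3); azimuths start uniformly at random per
    chain (or at the fixed ``phi0``) and advance by a fixed 100-degree
    step along the chain, which keeps the resulting bead chain
    self-avoiding at bead scale.

    Returns an array of shape (n_chains, n_bonds, 3).
    """
    theta = polar_angle_for_order(s_target)
    if phi0 is None:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        start = rng.uniform(0.0, 2.0 * math.pi, size=n_chains)
    else:
        start = np.full(n_chains, phi0)
    step = math.radians(CHAIN_AZIMUTH_STEP_DEG)
    phi = start[:, None] + step * np.arange(n_bonds)[None, :]
    st, ct = math.sin(theta), math.cos(theta)
    vec = np.empty((n_chains, n_bonds, 3))
    vec[..., 0] = st * np.cos(phi)
    vec[..., 1] = st * np.sin(phi)
    vec[..., 2] = ct
    return vec


# --------------------------------------------------------------------------
# Bilayer construction
# --------------------------------------------------------------------------


def _stripe_offset(registration: float, domain_fraction: float, box: float) -> float:
    """Lateral shift of the lower-leaflet domain producing the requested
    cross-leaflet density correlation.

    For a periodic stripe covering an area fraction f, the Pearson
    correlation between the occupancy field and a copy shifted by ``d`` is
    r(d) = ((f - d/L) - f^2) / (f (1 - f)); inverting gives
    d = f (1 - f) (1 - r) L.
    """
    f = min(max(domain_fraction, 1e-9), 1 - 1e-9)
    d = f * (1.0 - f) * (1.0 - registration) * box
    return min(d, box / 2.0)


def _n_slots(spec: MoleculeSpec) -> int:
    """Lattice slots a molecule occupies: one per acyl chain for lipids,
    one for sterol bodies (consistent with the 2:1 lipid:sterol area)."""
    if spec.is_sterol:
        return 1
    return max(1, len(spec.chains))


def _allocate_slots(
    species_list: np.ndarray,
    layout: PhaseLayout,
    registry: dict[str, MoleculeSpec],
    box: float,
    lower: bool,
    rng: np.random.Generator,
    assign_seed: int,
) -> list[np.ndarray]:
    """Per-molecule lateral slot coordinates on a chain-level lattice.

    Each leaflet is a square lattice with one slot per acyl chain (the
    lower leaflet staggered by half a pitch so opposing tails are not in
    lateral registry).  In separated/gel layouts the slot sequence is
    sorted by stripe (or disc) key and both leaflets draw their molecule
    order from the same seeded stream, so a registration target of 1
    yields identical domain placement in the two leaflets and lower
    targets shift the lower-leaflet domain laterally.
    """
    m = len(species_list)
    slots_per_mol = np.array([_n_slots(registry[s]) for s in species_list])
    total = int(slots_per_mol.sum())
    n_side = max(1, math.ceil(math.sqrt(total)))
    pitch = box / n_side
    idx = np.arange(n_side * n_side)
    xy = np.column_stack([(idx % n_side) + 0.5, (idx // n_side) + 0.5]) * pitch

    if layout.state == "mixed":
        mol_order = rng.permutation(m)
        slot_order = np.arange(n_side * n_side)
    else:
        is_domain = np.array([layout.is_domain_species(s) for s in species_list])
        frac = slots_per_mol[is_domain].sum() / total
        offset = _stripe_offset(layout.registration, frac, box) if lower else 0.0
        if layout.domain_geometry == "stripe":
            key = np.mod(xy[:, 0] - offset, box)
        else:
            center = np.array([box / 2.0 + offset, box / 2.0])
            d = xy - center
            d -= box * np.round(d / box)
            key = np.hypot(d[:, 0], d[:, 1])
        slot_order = np.argsort(key, kind="stable")
        # identical molecule order in both leaflets: registration is then
        # controlled purely by the lateral offset of the slot sorting
        arng = np.random.default_rng(assign_seed)
        dom = np.flatnonzero(is_domain)
        rest = np.flatnonzero(~is_domain)
        mol_order = np.concatenate([arng.permutation(dom), arng.permutation(rest)])

    slots: list[np.ndarray] = [np.empty(0)] * m
    cursor = 0
    for mol in mol_order:
        k = slots_per_mol[mol]
        slots[mol] = xy[slot_order[cursor:cursor + k]]
        cursor += k
    return slots


#: Fallback first-bond azimuth for near-flat chains.
_PHI0 = math.radians(45.0)
#: Spatial frequency (rad/nm) of the shared packing helix: the lateral
#: offset of a hydrophobic bead is a common function of its distance from
#: the midplane, so equal-depth beads of neighboring molecules stay a full
#: lattice pitch apart regardless of species.
_HELIX_OMEGA = 2.0 * math.pi / 1.4
#: Half-length (nm) of the tilted sterol order-axis segment.
_STEROL_AXIS_HALF = 0.1


def _helix_radius(theta: float) -> float | None:
    """Radius of the z-locked helix whose bonds realize polar angle theta.

    A chain whose beads sit on a helix of radius rho with azimuth
    omega * zeta (zeta = distance from the midplane) has bond lateral
    length 2 rho sin(omega dz / 2) for a bond rise dz; choosing rho so
    that this equals b sin(theta) makes every bond hit theta exactly.
    Returns None for near-flat chains (dz -> 0), where the construction
    degenerates and a plain azimuth walk is used instead.
    """
    dz = BOND_LENGTH_NM * math.cos(theta)
    s = math.sin(_HELIX_OMEGA * dz / 2.0)
    if math.cos(theta) < 0.1 or s < 1e-9:
        return None
    return BOND_LENGTH_NM * math.sin(theta) / (2.0 * s)


def _build_molecule(
    spec: MoleculeSpec,
    slots: np.ndarray,
    sign: int,
    s_target: float,
    head_z: float,
    tail_z: float,
) -> np.ndarray:
    """Bead coordinates (n_beads, 3) for one molecule on its lattice slots.

    The head/linker backbone stacks above the first slot; each acyl chain
    descends from its own slot on the shared packing helix with every bond
    at the deterministic polar angle realizing ``s_target``, anchored so
    the terminal tail bead lands exactly at ``sign * tail_z``.  Sterol
    bodies are bead columns on the same helix whose order-axis segment is
    tilted to the target polar angle, head bead at ``sign * head_z``.
    The helix phase is offset by pi between leaflets so opposing terminal
    tails avoid lateral registry at the midplane.
    """
    n = spec.n_beads
    pos = np.zeros((n, 3))
    theta = polar_angle_for_order(s_target)
    ct = math.cos(theta)
    chain_beads = {i for ch in spec.chains for i in ch}
    anchor = slots[0]
    phase0 = 0.0 if sign > 0 else math.pi

    def helix_xy(site: np.ndarray, zeta: float, rho: float) -> np.ndarray:
        ph = _HELIX_OMEGA * zeta + phase0
        return site + rho * np.array([math.cos(ph), math.sin(ph)])

    if spec.is_sterol:
        body = [b.index for b in spec.beads if b.role in ("ring", "chain", "tail")]
        heads = [b.index for b in spec.beads if b.index not in body]
        top_z = head_z - 0.25
        spacing = (top_z - tail_z) / max(1, len(body) - 1)
        rho = _helix_radius(theta) or 0.0
        zetas = {i: top_z - rank * spacing for rank, i in enumerate(body)}
        for i in body:
            xy = helix_xy(anchor, zetas[i], rho)
            pos[i - 1] = [xy[0], xy[1], sign * zetas[i]]
        if spec.order_axis is not None:
            # exact order axis: a short tilted segment about its midpoint
            a, b = spec.order_axis
            mid = (pos[a - 1] + pos[b - 1]) / 2.0
            ph = _HELIX_OMEGA * (zetas[a] + zetas[b]) / 2.0 + phase0
            u = np.array([math.sin(theta) * math.cos(ph),
                          math.sin(theta) * math.sin(ph),
                          sign * ct])
            pos[a - 1] = mid + _STEROL_AXIS_HALF * u
            pos[b - 1] = mid - _STEROL_AXIS_HALF * u
        for rank, i in enumerate(sorted(heads)):
            pos[i - 1] = [anchor[0], anchor[1], sign * (head_z + 0.25 * rank)]
        return pos

    # Phosphatidylcholine-like: backbone column above the first slot, then
    # one helix descent per chain from that chain's own slot.
    depth_rank = 0
    for b in spec.beads:
        if b.index in chain_beads:
            continue
        pos[b.index - 1] = [anchor[0], anchor[1], sign * (head_z - 0.15 * depth_rank)]
        depth_rank += 1
    for c, chain in enumerate(spec.chains):
        nb = len(chain) - 1
        site = slots[min(c, len(slots) - 1)]
        rho = _helix_radius(theta)
        if rho is not None:
            for k, bead in enumerate(chain):
                zeta = tail_z + (nb - k) * BOND_LENGTH_NM * ct
                xy = helix_xy(site, zeta, rho)
                pos[bead - 1] = [xy[0], xy[1], sign * zeta]
        else:
            # near-flat chain: plain fixed-step azimuth walk
            bonds = sample_chain_orientation(s_target, 1, nb, phi0=_PHI0)[0]
            bonds[:, 2] *= -sign
            pos[chain[0] - 1] = [site[0], site[1],
                                 sign * (tail_z + nb * BOND_LENGTH_NM * ct)]
            for j in range(nb):
                pos[chain[j + 1] - 1] = pos[chain[j] - 1] + BOND_LENGTH_NM * bonds[j]
    return pos


def build_bilayer(
    comp: CompositionSpec | None = None,
    layout: PhaseLayout | None = None,
    order: OrderTargets | None = None,
    asymmetric: bool = False,
    seed: int = 0,
    registry: dict[str, MoleculeSpec] | None = None,
) -> Frame:
    """Construct a two-leaflet bilayer Frame.

    With ``asymmetric=True`` the lower leaflet is replaced by pure DUPC at
    matched occupied area.  Deterministic for a fixed seed.
    """
    comp = comp or CompositionSpec()
    layout = layout or PhaseLayout()
    order = order or OrderTargets()
    registry = registry or build_all_species()
    for s in comp.counts:
        if s not in registry:
            raise KeyError(f"unknown species {s!r}")
    rng = np.random.default_rng(seed)
    box = comp.resolve_box(registry)

    leaflet_species: dict[int, np.ndarray] = {}
    upper = np.concatenate(
        [np.repeat(s, n) for s, n in sorted(comp.counts.items())]
    ) if comp.counts else np.array([], dtype="U16")
    leaflet_species[+1] = upper
    if asymmetric:
        need = comp.required_area(registry)
        n_dupc = int(round(need / comp.area_of("DUPC", {**registry})))
        leaflet_species[-1] = np.repeat("DUPC", n_dupc)
    else:
        leaflet_species[-1] = upper.copy()

    pos_blocks: list[np.ndarray] = []
    mol_species: list[str] = []
    mol_leaflet: list[int] = []
    mol_phase: list[str] = []
    mol_index: list[np.ndarray] = []
    bead_index: list[np.ndarray] = []
    mol_slots: list[np.ndarray] = []
    mol_id = 0
    for sign in (+1, -1):
        species_list = leaflet_species[sign]
        slots = _allocate_slots(species_list, layout, registry, box,
                                lower=(sign == -1), rng=rng,
                                assign_seed=seed + 7919)
        for s, slot in zip(species_list, slots):
            spec = registry[s]
            phase = layout.phase_of(s)
            if asymmetric and sign == -1:
                phase = "Ld"
            pos = _build_molecule(
                spec, slot, sign,
                order.s_for(s, phase),
                order.head_z_for(s, registry),
                order.tail_z_for(s, phase),
            )
            pos_blocks.append(pos)
            mol_species.append(s)
            mol_leaflet.append(sign)
            mol_phase.append(phase)
            mol_index.append(np.full(spec.n_beads, mol_id))
            bead_index.append(np.arange(1, spec.n_beads + 1))
            mol_slots.append(slot)
            mol_id += 1

    upos = np.concatenate(pos_blocks)
    pos = upos.copy()
    pos[:, :2] = np.mod(pos[:, :2], box)
    frame = Frame(
        pos=pos,
        box=np.array([box, box]),
        time=0.0,
        mol_index=np.concatenate(mol_index),
        bead_index=np.concatenate(bead_index),
        species=np.array(mol_species, dtype="U16"),
        leaflet=np.array(mol_leaflet),
        registry=registry,
        upos=upos,
        mol_phase=np.array(mol_phase, dtype="U8"),
    )
    frame.mol_slots = mol_slots  # lattice metadata for timecourse rebuilds
    return frame


# --------------------------------------------------------------------------
# Dynamics
# --------------------------------------------------------------------------


def simulate_lateral_dynamics(
    frame0: Frame,
    dyn: DynamicsParams,
    layout: PhaseLayout | None = None,
) -> Trajectory:
    """Per-molecule 2D Brownian motion with per-phase diffusion constants.

    Each molecule translates rigidly; displacements accumulate in unwrapped
    coordinates and are wrapped into the box for the wrapped view.
    Molecules labelled ``gel`` are frozen when ``dyn.gel_arrest`` is set.
    """
    rng = np.random.default_rng(dyn.seed)
    m = frame0.n_molecules
    if frame0.mol_phase is not None:
        phases = frame0.mol_phase
    elif layout is not None:
        phases = np.array([layout.phase_of(s) for s in frame0.species])
    else:
        phases = np.repeat("Ld", m)
    d_mol = np.array([dyn.d_of(s, p) for s, p in zip(frame0.species, phases)])
    sigma = np.sqrt(2.0 * d_mol * dyn.dt)  # per-axis step std dev

    frames = [frame0]
    upos = frame0.upos.copy() if frame0.upos is not None else frame0.pos.copy()
    box = frame0.box
    for i in range(1, dyn.n_frames + 1):
        step = rng.normal(size=(m, 2)) * sigma[:, None]
        upos = upos.copy()
        upos[:, :2] += step[frame0.mol_index]
        pos = upos.copy()
        pos[:, :2] = np.mod(pos[:, :2], box)
        f = frame0.copy()
        f.pos, f.upos, f.time = pos, upos, frame0.time + i * dyn.dt
        frames.append(f)
    return Trajectory(frames)


# --------------------------------------------------------------------------
# Scenario timecourses
# --------------------------------------------------------------------------


@dataclass
class TimecourseParams:
    """Knobs for :func:`generate_timecourse`."""

    comp: CompositionSpec | None = None
    order: OrderTargets | None = None
    n_frames: int = 21
    dt: float = 1.0  # ns
    registration: float = 1.0
    domain_geometry: str = "stripe"
    #: Fraction of the timecourse over which the transformation completes
    #: (the remainder is static -- for gelation this produces the arrest).
    schedule_end: float = 1.0


def _regroup_for_layout(
    start: Frame,
    layout: PhaseLayout,
    registry: dict[str, MoleculeSpec],
    assign_seed: int,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Reassign molecules to the frame's existing lattice slot-groups so
    the lateral occupancy realizes ``layout``.

    The physical slot-groups (one per molecule, sized by its chain count)
    are kept; only which molecule sits on which same-size group changes.
    Returns the new per-molecule slot arrays plus the permutation ``pi``
    with ``pi[m]`` = the molecule that originally owned m's new group, so
    the rearrangement decomposes into exchange cycles.
    """
    box = start.box[0]
    new_slots: list[np.ndarray | None] = [None] * start.n_molecules
    pi = np.arange(start.n_molecules)
    for sign in (+1, -1):
        mols = np.flatnonzero(start.leaflet == sign)
        if mols.size == 0:
            continue
        sizes = np.array([len(start.mol_slots[m]) for m in mols])
        centroids = np.stack([start.mol_slots[m].mean(axis=0) for m in mols])
        is_domain = np.array([layout.is_domain_species(start.species[m])
                              for m in mols])
        frac = sizes[is_domain].sum() / sizes.sum()
        offset = (_stripe_offset(layout.registration, frac, box)
                  if sign == -1 else 0.0)
        if layout.domain_geometry == "stripe":
            key = np.mod(centroids[:, 0] - offset, box)
        else:
            center = np.array([box / 2.0 + offset, box / 2.0])
            d = centroids - center
            d -= box * np.round(d / box)
            key = np.hypot(d[:, 0], d[:, 1])
        group_order = np.argsort(key, kind="stable")
        # separated layouts reuse one stream so the leaflets mirror (the
        # registration offset alone controls cross-leaflet placement);
        # mixed layouts shuffle each leaflet independently
        arng = np.random.default_rng(
            assign_seed if layout.state != "mixed" else assign_seed + (sign < 0)
        )
        if layout.state == "mixed":
            mol_queue = list(mols[arng.permutation(len(mols))])
        else:
            dom = mols[is_domain]
            rest = mols[~is_domain]
            mol_queue = list(np.concatenate([arng.permutation(dom),
                                             arng.permutation(rest)]))
        by_size: dict[int, list[int]] = {}
        for m in mol_queue:
            by_size.setdefault(len(start.mol_slots[m]), []).append(m)
        for g in group_order:
            owner = mols[g]
            k = len(start.mol_slots[owner])
            m = by_size[k].pop(0)
            new_slots[m] = start.mol_slots[owner]
            pi[m] = owner
    return new_slots, pi


def _cycles_of(pi: np.ndarray) -> list[list[int]]:
    seen = np.zeros(len(pi), dtype=bool)
    cycles = []
    for m in range(len(pi)):
        if seen[m]:
            continue
        cyc = []
        cur = m
        while not seen[cur]:
            seen[cur] = True
            cyc.append(cur)
            cur = int(pi[cur])
        if len(cyc) > 1:
            cycles.append(cyc)
    return cycles


def generate_timecourse(
    scenario: str,
    params: TimecourseParams | None = None,
    seed: int = 0,
) -> Trajectory:
    """Trajectory carrying a constructed mixing/demixing/gelation course.

    ``demixing``: mixed -> separated (order rising, domains registering).
    ``remixing``: separated -> mixed (order and correlation reverting).
    ``gelation``: mixed -> separated gel; the schedule completes at 70% of
    the frames and the system is frozen afterwards (MSD arrest).

    Lateral rearrangement is exchange dynamics on the fixed chain lattice:
    the permutation taking the initial occupancy to the final one is
    decomposed into exchange cycles which switch atomically at frames
    spread over the schedule, so every frame is a clash-free lattice
    configuration.  Chain order interpolates linearly (and hence
    monotonically) between the initial and final per-phase targets.
    """
    params = params or TimecourseParams()
    registry = build_all_species()
    comp = params.comp or CompositionSpec()
    order = params.order or OrderTargets()

    if scenario == "demixing":
        lay_a = PhaseLayout(state="mixed")
        lay_b = PhaseLayout(state="separated", registration=params.registration,
                            domain_geometry=params.domain_geometry)
        schedule_end = params.schedule_end
    elif scenario == "remixing":
        lay_a = PhaseLayout(state="separated", registration=params.registration,
                            domain_geometry=params.domain_geometry)
        lay_b = PhaseLayout(state="mixed")
        schedule_end = params.schedule_end
    elif scenario == "gelation":
        lay_a = PhaseLayout(state="mixed")
        lay_b = PhaseLayout(state="gel", registration=params.registration,
                            domain_geometry=params.domain_geometry)
        schedule_end = min(params.schedule_end, 0.7)
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    start = build_bilayer(comp, lay_a, order, seed=seed, registry=registry)
    end_slots, pi = _regroup_for_layout(start, lay_b, registry,
                                        assign_seed=seed + 7919)
    cycles = _cycles_of(pi)
    rng = np.random.default_rng(seed + 131)
    rng.shuffle(cycles)

    n = params.n_frames
    last_active = max(1, int(round(schedule_end * (n - 1))))
    switch_frame = {}
    for rank, cyc in enumerate(cycles):
        f_switch = 1 + (rank * last_active) // max(1, len(cycles))
        for m in cyc:
            switch_frame[m] = min(f_switch, last_active)

    end_phase = {m: ("Ld" if (scenario != "gelation"
                              and not lay_b.is_domain_species(start.species[m]))
                     else lay_b.phase_of(start.species[m]))
                 for m in range(start.n_molecules)}
    order_start = {m: order.s_for(start.species[m], str(start.mol_phase[m]))
                   for m in range(start.n_molecules)}
    order_end = {m: order.s_for(start.species[m], end_phase[m])
                 for m in range(start.n_molecules)}
    tail_start = {m: order.tail_z_for(start.species[m], str(start.mol_phase[m]))
                  for m in range(start.n_molecules)}
    tail_end = {m: order.tail_z_for(start.species[m], end_phase[m])
                for m in range(start.n_molecules)}

    frames = []
    box = start.box[0]
    for i in range(n):
        lam_raw = i / (n - 1) if n > 1 else 1.0
        lam = min(1.0, lam_raw / schedule_end) if schedule_end > 0 else 1.0
        pos_blocks = []
        for m in range(start.n_molecules):
            s = start.species[m]
            slots = (end_slots[m] if switch_frame.get(m, 0) <= i
                     else start.mol_slots[m])
            s_val = order_start[m] + lam * (order_end[m] - order_start[m])
            tail_val = tail_start[m] + lam * (tail_end[m] - tail_start[m])
            pos_blocks.append(_build_molecule(
                registry[s], slots, int(start.leaflet[m]), s_val,
                order.head_z_for(s, registry), tail_val,
            ))
        upos = np.concatenate(pos_blocks)
        pos = upos.copy()
        pos[:, :2] = np.mod(pos[:, :2], box)
        f = start.copy()
        f.pos, f.upos, f.time = pos, upos, i * params.dt
        frames.append(f)
    final_phase = np.array([end_phase[m] for m in range(start.n_molecules)],
                           dtype="U8")
    for f in frames:
        f.mol_phase = final_phase
    return Trajectory(frames)


def write_frames(traj: Trajectory | Frame, path_or_dir) -> list:
    """Write frames as GRO coordinate file(s); see :mod:`raftkit.io`."""
    from . import io as _io

    return _io.write_frames(traj, path_or_dir)
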