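"""Analysis observables for coarse-grained bilayer frames.

Implements the per-frame statistics used to characterize raft formation in
ternary lipid/cholesterol bilayers:

* leaflet assignment from head-bead z versus the global midplane,
* P2 chain order parameters, S = (3 <cos^2 theta_z> - 1)/2, averaged over
  consecutive chain bonds (sterols use their ring 3->5 axis),
* lateral mean-square displacement with multiple time origins, a log-log
  diffusive-slope fit and a gel-arrest (plateau) detector,
* 2D density grids (1.5 nm cells) and the Pearson cross-leaflet domain
  correlation computed cell-by-cell,
* local bilayer-center maps (3.0 nm cells, tail beads only, with species
  exclusions), z profiles of heads/tails relative to the local midplane,
  and the cross-leaflet tail-tail interdigitation distance,
* umbrella-model coverage of sterol heads by lipid head beads (0.25 nm /
  0.47 nm square criteria),
* pairwise nonbonded energy per species pair under the MARTINI shifted
  Lennard-Jones (shift from 0.9 nm) and shifted Coulomb (shift from 0,
  relative permittivity 15) forms with a 1.2 nm cutoff,
* plain coordinate RMSD against a reference frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .bilayer import Frame, Trajectory
from .cg_model import NonbondedMatrix

__all__ = [
    "LeafletAssignment",
    "OrderResult",
    "MSDResult",
    "GridField",
    "UmbrellaResult",
    "EnergyBreakdown",
    "InterdigitationResult",
    "assign_leaflets",
    "order_parameter",
    "msd",
    "grid_density",
    "interleaflet_correlation",
    "bilayer_center_map",
    "z_profile",
    "interdigitation",
    "umbrella_coverage",
    "pair_energy",
    "rmsd",
    "F_ELEC",
    "EPSILON_R",
]

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2.
F_ELEC = 138.935458
#: MARTINI relative dielectric screening constant.
EPSILON_R = 15.0


# --------------------------------------------------------------------------
# Leaflets
# --------------------------------------------------------------------------


@dataclass
class LeafletAssignment:
    labels: np.ndarray  # (n_molecules,) +1 / -1
    midplane_z: float
    degenerate: bool  # all molecules on one side


def assign_leaflets(frame: Frame) -> LeafletAssignment:
    """Label each molecule by the sign of its head-bead z relative to the
    global midplane (mean tail-bead z).

    A single-leaflet (degenerate) input is flagged, not rejected.  Labels
    are invariant under global translation of the frame.
    """
    all_mols = np.arange(frame.n_molecules)
    tails = frame.tail_flat_indices(all_mols)
    midplane = float(frame.pos[tails, 2].mean())
    head_z = frame.head_positions(all_mols)[:, 2]
    labels = np.where(head_z >= midplane, 1, -1)
    degenerate = bool(np.all(labels == labels[0]))
    return LeafletAssignment(labels, midplane, degenerate)


# --------------------------------------------------------------------------
# Order parameter
# --------------------------------------------------------------------------


@dataclass
class OrderResult:
    species: str
    S: float  # mean over molecules
    per_molecule: np.ndarray

    def __post_init__(self) -> None:
        if self.per_molecule.size and not (
            -0.5 - 1e-9 <= self.per_molecule.min()
            and self.per_molecule.max() <= 1.0 + 1e-9
        ):
            raise ValueError("order parameter outside [-0.5, 1]")


def _minimum_image_xy(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    vec = vec.copy()
    vec[..., :2] -= box * np.round(vec[..., :2] / box)
    return vec


def order_parameter(frame: Frame, species: str) -> OrderResult:
    """P2 order parameter of a species versus the bilayer normal (z).

    Chain-bearing molecules: per bond S_bond = (3 cos^2 theta_z - 1)/2 over
    every bond between consecutive chain beads, averaged over both chains.
    Sterols: the single axis through the molecule's order-axis beads (the
    ring 3->5 line for CHOL).
    """
    spec = frame.registry[species]
    mols = frame.molecules_of(species)
    if mols.size == 0:
        return OrderResult(species, float("nan"), np.empty(0))
    if spec.order_axis is not None:
        a, b = spec.order_axis
        vec = frame.bead_positions(mols, b) - frame.bead_positions(mols, a)
        vec = _minimum_image_xy(vec, frame.box)
        cos2 = vec[:, 2] ** 2 / np.einsum("ij,ij->i", vec, vec)
        per_mol = 1.5 * cos2 - 0.5
    elif spec.chains and any(len(ch) >= 2 for ch in spec.chains):
        cos2_sum = np.zeros(len(mols))
        n_bonds = 0
        for chain in spec.chains:
            for i, j in zip(chain[:-1], chain[1:]):
                vec = frame.bead_positions(mols, j) - frame.bead_positions(mols, i)
                vec = _minimum_image_xy(vec, frame.box)
                cos2_sum += vec[:, 2] ** 2 / np.einsum("ij,ij->i", vec, vec)
                n_bonds += 1
        per_mol = 1.5 * (cos2_sum / n_bonds) - 0.5
    else:
        raise ValueError(f"species {species!r} has neither chains nor an order axis")
    per_mol = np.clip(per_mol, -0.5, 1.0)
    return OrderResult(species, float(per_mol.mean()), per_mol)


# --------------------------------------------------------------------------
# Mean-square displacement
# --------------------------------------------------------------------------


@dataclass
class MSDResult:
    lags: np.ndarray  # ns
    msd: np.ndarray  # nm^2
    slope: float  # log-log slope over the fit window
    D: float  # nm^2/ns from the linear fit msd = 4 D t + c
    plateau: bool  # gel-like arrest detected
    fit_window: tuple[float, float]


def msd(
    traj: Trajectory,
    species: str | None = None,
    leaflet: int | None = None,
    n_lags: int = 60,
    fit_window: tuple[float, float] = (0.0, 20.0),
    plateau_slope: float = 0.2,
    max_origins: int = 50,
) -> MSDResult:
    """Lateral (x/y) MSD over molecules, with multiple time origins.

    Requires unwrapped coordinates.  The diffusive exponent is the slope of
    log(MSD) vs log(t) inside ``fit_window`` (default: lags below 20 ns,
    up to the diffusive regime); D comes from a linear fit MSD = 4 D t + c
    on the same window.  A plateau (log-log slope of the last half of the
    lag range below ``plateau_slope``) flags gel-like arrest.
    """
    if not traj.has_unwrapped:
        raise ValueError(
            "trajectory has wrapped coordinates only; provide unwrapped "
            "coordinates (e.g. from the generator or the columnar store)"
        )
    f0 = traj[0]
    mols = f0.molecules_of(species, leaflet)
    if mols.size == 0:
        raise ValueError(f"no molecules selected (species={species!r})")
    xy = np.stack([f.mol_centroids(unwrapped=True)[mols, :2] for f in traj])
    times = traj.times
    n_frames = len(traj)
    if n_frames < 2:
        raise ValueError("need at least two frames for an MSD")
    lag_idx = np.unique(np.geomspace(1, n_frames - 1, min(n_lags, n_frames - 1)).astype(int))
    msd_vals = np.empty(len(lag_idx))
    for k, lag in enumerate(lag_idx):
        origins = np.arange(0, n_frames - lag, max(1, (n_frames - lag) // max_origins))
        disp = xy[origins + lag] - xy[origins]
        msd_vals[k] = np.mean(np.sum(disp**2, axis=-1))
    lags_ns = times[lag_idx] - times[0]

    def _loglog_slope(sel: np.ndarray) -> float:
        ok = sel & (msd_vals > 0) & (lags_ns > 0)
        if ok.sum() < 2:
            return float("nan")
        return float(np.polyfit(np.log(lags_ns[ok]), np.log(msd_vals[ok]), 1)[0])

    in_window = (lags_ns > fit_window[0]) & (lags_ns <= fit_window[1])
    if in_window.sum() < 2:
        in_window = np.ones_like(lags_ns, dtype=bool)
    slope = _loglog_slope(in_window)
    if in_window.sum() >= 2:
        d_fit = float(np.polyfit(lags_ns[in_window], msd_vals[in_window], 1)[0] / 4.0)
    else:
        d_fit = float("nan")
    tail = lags_ns >= lags_ns[-1] / 2.0
    tail_slope = _loglog_slope(tail)
    # terminal immobility: no molecule moved over the last ~20% of frames
    k = max(2, n_frames // 5)
    frozen_tail = bool(np.max(np.abs(xy[-1] - xy[-k])) < 1e-6)
    arrested = bool(
        np.all(msd_vals == 0.0)
        or frozen_tail
        or (not math.isnan(tail_slope) and tail_slope < plateau_slope)
    )
    return MSDResult(lags_ns, msd_vals, slope, d_fit, arrested, fit_window)


# --------------------------------------------------------------------------
# Grids and correlation
# --------------------------------------------------------------------------


@dataclass
class GridField:
    """A 2D per-cell scalar field tiling the bilayer plane.

    The cell count per axis is round(box/cell_size) and the actual cell
    size is rescaled so the grid tiles the box exactly; every molecule
    maps to exactly one cell.
    """

    values: np.ndarray  # (n_x, n_y)
    box: np.ndarray  # (2,)
    label: str = ""
    interpolated: np.ndarray | None = None  # mask of neighbor-filled cells

    @property
    def n_x(self) -> int:
        return self.values.shape[0]

    @property
    def n_y(self) -> int:
        return self.values.shape[1]

    @property
    def cell_size(self) -> np.ndarray:
        return self.box / np.array(self.values.shape)

    def cell_of(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        wrapped = np.mod(xy, self.box)
        ix = np.minimum((wrapped[:, 0] / self.cell_size[0]).astype(int), self.n_x - 1)
        iy = np.minimum((wrapped[:, 1] / self.cell_size[1]).astype(int), self.n_y - 1)
        return ix, iy


def _grid_shape(box: np.ndarray, cell_size: float) -> tuple[int, int]:
    if cell_size > min(box):
        raise ValueError(f"cell size {cell_size} nm exceeds the box {box}")
    return (max(1, round(box[0] / cell_size)), max(1, round(box[1] / cell_size)))


def grid_density(
    frame: Frame, leaflet: int, species: str, cell_size: float = 1.5
) -> GridField:
    """Per-cell molecule count (head-bead position) of one species in one
    leaflet; cell counts sum to the species count in the leaflet."""
    shape = _grid_shape(frame.box, cell_size)
    mols = frame.molecules_of(species, leaflet)
    values = np.zeros(shape)
    if mols.size:
        gf = GridField(values, frame.box)
        ix, iy = gf.cell_of(frame.head_positions(mols)[:, :2])
        np.add.at(values, (ix, iy), 1.0)
    return GridField(values, frame.box, label=f"density:{species}:leaflet{leaflet:+d}")


def interleaflet_correlation(field_top: GridField, field_bottom: GridField) -> float:
    """Pearson correlation across corresponding cells of the two leaflets.

    Returns NaN (the 'undefined' flag) when either field is constant.
    """
    if field_top.values.shape != field_bottom.values.shape:
        raise ValueError("grid shapes differ between leaflets")
    a = field_top.values.ravel()
    b = field_bottom.values.ravel()
    if a.std() == 0.0 or b.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# --------------------------------------------------------------------------
# Bilayer center, z profiles, interdigitation
# --------------------------------------------------------------------------


def bilayer_center_map(
    frame: Frame,
    cell_size: float = 3.0,
    exclude: tuple[str, ...] = ("DPPC_3b", "DPPC_3b_plus1"),
) -> GridField:
    """Local midplane z per cell: mean z of terminal tail beads of both
    leaflets, excluding the listed species (short-tailed mimics would bias
    the center toward their own leaflet).  Empty cells are filled from
    periodic neighbor means and flagged."""
    shape = _grid_shape(frame.box, cell_size)
    mols = np.array([m for m in range(frame.n_molecules)
                     if frame.species[m] not in exclude], dtype=int)
    if mols.size == 0:
        raise ValueError("all molecules excluded from the bilayer center")
    tails = frame.tail_flat_indices(mols)
    if tails.size == 0:
        raise ValueError("no tail beads available for the bilayer center")
    sums = np.zeros(shape)
    counts = np.zeros(shape)
    gf = GridField(sums, frame.box)
    ix, iy = gf.cell_of(frame.pos[tails][:, :2])
    np.add.at(sums, (ix, iy), frame.pos[tails, 2])
    np.add.at(counts, (ix, iy), 1.0)
    values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    interpolated = counts == 0
    # iterative periodic neighbor fill for empty cells
    while np.isnan(values).any():
        nan_mask = np.isnan(values)
        neigh = np.stack([
            np.roll(values, 1, axis=0), np.roll(values, -1, axis=0),
            np.roll(values, 1, axis=1), np.roll(values, -1, axis=1),
        ])
        with np.errstate(invalid="ignore"):
            fill = np.nanmean(neigh, axis=0)
        newly = nan_mask & ~np.isnan(fill)
        if not newly.any():
            raise ValueError("bilayer-center grid is entirely empty")
        values = np.where(newly, fill, values)
    return GridField(values, frame.box, label="bilayer_center_z",
                     interpolated=interpolated)


@dataclass
class ZProfileEntry:
    species: str
    head_z: float  # nm relative to the local midplane, leaflet-folded
    tail_z: float
    interdigitated: bool  # tail beads cross the local midplane on average


def z_profile(frame: Frame, center_map: GridField | None = None) -> dict[str, ZProfileEntry]:
    """Per-species mean head and tail z relative to the local midplane.

    Both leaflets contribute with their sign folded (distances from the
    midplane are positive toward each leaflet's water phase), so the
    reported profile is symmetric across the bilayer center by
    construction and invariant under global z translation.
    """
    if center_map is None:
        center_map = bilayer_center_map(frame)
    out: dict[str, ZProfileEntry] = {}
    for species in sorted(set(frame.species)):
        mols = frame.molecules_of(species)
        signs = frame.leaflet[mols].astype(float)
        heads = frame.head_positions(mols)
        ix, iy = center_map.cell_of(heads[:, :2])
        head_rel = signs * (heads[:, 2] - center_map.values[ix, iy])
        tails = frame.tail_flat_indices(mols)
        tp = frame.pos[tails]
        tix, tiy = center_map.cell_of(tp[:, :2])
        tail_signs = frame.leaflet[frame.mol_index[tails]].astype(float)
        tail_rel = tail_signs * (tp[:, 2] - center_map.values[tix, tiy])
        out[species] = ZProfileEntry(
            species,
            float(head_rel.mean()),
            float(tail_rel.mean()),
            bool(tail_rel.mean() < 0.0),
        )
    return out


@dataclass
class InterdigitationResult:
    gap: float | None  # nm; negative = interdigitated
    applicable: bool
    sigma: float = 0.47  # MARTINI vdW diameter, the natural comparison scale


def interdigitation(
    frame: Frame, species_a: str, species_b: str | None = None
) -> InterdigitationResult:
    """Signed z separation between terminal tail beads across leaflets:
    (mean tail z of species_a, upper leaflet) - (mean tail z of species_b,
    lower leaflet).  Negative values mean tail overlap (interdigitation).
    Flagged not-applicable if either leaflet lacks the species."""
    species_b = species_b or species_a
    up = frame.molecules_of(species_a, +1)
    lo = frame.molecules_of(species_b, -1)
    if up.size == 0 or lo.size == 0:
        return InterdigitationResult(None, False)
    z_up = frame.pos[frame.tail_flat_indices(up), 2].mean()
    z_lo = frame.pos[frame.tail_flat_indices(lo), 2].mean()
    return InterdigitationResult(float(z_up - z_lo), True)


# --------------------------------------------------------------------------
# Umbrella coverage
# --------------------------------------------------------------------------


@dataclass
class UmbrellaResult:
    covered_fraction: float
    categories: np.ndarray  # per-sterol: "uncovered" | "one-lipid" | "two-lipid"
    sterol_mols: np.ndarray


def umbrella_coverage(
    frame: Frame,
    one_lipid_square: float = 0.25,
    two_lipid_square: float = 0.47,
) -> UmbrellaResult:
    """Umbrella-model coverage of sterol head beads by lipid head beads.

    A sterol head is covered by one lipid if at least one lipid head lies
    inside the axis-aligned square of side ``one_lipid_square`` centered on
    the sterol head's x/y and above it in z (toward the leaflet's water
    phase); covered by two lipids if at least two heads lie inside the
    ``two_lipid_square`` square.  Lateral distances are minimum-image.
    """
    sterol_mask = np.array([frame.registry[s].is_sterol for s in frame.species])
    sterols = np.flatnonzero(sterol_mask)
    if sterols.size == 0:
        raise ValueError("no sterol-like species in frame")
    lipids = np.flatnonzero(~sterol_mask)
    categories = np.full(len(sterols), "uncovered", dtype="U10")
    for leaf in (+1, -1):
        st = sterols[frame.leaflet[sterols] == leaf]
        li = lipids[frame.leaflet[lipids] == leaf]
        if st.size == 0 or li.size == 0:
            continue
        sp = frame.head_positions(st)
        lp = frame.head_positions(li)
        dxy = lp[None, :, :2] - sp[:, None, :2]
        dxy -= frame.box * np.round(dxy / frame.box)
        above = leaf * (lp[None, :, 2] - sp[:, None, 2]) > 0
        half1, half2 = one_lipid_square / 2.0, two_lipid_square / 2.0
        in_one = (np.abs(dxy[..., 0]) <= half1) & (np.abs(dxy[..., 1]) <= half1) & above
        in_two = (np.abs(dxy[..., 0]) <= half2) & (np.abs(dxy[..., 1]) <= half2) & above
        one_cov = in_one.any(axis=1)
        two_cov = in_two.sum(axis=1) >= 2
        local = np.full(len(st), "uncovered", dtype="U10")
        local[two_cov] = "two-lipid"
        local[one_cov] = "one-lipid"
        pos_in_sterols = np.searchsorted(sterols, st)
        categories[pos_in_sterols] = local
    covered = categories != "uncovered"
    return UmbrellaResult(float(covered.mean()), categories, sterols)


# --------------------------------------------------------------------------
# Pair energies (shifted LJ + shifted Coulomb)
# --------------------------------------------------------------------------


def _shift_constants(p: int, r1: float, rc: float) -> tuple[float, float, float]:
    """GROMACS shift-function constants for a 1/r^p term truncated at rc
    with the shift switched on at r1 (force and potential vanish at rc)."""
    d = rc - r1
    A = -p * ((p + 4) * rc - (p + 1) * r1) / (rc ** (p + 2) * d**2)
    B = p * ((p + 3) * rc - (p + 1) * r1) / (rc ** (p + 2) * d**3)
    C = 1.0 / rc**p - A / 3.0 * d**3 - B / 4.0 * d**4
    return A, B, C


def shifted_power(r: np.ndarray, p: int, r1: float, rc: float) -> np.ndarray:
    """Shifted 1/r^p potential kernel (zero at and beyond rc)."""
    A, B, C = _shift_constants(p, r1, rc)
    r = np.asarray(r, dtype=float)
    out = r ** (-float(p)) - C
    beyond = r > r1
    dr = np.where(beyond, r - r1, 0.0)
    out -= A / 3.0 * dr**3 + B / 4.0 * dr**4
    return np.where(r <= rc, out, 0.0)


def lj_shifted(r, eps, sigma, r1: float = 0.9, rc: float = 1.2):
    """MARTINI shifted Lennard-Jones potential (kJ/mol)."""
    c12 = 4.0 * eps * sigma**12
    c6 = 4.0 * eps * sigma**6
    return c12 * shifted_power(r, 12, r1, rc) - c6 * shifted_power(r, 6, r1, rc)


def coulomb_shifted(r, qq, eps_r: float = EPSILON_R, rc: float = 1.2):
    """MARTINI shifted Coulomb potential (kJ/mol), shift from r = 0."""
    return F_ELEC * np.asarray(qq) / eps_r * shifted_power(r, 1, 0.0, rc)


@dataclass
class EnergyBreakdown:
    """Pairwise intermolecular energies accumulated per species pair.

    ``vdw[a, b]`` / ``elec[a, b]`` hold the total energy between molecules
    of species a and b (the a == b diagonal counts each pair once; the
    bookkeeping is symmetric).  :meth:`per_molecule` normalizes by the
    molecule count of the first species.
    """

    species: list[str]
    vdw: np.ndarray  # (S, S) kJ
    elec: np.ndarray
    n_molecules: dict[str, int]

    @property
    def total_matrix(self) -> np.ndarray:
        return self.vdw + self.elec

    @property
    def total(self) -> float:
        """Sum over all pair terms (each intermolecular pair once)."""
        m = self.total_matrix
        return float(np.triu(m).sum())

    def per_molecule(self, a: str, b: str, component: str = "total") -> float:
        comp = {"vdw": self.vdw, "electrostatic": self.elec,
                "total": self.total_matrix}[component]
        i, j = self.species.index(a), self.species.index(b)
        return float(comp[i, j] / self.n_molecules[a])

    def species_total(self, a: str, component: str = "total") -> float:
        """Total interaction energy of species a with everything,
        normalized per molecule of a."""
        comp = {"vdw": self.vdw, "electrostatic": self.elec,
                "total": self.total_matrix}[component]
        i = self.species.index(a)
        return float(comp[i, :].sum() / self.n_molecules[a])


def pair_energy(
    frame: Frame,
    matrix: NonbondedMatrix,
    cutoff: float = 1.2,
    shift_start: float = 0.9,
    eps_r: float = EPSILON_R,
) -> EnergyBreakdown:
    """Intermolecular shifted-LJ + shifted-Coulomb energy per species pair.

    Pairs are found with a periodic (x/y minimum-image) neighbor search;
    the result matches an O(N^2) double loop to numerical precision.
    """
    species_names = sorted(set(frame.species))
    s_index = {s: i for i, s in enumerate(species_names)}
    mol_s = np.array([s_index[s] for s in frame.species])
    bead_types = _bead_type_tokens(frame)
    type_names = sorted(set(bead_types))
    t_index = {t: i for i, t in enumerate(type_names)}
    eps_table = np.array([
        [matrix.epsilon(a, b) for b in type_names] for a in type_names
    ])
    bead_t = np.array([t_index[t] for t in bead_types])
    from .cg_model import bead_charge

    bead_q = np.array([bead_charge(t) for t in bead_types])

    # Periodic KD-tree: x/y wrap in the box; z is lifted into a slab tall
    # enough that z never wraps within the cutoff.
    pts = frame.pos.copy()
    pts[:, :2] = np.mod(pts[:, :2], frame.box)
    z0 = pts[:, 2].min()
    pts[:, 2] += cutoff - z0
    z_span = pts[:, 2].max() + cutoff + 1.0
    tree = cKDTree(pts, boxsize=[frame.box[0], frame.box[1], z_span])
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        inter = frame.mol_index[i] != frame.mol_index[j]
        i, j = i[inter], j[inter]
    else:
        i = j = np.empty(0, dtype=int)

    d = frame.pos[i] - frame.pos[j]
    d[:, :2] -= frame.box * np.round(d[:, :2] / frame.box)
    r = np.linalg.norm(d, axis=1)
    eps = eps_table[bead_t[i], bead_t[j]]
    e_vdw = lj_shifted(r, eps, matrix.sigma, shift_start, cutoff)
    qq = bead_q[i] * bead_q[j]
    e_elec = np.zeros_like(e_vdw)
    charged = qq != 0
    if charged.any():
        e_elec[charged] = coulomb_shifted(r[charged], qq[charged], eps_r, cutoff)

    n_s = len(species_names)
    vdw = np.zeros((n_s, n_s))
    elec = np.zeros((n_s, n_s))
    si = mol_s[frame.mol_index[i]]
    sj = mol_s[frame.mol_index[j]]
    np.add.at(vdw, (si, sj), e_vdw)
    np.add.at(elec, (si, sj), e_elec)
    off = si != sj
    np.add.at(vdw, (sj[off], si[off]), e_vdw[off])
    np.add.at(elec, (sj[off], si[off]), e_elec[off])
    counts = {s: int((frame.species == s).sum()) for s in species_names}
    return EnergyBreakdown(species_names, vdw, elec, counts)


def _bead_type_tokens(frame: Frame) -> list[str]:
    tokens: list[str] = []
    for m in range(frame.n_molecules):
        spec = frame.registry[frame.species[m]]
        tokens.extend(b.bead_type for b in spec.beads)
    return tokens


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------


def rmsd(frame: Frame, reference: Frame, remove_xy_drift: bool = False) -> float:
    """Coordinate RMSD (nm) against a reference frame.

    No rotational superposition: the bilayer normal fixes the orientation.
    Optionally the mean x/y displacement (center-of-geometry drift) is
    removed first.
    """
    if frame.n_beads != reference.n_beads:
        raise ValueError("bead counts differ between frame and reference")
    a = frame.upos if (frame.upos is not None and reference.upos is not None) else frame.pos
    b = reference.upos if (frame.upos is not None and reference.upos is not None) else reference.pos
    diff = a - b
    if remove_xy_drift:
        diff = diff.copy()
        diff[:, :2] -= diff[:, :2].mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))
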