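"""Coarse-grained (MARTINI) species registry and force-field variant generator.

The ternary raft-forming mixture studied here is DPPC (fully saturated
phosphatidylcholine), DUPC (di-polyunsaturated PC) and cholesterol (CHOL),
represented with MARTINI beads.  Within the MARTINI description the three
molecules differ in a small, enumerable set of force-field terms:

* DPPC chain beads are all apolar type ``C1``; DUPC carries ``C4`` beads at
  the second and third chain positions (beads 6, 7, 10, 11 in the standard
  12-bead numbering), encoding its double bonds.
* DPPC chain angles are straight (theta0 = 180 deg, k = 25 kJ/mol); DUPC
  kinks at 100 deg (k = 10) and 120 deg (k = 45).
* CHOL is a rigid, planar ring body (small ``SCx`` beads) with a short,
  comparatively mobile two-bead tail.

This module builds the three standard species and every systematically
modified species used to dissect which of those differences drives
liquid-ordered/liquid-disordered (Lo/Ld) phase separation:

* ``DUa``/``DUs``/``DUas`` -- DUPC with chain angles and/or angle stiffnesses
  assimilated to DPPC's values,
* ``DUb2``/``DUb3``/``DUb23`` -- DUPC with the second and/or third chain
  beads retyped to ``C1``,
* ``DPPC_soft`` -- DPPC with softened chain angles (k = 10 kJ/mol),
* ``DPPC_3b`` -- a shortened, stiffened, ring-typed DPPC acting as a
  cholesterol mimic (three SC1 chain beads, k = 300 kJ/mol, an extra bond
  tying the two chain ends together),
* ``CHOL_300`` -- CHOL with the tail angle stiffened to 300 kJ/mol,
* ``CHOL_+1HB`` -- CHOL with an extra polar SP1 head bead (umbrella-model
  probe),
* ``DPPC_3b_plus1`` -- DPPC_3b with one extra mobile tail bead on one chain.

A validated nonbonded matrix (van der Waals well depths per bead-type pair,
with the 0.75x scaling rule for ring-ring pairs) and a GROMACS
topology-include (.itp) writer/parser round out the module.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "BeadSpec",
    "BondTerm",
    "AngleTerm",
    "MoleculeSpec",
    "NonbondedMatrix",
    "VariantRule",
    "ROLES",
    "REGISTERED_BEAD_TYPES",
    "build_standard_species",
    "apply_dupc_variant",
    "make_dppc_soft",
    "make_dppc_3b",
    "make_chol_variant",
    "build_all_species",
    "build_nonbonded_matrix",
    "epsilon",
    "write_itp",
    "parse_itp",
]

# --------------------------------------------------------------------------
# Bead-type registry
# --------------------------------------------------------------------------

ROLES = ("head", "linker", "chain", "ring", "tail")

#: Regular bead types with their partial charge (e).  Charges follow the
#: MARTINI 2.0 convention: the choline bead (Q0) carries +1, the phosphate
#: bead (Qa) carries -1, everything else is neutral.
_BASE_TYPES: dict[str, float] = {
    "Q0": +1.0,
    "Qa": -1.0,
    "Na": 0.0,
    "P1": 0.0,
    "C1": 0.0,
    "C2": 0.0,
    "C3": 0.0,
    "C4": 0.0,
    "C5": 0.0,
}

#: Small (ring) bead types map onto a regular parent type for nonbonded
#: lookups; among themselves they interact at reduced strength.
_S_TYPES: dict[str, str] = {
    "SC1": "C1",
    "SC2": "C2",
    "SC3": "C3",
    "SC4": "C4",
    "SC5": "C5",
    "SP1": "P1",
}

REGISTERED_BEAD_TYPES = tuple(_BASE_TYPES) + tuple(_S_TYPES)

#: Scaling of the vdW well depth for pairs of small/ring beads relative to
#: the corresponding regular-bead pair.
RING_EPSILON_SCALE = 0.75

#: Single vdW diameter for this bead family (nm).
SIGMA_NM = 0.47


def bead_charge(bead_type: str) -> float:
    """Partial charge (e) of a registered bead type."""
    base = _S_TYPES.get(bead_type, bead_type)
    if base not in _BASE_TYPES:
        raise KeyError(f"unregistered bead type {bead_type!r}")
    return _BASE_TYPES[base]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BeadSpec:
    """One coarse-grained bead: 1-based index, MARTINI type token, role."""

    index: int
    bead_type: str
    role: str
    name: str = ""  # atom name for topology/coordinate files

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown bead role {self.role!r}")
        if self.bead_type not in REGISTERED_BEAD_TYPES:
            raise KeyError(f"unregistered bead type {self.bead_type!r}")

    @property
    def charge(self) -> float:
        return bead_charge(self.bead_type)


@dataclass(frozen=True)
class BondTerm:
    """Harmonic bond between two beads (1-based indices)."""

    pair: tuple[int, int]
    length: float = 0.47  # nm
    k: float | None = 1250.0  # kJ/mol/nm^2; None marks a constraint


@dataclass(frozen=True)
class AngleTerm:
    """Cosine-harmonic angle term over an ordered bead-index triplet."""

    triple: tuple[int, int, int]
    theta0: float  # degrees
    k: float  # kJ/mol

    def __post_init__(self) -> None:
        if not (0.0 < self.theta0 <= 180.0):
            raise ValueError(f"theta0 must be in (0, 180], got {self.theta0}")
        if self.k <= 0:
            raise ValueError(f"angle force constant must be positive, got {self.k}")


@dataclass
class MoleculeSpec:
    """A named CG molecule: ordered beads, bond terms, angle terms, chains.

    ``chains`` lists the covalently consecutive chain/tail bead indices of
    each acyl chain; chain order parameters are computed over the bonds
    within these lists.  ``order_axis`` optionally names a bead-index pair
    whose connecting line defines the molecule's orientational axis (used
    for sterols, whose ring body rather than a chain carries the order).
    """

    name: str
    beads: list[BeadSpec]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    chains: list[list[int]] = field(default_factory=list)
    order_axis: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        indices = [b.index for b in self.beads]
        if len(set(indices)) != len(indices):
            raise ValueError(f"{self.name}: duplicate bead indices")
        known = set(indices)
        for bond in self.bonds:
            if not set(bond.pair) <= known:
                raise ValueError(f"{self.name}: bond {bond.pair} references unknown bead")
        for ang in self.angles:
            if not set(ang.triple) <= known:
                raise ValueError(f"{self.name}: angle {ang.triple} references unknown bead")
        by_index = {b.index: b for b in self.beads}
        for chain in self.chains:
            for i in chain:
                if by_index[i].role not in ("chain", "tail"):
                    raise ValueError(
                        f"{self.name}: chain bead {i} has role {by_index[i].role!r}"
                    )
        if self.order_axis is not None and not set(self.order_axis) <= known:
            raise ValueError(f"{self.name}: order_axis references unknown bead")

    # -- lookups ------------------------------------------------------------

    def bead(self, index: int) -> BeadSpec:
        for b in self.beads:
            if b.index == index:
                return b
        raise KeyError(f"{self.name}: no bead {index}")

    def angle(self, i: int, j: int, k: int) -> AngleTerm:
        for ang in self.angles:
            if ang.triple in ((i, j, k), (k, j, i)):
                return ang
        raise KeyError(f"{self.name}: no angle {i}-{j}-{k}")

    def bond(self, i: int, j: int) -> BondTerm:
        for b in self.bonds:
            if set(b.pair) == {i, j}:
                return b
        raise KeyError(f"{self.name}: no bond {i}-{j}")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def head_index(self) -> int:
        """Index of the (first) head bead, used for grids and umbrella tests."""
        for b in self.beads:
            if b.role == "head":
                return b.index
        raise ValueError(f"{self.name}: no head bead")

    @property
    def tail_indices(self) -> list[int]:
        """Terminal tail beads; exactly these enter bilayer-center and
        interdigitation computations."""
        return [b.index for b in self.beads if b.role == "tail"]

    @property
    def is_sterol(self) -> bool:
        return any(b.role == "ring" for b in self.beads)

    def chain_angles(self) -> list[AngleTerm]:
        """Angle terms whose beads all lie on acyl chains (chain/tail role)."""
        chainlike = {b.index for b in self.beads if b.role in ("chain", "tail")}
        return [a for a in self.angles if set(a.triple) <= chainlike]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MoleculeSpec):
            return NotImplemented
        return (
            self.name == other.name
            and self.beads == other.beads
            and sorted(self.bonds, key=lambda b: b.pair) == sorted(other.bonds, key=lambda b: b.pair)
            and sorted(self.angles, key=lambda a: a.triple)
            == sorted(other.angles, key=lambda a: a.triple)
            and self.chains == other.chains
            and self.order_axis == other.order_axis
        )


# --------------------------------------------------------------------------
# Standard species
# --------------------------------------------------------------------------

_PC_ATOM_NAMES = (
    "NC3", "PO4", "GL1", "GL2",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
)


def _pc_skeleton(name: str, chain_types: Mapping[int, str]) -> MoleculeSpec:
    """Common 12-bead phosphatidylcholine skeleton.

    Head/linker types and bond terms are MARTINI 2.0 registry defaults
    (choline Q0, phosphate Qa, glycerols Na; 0.47 nm bonds at 1250
    kJ/mol/nm^2); chain bead types are supplied per species.
    """
    roles = {1: "head", 2: "linker", 3: "linker", 4: "linker",
             8: "tail", 12: "tail"}
    beads = []
    for i in range(1, 13):
        role = roles.get(i, "chain")
        btype = {1: "Q0", 2: "Qa", 3: "Na", 4: "Na"}.get(i) or chain_types.get(i, "C1")
        beads.append(BeadSpec(i, btype, role, _PC_ATOM_NAMES[i - 1]))
    bonds = [BondTerm((i, j)) for i, j in
             [(1, 2), (2, 3), (3, 4), (3, 5), (5, 6), (6, 7), (7, 8),
              (4, 9), (9, 10), (10, 11), (11, 12)]]
    # Linker angles: MARTINI 2.0 defaults, identical for DPPC and DUPC.
    angles = [
        AngleTerm((2, 3, 4), 120.0, 25.0),
        AngleTerm((2, 3, 5), 180.0, 25.0),
        AngleTerm((3, 5, 6), 180.0, 25.0),
        AngleTerm((4, 9, 10), 180.0, 25.0),
    ]
    return MoleculeSpec(
        name=name,
        beads=beads,
        bonds=bonds,
        angles=angles,
        chains=[[5, 6, 7, 8], [9, 10, 11, 12]],
    )


def build_standard_species() -> dict[str, MoleculeSpec]:
    """Standard MARTINI DPPC, DUPC and CHOL molecules.

    DPPC: all chain beads C1, all four chain angles 180 deg / 25 kJ/mol.
    DUPC: beads 6, 7, 10, 11 are C4; kinked chain angles
    (5-6-7 and 9-10-11: 100 deg / 10 kJ/mol; 6-7-8 and 10-11-12:
    120 deg / 45 kJ/mol).  CHOL: SP1 head, five-bead SC ring body, a
    two-bead tail whose 4-7-8 angle is the molecule's only soft chain term.
    """
    dppc = _pc_skeleton("DPPC", {})
    dppc.angles += [
        AngleTerm((5, 6, 7), 180.0, 25.0),
        AngleTerm((6, 7, 8), 180.0, 25.0),
        AngleTerm((9, 10, 11), 180.0, 25.0),
        AngleTerm((10, 11, 12), 180.0, 25.0),
    ]

    dupc = _pc_skeleton("DUPC", {6: "C4", 7: "C4", 10: "C4", 11: "C4"})
    dupc.angles += [
        AngleTerm((5, 6, 7), 100.0, 10.0),
        AngleTerm((6, 7, 8), 120.0, 45.0),
        AngleTerm((9, 10, 11), 100.0, 10.0),
        AngleTerm((10, 11, 12), 120.0, 45.0),
    ]

    # CHOL ring-bead type assignments and bond terms are MARTINI 2.0
    # registry defaults (flagged as such; only the 4-7-8 tail angle and the
    # 3->5 order axis are modified/used by the analyses here).
    chol = MoleculeSpec(
        name="CHOL",
        beads=[
            BeadSpec(1, "SP1", "head", "ROH"),
            BeadSpec(2, "SC1", "ring", "R1"),
            BeadSpec(3, "SC3", "ring", "R2"),
            BeadSpec(4, "SC1", "ring", "R3"),
            BeadSpec(5, "SC1", "ring", "R4"),
            BeadSpec(6, "SC1", "ring", "R5"),
            BeadSpec(7, "SC1", "chain", "C1"),
            BeadSpec(8, "C1", "tail", "C2"),
        ],
        bonds=[BondTerm((i, j)) for i, j in
               [(1, 2), (2, 3), (3, 4), (4, 5), (5, 6), (6, 2), (4, 7), (7, 8)]],
        angles=[AngleTerm((4, 7, 8), 180.0, 25.0)],
        chains=[[7, 8]],
        order_axis=(3, 5),
    )
    return {"DPPC": dppc, "DUPC": dupc, "CHOL": chol}


# --------------------------------------------------------------------------
# DUPC variants
# --------------------------------------------------------------------------

_DUPC_CHAIN_ANGLE_PAIRS = ((5, 6, 7), (9, 10, 11))
_DUPC_CHAIN_ANGLE_ENDS = ((6, 7, 8), (10, 11, 12))
_DPPC_THETA0 = 180.0
_DPPC_ANGLE_K = 25.0
_BEAD2_INDICES = (6, 10)  # second bead of each chain
_BEAD3_INDICES = (7, 11)  # third bead of each chain


@dataclass(frozen=True)
class VariantRule:
    """Which DUPC -> DPPC assimilations to apply.

    The derived name follows the lower-letter scheme: 'a' = equilibrium
    angles, 's' = angle stiffnesses, 'b<n>' = chain bead n retyped to C1.
    """

    assimilate_angles: bool = False
    assimilate_stiffness: bool = False
    retype_bead2: bool = False
    retype_bead3: bool = False

    @property
    def name(self) -> str:
        letters = ""
        if self.assimilate_angles:
            letters += "a"
        if self.assimilate_stiffness:
            letters += "s"
        if self.retype_bead2 or self.retype_bead3:
            letters += "b"
            if self.retype_bead2:
                letters += "2"
            if self.retype_bead3:
                letters += "3"
        return "DU" + letters if letters else "DUPC"


def apply_dupc_variant(base: MoleculeSpec, rule: VariantRule) -> MoleculeSpec:
    """Assimilate DUPC chain features toward DPPC according to ``rule``.

    Both chains are always modified together.  Untouched terms are carried
    over unchanged, so applying a rule twice is idempotent and applying all
    assimilations yields chains identical to DPPC's.
    """
    if not _is_duplike(base):
        raise ValueError(f"apply_dupc_variant expects standard DUPC chains, got {base.name!r}")
    mol = copy.deepcopy(base)
    mol.name = rule.name
    new_angles = []
    for ang in mol.angles:
        t, k = ang.theta0, ang.k
        if ang.triple in _DUPC_CHAIN_ANGLE_PAIRS + _DUPC_CHAIN_ANGLE_ENDS:
            if rule.assimilate_angles:
                t = _DPPC_THETA0
            if rule.assimilate_stiffness:
                k = _DPPC_ANGLE_K
        new_angles.append(AngleTerm(ang.triple, t, k))
    mol.angles = new_angles
    retype = set()
    if rule.retype_bead2:
        retype |= set(_BEAD2_INDICES)
    if rule.retype_bead3:
        retype |= set(_BEAD3_INDICES)
    mol.beads = [
        replace(b, bead_type="C1") if b.index in retype else b for b in mol.beads
    ]
    mol.validate()
    return mol


def _is_duplike(mol: MoleculeSpec) -> bool:
    """True for standard DUPC or one of its named variants (a 12-bead PC
    with the DUPC chain layout); other species, including DPPC, are not
    valid variant bases."""
    return (
        (mol.name == "DUPC" or mol.name.startswith("DU"))
        and mol.n_beads == 12
        and mol.chains == [[5, 6, 7, 8], [9, 10, 11, 12]]
        and all(mol.bead(i).bead_type in ("C1", "C4") for i in (6, 7, 10, 11))
    )


# --------------------------------------------------------------------------
# DPPC and CHOL variants
# --------------------------------------------------------------------------


def make_dppc_soft(k_soft: float = 10.0) -> MoleculeSpec:
    """DPPC with softened chains: every chain angle constant set to
    ``k_soft`` (default 10 kJ/mol, a 60% reduction from the standard 25)."""
    if k_soft <= 0:
        raise ValueError("k_soft must be positive")
    mol = copy.deepcopy(build_standard_species()["DPPC"])
    mol.name = "DPPC_soft"
    chain_triples = {a.triple for a in mol.chain_angles()}
    mol.angles = [
        AngleTerm(a.triple, a.theta0, k_soft) if a.triple in chain_triples else a
        for a in mol.angles
    ]
    return mol


def make_dppc_3b() -> MoleculeSpec:
    """Shortened, stiffened, ring-typed DPPC used as a cholesterol mimic.

    Three chain beads per tail instead of four, all retyped to SC1 (so the
    self-interaction is damped by the ring rule, mirroring CHOL's aversion
    to itself), chain angle constants raised to 300 kJ/mol to keep the
    chains straight, and one extra bond tying the two chain-terminal beads
    together.  In the original 12-bead numbering that extra bond joins
    beads 7 and 11 -- the third chain beads, which become terminal once the
    fourth beads are removed; after renumbering it is the 7-10 bond.
    """
    dppc = build_standard_species()["DPPC"]
    # Drop the 4th chain bead of each tail (old indices 8 and 12).
    removed = {8, 12}
    old_to_new = {}
    n = 0
    for b in dppc.beads:
        if b.index in removed:
            continue
        n += 1
        old_to_new[b.index] = n
    beads = []
    for b in dppc.beads:
        if b.index in removed:
            continue
        i = old_to_new[b.index]
        role = b.role
        btype = b.bead_type
        if role in ("chain", "tail"):
            btype = "SC1"
        if b.index in (7, 11):  # third chain beads become the new terminals
            role = "tail"
        beads.append(BeadSpec(i, btype, role, b.name))
    bonds = [
        BondTerm((old_to_new[i], old_to_new[j]), bnd.length, bnd.k)
        for bnd in dppc.bonds
        for i, j in [bnd.pair]
        if not removed & {i, j}
    ]
    bonds.append(BondTerm((old_to_new[7], old_to_new[11])))  # chain-end tie
    angles = []
    for a in dppc.angles:
        if removed & set(a.triple):
            continue
        triple = tuple(old_to_new[i] for i in a.triple)
        k = a.k
        if a.triple in ((5, 6, 7), (9, 10, 11)):
            k = 300.0
        angles.append(AngleTerm(triple, a.theta0, k))
    chains = [[old_to_new[i] for i in ch if i not in removed] for ch in dppc.chains]
    return MoleculeSpec("DPPC_3b", beads, bonds, angles, chains)


def make_chol_variant(kind: str) -> MoleculeSpec:
    """Cholesterol-role variants probing tail entropy and the umbrella model.

    ``CHOL_300``: tail angle (4-7-8) stiffened from 25 to 300 kJ/mol.
    ``CHOL_+1HB``: one extra polar SP1 bead bonded above the ROH head.
    ``DPPC_3b_plus1``: DPPC_3b with one extra mobile chain bead on one
    chain, attached at an angle constant of 25 kJ/mol (the value of CHOL's
    4-7-8 tail angle).
    """
    if kind == "CHOL_300":
        mol = copy.deepcopy(build_standard_species()["CHOL"])
        mol.name = "CHOL_300"
        mol.angles = [
            AngleTerm(a.triple, a.theta0, 300.0) if a.triple == (4, 7, 8) else a
            for a in mol.angles
        ]
        return mol
    if kind == "CHOL_+1HB":
        mol = copy.deepcopy(build_standard_species()["CHOL"])
        mol.name = "CHOL_+1HB"
        new_index = mol.n_beads + 1
        mol.beads.append(BeadSpec(new_index, "SP1", "head", "ROH2"))
        mol.bonds.append(BondTerm((1, new_index)))
        mol.validate()
        return mol
    if kind == "DPPC_3b_plus1":
        mol = make_dppc_3b()
        mol.name = "DPPC_3b_plus1"
        new_index = mol.n_beads + 1  # appended after existing beads
        # Chain A terminal (bead 7 after renumbering) gains a 4th bead.
        mol.beads = [
            replace(b, role="chain") if b.index == 7 else b for b in mol.beads
        ]
        mol.beads.append(BeadSpec(new_index, "C1", "tail", "C4A"))
        mol.bonds.append(BondTerm((7, new_index)))
        mol.angles.append(AngleTerm((6, 7, new_index), 180.0, 25.0))
        mol.chains = [ch + [new_index] if ch[-1] == 7 else ch for ch in mol.chains]
        mol.validate()
        return mol
    raise ValueError(f"unknown CHOL variant kind {kind!r}")


def build_all_species() -> dict[str, MoleculeSpec]:
    """Every standard and modified species, keyed by name."""
    species = build_standard_species()
    dupc = species["DUPC"]
    for rule in (
        VariantRule(assimilate_angles=True),
        VariantRule(assimilate_stiffness=True),
        VariantRule(assimilate_angles=True, assimilate_stiffness=True),
        VariantRule(retype_bead2=True),
        VariantRule(retype_bead3=True),
        VariantRule(retype_bead2=True, retype_bead3=True),
    ):
        species[rule.name] = apply_dupc_variant(dupc, rule)
    species["DPPC_soft"] = make_dppc_soft()
    species["DPPC_3b"] = make_dppc_3b()
    for kind in ("CHOL_300", "CHOL_+1HB", "DPPC_3b_plus1"):
        species[kind] = make_chol_variant(kind)
    return species


# --------------------------------------------------------------------------
# Nonbonded matrix
# --------------------------------------------------------------------------

# vdW well depths (kJ/mol) between regular bead types.  The apolar block is
# uniform at 3.5 kJ/mol except the saturated/unsaturated cross pair C1-C4
# (3.1 kJ/mol), the enthalpic mismatch that drives DPPC/DUPC demixing.
# Head/linker entries are MARTINI 2.0 interaction-level registry defaults.
_EPSILON_LEVELS: dict[frozenset[str], float] = {}


def _set_eps(a: str, b: str, value: float) -> None:
    _EPSILON_LEVELS[frozenset((a, b))] = value


for _ct in ("C1", "C2", "C3", "C4", "C5"):
    for _ct2 in ("C1", "C2", "C3", "C4", "C5"):
        _set_eps(_ct, _ct2, 3.5)
_set_eps("C1", "C4", 3.1)

_set_eps("Q0", "Q0", 3.5)
_set_eps("Q0", "Qa", 4.5)
_set_eps("Qa", "Qa", 5.0)
_set_eps("Na", "Na", 4.0)
_set_eps("Q0", "Na", 4.0)
_set_eps("Qa", "Na", 4.0)
_set_eps("P1", "P1", 4.5)
_set_eps("P1", "Q0", 4.5)
_set_eps("P1", "Qa", 4.5)
_set_eps("P1", "Na", 4.0)
for _ct in ("C1", "C2", "C3", "C4", "C5"):
    _set_eps("Q0", _ct, 2.0)
    _set_eps("Qa", _ct, 2.0)
    _set_eps("Na", _ct, 2.7)
    _set_eps("P1", _ct, 2.7)


@dataclass(frozen=True)
class NonbondedMatrix:
    """Symmetric vdW well-depth lookup over bead-type pairs, plus sigma.

    Ring rule: a pair of small (S-prefixed) beads interacts at
    ``RING_EPSILON_SCALE`` (0.75) times the corresponding regular-bead
    pair; a small bead against a regular bead is unscaled.  A single sigma
    (0.47 nm) applies to the whole family.
    """

    base_epsilon: Mapping[frozenset, float]
    sigma: float = SIGMA_NM

    def epsilon(self, a: str, b: str) -> float:
        base_a = _S_TYPES.get(a)
        base_b = _S_TYPES.get(b)
        ka = base_a or a
        kb = base_b or b
        if ka not in _BASE_TYPES:
            raise KeyError(f"unregistered bead type {a!r}")
        if kb not in _BASE_TYPES:
            raise KeyError(f"unregistered bead type {b!r}")
        eps = self.base_epsilon[frozenset((ka, kb))]
        if base_a is not None and base_b is not None:
            eps *= RING_EPSILON_SCALE
        return eps

    @property
    def registered_types(self) -> tuple[str, ...]:
        return REGISTERED_BEAD_TYPES


def build_nonbonded_matrix() -> NonbondedMatrix:
    """The standard nonbonded matrix for this bead family."""
    return NonbondedMatrix(base_epsilon=dict(_EPSILON_LEVELS))


def epsilon(matrix: NonbondedMatrix, a: str, b: str) -> float:
    """vdW well depth (kJ/mol) for a bead-type pair; symmetric in (a, b)."""
    return matrix.epsilon(a, b)


# --------------------------------------------------------------------------
# Topology-include (.itp) writer / parser
# --------------------------------------------------------------------------

_G = "%.17g"  # lossless float formatting


def write_itp(mol: MoleculeSpec) -> str:
    """Emit a GROMACS topology-include for one molecule.

    The dialect uses standard [moleculetype]/[atoms]/[bonds]/[angles]
    sections (angle funct 2, the MARTINI cosine-harmonic form) plus
    structured comments carrying bead roles, chain definitions and the
    order axis, so that :func:`parse_itp` round-trips to an equal
    :class:`MoleculeSpec`.
    """
    mol.validate()
    lines = ["[ moleculetype ]", "; name  nrexcl", f"{mol.name}  1", ""]
    lines.append("[ atoms ]")
    lines.append("; nr  type  resnr  residue  atom  cgnr  charge  ; role")
    for b in mol.beads:
        lines.append(
            f"{b.index:>4d}  {b.bead_type:<4s}  1  {mol.name}  {b.name or b.bead_type:<4s}"
            f"  {b.index:>4d}  {_G % b.charge}  ; role={b.role}"
        )
    lines.append("")
    if mol.bonds:
        lines.append("[ bonds ]")
        lines.append(";  i   j  funct  length  force.c.")
        for bnd in mol.bonds:
            i, j = bnd.pair
            if bnd.k is None:
                lines.append(f"{i:>4d} {j:>4d}  1  {_G % bnd.length}  ; constraint")
            else:
                lines.append(f"{i:>4d} {j:>4d}  1  {_G % bnd.length}  {_G % bnd.k}")
        lines.append("")
    if mol.angles:
        lines.append("[ angles ]")
        lines.append(";  i   j   k  funct  angle  force.c.")
        for a in mol.angles:
            i, j, k = a.triple
            lines.append(
                f"{i:>4d} {j:>4d} {k:>4d}  2  {_G % a.theta0}  {_G % a.k}"
            )
        lines.append("")
    chains_txt = " | ".join("-".join(str(i) for i in ch) for ch in mol.chains)
    lines.append(f"; chains: {chains_txt}")
    if mol.order_axis is not None:
        lines.append(f"; order_axis: {mol.order_axis[0]}-{mol.order_axis[1]}")
    lines.append("")
    return "\n".join(lines)


def parse_itp(text: str) -> MoleculeSpec:
    """Parse a topology-include written by :func:`write_itp`."""
    name = None
    beads: list[BeadSpec] = []
    bonds: list[BondTerm] = []
    angles: list[AngleTerm] = []
    chains: list[list[int]] = []
    order_axis: tuple[int, int] | None = None
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = re.match(r"^;\s*chains:\s*(.*)$", line)
        if m:
            if m.group(1).strip():
                chains = [
                    [int(i) for i in part.strip().split("-")]
                    for part in m.group(1).split("|")
                ]
            continue
        m = re.match(r"^;\s*order_axis:\s*(\d+)-(\d+)\s*$", line)
        if m:
            order_axis = (int(m.group(1)), int(m.group(2)))
            continue
        comment = ""
        if ";" in line:
            line, comment = line.split(";", 1)
            line = line.strip()
            comment = comment.strip()
        if not line:
            continue
        m = re.match(r"^\[\s*(\w+)\s*\]$", line)
        if m:
            section = m.group(1).lower()
            continue
        fields = line.split()
        try:
            if section == "moleculetype":
                name = fields[0]
            elif section == "atoms":
                role_m = re.search(r"role=(\w+)", comment)
                if role_m is None:
                    raise ValueError("missing role annotation")
                beads.append(
                    BeadSpec(int(fields[0]), fields[1], role_m.group(1), fields[4])
                )
            elif section == "bonds":
                k = None if comment == "constraint" else float(fields[4])
                bonds.append(
                    BondTerm((int(fields[0]), int(fields[1])), float(fields[3]), k)
                )
            elif section == "angles":
                angles.append(
                    AngleTerm(
                        (int(fields[0]), int(fields[1]), int(fields[2])),
                        float(fields[4]),
                        float(fields[5]),
                    )
                )
        except (IndexError, ValueError) as exc:
            raise ValueError(f"malformed itp record at line {lineno}: {raw!r}") from exc
    if name is None:
        raise ValueError("no [moleculetype] section found")
    return MoleculeSpec(name, beads, bonds, angles, chains, order_axis)
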