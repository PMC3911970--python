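"""Shared fixtures: registries, small bilayer frames and brute-force
oracles used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from raftkit.bilayer import CompositionSpec, Frame, PhaseLayout, build_bilayer
from raftkit.cg_model import build_all_species, build_nonbonded_matrix
from raftkit.observables import coulomb_shifted, lj_shifted
from raftkit.cg_model import bead_charge


@pytest.fixture(scope="session")
def registry():
    return build_all_species()


@pytest.fixture(scope="session")
def matrix():
    return build_nonbonded_matrix()


@pytest.fixture(scope="session")
def small_comp():
    return CompositionSpec(counts={"DPPC": 20, "DUPC": 32, "CHOL": 10})


@pytest.fixture(scope="session")
def mixed_frame(small_comp):
    return build_bilayer(small_comp, PhaseLayout(state="mixed"), seed=11)


@pytest.fixture(scope="session")
def separated_frame(small_comp):
    return build_bilayer(small_comp, PhaseLayout(state="separated"), seed=11)


def make_frame(mols, registry, box=(10.0, 10.0), time=0.0, unwrapped=True):
    """Assemble a Frame from explicit per-molecule bead coordinates.

    ``mols``: list of (species_name, leaflet_sign, positions (n_beads, 3)).
    """
    pos_blocks, mol_index, bead_index, species, leaflet = [], [], [], [], []
    for mid, (name, leaf, coords) in enumerate(mols):
        coords = np.asarray(coords, dtype=float)
        assert coords.shape == (registry[name].n_beads, 3)
        pos_blocks.append(coords)
        mol_index.append(np.full(len(coords), mid))
        bead_index.append(np.arange(1, len(coords) + 1))
        species.append(name)
        leaflet.append(leaf)
    upos = np.concatenate(pos_blocks)
    box = np.asarray(box, dtype=float)
    pos = upos.copy()
    pos[:, :2] = np.mod(pos[:, :2], box)
    return Frame(
        pos=pos,
        box=box,
        time=time,
        mol_index=np.concatenate(mol_index),
        bead_index=np.concatenate(bead_index),
        species=np.array(species, dtype="U16"),
        leaflet=np.array(leaflet),
        registry=registry,
        upos=upos if unwrapped else None,
    )


def brute_force_energy(frame: Frame, matrix, cutoff=1.2, shift_start=0.9):
    """O(N^2) reference for the per-species-pair nonbonded energy: an
    explicit double loop over bead pairs with x/y minimum image."""
    types = []
    for m in range(frame.n_molecules):
        spec = frame.registry[frame.species[m]]
        types.extend(b.bead_type for b in spec.beads)
    types = np.array(types)
    charges = np.array([bead_charge(t) for t in types])
    species_names = sorted(set(frame.species))
    s_index = {s: i for i, s in enumerate(species_names)}
    n_s = len(species_names)
    vdw = np.zeros((n_s, n_s))
    elec = np.zeros((n_s, n_s))
    n = frame.n_beads
    pos = frame.pos
    for i in range(n):
        d = pos[i + 1:] - pos[i]
        d[:, :2] -= frame.box * np.round(d[:, :2] / frame.box)
        r = np.linalg.norm(d, axis=1)
        for k in np.flatnonzero((r <= cutoff)):
            j = i + 1 + k
            if frame.mol_index[i] == frame.mol_index[j]:
                continue
            eps = matrix.epsilon(types[i], types[j])
            ev = float(lj_shifted(r[k], eps, matrix.sigma, shift_start, cutoff))
            qq = charges[i] * charges[j]
            ee = float(coulomb_shifted(r[k], qq, rc=cutoff)) if qq else 0.0
            si = s_index[frame.species[frame.mol_index[i]]]
            sj = s_index[frame.species[frame.mol_index[j]]]
            vdw[si, sj] += ev
            elec[si, sj] += ee
            if si != sj:
                vdw[sj, si] += ev
                elec[sj, si] += ee
    return species_names, vdw, elec
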