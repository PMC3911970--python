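"""Observable statistics, each checked against an independent oracle or an
analytic construction."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.integrate import quad

import raftkit as rk
from raftkit.bilayer import (
    BOND_LENGTH_NM,
    CompositionSpec,
    DynamicsParams,
    PhaseLayout,
    Trajectory,
    build_bilayer,
    simulate_lateral_dynamics,
)
from raftkit.cg_model import BeadSpec, BondTerm, MoleculeSpec
from raftkit.observables import (
    EPSILON_R,
    F_ELEC,
    assign_leaflets,
    bilayer_center_map,
    coulomb_shifted,
    grid_density,
    interdigitation,
    interleaflet_correlation,
    lj_shifted,
    msd,
    order_parameter,
    pair_energy,
    rmsd,
    shifted_power,
    umbrella_coverage,
    z_profile,
)
from conftest import brute_force_energy, make_frame


# --------------------------------------------------------------------------
# Helper species: a 4-bead single-chain molecule (head + 2-bond chain)
# --------------------------------------------------------------------------


def _stick_registry():
    stick = MoleculeSpec(
        name="STK",
        beads=[
            BeadSpec(1, "Q0", "head", "NC3"),
            BeadSpec(2, "C1", "chain", "C1A"),
            BeadSpec(3, "C1", "chain", "C2A"),
            BeadSpec(4, "C1", "tail", "C3A"),
        ],
        bonds=[BondTerm((1, 2)), BondTerm((2, 3)), BondTerm((3, 4))],
        chains=[[2, 3, 4]],
    )
    return {"STK": stick}


def _stick(head_xy, head_z, bond1, bond2, leaflet=1):
    """Bead coordinates for one STK molecule with two given chain bonds."""
    p1 = np.array([head_xy[0], head_xy[1], head_z])
    p2 = p1 + [0, 0, -0.3]
    p3 = p2 + np.asarray(bond1, dtype=float)
    p4 = p3 + np.asarray(bond2, dtype=float)
    return np.stack([p1, p2, p3, p4])


# --------------------------------------------------------------------------
# Leaflet assignment
# --------------------------------------------------------------------------


def test_leaflet_assignment_symmetric(mixed_frame):
    la = assign_leaflets(mixed_frame)
    assert not la.degenerate
    assert np.array_equal(la.labels, mixed_frame.leaflet)


def test_leaflet_assignment_translation_invariant(mixed_frame):
    shifted = mixed_frame.copy()
    shifted.pos = shifted.pos + np.array([0.0, 0.0, 7.3])
    la0 = assign_leaflets(mixed_frame)
    la1 = assign_leaflets(shifted)
    assert np.array_equal(la0.labels, la1.labels)


def test_leaflet_assignment_degenerate_flagged():
    reg = _stick_registry()
    mols = [("STK", 1, _stick((x, 1.0), 2.0, [0, 0, -0.47], [0, 0, -0.47]))
            for x in (1.0, 2.0, 3.0)]
    la = assign_leaflets(make_frame(mols, reg))
    assert la.degenerate


# --------------------------------------------------------------------------
# Order parameter
# --------------------------------------------------------------------------


def test_order_all_parallel_is_one():
    reg = _stick_registry()
    b = [0, 0, -BOND_LENGTH_NM]
    frame = make_frame([("STK", 1, _stick((1, 1), 2.0, b, b))], reg)
    assert order_parameter(frame, "STK").S == pytest.approx(1.0)


def test_order_all_in_plane_is_minus_half():
    reg = _stick_registry()
    b = [BOND_LENGTH_NM, 0, 0]
    frame = make_frame([("STK", 1, _stick((1, 1), 2.0, b, b))], reg)
    assert order_parameter(frame, "STK").S == pytest.approx(-0.5)


def test_order_mixed_bonds_quarter():
    """One bond along z (cos^2 = 1) and one in-plane (cos^2 = 0):
    S = (3 * 0.5 - 1)/2 = 0.25 by direct evaluation of the formula."""
    reg = _stick_registry()
    frame = make_frame(
        [("STK", 1, _stick((1, 1), 2.0, [0, 0, -BOND_LENGTH_NM],
                           [BOND_LENGTH_NM, 0, 0]))], reg
    )
    assert order_parameter(frame, "STK").S == pytest.approx(0.25)


def test_order_mean_of_per_molecule(mixed_frame):
    res = order_parameter(mixed_frame, "DPPC")
    assert res.S == pytest.approx(res.per_molecule.mean())
    assert np.all(res.per_molecule >= -0.5) and np.all(res.per_molecule <= 1.0)


def test_order_sterol_axis():
    """CHOL order comes from the 3->5 ring axis, here placed at 45 deg:
    S = (3/2) cos^2(45) - 1/2 = 0.25."""
    reg = rk.build_all_species()
    chol = reg["CHOL"]
    coords = np.zeros((chol.n_beads, 3))
    coords[:, 2] = np.linspace(1.6, 0.2, chol.n_beads)
    a = 0.3 / np.sqrt(2)
    coords[4] = coords[2] + [a, 0.0, -a]  # bead 5 relative to bead 3
    frame = make_frame([("CHOL", 1, coords)], reg)
    assert order_parameter(frame, "CHOL").S == pytest.approx(0.25)


def test_order_species_without_chains_rejected():
    reg = _stick_registry()
    reg["BLOB"] = MoleculeSpec(
        "BLOB", [BeadSpec(1, "Q0", "head", "Q0")], [], [], []
    )
    frame = make_frame([("BLOB", 1, np.zeros((1, 3)))], reg)
    with pytest.raises(ValueError):
        order_parameter(frame, "BLOB")


# --------------------------------------------------------------------------
# MSD
# --------------------------------------------------------------------------


def _drift_traj(reg, v, n_frames=40):
    frames = []
    for t in range(n_frames):
        b = [0, 0, -BOND_LENGTH_NM]
        f = make_frame(
            [("STK", 1, _stick((1 + v * t, 1), 2.0, b, b)),
             ("STK", -1, -_stick((3 + v * t, 3), 2.0, b, b) * [1, 1, -1]
              + [6, 6, 0])],
            reg, box=(40 + v * n_frames, 40),
        )
        f.time = float(t)
        frames.append(f)
    return Trajectory(frames)


def test_msd_frozen_is_zero_and_arrested(mixed_frame):
    traj = simulate_lateral_dynamics(
        mixed_frame, DynamicsParams(default_D=0.0, n_frames=12, seed=0)
    )
    res = msd(traj)
    assert np.allclose(res.msd, 0.0)
    assert res.plateau


def test_msd_ballistic_slope_two():
    reg = _stick_registry()
    res = msd(_drift_traj(reg, v=0.1), fit_window=(0.0, 40.0))
    assert res.slope == pytest.approx(2.0, abs=1e-6)


def test_msd_translation_invariance(mixed_frame):
    traj = simulate_lateral_dynamics(
        mixed_frame, DynamicsParams(default_D=0.05, n_frames=30, seed=3)
    )
    shifted = Trajectory([f.copy() for f in traj])
    for f in shifted:
        f.upos = f.upos + np.array([3.0, -2.0, 1.0])
        f.pos = f.pos  # wrapped view irrelevant for MSD
    a = msd(traj, species="DPPC")
    b = msd(shifted, species="DPPC")
    assert np.allclose(a.msd, b.msd)


def test_msd_requires_unwrapped(mixed_frame):
    f = mixed_frame.copy()
    f.upos = None
    g = mixed_frame.copy()
    g.upos = None
    g.time = 1.0
    with pytest.raises(ValueError, match="unwrap"):
        msd(Trajectory([f, g]))


# --------------------------------------------------------------------------
# Grids and correlation
# --------------------------------------------------------------------------


def test_grid_density_conserves_counts(mixed_frame):
    for leaf in (+1, -1):
        for s in ("DPPC", "DUPC", "CHOL"):
            gf = grid_density(mixed_frame, leaf, s)
            expected = ((mixed_frame.species == s)
                        & (mixed_frame.leaflet == leaf)).sum()
            assert gf.values.sum() == expected


def test_grid_single_molecule_single_cell():
    reg = _stick_registry()
    b = [0, 0, -BOND_LENGTH_NM]
    frame = make_frame([("STK", 1, _stick((4.2, 7.7), 2.0, b, b))], reg)
    gf = grid_density(frame, 1, "STK")
    assert (gf.values > 0).sum() == 1
    assert gf.values.max() == 1.0


def test_grid_stripe_layout_zero_outside(small_comp):
    frame = build_bilayer(small_comp, PhaseLayout(state="separated"), seed=11)
    gf = grid_density(frame, 1, "DPPC")
    # DPPC confined to a stripe: a contiguous band of x-columns is empty
    col = gf.values.sum(axis=1)
    assert (col == 0).any() and (col > 0).any()


def test_grid_cell_size_exceeds_box():
    reg = _stick_registry()
    b = [0, 0, -BOND_LENGTH_NM]
    frame = make_frame([("STK", 1, _stick((1, 1), 2.0, b, b))], reg, box=(3, 3))
    with pytest.raises(ValueError):
        grid_density(frame, 1, "STK", cell_size=5.0)


def test_grid_rescales_to_tile_box(mixed_frame):
    gf = grid_density(mixed_frame, 1, "DPPC", cell_size=1.5)
    assert gf.n_x == round(mixed_frame.box[0] / 1.5)
    assert gf.cell_size[0] * gf.n_x == pytest.approx(mixed_frame.box[0])


def test_correlation_identical_and_anti(mixed_frame):
    top = grid_density(mixed_frame, 1, "DPPC")
    assert interleaflet_correlation(top, top) == pytest.approx(1.0)
    from raftkit.observables import GridField

    anti = GridField(2 * top.values.mean() - top.values, top.box)
    assert interleaflet_correlation(top, anti) == pytest.approx(-1.0)


def test_correlation_constant_field_flagged(mixed_frame):
    from raftkit.observables import GridField

    top = grid_density(mixed_frame, 1, "DPPC")
    flat = GridField(np.ones_like(top.values), top.box)
    assert np.isnan(interleaflet_correlation(top, flat))


def test_correlation_grid_mismatch(mixed_frame):
    top = grid_density(mixed_frame, 1, "DPPC", cell_size=1.5)
    bot = grid_density(mixed_frame, -1, "DPPC", cell_size=3.0)
    with pytest.raises(ValueError):
        interleaflet_correlation(top, bot)


def test_correlation_independent_fields_near_zero():
    """Null distribution: independent random 13x13 fields give |r| below
    3/sqrt(n) for most draws (checked in aggregate)."""
    from raftkit.observables import GridField

    rng = np.random.default_rng(0)
    box = np.array([19.5, 19.5])
    hits = 0
    n_draws = 200
    for _ in range(n_draws):
        a = GridField(rng.poisson(2.0, (13, 13)).astype(float), box)
        b = GridField(rng.poisson(2.0, (13, 13)).astype(float), box)
        if abs(interleaflet_correlation(a, b)) < 3.0 / 13.0:
            hits += 1
    assert hits / n_draws > 0.95


# --------------------------------------------------------------------------
# Bilayer center, z profile, interdigitation
# --------------------------------------------------------------------------


def test_center_map_flat_symmetric(mixed_frame):
    # tails sit at +/-0.2 nm; per-cell means deviate from zero only by the
    # statistical imbalance of top vs bottom tail counts in the cell
    cm = bilayer_center_map(mixed_frame)
    assert np.abs(cm.values).max() < 0.1
    assert abs(cm.values.mean()) < 0.02


def test_center_map_recovers_tilted_plane():
    reg = _stick_registry()
    b = [0, 0, -BOND_LENGTH_NM]
    slope = 0.05
    # tails exactly at mid(x) + 0.2 with mirrored partners at mid(x) - 0.2
    mols = []
    for x in np.arange(0.5, 12, 1.0):
        for y in np.arange(0.5, 12, 1.0):
            mid = slope * x
            up = _stick((x, y), mid + 2.0, b, b)
            up[3, 2] = mid + 0.2
            lo = up * [1, 1, -1] + [0, 0, 2 * mid]
            mols.append(("STK", 1, up))
            mols.append(("STK", -1, lo))
    frame = make_frame(mols, reg, box=(12, 12))
    cm = bilayer_center_map(frame, cell_size=3.0)
    xs = (np.arange(cm.n_x) + 0.5) * cm.cell_size[0]
    expected = slope * xs
    assert np.allclose(cm.values, expected[:, None], atol=0.06)


def test_center_map_exclusion_matches_clean_frame(small_comp, registry):
    """Adding short-tailed mimic molecules must not move the center when
    they are excluded."""
    comp = CompositionSpec(counts=dict(small_comp.counts))
    base = build_bilayer(comp, seed=11)
    comp2 = CompositionSpec(
        counts={**small_comp.counts, "DPPC_3b": 8}
    )
    with_mimic = build_bilayer(comp2, seed=11)
    cm2 = bilayer_center_map(with_mimic, exclude=("DPPC_3b",))
    assert np.allclose(cm2.values, 0.0, atol=1e-9)
    cm_incl = bilayer_center_map(with_mimic, exclude=())
    # the mimic's short tails sit at the same height here, so centers are
    # still defined; the exclusion path itself must stay clean
    assert cm2.values.shape == cm_incl.values.shape


def test_z_profile_reports_construction(mixed_frame):
    prof = z_profile(mixed_frame)
    for s in ("DPPC", "DUPC"):
        assert prof[s].head_z == pytest.approx(2.0, abs=0.02)
        assert prof[s].tail_z == pytest.approx(0.2, abs=0.02)
        assert not prof[s].interdigitated
    assert prof["CHOL"].head_z == pytest.approx(1.6, abs=0.02)


def test_z_profile_translation_invariant(mixed_frame):
    shifted = mixed_frame.copy()
    shifted.pos = shifted.pos + np.array([0, 0, 4.0])
    a = z_profile(mixed_frame)
    b = z_profile(shifted)
    for s in a:
        assert a[s].head_z == pytest.approx(b[s].head_z)
        assert a[s].tail_z == pytest.approx(b[s].tail_z)


def test_z_profile_interdigitated_flag():
    reg = _stick_registry()
    b = [0, 0, -BOND_LENGTH_NM]
    mols = []
    for x in np.arange(0.5, 6, 1.0):
        for y in np.arange(0.5, 6, 1.0):
            up = _stick((x, y), 2.0, b, b)
            up[3, 2] = -0.05  # tails cross the midplane
            lo = up * [1, 1, -1]
            mols.append(("STK", 1, up))
            mols.append(("STK", -1, lo))
    frame = make_frame(mols, reg, box=(6, 6))
    prof = z_profile(frame)
    assert prof["STK"].interdigitated
    assert prof["STK"].tail_z < 0


def test_interdigitation_gap(mixed_frame):
    res = interdigitation(mixed_frame, "DPPC")
    assert res.applicable
    assert res.gap == pytest.approx(0.4, abs=1e-6)
    assert res.sigma == 0.47


def test_interdigitation_mirror_identity(mixed_frame):
    """For a mirror-symmetric bilayer the gap equals twice the tail height."""
    prof = z_profile(mixed_frame)
    res = interdigitation(mixed_frame, "DPPC")
    assert res.gap == pytest.approx(2 * prof["DPPC"].tail_z, abs=0.02)


def test_interdigitation_not_applicable_asymmetric(small_comp):
    frame = build_bilayer(small_comp, asymmetric=True, seed=3)
    res = interdigitation(frame, "DPPC")
    assert not res.applicable and res.gap is None
    assert interdigitation(frame, "DUPC").applicable


# --------------------------------------------------------------------------
# Umbrella coverage
# --------------------------------------------------------------------------


def _umbrella_frame(registry, lipid_offsets, z_above=0.4):
    """One CHOL at the center plus lipid heads at given lateral offsets."""
    chol = registry["CHOL"]
    coords = np.zeros((chol.n_beads, 3))
    coords[:, 2] = np.linspace(1.6, 0.2, chol.n_beads)
    coords[:, 0] += 5.0
    coords[:, 1] += 5.0
    mols = [("CHOL", 1, coords)]
    for dx, dy in lipid_offsets:
        spec = registry["DPPC"]
        c = np.zeros((spec.n_beads, 3))
        c[:, 2] = np.linspace(1.6 + z_above, 0.2, spec.n_beads)
        c[:, 0] = 5.0 + dx
        c[:, 1] = 5.0 + dy
        mols.append(("DPPC", 1, c))
    return make_frame(mols, registry)


def test_umbrella_one_lipid_geometry(registry):
    res = umbrella_coverage(_umbrella_frame(registry, [(0.05, 0.05)]))
    assert res.covered_fraction == 1.0
    assert res.categories[0] == "one-lipid"


def test_umbrella_offset_outside_small_square(registry):
    # 0.2 > half-side 0.125: not covered by the one-lipid rule, and a
    # single head cannot satisfy the two-lipid rule
    res = umbrella_coverage(_umbrella_frame(registry, [(0.2, 0.0)]))
    assert res.covered_fraction == 0.0


def test_umbrella_two_lipid_rule(registry):
    res = umbrella_coverage(
        _umbrella_frame(registry, [(0.2, 0.0), (-0.2, 0.0)])
    )
    assert res.covered_fraction == 1.0
    assert res.categories[0] == "two-lipid"


def test_umbrella_below_not_covering(registry):
    res = umbrella_coverage(_umbrella_frame(registry, [(0.0, 0.0)], z_above=-0.8))
    assert res.covered_fraction == 0.0


def test_umbrella_no_lipids(registry):
    chol = registry["CHOL"]
    coords = np.zeros((chol.n_beads, 3))
    coords[:, 2] = np.linspace(1.6, 0.2, chol.n_beads)
    res = umbrella_coverage(make_frame([("CHOL", 1, coords)], registry))
    assert res.covered_fraction == 0.0


def test_umbrella_no_sterols_rejected(registry):
    spec = registry["DPPC"]
    c = np.zeros((spec.n_beads, 3))
    with pytest.raises(ValueError):
        umbrella_coverage(make_frame([("DPPC", 1, c)], registry))


def test_umbrella_vectorized_equals_exhaustive(registry):
    """Vectorized result identical to a per-sterol exhaustive geometric
    check on random frames (minimum-image, per-leaflet, z-above rule)."""
    rng = np.random.default_rng(12)
    for trial in range(10):
        mols = []
        box = np.array([8.0, 8.0])
        for _ in range(25):
            spec = registry["DPPC"]
            c = np.zeros((spec.n_beads, 3))
            c[:, 0] = rng.uniform(0, 8)
            c[:, 1] = rng.uniform(0, 8)
            c[:, 2] = np.linspace(rng.uniform(1.8, 2.2), 0.2, spec.n_beads)
            mols.append(("DPPC", 1, c))
        for _ in range(12):
            chol = registry["CHOL"]
            c = np.zeros((chol.n_beads, 3))
            c[:, 0] = rng.uniform(0, 8)
            c[:, 1] = rng.uniform(0, 8)
            c[:, 2] = np.linspace(rng.uniform(1.4, 2.0), 0.2, chol.n_beads)
            mols.append(("CHOL", 1, c))
        frame = make_frame(mols, registry, box=box)
        res = umbrella_coverage(frame)
        # exhaustive reference
        lipid_heads = [m[2][0] for m in mols if m[0] == "DPPC"]
        k = 0
        for name, leaf, coords in mols:
            if name != "CHOL":
                continue
            ch = coords[0]
            n_one = n_two = 0
            for lh in lipid_heads:
                d = lh[:2] - ch[:2]
                d -= box * np.round(d / box)
                if lh[2] <= ch[2]:
                    continue
                if abs(d[0]) <= 0.125 and abs(d[1]) <= 0.125:
                    n_one += 1
                if abs(d[0]) <= 0.235 and abs(d[1]) <= 0.235:
                    n_two += 1
            expected = ("one-lipid" if n_one >= 1
                        else "two-lipid" if n_two >= 2 else "uncovered")
            assert res.categories[k] == expected, f"trial {trial} sterol {k}"
            k += 1


# --------------------------------------------------------------------------
# Pair energy
# --------------------------------------------------------------------------


def _numeric_shifted(r, p, r1, rc):
    """Independent oracle: integrate the shifted force from r to rc."""
    d = rc - r1
    A = -p * ((p + 4) * rc - (p + 1) * r1) / (rc ** (p + 2) * d**2)
    B = p * ((p + 3) * rc - (p + 1) * r1) / (rc ** (p + 2) * d**3)

    def force(x):
        f = p / x ** (p + 1)
        if x > r1:
            f += A * (x - r1) ** 2 + B * (x - r1) ** 3
        return f

    val, _ = quad(force, r, rc, limit=400, epsabs=1e-13, epsrel=1e-12)
    return val


@pytest.mark.parametrize("p, r1", [(12, 0.9), (6, 0.9), (1, 0.0)])
@pytest.mark.parametrize("r", [0.45, 0.8, 0.95, 1.1, 1.19])
def test_shifted_kernel_matches_force_integral(p, r1, r):
    assert shifted_power(np.array([r]), p, r1, 1.2)[0] == pytest.approx(
        _numeric_shifted(r, p, r1, 1.2), rel=1e-8, abs=1e-12
    )


def test_shifted_kernel_zero_at_and_beyond_cutoff():
    for p, r1 in [(12, 0.9), (6, 0.9), (1, 0.0)]:
        assert shifted_power(np.array([1.2, 1.5, 3.0]), p, r1, 1.2) == pytest.approx(0.0)


def test_lj_minimum_closed_form(matrix):
    """Two C1 beads at r = sigma * 2^(1/6): the plain LJ equals -eps; the
    shifted value is -eps minus the constant potential-shift correction.
    Both relations are checked against the numeric force integral."""
    eps, sigma = 3.5, matrix.sigma
    rmin = sigma * 2 ** (1 / 6)
    c12, c6 = 4 * eps * sigma**12, 4 * eps * sigma**6
    # oracle: integrate the shifted force from rmin to the cutoff
    expected = (c12 * _numeric_shifted(rmin, 12, 0.9, 1.2)
                - c6 * _numeric_shifted(rmin, 6, 0.9, 1.2))
    got = lj_shifted(rmin, eps, sigma)
    assert got == pytest.approx(expected, rel=1e-8)
    # inside the shift-onset radius the correction is a pure constant:
    # V_shift(rmin) = -eps - (c12 C12 - c6 C6)
    c12_const = rmin**-12 - _numeric_shifted(rmin, 12, 0.9, 1.2)
    c6_const = rmin**-6 - _numeric_shifted(rmin, 6, 0.9, 1.2)
    assert got == pytest.approx(-eps - (c12 * c12_const - c6 * c6_const), rel=1e-8)


def test_coulomb_shifted_sign_and_cutoff():
    r = np.array([0.5, 1.0, 1.3])
    v = coulomb_shifted(r, qq=1.0)
    assert v[0] > v[1] > 0.0
    assert v[2] == 0.0
    assert coulomb_shifted(np.array([0.5]), qq=-1.0)[0] < 0.0
    # magnitude at short range approaches the bare screened Coulomb
    assert v[0] == pytest.approx(F_ELEC / EPSILON_R *
                                 _numeric_shifted(0.5, 1, 0.0, 1.2))


def test_pair_energy_beyond_cutoff_zero(registry, matrix):
    reg = _stick_registry()
    b = [0, 0, -BOND_LENGTH_NM]
    frame = make_frame(
        [("STK", 1, _stick((1, 1), 2.0, b, b)),
         ("STK", 1, _stick((4.0, 4.0), 2.0, b, b))],
        reg, box=(10, 10),
    )
    e = pair_energy(frame, matrix)
    assert e.total == 0.0


def test_pair_energy_matches_brute_force(small_comp, matrix):
    """Neighbor-list energy identical to the O(N^2) double loop within
    1e-10 kJ/mol on a ~60-molecule frame."""
    comp = CompositionSpec(counts={"DPPC": 12, "DUPC": 12, "CHOL": 6})
    frame = build_bilayer(comp, seed=8)
    fast = pair_energy(frame, matrix)
    names, vdw, elec = brute_force_energy(frame, matrix)
    assert names == fast.species
    assert np.allclose(fast.vdw, vdw, atol=1e-10)
    assert np.allclose(fast.elec, elec, atol=1e-10)


def test_pair_energy_translation_and_rewrap_invariant(matrix):
    comp = CompositionSpec(counts={"DPPC": 10, "DUPC": 10, "CHOL": 4})
    frame = build_bilayer(comp, seed=9)
    e0 = pair_energy(frame, matrix)
    moved = frame.copy()
    moved.pos = moved.pos + np.array([1.7, -0.9, 0.0])
    moved.pos[:, :2] = np.mod(moved.pos[:, :2], moved.box)
    e1 = pair_energy(moved, matrix)
    assert np.allclose(e0.total_matrix, e1.total_matrix, atol=1e-9)


def test_pair_energy_bookkeeping(matrix, mixed_frame):
    e = pair_energy(mixed_frame, matrix)
    # symmetric totals and consistent per-molecule normalization
    assert np.allclose(e.vdw, e.vdw.T)
    i, j = e.species.index("DPPC"), e.species.index("CHOL")
    n_dppc = e.n_molecules["DPPC"]
    n_chol = e.n_molecules["CHOL"]
    assert e.per_molecule("DPPC", "CHOL") * n_dppc == pytest.approx(
        e.per_molecule("CHOL", "DPPC") * n_chol
    )
    assert e.total == pytest.approx(
        np.triu(e.total_matrix).sum()
    )


# --------------------------------------------------------------------------
# RMSD
# --------------------------------------------------------------------------


def test_rmsd_identity(mixed_frame):
    assert rmsd(mixed_frame, mixed_frame) == 0.0


def test_rmsd_uniform_shift(mixed_frame):
    shifted = mixed_frame.copy()
    shifted.pos = shifted.pos + np.array([0, 0, 1.0])
    shifted.upos = shifted.upos + np.array([0, 0, 1.0])
    assert rmsd(shifted, mixed_frame) == pytest.approx(1.0)


def test_rmsd_xy_drift_removal(mixed_frame):
    shifted = mixed_frame.copy()
    shifted.pos = shifted.pos + np.array([2.0, 0.5, 0.0])
    shifted.upos = shifted.upos + np.array([2.0, 0.5, 0.0])
    assert rmsd(shifted, mixed_frame, remove_xy_drift=True) == pytest.approx(0.0, abs=1e-9)


def test_rmsd_gaussian_perturbation(mixed_frame):
    rng = np.random.default_rng(4)
    s = 0.1
    noisy = mixed_frame.copy()
    pert = rng.normal(0, s, size=noisy.pos.shape)
    noisy.pos = noisy.pos + pert
    noisy.upos = noisy.upos + pert
    assert rmsd(noisy, mixed_frame) == pytest.approx(s * np.sqrt(3), rel=0.05)


def test_rmsd_mismatched_beads(mixed_frame, registry):
    other = make_frame([("DPPC", 1, np.zeros((12, 3)))], registry)
    with pytest.raises(ValueError):
        rmsd(mixed_frame, other)
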