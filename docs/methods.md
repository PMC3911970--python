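# Methods

## Scope and model

raftkit covers the computational side of a coarse-grained (MARTINI 2.0
bead types) study of Lo/Ld phase separation in DPPC/DUPC/CHOL bilayers:
the force-field variant species, the analysis observables, and a
synthetic-trajectory generator that stands in for microsecond MD. The
package does **not** integrate equations of motion; the generator is
kinematic by design, so that every statistical property the analyses
measure is imposed exactly and can serve as ground truth in tests.

## Species registry and nonbonded matrix

The three standard molecules follow the published MARTINI 2.0
constructions. Values that the raft literature prints explicitly — the
DPPC/DUPC chain-bead types (C1 vs C4 at chain positions 2 and 3), the
chain angle terms (180°/25 kJ/mol vs 100°/10 and 120°/45), the C1–C4
cross well depth 3.1 kJ/mol vs 3.5 within a type, the 0.75× ring-pair
scaling, σ = 0.47 nm — are the load-bearing part of the registry and are
covered by exact tests. Head/linker bead types (Q0, Qa, Na), their
charges (±1 on choline/phosphate), bond terms (0.47 nm, 1250 kJ/mol/nm²),
the CHOL ring-bead assignments and the remaining ε entries are registry
defaults taken from MARTINI 2.0 conventions, *not* from the study this
package re-implements; the apolar ε block is uniform at 3.5 kJ/mol except
the C1–C4 pair. They only feed the synthetic energy observable and are
marked as defaults in the code.

Variant rules modify exactly what their names say: `a`/`s` assimilate
both chains' equilibrium angles / force constants to DPPC's, `b2`/`b3`
retype the second/third chain beads to C1. `DPPC_3b` removes the fourth
chain beads (so the original third beads, 7 and 11, become terminal; the
extra chain-tying bond is mapped to the new 7–10 pair after renumbering),
retypes all chain beads SC1 and stiffens chain angles to 300 kJ/mol.
`DPPC_3b_plus1`'s extra bead is typed C1, mirroring the mobile last bead
of CHOL whose 25 kJ/mol angle constant it borrows. Bond lengths and bond
force constants are never modified by any variant.

The topology-include writer prints floats with 17 significant digits and
carries bead roles, chain definitions and the sterol order axis in
structured comments, so write→parse is the identity on every species.

## Synthetic bilayer generator

**What it emulates.** Composition (default 255 DPPC + 405 DUPC +
119 CHOL per leaflet = 0.34:0.51:0.15), mixed/separated/gel lateral
layouts with stripe or disc domains, cross-leaflet domain registration,
per-species per-phase chain order, head/tail z-placement with a tunable
tail–tail gap, optional one-leaflet-pure-DUPC asymmetry, and per-phase
lateral Brownian diffusion.

**Box.** With the default composition and the placement areas
(0.64 nm²/lipid, 0.32 nm²/sterol) the required area is ~460 nm², so the
default box side is derived from the areas (~21.5 nm, the ~20 nm class of
system). Passing an explicit smaller box raises an overfull error.

**Lattice.** Placement is a square lattice with one slot per acyl chain
(sterol bodies take one slot), which preserves the 2:1 lipid:sterol area
ratio and gives a pitch of ~0.57 nm — just outside the LJ minimum, i.e. a
densely packed but clash-free hydrophobic core. In separated layouts the
slot sequence is sorted by stripe (or disc-distance) key; both leaflets
draw the molecule order from one seeded stream, so a registration target
of 1 produces exactly mirrored domain placement. Lower targets shift the
lower-leaflet domain by d = f(1−f)(1−r)L (f = domain area fraction), the
offset at which the correlation of a periodic stripe field with its
shifted copy equals r.

**Chain geometry.** Every chain bond makes the deterministic polar angle
θ\* with the bilayer normal, cos²θ\* = (2S+1)/3, so the measured P2 order
equals the target exactly (no sampling error); terminal tail beads are
anchored at ±gap/2 so the interdigitation distance is exact too. Lateral
bead offsets follow a **shared packing helix**: the offset of a
hydrophobic bead is a fixed function of its distance ζ from the midplane
(azimuth ωζ, ω = 2π/1.4 nm⁻¹; radius chosen per species so each bond hits
θ\*, phase shifted by π in the lower leaflet). Because the offset is a
common function of depth, equal-depth beads of neighboring molecules stay
a full lattice pitch apart regardless of species, and opposing terminal
tails avoid lateral registry at the midplane. Sterol bodies are bead
columns on the same helix whose 3→5 segment is tilted to the target polar
angle. The helix degenerates for near-flat chains (cosθ\* < 0.1), where a
fixed-step azimuth walk is used instead; such extreme order targets are
meant for order-statistic tests, not for energy work.
`sample_chain_orientation` (the public orientation sampler) keeps a
random per-chain azimuth, as its contract only concerns the orientation
statistics.

**Dynamics.** `simulate_lateral_dynamics` applies rigid per-molecule 2D
Gaussian steps of variance 2DΔt per axis, accumulated unwrapped and
wrapped into the box; molecules in gel domains are frozen when
`gel_arrest` is set. Excluded volume is *not* enforced during diffusion,
so pair energies are physically meaningful on as-built configurations
but only qualitatively on diffused ones. The per-phase diffusion
constants and the 1 ns frame spacing are generator defaults (nothing in
the source study fixes them numerically).

**Timecourses.** `generate_timecourse` produces demixing, remixing and
gelation courses as *exchange dynamics on the fixed chain lattice*: the
permutation mapping initial to final occupancy is decomposed into
exchange cycles that switch atomically at frames spread over the
schedule. Every frame is therefore a clash-free lattice configuration
(continuous interpolation was rejected: molecules passing through each
other mid-path produce unbounded LJ spikes). Chain order and the tail gap
interpolate linearly, so order series are monotone by construction, while
energy series are monotone in trend (not strictly per frame — each cycle
switch perturbs the energy locally). Gelation completes its schedule at
70% of the frames and is frozen afterwards, producing the MSD arrest the
classifier requires.

**Default targets.** Disordered-phase order: DPPC 0.40, DUPC 0.30, CHOL
0.60; ordered domain: 0.70/0.35/0.80; gel: 0.90/0.90/0.92. Head heights:
2.0 nm (lipids), 1.6 nm (sterols). Tail gap: 0.40 nm in Ld/Lo (slightly
interpenetrating relative to σ = 0.47 nm), widening to 0.70 nm in the gel
where the straightened tails withdraw from the midplane. Variant species
inherit targets from their family (DU\* → DUPC, CHOL\*/\*3b\* → CHOL,
DPPC\* → DPPC).

**What it does not emulate** — hence what passing tests do and do not
show about real membranes: no energetics-driven motion, no thermostat,
no area fluctuations, no flip-flop, no head-group crowding over sterols
(umbrella coverage of lattice-built bilayers is structurally zero; the
umbrella observable is validated on constructed geometries), no
interface roughness or nucleation kinetics. Tests passing on these
fixtures certify the *analysis machinery* — formulas, bookkeeping, edge
handling — not the physics of any force field.

## Observables

* **Leaflets**: sign of head-bead z against the global mean tail z;
  single-leaflet inputs are flagged, not rejected.
* **Order**: mean over consecutive chain-bond P2 values of both chains;
  bonds between the glycerol linker and the first chain bead are
  excluded (chains are the registry's `chains` lists). Sterols use the
  ring 3→5 axis. Reported values are clipped to [−0.5, 1].
* **Grids**: the per-axis cell count is round(box/cell); the actual cell
  is rescaled so the grid tiles the box exactly (1.5 or 3.0 nm nominal
  cells cannot tile an arbitrary box). Density grids bin head beads,
  PBC-wrapped, and conserve counts exactly.
* **Registration**: Pearson's r on raw per-cell counts of corresponding
  cells, no smoothing; constant fields return NaN as the "undefined"
  flag.
* **Bilayer center**: per-cell mean z of terminal tail beads of both
  leaflets; `DPPC_3b`-like short-tailed species are excluded by default
  (their tails would drag the center toward their own leaflet); empty
  cells are filled by iterated periodic neighbor means and flagged.
* **z-profiles / interdigitation**: distances from the local cell center,
  sign-folded per leaflet, so profiles are symmetric across the midplane
  and translation-invariant; the interdigitation distance is the
  difference of leaflet-mean terminal-tail z (negative = overlap),
  reported alongside σ = 0.47 nm.
* **Umbrella**: axis-aligned squares centered on the sterol head's x/y
  (0.25 nm side for one covering lipid head, 0.47 nm for two), "above"
  meaning toward the leaflet's water phase, minimum-image laterally.
  Centering on the head is a package choice; the source text does not
  state centered-vs-cornered.
* **Energy**: intermolecular shifted LJ (shift onset 0.9 nm) plus shifted
  Coulomb (onset 0, ε_r = 15) with a 1.2 nm cutoff; the shift constants
  make force and potential vanish at the cutoff and are verified against
  numeric force integration. Neighbor search is a periodic k-d tree
  (x/y minimum image; z lifted into a tall non-wrapping slab), verified
  identical to an O(N²) double loop to 1e-10 kJ/mol. Bookkeeping: the
  species-pair matrix is symmetric, the diagonal counts each pair once,
  and per-molecule values normalize by the first species' count.
* **MSD**: molecule-centroid x/y displacements over log-spaced lags with
  multiple time origins; diffusive exponent from the log-log fit below
  20 ns (up to the diffusive regime), D from the linear fit MSD = 4Dt+c.
  Arrest is flagged on a tail log-log slope < 0.2 *or* exact terminal
  immobility (no molecule moved over the last fifth of the frames — the
  signature of the generator's frozen gel states).
* **RMSD**: no rotational superposition (the bilayer normal fixes the
  frame); optional removal of the mean x/y drift only.

## Pipeline and classification

Energy gains are ΔE(t) = E(t) − E(t_ref) with t_ref = 1 ns by default;
off-grid references use the nearest frame and note it. Replicates are
averaged with standard errors over ≥2 runs (a single run carries none,
noted). Phase thresholds are package defaults, echoed into every call's
evidence: gel requires S ≥ 0.8 *and* arrested MSD, Lo is S ≥ 0.45 and
mobile, Ld otherwise. The boundaries are configurable because the
literature gives only "around 0.9" for gel order and no numeric Lo/Ld
boundary; a single gel label is exposed (no sub-gel distinction). The
system-level call is "separated" when the tracked domain species (DPPC
by default) is ordered and its largest 4-connected periodic component
holds ≥ 50% of the occupied cells at 1.5× mean density; the density-
scaled threshold keeps percolating mixed states from masquerading as
domains.

## Numerical choices and degenerate inputs

Grid cells rescale to tile the box; constant fields yield NaN
correlations; empty center-map cells interpolate from neighbors and
error only if the whole grid is empty; molecules map to exactly one cell
via wrapped positions with an upper-edge clamp. The helix construction is
exact for cosθ\* ≥ 0.1 and falls back to an azimuth walk below. MSD
requires unwrapped coordinates and rejects wrapped-only trajectories
with an instruction rather than silently producing artifacts.

## Problem sizes

Tests run the full default composition (1558 molecules) for composition
and single-frame observables, reduced compositions (~120–250 molecules)
for multi-frame pipeline work, and 1000-frame Brownian trajectories for
diffusion recovery; these sizes give per-test runtimes of seconds while
keeping grid statistics meaningful (≥ 6×6 correlation cells).

## Known limitations

Energies on diffused (Brownian) trajectories include excluded-volume
violations; absolute energy values are not comparable to MD averages and
no such claim is made. Exchange-dynamics timecourses have discontinuous
molecule paths, so their MSDs are not diffusive (use
`simulate_lateral_dynamics` for diffusion studies). Umbrella coverage of
lattice-generated bilayers is zero by construction. The GRO surface
carries wrapped coordinates only; unwrapped trajectories travel through
the internal `.npz` columnar store.
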