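# raftkit

Tools for studying **raft formation in ternary lipid/cholesterol
membranes** with the MARTINI coarse-grained description: a generator for
the family of systematically modified DPPC/DUPC/CHOL force-field species,
a synthetic-bilayer trajectory generator, the full set of raft-analysis
observables, and a liquid-ordered / liquid-disordered / gel phase
classifier.

The package is aimed at membrane-biophysics researchers who want to (a)
emit and audit the variant topologies that dissect *which* molecular
property drives Lo/Ld phase separation — the saturated/unsaturated
enthalpic mismatch, chain conformational freedom, or the sterol's rigid
planar body — and (b) develop and test raft-analysis pipelines against
synthetic bilayer configurations with exactly known ground truth, without
running microsecond MD.

## The model in brief

In MARTINI, DPPC and DUPC differ only in the middle chain beads
(`C1` vs `C4`, cross-interaction ε(C1,C4) = 3.1 kJ/mol vs 3.5 within a
type) and in the chain angle terms (DPPC: θ₀ = 180°, k = 25 kJ/mol;
DUPC: 100°/120°, k = 10/45 kJ/mol). CHOL is a rigid planar body of small
`SCx` beads — pairs of small beads interact at 0.75× the regular well
depth — with a short mobile tail. `raftkit.cg_model` builds these species
and every named variant (`DUa`, `DUs`, `DUas`, `DUb2`, `DUb3`, `DUb23`,
`DPPC_soft`, `DPPC_3b`, `CHOL_300`, `CHOL_+1HB`, `DPPC_3b_plus1`) and
writes/parses GROMACS topology includes.

The analysis layer implements the standard raft observables:

* chain order parameter S = (3⟨cos²θ_z⟩ − 1)/2 per species (sterols use
  the ring 3→5 axis), range [−0.5, 1];
* interleaflet domain registration: Pearson correlation of per-species
  density fields on 1.5 nm square cells, leaflet against leaflet;
* local bilayer-center maps (3.0 nm cells, terminal tail beads only),
  head/tail z-profiles and the cross-leaflet tail–tail interdigitation
  distance (compared against σ = 0.47 nm);
* umbrella coverage of sterol heads (0.25 nm one-lipid / 0.47 nm
  two-lipid squares);
* pairwise shifted-LJ + shifted-Coulomb energies (1.2 nm cutoff, shift
  onset 0.9 nm / 0 nm, ε_r = 15) accumulated per species pair and
  normalized per molecule;
* lateral MSD with multiple time origins, log-log diffusive slope and a
  gel-arrest detector.

`raftkit.bilayer` generates two-leaflet configurations (default
510 DPPC : 810 DUPC : 238 CHOL, mole fractions 0.34:0.51:0.15, ~21.5 nm
box) in mixed, separated or gel layouts with controllable per-species
order parameters, cross-leaflet domain registration, tail interdigitation
and per-phase Brownian diffusion — the statistical signatures the
analyses consume, with exactly known ground truth. `raftkit.pipeline`
turns trajectories into energy-gain/order/correlation time series
(ΔE(t) = E(t) − E(1 ns)) and phase calls.

## Worked example

```python
import raftkit as rk
from raftkit.bilayer import CompositionSpec, TimecourseParams

frame = rk.build_bilayer(seed=1)          # mixed 1558-molecule bilayer
for s in ("DPPC", "DUPC", "CHOL"):
    print(f"S_{s} = {rk.order_parameter(frame, s).S:.2f}")
e = rk.pair_energy(frame, rk.build_nonbonded_matrix())
print("E_DPPC = %.1f kJ/mol per molecule" % e.species_total("DPPC"))
print("gap = %.2f nm" % rk.interdigitation(frame, "DPPC").gap)

traj = rk.generate_timecourse(
    "demixing",
    TimecourseParams(comp=CompositionSpec(counts={"DPPC": 40, "DUPC": 64, "CHOL": 19}),
                     n_frames=15),
    seed=3,
)
series = rk.run_timecourse(traj)
calls = rk.classify_phase(series)
print("dE_DPPC(final) = %.1f kJ/mol" % series.dE["DPPC"][-1])
print("corr: %.2f -> %.2f" % (series.corr[0], series.corr[-1]))
print({k: c.label for k, c in calls.items()})
```

prints

```
S_DPPC = 0.40
S_DUPC = 0.30
S_CHOL = 0.60
E_DPPC = -148.8 kJ/mol per molecule
gap = 0.40 nm
dE_DPPC(final) = -61.9 kJ/mol
corr: 0.02 -> 0.87
{'CHOL': 'Lo', 'DPPC': 'Lo', 'DUPC': 'Ld', 'system': 'separated'}
```

Reading this: the mixed bilayer realizes its target order parameters
exactly (disordered DPPC 0.40, DUPC 0.30, CHOL 0.60) with opposing tails
0.40 nm apart. Over the demixing course the saturated lipid gains
interaction energy (ΔE_DPPC falls to −61.9 kJ/mol per molecule as
DPPC/CHOL contacts replace the weaker C1–C4 cross contacts), the DPPC
domains in the two leaflets register (correlation 0.02 → 0.87), and the
classifier calls an ordered-but-mobile DPPC/CHOL domain (Lo) coexisting
with a disordered DUPC phase (Ld) in a laterally separated system.

## Command line

```bash
raftkit make-topologies --variants DUas,DUb23,DPPC_soft --out tops/
raftkit make-fixture --scenario demixing --seed 7 --out fx/
raftkit analyze order --traj fx/traj.npz --out analysis/
raftkit classify --traj fx/traj.npz --out calls/
```

Every output CSV/JSON embeds the seed and a configuration hash, so any
result file is regenerable from its own header.

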