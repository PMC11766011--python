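# vsdgate

Tools for studying how charge reversal of the uppermost S4 arginine in a
voltage-sensor domain (VSD) affects gating, in two independent arms:

1. **Structural arm** — build a toy four-helix VSD (or read any PDB), drive
   the S4 "sliding helix" down in 0.5 Å steps with plane constraints on its
   four basic-residue CA atoms, flat-bottom positional restraints on S1–S3,
   and Monte-Carlo minimization of a documented coarse-grained surrogate
   energy (Coulomb with distance-dependent dielectric, 12-6 Lennard-Jones,
   harmonic helix virtual bonds). Analyze salt bridges, bridge-distance
   series, and S4 rotation direction along the trajectory.
2. **Electrophysiology arm** — generate synthetic whole-cell Na⁺-current
   sweeps from a known gating truth under four protocols (IV,
   steady-state inactivation with 500 ms prepulse, fast inactivation with
   20 ms prepulse, two-pulse recovery), then run the standard patch-clamp
   analysis chain: peak/time-to-peak/50%-decay sweep features, current
   density, chord conductance `G = I/(V − V_rev)`, Boltzmann fits of
   activation and availability, bi-exponential recovery fits, and unpaired
   two-sample t statistics. Shipped gating presets `WT` and `R219E` let the
   whole chain be validated as a closed loop (simulate → analyze → recover
   the generating parameters).

## CLI

All functionality is exposed through one entry point, `vsdgate`:

```sh
vsdgate build-vsd --variant WT --out vsd.pdb
vsdgate deactivate --in vsd.pdb --s4-helix S4 --steps 21 --step-size 0.5 \
        --seed 1 --out traj.pdb --energies energies.csv
vsdgate contacts --in vsd.pdb --cutoff 4.5 --out contacts.csv
vsdgate bridge-series --traj traj.pdb --pair A:63 A:23 --out series.csv
vsdgate rotation --traj traj.pdb --marker A:63 --out rotation.csv
vsdgate align --mobile a.pdb --reference b.pdb --out aligned.pdb
vsdgate synth --preset WT --protocol iv --seed 1 --noise 50 --out traces.csv
vsdgate analyze --traces traces.csv --protocol traces.json \
        --capacitance 9.2 --out results/
vsdgate compare --summary-a 8.6 0.5 32 --summary-b 9.2 0.8 21
vsdgate demo --seed 7 --out demo/        # full WT-vs-R1E synthetic study
vsdgate show-config
```

Trajectories are multi-model PDB files (HELIX records carry the helix
annotations). `energies.csv` has columns
`step, z_offset, coulomb, lj, backbone, restraint, total` (kcal/mol).
Traces are long-format CSV (`sweep_id, voltage_or_interval, time_ms,
current_pA`) with a JSON sidecar holding protocol and generating truth.
Every subcommand writes a provenance JSON (config + version + seed) next
to its outputs.

In the toy VSD the uppermost S4 arginine (R1) is residue A:63 and the S2
glutamate (E1) is A:23; the WT deactivation trajectory ends with their
charged sites salt-bridged, while the charge-reversal variant (`R1E`)
shows repulsion between the two glutamates throughout.

## Module map

| module                 | contents |
|------------------------|----------|
| `structures_io`        | Atom/Structure types, fixed-column PDB I/O, toy VSD builder, Kabsch superposition |
| `steered_deactivation` | surrogate energy model, restraints, MC minimizer, stepped S4 downshift driver |
| `contact_analysis`     | charged sites, salt bridges/repulsive pairs, bridge-distance and rotation series |
| `ephys_synth`          | gating truth (`GatingParams`), protocols, trace simulation, WT/R219E presets |
| `ephys_analysis`       | sweep features, IV/conductance, Boltzmann/recovery fits, group statistics |
| `cli`                  | `vsdgate` command-line interface and provenance records |

## Notes on the surrogate energy

The structural arm is deliberately coarse-grained: a CA trace plus one
charged interaction site per ionizable side chain (Arg 4.1 Å, Lys 3.9 Å,
Glu 3.1 Å, Asp 2.5 Å from the CA along the outward radial), Coulomb
`332.06·q₁q₂/(ε(r)·r)` with `ε(r) = r`, LJ σ = 4.0 Å / ε = 0.1 kcal/mol,
and virtual bonds (i,i+1 at 3.8 Å; i,i+4 at 6.2 Å; site tethers; k = 10).
It preserves the protocol structure and the sign of every interaction, not
all-atom energetics. All constants are configurable via `EnergyModel`.
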