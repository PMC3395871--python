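# icbem

Boundary-element electrostatics for systems of discrete point charges in
piecewise-uniform dielectrics with sharp boundaries. The package computes the
polarization (induced) surface-charge density on a discretized dielectric
boundary and evaluates potentials, reaction potentials and Gauss's-law
consistency, at the scale of nano-scale biophysical systems such as ion
channels.

Two solution routes are provided for the dense tile equations `A h = b`:

* **ICC** — direct dense LU solve. The matrix depends only on the geometry,
  so its factorization is computed once and reused for any number of
  source-charge configurations (`icbem.ICCSolver`).
* **ITER** — Jacobi-style iterative refinement starting from the direct
  source term, stopped when the per-tile relative update drops below a
  threshold (`icbem.solve_iter`).

## Layout

| module            | contents |
|-------------------|----------|
| `icbem.geometry`  | analytic tilings: sphere (uniform θ/φ bands) and axisymmetric channel (faces, pore wall, toroidal corners); dielectric assignment |
| `icbem.solvers`   | matrix/source assembly (centroid quadrature, optional curved self-terms and graded near-field quadrature), ICC and ITER solvers |
| `icbem.field`     | total/reaction potential evaluation, potential maps, Gauss's-law audit |
| `icbem.analytic`  | Legendre-series reaction potential of a charge in a dielectric sphere; Gauss closed forms (test oracles) |
| `icbem.scenarios` | benchmark builders: dielectric sphere, toy ion channel, dipole rings, ion trajectory sweeps |
| `icbem.cli` / `icbem.config` / `icbem.io` | command line, validated YAML configs, CSV/JSON/OBJ writers |

Units: lengths in Å, charges in elementary charges, relative permittivities;
potentials in reduced units `e/(4πε₀·Å)` (multiply by
`icbem.REDUCED_TO_VOLTS = 14.3996` for volts).

## CLI

```sh
icbem run config.yaml                 # configured scenario -> artifacts
icbem compare-solvers -t 8 -t 16      # ICC vs ITER sweep (timings informational)
icbem sphere-benchmark                # error table vs the analytic series
icbem channel-sweep                   # ion-trajectory reaction potential + Gauss audit
icbem potential-map --broken          # dipole-ring map at z = 0
icbem export-mesh --scenario channel  # mesh CSV/OBJ
```

Example `config.yaml`:

```yaml
scenario: channel            # sphere | channel | channel-dipoles | channel-dipoles-broken
solver: both                 # icc | iter | both
delta_stop: 1.0e-4
channel:
  pore_radius_angstrom: 6.5
  membrane_width_angstrom: 30.0
  n_tiles_target: 860
ion_position_angstrom: [0.0, 0.0, -25.0]
out_dir: out
```

Every run writes the mesh, per-tile solution, and a diagnostics JSON that
always includes the Gauss audit (total induced charge vs the closed-form
expectation from the enclosed charges). Identical configs produce
byte-identical outputs.

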