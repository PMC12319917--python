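# atomflow

A desk-scale, flowchart-driven molecular modelling workbench for
computational chemists and materials scientists who want reproducible,
scriptable simulation workflows without a cluster: build liquid cells
from SMILES, type them with a SMARTS-annotated force field, analyze
trajectories and time series (diffusion, ionic conductivity, thermal
conductivity, RDFs, thermal expansion, convex-hull stability), and run
potential-energy-surface thermochemistry — all as versioned, re-runnable
workflow steps over a shared relational data model.

## What's inside

| module | what it does |
|---|---|
| `atomflow.datamodel` | systems/configurations with shared atom & bond sets, subsets, templates; bit-exact relational persistence; molecular-graph traversal (molecules, angles, dihedrals, substructure matching) |
| `atomflow.properties` | star-schema property store: new result types are metadata rows, not schema migrations |
| `atomflow.flowchart` | flowchart JSON (+ shebang), plug-in registry/API, sequential interpreter, file-backed job datastore with rebuildable index, citation aggregation; CLI `atomflow run/validate/jobs/synth` |
| `atomflow.builder` | SMILES → 3-D molecules (RDKit ETKDG); density-driven cell sizing; clash-free random packing into a reduced region |
| `atomflow.forcefield` | `.ff` text format with SMARTS atom typing; harmonic bonded terms, LJ + tail correction, cutoff Coulomb, Buckingham `A e^(−r/ρ) − C/r⁶`; analytic gradients |
| `atomflow.analysis` | ACF/statistical inefficiency `g`, equilibration detection, steady-state averages; MSD → `D = slope/6`; `D_salt = 2D₊D₋/(D₊+D₋)`; Nernst–Einstein `σ = Ne²(D₊+D₋)/(Vk_BT)`; `t₊ = D₊/(D₊+D₋)`; RDF/CN; expansion `α = ΔL/(LΔT)`; lower convex hulls |
| `atomflow.thermal` | Green–Kubo `κ = (1/k_BT²V)∫⟨J(0)J(t)⟩dt`, Helfand moments `M(t) = ⟨(G(t)−G(0))²⟩` with `κ = slope/(2k_BT²V)`, and Helfand derivatives |
| `atomflow.pes` | finite-difference Hessians, Eckart-projected harmonic frequencies, RRHO thermochemistry, improved-tangent NEB with climbing image, eigenvector-following TS refinement with imaginary-mode verification |
| `atomflow.synth` | generators with known ground truth: Brownian walkers, OU series, synthetic heat flux, step series, a velocity-Verlet LJ integrator |

## Worked example: sizing and packing a liquid-ethanol cell

```python
from atomflow import builder

ethanol = builder.structure_from_smiles("CCO")   # 9 atoms, 8 bonds
plan = builder.plan_cell([(ethanol, 1)], density_guess=0.7, target_atoms=2000)
print(plan.components[0][1], round(plan.outer_edge, 4),
      round(plan.outer_edge - plan.inner_margin, 4))
```

prints

```
222 28.9493 26.9493
```

i.e. 222 ethanol molecules (1998 atoms ≈ the 2000-atom target), a final
cubic periodic cell of edge 28.9493 Å fixed by mass/density, and the
reduced 26.9493 Å packing cube that keeps periodic images from clashing.
`builder.pack(plan, seed=1)` then places the molecules with random rigid
rotations so that no intermolecular atom pair — including across periodic
images — is closer than 2 Å.

The same workflow as a flowchart job:

```bash
atomflow run examples/ethanol.flow --var smiles=CCO --seed 1 --datastore ds
atomflow jobs list --datastore ds
```

Each step runs in its own directory under `ds/job_000001/`, results land
in the shared property store, and `citations.bib` collects one entry per
tool the run actually used.

Transport analysis on data with known truth:

```python
from atomflow import synth, thermal, analysis as an

runs, kappa_true = synth.heat_flux(C0=1.0, tau=5.0, T=1.0, V=1.0,
                                   dt=1.0, n=100_000, n_runs=10, seed=3)
for method, est in thermal.estimate_all(runs).items():
    print(f"{method:20s} {est.kappa:.3f} +/- {est.uncertainty:.3f}")
```

```
green-kubo           4.975 +/- 0.033
helfand-moment       5.090 +/- 0.179
helfand-derivative   5.054 +/- 0.132
```

against the closed-form value `kappa_true = 5.0` (reduced units): three
independent estimators agreeing with the truth and each other within a
few percent.

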