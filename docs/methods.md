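# Methods

This note documents the models, estimators and numerical choices behind
`atomflow`, and what the synthetic-data tests do and do not demonstrate
about real simulation data.

## Data model

A *system* is an ordered collection of *configurations*; a configuration
is a snapshot of atoms, bonds, Cartesian coordinates (Å), a periodic cell,
total charge and spin multiplicity.  Atom sets and bond sets are
first-class, shareable objects: two conformers of one molecule reference
the same atom set with different coordinate arrays, and a reaction's
reactant and product can share atoms while holding different bond sets.
Sharing is by Python object reference in memory and by junction tables
(`atomset_atom`, `bondset_bond`) in the embedded sqlite store.  sqlite
stores REAL columns as IEEE-754 doubles, so the persistence round trip is
bit-exact; the test suite asserts this on randomized systems.

Aromatic bonds carry a distinct `aromatic` order label rather than the
ambiguous 1.5 so that round trips are lossless.  Symmetry is stored as an
opaque group label; no symmetry expansion is performed.

Template matching is element- and bond-order-preserving subgraph
*monomorphism* (networkx VF2), so a methyl template matches a methyl group
even though its carbon has an extra ring/chain bond in the target.
Hydrogens are matched explicitly — a template with three H atoms requires
three explicit H atoms in the target.  Matches covering the same atom set
(template automorphisms) are reported once.

## Property store

Results live in a star schema: a `property` dimension table carries
name/kind/units metadata, and a dense `data` fact table carries one row
per stored scalar (vector values become ordered child rows keyed by
index).  Defining a new property type while the store is open is a single
metadata row insert; no migration touches existing records.  Uncertainties
are companion properties named `<name>,stderr`, keeping the fact table
scalar.  Queries are SQL filters plus a small in-Python range filter, and
are checked against a linear-scan oracle in tests.

## Flowcharts and the plug-in contract

A flowchart is JSON (optionally behind a shebang line) with
`format_version`, `variables`, `start`, `nodes` and `edges`.  Every node
records the plug-in's `module_id`, `class_id` and `version`; parameters
are opaque to the engine and round-trip byte-for-byte.  `${name}`
placeholders in string parameters are substituted at step start;
placeholders naming variables that do not exist yet are left verbatim,
which is what lets loop bodies reference their iteration variable.

Execution is sequential and single-process.  Each step runs in its own
`step_<n>_<class_id>` directory and touches shared state only through the
system and property stores in its context — that is the entire interface
between plug-ins.  Per-step seeds are derived deterministically from the
job seed, so a re-run with the same seed reproduces the property store
exactly.  Loops create `iter_<k>` subdirectories; subflowcharts nest
without depth limit and write under the parent step's directory.  Each job
directory carries a `job_data.json` sufficient to rebuild the index, and
`rebuild_index` is tested to equal the incrementally built index.
Citations raised by steps are de-duplicated by key in order of first use
and written to `citations.bib`; malformed BibTeX is kept verbatim with a
logged warning, since dropping a citation is worse than keeping an ugly
one.

## Liquid-cell construction

Cell sizing: molecule counts are the mixing ratios scaled so the total
atom count is as close as possible to the target (default 2000 atoms,
counting hydrogens; the scale factor is rounded half-up), and the cubic
edge follows from `L = (m/ρ)^(1/3)` using IUPAC standard atomic weights.
For ethanol at 0.7 g/ml this gives 222 molecules and L = 28.9492 Å.
Packing uses a *reduced* region — cube edge `L − margin` with margin
2.0 Å, inferred from the printed 26.9492/28.9492 pair and configurable —
so that making the cell periodic cannot create short contacts across the
boundary.  A droplet is sized to the equal-volume sphere; its exact sizing
rule is an assumption and is flagged as such.

Placement is sampling-based, not force-field optimization: molecules are
assigned to a shuffled lattice of candidate sites spanning the region,
each receives random rigid rotations and jitters, and candidates leaving
any intermolecular atom–atom distance (minimum image for cubic cells)
below `clash_distance` = 2.0 Å are rejected and resampled, sweeping over
offenders until the packing is clash-free.  Pure sequential rejection
sampling jams well below liquid density (random sequential adsorption
saturates early), so the sampler adds two purely stochastic repairs:
re-drawing orientations of offending molecules, and relocating a stuck
molecule to a vacant lattice site when sweeps stall.  Packing is
deterministic given the seed.  Note the margin makes the *interior*
density higher than nominal; for small cells or droplets (where the
margin shell is a large volume fraction) packing at full liquid density
can be genuinely infeasible and fails with a diagnostic rather than
degrading the clash guarantee.

## Force field

The `.ff` file format is this package's own sectioned text format:
`[types]` (SMARTS-annotated atom types), `[bonds]`, `[angles]`,
`[torsions]`, `[nonbonded]`, `[buckingham]`.  Typing matches every SMARTS
rule (via RDKit) against the molecular graph; among rules matching an
atom, highest priority wins, ties broken by longest pattern then file
order.  This precedence is a documented assumption — force-field
distributions do not agree on one.  Any untyped atom is an error listing
index and element: silent fallback types produce silently wrong energies.

Energy terms (kcal/mol internally; Buckingham sections may be given in eV
and are converted on parse):

* bonds `k_b (r − r0)²`, angles `k_θ (θ − θ0)²` (θ in radians),
* torsions `Σ_n k_n (1 + cos(nφ − δ_n))`,
* Lennard-Jones 12-6, Lorentz–Berthelot combination, cutoff 10 Å with
  minimum image, and for periodic systems the analytic tail correction
  `U_tail = Σ_ab (8/3)π (N_a N_b/V) ε σ³ [(1/3)(σ/r_c)⁹ − (σ/r_c)³]`,
* Buckingham `A e^(−r/ρ) − C/r⁶` for pairs listed in `[buckingham]`,
* Coulomb `q_i q_j / r` inside the cutoff.  Electrostatics are
  cutoff-only by design; there is no Ewald/PPPM, which is a documented
  inaccuracy for strongly ionic periodic systems.

1-2 and 1-3 pairs are excluded from nonbonded terms.  All gradients are
analytic and validated against central differences (step 1e-5 Å, agreement
1e-6) on randomized geometries for every term.

## Time-series statistics

The ACF uses the unbiased-normalization estimator (FFT-based) with a
Bartlett standard-error band.  The correlation time τ is a least-squares
fit of `exp(−t/τ)` over lags up to the first zero crossing.  Statistical
inefficiency is `g = 1 + 2 Σ_k (1 − k/n) ρ_k` with the sum truncated at
the first negative ACF value — a standard bias/variance compromise — and
the standard error of a mean is `sqrt(g·var/n)`.  Equilibration detection
picks the truncation point t₀ maximizing the effective sample count
`(n − t₀)/g` over a 40-point grid spanning the first 80% of the series;
this pins down a reproducible rule for the stated goal (discard the
transient, keep the most information).  The cross-check oracle is a family
of constructed change-point series with known truth.

## Transport coefficients

MSD uses all time origins via the standard FFT decomposition; wrapped
trajectories are unwrapped from minimum-image frame-to-frame increments
(valid while no particle moves more than half a box edge per frame).  The
diffusion constant is the least-squares slope of the linear regime divided
by 6, with the fit window defaulting to 20–80% of the available lag range;
callers should keep the maximum lag well below the series length, since
long lags have few independent origins and only add noise.  Salt
diffusivity, Nernst–Einstein conductivity
`σ = N e² (D₊ + D₋)/(V k_B T)` and the transference number
`t₊ = D₊/(D₊+D₋)` are direct arithmetic on the fitted diffusivities;
Nernst–Einstein neglects ion–ion correlations by construction.  All
physical constants come from one table (CODATA 2018 via scipy).

RDF uses standard shell normalization under minimum image; the
coordination number is `CN(r) = 4πρ_b ∫ g s² ds`, and the first-shell CN
is read at the first local minimum of window-3-smoothed g(r).  Thermal
expansion fits `L(T)/L(T_ref)` per axis by least squares; the average is
the arithmetic mean of the axes.  The composition stability construction
is a monotone-chain lower convex hull with per-point vertical distances;
duplicate compositions keep the lower energy.

## Thermal conductivity

Three estimators over the same heat-current input J(t):

* **Green–Kubo**: κ(t) is the cumulative trapezoid of the multi-origin
  flux autocovariance times `1/(k_B T² V)`; the plateau is extracted by
  fitting `κ∞ (1 − e^(−t/τ_f))`, which is exact for an exponential-ACF
  integrand.
* **Helfand moments**: `G(t) = ∫ J dτ` (cumulative trapezoid);
  `M(t) = ⟨(G(t) − G(0))²⟩` with the ensemble realized as non-overlapping
  segments re-originated at G = 0, pooled across runs and Cartesian
  components; κ is the slope of M over its latter half divided by
  `2 k_B T² V`.
* **Helfand derivative**: κ from the plateau (mean over the last half) of
  the smoothed dM/dt; a >20% drift across the plateau flags the estimate.

Window lengths matter: integrating or fitting far beyond the flux
correlation time only accumulates noise.  `estimate_all` therefore fits an
exponential to the flux ACF first and sets the GK lag window to ~20τ and
the Helfand segment length to ~100τ.  With those windows all three
estimators recover the closed-form κ of exponential-ACF synthetic fluxes
within a few percent across τ ∈ {2, 5, 20} frames, and agree with each
other within 15% under the test conditions (10 runs × 1e5 frames).

## Potential-energy surfaces

Engines expose `energy(x)` and `gradient(x)` on flat coordinate vectors;
everything downstream needs nothing else.  Numerical Hessians are central
differences of gradients (default step 0.01 Å, 6N gradient calls),
symmetrized as `(H + Hᵀ)/2`.  Frequencies come from the mass-weighted
eigenproblem with Eckart-frame projection of translations and rotations
(the standard scheme; verified via the 3N−6 mode count), converted by
`ν̃ = sqrt(λ)/(2πc)` with negative eigenvalues reported as imaginary
("458.0i") frequencies.  On the analytic toy-engine suite (harmonic,
Morse dimer) the finite-difference route reproduces analytic frequencies
to well under 1 cm⁻¹ at the default step.

RRHO thermochemistry uses ideal-gas rigid-rotor harmonic-oscillator
partition functions; imaginary and near-zero modes are excluded and
counted.  Rotational terms are included only when principal moments of
inertia are supplied; otherwise results are meaningful as differences
between similar configurations.

NEB uses the improved-tangent (upwind) scheme with an optional climbing
image (enabled after the first 20 iterations) and a quick-min projected
velocity integrator.  Transition-state refinement is Newton /
eigenvector-following on numerical Hessians — the lowest mode is followed
uphill — with verification that exactly one imaginary mode remains; landing
on a minimum or higher-order saddle is an explicit failure naming the
imaginary-mode count.  On the two-dimensional Müller–Brown benchmark the
climbing-image path plus refinement reproduces the saddle located by an
independent grid+Newton search to ~1e-4.

## Synthetic data: what passing tests show

The generators produce data whose ground truth is known by construction:
Brownian walkers (per-frame displacement variance `2 D dt` per component),
Ornstein–Uhlenbeck series (exact discrete update, ACF `e^(−t/τ)`),
heat-flux triplets of independent OU components (closed-form
`κ = C₀τ/(k_B T² V)`), step series with known change points, and a
velocity-Verlet Lennard-Jones integrator (truncated-shifted potential,
NVE or BAOAB Langevin) for physically coherent frames.  Passing tests
demonstrate that the estimators are *correct* — they recover known
coefficients at stated precision from data obeying their assumptions.
They do not demonstrate robustness to real-MD pathologies: cross-correlated
flux components, aging/non-stationarity, barostat coupling artifacts, or
ions with correlated motion (where Nernst–Einstein is known to overestimate
conductivity).  Generator defaults are the package's study conditions and
are not tuned per run.

## Known limitations

* Cutoff Coulomb only; ionic periodic systems need an external Ewald code.
* The packing sampler guarantees the clash criterion or fails loudly; it
  does not produce equilibrated liquid structure (use the LJ integrator or
  an external engine to relax).
* Droplet packing at full liquid density can be infeasible because the
  margin shell concentrates the interior density (see above).
* Template matching is explicit-hydrogen only.
* RRHO rotational terms require caller-supplied moments of inertia.
* The job engine is sequential and local; there is no queueing system,
  web dashboard or remote execution.
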