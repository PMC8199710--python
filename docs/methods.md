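# Methods

## Scope and model structure

`radiolysim` simulates the chemical stage of water radiolysis in a cubic
water volume with reflective walls.  The physical and physico-chemical
stages (track-structure transport, sub-picosecond electron physics) are
out of scope; initial conditions are supplied directly, either as
molecules placed in a voxel or as a *synthetic* track of Gaussian spurs
(see below).  The chemical stage is split into three sub-stages sharing
one chemistry table:

* **microscopic** (0 → t₁): explicit Brownian particles — required while
  species are concentrated in spurs and no compartment can be called
  well-mixed;
* **mesoscopic** (t₁ → t_n): lattice reaction–diffusion master equation
  (RDME) advanced by the next sub-volume method (NSM), with the mesh
  hierarchically coarsened as the system homogenizes;
* **homogeneous** (t_n → end): a single well-mixed voxel sampled with
  the direct-method Gillespie algorithm (CME) over reactions only.

Total molecule counts per species are asserted equal across every
representation change (particles→mesh, each merge, mesh→CME); a
violation is a hard failure, not a warning.

## Chemistry

A chemistry table lists species (diffusion coefficient in m²/s, charge
for bookkeeping) and second-order reactions (rate in M⁻¹s⁻¹, optional
explicit reaction radius).  The bundled `pure_water_25C` table carries
the standard nine diffusion-controlled reactions of the pure-water
radiolysis set at ambient temperature.  Water is the continuum solvent;
H₂O written as a reactant or product is stripped at load time.  The
solvated-electron diffusion coefficient is 4.9×10⁻⁹ m²/s (25 °C); the
other defaults (•OH 2.8, H• 7.0, H₃O⁺ 9.46, H₂ 4.8, OH⁻ 5.3, H₂O₂
2.3, ×10⁻⁹ m²/s) are the values in common use in track-chemistry codes
and can be overridden in any config.

All rates are converted to SI at load time, at a single point:
`rate_to_per_molecule(k, V) = k / (N_A · V_litres)` is the event rate of
one distinct reactant pair sharing a well-mixed volume V.

### Reaction radii and the symmetry convention

Unless configured explicitly, the encounter radius is the Smoluchowski
inversion σ = k_mol / (4π D′), with k_mol = k/(1000·N_A) the rate in
m³/s and D′ the sum of the reactant diffusion coefficients.  One
convention choice deserves a note: with compartment propensities written
as S_m·S_l·k′ for distinct and ½S(S−1)·k′ for identical reactants, each
*distinct pair* reacts at rate k′ — so the particle picture must give
each distinct pair an encounter rate 4πσD′/V = k′, i.e. the same σ
formula for identical and distinct reactants, with **no** extra factor
of two.  We verified this numerically: with a doubled σ the particle
engine decays exactly twice as fast as the exact CME limit of the same
table, while with the convention above the two engines and the
mean-field ODE (1/N = 1/N₀ + k′t) agree.

Configured radii override the formula (used, e.g., to model the 0.36 nm
electron-recombination radius, for which π·σ = 1.13 nm is the critical
voxel size in the mesh-choice example); the inversion is a closure for
rates, not a claim about physical encounter distances.

## Particle engine (step-by-step Brownian dynamics)

Per step: (1) choose Δt; (2) sample reactions; (3) propagate.

**Dynamic time step.**  For the closest pair of every reactive channel
the engine inverts the absorbing-sphere first-passage probability

    P(t) = (σ/r) · erfc((r − σ) / √(4 D′ t))

for P = 1 − confidence (default 0.95) and takes the minimum over
channels, clipped to [min step, max step] (defaults 1 ps, 1 ns).  Pairs
with σ/r < 1 − confidence can never reach that reaction probability and
do not constrain the step.

**Reaction sampling.**  Each reactive pair at separation d reacts within
the step with probability P(Δt) evaluated at d (certainty at d ≤ σ).
Hits are applied greedily, nearest pair first, ties broken by lowest
particle index; each molecule reacts at most once per step; products
appear at the reactants' midpoint.  Because the dynamic step caps every
pair's per-step probability at 1 − confidence, the scheme follows the
exact pair kinetics closely: on an isolated pair at r = 10σ it yields a
10 ns reaction probability of 0.095 against the exact 0.091.  Two
simpler schemes were evaluated and rejected: a pure end-of-step overlap
test misses almost all crossings once the step length exceeds σ (the
electron-recombination benchmark then stalls), and the one-dimensional
Brownian-bridge crossing probability over-reacts by ~3× at these step
sizes because it ignores the 3-D geometric factor σ/r.  The residual
approximation is that survivors' end-of-step positions are drawn from
free propagation (not conditioned on no encounter); its bias is bounded
by the per-step probability cap.

**Propagation and walls.**  Isotropic Gaussian displacement with
per-axis variance 2DΔt, then mirror reflection into [0, L]³ (folded as
often as needed).  No inter-particle forces; ions are treated as neutral
diffusers.

## Lattice engine (RDME / NSM)

The mesh is M³ cubic voxels (x-fastest linear indexing), sparse storage
for occupied voxels only.  Voxel propensity = Σ reactions + Σ diffusion
channels; diffusion to each existing face neighbour at λ = D/h² per
molecule (reflective walls simply contribute no channel).  The NSM keeps
one pending event per active voxel, keyed by an exponential firing time
τ = now − ln(ξ)/a, in a lazy-invalidation binary heap (ties resolve to
the lower voxel index).  After an event, affected voxels get fresh
exponential draws from their updated propensities — the per-voxel direct
method, not the rate-rescaling of the next-reaction method.  The event
channel is drawn at firing time; this is statistically identical to
drawing it at scheduling time because a voxel's propensities cannot
change without that voxel being rescheduled.

**Hierarchical coarsening.**  Meshes with side 2^m merge eight octant
voxels into one (side/2); meshes with side 3^m merge twenty-seven into
one (side/3).  Merge n is scheduled at t₁ + Σ_{k≤n} Δt_k with

    Δt_n = 20 · h_n² / (6 · D_min)

where h_n is the voxel size of the *coarser* (post-merge) mesh — the
transfer time must allow diffusive mixing across the voxel being formed,
which is the coarse one — and D_min is the lowest diffusion coefficient
in the chemistry table (not of the species currently alive), so the
schedule is computable up front.  Both readings of h_n are one flag
apart in `transfer_time`; the coarser-mesh reading is the default.
Merges conserve every species total exactly and discard pending events;
the queue is rebuilt on the coarse mesh.

**Voxel-size validity.**  h should lie between the critical size π·σ_max
(below which in-voxel well-mixed rates miss reactions) and the mean
inter-particle distance d = (V/N)^{1/3} (above which initial voxels are
not well-mixed).  `mesh_resolution` and `build_merge_schedule` warn, not
fail, on violations, since transiently invalid meshes can still be
useful.

## Synthetic initial conditions

`central_voxel_injection` places N molecules uniformly in the central
voxel of an odd mesh — the dense starting state of the diffusion and
reaction–diffusion benchmarks.

`synthetic_track` stands in for an electron track: spurs evenly spaced
on a straight segment, each releasing a configured species mix from an
isotropic Gaussian (default width 2 nm, tails reflected into the box so
multiplicities are conserved).  The default spur (40 eV; 2 e⁻aq, 2 •OH,
2 H₃O⁺, 1 H•) gives early G-values of 5/5/5/2.5 molecules per 100 eV —
representative low-LET early-chemistry yields.  It reproduces none of
the microscopic structure of a transport calculation (energy-loss
straggling, δ-rays, spur-size distributions, charge imbalance from
escaping electrons), so absolute G-value curves from this generator are
illustrative; the quantitative claims of this package are
engine-vs-engine agreements on identical initial states.
`dose_to_energy` converts an absorbed dose to deposited energy
(dose·ρ·V/e; 100 Gy in a (0.2 µm)³ water box ≈ 5 keV).

## Observables

Yield series are per-species totals on a log-spaced grid (the state is
piecewise constant between events, so each grid time records the state
immediately before the first later event).  G-value = count × 100 /
deposited energy (eV).  Radial histograms use 21 bins on
[0, (L/2)√3] about the box centre; mesh states bin each voxel's count at
its centre radius.

Engine comparisons use a two-sample Kolmogorov–Smirnov test with two
conventions: the default treats the two 21-bin count vectors as
21-point samples (D is then a multiple of 1/21) with the classical
asymptotic p = Q_KS(√(nm/(n+m))·D); the alternative compares the
molecule-weighted radial CDFs with effective sample sizes from the
histogram totals.  The bin-level convention is the one used in this
package's benchmark tables; `compare` reports both.

## Numerical choices and problem sizes

* RNG: one `numpy` Generator per run, seeded from the run config; all
  scenario generation, both engines, and the CLI derive from it.  Fixed
  seed ⇒ bit-identical output.
* Degenerate inputs: zero propensity ⇒ +∞ firing time (voxel simply
  absent from the queue); empty meshes and particle sets return at the
  end time immediately; a reaction popped against absent reactants
  raises (it would indicate a stale queue).
* Exact boundary coordinates bin into the last voxel (half-open voxel
  intervals elsewhere).
* Test problem sizes: benchmarks run at the canonical 200-molecule /
  0.2 µm scale; the reaction–diffusion engine comparison uses 4–5
  replicates from 1 ns to 1 µs, and distributional engine-equivalence
  tests use 400–1000 replicates at 40–200 molecules, sizes at which the
  asserted 3σ bands are meaningful while the suite stays quick.

## Known limitations

* Reactions are strictly diffusion-controlled second order: no partially
  diffusion-controlled kinetics, no first-order scavenging, no
  temperature or pH dependence.
* No electrostatics: H₃O⁺, OH⁻ and e⁻aq diffuse as neutral particles.
* The particle engine ignores pair survival conditioning between steps
  and inter-pair competition within a step (both bounded by the per-step
  probability cap), and does not model encounters interrupted by a third
  body.
* The lattice engine's accuracy near the critical voxel size degrades
  for the largest reaction radii in the default table (π·σ up to ~3 nm
  for the acid–base neutralization); warnings flag such meshes.
* Coarsening is global and monotone (no refinement, no spatially
  adaptive meshes); volumes are cubic.
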