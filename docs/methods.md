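# Methods

`lipocap` simulates the coating of a lecithin nanoliposome by chitosan and
the encapsulation of capsaicin at the mesoscale, using dissipative particle
dynamics (DPD), and computes the observables used to characterize such
nanocapsules: density maps, radial density profiles, potentials of mean
force, vesicle size and encapsulation efficiency.

## The DPD model

All beads interact pairwise inside a cutoff r_c with three forces:

* conservative soft repulsion `F_C = a_ij (1 − r/r_c) r̂`,
* dissipative drag `F_D = −γ w_D(r) (r̂·v_ij) r̂`, with `w_D = (1 − r/r_c)²`,
* random kicks `F_R = σ w_R(r) θ_ij r̂ / √dt`, with `w_R = (1 − r/r_c)`,

where θ_ij is a symmetric, unit-variance random variate redrawn every step.
Because `w_D = w_R²` and `σ² = 2 γ kT` (enforced at parameter construction),
the dissipative/random pair is a momentum-conserving thermostat at
temperature kT. Bonded beads add a harmonic spring `−k (r − r₀) r̂`.

Everything is in reduced units: r_c = 1, m = 1, kT = 1. The physical length
mapping is configurable; the default r_c = 0.646 nm corresponds to the usual
coarse-graining of three water molecules per solvent bead at reduced density
ρ = 3.

Integration is the modified velocity-Verlet scheme with a velocity
prediction factor λ: positions advance with the current forces, forces are
recomputed at velocities predicted with factor λ, and velocities are then
corrected with the mean of old and new forces. Defaults are the standard
choices for ρ = 3 fluids: dt = 0.03, λ = 0.65, γ = 4.5 (hence σ = 3).
With these settings a pure solvent fluid holds kT = 1.00 within a few
percent (the well-known small positive bias of the scheme is within the 5%
band our tests allow).

## Coarse-grained molecules

* **Lecithin** — 8 beads: head `L1`, neck `L2`, and two tails of three `L3`
  beads each, reflecting the two acyl chains of a C42 phosphatidylcholine.
  The per-molecule bead count is configurable (`lecithin_topology`).
* **Capsaicin** — a linear 3-bead chain `C1–C2–C3` (vanillyl head, amide
  neck, hydrocarbon tail).
* **Chitosan** — one bead per monomer: `G` (d-glucosamine, deacetylated) or
  `A` (N-acetyl-d-glucosamine), bonded linearly. Chains are specified in a
  block notation, e.g. `[-GlucNA-[GlcN]3-GlucNA-[GlcN]3-GlucNA-GlcN-]5`,
  expanded left-to-right with repeat counts applying to the preceding token
  or bracketed group. Two reference 50-mers are built in: `S1`
  (quasi-uniformly spread acetyl units) and `S2` (blocky pattern,
  `[-[GlucNA]4-[GlcN]9]3-[GlucNA]3-[GlcN]8`); both have acetyl fraction
  exactly 0.30.
* **Water** — explicit single beads `W`.

Terminology: "degree of acetylation" in this package always means the
fraction of `A` (N-acetylated) monomers; the deacetylation degree is its
complement. The literature uses "DA" for both conventions, so the package
standardizes on the acetyl fraction.

## Interaction parameters

The conservative repulsions a_ij (units kT/r_c) are fully configurable; the
defaults follow the compressibility rule a_ii = 25 at ρ = 3 and encode the
hydrophobic/hydrophilic contrasts that drive the relevant physics:

* water strongly repels the hydrocarbon tails (`W–L3 = W–C3 = 80`), which
  keeps the bilayer assembled and partitions capsaicin's tail into it;
* head groups and glucosamine are water-like (`W–L1 = W–G = 25`);
* glucosamine is mildly attracted to the lecithin head group *relative to
  water* (`G–L1 = 18 < 25`), the soft-repulsion sense of "attraction" that
  drives chitosan adsorption onto the vesicle surface;
* acetyl-glucosamine is slightly hydrophobic (`W–A = 35`) and slightly
  self-associating (`A–A = 22`), which is what makes the acetylation
  *pattern* (S1 vs S2) matter;
* capsaicin's head prefers the interface (`C1–L1 = 28`, `C1–W = 30`) while
  its tail mixes with lipid tails (`C3–L3 = 25`).

These are package defaults chosen for qualitative fidelity, not a fitted
parameter set; any matrix can be supplied through the config file. Bonds
default to k = 100 kT/r_c², r₀ = 0.7 r_c for all bonded pairs.

## System construction

The builder reproduces the study's initial condition: a preformed spherical
bilayer at the box centre, solutes scattered randomly outside it, and
solvent filled to exactly `round(3 V)` total beads.

* **Vesicle.** Lipid count per leaflet is `round(4πR²/a_pl)` with R the
  leaflet's head-sphere radius (outer R_out, inner R_out − thickness) and
  a_pl the nominal area per lipid (default 1.25 r_c²). Head positions come
  from a Fibonacci sphere lattice rotated by a seeded random rotation per
  leaflet; chains point radially toward the bilayer mid-surface, with the
  five bead layers spaced to just reach it. The initial radial compression
  (spacing < r₀) relaxes outward within the first few hundred steps.
  Default geometry: thickness 3.0 r_c between head spheres. The reduced
  reference system (R_out = 8) then holds 894 lipids; the full-scale
  default (R_out = 13.9) about 2 900.
* **Solutes.** Each capsaicin molecule and chitosan chain is grown as a free
  random walk with steps of the equilibrium bond length from a uniformly
  sampled start, and accepted only if every bead lies farther than
  R_out + 1 r_c from the vesicle centre (minimum image).
* **Solvent.** W beads are placed uniformly at random. No overlap exclusion
  is applied anywhere — DPD potentials are soft — but the engine provides a
  capped-force pre-equilibration (default 10³ steps with the per-pair
  scalar force clamped at 30) to relax the build gently.
* **Box calibration.** The physical box volume is fixed by the printed
  correspondence *50 chitosan chains ≙ 6 mM*: V = N/(N_A c) = 1.384×10⁴ nm³,
  i.e. a cube of 37.16 r_c at the default length scale. 100/150/200 chains
  in the same box give 12/18/24 mM by construction.

Builds are bitwise deterministic given the seed: the vesicle, solute and
solvent stages draw from independently keyed child generators, and initial
velocities are Maxwell–Boltzmann with the centre-of-mass drift removed.

## Numerical implementation

The pair loop uses cell columns: the xy plane is tiled into 1 r_c columns,
particles are counting-sorted per column and z-ordered, and each particle
interacts with a sliding z-window of its own and four half-shell neighbour
columns (periodic images handled per column pair and at column ends). The
column search is exactly equivalent to brute-force enumeration, which the
test suite asserts on random configurations; a plain all-pairs loop is used
automatically when a box side is below 3 r_c.

The per-pair noise is counter-based: θ_ij is a hash (splitmix64) of
(seed, step, i, j) with ordered indices, so θ_ij = θ_ji exactly, runs are
reproducible under any pair-iteration order, and a restarted run continues
the identical noise stream. Coincident beads (r = 0) exert no force — a
measure-zero event under soft potentials. Coordinates are wrapped to [0, L)
every step; bond vectors always use the minimum image; analyses unwrap each
molecule by walking its bond tree before averaging beads.

## Observables

* **Density maps** (xy): time-averaged bead counts in a z-slab (default the
  central 2 r_c slice through the vesicle), normalized by bin area × slab
  thickness × frames, so integrating the map recovers the mean in-slab
  count.
* **Radial profiles**: spherical-shell histograms around the per-frame
  lecithin centroid, normalized by shell volume and frame count.
* **PMF**: w(r) = −kT ln g(r), where g(r) is the minimum-image histogram of
  molecular centre-of-mass separations normalized by the ideal-gas shell
  expectation, restricted to r < L/2. The curve is anchored to zero on the
  outermost 10% of sampled bins; bins with g = 0 are reported as undefined
  (NaN). The well depth statistic is the most negative defined w value.
* **Vesicle diameter**: 2× the outermost radius at which the lecithin
  radial density falls to half its peak (linear interpolation between
  bins); converted to nm via the length scale. A profile without a membrane
  peak (max < 2× far field) is an error, not a number.
* **Encapsulation efficiency**: EE = (CapsT − CapsF)/CapsT × 100, with free
  capsaicin counted as molecules whose COM lies outside the measured
  membrane edge (lecithin outer half-maximum radius) + 1 r_c. Tying the
  boundary to the measured edge avoids a magic radius; the margin is
  configurable.
* **Uncertainties**: diameter and EE are reported as mean ± standard
  deviation over four equal blocks of the analysis frames. Whether the
  study's published ± values are std or sem is not derivable from the main
  text; block-std is our documented choice.

## Desk-scale study conditions

The full-scale system (box 37.16 r_c ≈ 154 000 beads, 250 capsaicin, 50–200
chitosan chains, multi-microsecond trajectories) is what the original
GPU-scale study ran; it is expressible here but not what the test suite
exercises. The package's reference desk system shrinks the geometry while
keeping the physics:

* vesicle R_out = 8 r_c (894 lipids), 25 capsaicin, 5 chitosan 50-mers,
  box 21.39 r_c (the calibrated box scaled by 8/13.9), ≈ 29 400 beads;
* 10³ capped pre-equilibration steps + 4×10⁴ production steps, snapshots
  every 500 steps, analysis on the second half;
* the chitosan-concentration comparison doubles the chain count to 10 and
  compares lecithin–chitosan PMFs over matched step windows of the two runs.

These lengths were chosen so that the full suite runs on one CPU core in
well under half an hour; pilot runs showed capsaicin uptake and chitosan
adsorption plateau within the first ~15 000 steps at this size.

What the desk runs *do* show: the preformed vesicle is mechanically stable
(persistent membrane peak), capsaicin partitions into the membrane shell
rather than the aqueous core, chitosan deposits at/outside the head-group
radius, EE is high, and the lecithin–chitosan attraction weakens at higher
chitosan load. What they *cannot* show: quantitative agreement with the
published full-scale numbers (≈18 nm diameter, ≈96–97% EE), which depend on
the vesicle size, the SI-only interaction parameters, and microsecond-scale
relaxation; the reduced-time-to-physical-time mapping is deliberately not
attempted.

## Known limitations

* No electrostatics: chitosan's pH-dependent protonation is outside scope;
  adsorption is encoded through the a_ij contrasts instead.
* The interaction matrix is a documented stand-in, not the (unavailable)
  fitted set; all entries are config-exposed for when fitted values exist.
* Bead-level granularity of lecithin/capsaicin (8 and 3 beads) is a
  defensible default, not a derived mapping.
* Constant-volume ensemble only; no angle/dihedral potentials; chitosan
  chains are monodisperse 50-mers.
* The vesicle must not straddle the periodic boundary (true for all
  configurations the builder produces and the runs preserve); the radial
  analyses rely on this.
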