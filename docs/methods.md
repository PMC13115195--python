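# Methods

## Model and assumptions

The engine treats docking as rigid-body placement of one or more
conformationally fixed ligands inside a *truncated active-site cluster
model*: the atoms of an explicit `(residue_name, residue_number)`
selection, heavy atoms frozen, hydrogens (when present) nominally free.
This mirrors how quantum-chemical scoring is made tractable for
enzymes — the electronic structure method sees only the pocket, and the
frozen heavy-atom lattice stands in for the protein scaffold.  Three
consequences are accepted deliberately:

* chain breaks in the truncated model are left uncapped; with all heavy
  atoms frozen the dangling termini cannot relax into artefacts during
  rigid docking, and refinement decks freeze them too;
* protonation is the user's problem: quantum-chemical backends and the
  surrogate scorer both need explicit hydrogens, but the engine accepts
  bare heavy-atom models for geometry-only work (sampling, clash
  filtering, distance analysis);
* residue identity is checked as `(name, number)` pairs so renumbered
  input files fail fast instead of silently selecting wrong residues.

Ligands declared `rigid` move only by rotation + translation; every pose
application preserves intra-ligand distances to 1e−9 Å, and this is
enforced by property tests rather than assumed.

## Sampling

A pose is a centroid translation plus a unit quaternion (scalar-first).
Rotations act about the ligand centroid, which decouples the rotation
and translation draws.  Quaternions come from Shoemake's subgroup
algorithm (three uniforms → exactly uniform on SO(3)); translations are
uniform over the sampling region.  The default region is the axis-aligned
bounding box of the receptor atoms *shrunk* by 2 Å per side, which keeps
sampled centroids interior to the model; a box or sphere can be given
explicitly.  Where the spatial bounds of a published protocol are
unstated, this default is an engineering choice and is recorded in the
run config echo.

Reproducibility contract: the proposal stream is a pure function of
`(seed, config)`.  The generator is numpy's PCG64; the draw order is
fixed as (translation x, y, z, then quaternion u₁, u₂, u₃) per ligand,
ligands in index order, proposals consecutive.  The batched sampler
draws the identical sequence, so batch size never changes results —
tested by comparing streamed and batched runs draw-for-draw.

## Clash filter

A pose is discarded when any inter-molecular pair (ligand–receptor or
ligand–ligand) is closer than `scale · (r_i + r_j)` on Bondi-style van
der Waals radii (shipped table, H = 1.10 Å revision).  `scale = 0.7` is
the common steric-overlap convention; it is configurable because the
binary "atomic overlap" criterion has no unique literature value.
Hydrogens participate by default (they exist in quantum-chemical
models) and can be excluded.  The accelerated path (k-d tree single
checks, fully vectorised batch masks) is held to *exact* agreement with
the all-pairs brute-force oracle in the tests — that equivalence, not
speed, is the correctness surface.

## Energy scoring

All internal energies are kJ mol⁻¹; adapters convert at the boundary
(1 kcal = 4.184 kJ; 1 Hartree = 2625.4996 kJ mol⁻¹).

**Surrogate backend.** A classical inter-molecular potential for
desk-scale work: 12-6 Lennard-Jones with Lorentz–Berthelot combination
plus a dielectric-screened point-charge term, truncated at 12 Å (plain
truncation, exact zero beyond).  Per-element ε/σ defaults carry generic
organic-forcefield magnitudes; partial charges default to zero per
element and are introduced per atom (`Atom.charge`) or per element in
`SurrogateParams.charges`.  Intra-molecular pairs are excluded, so an
isolated rigid species scores exactly zero and the complex score *is*
the binding energy — the generic ΔE = E(complex) − E(site) − Σ E(ligand)
formula is still applied so engine backends drop in unchanged.  The
surrogate is an arbitrary-zero potential, not a heat of formation; only
differences are meaningful.

**Engine backends.** MOPAC-style and Gaussian-style dialects for input
decks (per-atom optimisation flags encoding the frozen convention:
receptor heavy 0/frozen, receptor H and ligands free) and output parsing
(final heat of formation with unit handling, thermochemistry block,
termination marker → `converged`).  The parser implements each
dialect's minimal grammar, not full log replay; a non-converged job is a
flagged result, a truncated file (no energy) is an error.  In-process
scoring through a configured engine executable is supported but the
intended production route is emitting decks (`emit_refinement_jobs`) and
collecting outputs (`collect_refinement`).

At the screening stage both the absolute complex energy and the binding
difference are recorded per retained pose; ranking uses the binding
difference.

## Retention and clustering

The K = 1000 default retention is a bounded-size exact selection of the
lowest `(energy, proposal id)` keys — single pass, independent of batch
scheduling, ties broken by lowest proposal id everywhere (required for
determinism).

Clustering is agglomerative on the 1-D distance |Eᵢ − Eⱼ| (single
linkage by default; complete/average available).  The default *gap cut*
severs the hierarchy just below its maximal merge height, undoing every
merge at that height; for 1-D data this is provably the partition
obtained by splitting the sorted energies at the largest adjacent
gap(s), and the tests hold the scipy-based implementation to that closed
form.  The degenerate all-equal case yields one cluster.  A fixed-k cut
(`cut="k"`) reproduces fixed-cluster-count reporting (e.g. the
two-position convention for the BChE system) without baking k into the
default.  Cluster labels are renumbered so cluster 1 has the lowest
representative energy; representatives are minimum-energy members with
lowest-index tie-breaks.  An RMSD-style geometric clustering is
deliberately absent: the protocol clusters on energy only.

## Thermodynamics

Entropy is handled throughout as the pre-multiplied T·S term
(kJ mol⁻¹ at 298.15 K), matching thermochemistry tables and avoiding
the J↔kJ conversion trap; pressure (101 325 Pa) only defines the
standard state.  `ThermoRecord` and `BindingThermo` enforce
G = H − T·S to 0.02 kJ mol⁻¹, the slack two-decimal rounding requires.
The cooperativity reference for dual occupancy is defined as the *sum of
the two single-ligand cluster Gibbs energies*; reported tables round to
two decimals while full precision is kept internally.  The shipped
reference tables for the BChE/three-membered-ring system satisfy
G = H − T·S to ≤ 0.01 kJ mol⁻¹ on all fifteen rows, and give
ΔΔG_coop = −35.33 kJ mol⁻¹ (synergistic) for dual thiirane and
+2.92 kJ mol⁻¹ (not synergistic) for dual cyclopropane.

## Interaction analysis

Contacts are minimum distances over the cross product of a ligand-atom
selector (element, index, or any) and a residue-atom selector (PDB
atom-name glob or any), heavy atoms unless hydrogens are named
explicitly.  The *strong* flag needs distance ≤ cutoff (default 3.2 Å)
**and** both partners polar (N/O/S/P or a polar hydrogen).  The cutoff
is configurable because published bold/plain distance annotations
follow no single stated criterion; no hydrogen-bond angle term is
applied.

## Synthetic fixtures — what they do and do not show

`make_toy_cage` builds a spherical shell of frozen carbons (Fibonacci
lattice with small seeded jitter, renormalised to the sphere) around a
designed binding well: an equilateral triangle of negatively charged
oxygens plus a neutral carbon plug that blocks the mirror-image site,
making the minimum a unique point.  The attractor charge is solved
numerically (bisection on the pair-potential depth) so three equidistant
contacts give approximately the requested well depth; the constructor
then *re-verifies* the designed minimum by grid search and refuses to
return a cage whose true minimum strays beyond 0.5 Å.  The independent
oracle for tests is a dense 0.25 Å grid scan.

The rigid rings use idealized textbook bond lengths (e.g. C–C 1.51 Å in
cyclopropane, C–O 1.436 Å in oxirane, C–P 1.867 Å in phosphirane) with
explicit hydrogens — sufficient because the engine never flexes them.
The residue scaffold is a synthetic backbone trace whose only meaningful
content is its residue bookkeeping.

Passing on these fixtures demonstrates that the *protocol* is correct:
sampling is uniform and reproducible, the filter and clustering match
their oracles, a designed global minimum is found, and the arithmetic is
exact.  It does **not** demonstrate chemical accuracy on real
receptors — the surrogate potential is not a quantum-chemical method,
the toy cage is not an enzyme pocket, and no claim about real binding
energies follows from green tests.

## Problem sizes and numerical choices

Tests and the acceptance script run the pipeline at desk scale chosen
as the package's own verification sizes: 10⁴ proposals per run (20
seeded repetitions for the recovery rate), 10⁵ rotation samples for the
SO(3) goodness-of-fit (KS test at α = 0.01 against the (1 − cos θ)/π
angle density), 10³ random placements against a 500-atom receptor for
clash-oracle agreement, and 10² random instances for the clustering
closed form.  The production default of 10⁶ proposals remains the
config default.  Other numerics: quaternion norm tolerance 1e−9; rigid
motion preservation asserted to 1e−9 Å; XYZ round-trip 1e−6 Å and PDB
round-trip 1e−4 Å (format precision); cluster-height ties resolved with
a 1e−12 tolerance; checkpoints store the retained set and config hash so
re-running resumes clustering/analysis without re-sampling.

## Known limitations

* No flexible-ligand (torsional) sampling and no biased/importance
  sampling of the region — uniform rigid-body proposals only.
* The surrogate has no polarisation, dispersion correction or solvent
  model; its charges are user-supplied, not derived.
* Gap-cut clustering can return more than two clusters when several
  adjacent gaps tie for largest; fixed-k exists for conventional
  reporting.
* The strong-contact rule cannot reproduce every published bold/plain
  annotation (the underlying criteria are unstated).
* mmCIF, protonation assignment and missing-residue modelling are out
  of scope; inputs are taken as supplied.
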