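# Methods

This note records the models, conventions and numerical choices behind
`rpskit`, and what the toy surfaces do and do not establish about behavior
on real electronic-structure potentials.

## Molecular data model

Geometries are element lists with Cartesian coordinates (Å) and optional
energy/force labels (eV, eV/Å) plus a theory-level tag. Connectivity is a
simple graph over atoms without bond orders: driving coordinates specify
connectivity changes only, so a double bond and a single bond are the same
edge. Two valence vocabularies follow from this:

- **Maximum coordination** (H 1, C 4, N 3, O 2, S 4, Cl 1) bounds the
  *degree* of an atom. Under-coordination is always allowed — reaction
  intermediates are legitimately under-coordinated — only the maxima bind.
  Perceived graphs along a path may transiently exceed the maxima (a
  bridging hydrogen at a transfer TS has degree 2); they are constructed
  non-strict and judged by the feasibility filter instead.
- **Full valence** (H 1, C 4, N 3, O 2, S 2, Cl 1) is the total bond order
  of a saturated neutral atom. A graph is *closed-shell realizable* when
  extra bond orders of 0–2 per edge can absorb every atom's deficiency
  exactly; this is decided by a small exact search.

Bond perception uses a fixed covalent-radius table (Cordero 2008 consensus
values) with a bond iff d < scale × (rᵢ + rⱼ), default scale 1.2. The table
is shipped with the package so perception is identical across installs. The
perception rule is this package's choice; nothing in the workflow depends
on its fine details beyond consistency between stages.

Canonical graph keys come from iterative neighborhood-refinement coloring
followed by individualization-refinement with a lexicographically minimal
certificate — a genuine canonical form, exponential only in pathological
regular graphs far larger than the ≤13-atom molecules handled here. An
exhaustive permutation-isomorphism oracle guards it in the tests.

## Driving-coordinate enumeration

Enumeration is exhaustive over sets with 0–2 BREAKs of existing bonds and
0–2 ADDs of non-bonded pairs (at least one change), filtered by: maximum
coordination of the altered graph; no pair appearing twice; altered graph
not isomorphic to the reactant. Sets acting on symmetry-equivalent atoms
are kept distinct — driving coordinates act on labeled atoms. Hydrogens
participate by default (hydrogen transfer is chemically essential); a
`heavy_only` flag restricts to heavy atoms.

`closed_shell_products=True` additionally discards altered graphs that are
not closed-shell realizable. This is the appropriate mode for saturated
organic reactants, where homolytic radical fragments are not meaningful
products, and it is what makes enumeration counts on such molecules small
and chemically interpretable. It is off by default because the package also
drives open-shell toy species (an isolated H₂ BREAK is a legitimate driven
dissociation even though its products are radicals).

**The C4H4ClNO demonstration reactant.** The enumeration demo and the
acceptance script use a chloro-dihydropyrrolone connectivity
(`O=C1CC(Cl)C=N1`): a five-membered N1–C2(=O)–C3H₂–C4(H)(Cl)–C5(H)=N1 ring.
With default limits and the closed-shell rule it enumerates to exactly 231
driving-coordinate sets, and the count is invariant under atom relabeling.
Two caveats are deliberate: the specific isomer is this package's choice
among many chemically valid C4H4ClNO structures, and without the
closed-shell rule (plain coordination-legality only) the same molecule
yields thousands of sets, most of them radical-producing. The binding
correctness property is not the count itself but agreement with an
exhaustive subset-with-filters oracle, which the test suite checks on every
fixture graph in both modes.

## Potentials

All stages consume a `PotentialModel`: deterministic energy/forces with
forces equal to the negative energy gradient (finite-difference checked in
the tests to 1e−4 eV/Å).

**Morse cluster.** Total energy is a sum over atom pairs of
D(1 − e^{−a(r−r₀)})² − D with per-element-pair parameters shipped as a data
table. The default table is designed so the toy chemistry behaves like
chemistry rather than like a generic pair fluid:

- bondable pairs (O–H, N–H, C–H, C–C, …) have deep, *narrow* wells
  (a ≈ 3–3.5 /Å), so an atom's attraction to a partner it is not bonded to
  decays quickly;
- heavy-atom pairs that should not bind in the toys (N–O, O–O, …) carry a
  weak well at long range (D = 0.1 eV, a = 1.8 /Å, r₀ ≈ 3.3–3.8 Å) whose
  repulsive inner wall acts as a soft steric barrier;
- H–H is non-bonding at short range (r₀ = 1.6 Å), which keeps the
  hydrogens of one molecule apart.

This matters because purely additive attractive potentials famously
stabilize shared-atom complexes (the H₃ problem) and then no exchange
reaction has a barrier. With the shipped table the O–H + N hydrogen
transfer has a genuine first-order saddle: 0.89 eV forward, 0.21 eV
reverse, verified in the tests against an independent grid+Newton saddle
search written directly from the Morse formula. Barriers of this order
(0.5–2 eV) put the toy reactions on the scale of real organic activation
energies.

**Müller–Brown.** The standard four-Gaussian 2-D benchmark, exposed as a
single pseudo-atom whose first two coordinates are (x, y) and whose z
coordinate is inert (zero force, zero curvature). Every chain-of-states,
Hessian and TS-signature code path runs unchanged on it; the inert
direction contributes an exactly-zero Hessian eigenvalue, below the
negative-eigenvalue threshold, so signature counting is unaffected.
Stationary points (minima at (−0.558, 1.442), (−0.050, 0.467),
(0.623, 0.028); saddles at (−0.822, 0.624) and (0.212, 0.293)) are
recomputed in the tests by grid scan plus Newton refinement.

**External engines.** The adapter runs `<command> geometry.xyz` in a
temporary directory and parses an `energy <eV>` line plus one
`force <fx> <fy> <fz>` line per atom. Missing binaries, malformed output
and non-finite results raise distinct errors; a non-finite result is a
calculator failure that downstream stages treat as a non-convergent
pathway. Engine flags are passed through verbatim — the adapter imposes no
settings of its own.

## Optimization, Hessians, normal modes

The minimizer is FIRE-style damped dynamics with two guards: per-atom
displacement capped at 1 Å per step, and an energy-monotonicity check that
rejects any step raising the energy and restarts the dynamics with a
smaller time step. Convergence is judged on F_max, the largest per-atom
force norm (default tolerance 0.01 eV/Å for free minimization).

Hessians are central finite differences of forces (default step 0.01 Å,
valid range 1e−4 to 5e−2 Å), symmetrized as (H + Hᵀ)/2. Vibrational
analysis mass-weights by 1/√(mᵢmⱼ), projects out rigid modes via an
explicitly constructed translation/rotation basis (Gram–Schmidt with null
vectors dropped, which handles linear molecules and single atoms without a
separate detection step), and diagonalizes. The TS test counts vibrational
eigenvalues below −1e−4 in mass-weighted units; whether the reference
protocol mass-weights before counting is unknowable from the outside, so
the mass-weighted convention is fixed here and recorded.

## Growing-string product search

This is a deliberate simplification of full internal-coordinate SE-GSM and
the package's largest methodological substitution: growth is by constrained
relaxation rather than Hessian-guided string reparametrization. The
justification is the protocol's structure — the string is only a
product/TS *proposal* stage whose output is re-refined by CI-NEB, so
proposal fidelity is recovered downstream.

Per growth step each targeted distance moves by 0.3 Å toward its target
(ADD: 1.1 × covalent-radius sum; BREAK: 1.5 × the perception cutoff), then
the node relaxes with force components along the still-active constraint
directions projected out. Constraint handling is asymmetric on purpose:

- an **ADD** constraint is released once its pair reaches the target — the
  new bond holds by itself, and the freed tail relaxes into the product
  basin so the saddle ends up interior to the path;
- a **BREAK** pair stays constrained for the whole growth — on a barrierless
  pair well a freed broken bond would simply slide back and re-form.

Growth stops when the perceived connectivity matches the driven target, the
string settles, the 30-node budget runs out, or a node rises more than
10 eV above the reactant (the driven connectivity is then unreachable at
chemically relevant energies and the path is classified failed-no-barrier).
A budget-exhausted string is still returned as a proposal: the filters, not
the growth loop, decide its fate. Because the force projection only removes
first-order constraint violation, the constrained distances drift downhill
during relaxation; empirically this makes the string hug the reaction
valley, and the extracted barrier lands within ≈0.05 eV of the independent
saddle oracle on the toy transfer despite the coarse 0.3 Å growth step.

Triad extraction takes the maximum-energy interior node, refines it by one
parabolic interpolation over the three bracketing nodes (keeping whichever
candidate is higher in energy), and minimizes the final node to the
product. A maximum at an endpoint means no barrier was crossed — pure
dissociations end up here or at the strictly-uphill filter.

## CI-NEB and harvesting

Bands hold 10 images by default (endpoints included, fixed bitwise).
Initialization is linear Cartesian interpolation, optionally refined by an
image-dependent pair-distance objective (weights 1/d⁴ against the linearly
interpolated distance profile) minimized with the same FIRE integrator —
this is what prevents atom-through-atom interpolation artifacts. Band
forces use the improved-tangent scheme (tangent toward the higher-energy
neighbor, energy-weighted at extrema, geometric fallback when neighbor
energies are exactly equal); springs are uniform k = 0.1 eV/Å² along the
tangent. Plain NEB runs until F_max ≤ 2× tolerance (default tolerance
0.05 eV/Å), then the current maximum-energy interior image climbs — true
force with inverted tangent component, no spring — until convergence or the
500-step cap. All interior images are integrated jointly by FIRE without
the energy-rejection guard (band forces are not the gradient of any single
energy).

**Harvesting.** After every iteration the current F_max is added to an
accumulator; when the accumulator reaches 0.1 eV/Å the whole band is
snapshotted into the dataset and the accumulator resets to zero, so
consecutive harvested bands are separated by at least 0.1 eV/Å of summed
per-iteration F_max. The converged (or final) band is always included. The
accumulated quantity is the per-iteration F_max itself; accumulating the
*change* in F_max instead was considered and rejected as the default
because it would harvest almost nothing from smoothly converging bands.

On Müller–Brown the climbing image reproduces the (−0.822, 0.624) saddle to
4 decimal places in energy from a 10-image linear band.

## Filters

- *uphill*: energies non-decreasing within 1e−3 eV per step and total rise
  above the flat threshold — catches pure dissociations.
- *flat*: total variation below 0.1 eV. The threshold is not printed in any
  reference; 0.1 eV sits well below chemically meaningful barriers while
  absorbing optimizer noise, and is exposed in the configuration.
- *repetitive*: product graph isomorphic to the reactant or to a previously
  seen product (canonical keys, tracked per reactant).
- *infeasible*: any interatomic distance below 0.7 Å, or any atom above its
  maximum coordination in the perceived graph.
- *TS signature*: exactly one negative mass-weighted vibrational eigenvalue,
  applied at the sampling level (the level that produced the geometry).

## Normal-mode sampling

The NMS baseline draws, for each sample, every vibrational mode coefficient
independently from a zero-mean Gaussian with variance k_BT/k_mode — the
classical harmonic Boltzmann distribution — un-mass-weights and sums the
displacements. Defaults: 1500 K, 1000 samples per equilibrium structure,
seeded and fully deterministic. Equipartition (mean harmonic energy k_BT/2
per mode within Monte-Carlo error) is the binding test. Inputs must be true
minima: residual force above tolerance or a negative vibrational eigenvalue
raises. Quantum (Wigner) sampling and anharmonic corrections are out of
scope; at 1500 K classical sampling overpopulates low-frequency modes
relative to a quantum ensemble, which is acceptable for a
diversity-contrast baseline.

## Dataset layer

Relabeling replaces energies and forces only; geometry arrays pass through
bitwise. Structures whose refinement evaluation fails are dropped with a
logged reason, mirroring the discarding of non-converged points. Per
reaction, harvested structures are deduplicated on bitwise-identical
positions (band endpoints recur in every snapshot), then uniformly
subsampled without replacement (default 1000, seeded deterministically from
the run seed and the reaction ordinal). Subsampling happens after all
filters. Storage is float64 HDF5 under `/{formula}/{reaction_id}/` with
unit attributes and the labeling level as a group attribute; energies are
raw model outputs with no atomization offsetting. Reaction ids are
zero-padded ordinals in discovery order. HDF5 object timestamps are
disabled so identical runs produce bitwise-identical files — the
end-to-end determinism test relies on this.

## Diversity analytics

Pairwise distances are binned at 0.1 Å over 0–8 Å with an overflow bin;
mass above 5 Å is the dissociation indicator separating RPS from NMS
datasets. Angles (bonded triplets) and dihedrals (bonded quartets) use 5°
bins over [0°, 180°] and (−180°, 180°]. Histograms report raw counts and
derived densities, leaving normalization to the consumer. Activation
energies group by the bond-change count |added| + |removed| between
perceived reactant and product graphs, reporting per-group count, median
and quartiles.

## Pipeline

Execution is single-process and deterministic for a fixed seed on the
built-in potentials; per-reaction subsample seeds derive from the run seed.
Stage reports track attempted/succeeded/rejected with reason codes and are
checked for conservation (attempted = succeeded + rejected) on every run.
An empty final dataset is a warning, not an error. The study-scale default
conditions (1500 K, 1000 samples per structure, 1000 points per reaction,
harvest threshold 0.1 eV/Å) are kept at their stated values; the toy
demonstrations are small because the toy systems have few atoms, not
because the conditions differ.

## What the toys do and do not show

The analytic surfaces exercise every algorithmic path: enumeration
legality, constrained growth, tangent projection, climbing-image
convergence, Hessian signatures, harvest bookkeeping, two-level relabeling
and the storage layout. They do not emulate electronic structure:
multi-reference character near TSs, charge transfer, bond-order effects
beyond the closed-shell feasibility check, or the conformational
complexity of real GDB molecules. Passing tests establish the machinery
and its bookkeeping, not the chemical accuracy of any particular external
engine attached through the adapter.

## Known limitations

- The growing string is Cartesian and constraint-projected, not an
  internal-coordinate GSM; very stiff or strongly curved pathways may need
  smaller growth increments than the 0.3 Å default.
- Graphs are neutral closed-shell; formal charges are carried but unused by
  the valence rules. Stereochemistry, aromaticity and tautomers are out of
  scope.
- Bimolecular reactions enter only as reversed unimolecular paths.
- TS structures are accepted from CI-NEB without further eigenvector-
  following refinement.
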