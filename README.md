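# rpskit — reaction pathway sampling for MLIP training sets

Machine-learning interatomic potentials (MLIPs) learn the potential energy
surface (PES) from labeled structures, and they are only as good as the
regions of the PES their training data covers. Datasets built from
equilibrium structures or normal-mode perturbations cluster inside
equilibrium wells, so the resulting potentials extrapolate poorly exactly
where chemistry happens — near transition states and along bond breaking
and formation. `rpskit` implements a fully automated **reaction pathway
sampling (RPS)** protocol that fills this gap: starting from a reactant it
enumerates candidate bond rearrangements without human input, grows reaction
paths toward unknown products, refines them with climbing-image NEB while
*harvesting* the intermediate bands, validates transition states by their
Hessian signature, relabels the surviving structures at a second theory
level, and stores everything in a hierarchical HDF5 dataset ready for MLIP
training. A normal-mode-sampling (NMS) baseline generator and diversity
analytics (pairwise-distance, angle and activation-energy distributions) are
included for comparison.

The package is calculator-agnostic: every stage runs against a uniform
energy/force contract. Built-in analytic surfaces — pairwise Morse clusters
with a tuned element-pair table and the Müller–Brown benchmark — make the
entire pipeline executable and testable on a laptop; a subprocess adapter
defines the boundary to external tight-binding or DFT engines.

## The protocol

For a reactant with connectivity graph *G*:

1. **Driving-coordinate enumeration.** All sets of bond alterations with up
   to 2 BREAKs of existing bonds and up to 2 ADDs of non-bonded pairs, kept
   only if the altered graph respects per-element maximum valences and is
   not isomorphic to the reactant (identity transformations are excluded).
   An optional closed-shell mode additionally requires the altered graph to
   admit a full bond-order saturation (no radical products), the natural
   setting for saturated GDB-style organic reactants.
2. **Product search (simplified single-ended growing string).** Each
   driving-coordinate set steers a string of nodes: targeted pair distances
   are displaced stepwise (ADD pairs toward 1.1× the covalent-radius sum,
   BREAK pairs apart) while all other degrees of freedom relax with the
   targeted distances constrained by force projection. The maximum-energy
   interior node is a transition-state proposal; the final node minimizes
   freely to the product, giving a reactant–TS–product triad with barrier
   ΔE‡ = E(TS) − E(R).
3. **Landscape search (CI-NEB with harvesting).** The triad endpoints are
   joined by an interpolated band (linear or IDPP) and optimized with the
   improved-tangent nudged elastic band; once F<sub>max</sub> falls below
   twice the tolerance the maximum-energy image climbs to the saddle. After
   every iteration the current F<sub>max</sub> accumulates, and each time the
   accumulator crosses 0.1 eV/Å the whole band is harvested into the dataset
   and the accumulator resets — dense sampling near reactive regions without
   storing near-duplicate bands.
4. **Filtering.** Strictly uphill profiles (pure dissociations), profiles
   with less than 0.1 eV variation, repeated products (canonical-graph-key
   deduplication), clashing or over-coordinated structures, non-convergent
   bands, and transition states whose mass-weighted, rigid-projected Hessian
   does not have exactly one negative eigenvalue are all rejected.
5. **Refinement and database generation.** Survivors are relabeled by the
   refinement-level potential (geometries untouched), subsampled per
   reaction (default 1000 structures), and written to
   `/{formula}/{reaction_id}/{atomic_numbers, positions, energies, forces}`
   in eV and Å.

## Worked example

The bundled toy system is an O–H molecule with a nitrogen acceptor on the
default Morse-cluster chemistry; driving `ADD 2 3 / BREAK 1 2` transfers the
hydrogen over a ≈0.85 eV barrier.

```python
from rpskit.pipeline import RunConfig, run_pipeline
from rpskit.toys import hydrogen_transfer_reactant

reactant = hydrogen_transfer_reactant()
out, report = run_pipeline(RunConfig(reactants=[reactant],
                                     output="toy.h5", seed=7))
print(report.summary())
```

prints

```
seed: 7
prepare: 1/1 succeeded
enumerate: 5/5 succeeded
gsm: 2/5 succeeded (failed-no-barrier=3)
filter: 1/2 succeeded (repetitive=1)
neb: 1/1 succeeded
ts-validation: 1/1 succeeded
refine: 474/474 succeeded
dataset: 1 reactions, 474 structures
```

Reading the report: of the 5 enumerated driving-coordinate sets, 3 produce
no interior energy maximum (pure stretches), 2 grow into product proposals,
1 of those duplicates the other's product and is dropped as repetitive, and
the survivor — the hydrogen transfer — converges under CI-NEB, passes the
single-negative-eigenvalue test, and contributes 474 harvested structures
relabeled at the refinement level to the reaction group `HNO/0000`.

The same stages are exposed on the command line
(`rpskit prep|enumerate|gsm|neb|refine|nms|stats|run`), e.g.

```bash
rpskit enumerate reactant.xyz          # BREAK/ADD lines per candidate set
rpskit run config.yaml                 # the full pipeline from a YAML config
rpskit stats toy.h5                    # dataset diversity summary
```

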