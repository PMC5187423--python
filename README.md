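# kinens

Ensemble elementary-kinetics modelling of metabolic networks, fitted to
steady-state flux data from panels of mutant strains.

The package implements the full workflow:

1. **Network I/O** (`kinens.model_io`) — a tabular CSV dialect (plus an
   SBML import for stoichiometry) for metabolites, reactions with
   isozyme assignments, substrate-level regulatory interactions, mutant
   flux datasets and strain designs.
2. **Reference state** (`kinens.constraint_lp`) — FBA with imposed flux
   measurements, flux-variability analysis, an L1 tie-break, biomass
   coupling analysis, and the FBA / MOMA / max-yield comparator
   predictions for knockouts.
3. **Elementary decomposition** (`kinens.decomposition`) — every
   catalysed reaction becomes an ordered-sequential cycle of elementary
   mass-action steps with explicit enzyme forms; competitive /
   uncompetitive / mixed inhibition add dead-end binding steps,
   activation makes activator binding obligatory.
4. **Kinetics** (`kinens.kinetics`) — step reversibilities in [0, 1) and
   per-pool enzyme-form fractions are sampled and anchored so the
   reference flux distribution is an exact fixed point of the mass-action
   ODEs; perturbed steady states are found with a numba-accelerated
   implicit-Euler march plus Newton polish.
5. **Two-stage GA fit** (`kinens.ga_fit`) — stage 1 evolves whole
   parameterizations (reaction-block recombination, prior-resampling
   mutation, elitism) against knockout flux datasets under one condition,
   with surviving-isozyme levels as extra fit variables; stage 2 freezes
   the elementary parameters and fits only per-enzyme total levels in
   [0, 10] per condition group. Leave-one-out / leave-two-out
   cross-validation is included.
6. **Michaelis–Menten conversion** (`kinens.mm_convert`) — apparent K_m
   and k_cat extracted numerically from quasi-steady-state saturation
   curves, rescaled to absolute units by reference concentration ranges,
   and compared to measured ranges by interval overlap.
7. **Strain evaluation** (`kinens.strain_eval`) — product yields for
   designed strains from the kinetic model (bounded enzyme-level
   interventions resolved by box search) and the three stoichiometric
   comparators, with Pearson/within-20% agreement statistics.
8. **Synthetic fixtures** (`kinens.synthetic_fixtures`) — deterministic
   toy networks (`linear-8`, `branched-14`, `core-24`) with ground-truth
   kinetics, noisy mutant datasets, measured-range tables and
   overproducer designs so that the entire pipeline is testable offline.

## CLI

```sh
kinens fixtures --preset branched-14 --seed 7 -o fx/   # make a toy model
kinens validate fx/model
kinens refflux fx/model --measurements meas.csv -o ref.json
kinens decompose fx/model --reference ref.json -o elementary.json
kinens simulate fx/model fx/truth_params.json --reference fx/reference.json --ko e9
kinens fit fx/model --stage 1 --data fx/fluxes.csv --reference fx/reference.json
kinens mmconvert fx/model fit.json --reference fx/reference.json -o mm.csv
kinens evaluate fx/model --designs fx/designs.csv --params fit.json \
    --reference fx/reference.json
```

## Conventions

- Fluxes are carried internally on the "uptake = 100" basis; mutant
  predictions are rescaled to that basis before comparison with data,
  which are themselves normalized per substrate uptake.
- Metabolite concentrations are normalized to 1 at the reference state;
  enzyme pools to a total of 1 per enzyme (isozymes of one reaction share
  a total of 1).
- The substrate-uptake boundary step keeps a sampled backward term in its
  internal product, so uptake self-limits when downstream metabolism
  backs up; secretion and drain steps are irreversible mass action.
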