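"""Deterministic toy networks with ground-truth elementary kinetics.

Presets (glycolysis-like structural stand-ins, not biological models):

``linear-8``
    uptake -> 6 catalysed steps -> biomass drain; an ATP-like cofactor
    pair is consumed by the second reaction and regenerated by the fifth.
``branched-14``
    a backbone with an alternative branch, two cofactor pairs, one
    secreted fermentative product plus a second minor product, a
    respiration-like cofactor recycler, an isozyme pair on the first
    backbone reaction and one competitive inhibition on the branch.
``core-24``
    branched-14 plus two further drain pathways with their exchanges.

Every output is fully determined by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config
from .constraint_lp import ReferenceState, compute_reference_flux
from .decomposition import ElementaryNetwork, decompose_network
from .kinetics import (Parameterization, SteadyStateSolver,
                       apply_perturbation, sample_parameterization)
from .mm_convert import elementary_to_mm
from .model_io import (Condition, FluxDataset, FluxMeasurement, Genotype,
                       MetabolicNetwork, Metabolite, Reaction, Regulation,
                       StrainDesign)

PRESETS = ("linear-8", "branched-14", "core-24")


@dataclass
class ToySpec:
    preset: str = "branched-14"
    isozymes: int = 2            # isozyme count on the first backbone step
    regulations: int = 1
    noise_cv: float = 0.1
    seed: int = 0
    genotypes: list[Genotype] = field(default_factory=list)
    condition: Condition = Condition()

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}")


def _met(mid, name="", cofactor=False, boundary=False, rng=(0.5, 2.0)):
    return Metabolite(id=mid, name=name or mid, cofactor=cofactor,
                      boundary=boundary,
                      conc_range=None if boundary else rng)


def make_toy_network(spec: ToySpec) -> MetabolicNetwork:
    """Build the preset network; identical output for identical specs."""
    if spec.preset == "linear-8":
        net = _linear8(spec)
    else:
        net = _branched(spec, core=spec.preset == "core-24")
    net.validate()
    return net


def _linear8(spec: ToySpec) -> MetabolicNetwork:
    mets = [_met("glcx", boundary=True),
            _met("A"), _met("B"), _met("C"), _met("D"), _met("E"),
            _met("F"), _met("Q"),
            _met("atp", cofactor=True), _met("adp", cofactor=True)]
    rxns = [
        Reaction("upt", {"glcx": -1, "A": 1}, exchange=True),
        Reaction("v1", {"A": -1, "atp": -1, "B": 1, "adp": 1},
                 enzymes=["e1"]),
        Reaction("v2", {"B": -1, "C": 1}, enzymes=["e2"]),
        Reaction("v3", {"C": -1, "D": 1}, enzymes=["e3"]),
        Reaction("v4", {"D": -1, "adp": -1, "E": 1, "atp": 1},
                 enzymes=["e4"]),
        Reaction("v5", {"E": -1, "F": 1}, enzymes=["e5"]),
        Reaction("v6", {"F": -1, "Q": 1}, enzymes=["e6"]),
        Reaction("bm", {"Q": -1}, exchange=True),
    ]
    return MetabolicNetwork(metabolites=mets, reactions=rxns,
                            regulations=[], biomass_id="bm",
                            uptake_id="upt")


def _branched(spec: ToySpec, core: bool) -> MetabolicNetwork:
    mets = [_met("glcx", boundary=True),
            _met("A"), _met("B"), _met("C"), _met("D"), _met("E"),
            _met("F"), _met("P"), _met("P2"), _met("Q"),
            _met("atp", cofactor=True), _met("adp", cofactor=True),
            _met("nad", cofactor=True), _met("nadh", cofactor=True)]
    v1_enzymes = [f"e1{chr(ord('a') + i)}" for i in range(spec.isozymes)] \
        if spec.isozymes >= 2 else ["e1"]
    rxns = [
        Reaction("upt", {"glcx": -1, "A": 1}, exchange=True),
        Reaction("v1", {"A": -1, "atp": -1, "B": 1, "adp": 1},
                 enzymes=v1_enzymes),
        Reaction("v2", {"B": -1, "C": 1}, enzymes=["e2"]),
        Reaction("v3", {"C": -1, "nad": -1, "D": 1, "nadh": 1},
                 enzymes=["e3"]),
        Reaction("v4", {"D": -1, "adp": -1, "E": 1, "atp": 1},
                 enzymes=["e4"]),
        Reaction("v5", {"A": -1, "F": 1}, enzymes=["e5"]),
        Reaction("v6", {"F": -1, "adp": -1, "E": 1, "atp": 1},
                 enzymes=["e6"]),
        Reaction("v7", {"E": -1, "nadh": -1, "P": 1, "nad": 1},
                 enzymes=["e7"]),
        Reaction("v8", {"E": -1, "Q": 1}, enzymes=["e8"]),
        Reaction("v9", {"D": -1, "nad": -1, "P2": 1, "nadh": 1},
                 enzymes=["e9"]),
        Reaction("resp", {"nadh": -1, "nad": 1}, enzymes=["e10"]),
        Reaction("secP", {"P": -1}, exchange=True),
        Reaction("secP2", {"P2": -1}, exchange=True),
        Reaction("bm", {"Q": -1, "atp": -1, "adp": 1}, exchange=True),
    ]
    regulations = []
    if spec.regulations >= 1:
        # branch-point inhibition: downstream backbone metabolite B
        # competitively inhibits the branch reaction v5
        regulations.append(Regulation("B", "v5", "competitive-inhibition"))
    if core:
        mets += [_met("G"), _met("H"), _met("J"), _met("K"), _met("L")]
        rxns += [
            Reaction("v10", {"C": -1, "atp": -1, "G": 1, "adp": 1},
                     enzymes=["e11"]),
            Reaction("v11", {"G": -1, "nadh": -1, "H": 1, "nad": 1},
                     enzymes=["e12"]),
            Reaction("v12", {"H": -1, "J": 1}, enzymes=["e13"]),
            Reaction("secJ", {"J": -1}, exchange=True),
            Reaction("v13", {"E": -1, "nad": -1, "K": 1, "nadh": 1},
                     enzymes=["e14"]),
            Reaction("v14", {"K": -1, "adp": -1, "L": 1, "atp": 1},
                     enzymes=["e15"]),
            Reaction("secL", {"L": -1}, exchange=True),
            Reaction("v15", {"F": -1, "nad": -1, "P2": 1, "nadh": 1},
                     enzymes=["e16"]),
            Reaction("v16", {"B": -1, "adp": -1, "C": 1, "atp": 1},
                     enzymes=["e17"]),
            Reaction("v17", {"J": -1, "Q": 1}, enzymes=["e18"]),
        ]
        if spec.regulations >= 2:
            regulations.append(
                Regulation("P", "v7", "uncompetitive-inhibition"))
    return MetabolicNetwork(metabolites=mets, reactions=rxns,
                            regulations=regulations, biomass_id="bm",
                            uptake_id="upt")


# ---------------------------------------------------------------------------
# ground-truth reference and parameterization
# ---------------------------------------------------------------------------

#: wild-type flux measurements imposed during reference construction,
#: per preset (mean, s.d.) on the uptake=100 basis
PRESET_MEASUREMENTS = {
    "linear-8": {"upt": (100.0, 1.0)},
    "branched-14": {"upt": (100.0, 1.0), "v1": (60.0, 3.0),
                    "v9": (10.0, 0.5)},
    "core-24": {"upt": (100.0, 1.0), "v1": (60.0, 3.0), "v9": (8.0, 0.5),
                "v10": (12.0, 0.8), "v13": (6.0, 0.5), "v15": (5.0, 0.5),
                "v16": (2.0, 0.2)},
}

DEFAULT_GENOTYPES = {
    "linear-8": [Genotype(knockouts=("e5",))],
    "branched-14": [
        Genotype(knockouts=("e9",)),
        Genotype(knockouts=("e8",)),
        Genotype(knockouts=("e4",)),
        Genotype(isozyme_deletions=("e1a",)),
        Genotype(level_bounds=(("e7", 0.5, 0.5),)),
        Genotype(level_bounds=(("e10", 0.3, 0.3),)),
    ],
}
DEFAULT_GENOTYPES["core-24"] = DEFAULT_GENOTYPES["branched-14"]


def make_reference(network: MetabolicNetwork, preset: str
                   ) -> ReferenceState:
    meas = PRESET_MEASUREMENTS[preset]
    return compute_reference_flux(
        network, {k: v for k, v in meas.items()},
        uptake_bounds={network.uptake_id: (0.0, config.GLUCOSE_UPTAKE)})


@dataclass
class ToyModel:
    """Bundled fixture: network, reference, decomposition, ground truth."""

    spec: ToySpec
    network: MetabolicNetwork
    reference: ReferenceState
    elementary: ElementaryNetwork
    truth: Parameterization


def make_toy_model(spec: ToySpec) -> ToyModel:
    network = make_toy_network(spec)
    reference = make_reference(network, spec.preset)
    elem = decompose_network(network, reference.fluxes)
    rng = np.random.default_rng(spec.seed)
    truth = sample_parameterization(elem, reference.fluxes, rng,
                                    provenance={"seed": spec.seed,
                                                "role": "ground-truth"})
    return ToyModel(spec=spec, network=network, reference=reference,
                    elementary=elem, truth=truth)


# ---------------------------------------------------------------------------
# dataset emission
# ---------------------------------------------------------------------------


_SOLVERS: dict[int, SteadyStateSolver] = {}


def _cached_solver(elem: ElementaryNetwork) -> SteadyStateSolver:
    key = id(elem)
    if key not in _SOLVERS:
        _SOLVERS[key] = SteadyStateSolver(elem)
    return _SOLVERS[key]


def ground_truth_datasets(model: ToyModel,
                          genotypes: list[Genotype] | None = None,
                          noise_cv: float | None = None,
                          seed: int | None = None,
                          measured_reactions: list[str] | None = None,
                          iso_surviving_level: float = 0.8,
                          e_total_overrides: dict[str, float] | None = None,
                          condition: Condition | None = None
                          ) -> list[FluxDataset]:
    """Solve the ground-truth steady state per genotype and emit noisy
    measured-flux datasets (wild type always included).

    Noise is multiplicative Gaussian with the configured CV; the emitted CV
    equals the configured one (floored at 1e-6 for noiseless fixtures).
    A genotype with no steady state yields a dataset flagged lethal.
    """
    spec = model.spec
    genotypes = genotypes if genotypes is not None else \
        (spec.genotypes or DEFAULT_GENOTYPES[spec.preset])
    noise_cv = spec.noise_cv if noise_cv is None else noise_cv
    seed = spec.seed if seed is None else seed
    condition = condition or spec.condition
    rng = np.random.default_rng(seed + 1)
    solver = _cached_solver(model.elementary)
    measured = measured_reactions or [r.id for r in model.network.reactions]
    cv_out = max(noise_cv, 1e-6)

    datasets = []
    for k, genotype in enumerate([Genotype()] + list(genotypes)):
        strain = "WT" if genotype.is_wildtype else f"M{k}"
        pert = apply_perturbation(model.elementary, genotype,
                                  condition=str(condition))
        assignments = {}
        for pool, v in pert.e_total.items():
            if isinstance(v, tuple):
                group = next(g for g, members in
                             model.elementary.isozyme_groups.items()
                             if pool in members)
                survivors = [p for p in
                             model.elementary.isozyme_groups[group]
                             if isinstance(pert.e_total.get(p), tuple)]
                tot = sum(model.truth.e_total[p] for p in survivors)
                assignments[pool] = iso_surviving_level * \
                    model.truth.e_total[pool] / tot
        et = pert.resolved(assignments)
        if e_total_overrides:
            et.update(e_total_overrides)
        res = solver.solve(model.truth, e_total=et)
        uptake = res.fluxes.get(model.network.uptake_id, 0.0) \
            if res.converged else 0.0
        if not res.converged or uptake <= 1e-6 * config.UPTAKE_BASIS:
            datasets.append(FluxDataset(
                strain=strain, genotype=genotype, condition=condition,
                measurements={}, uptake_reaction=model.network.uptake_id,
                lethal=True))
            continue
        scale = config.UPTAKE_BASIS / uptake  # data normalized per uptake
        measurements = {}
        for rid in measured:
            true = res.fluxes[rid] * scale
            noisy = true * (1.0 + noise_cv * rng.standard_normal()) \
                if noise_cv > 0 else true
            # zero-flux reactions get no s.d.; their CV follows the
            # wild-type reuse rule when the CSV is read back
            sd = cv_out * abs(noisy) if (noise_cv > 0 and noisy != 0) \
                else None
            measurements[rid] = FluxMeasurement(mean=noisy, sd=sd,
                                                cv=cv_out)
        ds = FluxDataset(strain=strain, genotype=genotype,
                         condition=condition, measurements=measurements,
                         uptake_reaction=model.network.uptake_id)
        datasets.append(ds)
    return datasets


def ground_truth_mm_ranges(model: ToyModel, jitter: float = 0.0,
                           seed: int | None = None,
                           reactions: list[str] | None = None
                           ) -> pd.DataFrame:
    """Apparent-constant table with jittered "measured" single values
    wrapped in +/-10% ranges (columns: reaction, constant, substrate,
    predicted, measured_lo, measured_hi).

    jitter is a log10 scale: measured = true * 10**(jitter * N(0,1)).
    """
    seed = model.spec.seed if seed is None else seed
    rng = np.random.default_rng(seed + 2)
    rows = []
    targets = reactions or sorted({r for (r, _) in
                                   model.elementary.cycles})
    for rxn in targets:
        mm = elementary_to_mm(model.elementary, model.truth, rxn)
        entries = [("Km", sub, val) for sub, val in mm.km.items()]
        entries.append(("kcat", "", mm.kcat))
        for kind, sub, true in entries:
            if not np.isfinite(true):
                continue
            measured = true * 10.0 ** (jitter * rng.standard_normal())
            lo, hi = sorted((0.9 * measured, 1.1 * measured))
            rows.append({"reaction": rxn, "constant": kind,
                         "substrate": sub, "predicted": true,
                         "measured_lo": lo, "measured_hi": hi})
    return pd.DataFrame(rows)


def overproducer_designs(model: ToyModel) -> list[StrainDesign]:
    """Small design set against the branched presets' secreted product P:
    knocking out the competing drains raises the P yield."""
    cond = model.spec.condition
    return [
        StrainDesign("D1", {"e9": "knockout"}, cond, "P", "secP", 0.7),
        StrainDesign("D2", {"e8": "knockout"}, cond, "P", "secP", 0.9),
        StrainDesign("D3", {"e9": "knockout", "e7": "upregulate"}, cond,
                     "P", "secP", 0.8),
    ]
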