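"""Decomposition of catalysed reactions and regulatory interactions into
elementary mass-action steps with explicit enzyme forms.

Mechanism convention: ordered sequential binding in the declared
stoichiometric order (cofactors are ordinary substrates), one central
conversion step, ordered product release (first declared product first).
A stoichiometric coefficient of n produces n sequential binding/release
steps. Exchange reactions and enzyme-free reactions are kept as single
lumped mass-action "boundary" steps and are not decomposed.

Regulatory interactions add steps:

* competitive inhibition: dead-end ``E + I <-> EI`` on the free enzyme;
* uncompetitive inhibition: dead-end inhibitor binding on the fully
  substrate-loaded complex;
* mixed inhibition: both of the above;
* activation: obligatory activator binding before the first substrate
  binding (catalysis proceeds only from the activator-bound form; the
  activator is released at the end of each catalytic cycle).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model_io import (MetabolicNetwork, Reaction, Regulation,
                       ValidationError)

STEP_KINDS = ("bind", "convert", "release", "regulatory", "boundary")


class DecompositionError(ValueError):
    pass


@dataclass(frozen=True)
class ElementaryStep:
    sid: str
    reaction: str
    enzyme: str | None
    reactants: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    kind: str

    @property
    def regulatory(self) -> bool:
        return self.kind == "regulatory"

    @property
    def dead_end(self) -> bool:
        return self.kind == "regulatory"


def _free_form(enzyme: str) -> str:
    return f"enz:{enzyme}"


def _form_name(enzyme: str, acts: tuple[str, ...], subs: tuple[str, ...],
               prods: tuple[str, ...]) -> str:
    parts = list(acts) + list(subs) + [">" + p for p in prods]
    if not parts:
        return _free_form(enzyme)
    return f"enz:{enzyme}:" + ".".join(parts)


def _expand(stoich: dict[str, float], sign: int, context: str
            ) -> list[str]:
    """Expand one side of a reaction into a repeated-metabolite list,
    preserving declared order."""
    out: list[str] = []
    for met, coeff in stoich.items():
        c = sign * coeff
        if c <= 0:
            continue
        n = int(round(c))
        if abs(c - n) > 1e-9 or n < 1:
            raise DecompositionError(
                f"{context}: stoichiometric coefficient {coeff} for {met} "
                f"is not a positive integer after splitting")
        out.extend([met] * n)
    return out


def decompose_reaction(reaction: Reaction, enzyme: str,
                       activators: tuple[str, ...] = (),
                       orientation: int = 1
                       ) -> tuple[list[ElementaryStep], list[str]]:
    """Ordered-sequential elementary steps of one reaction under one enzyme
    pool. Returns (steps, enzyme forms); the free enzyme form is first.

    *orientation* = -1 decomposes the reaction in its reversed direction
    (used when the reference net flux is negative).
    """
    if not reaction.enzymes:
        raise DecompositionError(
            f"reaction {reaction.id} has no enzyme and cannot be decomposed")
    if reaction.exchange:
        raise DecompositionError(
            f"exchange reaction {reaction.id} is boundary mass-action and "
            f"is not decomposed")
    sign = 1 if orientation >= 0 else -1
    subs = _expand(reaction.stoichiometry, -sign, f"reaction {reaction.id}")
    prods = _expand(reaction.stoichiometry, sign, f"reaction {reaction.id}")
    if not subs or not prods:
        raise DecompositionError(
            f"reaction {reaction.id} lacks substrates or products")

    steps: list[ElementaryStep] = []
    forms: list[str] = [_free_form(enzyme)]
    bound_acts: tuple[str, ...] = ()
    current = _free_form(enzyme)
    k = 0
    for x in activators:
        nxt = _form_name(enzyme, bound_acts + (x,), (), ())
        k += 1
        steps.append(ElementaryStep(
            sid=f"{reaction.id}:{enzyme}:a{k}", reaction=reaction.id,
            enzyme=enzyme, reactants=((current, 1.0), (x, 1.0)),
            products=((nxt, 1.0),), kind="bind"))
        bound_acts += (x,)
        forms.append(nxt)
        current = nxt
    bound: tuple[str, ...] = ()
    for i, met in enumerate(subs, 1):
        nxt = _form_name(enzyme, bound_acts, bound + (met,), ())
        steps.append(ElementaryStep(
            sid=f"{reaction.id}:{enzyme}:b{i}", reaction=reaction.id,
            enzyme=enzyme, reactants=((current, 1.0), (met, 1.0)),
            products=((nxt, 1.0),), kind="bind"))
        bound += (met,)
        forms.append(nxt)
        current = nxt
    loaded = _form_name(enzyme, bound_acts, (), tuple(prods))
    steps.append(ElementaryStep(
        sid=f"{reaction.id}:{enzyme}:c", reaction=reaction.id,
        enzyme=enzyme, reactants=((current, 1.0),),
        products=((loaded, 1.0),), kind="convert"))
    forms.append(loaded)
    current = loaded
    remaining = list(prods)
    for j in range(len(prods)):
        met = remaining.pop(0)
        nxt = _form_name(enzyme, bound_acts, (), tuple(remaining))
        steps.append(ElementaryStep(
            sid=f"{reaction.id}:{enzyme}:r{j + 1}", reaction=reaction.id,
            enzyme=enzyme, reactants=((current, 1.0),),
            products=((nxt, 1.0), (met, 1.0)), kind="release"))
        if nxt not in forms:
            forms.append(nxt)
        current = nxt
    # release activators (reverse binding order) to regenerate free enzyme
    for j, x in enumerate(reversed(activators), 1):
        bound_acts = bound_acts[:-1]
        nxt = _form_name(enzyme, bound_acts, (), ())
        steps.append(ElementaryStep(
            sid=f"{reaction.id}:{enzyme}:ra{j}", reaction=reaction.id,
            enzyme=enzyme, reactants=((current, 1.0),),
            products=((nxt, 1.0), (x, 1.0)), kind="release"))
        current = nxt
    assert current == _free_form(enzyme)
    return steps, forms


def boundary_step(reaction: Reaction, internal: set[str],
                  orientation: int = 1) -> ElementaryStep:
    """Single lumped mass-action step for an exchange / enzyme-free
    reaction; boundary metabolites are dropped (they are clamped)."""
    sign = 1 if orientation >= 0 else -1
    reactants = tuple((m, -sign * c) for m, c in reaction.stoichiometry.items()
                      if sign * c < 0 and m in internal)
    products = tuple((m, sign * c) for m, c in reaction.stoichiometry.items()
                     if sign * c > 0 and m in internal)
    return ElementaryStep(sid=f"{reaction.id}:x", reaction=reaction.id,
                          enzyme=None, reactants=reactants,
                          products=products, kind="boundary")


@dataclass
class ElementaryNetwork:
    """Mass-action step system with explicit enzyme forms."""

    network: MetabolicNetwork
    steps: list[ElementaryStep]
    pools: dict[str, list[str]]               # enzyme -> form species
    cycles: dict[tuple[str, str], list[int]]  # (reaction, enzyme) -> steps
    reg_steps: dict[tuple[str, str], list[int]]
    boundary_steps: dict[str, int]            # reaction -> step index
    orientation: dict[str, int]
    isozyme_groups: dict[str, list[str]]      # reaction -> isozymes (>=2)

    def __post_init__(self) -> None:
        self.form_pool = {f: e for e, forms in self.pools.items()
                          for f in forms}
        mets = [m.id for m in self.network.internal_metabolites]
        forms = [f for e in self.pools for f in self.pools[e]]
        self.species: list[str] = mets + forms
        self.species_index = {s: i for i, s in enumerate(self.species)}
        self.n_metabolites = len(mets)

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    def pool_of_step(self, idx: int) -> str | None:
        return self.steps[idx].enzyme

    def conversion_step(self, reaction: str, enzyme: str) -> int:
        for idx in self.cycles[(reaction, enzyme)]:
            if self.steps[idx].kind == "convert":
                return idx
        raise KeyError((reaction, enzyme))

    def reaction_pools(self, reaction: str) -> list[str]:
        return [e for (r, e) in self.cycles if r == reaction]

    def net_step_stoichiometry(self, reaction: str) -> dict[str, float]:
        """Summed metabolite stoichiometry of one catalytic cycle (or the
        boundary step), oriented back to the declared direction."""
        if reaction in self.boundary_steps:
            idxs = [self.boundary_steps[reaction]]
        else:
            enzymes = self.reaction_pools(reaction)
            idxs = self.cycles[(reaction, enzymes[0])]
        net: dict[str, float] = {}
        for i in idxs:
            s = self.steps[i]
            for m, c in s.reactants:
                if m not in self.form_pool:
                    net[m] = net.get(m, 0.0) - c
            for m, c in s.products:
                if m not in self.form_pool:
                    net[m] = net.get(m, 0.0) + c
        sign = self.orientation.get(reaction, 1)
        return {m: sign * c for m, c in net.items() if abs(c) > 1e-12}


def attach_regulation(elem: ElementaryNetwork, regulation: Regulation
                      ) -> ElementaryNetwork:
    """Return a new ElementaryNetwork with *regulation* attached to every
    isozyme pool of the target reaction."""
    if regulation.mode not in ("competitive-inhibition",
                               "uncompetitive-inhibition",
                               "mixed-inhibition", "activation"):
        raise ValidationError(f"unknown regulation mode {regulation.mode!r}")
    target = regulation.target
    enzymes = elem.reaction_pools(target)
    if not enzymes:
        raise DecompositionError(
            f"regulation targets {target}, which has no catalytic cycle")
    if regulation.mode == "activation":
        return _attach_activation(elem, regulation, enzymes)

    steps = list(elem.steps)
    pools = {e: list(f) for e, f in elem.pools.items()}
    reg_steps = {k: list(v) for k, v in elem.reg_steps.items()}
    inhibitor = regulation.regulator
    for enz in enzymes:
        new: list[ElementaryStep] = []
        if regulation.mode in ("competitive-inhibition", "mixed-inhibition"):
            free = _free_form(enz)
            dead = f"{free}#{inhibitor}"
            new.append(ElementaryStep(
                sid=f"{target}:{enz}:reg:{inhibitor}:c", reaction=target,
                enzyme=enz, reactants=((free, 1.0), (inhibitor, 1.0)),
                products=((dead, 1.0),), kind="regulatory"))
            pools[enz].append(dead)
        if regulation.mode in ("uncompetitive-inhibition",
                               "mixed-inhibition"):
            conv = elem.steps[elem.conversion_step(target, enz)]
            loaded = conv.reactants[0][0]
            dead = f"{loaded}#{inhibitor}"
            new.append(ElementaryStep(
                sid=f"{target}:{enz}:reg:{inhibitor}:u", reaction=target,
                enzyme=enz, reactants=((loaded, 1.0), (inhibitor, 1.0)),
                products=((dead, 1.0),), kind="regulatory"))
            pools[enz].append(dead)
        key = (target, enz)
        reg_steps.setdefault(key, [])
        for s in new:
            reg_steps[key].append(len(steps))
            steps.append(s)
    return ElementaryNetwork(network=elem.network, steps=steps, pools=pools,
                             cycles=dict(elem.cycles), reg_steps=reg_steps,
                             boundary_steps=dict(elem.boundary_steps),
                             orientation=dict(elem.orientation),
                             isozyme_groups=dict(elem.isozyme_groups))


def _attach_activation(elem: ElementaryNetwork, regulation: Regulation,
                       enzymes: list[str]) -> ElementaryNetwork:
    """Rebuild the target reaction's cycles with the activator bound first."""
    target = regulation.target
    rxn = elem.network.reaction(target)
    orientation = elem.orientation.get(target, 1)
    # collect activators already attached (stacking supported)
    existing = _activators_of(elem, target, enzymes[0])
    activators = existing + (regulation.regulator,)

    keep_idx = [i for i, s in enumerate(elem.steps)
                if not (s.reaction == target and s.enzyme in enzymes)]
    remap = {old: new for new, old in enumerate(keep_idx)}
    steps = [elem.steps[i] for i in keep_idx]
    pools = {e: list(f) for e, f in elem.pools.items()}
    cycles = {k: [remap[i] for i in v] for k, v in elem.cycles.items()
              if k[0] != target}
    reg_steps = {k: [remap[i] for i in v] for k, v in elem.reg_steps.items()
                 if k[0] != target}
    for enz in enzymes:
        new_steps, forms = decompose_reaction(rxn, enz,
                                              activators=activators,
                                              orientation=orientation)
        pools[enz] = forms
        idxs = []
        for s in new_steps:
            idxs.append(len(steps))
            steps.append(s)
        cycles[(target, enz)] = idxs
    out = ElementaryNetwork(network=elem.network, steps=steps, pools=pools,
                            cycles=cycles, reg_steps=reg_steps,
                            boundary_steps=dict(elem.boundary_steps),
                            orientation=dict(elem.orientation),
                            isozyme_groups=dict(elem.isozyme_groups))
    # re-attach inhibitions that were dropped with the rebuilt cycles
    for reg in elem.network.regulations:
        if reg.target == target and reg.mode != "activation" and \
                reg is not regulation:
            out = attach_regulation(out, reg)
    return out


def _activators_of(elem: ElementaryNetwork, reaction: str, enzyme: str
                   ) -> tuple[str, ...]:
    acts: list[str] = []
    for i in elem.cycles.get((reaction, enzyme), []):
        s = elem.steps[i]
        if s.sid.startswith(f"{reaction}:{enzyme}:a"):
            acts.append(s.reactants[1][0])
    return tuple(acts)


def decompose_network(network: MetabolicNetwork,
                      reference_fluxes: dict[str, float] | None = None
                      ) -> ElementaryNetwork:
    """Decompose every catalysed reaction (one independent pool per
    isozyme), lump exchange / enzyme-free reactions into boundary steps,
    and attach all regulations.

    If *reference_fluxes* is given, reactions with negative reference flux
    are decomposed in their reversed orientation so that anchoring sees a
    positive net flux.
    """
    network.validate()
    internal = {m.id for m in network.internal_metabolites}
    orientation: dict[str, int] = {}
    for r in network.reactions:
        v = (reference_fluxes or {}).get(r.id, 0.0)
        orientation[r.id] = -1 if v < 0 else 1

    steps: list[ElementaryStep] = []
    pools: dict[str, list[str]] = {}
    cycles: dict[tuple[str, str], list[int]] = {}
    boundary: dict[str, int] = {}
    iso_groups: dict[str, list[str]] = {}
    for r in network.reactions:
        if r.exchange or not r.enzymes:
            boundary[r.id] = len(steps)
            steps.append(boundary_step(r, internal, orientation[r.id]))
            continue
        if len(r.enzymes) >= 2:
            iso_groups[r.id] = list(r.enzymes)
        for enz in r.enzymes:
            if enz in pools:
                raise DecompositionError(
                    f"enzyme pool {enz} catalyses more than one reaction; "
                    f"give each (reaction, isozyme) pair a unique id")
            cyc_steps, forms = decompose_reaction(
                r, enz, orientation=orientation[r.id])
            pools[enz] = forms
            idxs = []
            for s in cyc_steps:
                idxs.append(len(steps))
                steps.append(s)
            cycles[(r.id, enz)] = idxs
    elem = ElementaryNetwork(network=network, steps=steps, pools=pools,
                             cycles=cycles, reg_steps={},
                             boundary_steps=boundary,
                             orientation=orientation,
                             isozyme_groups=iso_groups)
    for reg in network.regulations:
        elem = attach_regulation(elem, reg)
    _check_closure(elem)
    return elem


def _check_closure(elem: ElementaryNetwork) -> None:
    known = set(elem.species_index)
    for s in elem.steps:
        for m, _ in s.reactants + s.products:
            if m not in known:
                raise DecompositionError(
                    f"step {s.sid} references unknown species {m}")


def step_matrices(elem: ElementaryNetwork
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(E_react, E_prod, N) over elem.species: integer-exponent matrices of
    shape (n_steps, n_species) and the step stoichiometric matrix
    N = (E_prod - E_react)^T of shape (n_species, n_steps)."""
    n_steps, n_sp = elem.n_steps, len(elem.species)
    Er = np.zeros((n_steps, n_sp))
    Ep = np.zeros((n_steps, n_sp))
    for i, s in enumerate(elem.steps):
        for m, c in s.reactants:
            Er[i, elem.species_index[m]] += c
        for m, c in s.products:
            Ep[i, elem.species_index[m]] += c
    return Er, Ep, (Ep - Er).T
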