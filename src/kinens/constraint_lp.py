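"""Stoichiometric analyses: reference-flux construction, FVA, biomass
coupling and the FBA/MOMA/max-yield comparator predictions.

All problems are posed over the internal (non-boundary) metabolite balances
``S.v = 0`` with per-reaction bounds, on the uptake = 100 flux basis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from . import config
from .model_io import Genotype, MetabolicNetwork


class InfeasibleError(RuntimeError):
    """The constraint set admits no feasible flux vector."""


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded" | "error"
    objective: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class KnockoutPrediction:
    fluxes: dict[str, float]
    growth: float
    lethal: bool
    method: str


@dataclass
class ReferenceState:
    """Wild-type anchor: fluxes plus unit-normalized concentrations."""

    fluxes: dict[str, float]
    concentrations: dict[str, float]
    conc_ranges: dict[str, tuple[float, float]]
    basis: float = config.UPTAKE_BASIS

    def flux_vector(self, reaction_ids: list[str]) -> np.ndarray:
        return np.array([self.fluxes[r] for r in reaction_ids])


class ScipyLinearSolver:
    """Default LP backend (HiGHS via scipy.optimize.linprog).

    The solver contract is ``solve(c, A_eq, b_eq, bounds, sense)`` returning
    ``(status, objective, x)``; any object with that method can be passed in
    place of this class.
    """

    def solve(self, c, A_eq, b_eq, bounds, sense="min"):
        sign = 1.0 if sense == "min" else -1.0
        res = optimize.linprog(sign * np.asarray(c, dtype=float),
                               A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                               method="highs")
        if res.status == 0:
            return "optimal", sign * res.fun, res.x
        if res.status == 2:
            return "infeasible", np.nan, None
        if res.status == 3:
            return "unbounded", np.nan, None
        return "error", np.nan, None


DEFAULT_SOLVER = ScipyLinearSolver()


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------


def stoichiometric_matrix(network: MetabolicNetwork
                          ) -> tuple[np.ndarray, list[str], list[str]]:
    """Dense S over internal metabolites; returns (S, met_ids, rxn_ids)."""
    mets = [m.id for m in network.internal_metabolites]
    rxns = [r.id for r in network.reactions]
    midx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(rxns)))
    for j, r in enumerate(network.reactions):
        for mid, coeff in r.stoichiometry.items():
            i = midx.get(mid)
            if i is not None:
                S[i, j] += coeff
    return S, mets, rxns


def default_bounds(network: MetabolicNetwork) -> list[tuple[float, float]]:
    return [r.default_bounds() for r in network.reactions]


def _apply_extra(bounds: list[tuple[float, float]], rxns: list[str],
                 extra: dict[str, tuple[float, float]] | None
                 ) -> list[tuple[float, float]]:
    if not extra:
        return list(bounds)
    idx = {r: j for j, r in enumerate(rxns)}
    out = list(bounds)
    for rid, (lo, hi) in extra.items():
        j = idx[rid]
        lo = max(out[j][0], lo)
        hi = min(out[j][1], hi)
        if lo > hi + 1e-12:
            raise InfeasibleError(
                f"conflicting bounds on reaction {rid}: [{lo}, {hi}]")
        out[j] = (lo, hi)
    return out


def knockout_bounds(network: MetabolicNetwork, genotype: Genotype
                    ) -> dict[str, tuple[float, float]]:
    """Reaction bounds implied by a genotype: a reaction is shut only when
    every one of its isozymes is deleted (enzyme KO or isozyme deletion)."""
    gone = set(genotype.knockouts) | set(genotype.isozyme_deletions)
    out: dict[str, tuple[float, float]] = {}
    for r in network.reactions:
        if r.enzymes and all(e in gone for e in r.enzymes):
            out[r.id] = (0.0, 0.0)
    return out


def _solve(network, c, bounds, sense, solver):
    S, _, rxns = stoichiometric_matrix(network)
    status, obj, x = solver.solve(c, S, np.zeros(S.shape[0]), bounds, sense)
    if status != "optimal":
        return LPResult(status, np.nan, {})
    return LPResult("optimal", obj, dict(zip(rxns, x)))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def fba(network: MetabolicNetwork,
        extra_bounds: dict[str, tuple[float, float]] | None = None,
        objective: str | None = None,
        solver=DEFAULT_SOLVER) -> LPResult:
    """Maximize *objective* (default: biomass) under S.v=0 and bounds."""
    objective = objective or network.biomass_id
    if objective is None:
        raise ValueError("no objective reaction designated")
    _, _, rxns = stoichiometric_matrix(network)
    bounds = _apply_extra(default_bounds(network), rxns, extra_bounds)
    c = np.zeros(len(rxns))
    c[rxns.index(objective)] = 1.0
    return _solve(network, c, bounds, "max", solver)


def flux_variability(network: MetabolicNetwork,
                     fixed_constraints: dict[str, tuple[float, float]]
                     | None = None,
                     reactions: list[str] | None = None,
                     solver=DEFAULT_SOLVER
                     ) -> dict[str, tuple[float, float]]:
    """Per-reaction [min, max] flux subject to S.v=0, bounds and
    *fixed_constraints*."""
    _, _, rxns = stoichiometric_matrix(network)
    bounds = _apply_extra(default_bounds(network), rxns, fixed_constraints)
    targets = reactions if reactions is not None else rxns
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        c = np.zeros(len(rxns))
        c[rxns.index(rid)] = 1.0
        lo = _solve(network, c, bounds, "min", solver)
        hi = _solve(network, c, bounds, "max", solver)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleError(f"FVA infeasible at reaction {rid}")
        out[rid] = (lo.objective, hi.objective)
    return out


def compute_reference_flux(network: MetabolicNetwork,
                           measured_fluxes: dict[str, tuple[float,
                                                            float | None]],
                           uptake_bounds: dict[str, tuple[float, float]]
                           | None = None,
                           solver=DEFAULT_SOLVER) -> ReferenceState:
    """Three-phase reference-state construction.

    1. FBA max-biomass with measurements imposed (mean +/- s.d., or equality
       when no s.d. is given).
    2. FVA at the fixed biomass optimum for unmeasured reactions.
    3. One feasible max-biomass solution within those ranges; ties broken by
       minimizing ||v||_1.

    *measured_fluxes* maps reaction id -> (mean, sd or None).
    """
    if network.biomass_id is None:
        raise ValueError("network has no biomass reaction designated")
    _, _, rxns = stoichiometric_matrix(network)
    meas_bounds: dict[str, tuple[float, float]] = {}
    for rid, (mean, sd) in measured_fluxes.items():
        if not network.has_reaction(rid):
            raise KeyError(f"measured reaction {rid} not in network")
        half = 0.0 if sd is None else abs(sd)
        meas_bounds[rid] = (mean - half, mean + half)
    extra = dict(meas_bounds)
    if uptake_bounds:
        for rid, b in uptake_bounds.items():
            extra[rid] = b if rid not in extra else (
                max(extra[rid][0], b[0]), min(extra[rid][1], b[1]))

    phase1 = fba(network, extra_bounds=extra, solver=solver)
    if not phase1.optimal:
        raise InfeasibleError(
            "reference construction infeasible: the measurement set "
            "conflicts with mass balance / bounds")
    z_bio = phase1.objective

    fixed = dict(extra)
    fixed[network.biomass_id] = (z_bio - 1e-9, z_bio + 1e-9)
    unmeasured = [r for r in rxns
                  if r not in meas_bounds and r != network.biomass_id]
    ranges = flux_variability(network, fixed_constraints=fixed,
                              reactions=unmeasured, solver=solver)

    phase3_bounds = dict(extra)
    for rid, (lo, hi) in ranges.items():
        phase3_bounds[rid] = (lo - 1e-9, hi + 1e-9)
    phase3 = fba(network, extra_bounds=phase3_bounds, solver=solver)
    if not phase3.optimal:
        raise InfeasibleError("phase-3 reference LP infeasible")

    v = _min_l1_at_optimum(network, phase3_bounds, network.biomass_id,
                           phase3.objective, solver)
    v = _project_mass_balance(network, v)
    concentrations = {m.id: 1.0 for m in network.internal_metabolites}
    conc_ranges = {m.id: m.conc_range for m in network.metabolites
                   if m.conc_range is not None}
    return ReferenceState(fluxes=v, concentrations=concentrations,
                          conc_ranges=conc_ranges,
                          basis=network.uptake_basis)


def _min_l1_at_optimum(network, extra_bounds, objective_rxn, z_opt, solver
                       ) -> dict[str, float]:
    """min ||v||_1 s.t. S.v=0, bounds, objective fixed at its optimum."""
    S, _, rxns = stoichiometric_matrix(network)
    n = len(rxns)
    bounds = _apply_extra(default_bounds(network), rxns, extra_bounds)
    j_obj = rxns.index(objective_rxn)
    bounds[j_obj] = (z_opt - 1e-9, z_opt + 1e-9)
    # variables [v, t]; t >= |v| via  v - t <= 0  and  -v - t <= 0
    A_eq = np.hstack([S, np.zeros_like(S)])
    A_ub = np.vstack([np.hstack([np.eye(n), -np.eye(n)]),
                      np.hstack([-np.eye(n), -np.eye(n)])])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    lp_bounds = bounds + [(0.0, None)] * n
    res = optimize.linprog(c, A_ub=A_ub, b_ub=np.zeros(2 * n), A_eq=A_eq,
                           b_eq=np.zeros(S.shape[0]), bounds=lp_bounds,
                           method="highs")
    if res.status != 0:
        raise InfeasibleError("L1 tie-break LP failed")
    return dict(zip(rxns, res.x[:n]))


def _project_mass_balance(network: MetabolicNetwork,
                          fluxes: dict[str, float]) -> dict[str, float]:
    """Remove the solver's O(1e-9) mass imbalance by least-squares
    projection onto {v : S.v = 0} (bounds move by the same tiny amount)."""
    S, _, rxns = stoichiometric_matrix(network)
    v = np.array([fluxes[r] for r in rxns])
    if S.size:
        corr, *_ = np.linalg.lstsq(S, S @ v, rcond=None)
        v = v - corr
    return dict(zip(rxns, v))


def biomass_coupled_reactions(network: MetabolicNetwork,
                              solver=DEFAULT_SOLVER) -> set[str]:
    """Reactions whose flux ratio to biomass is structurally fixed.

    Biomass is fixed at 1 (with default bounds widened so magnitude caps do
    not bind) and a reaction is fully coupled when its FVA min and max
    coincide within ``config.COUPLING_TOL``. The biomass reaction itself is
    excluded.
    """
    if network.biomass_id is None:
        raise ValueError("network has no biomass reaction designated")
    _, _, rxns = stoichiometric_matrix(network)
    # ratio analysis: keep directionality, relax magnitude caps
    wide = []
    for r in network.reactions:
        lb, ub = r.default_bounds()
        wide.append((lb if lb > -config.FLUX_BOUND + 1 else -1e6,
                     ub if ub < config.FLUX_BOUND - 1 else 1e6))
    idx = {r: j for j, r in enumerate(rxns)}
    wide[idx[network.biomass_id]] = (1.0, 1.0)
    coupled = set()
    for rid in rxns:
        if rid == network.biomass_id:
            continue
        c = np.zeros(len(rxns))
        c[idx[rid]] = 1.0
        lo = _solve(network, c, wide, "min", solver)
        hi = _solve(network, c, wide, "max", solver)
        if not (lo.optimal and hi.optimal):
            raise InfeasibleError("biomass=1 constraint set infeasible")
        if hi.objective - lo.objective < config.COUPLING_TOL:
            coupled.add(rid)
    return coupled


def fba_predict(network: MetabolicNetwork, genotype: Genotype,
                objective: str | None = None,
                extra_bounds: dict[str, tuple[float, float]] | None = None,
                solver=DEFAULT_SOLVER) -> KnockoutPrediction:
    """Max-biomass flux vector under knockout bounds."""
    ko = knockout_bounds(network, genotype)
    merged = dict(extra_bounds or {})
    merged.update(ko)
    objective = objective or network.biomass_id
    try:
        res = fba(network, extra_bounds=merged, objective=objective,
                  solver=solver)
    except InfeasibleError:
        res = LPResult("infeasible", np.nan, {})
    if not res.optimal or res.objective <= config.LP_MASS_TOL:
        fluxes = res.fluxes if res.optimal else \
            {r.id: 0.0 for r in network.reactions}
        growth = res.objective if res.optimal else 0.0
        return KnockoutPrediction(fluxes=fluxes, growth=growth,
                                  lethal=True, method="FBA")
    return KnockoutPrediction(fluxes=res.fluxes, growth=res.objective,
                              lethal=False, method="FBA")


def moma_predict(network: MetabolicNetwork, genotype: Genotype,
                 reference_flux: dict[str, float],
                 extra_bounds: dict[str, tuple[float, float]] | None = None
                 ) -> KnockoutPrediction:
    """Minimize ||v - v_ref||_2 subject to S.v=0 and knockout bounds.

    Solved in the nullspace of S so that mass balance holds to machine
    precision; bound constraints are handled by SLSQP.
    """
    S, _, rxns = stoichiometric_matrix(network)
    ko = knockout_bounds(network, genotype)
    merged = dict(extra_bounds or {})
    merged.update(ko)
    bounds = _apply_extra(default_bounds(network), rxns, merged)
    ref = np.array([reference_flux[r] for r in rxns])

    lb = np.array([b[0] for b in bounds])
    ub = np.array([b[1] for b in bounds])
    # fast path: the reference satisfies the mutant bounds -> distance 0
    if np.all(ref >= lb - 1e-12) and np.all(ref <= ub + 1e-12):
        growth = ref[rxns.index(network.biomass_id)] \
            if network.biomass_id else np.nan
        return KnockoutPrediction(fluxes=dict(zip(rxns, ref)), growth=growth,
                                  lethal=False, method="MOMA")

    N = linalg.null_space(S)
    if N.size == 0:
        raise InfeasibleError("stoichiometric nullspace is trivial")
    # feasible start from an LP (any feasible point)
    start = optimize.linprog(np.zeros(len(rxns)), A_eq=S,
                             b_eq=np.zeros(S.shape[0]), bounds=bounds,
                             method="highs")
    if start.status != 0:
        raise InfeasibleError("MOMA knockout set infeasible")
    z0, *_ = np.linalg.lstsq(N, start.x, rcond=None)

    def obj(z):
        d = N @ z - ref
        return float(d @ d)

    def jac(z):
        return 2.0 * N.T @ (N @ z - ref)

    cons = [{"type": "ineq", "fun": lambda z: N @ z - lb,
             "jac": lambda z: N},
            {"type": "ineq", "fun": lambda z: ub - N @ z,
             "jac": lambda z: -N}]
    res = optimize.minimize(obj, z0, jac=jac, constraints=cons,
                            method="SLSQP",
                            options={"maxiter": 500, "ftol": 1e-14})
    v = N @ res.x
    v = np.clip(v, lb, ub)  # remove O(ftol) bound violations
    growth = v[rxns.index(network.biomass_id)] if network.biomass_id \
        else np.nan
    return KnockoutPrediction(fluxes=dict(zip(rxns, v)), growth=growth,
                              lethal=growth <= config.LP_MASS_TOL,
                              method="MOMA")


def max_yield_predict(network: MetabolicNetwork, genotype: Genotype,
                      product_reaction: str,
                      uptake_value: float | None = None,
                      solver=DEFAULT_SOLVER) -> KnockoutPrediction:
    """Maximize product flux per unit uptake under knockout bounds
    (biomass constrained only to be >= 0)."""
    if network.uptake_id is None:
        raise ValueError("network has no uptake reaction designated")
    ko = knockout_bounds(network, genotype)
    if uptake_value is not None:
        uptake = uptake_value
    else:
        up_ub = network.reaction(network.uptake_id).ub
        uptake = min(network.uptake_basis,
                     up_ub if up_ub is not None else np.inf)
    merged = dict(ko)
    merged[network.uptake_id] = (uptake, uptake)
    if network.biomass_id is not None and \
            network.biomass_id not in merged:
        merged[network.biomass_id] = (0.0, config.FLUX_BOUND)
    try:
        res = fba(network, extra_bounds=merged, objective=product_reaction,
                  solver=solver)
    except InfeasibleError:
        res = LPResult("infeasible", np.nan, {})
    if not res.optimal:
        return KnockoutPrediction(
            fluxes={r.id: 0.0 for r in network.reactions}, growth=0.0,
            lethal=True, method="max-yield")
    growth = res.fluxes.get(network.biomass_id, np.nan) \
        if network.biomass_id else np.nan
    return KnockoutPrediction(fluxes=res.fluxes, growth=growth,
                              lethal=False, method="max-yield")


def mass_balance_residual(network: MetabolicNetwork,
                          fluxes: dict[str, float]) -> float:
    """||S.v||_inf for a flux dictionary (diagnostic invariant)."""
    S, _, rxns = stoichiometric_matrix(network)
    v = np.array([fluxes[r] for r in rxns])
    return float(np.max(np.abs(S @ v))) if S.size else 0.0
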