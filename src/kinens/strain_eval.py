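"""Product-yield prediction for designed strains (kinetic model plus the
three stoichiometric comparators) and the agreement statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import config, constraint_lp
from .decomposition import ElementaryNetwork
from .kinetics import Parameterization, SteadyStateSolver
from .model_io import Genotype, MetabolicNetwork, StrainDesign

log = logging.getLogger(__name__)

STOICH_METHODS = ("FBA", "MOMA", "max-yield")


@dataclass
class YieldRecord:
    design: StrainDesign
    y_exp: float
    y_pre: dict[str, float] = field(default_factory=dict)
    condition: str = ""
    product: str = ""

    def relative_error(self, method: str) -> float:
        if self.y_exp <= 0:
            return float("nan")
        return abs(self.y_exp - self.y_pre[method]) / self.y_exp


@dataclass
class KineticYield:
    y: float
    e_levels: dict[str, float]
    converged: bool


def _design_box(elem: ElementaryNetwork, design: StrainDesign
                ) -> tuple[dict[str, float], list[str],
                           list[tuple[float, float]]]:
    """Fixed e_total assignments plus the box over bounded interventions.

    Knockout -> 0; downregulation -> [0.1, 1]; upregulation -> [1, 10].
    """
    fixed: dict[str, float] = {}
    free: list[str] = []
    boxes: list[tuple[float, float]] = []
    for enz, kind in design.interventions.items():
        if enz not in elem.pools:
            raise KeyError(f"design {design.design_id}: unknown enzyme "
                           f"{enz!r}")
        if kind == "knockout":
            fixed[enz] = 0.0
        elif kind == "downregulate":
            free.append(enz)
            boxes.append((0.1, 1.0))
        elif kind == "upregulate":
            free.append(enz)
            boxes.append((1.0, 10.0))
        else:
            raise ValueError(f"unknown intervention {kind!r}")
    return fixed, free, boxes


def predict_yield_kinetic(elem: ElementaryNetwork, param: Parameterization,
                          design: StrainDesign,
                          grid_points: int = 4,
                          refine: bool = True,
                          seed: int = 0) -> KineticYield:
    """Steady-state product flux per uptake flux, with bounded enzyme-level
    interventions resolved by maximizing product flux over the box
    (coarse grid, then Nelder-Mead refinement)."""
    network = elem.network
    if network.uptake_id is None:
        raise ValueError("network has no uptake reaction designated")
    product = design.product_reaction
    if not network.has_reaction(product):
        raise KeyError(f"unknown product reaction {product}")
    fixed, free, boxes = _design_box(elem, design)
    solver = SteadyStateSolver(elem)

    def product_flux(levels: np.ndarray) -> tuple[float, float] | None:
        et = dict(fixed)
        et.update({e: float(np.clip(v, lo, hi))
                   for e, v, (lo, hi) in zip(free, levels, boxes)})
        res = solver.solve(param, e_total=et)
        if not res.converged:
            return None
        uptake = res.fluxes[network.uptake_id]
        if abs(uptake) < 1e-12:
            return None
        return res.fluxes[product], uptake

    if not free:
        out = product_flux(np.zeros(0))
        if out is None:
            log.warning("design %s: no converged steady state",
                        design.design_id)
            return KineticYield(0.0, dict(fixed), False)
        return KineticYield(max(out[0] / out[1], 0.0), dict(fixed), True)

    # coarse search over the intervention box
    if len(free) <= 3:
        axes = [np.geomspace(lo, hi, grid_points) for lo, hi in boxes]
        mesh = np.stack([m.ravel() for m in np.meshgrid(*axes)], axis=-1)
    else:
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in boxes])
        hi = np.array([b[1] for b in boxes])
        mesh = lo * (hi / lo) ** rng.random((64, len(free)))
    best_x, best_v = None, -np.inf
    for x in mesh:
        out = product_flux(x)
        if out is not None and out[0] / out[1] > best_v:
            best_v, best_x = out[0] / out[1], x
    if best_x is None:
        log.warning("design %s: no converged steady state in the "
                    "intervention box", design.design_id)
        return KineticYield(0.0, dict(fixed), False)
    if refine:
        def neg_yield(x):
            out = product_flux(x)
            return np.inf if out is None else -out[0] / out[1]

        res = optimize.minimize(neg_yield, best_x, method="Nelder-Mead",
                                options={"xatol": 1e-3, "fatol": 1e-7,
                                         "maxfev": 200})
        if np.isfinite(res.fun) and -res.fun > best_v:
            best_v = -res.fun
            best_x = np.array([np.clip(v, lo, hi)
                               for v, (lo, hi) in zip(res.x, boxes)])
    levels = dict(fixed)
    levels.update({e: float(np.clip(v, lo, hi))
                   for e, v, (lo, hi) in zip(free, best_x, boxes)})
    return KineticYield(max(best_v, 0.0), levels, True)


def predict_yield_stoichiometric(network: MetabolicNetwork,
                                 design: StrainDesign, method: str,
                                 reference_flux: dict[str, float]
                                 | None = None) -> float:
    """Yield from the FBA / MOMA / max-yield comparator flux vector.

    Only knockouts are honoured; up/down regulations have no stoichiometric
    counterpart and are logged and ignored.
    """
    if method not in STOICH_METHODS:
        raise ValueError(f"method must be one of {STOICH_METHODS}")
    kos = tuple(e for e, kind in design.interventions.items()
                if kind == "knockout")
    ignored = [e for e, kind in design.interventions.items()
               if kind != "knockout"]
    if ignored:
        log.info("design %s: %s ignores non-knockout interventions %s",
                 design.design_id, method, ignored)
    genotype = Genotype(knockouts=kos)
    uptake_fixed = {network.uptake_id: (network.uptake_basis,
                                        network.uptake_basis)}
    if method == "FBA":
        pred = constraint_lp.fba_predict(network, genotype,
                                         extra_bounds=uptake_fixed)
    elif method == "MOMA":
        if reference_flux is None:
            ref = constraint_lp.fba_predict(network, Genotype(),
                                            extra_bounds=uptake_fixed)
            reference_flux = ref.fluxes
        pred = constraint_lp.moma_predict(network, genotype, reference_flux,
                                          extra_bounds=uptake_fixed)
    else:
        pred = constraint_lp.max_yield_predict(network, genotype,
                                               design.product_reaction)
    uptake = pred.fluxes.get(network.uptake_id, 0.0)
    if abs(uptake) < 1e-9:
        return 0.0
    return max(pred.fluxes[design.product_reaction] / uptake, 0.0)


def compare_yields(records: list[YieldRecord],
                   within: float = 0.20) -> dict:
    """Pearson correlation, within-tolerance counts and grouped mean
    relative errors per prediction method."""
    usable = [r for r in records if r.y_exp > 0]
    if len(usable) < 2:
        raise ValueError("need >= 2 records with positive measured yield")
    methods = sorted({m for r in usable for m in r.y_pre})
    out: dict = {"n": len(usable), "pcc": {}, "within": {},
                 "mean_relative_error": {}, "grouped": None}
    rows = []
    for method in methods:
        y_exp = np.array([r.y_exp for r in usable])
        y_pre = np.array([r.y_pre[method] for r in usable])
        if np.std(y_exp) == 0 or np.std(y_pre) == 0:
            out["pcc"][method] = float("nan")
        else:
            out["pcc"][method] = float(stats.pearsonr(y_exp, y_pre)[0])
        rel = np.abs(y_exp - y_pre) / y_exp
        out["within"][method] = int(np.sum(rel <= within))
        out["mean_relative_error"][method] = float(np.mean(rel))
        for r in usable:
            rows.append({"method": method, "product": r.product,
                         "condition": r.condition,
                         "relative_error": r.relative_error(method)})
    df = pd.DataFrame(rows)
    out["grouped"] = (df.groupby(["method", "product", "condition"])
                      ["relative_error"].mean().reset_index())
    return out


def evaluate_designs(elem: ElementaryNetwork, param: Parameterization,
                     designs: list[StrainDesign],
                     methods: tuple[str, ...] = ("kinetic",) + STOICH_METHODS,
                     reference_flux: dict[str, float] | None = None
                     ) -> list[YieldRecord]:
    records = []
    for d in designs:
        rec = YieldRecord(design=d, y_exp=d.y_exp,
                          condition=str(d.condition),
                          product=d.product_metabolite)
        for method in methods:
            if method == "kinetic":
                rec.y_pre["kinetic"] = predict_yield_kinetic(
                    elem, param, d).y
            else:
                rec.y_pre[method] = predict_yield_stoichiometric(
                    elem.network, d, method, reference_flux=reference_flux)
        records.append(rec)
    return records
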