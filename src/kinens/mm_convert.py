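"""Effective Michaelis–Menten constants from anchored elementary
parameterizations, plus the interval machinery used to compare estimated
constants against measured ranges.

Apparent constants are extracted numerically from the quasi-steady-state
flux curve: one substrate is clamped over a log grid with co-substrates at
their reference levels and products at zero, the enzyme-form subsystem is
relaxed to steady state, and v_max / apparent K_m are read off the curve.
Competitive inhibitors are held at their reference level, so the constants
are apparent ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import config
from .decomposition import ElementaryNetwork
from .kinetics import Parameterization, SteadyStateSolver


class UnresolvedCurveError(RuntimeError):
    """The flux curve did not saturate within the widened grid."""


@dataclass(frozen=True)
class IntervalRange:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(
                f"interval lower {self.lower} exceeds upper {self.upper}")

    def intersects(self, other: "IntervalRange") -> bool:
        return self.lower <= other.upper and other.lower <= self.upper


def range_overlap(predicted: IntervalRange, measured: IntervalRange) -> bool:
    """True iff the closed intervals intersect."""
    return predicted.intersects(measured)


def measured_range(values) -> IntervalRange:
    """Mean +/- 1 sample s.d. for >= 2 values; +/- 10% for a single value."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("measured_range requires at least one value")
    if vals.size == 1:
        v = float(vals[0])
        lo, hi = sorted((0.9 * v, 1.1 * v))
        return IntervalRange(lo, hi)
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    return IntervalRange(mean - sd, mean + sd)


@dataclass
class MMParameters:
    reaction: str
    #: apparent K_m per substrate, normalized concentration units
    km: dict[str, float]
    #: plateau flux (basis-100 flux units)
    vmax: float
    #: v_max per total enzyme pool (1 / normalized time)
    kcat: float
    #: absolute K_m ranges in mM after rescaling, per substrate
    km_absolute: dict[str, IntervalRange] = field(default_factory=dict)
    unresolved: bool = False


# ---------------------------------------------------------------------------
# numerical QSSA curve
# ---------------------------------------------------------------------------


def flux_curve(elem: ElementaryNetwork, param: Parameterization,
               reaction: str, substrate: str, levels: np.ndarray,
               co_substrate_levels: dict[str, float] | None = None
               ) -> np.ndarray:
    """Net flux of *reaction* with *substrate* clamped at each level.

    All metabolites are clamped: the varied substrate at the grid level,
    the reaction's products at 0, everything else (co-substrates,
    regulators) at its reference/supplied level. Only the enzyme forms
    relax, so each point is a small linear steady-state problem.
    """
    net = elem.network.reaction(reaction)
    sign = elem.orientation.get(reaction, 1)
    stoich = {m: sign * c for m, c in net.stoichiometry.items()}
    products = {m for m, c in stoich.items() if c > 0}
    clamp = {m.id: 1.0 for m in elem.network.internal_metabolites}
    clamp.update(co_substrate_levels or {})
    for p in products:
        if p in clamp:
            clamp[p] = 0.0
    clamp[substrate] = float(levels[0])
    solver = SteadyStateSolver(elem, clamp=clamp)
    out = np.empty(len(levels))
    for i, s_level in enumerate(levels):
        solver.set_clamp_values({substrate: float(s_level)})
        res = solver.solve(param)
        if not res.converged:
            raise UnresolvedCurveError(
                f"enzyme subsystem of {reaction} did not relax at "
                f"substrate level {s_level}")
        out[i] = res.fluxes[reaction]
    return out


def elementary_to_mm(elem: ElementaryNetwork, param: Parameterization,
                     reaction: str,
                     co_substrate_levels: dict[str, float] | None = None,
                     grid_points: int = 61,
                     grid_decades: tuple[float, float] = (-3.0, 3.0),
                     plateau_rtol: float = 1e-3) -> MMParameters:
    """Apparent K_m (per substrate), v_max and k_cat of one decomposed
    reaction.

    The saturation grid spans ``10**grid_decades`` times the reference
    level; if the curve has not plateaued (last-decade change below
    *plateau_rtol*) the grid is widened once to 1e6, after which the
    constants are flagged unresolved.
    """
    enzymes = elem.reaction_pools(reaction)
    if not enzymes:
        raise KeyError(f"reaction {reaction} has no catalytic cycle")
    net = elem.network.reaction(reaction)
    sign = elem.orientation.get(reaction, 1)
    substrates = [m for m, c in net.stoichiometry.items() if sign * c < 0]
    e_tot = sum(param.e_total.get(e, 1.0) for e in enzymes)

    km: dict[str, float] = {}
    vmax = 0.0
    unresolved = False
    for sub in substrates:
        lo, hi = grid_decades
        for attempt in range(2):
            levels = np.logspace(lo, hi, grid_points)
            v = flux_curve(elem, param, reaction, sub, levels,
                           co_substrate_levels)
            top = v[-1]
            decade_mask = levels >= levels[-1] / 10.0
            dv = np.max(np.abs(v[decade_mask] - top))
            if top > 0 and dv <= plateau_rtol * abs(top):
                break
            hi += 3.0  # widen to 1e6 x reference
            grid_points = grid_points + 30
        else:
            pass
        if not (top > 0 and dv <= plateau_rtol * abs(top)):
            unresolved = True
        vmax = float(top)
        half = vmax / 2.0
        idx = np.searchsorted(v, half)
        if idx == 0 or idx >= len(v):
            km[sub] = float("nan")
            unresolved = True
        else:
            x0, x1 = math.log10(levels[idx - 1]), math.log10(levels[idx])
            y0, y1 = v[idx - 1], v[idx]
            frac = (half - y0) / (y1 - y0)
            km[sub] = float(10.0 ** (x0 + frac * (x1 - x0)))
    kcat = vmax / e_tot if e_tot > 0 else float("nan")
    return MMParameters(reaction=reaction, km=km, vmax=vmax, kcat=kcat,
                        unresolved=unresolved)


def rescale_to_absolute(mm: MMParameters,
                        reference_ranges: dict[str, tuple[float, float]],
                        default_range: tuple[float, float] | None = None
                        ) -> MMParameters:
    """Convert normalized apparent K_m values into absolute mM ranges via
    interval product with each substrate's reference concentration range."""
    for sub, val in mm.km.items():
        rng = reference_ranges.get(sub, default_range)
        if rng is None:
            mm.unresolved = True
            continue
        lo, hi = rng
        if lo > hi:
            raise ValueError(f"bad reference range for {sub}: {rng}")
        if not np.isfinite(val):
            mm.unresolved = True
            continue
        mm.km_absolute[sub] = IntervalRange(val * lo, val * hi)
    return mm
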