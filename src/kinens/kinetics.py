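"""Elementary mass-action kinetics: reversibility/fraction sampling,
reference-state anchoring, ODE assembly and perturbed steady states.

Scaling conventions: fluxes on the uptake = 100 basis, metabolite
concentrations normalized to 1 at the reference state, enzyme pools
normalized to a total of 1 per enzyme (isozymes of one reaction share a
total of 1 across their pools).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize

from . import _fastpath, config
from .decomposition import ElementaryNetwork
from .model_io import Genotype, ValidationError


class AnchoringError(ValueError):
    pass


# ---------------------------------------------------------------------------
# parameterization container
# ---------------------------------------------------------------------------


@dataclass
class Parameterization:
    """Sampled reversibilities/fractions plus anchored rate constants."""

    step_ids: list[str]
    R: np.ndarray                      # per step, in [0, 1 - delta]
    fractions: dict[str, np.ndarray]   # pool -> per-form fractions (sum 1)
    e_total: dict[str, float]          # pool -> total normalized level
    kf: np.ndarray
    kb: np.ndarray
    vmag: np.ndarray                   # sampled |rate| for zero-net steps
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        if np.any(self.R < 0) or np.any(self.R > 1.0 - config.R_DELTA + 1e-15):
            raise ValidationError("reversibility outside [0, 1 - delta]")
        for pool, f in self.fractions.items():
            if np.any(f < 0) or np.any(f > 1):
                raise ValidationError(f"pool {pool}: fraction outside [0,1]")
            if abs(float(np.sum(f)) - 1.0) > 1e-12:
                raise ValidationError(
                    f"pool {pool}: fractions sum to {float(np.sum(f))!r}, "
                    f"not 1")
        if np.any(self.kf < 0) or np.any(self.kb < 0):
            raise ValidationError("negative rate constant")

    def copy(self) -> "Parameterization":
        return Parameterization(
            step_ids=list(self.step_ids), R=self.R.copy(),
            fractions={p: f.copy() for p, f in self.fractions.items()},
            e_total=dict(self.e_total), kf=self.kf.copy(),
            kb=self.kb.copy(), vmag=self.vmag.copy(),
            provenance=dict(self.provenance))

    # -- lossless JSON round-trip ------------------------------------------
    def to_dict(self) -> dict:
        return {"step_ids": self.step_ids,
                "R": self.R.tolist(),
                "fractions": {p: f.tolist()
                              for p, f in self.fractions.items()},
                "e_total": self.e_total,
                "kf": self.kf.tolist(), "kb": self.kb.tolist(),
                "vmag": self.vmag.tolist(),
                "provenance": self.provenance}

    @classmethod
    def from_dict(cls, d: dict) -> "Parameterization":
        return cls(step_ids=list(d["step_ids"]),
                   R=np.asarray(d["R"], dtype=float),
                   fractions={p: np.asarray(f, dtype=float)
                              for p, f in d["fractions"].items()},
                   e_total={p: float(v) for p, v in d["e_total"].items()},
                   kf=np.asarray(d["kf"], dtype=float),
                   kb=np.asarray(d["kb"], dtype=float),
                   vmag=np.asarray(d["vmag"], dtype=float),
                   provenance=dict(d.get("provenance", {})))

    def equals(self, other: "Parameterization", tol: float = 0.0) -> bool:
        if self.step_ids != other.step_ids:
            return False
        if set(self.fractions) != set(other.fractions):
            return False
        arrays = [(self.R, other.R), (self.kf, other.kf),
                  (self.kb, other.kb), (self.vmag, other.vmag)]
        arrays += [(self.fractions[p], other.fractions[p])
                   for p in self.fractions]
        close = all(np.allclose(a, b, rtol=0, atol=tol, equal_nan=True)
                    for a, b in arrays)
        et = all(abs(self.e_total[p] - other.e_total[p]) <= tol
                 for p in self.e_total)
        return close and et and set(self.e_total) == set(other.e_total)


@dataclass
class Perturbation:
    """Per-pool total-enzyme assignment: 0 (knockout), a fixed value, or a
    [lo, hi] interval to be resolved by a downstream fit/search."""

    e_total: dict[str, float | tuple[float, float]] = field(
        default_factory=dict)
    condition: str = ""
    #: reactions whose surviving isozyme pools are free fit variables
    free_isozyme_reactions: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for pool, v in self.e_total.items():
            lo, hi = (v, v) if np.isscalar(v) else v
            if not (0.0 <= lo <= hi <= 10.0):
                raise ValidationError(
                    f"pool {pool}: e_total assignment {v} outside [0, 10]")

    def resolved(self, assignments: dict[str, float] | None = None
                 ) -> dict[str, float]:
        """Concrete e_total dict; interval entries must be covered by
        *assignments*."""
        out: dict[str, float] = {}
        for pool, v in self.e_total.items():
            if np.isscalar(v):
                out[pool] = float(v)
            else:
                if assignments is None or pool not in assignments:
                    raise ValueError(
                        f"pool {pool}: interval assignment unresolved")
                lo, hi = v
                out[pool] = float(np.clip(assignments[pool], lo, hi))
        return out


@dataclass
class SteadyStateResult:
    concentrations: dict[str, float]
    fluxes: dict[str, float]
    converged: bool
    residual: float
    time_used: float
    #: raw state over elem.species (solver warm-start plumbing)
    state: np.ndarray | None = None


# ---------------------------------------------------------------------------
# anchoring
# ---------------------------------------------------------------------------


def _reference_activity(elem: ElementaryNetwork, species: str,
                        fractions: dict[str, np.ndarray],
                        e_total: dict[str, float]) -> float:
    pool = elem.form_pool.get(species)
    if pool is None:
        return 1.0  # normalized metabolite concentration at reference
    i = elem.pools[pool].index(species)
    return float(fractions[pool][i]) * e_total.get(pool, 1.0)


def anchor_rate_constants(elem: ElementaryNetwork,
                          reference_fluxes: dict[str, float],
                          R: np.ndarray,
                          fractions: dict[str, np.ndarray],
                          e_total: dict[str, float] | None = None,
                          vmag: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Back-compute (k_f, k_b) per step so the reference state is an exact
    fixed point.

    Per step with net reference flux V: forward elementary flux
    v_f = V / (1 - R), backward v_b = V.R / (1 - R); k_f (k_b) divide these
    by the product of reference reactant (product) activities. Dead-end
    regulatory steps and steps of zero-reference-flux reactions carry zero
    net flux; their elementary magnitude is taken from *vmag* and they are
    anchored at equilibrium (v_f = v_b = vmag).
    """
    e_total = e_total or {p: 1.0 for p in elem.pools}
    n = elem.n_steps
    kf = np.zeros(n)
    kb = np.zeros(n)
    group_total = {}
    for rxn, members in elem.isozyme_groups.items():
        group_total[rxn] = sum(e_total.get(m, 1.0) for m in members)
    for i, s in enumerate(elem.steps):
        vnet = abs(reference_fluxes.get(s.reaction, 0.0))
        if s.enzyme is not None and s.reaction in group_total:
            tot = group_total[s.reaction]
            share = e_total.get(s.enzyme, 1.0) / tot if tot > 0 else 0.0
            vnet *= share
        if s.dead_end or vnet == 0.0:
            if vmag is None:
                raise AnchoringError(
                    f"step {s.sid}: zero net reference flux requires a "
                    f"sampled elementary magnitude (vmag)")
            vf = vb = float(vmag[i])
        else:
            r = float(R[i])
            if not 0.0 <= r <= 1.0 - config.R_DELTA + 1e-15:
                raise AnchoringError(f"step {s.sid}: R={r} outside [0,1-d]")
            vf = vnet / (1.0 - r)
            vb = vnet * r / (1.0 - r)
        af = 1.0
        for m, c in s.reactants:
            af *= _reference_activity(elem, m, fractions, e_total) ** c
        ab = 1.0
        for m, c in s.products:
            ab *= _reference_activity(elem, m, fractions, e_total) ** c
        if vf > 0 and af == 0.0:
            raise AnchoringError(
                f"step {s.sid}: zero reference activity in a reactant form "
                f"would require an infinite rate constant")
        if vb > 0 and ab == 0.0:
            raise AnchoringError(
                f"step {s.sid}: zero reference activity in a product form")
        kf[i] = vf / af if vf > 0 else 0.0
        kb[i] = vb / ab if vb > 0 else 0.0
    return kf, kb


def sample_parameterization(elem: ElementaryNetwork,
                            reference_fluxes: dict[str, float],
                            rng: np.random.Generator,
                            provenance: dict | None = None
                            ) -> Parameterization:
    """One ensemble member: R ~ U(0, 1-delta) per step, enzyme-form
    fractions ~ Dirichlet(1) per pool (floored and renormalized), isozyme
    shares ~ Dirichlet(1) per reaction, then anchoring."""
    n = elem.n_steps
    R = rng.uniform(0.0, 1.0 - config.R_DELTA, size=n)
    for rid, idx in elem.boundary_steps.items():
        # secretions and drains are irreversible mass action; the uptake
        # step keeps a sampled backward term in its internal product so
        # uptake self-limits when downstream metabolism backs up
        # (mutant predictions are rescaled to the uptake basis downstream)
        if rid != elem.network.uptake_id:
            R[idx] = 0.0
    fractions: dict[str, np.ndarray] = {}
    for pool in elem.pools:
        f = rng.dirichlet(np.ones(len(elem.pools[pool])))
        f = np.maximum(f, config.FRACTION_FLOOR)
        fractions[pool] = f / f.sum()
    e_total = {p: 1.0 for p in elem.pools}
    for rxn, members in elem.isozyme_groups.items():
        shares = rng.dirichlet(np.ones(len(members)))
        shares = np.maximum(shares, config.FRACTION_FLOOR)
        shares = shares / shares.sum()
        for m, s in zip(members, shares):
            e_total[m] = float(s)
    vmag = rng.uniform(0.01, 1.0, size=n) * config.UPTAKE_BASIS
    kf, kb = anchor_rate_constants(elem, reference_fluxes, R, fractions,
                                   e_total, vmag)
    p = Parameterization(step_ids=[s.sid for s in elem.steps], R=R,
                         fractions=fractions, e_total=e_total, kf=kf,
                         kb=kb, vmag=vmag,
                         provenance=dict(provenance or {}))
    p.validate()
    return p


def reanchor(elem: ElementaryNetwork, reference_fluxes: dict[str, float],
             param: Parameterization) -> Parameterization:
    """Recompute k_f/k_b from the stored R/fractions (after crossover or
    mutation of reaction blocks)."""
    kf, kb = anchor_rate_constants(elem, reference_fluxes, param.R,
                                   param.fractions, param.e_total,
                                   param.vmag)
    param.kf = kf
    param.kb = kb
    return param


# ---------------------------------------------------------------------------
# ODE system
# ---------------------------------------------------------------------------


def _pad_slots(elem: ElementaryNetwork, side: str, dummy: int
               ) -> np.ndarray:
    """(n_steps, L) species-index matrix; integer stoichiometries expand to
    repeated slots, empty slots point at a dummy species fixed to 1."""
    rows: list[list[int]] = []
    for s in elem.steps:
        row: list[int] = []
        for m, c in (s.reactants if side == "r" else s.products):
            n = int(round(c))
            if abs(c - n) > 1e-9 or n < 0:
                raise ValidationError(
                    f"step {s.sid}: non-integer stoichiometry {c} is not "
                    f"supported by the mass-action evaluator")
            row.extend([elem.species_index[m]] * n)
        rows.append(row)
    width = max(1, max(len(r) for r in rows))
    out = np.full((len(rows), width), dummy, dtype=int)
    for i, row in enumerate(rows):
        out[i, :len(row)] = row
    return out


class ODESystem:
    """Vectorized mass-action right-hand side over elem.species.

    Elementary rate i = kf_i * prod(reactants) - kb_i * prod(products);
    clamped species have zero time derivative. The per-pool totals are
    structurally conserved (each step consumes exactly the enzyme forms it
    regenerates elsewhere in its cycle). Rate constants can be swapped via
    :meth:`set_parameterization` without rebuilding the structure.
    """

    def __init__(self, elem: ElementaryNetwork, param: Parameterization,
                 clamp: dict[str, float] | None = None):
        self.elem = elem
        self.n_species = len(elem.species)
        self.n_steps = elem.n_steps
        dummy = self.n_species
        self._slots_r = _pad_slots(elem, "r", dummy)
        self._slots_p = _pad_slots(elem, "p", dummy)
        N = np.zeros((self.n_species, self.n_steps))
        for i, s in enumerate(elem.steps):
            for m, c in s.reactants:
                N[elem.species_index[m], i] -= c
            for m, c in s.products:
                N[elem.species_index[m], i] += c
        self.N = N
        self.clamp = dict(clamp or {})
        self._clamp_idx = np.array(
            [elem.species_index[s] for s in self.clamp], dtype=int)
        self._clamp_val = np.array([self.clamp[s] for s in self.clamp])
        self.set_parameterization(param)

    def set_parameterization(self, param: Parameterization) -> None:
        if param.step_ids != [s.sid for s in self.elem.steps]:
            raise ValidationError(
                "parameterization does not match the elementary network")
        self.param = param
        self.kf = param.kf
        self.kb = param.kb

    # -- state helpers ------------------------------------------------------
    def reference_state(self, e_total: dict[str, float] | None = None
                        ) -> np.ndarray:
        """Initial state: metabolites at 1, forms at fraction * e_total."""
        c = np.ones(self.n_species)
        et = e_total or self.param.e_total
        for pool, forms in self.elem.pools.items():
            f = self.param.fractions[pool] * et.get(pool, 1.0)
            for name, val in zip(forms, f):
                c[self.elem.species_index[name]] = val
        if len(self._clamp_idx):
            c[self._clamp_idx] = self._clamp_val
        return c

    def rates(self, c: np.ndarray) -> np.ndarray:
        ca = np.append(c, 1.0)
        pr = np.prod(ca[self._slots_r], axis=1)
        pp = np.prod(ca[self._slots_p], axis=1)
        return self.kf * pr - self.kb * pp

    def rate_jacobian(self, c: np.ndarray) -> np.ndarray:
        """d(rates)/d(c), dense (n_steps, n_species)."""
        ca = np.append(c, 1.0)
        ncols = self.n_species + 1
        size = self.n_steps * ncols
        out = np.zeros(size)
        base = np.arange(self.n_steps) * ncols
        for slots, k, sign in ((self._slots_r, self.kf, 1.0),
                               (self._slots_p, self.kb, -1.0)):
            V = ca[slots]
            L = slots.shape[1]
            for j in range(L):
                comp = sign * k
                for l in range(L):
                    if l != j:
                        comp = comp * V[:, l]
                out += np.bincount(base + slots[:, j], weights=comp,
                                   minlength=size)
        return out.reshape(self.n_steps, ncols)[:, :-1]

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        dc = self.N @ self.rates(c)
        if len(self._clamp_idx):
            dc[self._clamp_idx] = 0.0
        return dc

    def rhs_jacobian(self, c: np.ndarray) -> np.ndarray:
        J = self.N @ self.rate_jacobian(c)
        if len(self._clamp_idx):
            J[self._clamp_idx, :] = 0.0
        return J

    def reaction_fluxes(self, c: np.ndarray) -> dict[str, float]:
        """Net flux per original reaction in its declared direction (sum of
        isozyme-pool conversion rates, or the boundary step rate)."""
        r = self.rates(c)
        out: dict[str, float] = {}
        for rid, idx in self.elem.boundary_steps.items():
            out[rid] = self.elem.orientation[rid] * float(r[idx])
        by_rxn: dict[str, float] = {}
        for (rxn, enz) in self.elem.cycles:
            conv = self.elem.conversion_step(rxn, enz)
            by_rxn[rxn] = by_rxn.get(rxn, 0.0) + float(r[conv])
        for rxn, v in by_rxn.items():
            out[rxn] = self.elem.orientation[rxn] * v
        return out

    def pool_totals(self, c: np.ndarray) -> dict[str, float]:
        return {pool: float(sum(c[self.elem.species_index[f]]
                                for f in forms))
                for pool, forms in self.elem.pools.items()}


def build_odes(elem: ElementaryNetwork, param: Parameterization,
               clamp: dict[str, float] | None = None) -> ODESystem:
    return ODESystem(elem, param, clamp=clamp)


# ---------------------------------------------------------------------------
# steady-state solving
# ---------------------------------------------------------------------------


class SteadyStateSolver:
    """Newton-first steady-state solver with an integration fallback.

    The Newton system replaces one species row per conservation law (enzyme
    pools and any metabolite moiety conservation) with the corresponding
    linear conservation equation, making the Jacobian generically
    nonsingular. The structure is computed once per (network, clamp,
    dead-pool set) and reused across parameterizations — the GA hot path.
    """

    def __init__(self, elem: ElementaryNetwork,
                 clamp: dict[str, float] | None = None):
        self.elem = elem
        self.clamp = dict(clamp or {})
        self._structure_cache: dict[frozenset, tuple] = {}

    def set_clamp_values(self, values: dict[str, float]) -> None:
        """Update clamped-species values (the clamp key set is fixed, so
        cached structures stay valid)."""
        for k, v in values.items():
            if k not in self.clamp:
                raise KeyError(f"species {k} is not clamped in this solver")
            self.clamp[k] = float(v)
        tpl = getattr(self, "_template", None)
        if tpl is not None:
            tpl.clamp.update(values)
            tpl._clamp_val = np.array([tpl.clamp[s] for s in tpl.clamp])

    #: normalized concentrations beyond this are treated as divergence
    #: (no physiological steady state reachable from the reference)
    DIVERGENCE_CAP = 1e5

    def _system(self, param: Parameterization) -> ODESystem:
        sys_ = getattr(self, "_template", None)
        if sys_ is None:
            sys_ = ODESystem(self.elem, param, clamp=self.clamp)
            self._template = sys_
        else:
            sys_.set_parameterization(param)
        return sys_

    def _structure(self, system: ODESystem, dead_pools: frozenset):
        hit = self._structure_cache.get(dead_pools)
        if hit is not None:
            return hit
        elem = self.elem
        dead_species = {f for p in dead_pools for f in elem.pools[p]}
        live = [i for i, s in enumerate(elem.species)
                if s not in self.clamp and s not in dead_species]
        live_idx = np.array(live, dtype=int)
        active = [i for i, s in enumerate(elem.steps)
                  if all(m not in dead_species
                         for m, _ in s.reactants + s.products)]
        N_live = system.N[np.ix_(live_idx, np.array(active, dtype=int))] \
            if active else system.N[live_idx][:, :0]
        # conservation laws: left null space of N restricted to live/active
        if N_live.shape[1]:
            u, sv, _ = np.linalg.svd(N_live)
            rank = int(np.sum(sv > 1e-10 * (sv[0] if len(sv) else 1.0)))
            cons = u[:, rank:].T
        else:
            cons = np.eye(len(live_idx))
        pivots: list[int] = []
        cons_rows: list[np.ndarray] = []
        used: set[int] = set()
        for w in cons:
            order = np.argsort(-np.abs(w))
            pivot = next((int(j) for j in order
                          if j not in used and abs(w[j]) > 1e-8), None)
            if pivot is None:
                continue
            used.add(pivot)
            pivots.append(pivot)
            cons_rows.append(w)
        N_live = np.ascontiguousarray(system.N[live_idx, :])
        pos = np.full(len(elem.species) + 1, -1, dtype=np.int64)
        for i, s in enumerate(live_idx):
            pos[s] = i
        out = (live_idx, pivots,
               np.array(cons_rows) if cons_rows else
               np.zeros((0, len(live_idx))), N_live, pos)
        self._structure_cache[dead_pools] = out
        return out

    def solve(self, param: Parameterization,
              e_total: dict[str, float] | None = None,
              x0: np.ndarray | None = None,
              tol: float = config.SS_TOL,
              max_horizon: float = config.MAX_HORIZON) -> SteadyStateResult:
        system = self._system(param)
        et = dict(param.e_total)
        if e_total:
            et.update(e_total)
        dead = frozenset(p for p, v in et.items() if v <= 0.0)
        live_idx, pivots, cons_rows, N_live, pos = self._structure(system,
                                                                   dead)
        piv_arr = np.array(pivots, dtype=int)
        c0 = system.reference_state(et)
        c_full = c0.copy()
        x_init = c0[live_idx] if x0 is None else np.asarray(x0, dtype=float)
        targets = cons_rows @ c0[live_idx] if len(cons_rows) else np.zeros(0)

        if len(live_idx) == 0:
            return self._result(system, c_full, True, 0.0, 0.0)

        def newton_fun(x):
            c_full[live_idx] = x
            f = system.rhs(0.0, c_full)[live_idx]
            if len(piv_arr):
                f[piv_arr] = cons_rows @ x - targets
            return f

        def newton_jac(x):
            c_full[live_idx] = x
            J = system.rhs_jacobian(c_full)[np.ix_(live_idx, live_idx)]
            if len(piv_arr):
                J[piv_arr, :] = cons_rows
            return J

        def accept(x, t_used=0.0) -> SteadyStateResult | None:
            c_full[live_idx] = np.maximum(x, 0.0)
            res = float(np.max(np.abs(system.rhs(0.0, c_full))))
            if res < tol and np.all(x > -1e-9):
                return self._result(system, c_full, True, res, t_used)
            return None

        got = accept(x_init)
        if got is not None:  # anchored reference is already a fixed point
            return got

        if _fastpath.HAVE_NUMBA:
            cw = c_full.copy()
            cw[live_idx] = np.maximum(x_init, 0.0)
            status, x, t_be = _fastpath.be_march(
                system._slots_r, system._slots_p, system.kf, system.kb,
                N_live, live_idx, pos, cw, tol, max_horizon,
                self.DIVERGENCE_CAP, 600)
            if status != 2 and np.all(np.isfinite(x)):
                okp, xp = _fastpath.newton_polish(
                    system._slots_r, system._slots_p, system.kf, system.kb,
                    N_live, live_idx, pos, piv_arr,
                    np.ascontiguousarray(cons_rows), targets, cw, x, 60)
                if okp:
                    got = accept(xp, t_be)
                    if got is not None:
                        return got
                got = accept(x, t_be)
                if got is not None:
                    return got
            if status == 1:  # diverged: no reachable steady state
                c_full[live_idx] = np.minimum(np.maximum(x, 0.0),
                                              self.DIVERGENCE_CAP)
                res = float(np.max(np.abs(system.rhs(0.0, c_full))))
                return self._result(system, c_full, False, res, t_be)
        else:
            def raw_f(x):
                c_full[live_idx] = x
                return system.rhs(0.0, c_full)[live_idx]

            def raw_j(x):
                c_full[live_idx] = x
                return system.rhs_jacobian(c_full)[np.ix_(live_idx,
                                                          live_idx)]

            x, t_be, diverged = self._backward_euler(
                raw_f, raw_j, np.maximum(x_init, 0.0), tol=tol,
                max_time=max_horizon)
            if x is not None:
                xp = self._damped_newton(newton_fun, newton_jac, x)
                if xp is not None:
                    got = accept(xp, t_be)
                    if got is not None:
                        return got
                got = accept(x, t_be)
                if got is not None:
                    return got
            if diverged:
                c_full[live_idx] = np.maximum(
                    x if x is not None else x_init, 0.0)
                res = float(np.max(np.abs(system.rhs(0.0, c_full))))
                return self._result(system, c_full, False, res, t_be)
        # stiff integration fallback with Newton polish per horizon; bail
        # early on divergence (unbounded accumulation) or a stalled residual
        t_used = 0.0
        x = np.maximum(x_init, 0.0)
        horizon = 100.0
        diverged = False
        prev_res = np.inf
        while t_used < max_horizon and not diverged:
            span = min(horizon, max_horizon - t_used)

            def ivp_rhs(t, xv):
                c_full[live_idx] = xv
                return system.rhs(0.0, c_full)[live_idx]

            def ivp_jac(t, xv):
                c_full[live_idx] = xv
                return system.rhs_jacobian(c_full)[np.ix_(live_idx,
                                                          live_idx)]

            def blowup(t, xv):
                return self.DIVERGENCE_CAP - float(np.max(np.abs(xv)))
            blowup.terminal = True

            ode = integrate.solve_ivp(ivp_rhs, (0.0, span), x,
                                      method="BDF", jac=ivp_jac,
                                      rtol=1e-6, atol=1e-9,
                                      events=[blowup])
            if ode.status == 1:  # divergence event fired
                diverged = True
            elif not ode.success:
                break
            x = ode.y[:, -1]
            t_used += span
            horizon *= 10.0
            got = accept(x, t_used)
            if got is not None:
                return got
            xn = self._damped_newton(newton_fun, newton_jac, x)
            if xn is not None:
                got = accept(xn, t_used)
                if got is not None:
                    return got
            res_now = float(np.max(np.abs(ivp_rhs(0.0, x))))
            if t_used >= 1e3 and res_now > 0.5 * prev_res:
                break  # residual stalled: treat as no reachable steady state
            prev_res = res_now
        c_full[live_idx] = np.maximum(x, 0.0)
        res = float(np.max(np.abs(system.rhs(0.0, c_full))))
        return self._result(system, c_full, False, res, t_used)

    @classmethod
    def _backward_euler(cls, fun, jac, x0, tol, max_time,
                        max_steps=600):
        """March x' = f(x) to its attractor with adaptive implicit Euler.

        Each step solves y - x - dt f(y) = 0 by simplified Newton with a
        frozen LU of (I - dt J); dt grows geometrically while the inner
        iteration converges fast, so the march turns into Newton near the
        fixed point. Returns (x or None, pseudo-time used, diverged)."""
        from scipy.linalg import lu_factor, lu_solve

        x = x0.copy()
        n = len(x)
        eye = np.eye(n)
        f = fun(x)
        dt = 1e-2
        t_used = 0.0
        M = None
        fresh = False
        for _ in range(max_steps):
            nf = float(np.max(np.abs(f)))
            if nf < tol:
                return x, t_used, False
            if not np.isfinite(nf):
                return None, t_used, False
            if M is None:
                try:
                    M = lu_factor(eye - dt * jac(x))
                    fresh = True
                except (np.linalg.LinAlgError, ValueError):
                    return None, t_used, False
            y = x + dt * f  # explicit predictor
            ok = False
            theta = 1.0
            prev = None
            for _inner in range(10):
                r = y - x - dt * fun(y)
                if not np.all(np.isfinite(r)):
                    break
                dy = lu_solve(M, -r)
                step = float(np.linalg.norm(dy))
                y = y + dy
                if prev is not None and prev > 0:
                    theta = step / prev
                if theta > 0.9 and _inner >= 2:
                    break  # inner iteration not contracting
                prev = step
                if step <= 1e-10 * (1.0 + float(np.linalg.norm(x))):
                    ok = True
                    break
            if not ok:
                if not fresh:
                    M = None  # stale frozen Jacobian: refresh at same dt
                    continue
                dt *= 0.25
                M = None
                if dt < 1e-10:
                    return None, t_used, False
                continue
            y = np.maximum(y, 0.0)
            x = y
            f = fun(x)
            fresh = False
            t_used += dt
            if float(np.max(np.abs(x))) > cls.DIVERGENCE_CAP:
                return x, t_used, True
            if t_used > max_time:
                return (x, t_used, False) if nf < tol else \
                    (None, t_used, False)
            if theta < 0.2:
                dt_new = min(dt * 2.5, 1e9)
            elif theta < 0.5:
                dt_new = min(dt * 1.5, 1e9)
            else:
                dt_new = dt
            if dt_new != dt:
                dt = dt_new
                M = None
        return (x if float(np.max(np.abs(f))) < tol else None,
                t_used, False)

    @staticmethod
    def _damped_newton(fun, jac, x0, max_iter=60):
        x = x0.copy()
        f = fun(x)
        nf = float(np.linalg.norm(f))
        for _ in range(max_iter):
            if not np.isfinite(nf):
                return None
            if nf < 1e-13:
                return x
            try:
                dx = np.linalg.solve(jac(x), -f)
            except np.linalg.LinAlgError:
                return None
            t = 1.0
            improved = False
            while t >= 1.0 / 1024.0:
                xn = x + t * dx
                fn = fun(xn)
                nfn = float(np.linalg.norm(fn))
                if np.isfinite(nfn) and nfn < nf:
                    x, f, nf = xn, fn, nfn
                    improved = True
                    break
                t *= 0.5
            if not improved:
                return x if nf < 1e-10 else None
        return x if nf < 1e-10 else None

    def _result(self, system: ODESystem, c: np.ndarray, converged: bool,
                residual: float, t_used: float) -> SteadyStateResult:
        conc = {s: float(c[i])
                for i, s in enumerate(self.elem.species)}
        return SteadyStateResult(concentrations=conc,
                                 fluxes=system.reaction_fluxes(c),
                                 converged=converged, residual=residual,
                                 time_used=t_used, state=c.copy())


def solve_steady_state(elem: ElementaryNetwork, param: Parameterization,
                       perturbation: Perturbation | None = None,
                       assignments: dict[str, float] | None = None,
                       clamp: dict[str, float] | None = None,
                       tol: float = config.SS_TOL,
                       max_horizon: float = config.MAX_HORIZON
                       ) -> SteadyStateResult:
    """Solve for the perturbed steady state starting at the reference."""
    solver = SteadyStateSolver(elem, clamp=clamp)
    et = None
    if perturbation is not None:
        perturbation.validate()
        et = perturbation.resolved(assignments)
    return solver.solve(param, e_total=et, tol=tol,
                        max_horizon=max_horizon)


# ---------------------------------------------------------------------------
# genotype -> perturbation
# ---------------------------------------------------------------------------


def apply_perturbation(elem: ElementaryNetwork, genotype: Genotype,
                       condition: str = "") -> Perturbation:
    """Map a genotype onto per-pool e_total assignments.

    Knockouts zero the named pools. Deleting one isozyme of a multi-isozyme
    reaction zeroes that pool and frees the surviving pools on [0, 1] (their
    joint level is a downstream fit variable). Fold-change bounds are
    clipped to [0, 10] with a warning.
    """
    known = set(elem.pools)
    pert = Perturbation(condition=condition)
    for enz in genotype.knockouts:
        if enz not in known:
            raise KeyError(f"unknown enzyme {enz!r} in knockout")
        pert.e_total[enz] = 0.0
    for enz in genotype.isozyme_deletions:
        if enz not in known:
            raise KeyError(f"unknown enzyme {enz!r} in isozyme deletion")
        pert.e_total[enz] = 0.0
        for rxn, members in elem.isozyme_groups.items():
            if enz in members:
                if rxn not in pert.free_isozyme_reactions:
                    pert.free_isozyme_reactions.append(rxn)
                for other in members:
                    if other != enz and other not in pert.e_total:
                        pert.e_total[other] = (0.0, 1.0)
    for enz, lo, hi in genotype.level_bounds:
        if enz not in known:
            raise KeyError(f"unknown enzyme {enz!r} in level bounds")
        clo, chi = float(np.clip(lo, 0.0, 10.0)), float(np.clip(hi, 0.0,
                                                                10.0))
        if (clo, chi) != (lo, hi):
            warnings.warn(
                f"enzyme {enz}: level bounds [{lo}, {hi}] clipped to "
                f"[{clo}, {chi}] (10-fold cap)", stacklevel=2)
        pert.e_total[enz] = (clo, chi) if clo < chi else clo
    pert.validate()
    return pert
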