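"""Two-stage GA parameterization against multi-mutant flux datasets.

Stage 1 evolves whole parameterizations (reaction-wise recombination of
reversibilities/fractions, mutation = prior resampling of one reaction
block, anchored throughout) against the aerobic-glucose knockout datasets;
surviving-isozyme pool levels are appended fit variables. Stage 2 freezes
the elementary parameters and fits only per-enzyme total levels (one fit
per condition group). Fixed seeds give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import config
from .config import GAConfig
from .decomposition import ElementaryNetwork
from .kinetics import (Parameterization, SteadyStateSolver,
                       apply_perturbation, reanchor, sample_parameterization)
from .model_io import FluxDataset


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# objective
# ---------------------------------------------------------------------------


def objective_z(predictions, datasets: list[FluxDataset],
                penalty: float = config.PENALTY,
                eps: float | None = None) -> float:
    """Average CV-scaled relative flux deviation.

    z = (1/M) sum_m (1/N_m) sum_j (1/CV_j) |v_j - v_j^exp| /
    max(|v_j^exp|, eps); a dataset whose prediction is None (no converged
    steady state) contributes *penalty*.
    """
    if eps is None:
        eps = config.EPS_REL_FRACTION * config.UPTAKE_BASIS
    if len(predictions) != len(datasets):
        raise ValueError("predictions and datasets differ in length")
    terms = []
    for pred, ds in zip(predictions, datasets):
        if pred is None:
            terms.append(penalty)
            continue
        n = len(ds.measurements)
        if n == 0:
            continue
        acc = 0.0
        for rid, meas in ds.measurements.items():
            if rid not in pred:
                raise KeyError(
                    f"missing prediction for measured reaction {rid} in "
                    f"strain {ds.strain} (no penalty flag set)")
            rel = abs(pred[rid] - meas.mean) / max(abs(meas.mean), eps)
            acc += rel / meas.cv
        terms.append(acc / n)
    return float(np.mean(terms)) if terms else 0.0


# ---------------------------------------------------------------------------
# individuals and variation operators
# ---------------------------------------------------------------------------


@dataclass
class Individual:
    param: Parameterization
    iso_genes: np.ndarray  # joint surviving-isozyme levels, one per slot
    z: float | None = None

    def copy(self) -> "Individual":
        return Individual(self.param.copy(), self.iso_genes.copy(), self.z)

    def key(self) -> bytes:
        parts = [self.param.R.tobytes(), self.param.vmag.tobytes(),
                 self.iso_genes.tobytes()]
        for pool in sorted(self.param.fractions):
            parts.append(self.param.fractions[pool].tobytes())
        parts.append(np.array(sorted(self.param.e_total.items()),
                              dtype=object).tobytes())
        return b"".join(parts)


def _reaction_blocks(elem: ElementaryNetwork) -> list[tuple[str, list[int],
                                                            list[str]]]:
    """Crossover/mutation loci: (reaction, step indices, pools), catalysed
    reactions only (boundary steps carry no sampled degrees of freedom)."""
    by_rxn: dict[str, tuple[list[int], list[str]]] = {}
    for (rxn, enz), idxs in elem.cycles.items():
        steps, pools = by_rxn.setdefault(rxn, ([], []))
        steps.extend(idxs)
        pools.append(enz)
        steps.extend(elem.reg_steps.get((rxn, enz), []))
    return [(rxn, sorted(v[0]), v[1]) for rxn, v in sorted(by_rxn.items())]


def crossover(parent_a: Individual, parent_b: Individual,
              elem: ElementaryNetwork, reference_fluxes: dict[str, float],
              rng: np.random.Generator
              ) -> tuple[Individual, Individual]:
    """Reaction-wise uniform crossover: each reaction's full block (R,
    fractions, isozyme shares, zero-flux magnitudes) is swapped with
    probability 0.5; children are re-anchored."""
    if parent_a.param.step_ids != parent_b.param.step_ids:
        raise FitError("parents built on different elementary networks")
    ca, cb = parent_a.copy(), parent_b.copy()
    for rxn, steps, pools in _reaction_blocks(elem):
        if rng.random() < 0.5:
            idx = np.array(steps, dtype=int)
            for arr_a, arr_b in ((ca.param.R, cb.param.R),
                                 (ca.param.vmag, cb.param.vmag)):
                arr_a[idx], arr_b[idx] = (arr_b[idx].copy(),
                                          arr_a[idx].copy())
            for pool in pools:
                ca.param.fractions[pool], cb.param.fractions[pool] = \
                    (cb.param.fractions[pool].copy(),
                     ca.param.fractions[pool].copy())
                ca.param.e_total[pool], cb.param.e_total[pool] = \
                    cb.param.e_total[pool], ca.param.e_total[pool]
    for g in range(len(ca.iso_genes)):
        if rng.random() < 0.5:
            ca.iso_genes[g], cb.iso_genes[g] = \
                cb.iso_genes[g], ca.iso_genes[g]
    reanchor(elem, reference_fluxes, ca.param)
    reanchor(elem, reference_fluxes, cb.param)
    ca.z = cb.z = None
    return ca, cb


def mutate(ind: Individual, elem: ElementaryNetwork,
           reference_fluxes: dict[str, float], rng: np.random.Generator,
           prob: float) -> Individual:
    """Per-reaction-block mutation with probability *prob*: half of the
    time the block is resampled from the prior (exploration), half of the
    time its values are jittered locally (refinement)."""
    changed = False
    for rxn, steps, pools in _reaction_blocks(elem):
        if rng.random() >= prob:
            continue
        changed = True
        idx = np.array(steps, dtype=int)
        if rng.random() < 0.5:  # prior resample
            ind.param.R[idx] = rng.uniform(0.0, 1.0 - config.R_DELTA,
                                           size=len(idx))
            ind.param.vmag[idx] = rng.uniform(0.01, 1.0, size=len(idx)) \
                * config.UPTAKE_BASIS
            for pool in pools:
                f = rng.dirichlet(np.ones(len(elem.pools[pool])))
                f = np.maximum(f, config.FRACTION_FLOOR)
                ind.param.fractions[pool] = f / f.sum()
            if rxn in elem.isozyme_groups:
                shares = rng.dirichlet(np.ones(len(pools)))
                shares = np.maximum(shares, config.FRACTION_FLOOR)
                shares = shares / shares.sum()
                for pool, s in zip(pools, shares):
                    ind.param.e_total[pool] = float(s)
        else:  # local jitter
            R = ind.param.R[idx] + 0.03 * rng.standard_normal(len(idx))
            ind.param.R[idx] = np.clip(R, 0.0, 1.0 - config.R_DELTA)
            ind.param.vmag[idx] = ind.param.vmag[idx] * np.exp(
                0.1 * rng.standard_normal(len(idx)))
            for pool in pools:
                f = ind.param.fractions[pool] * np.exp(
                    0.1 * rng.standard_normal(len(elem.pools[pool])))
                f = np.maximum(f, config.FRACTION_FLOOR)
                ind.param.fractions[pool] = f / f.sum()
            if rxn in elem.isozyme_groups:
                shares = np.array([ind.param.e_total[p] for p in pools])
                shares = shares * np.exp(0.1 * rng.standard_normal(
                    len(pools)))
                shares = np.maximum(shares, config.FRACTION_FLOOR)
                shares = shares / shares.sum()
                for pool, s in zip(pools, shares):
                    ind.param.e_total[pool] = float(s)
    for g in range(len(ind.iso_genes)):
        if rng.random() < prob:
            if rng.random() < 0.5:
                ind.iso_genes[g] = rng.uniform(0.0, 1.0)
            else:
                ind.iso_genes[g] = float(np.clip(
                    ind.iso_genes[g] + 0.05 * rng.standard_normal(),
                    0.0, 1.0))
            changed = True
    if changed:
        reanchor(elem, reference_fluxes, ind.param)
        ind.z = None
    return ind


# ---------------------------------------------------------------------------
# fitness machinery
# ---------------------------------------------------------------------------


def basis_fluxes(fluxes: dict[str, float] | None, uptake_id: str,
                 basis: float = config.UPTAKE_BASIS
                 ) -> dict[str, float] | None:
    """Rescale a predicted flux vector to the uptake basis (measured data
    are normalized per substrate uptake); None if uptake collapsed."""
    if fluxes is None:
        return None
    u = fluxes.get(uptake_id, 0.0)
    if u <= 1e-6 * basis:
        return None
    f = basis / u
    return {k: v * f for k, v in fluxes.items()}


@dataclass
class FitResult:
    best: Parameterization
    z: float
    predictions: dict[str, dict[str, float] | None]
    trajectory: list[float]
    iso_genes: dict[str, float] = field(default_factory=dict)
    e_levels: dict[str, float] | None = None

    def check_monotone(self) -> bool:
        return all(b <= a + 1e-12
                   for a, b in zip(self.trajectory, self.trajectory[1:]))


class _Evaluator:
    """Shared steady-state machinery for one dataset collection."""

    def __init__(self, elem: ElementaryNetwork, datasets: list[FluxDataset],
                 penalty: float):
        self.elem = elem
        self.datasets = datasets
        self.penalty = penalty
        self.solver = SteadyStateSolver(elem)
        self.perturbations = [
            apply_perturbation(elem, ds.genotype, condition=str(ds.condition))
            for ds in datasets]
        # ordered slots for free surviving-isozyme levels
        self.iso_slots: list[tuple[int, str]] = []
        for m, pert in enumerate(self.perturbations):
            for rxn in pert.free_isozyme_reactions:
                self.iso_slots.append((m, rxn))
        self._cache: dict[bytes, tuple[float, list]] = {}
        # per-dataset warm-start states (last converged steady state)
        self._warm: dict[int, np.ndarray] = {}
        self._pool_idx = {
            pool: np.array([elem.species_index[f] for f in forms],
                           dtype=int)
            for pool, forms in elem.pools.items()}
        self._live_idx: dict[int, np.ndarray] = {}

    def _warm_x0(self, m: int, et: dict[str, float]) -> np.ndarray | None:
        """Previous converged state, with each live pool rescaled to the
        current e_total so conserved totals match."""
        c = self._warm.get(m)
        live = self._live_idx.get(m)
        if c is None or live is None:
            return None
        c = c.copy()
        for pool, idxs in self._pool_idx.items():
            target = et.get(pool, 1.0)
            if target <= 0.0:
                continue
            s = float(c[idxs].sum())
            if s > 0.0:
                c[idxs] *= target / s
        return c[live]

    def n_iso_genes(self) -> int:
        return len(self.iso_slots)

    def iso_assignments(self, m: int, genes: np.ndarray,
                        param: Parameterization) -> dict[str, float]:
        """Split the joint surviving level of each freed reaction across its
        surviving pools in proportion to their sampled shares."""
        out: dict[str, float] = {}
        pert = self.perturbations[m]
        for slot, (mm, rxn) in enumerate(self.iso_slots):
            if mm != m:
                continue
            g = float(genes[slot])
            survivors = [p for p in self.elem.isozyme_groups[rxn]
                         if not np.isscalar(pert.e_total.get(p)) or
                         pert.e_total.get(p) != 0.0]
            survivors = [p for p in survivors
                         if isinstance(pert.e_total.get(p), tuple)]
            tot = sum(param.e_total.get(p, 1.0) for p in survivors)
            for p in survivors:
                share = param.e_total.get(p, 1.0) / tot if tot > 0 else \
                    1.0 / len(survivors)
                out[p] = g * share
        return out

    def predict(self, ind: Individual) -> list:
        uptake_id = self.elem.network.uptake_id
        preds = []
        for m, (ds, pert) in enumerate(zip(self.datasets,
                                           self.perturbations)):
            assignments = self.iso_assignments(m, ind.iso_genes, ind.param)
            et = pert.resolved(assignments)
            x0 = self._warm_x0(m, et)
            res = self.solver.solve(ind.param, e_total=et, x0=x0)
            if x0 is not None and not res.converged:
                res = self.solver.solve(ind.param, e_total=et)  # cold retry
            if res.converged:
                self._warm[m] = res.state
                if m not in self._live_idx:
                    dead = frozenset(p for p, v in et.items() if v <= 0.0)
                    self._live_idx[m] = self.solver._structure(
                        self.solver._template, dead)[0]
            preds.append(basis_fluxes(res.fluxes if res.converged else None,
                                      uptake_id, ds.basis))
        return preds

    def evaluate(self, ind: Individual) -> float:
        if ind.z is not None:
            return ind.z
        key = ind.key()
        hit = self._cache.get(key)
        if hit is not None:
            ind.z = hit[0]
            return ind.z
        preds = self.predict(ind)
        z = objective_z(preds, self.datasets, penalty=self.penalty)
        self._cache[key] = (z, preds)
        ind.z = z
        return z

    def predictions_of(self, ind: Individual) -> list:
        self.evaluate(ind)
        return self._cache[ind.key()][1]


def _tournament(population: list[Individual], rng: np.random.Generator,
                k: int) -> Individual:
    idx = rng.integers(0, len(population), size=k)
    best = min(idx, key=lambda i: population[i].z)
    return population[best]


# ---------------------------------------------------------------------------
# stage 1
# ---------------------------------------------------------------------------


def stage1_fit(elem: ElementaryNetwork, reference_fluxes: dict[str, float],
               datasets: list[FluxDataset], ga_config: GAConfig
               ) -> FitResult:
    """GA over sampled parameterizations against same-condition knockout
    datasets; returns the best individual with its per-mutant predictions.
    """
    ga_config.validate()
    if not datasets:
        raise FitError("stage-1 requires at least one dataset")
    conditions = {str(ds.condition) for ds in datasets}
    if len(conditions) > 1:
        raise FitError(
            f"stage-1 datasets must share one condition, got {conditions}")
    rng = np.random.default_rng(ga_config.seed)
    ev = _Evaluator(elem, datasets, ga_config.penalty)
    n_iso = ev.n_iso_genes()

    population = []
    for i in range(ga_config.population):
        param = sample_parameterization(
            elem, reference_fluxes, rng,
            provenance={"seed": ga_config.seed, "sample": i})
        population.append(Individual(param, rng.uniform(0.0, 1.0,
                                                        size=n_iso)))
    for ind in population:
        ev.evaluate(ind)
    if all(ind.z >= ga_config.penalty for ind in population):
        raise FitError(
            "every generation-0 individual was penalized: no sampled "
            "parameterization reaches a steady state for the training "
            "mutants (pathological network or data)")

    trajectory = []
    best = min(population, key=lambda i: i.z).copy()
    trajectory.append(best.z)
    for gen in range(ga_config.generations):
        offspring: list[Individual] = [best.copy()
                                       for _ in range(ga_config.elitism)]
        while len(offspring) < ga_config.population:
            pa = _tournament(population, rng, ga_config.tournament_size)
            pb = _tournament(population, rng, ga_config.tournament_size)
            if rng.random() < ga_config.crossover_prob:
                ca, cb = crossover(pa, pb, elem, reference_fluxes, rng)
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                mutate(child, elem, reference_fluxes, rng,
                       ga_config.mutation_prob)
                if len(offspring) < ga_config.population:
                    offspring.append(child)
        population = offspring
        for ind in population:
            ev.evaluate(ind)
        gen_best = min(population, key=lambda i: i.z)
        if gen_best.z < best.z:
            best = gen_best.copy()
        trajectory.append(best.z)

    preds = ev.predictions_of(best)
    iso_genes = {f"{m}:{rxn}": float(best.iso_genes[i])
                 for i, (m, rxn) in enumerate(ev.iso_slots)}
    return FitResult(best=best.param, z=best.z,
                     predictions={ds.strain: p
                                  for ds, p in zip(datasets, preds)},
                     trajectory=trajectory, iso_genes=iso_genes)


# ---------------------------------------------------------------------------
# stage 2
# ---------------------------------------------------------------------------


def stage2_fit(elem: ElementaryNetwork, reference_fluxes: dict[str, float],
               stage1_param: Parameterization,
               datasets: list[FluxDataset], ga_config: GAConfig,
               whitelist: list[str] | None = None,
               polish: bool = True) -> FitResult:
    """Fit only per-enzyme total levels (each in [0, 10]) for one condition
    group, elementary parameters frozen at the stage-1 values.

    *whitelist* names the enzymes allowed to vary (kept small to avoid
    overparameterization); an empty whitelist returns the stage-1 model
    evaluated on the data.
    """
    import warnings

    ga_config.validate()
    whitelist = list(whitelist or [])
    for enz in whitelist:
        if enz not in elem.pools:
            raise KeyError(f"whitelisted enzyme {enz!r} not in network")
    ev = _Evaluator(elem, datasets, ga_config.penalty)
    rng = np.random.default_rng(ga_config.seed)

    uptake_id = elem.network.uptake_id

    def z_of(levels: np.ndarray) -> float:
        overrides = {e: float(v) for e, v in zip(whitelist, levels)}
        preds = []
        for pert, ds in zip(ev.perturbations, datasets):
            et = pert.resolved({})
            et.update(overrides)
            res = ev.solver.solve(stage1_param, e_total=et)
            preds.append(basis_fluxes(
                res.fluxes if res.converged else None, uptake_id, ds.basis))
        return objective_z(preds, datasets, penalty=ga_config.penalty)

    if not whitelist:
        z0 = z_of(np.zeros(0))
        if z0 > 1e-9:
            warnings.warn(
                f"stage-2 whitelist is empty but the data misfit is "
                f"z={z0:.3g}; no degrees of freedom to improve it",
                stacklevel=2)
        return _stage2_result(elem, stage1_param, ev, datasets, {},
                              [z0], z0)

    n = len(whitelist)
    pop = [np.ones(n)] + [rng.uniform(0.0, 10.0, size=n)
                          for _ in range(ga_config.population - 1)]
    zs = [z_of(x) for x in pop]
    order = int(np.argmin(zs))
    best_x, best_z = pop[order].copy(), zs[order]
    trajectory = [best_z]
    for gen in range(ga_config.generations):
        new_pop = [best_x.copy()]
        new_zs = [best_z]
        while len(new_pop) < ga_config.population:
            ia = min(rng.integers(0, len(pop), ga_config.tournament_size),
                     key=lambda i: zs[i])
            ib = min(rng.integers(0, len(pop), ga_config.tournament_size),
                     key=lambda i: zs[i])
            child = pop[ia].copy()
            mask = rng.random(n) < 0.5
            child[mask] = pop[ib][mask]
            for g in range(n):
                r = rng.random()
                if r < ga_config.mutation_prob:
                    child[g] = rng.uniform(0.0, 10.0)
                elif r < 3 * ga_config.mutation_prob:
                    child[g] = float(np.clip(
                        child[g] * np.exp(0.2 * rng.standard_normal()),
                        0.0, 10.0))
            new_pop.append(child)
            new_zs.append(z_of(child))
        pop, zs = new_pop, new_zs
        gi = int(np.argmin(zs))
        if zs[gi] < best_z:
            best_x, best_z = pop[gi].copy(), zs[gi]
        trajectory.append(best_z)

    if polish:
        from scipy import optimize as _opt
        res = _opt.minimize(lambda x: z_of(np.clip(x, 0.0, 10.0)),
                            best_x, method="Nelder-Mead",
                            options={"xatol": 1e-4, "fatol": 1e-8,
                                     "maxfev": 400})
        cand = np.clip(res.x, 0.0, 10.0)
        zc = z_of(cand)
        if zc < best_z:
            best_x, best_z = cand, zc
        trajectory.append(best_z)

    levels = {e: float(v) for e, v in zip(whitelist, best_x)}
    return _stage2_result(elem, stage1_param, ev, datasets, levels,
                          trajectory, best_z)


def _stage2_result(elem, param, ev, datasets, levels, trajectory, z
                   ) -> FitResult:
    preds = []
    for pert, ds in zip(ev.perturbations, datasets):
        et = pert.resolved({})
        et.update(levels)
        res = ev.solver.solve(param, e_total=et)
        preds.append(basis_fluxes(res.fluxes if res.converged else None,
                                  elem.network.uptake_id, ds.basis))
    return FitResult(best=param, z=z,
                     predictions={ds.strain: p
                                  for ds, p in zip(datasets, preds)},
                     trajectory=trajectory, e_levels=levels)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def cross_validate(elem: ElementaryNetwork,
                   reference_fluxes: dict[str, float],
                   datasets: list[FluxDataset], ga_config: GAConfig,
                   mode: str = "loo") -> pd.DataFrame:
    """Leave-one-out / leave-two-out deviation of held-out predictions.

    Each fold refits on the remaining datasets and reports the average
    CV-scaled relative deviation between the fold model's held-out
    predictions and the full-data fit's predictions for the same reactions.
    """
    if mode not in ("loo", "lto"):
        raise ValueError("mode must be 'loo' or 'lto'")
    fold_size = 1 if mode == "loo" else 2
    if len(datasets) < max(3, fold_size + 1):
        raise ValueError("too few datasets for cross-validation")
    eps = config.EPS_REL_FRACTION * config.UPTAKE_BASIS
    full = stage1_fit(elem, reference_fluxes, datasets, ga_config)
    folds = [tuple(range(i, i + fold_size))
             for i in range(0, len(datasets) - fold_size + 1, fold_size)]
    rows = []
    ev = _Evaluator(elem, datasets, ga_config.penalty)
    for fold in folds:
        keep = [d for i, d in enumerate(datasets) if i not in fold]
        held = [datasets[i] for i in fold]
        fit = stage1_fit(elem, reference_fluxes, keep, ga_config)
        devs = []
        for ds in held:
            m = datasets.index(ds)
            pert = ev.perturbations[m]
            # no fitted iso genes for unseen mutants: mid-interval levels
            assign = {p: 0.5 * (v[0] + v[1])
                      for p, v in pert.e_total.items()
                      if isinstance(v, tuple)}
            res = ev.solver.solve(fit.best, e_total=pert.resolved(assign))
            res_full = ev.solver.solve(full.best,
                                       e_total=pert.resolved(assign))
            uptake_id = elem.network.uptake_id
            f_fold = basis_fluxes(res.fluxes if res.converged else None,
                                  uptake_id, ds.basis)
            f_full = basis_fluxes(
                res_full.fluxes if res_full.converged else None,
                uptake_id, ds.basis)
            if f_fold is None or f_full is None:
                devs.append(np.nan)
                continue
            acc = []
            for rid, meas in ds.measurements.items():
                vf = f_full[rid]
                acc.append(abs(f_fold[rid] - vf)
                           / max(abs(vf), eps) / meas.cv)
            devs.append(float(np.mean(acc)))
        rows.append({"fold": "+".join(datasets[i].strain for i in fold),
                     "held_out": len(held),
                     "mean_scaled_deviation": float(np.nanmean(devs))})
    return pd.DataFrame(rows)
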