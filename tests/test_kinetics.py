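import warnings

import numpy as np
import pytest
from scipy import integrate

from kinens import config
from kinens.decomposition import decompose_network
from kinens.kinetics import (AnchoringError, Parameterization, Perturbation,
                             SteadyStateSolver, anchor_rate_constants,
                             apply_perturbation, build_odes, reanchor,
                             sample_parameterization, solve_steady_state)
from kinens.model_io import (Genotype, MetabolicNetwork, Metabolite,
                             Reaction, ValidationError)

from ._oracles import king_altman_uni_uni


def uni_uni_elem():
    """Single catalysed A -> B with boundary source/sink, reference flux 1."""
    net = MetabolicNetwork(
        metabolites=[Metabolite("A"), Metabolite("B")],
        reactions=[Reaction("v", {"A": -1, "B": 1}, enzymes=["E"]),
                   Reaction("src", {"A": 1}, exchange=True),
                   Reaction("snk", {"B": -1}, exchange=True)],
        uptake_id="src")
    ref = {"v": 1.0, "src": 1.0, "snk": 1.0}
    return decompose_network(net, ref), ref


def manual_param(elem, ref, R_value, fractions, vmag_value=10.0):
    n = elem.n_steps
    R = np.full(n, R_value)
    for rid, idx in elem.boundary_steps.items():
        if rid != elem.network.uptake_id:
            R[idx] = 0.0
    fr = {p: np.asarray(f, dtype=float) for p, f in fractions.items()}
    vmag = np.full(n, vmag_value)
    kf, kb = anchor_rate_constants(elem, ref, R, fr, None, vmag)
    return Parameterization(step_ids=[s.sid for s in elem.steps], R=R,
                            fractions=fr, e_total={p: 1.0 for p in fr},
                            kf=kf, kb=kb, vmag=vmag)


class TestAnchoring:
    def test_forward_backward_split(self):
        # V=1, R=0.5 -> elementary forward 2, backward 1
        elem, ref = uni_uni_elem()
        p = manual_param(elem, ref, 0.5,
                         {"E": [0.25, 0.5, 0.25]})
        i_bind = elem.cycles[("v", "E")][0]
        # kf * f_E * [A] = v_f and kb * f_EA = v_b at reference
        s = elem.steps[i_bind]
        assert p.kf[i_bind] * 0.25 == pytest.approx(2.0)
        assert p.kb[i_bind] * 0.5 == pytest.approx(1.0)

    def test_irreversible_limit(self):
        elem, ref = uni_uni_elem()
        p = manual_param(elem, ref, 0.0, {"E": [0.25, 0.5, 0.25]})
        i_bind = elem.cycles[("v", "E")][0]
        assert p.kb[i_bind] == 0.0
        assert p.kf[i_bind] * 0.25 == pytest.approx(1.0)

    def test_kf_equals_vf_over_activity(self):
        # V=1, R=0.5, free-enzyme fraction 0.25, substrate at 1 -> kf = 8
        elem, ref = uni_uni_elem()
        p = manual_param(elem, ref, 0.5, {"E": [0.25, 0.5, 0.25]})
        i_bind = elem.cycles[("v", "E")][0]
        assert p.kf[i_bind] == pytest.approx(8.0)
        sys_ = build_odes(elem, p)
        c0 = sys_.reference_state()
        assert np.max(np.abs(sys_.rhs(0.0, c0))) < 1e-12

    def test_zero_flux_requires_vmag(self):
        elem, ref = uni_uni_elem()
        ref0 = {"v": 0.0, "src": 0.0, "snk": 0.0}
        with pytest.raises(AnchoringError, match="vmag"):
            anchor_rate_constants(elem, ref0, np.full(elem.n_steps, 0.3),
                                  {"E": np.array([0.25, 0.5, 0.25])})

    def test_zero_fraction_rejected(self):
        elem, ref = uni_uni_elem()
        with pytest.raises(AnchoringError, match="infinite|activity"):
            anchor_rate_constants(elem, ref, np.full(elem.n_steps, 0.3),
                                  {"E": np.array([0.0, 0.5, 0.5])},
                                  None, np.full(elem.n_steps, 1.0))


class TestSampling:
    def test_fixed_seed_reproducible(self, branched_model):
        m = branched_model
        p1 = sample_parameterization(m.elementary, m.reference.fluxes,
                                     np.random.default_rng(42))
        p2 = sample_parameterization(m.elementary, m.reference.fluxes,
                                     np.random.default_rng(42))
        assert p1.equals(p2, tol=0.0)

    def test_distinct_samples(self, branched_model):
        m = branched_model
        rng = np.random.default_rng(0)
        ps = [sample_parameterization(m.elementary, m.reference.fluxes,
                                      rng) for _ in range(3)]
        assert not ps[0].equals(ps[1], tol=1e-12)
        assert not ps[1].equals(ps[2], tol=1e-12)

    def test_anchored_at_reference(self, branched_model):
        m = branched_model
        rng = np.random.default_rng(1)
        p = sample_parameterization(m.elementary, m.reference.fluxes, rng)
        sys_ = build_odes(m.elementary, p)
        assert np.max(np.abs(sys_.rhs(0.0, sys_.reference_state()))) < 1e-9

    def test_isozyme_shares_sum_to_one(self, branched_model):
        m = branched_model
        p = sample_parameterization(m.elementary, m.reference.fluxes,
                                    np.random.default_rng(2))
        tot = sum(p.e_total[e]
                  for e in m.elementary.isozyme_groups["v1"])
        assert tot == pytest.approx(1.0, abs=1e-12)


class TestODEs:
    def test_rhs_zero_at_reference(self, branched_model):
        m = branched_model
        sys_ = build_odes(m.elementary, m.truth)
        assert np.max(np.abs(sys_.rhs(0.0, sys_.reference_state()))) < 1e-12

    def test_time_rescaled_cycle_same_form_fixed_point(self):
        # doubling every k_f and k_b of one cycle doubles its net rate but
        # leaves the enzyme-form distribution (metabolites clamped) fixed
        elem, ref = uni_uni_elem()
        p = manual_param(elem, ref, 0.4, {"E": [0.3, 0.4, 0.3]})
        p2 = p.copy()
        idx = np.array(elem.cycles[("v", "E")])
        p2.kf[idx] *= 2.0
        p2.kb[idx] *= 2.0
        clamp = {"A": 1.0, "B": 1.0}
        r1 = SteadyStateSolver(elem, clamp=clamp).solve(p)
        r2 = SteadyStateSolver(elem, clamp=clamp).solve(p2)
        assert r1.converged and r2.converged
        for form in elem.pools["E"]:
            assert r2.concentrations[form] == pytest.approx(
                r1.concentrations[form], abs=1e-9)
        assert r2.fluxes["v"] == pytest.approx(2.0 * r1.fluxes["v"],
                                               rel=1e-9)

    def test_pool_conservation_along_trajectory(self, branched_model):
        m = branched_model
        sys_ = build_odes(m.elementary, m.truth)
        c0 = sys_.reference_state()
        c0 = c0 * (1 + 0.05 * np.sin(np.arange(len(c0))))  # perturb
        sol = integrate.solve_ivp(sys_.rhs, (0, 10.0), c0, method="LSODA",
                                  rtol=1e-10, atol=1e-12)
        assert sol.success
        t0 = sys_.pool_totals(c0)
        t1 = sys_.pool_totals(sol.y[:, -1])
        for pool in t0:
            assert abs(t1[pool] - t0[pool]) < 1e-9


class TestSteadyState:
    def test_empty_perturbation_returns_reference(self, branched_model):
        m = branched_model
        res = solve_steady_state(m.elementary, m.truth)
        assert res.converged
        for rid, v in m.reference.fluxes.items():
            assert res.fluxes[rid] == pytest.approx(v, abs=1e-9)

    def test_ko_terminal_enzyme_zeroes_product_flux(self, branched_model):
        m = branched_model
        res = solve_steady_state(
            m.elementary, m.truth,
            Perturbation(e_total={"e9": 0.0}))
        assert res.converged
        assert res.fluxes["v9"] == pytest.approx(0.0, abs=1e-9)
        assert res.fluxes["secP2"] == pytest.approx(0.0, abs=1e-9)

    def test_cycle_flux_consistency(self, branched_model):
        m = branched_model
        res = solve_steady_state(m.elementary, m.truth,
                                 Perturbation(e_total={"e7": 0.5}))
        assert res.converged
        sys_ = build_odes(m.elementary, m.truth)
        c = np.array([res.concentrations[s] for s in m.elementary.species])
        rates = sys_.rates(c)
        for (rxn, enz), idxs in m.elementary.cycles.items():
            cyc = [rates[i] for i in idxs]
            assert max(cyc) - min(cyc) < 1e-9

    def test_pools_conserved_at_steady_state(self, branched_model):
        m = branched_model
        pert = Perturbation(e_total={"e7": 0.5})
        res = solve_steady_state(m.elementary, m.truth, pert)
        assert res.converged
        sys_ = build_odes(m.elementary, m.truth)
        c = np.array([res.concentrations[s] for s in m.elementary.species])
        totals = sys_.pool_totals(c)
        for pool, tot in totals.items():
            expected = 0.5 if pool == "e7" else m.truth.e_total[pool]
            assert abs(tot - expected) < 1e-9

    def test_mm_limit_single_draw(self):
        # clamped-substrate elementary flux matches the symbolic
        # King-Altman steady state of the same constants
        elem, ref = uni_uni_elem()
        p = manual_param(elem, ref, 0.35, {"E": [0.3, 0.45, 0.25]})
        idx = elem.cycles[("v", "E")]
        k = {}
        for j, i in enumerate(idx):
            k[f"k{j + 1}"] = p.kf[i]
            k[f"km{j + 1}"] = p.kb[i]
        for a in (0.2, 1.0, 5.0):
            solver = SteadyStateSolver(elem, clamp={"A": a, "B": 0.0})
            res = solver.solve(p)
            assert res.converged
            expected = king_altman_uni_uni(
                k["k1"], k["km1"], k["k2"], k["km2"], k["k3"], k["km3"],
                a, 0.0)
            assert res.fluxes["v"] == pytest.approx(expected, rel=1e-6)

    def test_vmax_scales_with_e_total(self):
        elem, ref = uni_uni_elem()
        p = manual_param(elem, ref, 0.2, {"E": [0.3, 0.4, 0.3]})
        sat = {"A": 1e4, "B": 0.0}
        v1 = SteadyStateSolver(elem, clamp=sat).solve(p).fluxes["v"]
        v2 = SteadyStateSolver(elem, clamp=sat).solve(
            p, e_total={"E": 3.0}).fluxes["v"]
        assert v2 / v1 == pytest.approx(3.0, rel=1e-6)


class TestPerturbations:
    def test_knockout_zeroes_pool(self, branched_model):
        pert = apply_perturbation(branched_model.elementary,
                                  Genotype(knockouts=("e9",)))
        assert pert.e_total["e9"] == 0.0

    def test_isozyme_deletion_frees_survivors(self, branched_model):
        pert = apply_perturbation(branched_model.elementary,
                                  Genotype(isozyme_deletions=("e1a",)))
        assert pert.e_total["e1a"] == 0.0
        assert pert.e_total["e1b"] == (0.0, 1.0)
        assert pert.free_isozyme_reactions == ["v1"]

    def test_overexpression_clipped_with_warning(self, branched_model):
        with pytest.warns(UserWarning, match="clipped"):
            pert = apply_perturbation(
                branched_model.elementary,
                Genotype(level_bounds=(("e7", 50.0, 50.0),)))
        assert pert.e_total["e7"] == 10.0

    def test_unknown_enzyme_rejected(self, branched_model):
        with pytest.raises(KeyError):
            apply_perturbation(branched_model.elementary,
                               Genotype(knockouts=("nope",)))

    def test_unresolved_interval_needs_assignment(self):
        pert = Perturbation(e_total={"x": (0.0, 1.0)})
        with pytest.raises(ValueError, match="unresolved"):
            pert.resolved()
        assert pert.resolved({"x": 0.7})["x"] == pytest.approx(0.7)
        assert pert.resolved({"x": 3.0})["x"] == 1.0  # clipped into box
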