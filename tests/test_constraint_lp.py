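import numpy as np
import pytest

from kinens import constraint_lp as clp
from kinens.model_io import (Genotype, MetabolicNetwork, Metabolite,
                             Reaction)

from ._oracles import fba_oracle, fva_oracle, moma_oracle


def chain_network(cap=10.0):
    """ext -> A -> B -> biomass, uptake capped."""
    mets = [Metabolite("ext", boundary=True), Metabolite("A"),
            Metabolite("B")]
    rxns = [Reaction("upt", {"ext": -1, "A": 1}, exchange=True, lb=0,
                     ub=cap),
            Reaction("r1", {"A": -1, "B": 1}, enzymes=["E1"]),
            Reaction("bm", {"B": -1}, exchange=True)]
    return MetabolicNetwork(metabolites=mets, reactions=rxns,
                            biomass_id="bm", uptake_id="upt")


def branch_network():
    """Two equivalent parallel routes A -> B, uptake fixed at 10."""
    mets = [Metabolite("ext", boundary=True), Metabolite("A"),
            Metabolite("B")]
    rxns = [Reaction("upt", {"ext": -1, "A": 1}, exchange=True, lb=10,
                     ub=10),
            Reaction("p1", {"A": -1, "B": 1}, enzymes=["E1"]),
            Reaction("p2", {"A": -1, "B": 1}, enzymes=["E2"]),
            Reaction("bm", {"B": -1}, exchange=True)]
    return MetabolicNetwork(metabolites=mets, reactions=rxns,
                            biomass_id="bm", uptake_id="upt")


class TestReferenceFlux:
    def test_linear_chain_max_biomass(self):
        net = chain_network(cap=10.0)
        ref = clp.compute_reference_flux(net, {})
        for rid in ("upt", "r1", "bm"):
            assert ref.fluxes[rid] == pytest.approx(10.0, abs=1e-6)
        assert all(v == 1.0 for v in ref.concentrations.values())

    def test_fully_constrained_measurements_pass_through(self):
        net = chain_network(cap=10.0)
        ref = clp.compute_reference_flux(net, {"upt": (4.0, None),
                                               "r1": (4.0, None)})
        assert ref.fluxes["bm"] == pytest.approx(4.0, abs=1e-6)
        assert ref.fluxes["r1"] == pytest.approx(4.0, abs=1e-6)

    def test_mass_balance_violation_infeasible(self):
        net = chain_network(cap=10.0)
        with pytest.raises(clp.InfeasibleError):
            clp.compute_reference_flux(net, {"upt": (5.0, None),
                                             "r1": (7.0, None)})

    def test_reference_mass_balance_tight(self, branched_model):
        assert clp.mass_balance_residual(
            branched_model.network,
            branched_model.reference.fluxes) < 1e-8


class TestFVA:
    def test_linear_chain_fixed(self):
        net = chain_network(cap=10.0)
        ranges = clp.flux_variability(net, {"upt": (10.0, 10.0)})
        for rid in ("upt", "r1", "bm"):
            lo, hi = ranges[rid]
            assert lo == pytest.approx(10.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_parallel_branches_each_0_to_10(self):
        net = branch_network()
        ranges = clp.flux_variability(net)
        for rid in ("p1", "p2"):
            assert ranges[rid][0] == pytest.approx(0.0, abs=1e-6)
            assert ranges[rid][1] == pytest.approx(10.0, abs=1e-6)

    def test_blocked_reaction(self):
        mets = [Metabolite("ext", boundary=True), Metabolite("A"),
                Metabolite("B"), Metabolite("C")]
        rxns = [Reaction("upt", {"ext": -1, "A": 1}, exchange=True, lb=0,
                         ub=10),
                Reaction("r1", {"A": -1, "B": 1}, enzymes=["E1"]),
                # C has no sink: r2 is structurally blocked
                Reaction("r2", {"A": -1, "C": 1}, enzymes=["E2"]),
                Reaction("bm", {"B": -1}, exchange=True)]
        net = MetabolicNetwork(metabolites=mets, reactions=rxns,
                               biomass_id="bm", uptake_id="upt")
        ranges = clp.flux_variability(net)
        assert ranges["r2"] == (pytest.approx(0.0, abs=1e-9),
                                pytest.approx(0.0, abs=1e-9))


class TestBiomassCoupling:
    def test_linear_pathway_fully_coupled(self):
        net = chain_network(cap=10.0)
        assert clp.biomass_coupled_reactions(net) == {"upt", "r1"}

    def test_branch_with_drain_not_coupled(self):
        mets = [Metabolite("ext", boundary=True), Metabolite("A"),
                Metabolite("B"), Metabolite("P")]
        rxns = [Reaction("upt", {"ext": -1, "A": 1}, exchange=True, lb=0,
                         ub=10),
                Reaction("r1", {"A": -1, "B": 1}, enzymes=["E1"]),
                Reaction("r2", {"A": -1, "P": 1}, enzymes=["E2"]),
                Reaction("sec", {"P": -1}, exchange=True),
                Reaction("bm", {"B": -1}, exchange=True)]
        net = MetabolicNetwork(metabolites=mets, reactions=rxns,
                               biomass_id="bm", uptake_id="upt")
        coupled = clp.biomass_coupled_reactions(net)
        assert "r1" in coupled  # only route into biomass
        assert "upt" not in coupled  # can overflow through sec
        assert "r2" not in coupled

    def test_agrees_with_ratio_fva_oracle(self, branched_model):
        net = branched_model.network
        coupled = clp.biomass_coupled_reactions(net)
        # brute-force ratio FVA: biomass pinned at 1, bounds wide
        S, _, rxns = clp.stoichiometric_matrix(net)
        lb, ub = [], []
        for r in net.reactions:
            l, u = r.default_bounds()
            lb.append(-1e6 if l <= -clp.config.FLUX_BOUND + 1 else l)
            ub.append(1e6 if u >= clp.config.FLUX_BOUND - 1 else u)
        j_bm = rxns.index("bm")
        lb[j_bm] = ub[j_bm] = 1.0
        from scipy.optimize import linprog
        oracle = set()
        for j, rid in enumerate(rxns):
            if rid == "bm":
                continue
            c = np.zeros(len(rxns))
            c[j] = 1.0
            lo = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         bounds=list(zip(lb, ub)), method="highs")
            hi = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                         bounds=list(zip(lb, ub)), method="highs")
            if -hi.fun - lo.fun < 1e-9:
                oracle.add(rid)
        assert coupled == oracle


class TestKnockoutPredictions:
    def test_fba_no_interventions_is_wildtype(self):
        net = chain_network(cap=10.0)
        pred = clp.fba_predict(net, Genotype())
        assert not pred.lethal
        assert pred.growth == pytest.approx(10.0, abs=1e-6)

    def test_fba_ko_only_route_lethal(self):
        net = chain_network(cap=10.0)
        pred = clp.fba_predict(net, Genotype(knockouts=("E1",)))
        assert pred.lethal
        assert pred.growth == pytest.approx(0.0, abs=1e-6)

    def test_fba_partial_isozyme_deletion_keeps_reaction(self):
        net = branch_network()
        net.reaction("p1").enzymes = ["Ea", "Eb"]
        pred = clp.fba_predict(net, Genotype(isozyme_deletions=("Ea",)))
        assert not pred.lethal  # Eb still catalyses p1

    def test_fba_matches_vertex_oracle_on_branched_toy(self):
        net = branch_network()
        pred = clp.fba_predict(net, Genotype(knockouts=("E1",)))
        S, _, rxns = clp.stoichiometric_matrix(net)
        lb = np.array([10, 0, 0, 0.0])
        ub = np.array([10, 0, 1000, 1000.0])  # p1 knocked out
        c = np.zeros(4)
        c[rxns.index("bm")] = 1.0
        obj, _ = fba_oracle(S, lb, ub, c)
        assert pred.growth == pytest.approx(obj, abs=1e-6)

    def test_fva_matches_vertex_oracle(self):
        net = branch_network()
        S, _, rxns = clp.stoichiometric_matrix(net)
        lb = np.array([10, 0, 0, 0.0])
        ub = np.array([10, 1000, 1000, 1000.0])
        oracle = fva_oracle(S, lb, ub)
        got = clp.flux_variability(net)
        for j, rid in enumerate(rxns):
            assert got[rid][0] == pytest.approx(oracle[j][0], abs=1e-6)
            assert got[rid][1] == pytest.approx(oracle[j][1], abs=1e-6)

    def test_moma_empty_genotype_returns_reference(self):
        net = branch_network()
        ref = clp.fba_predict(net, Genotype()).fluxes
        pred = clp.moma_predict(net, Genotype(), ref)
        for rid, v in ref.items():
            assert pred.fluxes[rid] == pytest.approx(v, abs=1e-12)

    def test_moma_ko_zero_flux_reaction_unchanged(self):
        net = branch_network()
        ref = {"upt": 10.0, "p1": 10.0, "p2": 0.0, "bm": 10.0}
        pred = clp.moma_predict(net, Genotype(knockouts=("E2",)), ref)
        for rid, v in ref.items():
            assert pred.fluxes[rid] == pytest.approx(v, abs=1e-9)

    def test_moma_two_branch_quadratic_optimum(self):
        # reference splits 10 as (7, 3); KO p1 forces (0, 10): the QP
        # optimum is the only feasible point on the closed branch
        net = branch_network()
        ref = {"upt": 10.0, "p1": 7.0, "p2": 3.0, "bm": 10.0}
        pred = clp.moma_predict(net, Genotype(knockouts=("E1",)), ref)
        assert pred.fluxes["p1"] == pytest.approx(0.0, abs=1e-7)
        assert pred.fluxes["p2"] == pytest.approx(10.0, abs=1e-7)

    def test_moma_matches_kkt_oracle(self):
        net = branch_network()
        # free uptake in [0, 10]: the QP now trades uptake against the
        # reference disparity
        net.reaction("upt").lb = 0.0
        ref = np.array([10.0, 7.0, 3.0, 10.0])
        S, _, rxns = clp.stoichiometric_matrix(net)
        lb = np.array([0, 0, 0, 0.0])
        ub = np.array([10, 0, 1000, 1000.0])  # KO p1
        oracle = moma_oracle(S, lb, ub, ref)
        pred = clp.moma_predict(net, Genotype(knockouts=("E1",)),
                                dict(zip(rxns, ref)))
        got = np.array([pred.fluxes[r] for r in rxns])
        assert np.allclose(got, oracle, atol=1e-5)

    def test_max_yield_theoretical_max(self):
        net = branch_network()
        pred = clp.max_yield_predict(net, Genotype(), "bm")
        # all of the fixed uptake is routable to B
        assert pred.fluxes["bm"] == pytest.approx(10.0, abs=1e-6)

    def test_max_yield_product_blocked(self):
        net = branch_network()
        pred = clp.max_yield_predict(
            net, Genotype(knockouts=("E1", "E2")), "bm")
        assert pred.lethal or pred.fluxes["bm"] == pytest.approx(
            0.0, abs=1e-6)

    def test_solutions_satisfy_mass_balance(self, branched_model):
        net = branched_model.network
        for pred in (clp.fba_predict(net, Genotype()),
                     clp.fba_predict(net, Genotype(knockouts=("e9",))),
                     clp.max_yield_predict(net, Genotype(), "secP")):
            if not pred.lethal:
                assert clp.mass_balance_residual(net, pred.fluxes) < 1e-8

    def test_fva_brackets_fba_optimum(self, branched_model):
        net = branched_model.network
        pred = clp.fba_predict(net, Genotype())
        ranges = clp.flux_variability(net)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= pred.fluxes[rid] <= hi + 1e-6
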