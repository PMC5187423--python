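import numpy as np
import pytest

from kinens.config import GAConfig
from kinens.ga_fit import (FitError, Individual, _Evaluator, basis_fluxes,
                           cross_validate, crossover, mutate, objective_z,
                           stage1_fit, stage2_fit)
from kinens.kinetics import build_odes, sample_parameterization
from kinens.model_io import (Condition, FluxDataset, FluxMeasurement,
                             Genotype)
from kinens.synthetic_fixtures import ground_truth_datasets

SMALL = dict(population=12, generations=3, seed=4)


def make_dataset(measurements, strain="M", genotype=Genotype(),
                 condition=Condition()):
    return FluxDataset(strain=strain, genotype=genotype,
                       condition=condition,
                       measurements={k: FluxMeasurement(v, cv * abs(v), cv)
                                     for k, (v, cv) in
                                     measurements.items()},
                       uptake_reaction="upt")


cv = 0.1


class TestObjective:
    def test_perfect_predictions_zero(self):
        ds = make_dataset({"r1": (10.0, cv), "r2": (5.0, cv)})
        z = objective_z([{"r1": 10.0, "r2": 5.0}], [ds])
        assert z == 0.0

    def test_hand_computed_single_case(self):
        # one mutant, one reaction: v=1.2, v_exp=1.0, CV=0.1 -> z = 2.0
        ds = make_dataset({"r1": (1.0, 0.1)})
        z = objective_z([{"r1": 1.2}], [ds])
        assert z == pytest.approx(2.0, abs=1e-12)

    def test_halving_cv_doubles_contribution(self):
        d1 = make_dataset({"r1": (1.0, 0.1)})
        d2 = make_dataset({"r1": (1.0, 0.05)})
        z1 = objective_z([{"r1": 1.2}], [d1])
        z2 = objective_z([{"r1": 1.2}], [d2])
        assert z2 == pytest.approx(2.0 * z1)

    def test_penalty_for_missing_dataset(self):
        ds = make_dataset({"r1": (1.0, 0.1)})
        z = objective_z([None], [ds], penalty=1e6)
        assert z == 1e6

    def test_average_over_mutants(self):
        d1 = make_dataset({"r1": (1.0, 0.1)})
        d2 = make_dataset({"r1": (1.0, 0.1)})
        z = objective_z([{"r1": 1.2}, {"r1": 1.0}], [d1, d2])
        assert z == pytest.approx(1.0)

    def test_missing_prediction_raises(self):
        ds = make_dataset({"r1": (1.0, 0.1), "r2": (2.0, 0.1)})
        with pytest.raises(KeyError):
            objective_z([{"r1": 1.0}], [ds])

    def test_near_zero_flux_floored(self):
        ds = make_dataset({"r1": (0.0001, 0.1)})
        z = objective_z([{"r1": 0.2}], [ds])
        # floored at eps = 0.1 on the basis-100 scale
        assert z == pytest.approx((0.2 - 0.0001) / 0.1 / 0.1)


class TestBasisFluxes:
    def test_rescale(self):
        out = basis_fluxes({"upt": 50.0, "v": 10.0}, "upt", 100.0)
        assert out == {"upt": pytest.approx(100.0),
                       "v": pytest.approx(20.0)}

    def test_collapsed_uptake(self):
        assert basis_fluxes({"upt": 0.0, "v": 1.0}, "upt") is None
        assert basis_fluxes(None, "upt") is None


class TestVariation:
    def _individual(self, model, seed):
        p = sample_parameterization(model.elementary,
                                    model.reference.fluxes,
                                    np.random.default_rng(seed))
        return Individual(p, np.zeros(0))

    def test_identical_parents_identical_children(self, branched_model):
        m = branched_model
        pa = self._individual(m, 1)
        pb = self._individual(m, 1)
        ca, cb = crossover(pa, pb, m.elementary, m.reference.fluxes,
                           np.random.default_rng(0))
        assert ca.param.equals(pa.param, tol=0.0)
        assert cb.param.equals(pa.param, tol=0.0)

    def test_single_block_difference_two_combinations(self, branched_model):
        m = branched_model
        pa = self._individual(m, 1)
        pb = self._individual(m, 1)
        # make parents differ in exactly one reaction block (v2 / pool e2)
        idx = np.array(m.elementary.cycles[("v2", "e2")])
        pb.param.R[idx] = (pb.param.R[idx] + 0.3) % 0.9
        pb.param.fractions["e2"] = np.array([0.2, 0.3, 0.5])
        from kinens.kinetics import reanchor
        reanchor(m.elementary, m.reference.fluxes, pb.param)
        ca, cb = crossover(pa, pb, m.elementary, m.reference.fluxes,
                           np.random.default_rng(3))
        for child in (ca, cb):
            same_a = np.allclose(child.param.R[idx], pa.param.R[idx])
            same_b = np.allclose(child.param.R[idx], pb.param.R[idx])
            assert same_a or same_b
        # the two children carry the two complementary assignments
        assert not np.allclose(ca.param.R[idx], cb.param.R[idx])

    def test_children_remain_anchored(self, branched_model):
        m = branched_model
        ca, cb = crossover(self._individual(m, 1), self._individual(m, 2),
                           m.elementary, m.reference.fluxes,
                           np.random.default_rng(0))
        for child in (ca, cb):
            sys_ = build_odes(m.elementary, child.param)
            assert np.max(np.abs(
                sys_.rhs(0.0, sys_.reference_state()))) < 1e-9

    def test_mutation_keeps_anchoring(self, branched_model):
        m = branched_model
        ind = self._individual(m, 5)
        mutate(ind, m.elementary, m.reference.fluxes,
               np.random.default_rng(1), prob=0.8)
        sys_ = build_odes(m.elementary, ind.param)
        assert np.max(np.abs(sys_.rhs(0.0, sys_.reference_state()))) < 1e-9

    def test_network_mismatch_rejected(self, branched_model, linear_model):
        a = self._individual(branched_model, 1)
        b = self._individual(linear_model, 1)
        with pytest.raises(FitError):
            crossover(a, b, branched_model.elementary,
                      branched_model.reference.fluxes,
                      np.random.default_rng(0))


@pytest.fixture(scope="module")
def small_fit(branched_model):
    datasets = ground_truth_datasets(branched_model)[:4]
    cfg = GAConfig(**SMALL)
    res = stage1_fit(branched_model.elementary,
                     branched_model.reference.fluxes, datasets, cfg)
    return datasets, cfg, res


class TestStage1:
    def test_trajectory_monotone_under_elitism(self, small_fit):
        _, _, res = small_fit
        assert res.check_monotone()

    def test_seed_reproducibility(self, branched_model, small_fit):
        datasets, cfg, res = small_fit
        res2 = stage1_fit(branched_model.elementary,
                          branched_model.reference.fluxes, datasets,
                          GAConfig(**SMALL))
        assert res2.z == res.z
        assert res2.best.equals(res.best, tol=0.0)
        assert res2.trajectory == res.trajectory

    def test_predictions_cover_measured_reactions(self, small_fit):
        datasets, _, res = small_fit
        for ds in datasets:
            pred = res.predictions[ds.strain]
            assert pred is None or \
                set(ds.measurements).issubset(pred)

    def test_mixed_conditions_rejected(self, branched_model):
        ds1 = make_dataset({"upt": (100.0, 0.1)})
        ds2 = make_dataset({"upt": (100.0, 0.1)},
                           condition=Condition(aerobic=False))
        with pytest.raises(FitError, match="condition"):
            stage1_fit(branched_model.elementary,
                       branched_model.reference.fluxes, [ds1, ds2],
                       GAConfig(**SMALL))

    def test_empty_datasets_rejected(self, branched_model):
        with pytest.raises(FitError):
            stage1_fit(branched_model.elementary,
                       branched_model.reference.fluxes, [],
                       GAConfig(**SMALL))


class TestConvergence:
    def test_noiseless_z_drops_tenfold_between_gen5_and_gen60(
            self, branched_model):
        # parameter-recovery property: on noiseless data from a
        # ground-truth model, best z keeps decreasing as generations grow
        m = branched_model
        ds = ground_truth_datasets(
            m, genotypes=[Genotype(knockouts=("e9",)),
                          Genotype(knockouts=("e8",))], noise_cv=0.0)
        cfg = GAConfig(population=64, generations=60, seed=3)
        res = stage1_fit(m.elementary, m.reference.fluxes, ds, cfg)
        assert res.trajectory[60] < res.trajectory[5] / 10.0


class TestStage2:
    def test_empty_whitelist_identity(self, branched_model):
        m = branched_model
        ds = ground_truth_datasets(m, genotypes=[], noise_cv=0.0)
        res = stage2_fit(m.elementary, m.reference.fluxes, m.truth, ds,
                         GAConfig(**SMALL), whitelist=[])
        assert res.e_levels == {}
        assert res.z == pytest.approx(0.0, abs=1e-6)

    def test_empty_whitelist_with_misfit_warns(self, branched_model):
        m = branched_model
        ds = ground_truth_datasets(m, genotypes=[], noise_cv=0.0,
                                   e_total_overrides={"e7": 2.0})
        with pytest.warns(UserWarning, match="whitelist"):
            stage2_fit(m.elementary, m.reference.fluxes, m.truth, ds,
                       GAConfig(**SMALL), whitelist=[])

    def test_recovers_single_level_change(self, branched_model):
        m = branched_model
        ds = ground_truth_datasets(m, genotypes=[], noise_cv=0.0,
                                   e_total_overrides={"e7": 2.0})
        cfg = GAConfig(population=16, generations=8, seed=2)
        res = stage2_fit(m.elementary, m.reference.fluxes, m.truth, ds,
                         cfg, whitelist=["e7"])
        assert res.e_levels["e7"] == pytest.approx(2.0, rel=0.2)

    def test_seed_reproducibility(self, branched_model):
        m = branched_model
        ds = ground_truth_datasets(m, genotypes=[], noise_cv=0.0,
                                   e_total_overrides={"e7": 2.0})
        cfg = GAConfig(population=10, generations=3, seed=9)
        r1 = stage2_fit(m.elementary, m.reference.fluxes, m.truth, ds,
                        cfg, whitelist=["e7"], polish=False)
        r2 = stage2_fit(m.elementary, m.reference.fluxes, m.truth, ds,
                        GAConfig(population=10, generations=3, seed=9),
                        whitelist=["e7"], polish=False)
        assert r1.e_levels == r2.e_levels
        assert r1.trajectory == r2.trajectory

    def test_unknown_whitelist_enzyme(self, branched_model):
        m = branched_model
        ds = ground_truth_datasets(m, genotypes=[], noise_cv=0.0)
        with pytest.raises(KeyError):
            stage2_fit(m.elementary, m.reference.fluxes, m.truth, ds,
                       GAConfig(**SMALL), whitelist=["nope"])


class TestCrossValidate:
    def test_shape_and_redundancy(self, branched_model):
        m = branched_model
        base = ground_truth_datasets(m, genotypes=[
            Genotype(knockouts=("e9",)),
            Genotype(knockouts=("e9",)),       # redundant duplicate
            Genotype(level_bounds=(("e10", 0.3, 0.3),)),  # unique
        ], noise_cv=0.05)
        # rename the duplicate so strains stay distinct
        base[2].strain = "M2dup"
        cfg = GAConfig(population=10, generations=3, seed=6)
        table = cross_validate(m.elementary, m.reference.fluxes, base,
                               cfg, mode="loo")
        assert len(table) == len(base)
        assert set(table.columns) >= {"fold", "mean_scaled_deviation"}
        dev = dict(zip(table["fold"], table["mean_scaled_deviation"]))
        # removing the redundant duplicate hurts less than removing the
        # unique-condition mutant
        assert dev["M2dup"] < dev["M3"]

    def test_too_few_datasets(self, branched_model):
        m = branched_model
        ds = ground_truth_datasets(m, genotypes=[])[:1]
        with pytest.raises(ValueError):
            cross_validate(m.elementary, m.reference.fluxes, ds,
                           GAConfig(**SMALL))

    def test_bad_mode(self, branched_model):
        with pytest.raises(ValueError):
            cross_validate(branched_model.elementary,
                           branched_model.reference.fluxes, [],
                           GAConfig(**SMALL), mode="loco")
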