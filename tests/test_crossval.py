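"""Balanced folds, leakage guards and the six scenario designs."""

import numpy as np
import pandas as pd
import pytest

import genobank as gb
from genobank.crossval import _evaluate_split


class TestBalancedKfold:
    def test_exact_divisibility(self):
        ids = [f"a{i}" for i in range(100)]
        strata = pd.Series(["A"] * 80 + ["B"] * 20, index=ids)
        plan = gb.balanced_kfold(ids, strata, 5, seed=1)
        for fold in plan.folds:
            labs = strata.loc[fold]
            assert (labs == "A").sum() == 16
            assert (labs == "B").sum() == 4

    def test_deterministic_under_seed(self):
        ids = [f"a{i}" for i in range(37)]
        p1 = gb.balanced_kfold(ids, None, 4, seed=9)
        p2 = gb.balanced_kfold(ids, None, 4, seed=9)
        assert p1.folds == p2.folds
        p3 = gb.balanced_kfold(ids, None, 4, seed=10)
        assert p1.folds != p3.folds

    def test_small_population_partition_constraints(self):
        ids = [f"a{i}" for i in range(7)]
        plan = gb.balanced_kfold(ids, None, 5, seed=2)
        sizes = [len(f) for f in plan.folds]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(sum(plan.folds, [])) == sorted(ids)

    def test_stratum_smaller_than_k_warns_but_partitions(self):
        ids = [f"a{i}" for i in range(12)]
        strata = pd.Series(["big"] * 10 + ["tiny"] * 2, index=ids)
        with pytest.warns(RuntimeWarning, match="fewer members"):
            plan = gb.balanced_kfold(ids, strata, 4, seed=3)
        assert sorted(sum(plan.folds, [])) == sorted(ids)

    def test_proportions_within_one_member(self):
        rng = np.random.default_rng(3)
        ids = [f"a{i}" for i in range(83)]
        strata = pd.Series(rng.choice(["x", "y", "z"], size=83), index=ids)
        plan = gb.balanced_kfold(ids, strata, 4, seed=4)
        for s in "xyz":
            counts = [sum(strata.loc[f].eq(s)) for f in plan.folds]
            assert max(counts) - min(counts) <= 1

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            gb.balanced_kfold(["a", "b"], None, 1, seed=0)


class TestLeakageGuard:
    def test_overlapping_split_refused(self, quantitative_sim):
        _, geno, _, blues, kin, _ = quantitative_sim
        ids = list(blues.index[:30])
        with pytest.raises(ValueError, match="both training and test"):
            _evaluate_split(blues["blue"], kin, ids, ids[:5])

    def test_empty_side_refused(self, quantitative_sim):
        _, _, _, blues, kin, _ = quantitative_sim
        with pytest.raises(ValueError, match="non-empty"):
            _evaluate_split(blues["blue"], kin, list(blues.index), [])


@pytest.fixture(scope="module")
def shifted_sim():
    """Two subpopulations, large non-genetic mean shift, minority pop2."""
    cfg = gb.SimConfig(
        seed=13,
        n_per_subpop=(300, 100),
        m=500,
        fst=0.1,
        traits=(gb.TraitSpec("t", h2=0.8, n_qtl=120, subpop_shifts=(0.0, 3.0)),),
    )
    geno, truth = gb.simulate_genotypes(cfg)
    records = gb.simulate_quantitative(geno, cfg, truth)
    blues = gb.estimate_blues(records, "t")
    kin = gb.compute_grm(geno)
    return blues, kin, truth


class TestScenarioWithin:
    def test_heritable_trait_ability_envelope(self):
        cfg = gb.SimConfig(
            seed=23,
            n_per_subpop=(1000,),
            m=500,
            fst=0.0,
            traits=(gb.TraitSpec("t", h2=0.8, n_qtl=150),),
        )
        geno, truth = gb.simulate_genotypes(cfg)
        blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
        kin = gb.compute_grm(geno)
        res = gb.run_scenario_within(blues, kin, truth.subpop, "t", seed=1)
        mean_ability = res.per_subpop["pop1"][0]
        assert 0.6 <= mean_ability <= 0.95

    def test_noise_trait_ability_near_zero(self):
        cfg = gb.SimConfig(
            seed=29,
            n_per_subpop=(300,),
            m=400,
            fst=0.0,
            traits=(gb.TraitSpec("t", h2=0.0, n_qtl=50),),
        )
        geno, truth = gb.simulate_genotypes(cfg)
        blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
        kin = gb.compute_grm(geno)
        res = gb.run_scenario_within(blues, kin, truth.subpop, "t", seed=2)
        assert abs(res.per_subpop["pop1"][0]) <= 0.1

    def test_small_subpopulation_excluded(self, shifted_sim):
        blues, kin, truth = shifted_sim
        res = gb.run_scenario_within(
            blues, kin, truth.subpop, "t", seed=3, min_subpop=200
        )
        assert "pop2" not in res.per_subpop
        assert "pop1" in res.per_subpop


class TestScenarioPooled:
    def test_covariate_mode_helps_minority_under_shift(self, shifted_sim):
        blues, kin, truth = shifted_sim
        ign = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="ignored", seed=4
        )
        cov = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="covariate", seed=4
        )
        assert cov.per_subpop["pop2"][0] >= ign.per_subpop["pop2"][0] - 0.02

    def test_no_shift_covariate_mode_equivalent(self):
        cfg = gb.SimConfig(
            seed=37,
            n_per_subpop=(150, 150),
            m=400,
            fst=0.05,
            traits=(gb.TraitSpec("t", h2=0.8, n_qtl=100),),
        )
        geno, truth = gb.simulate_genotypes(cfg)
        blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
        kin = gb.compute_grm(geno)
        ign = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="ignored", seed=5
        )
        cov = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="covariate", seed=5
        )
        assert abs(cov.overall[0] - ign.overall[0]) <= 0.05

    def test_dummy_ancestry_reproduces_covariate_mode(self, shifted_sim):
        blues, kin, truth = shifted_sim
        anc = pd.get_dummies(truth.subpop, dtype=float)
        cov = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="covariate", seed=6
        )
        via_anc = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="ancestry",
            ancestry=anc, seed=6,
        )
        np.testing.assert_allclose(
            via_anc.table["ability"], cov.table["ability"], atol=1e-8
        )

    def test_missing_ancestry_accessions_rejected(self, shifted_sim):
        blues, kin, truth = shifted_sim
        anc = pd.get_dummies(truth.subpop, dtype=float).iloc[:-5]
        with pytest.raises(ValueError, match="missing"):
            gb.run_scenario_pooled(
                blues, kin, truth.subpop, "t", covariate_mode="ancestry",
                ancestry=anc, seed=7,
            )


@pytest.fixture(scope="module")
def divergent_sim():
    """Two subpopulations whose QTL effects correlate only at 0.3."""
    cfg = gb.SimConfig(
        seed=41,
        n_per_subpop=(200, 200),
        m=500,
        fst=0.1,
        traits=(gb.TraitSpec("t", h2=0.8, n_qtl=120, effect_correlation=0.3),),
    )
    geno, truth = gb.simulate_genotypes(cfg)
    blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
    kin = gb.compute_grm(geno)
    return blues, kin, truth


class TestScenarioAcross:
    def test_divergent_effects_reduce_transfer(self, divergent_sim):
        blues, kin, truth = divergent_sim
        res = gb.run_scenario_across(blues, kin, truth.subpop, "t", reps=5, seed=8)
        m = res.extras["matrix"]
        assert m[("pop1", "pop2")][0] < m[("pop1", "pop1")][0]
        assert m[("pop2", "pop1")][0] < m[("pop2", "pop2")][0]

    def test_exchangeable_groups_transfer_fully(self):
        # one homogeneous population split by an arbitrary label; single
        # records without year structure so measured abilities are directly
        # comparable between the small CV folds and the large across sets
        cfg = gb.SimConfig(
            seed=43,
            n_per_subpop=(300,),
            m=400,
            fst=0.0,
            traits=(gb.TraitSpec("t", h2=0.8, n_qtl=100),),
            years=(2015,),
            records_per_accession=(1, 1),
            sigma_year2=0.0,
        )
        geno, truth = gb.simulate_genotypes(cfg)
        blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
        kin = gb.compute_grm(geno)
        rng = np.random.default_rng(9)
        fake = pd.Series(
            rng.permutation(["g1"] * 150 + ["g2"] * 150), index=geno.accession_ids
        )
        res = gb.run_scenario_across(blues, kin, fake, "t", reps=5, seed=10)
        m = res.extras["matrix"]
        off = (m[("g1", "g2")][0] + m[("g2", "g1")][0]) / 2
        diag = (m[("g1", "g1")][0] + m[("g2", "g2")][0]) / 2
        assert abs(off - diag) <= 0.1

    def test_single_group_rejected(self, quantitative_sim):
        _, _, _, blues, kin, truth = quantitative_sim
        with pytest.raises(ValueError, match="2 subpopulations"):
            gb.run_scenario_across(blues, kin, truth.subpop, "yield", seed=1)


@pytest.fixture(scope="module")
def dense_training_sim():
    """Relationship-dense design: marker panel small relative to the training
    set, emulating the low effective marker dimensionality (long-range LD)
    of real gene-bank SNP data, where training-set reduction erodes ability
    only moderately."""
    cfg = gb.SimConfig(
        seed=59,
        n_per_subpop=(600, 600),
        m=100,
        fst=0.1,
        traits=(gb.TraitSpec("t", h2=0.8, n_qtl=60),),
    )
    geno, truth = gb.simulate_genotypes(cfg)
    blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
    kin = gb.compute_grm(geno)
    return blues, kin, truth


class TestScenarioCore:
    def test_core_covering_all_phenotyped_refused(self, quantitative_sim):
        _, _, _, blues, kin, _ = quantitative_sim
        with pytest.raises(ValueError, match="no test set"):
            gb.run_scenario_core(blues, kin, list(blues.index), "yield")

    def test_stratified_tenth_core_retains_most_ability(self, dense_training_sim):
        blues, kin, truth = dense_training_sim
        core = gb.nominate_core(truth.subpop, 0.1, seed=11)
        res_core = gb.run_scenario_core(blues, kin, core, "t")
        res_full = gb.run_scenario_pooled(
            blues, kin, truth.subpop, "t", covariate_mode="ignored", seed=12
        )
        ratio = res_core.overall[0] / res_full.overall[0]
        assert 0.7 <= ratio <= 1.0

    def test_single_member_core_flagged(self, quantitative_sim):
        _, _, _, blues, kin, _ = quantitative_sim
        with pytest.warns(RuntimeWarning):
            res = gb.run_scenario_core(blues, kin, [blues.index[0]], "yield")
        assert res.extras["low_confidence"]
        # the intercept fits the single training record exactly, so the
        # predictions are flat and the ability is undefined
        assert np.isnan(res.overall[0])


class TestScenarioPredictAll:
    def test_unrelated_unphenotyped_zero_reliability(self, rng):
        n_phen, n_un = 40, 10
        W = rng.normal(size=(n_phen, 120))
        G = np.eye(n_phen + n_un)
        G[:n_phen, :n_phen] = W @ W.T / 120 + 0.05 * np.eye(n_phen)
        ids = [f"i{j}" for j in range(n_phen + n_un)]
        kin = gb.Kinship(ids, G)
        y = pd.Series(rng.normal(size=n_phen), index=ids[:n_phen])
        y = y + 0.5 * pd.Series(np.diag(G)[:n_phen], index=ids[:n_phen])
        res = gb.run_scenario_predict_all(y, kin, "t")
        assert res.extras["reliability_unphenotyped"]["mean"] <= 0.05

    def test_random_half_reliability_envelope(self):
        cfg = gb.SimConfig(
            seed=47,
            n_per_subpop=(600,),
            m=400,
            fst=0.0,
            traits=(gb.TraitSpec("t", h2=0.8, n_qtl=120),),
            missing_phenotype_rate=0.5,
        )
        geno, truth = gb.simulate_genotypes(cfg)
        blues = gb.estimate_blues(gb.simulate_quantitative(geno, cfg, truth), "t")
        kin = gb.compute_grm(geno)
        res = gb.run_scenario_predict_all(blues, kin, "t")
        mean_un = res.extras["reliability_unphenotyped"]["mean"]
        assert 0.4 <= mean_un <= 0.9
        assert (
            res.extras["reliability_phenotyped"]["mean"]
            >= res.extras["reliability_unphenotyped"]["mean"]
        )
        assert 0.0 <= res.extras["fraction_unphenotyped_above_threshold"] <= 1.0

    def test_fully_phenotyped_rejected(self, quantitative_sim):
        _, _, _, blues, kin, _ = quantitative_sim
        with pytest.raises(ValueError, match="unphenotyped"):
            gb.run_scenario_predict_all(blues, kin, "yield")


@pytest.fixture(scope="module")
def habit_sim():
    cfg = gb.SimConfig(
        seed=53,
        n_per_subpop=(200, 200),
        m=500,
        fst=0.1,
        traits=(
            gb.TraitSpec("shared", h2=0.8, n_qtl=120, effect_correlation=1.0),
            gb.TraitSpec("specific", h2=0.8, n_qtl=120, effect_correlation=0.2),
        ),
    )
    geno, truth = gb.simulate_genotypes(cfg)
    records = gb.simulate_quantitative(geno, cfg, truth)
    kin = gb.compute_grm(geno)
    habit = truth.subpop.map({"pop1": "spring", "pop2": "winter"})
    return records, kin, habit


class TestScenarioCrossHabit:
    def test_shared_architecture_transfers(self, habit_sim):
        records, kin, habit = habit_sim
        blues = gb.estimate_blues(records, "shared")
        res = gb.run_scenario_cross_habit(blues, blues, kin, habit, "shared", seed=1)
        cross = res.per_subpop["spring->winter"][0]
        within = res.per_subpop["winter->winter"][0]
        assert cross >= within - 0.15

    def test_group_specific_architecture_transfers_poorly(self, habit_sim):
        records, kin, habit = habit_sim
        blues = gb.estimate_blues(records, "specific")
        res = gb.run_scenario_cross_habit(blues, blues, kin, habit, "specific", seed=2)
        assert res.per_subpop["spring->winter"][0] < res.per_subpop["winter->winter"][0]
        assert res.per_subpop["winter->spring"][0] < res.per_subpop["spring->spring"][0]

    def test_incomparable_trait_refused(self, habit_sim):
        records, kin, habit = habit_sim
        blues = gb.estimate_blues(records, "shared")
        with pytest.raises(ValueError, match="incomparable"):
            gb.run_scenario_cross_habit(
                blues, blues, kin, habit, "flowering_time", comparable=False
            )

    def test_unphenotyped_group_rejected(self, habit_sim):
        records, kin, habit = habit_sim
        blues = gb.estimate_blues(records, "shared")
        spring_only = blues[blues.index.isin(habit[habit == "spring"].index)]
        with pytest.raises(ValueError, match="phenotyped members"):
            gb.run_scenario_cross_habit(
                spring_only, spring_only, kin, habit, "shared"
            )
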