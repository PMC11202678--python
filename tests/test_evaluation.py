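"""Fold plans, cross-validation, model comparison, scenarios, haplotypes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phsgp.evaluation import (
    CVResult,
    ModelSpec,
    ScenarioSpec,
    compare_models,
    cross_season_predict,
    cross_validate,
    haplotype_analysis,
    make_folds,
    season_correlations,
)
from phsgp.synthetic import simulate_study_cohort
from tests.conftest import line_level_phenotypes


class TestMakeFolds:
    def test_equal_programs_divide_exactly(self):
        ids = [f"l{i}" for i in range(300)]
        progs = np.repeat([f"P{j}" for j in range(6)], 50)
        plan = make_folds(ids, progs, k=5, reps=10, seed=1)
        for rep in range(10):
            for fold in range(5):
                test = plan.test_lines(rep, fold)
                assert len(test) == 60
                counts = pd.Series(progs[np.isin(ids, test)]).value_counts()
                assert (counts == 10).all()

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 40), min_size=1, max_size=8), st.integers(0, 10_000))
    def test_partition_axioms_and_balance(self, sizes, seed):
        ids = np.array([f"l{i}" for i in range(sum(sizes))])
        progs = np.concatenate([[f"P{j}"] * s for j, s in enumerate(sizes)])
        plan = make_folds(ids, progs, k=5, reps=2, seed=seed)
        for rep in range(2):
            folds = [set(plan.test_lines(rep, f)) for f in range(5)]
            assert set().union(*folds) == set(ids)
            assert sum(len(f) for f in folds) == len(ids)  # pairwise disjoint
            for prog, size in zip([f"P{j}" for j in range(len(sizes))], sizes):
                per_fold = [
                    sum(progs[np.isin(ids, list(f))] == prog) for f in folds
                ]
                assert max(per_fold) - min(per_fold) <= 1

    def test_seven_line_program_fold_sizes(self):
        ids = [f"l{i}" for i in range(7)]
        plan = make_folds(ids, ["P"] * 7, k=5, reps=1, seed=0)
        sizes = sorted(len(plan.test_lines(0, f)) for f in range(5))
        assert sizes == [1, 1, 1, 2, 2]

    def test_deterministic_and_identity_stable(self):
        ids = [f"l{i}" for i in range(30)]
        progs = ["A"] * 15 + ["B"] * 15
        a = make_folds(ids, progs, seed=3)
        b = make_folds(ids, progs, seed=3)
        assert a.identity() == b.identity()
        np.testing.assert_array_equal(a.assignments, b.assignments)


class TestCrossValidate:
    def test_null_heritability_gives_zero_mean_ability(
        self, small_population, small_grm
    ):
        y = line_level_phenotypes(small_population, None, 0, seed=2)
        plan = make_folds(
            small_population.line_ids, small_population.program, k=5, reps=5, seed=4
        )
        res = cross_validate(y, small_population, small_grm, ModelSpec("model1"), plan)
        assert len(res.runs) == 25
        assert res.mean_ability == pytest.approx(0.0, abs=0.1)

    def test_signal_gives_positive_ability_and_pairing(
        self, small_population, small_architecture, small_grm
    ):
        y = line_level_phenotypes(small_population, small_architecture, 0.85, seed=3)
        plan = make_folds(
            small_population.line_ids, small_population.program, k=5, reps=2, seed=5
        )
        r1 = cross_validate(y, small_population, small_grm, ModelSpec("model1"), plan)
        spec2 = ModelSpec.from_architecture("model2_phs", small_architecture)
        r2 = cross_validate(y, small_population, small_grm, spec2, plan)
        assert r1.mean_ability > 0.2
        assert r1.plan_identity == r2.plan_identity
        cmp = compare_models(r1, r2)
        assert cmp["n_pairs"] == 10

    def test_fns_regime_ability_lands_in_the_expected_band(self):
        # high-heritability regime calibrated to breeding-material accuracies:
        # the plain model's mean ability should sit in a broad 0.45-0.70 band
        from phsgp.genotypes import vanraden_grm
        from phsgp.synthetic import PopulationSpec, make_qtl_architecture, simulate_population

        abilities = []
        for seed in range(5):
            spec = PopulationSpec(
                n_lines=300, programs=[(f"P{j}", 50) for j in range(6)],
                season_split={"CS": 300, "VS15": 0, "VS16": 0},
                n_markers=600, seed=800 + seed,
            )
            geno = simulate_population(spec)
            arch = make_qtl_architecture(
                geno, major_var_share=0.30, n_polygenic=150, seed=810 + seed
            )
            A = vanraden_grm(geno)
            y = line_level_phenotypes(geno, arch, 0.85, seed=820 + seed)
            plan = make_folds(geno.line_ids, geno.program, k=5, reps=2, seed=830 + seed)
            abilities.append(
                cross_validate(y, geno, A, ModelSpec("model1"), plan).mean_ability
            )
        assert 0.45 < np.mean(abilities) < 0.70

    def test_constant_response_recorded_as_missing(self, small_population, small_grm):
        y = pd.Series(1.0, index=small_population.line_ids)
        plan = make_folds(
            small_population.line_ids, small_population.program, k=5, reps=1, seed=0
        )
        res = cross_validate(y, small_population, small_grm, ModelSpec("model1"), plan)
        assert res.runs["r"].isna().all()


class TestCompareModels:
    def _result(self, rs, ident="x"):
        runs = pd.DataFrame(
            {"replicate": 1, "fold": np.arange(len(rs)) + 1, "r": rs, "n_test": 10}
        )
        return CVResult(trait="FNS", variant="model1", runs=runs, plan_identity=ident)

    def test_identical_results_give_no_difference(self):
        a = self._result([0.5, 0.6, 0.55, 0.58, 0.61])
        out = compare_models(a, a)
        assert out["t"] == 0.0 and out["p"] == 1.0 and out["stars"] == "ns"

    def test_consistent_separation_is_significant(self):
        rng = np.random.default_rng(0)
        base = 0.5 + 0.02 * rng.normal(size=50)
        a = self._result(base)
        b = self._result(base + 0.01 + 1e-4 * rng.normal(size=50))
        out = compare_models(a, b)
        assert out["p"] < 0.001 and out["stars"] == "***"

    def test_mismatched_plans_rejected(self):
        a = self._result([0.5, 0.6], ident="x")
        b = self._result([0.5, 0.6], ident="y")
        with pytest.raises(ValueError, match="fold plans"):
            compare_models(a, b)


@pytest.fixture(scope="module")
def cohort():
    return simulate_study_cohort(seed=123, n_markers=300)


class TestScenarios:
    def test_scenario_sizes(self, cohort):
        spec = ScenarioSpec("S15", "S16", "all", "cs")
        m = ModelSpec("model1")
        out = cross_season_predict(spec, cohort["means_by_season"], cohort["geno"],
                                   cohort["A"], m)
        assert (out["n_es"], out["n_ts"]) == (298, 199)
        spec = ScenarioSpec("S15", "S16", "cs", "vs")
        out = cross_season_predict(spec, cohort["means_by_season"], cohort["geno"],
                                   cohort["A"], m)
        assert (out["n_es"], out["n_ts"]) == (199, 99)

    def test_exchangeable_seasons_track_within_season_ability(self, cohort):
        m = ModelSpec("model1")
        out = cross_season_predict(
            ScenarioSpec("S15", "S16", "all", "vs"), cohort["means_by_season"],
            cohort["geno"], cohort["A"], m,
        )
        assert 0.2 < out["r"] <= 1.0

    def test_gebv_correlation_beats_obv_correlation(self, cohort):
        out = season_correlations(
            cohort["means_by_season"], cohort["geno"], cohort["A"],
            ModelSpec("model1"), ("S15", "S16"),
        )
        assert out["n_cs"] == 199
        assert out["r_gebv"] >= out["r_obv"] - 0.02

    def test_same_season_scenario_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec("S15", "S15")


class TestHaplotypes:
    def test_constructed_effect_is_detected(self):
        c = simulate_study_cohort(seed=5, n_markers=300)
        pair = list(c["arch"].major_marker_ids[:2])
        table, tests = haplotype_analysis(c["geno"], pair, c["means_by_season"]["S15"])
        assert table["n"].sum() <= c["geno"].n_lines
        assert tests["significant"].any()

    def test_null_effect_rarely_significant(self, small_population):
        rng = np.random.default_rng(0)
        n_sig = 0
        trials = 40
        for s in range(trials):
            y = pd.Series(rng.normal(size=small_population.n_lines),
                          index=small_population.line_ids)
            try:
                _, tests = haplotype_analysis(
                    small_population, ["M00001", "M00002"], y
                )
            except ValueError:
                continue
            n_sig += tests["significant"].any()
        assert n_sig <= 0.15 * trials

    def test_class_bookkeeping_excludes_heterozygotes(self, small_population):
        y = pd.Series(np.arange(small_population.n_lines, dtype=float),
                      index=small_population.line_ids)
        table, _ = haplotype_analysis(small_population, ["M00001", "M00002"], y)
        dos = small_population.subset(markers=["M00001", "M00002"]).dosages
        n_hom = int((np.isin(dos[:, 0], (0, 2)) & np.isin(dos[:, 1], (0, 2))).sum())
        assert table["n"].sum() == n_hom
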