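"""Stratified CV, accuracy scaling, model comparison, subsets, distances."""

import numpy as np
import pandas as pd
import pytest

from nampred import (
    CVResult,
    MarkerEffects,
    RRBLUP,
    SubsetSpec,
    compare_models,
    distance_matrix_comparison,
    effect_correlation_matrix,
    fit_rrblup,
    prediction_accuracy,
    reduction_experiment,
    run_cross_validation,
    stratified_partition,
    subset_predictors,
    trait_metabolite_correlations,
)


class TestStratifiedPartition:
    def test_even_split_within_families(self):
        families = np.repeat([f"F{i}" for i in range(25)], 10)
        folds = stratified_partition(families, n_folds=5, seed=1)
        for fam in np.unique(families):
            counts = np.bincount(folds[families == fam], minlength=5)
            assert (counts == 2).all()
        assert np.bincount(folds).tolist() == [50] * 5

    def test_partition_covers_all_lines_disjointly(self):
        rng = np.random.default_rng(2)
        families = rng.choice(["A", "B", "C"], size=47)
        folds = stratified_partition(families, n_folds=5, seed=3)
        assert folds.min() >= 0 and folds.max() < 5
        assert len(folds) == 47  # every line assigned exactly once

    def test_deterministic_given_seed(self):
        families = np.repeat(["A", "B"], 20)
        a = stratified_partition(families, seed=9)
        b = stratified_partition(families, seed=9)
        c = stratified_partition(families, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_small_family_spreads_over_distinct_folds(self):
        families = np.array(["A"] * 3 + ["B"] * 10)
        folds = stratified_partition(families, n_folds=5, seed=0)
        assert len(set(folds[:3])) == 3


class TestRunCrossValidation:
    def test_records_requested_number_of_runs(self, nam):
        geno = nam["geno"]
        rng = np.random.default_rng(1)
        y = rng.normal(size=geno.n_lines)
        res = run_cross_validation(
            y, geno.dosage[:, :50], geno.family_ids, RRBLUP(lam=10.0),
            n_runs=100, seed=4,
        )
        assert len(res.per_run_ability) == 100

    def test_pure_noise_has_no_ability(self, nam):
        geno = nam["geno"]
        rng = np.random.default_rng(5)
        y = rng.normal(size=geno.n_lines)
        res = run_cross_validation(
            y, geno.dosage, geno.family_ids, RRBLUP(lam=50.0), n_runs=50, seed=6
        )
        assert abs(res.r_ab) < 0.1

    def test_heritable_trait_predicted_well(self, nam):
        from nampred import broad_sense_heritability, compute_blues, estimate_variance_components
        from nampred import rrblup_lambda

        geno, phen = nam["geno"], nam["phen"]
        vc = estimate_variance_components(phen, "TRAIT")
        h2 = broad_sense_heritability(vc)
        blues = compute_blues(phen, "TRAIT", h2=h2)
        lam = rrblup_lambda(vc.v_g, vc.v_r, geno.n_markers, vc.n_years)
        res = run_cross_validation(
            blues, geno.dosage, geno.family_ids, RRBLUP(lam=lam), n_runs=50, seed=7
        )
        assert 0.6 < res.r_ab <= 1.0
        # ability bounded by the accuracy of the BLUEs themselves
        assert res.r_ab < np.sqrt(h2) + 0.1

    def test_shuffled_targets_leak_nothing(self, nam):
        """Permuting the response destroys held-out ability, showing test
        lines never influence the training fit."""
        geno, phen = nam["geno"], nam["phen"]
        from nampred import compute_blues

        blues = compute_blues(phen, "TRAIT")
        rng = np.random.default_rng(8)
        y_perm = rng.permutation(blues.values.to_numpy())
        res = run_cross_validation(
            y_perm, geno.dosage, geno.family_ids, RRBLUP(lam=100.0), n_runs=30, seed=9
        )
        assert abs(res.r_ab) < 0.1


class TestPredictionAccuracy:
    @pytest.mark.parametrize(
        "r_ab, h2, expected",
        [(0.93, 0.91, 0.97), (0.86, 0.83, 0.94), (0.77, 0.58, 1.01)],
    )
    def test_published_style_worked_examples(self, r_ab, h2, expected):
        assert round(prediction_accuracy(r_ab, h2), 2) == expected

    def test_identity_at_full_heritability(self):
        assert prediction_accuracy(0.42, 1.0) == pytest.approx(0.42)

    @pytest.mark.parametrize("h2", [0.0, -0.5, 1.5])
    def test_invalid_heritability_rejected(self, h2):
        with pytest.raises(ValueError):
            prediction_accuracy(0.5, h2)


def _cv_result(values, tag="m", key=None):
    return CVResult(
        per_run_ability=np.asarray(values), model_tag=tag, predictor_set_tag="snp",
        trait="T", h2=1.0, partition_key=key,
    )


class TestCompareModels:
    def test_identical_results_not_significant(self):
        rng = np.random.default_rng(10)
        vals = rng.normal(0.8, 0.03, 100).clip(-1, 1)
        t, p, sig = compare_models(_cv_result(vals), _cv_result(vals))
        assert p == pytest.approx(1.0)
        assert not sig

    def test_true_gap_detected(self):
        rng = np.random.default_rng(11)
        a = _cv_result(rng.normal(0.80, 0.03, 100).clip(-1, 1))
        b = _cv_result(rng.normal(0.70, 0.03, 100).clip(-1, 1))
        t, p, sig = compare_models(a, b)
        assert sig and p < 1e-6 and t > 0

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        a = _cv_result(rng.normal(0.8, 0.05, 50).clip(-1, 1))
        b = _cv_result(rng.normal(0.75, 0.05, 50).clip(-1, 1))
        ta, pa, _ = compare_models(a, b)
        tb, pb, _ = compare_models(b, a)
        assert ta == pytest.approx(-tb) and pa == pytest.approx(pb)

    def test_paired_mode_used_for_shared_partitions(self):
        rng = np.random.default_rng(13)
        base = rng.normal(0.8, 0.05, 60).clip(-1, 0.99)
        a = _cv_result(base, key=("s", 5, 60, 100))
        shift = 0.005 + rng.normal(0, 0.001, 60)
        b = _cv_result((base + shift).clip(-1, 1), key=("s", 5, 60, 100))
        # paired test sees the constant shift despite large between-run spread
        _, p_paired, _ = compare_models(a, b)
        _, p_welch, _ = compare_models(a, b, paired=False)
        assert p_paired < p_welch

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_models(_cv_result(np.full(10, 0.5)), _cv_result(np.full(10, 0.5)))


class TestSubsetPredictors:
    def _effects(self, g):
        return MarkerEffects(
            mu=0.0, g=np.asarray(g, dtype=float), model_tag="bayes_b",
            coding_tag="dosage_012",
            predictor_ids=np.arange(len(g)).astype(object),
        )

    def test_quarter_of_paper_scale_marker_set(self):
        e = self._effects(np.random.default_rng(0).normal(size=33005))
        idx = subset_predictors(e, SubsetSpec(fraction=0.25, mode="best"))
        assert len(idx) == 8251

    def test_full_fraction_is_identity(self):
        e = self._effects([0.1, -0.2, 0.3])
        idx = subset_predictors(e, SubsetSpec(fraction=1.0, mode="best"))
        assert np.array_equal(idx, [0, 1, 2])

    def test_best_mode_keeps_largest_effect(self):
        e = self._effects([0.1, -5.0, 0.3, 0.2])
        idx = subset_predictors(e, SubsetSpec(fraction=0.5, mode="best"))
        assert 1 in idx

    def test_random_mode_seeded_and_sized(self):
        e = self._effects(np.arange(100.0))
        a = subset_predictors(e, SubsetSpec(fraction=0.1, mode="random", seed=5))
        b = subset_predictors(e, SubsetSpec(fraction=0.1, mode="random", seed=5))
        assert len(a) == 10 and np.array_equal(a, b)

    def test_empty_selection_rejected(self):
        e = self._effects([0.1, 0.2])
        with pytest.raises(ValueError):
            subset_predictors(e, SubsetSpec(fraction=0.1, mode="best"))


class TestReductionExperiment:
    def test_full_fraction_matches_baseline_within_mc_error(self, nam):
        geno = nam["geno"]
        gv = nam["truth"].genotypic_values
        rng = np.random.default_rng(14)
        y = gv + rng.normal(0, gv.std() * 0.3, size=len(gv))
        model = RRBLUP(lam=50.0)
        base = run_cross_validation(
            y, geno.dosage, geno.family_ids, model, n_runs=30, seed=15, h2=0.9
        )
        tab = reduction_experiment(
            y, geno.dosage, geno.family_ids, model, fractions=(1.0,), modes=("best",),
            seed=16, n_runs=30, h2=0.9,
        )
        assert tab.loc[0, "r_ab"] == pytest.approx(base.r_ab, abs=2 * base.sd)

    def test_best_subset_beats_random_on_sparse_trait(self, nam):
        geno = nam["geno"]
        gv = nam["truth"].genotypic_values  # 50 QTL among 560 markers
        rng = np.random.default_rng(17)
        y = gv + rng.normal(0, gv.std() * 0.3, size=len(gv))
        model = RRBLUP(lam=50.0)
        tab = reduction_experiment(
            y, geno.dosage, geno.family_ids, model, fractions=(0.1,),
            modes=("best", "random"), seed=18, n_runs=20, h2=0.9,
        )
        best = tab[tab["mode"] == "best"]["r_ab"].iloc[0]
        rand = tab[tab["mode"] == "random"]["r_ab"].iloc[0]
        assert best >= rand


class TestCorrelationAnalyses:
    def test_metabolite_equal_to_trait_gives_unit_correlation(self):
        idx = pd.Index([f"L{i}" for i in range(20)], name="line_id")
        s = pd.Series(np.arange(20.0), index=idx)
        mets = pd.DataFrame({"m1": s, "m2": -s + 3})
        tab = trait_metabolite_correlations({"T": s}, mets)
        assert tab.loc["T", "m1"] == pytest.approx(1.0)
        assert tab.loc["T", "m2"] == pytest.approx(-1.0)

    def test_null_correlations_concentrate_near_zero(self):
        rng = np.random.default_rng(19)
        idx = pd.Index([f"L{i}" for i in range(1300)], name="line_id")
        s = pd.Series(rng.normal(size=1300), index=idx)
        mets = pd.DataFrame(rng.normal(size=(1300, 100)), index=idx,
                            columns=[f"m{j}" for j in range(100)])
        tab = trait_metabolite_correlations({"T": s}, mets)
        assert (tab.abs() < 0.1).to_numpy().mean() >= 0.99

    def test_too_few_shared_lines_rejected(self):
        idx = pd.Index(["L1", "L2"], name="line_id")
        s = pd.Series([1.0, 2.0], index=idx)
        with pytest.raises(ValueError):
            trait_metabolite_correlations({"T": s}, pd.DataFrame({"m": s}))


class TestEffectCorrelations:
    def test_shared_architecture_yields_correlated_effects(self, nam):
        geno = nam["geno"]
        gv = nam["truth"].genotypic_values
        rng = np.random.default_rng(20)
        y1 = gv + rng.normal(0, 0.3 * gv.std(), len(gv))
        y2 = gv + rng.normal(0, 0.3 * gv.std(), len(gv))
        y3 = rng.permutation(gv)  # unrelated architecture
        effects = {
            "A": fit_rrblup(y1, geno.dosage, 50.0),
            "B": fit_rrblup(y2, geno.dosage, 50.0),
            "C": fit_rrblup(y3, geno.dosage, 50.0),
        }
        C = effect_correlation_matrix(effects)
        assert np.allclose(np.diag(C), 1.0)
        assert C.loc["A", "B"] > 0.8
        assert abs(C.loc["A", "C"]) < 0.3

    def test_mismatched_predictors_rejected(self):
        rng = np.random.default_rng(21)
        e1 = fit_rrblup(rng.normal(size=10), rng.normal(size=(10, 4)), 1.0,
                        predictor_ids=list("abcd"))
        e2 = fit_rrblup(rng.normal(size=10), rng.normal(size=(10, 4)), 1.0,
                        predictor_ids=list("abce"))
        with pytest.raises(ValueError):
            effect_correlation_matrix({"A": e1, "B": e2})


class TestDistanceMatrices:
    def test_identical_matrices_fully_correlated(self):
        rng = np.random.default_rng(22)
        X = rng.normal(size=(30, 8))
        D1, D2, r = distance_matrix_comparison(X, X)
        assert r == pytest.approx(1.0)
        assert np.allclose(D1, D1.T) and np.allclose(np.diag(D1), 0.0)

    def test_independent_matrices_uncorrelated(self):
        rng = np.random.default_rng(23)
        _, _, r = distance_matrix_comparison(
            rng.normal(size=(200, 40)), rng.normal(size=(200, 25))
        )
        assert abs(r) < 0.1

    def test_too_few_lines_rejected(self):
        with pytest.raises(ValueError):
            distance_matrix_comparison(np.zeros((2, 3)), np.zeros((2, 3)))
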