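import itertools

import numpy as np
import pytest

import fabrynet as fn
from fabrynet.errors import ConfigError, EmptyScreenError, FoldError, ValidationError
from fabrynet.screen import (
    FEATURE_METHODS,
    _candidate_cuts,
    fit_threshold_1d,
    predict_threshold,
)
from fabrynet.synthetic import plant_solution_matrix


def make_ensemble(matrix, names=None):
    matrix = np.asarray(matrix, dtype=float)
    names = names or [f"V{j}" for j in range(matrix.shape[1])]
    return fn.SolutionEnsemble(protein_index=names, matrix=matrix)


class TestCleanVariables:
    def test_constant_column_dropped(self):
        ens = make_ensemble([[0.0, 0.5], [0.0, -0.5], [0.0, 0.1], [0.0, 0.2]])
        assert fn.clean_variables(ens, [0, 0, 1, 1]) == ["V1"]

    def test_duplicate_informative_columns_both_kept(self):
        col = [0.1, 0.9, 0.2, 0.8]
        ens = make_ensemble(np.column_stack([col, col]))
        assert fn.clean_variables(ens, [0, 1, 0, 1]) == ["V0", "V1"]

    def test_planted_constant_columns_removed_exactly(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(-1, 1, size=(30, 100))
        m[:, :5] = 0.7  # five constant columns
        ens = make_ensemble(m)
        kept = fn.clean_variables(ens, [0] * 15 + [1] * 15)
        assert len(kept) == 95 and "V0" not in kept

    def test_all_dropped_raises(self):
        ens = make_ensemble(np.zeros((4, 3)))
        with pytest.raises(EmptyScreenError):
            fn.clean_variables(ens, [0, 0, 1, 1])

    def test_single_label_group_rejected(self):
        ens = make_ensemble([[0.1], [0.2]])
        with pytest.raises(ValidationError):
            fn.clean_variables(ens, [1, 1])


def brute_force_best_accuracy(x, y, mode):
    """Independent oracle: nested-loop search over the same cut grid."""
    cuts = _candidate_cuts(np.sort(np.asarray(x, dtype=float)))
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    best = 0.0
    if mode == "linear":
        for c in cuts:
            for predict_above in (True, False):
                pred = (x >= c) if predict_above else (x < c)
                best = max(best, float((pred.astype(int) == y).mean()))
    else:
        for a, b in itertools.combinations(cuts, 2):
            inside = (x >= a) & (x <= b)
            for inside_is_one in (True, False):
                pred = inside if inside_is_one else ~inside
                best = max(best, float((pred.astype(int) == y).mean()))
    return best


class TestThreshold1D:
    def test_simple_midpoint_cut(self):
        params, acc = fit_threshold_1d([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], "linear")
        assert params == {"cut": 0.5, "direction": 1} and acc == 1.0

    def test_flipped_orientation(self):
        params, acc = fit_threshold_1d([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0], "linear")
        assert params["direction"] == -1 and acc == 1.0

    def test_nested_pattern_quadratic_dominates(self):
        x = [0.0, 0.1, 0.45, 0.5, 0.55, 0.9, 1.0]
        y = [0, 0, 1, 1, 1, 0, 0]
        _, acc_lin = fit_threshold_1d(x, y, "linear")
        params, acc_quad = fit_threshold_1d(x, y, "quadratic")
        assert acc_quad == 1.0 > acc_lin
        assert np.array_equal(predict_threshold(params, x), y)

    @pytest.mark.parametrize("mode", ["linear", "quadratic"])
    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_oracle(self, seed, mode):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 51))
        x = rng.uniform(-1, 1, n)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        _, acc = fit_threshold_1d(x, y, mode)
        assert acc == pytest.approx(brute_force_best_accuracy(x, y, mode))

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_threshold_1d([0.1, 0.2], [1, 1], "linear")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            fit_threshold_1d([0.1, 0.9], [0, 1], "cubic")


class TestCrossValidate:
    def test_perfect_separation_scores_100(self):
        x = np.concatenate([np.linspace(-0.9, -0.5, 20), np.linspace(0.5, 0.9, 20)])
        y = np.array([0] * 20 + [1] * 20)
        ens = make_ensemble(x[:, None])
        r = fn.cross_validate("linear-threshold", ("V0",), ens, y, k=10, seed=0)
        assert r.cv_accuracy == 100.0
        assert r.cv_pvalue < 1e-4

    def test_accuracy_is_exact_mean_of_folds(self, ):
        ps = plant_solution_matrix(60, 5, 1, 1.0, 0.4, seed=2)
        r = fn.cross_validate(
            "linear-threshold", (ps.informative[0],), ps.ensemble, ps.labels, seed=1
        )
        assert r.cv_accuracy == pytest.approx(np.mean(r.fold_accuracies))
        assert 0 < r.cv_pvalue <= 1

    def test_identical_fold_data_averages_to_same_threshold(self):
        # 10 copies of each of four values: every training split contains all
        # distinct values, so every fold fits the same cut and the average
        # equals it
        x = np.array([0.1] * 10 + [0.2] * 10 + [0.8] * 10 + [0.9] * 10)
        y = (x > 0.5).astype(int)
        ens = make_ensemble(x[:, None])
        r = fn.cross_validate("linear-threshold", ("V0",), ens, y, k=10, seed=3)
        assert r.final_params["cut"] == pytest.approx(0.5)

    @pytest.mark.parametrize("family", ["glm-binomial", "naive-bayes", "mlp"])
    def test_two_variable_families_fit_separable_pairs(self, family):
        ps = plant_solution_matrix(60, 4, 2, 6.0, 0.1, seed=4)
        pair = tuple(ps.informative[:2])
        r = fn.cross_validate(family, pair, ps.ensemble, ps.labels, k=5, seed=0)
        assert r.cv_accuracy >= 90.0
        assert r.spec.family == family

    def test_too_many_folds_rejected(self):
        ens = make_ensemble(np.random.default_rng(0).uniform(-1, 1, (8, 1)))
        with pytest.raises(FoldError):
            fn.cross_validate("linear-threshold", ("V0",), ens, [0, 0, 0, 0, 1, 1, 1, 1], k=10)

    def test_one_variable_spec_requires_threshold_family(self):
        with pytest.raises(ValidationError):
            fn.ClassifierSpec(variables=("A",), family="glm-binomial")


class TestFeatureSelection:
    def test_single_method_topk2_gives_both_orderings(self):
        ps = plant_solution_matrix(60, 6, 2, 4.0, 0.2, seed=5)
        pairs = fn.select_feature_pairs(
            ps.ensemble, ps.labels, methods=("mrmr",), top_k=2, seed=0
        )
        assert len(pairs) == 2
        assert pairs[0] == tuple(reversed(pairs[1]))

    def test_unknown_method_rejected(self):
        ps = plant_solution_matrix(20, 4, 1, 2.0, 0.3, seed=6)
        with pytest.raises(ConfigError):
            fn.select_feature_pairs(ps.ensemble, ps.labels, methods=("pca",))

    @pytest.mark.parametrize("method", FEATURE_METHODS)
    def test_every_method_finds_strong_planted_variables(self, method):
        hits = 0
        for seed in range(10):
            ps = plant_solution_matrix(100, 20, 2, 3.0, 0.3, seed=700 + seed)
            pairs = fn.select_feature_pairs(
                ps.ensemble, ps.labels, methods=(method,), top_k=5, seed=seed
            )
            chosen = {p for pair in pairs for p in pair}
            hits += all(p in chosen for p in ps.informative)
        assert hits >= 9

    def test_empty_methods_fall_back_to_single_variables(self):
        ps = plant_solution_matrix(40, 5, 1, 2.0, 0.3, seed=8)
        out = fn.screen_all(ps.ensemble, ps.labels, fn.ScreenConfig(methods=(), seed=0))
        assert all(len(r.spec.variables) == 1 for r in out.results)


class TestScreenAll:
    def test_pair_universe_arithmetic(self):
        assert fn.pair_universe(3) == 6
        ps = plant_solution_matrix(30, 3, 1, 2.0, 0.3, seed=9)
        out = fn.screen_all(ps.ensemble, ps.labels, fn.ScreenConfig(methods=(), seed=0))
        assert out.pair_universe == 6

    def test_ordering_is_stable_total_order(self):
        ps = plant_solution_matrix(60, 10, 2, 1.5, 0.4, seed=10)
        cfg = fn.ScreenConfig(methods=("mrmr",), top_k=3,
                              families=("glm-binomial",), seed=4)
        a = fn.screen_all(ps.ensemble, ps.labels, cfg)
        b = fn.screen_all(ps.ensemble, ps.labels, cfg)
        assert [r.spec for r in a.results] == [r.spec for r in b.results]
        keys = [(-r.cv_accuracy, r.cv_pvalue, r.spec.variables) for r in a.results]
        assert keys == sorted(keys)

    def test_exhaustive_pairs_evaluates_full_universe(self):
        ps = plant_solution_matrix(40, 4, 1, 2.0, 0.3, seed=11)
        cfg = fn.ScreenConfig(
            methods=(), exhaustive_pairs=True, families=("naive-bayes",), seed=0
        )
        out = fn.screen_all(ps.ensemble, ps.labels, cfg)
        assert out.n_pairs_evaluated == fn.pair_universe(4) == 12

    def test_results_frame_columns(self):
        ps = plant_solution_matrix(30, 3, 1, 2.0, 0.3, seed=12)
        out = fn.screen_all(ps.ensemble, ps.labels, fn.ScreenConfig(methods=(), seed=0))
        df = out.to_frame()
        assert list(df.columns) == [
            "rank", "variables", "family", "cv_accuracy", "cv_pvalue",
            "final_params_json",
        ]
        assert (df["rank"] == np.arange(1, len(df) + 1)).all()
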