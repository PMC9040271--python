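"""Thresholding, splitting, logistic fitting, selection and metrics."""

import numpy as np
import pytest
from scipy.special import expit

from markstate import (
    ExpressionTable,
    GeneStateLogit,
    binarise,
    evaluate,
    fit_logistic,
    median_threshold,
    run_experiment,
    select_hyperparameters,
    split_dataset,
    valley_threshold,
)
from markstate.model import SeparationError
from conftest import brute_force_auroc


class TestThresholds:
    @pytest.mark.parametrize("values,expected", [
        ([0, 1, 2], 1.0),
        ([0, 1, 2, 3], 1.5),
        ([5, 5, 5, 5], 5.0),
    ])
    def test_median_matches_order_statistics(self, values, expected):
        expr = ExpressionTable({f"g{i}": v for i, v in enumerate(values)})
        assert median_threshold(expr) == expected

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            median_threshold(ExpressionTable())

    def test_all_equal_labels_everything_off(self):
        expr = ExpressionTable({f"g{i}": 2.0 for i in range(10)})
        labels = binarise(expr, median_threshold(expr))
        assert not labels.T.any()

    def test_valley_recovers_planted_gap(self):
        rng = np.random.default_rng(3)
        low = rng.exponential(0.2, 600)
        high = rng.lognormal(np.log(100), 0.5, 600)
        expr = ExpressionTable({f"g{i}": v for i, v in enumerate(np.r_[low, high])})
        t_bar = valley_threshold(expr)
        # strictly between the modes: above essentially all low mass,
        # below essentially all high mass
        assert np.quantile(low, 0.99) < t_bar < np.quantile(high, 0.01)

    def test_valley_falls_back_to_median_when_unimodal(self, caplog):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(1.0, 0.3, 500)
        expr = ExpressionTable({f"g{i}": v for i, v in enumerate(vals)})
        with caplog.at_level("WARNING"):
            t_bar = valley_threshold(expr)
        assert t_bar == median_threshold(expr)
        assert any("median" in r.message for r in caplog.records)


class TestBinarise:
    def test_rule_applied_exactly(self):
        expr = ExpressionTable({"a": 0.0, "b": 1.0, "c": 2.0, "d": 3.0})
        labels = binarise(expr, 1.5)
        assert labels.T.tolist() == [0, 0, 1, 1]

    def test_tie_at_threshold_goes_off(self):
        expr = ExpressionTable({"a": 1.5, "b": 1.6})
        assert binarise(expr, 1.5).T.tolist() == [0, 1]

    def test_zero_threshold_keeps_only_zero_genes_off(self):
        expr = ExpressionTable({"a": 0.0, "b": 0.0, "c": 0.1})
        assert binarise(expr, 0.0).T.tolist() == [0, 0, 1]

    def test_median_rule_balances_classes_without_ties(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0.01, 50, 501)
        expr = ExpressionTable({f"g{i}": v for i, v in enumerate(vals)})
        labels = binarise(expr, median_threshold(expr), rule="median")
        n_off, n_on = (labels.T == 0).sum(), (labels.T == 1).sum()
        assert abs(n_off - n_on) <= 1
        assert n_off >= len(vals) / 2

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            binarise(ExpressionTable({"a": 1.0}), -0.1)


class TestSplitDataset:
    def test_study_scale_split_arithmetic(self):
        split = split_dataset(19_802, seed=0)
        assert split.sizes == (6601, 6601, 6600)

    @pytest.mark.parametrize("n,expected", [(3, (1, 1, 1)), (4, (2, 1, 1)),
                                            (5, (2, 2, 1)), (10, (4, 3, 3))])
    def test_ceil_balanced_thirds(self, n, expected):
        assert split_dataset(n, seed=1).sizes == expected

    def test_disjoint_and_exhaustive(self):
        split = split_dataset(100, seed=5)
        pooled = np.concatenate([split.train_idx, split.val_idx, split.test_idx])
        assert sorted(pooled) == list(range(100))

    def test_deterministic_in_seed(self):
        a, b = split_dataset(50, seed=9), split_dataset(50, seed=9)
        c = split_dataset(50, seed=10)
        assert np.array_equal(a.train_idx, b.train_idx)
        assert not np.array_equal(a.train_idx, c.train_idx)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(2, seed=0)


class TestFitLogistic:
    def test_separable_one_dimensional_toy(self):
        Phi = np.r_[np.zeros(20), np.full(20, 10.0)].reshape(-1, 1)
        T = np.r_[np.zeros(20, int), np.ones(20, int)]
        res = fit_logistic(Phi, T)
        assert res.w[0] > 0
        scores = res.predict(Phi)
        assert brute_force_auroc(scores, T) == 1.0

    def test_parameter_recovery_within_three_se(self):
        rng = np.random.default_rng(12)
        n = 5000
        Phi = rng.lognormal(0.5, 0.6, (n, 2))
        truth = np.array([-1.0, 0.8, -0.5])  # b, w1, w2
        T = (rng.random(n) < expit(truth[0] + Phi @ truth[1:])).astype(int)
        res = fit_logistic(Phi, T)
        err = np.abs(res.params - truth)
        assert (err <= 3 * res.bse).all()

    def test_dimensional_contract(self, fitted):
        assert len(fitted.w) == 5 and np.isscalar(fitted.b)
        assert len(fitted.params) == 6

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            GeneStateLogit(np.ones((10, 2)), np.zeros(10, int))

    def test_separation_flagged_and_inference_refused(self):
        Phi = np.r_[np.zeros(10), np.full(10, 10.0)].reshape(-1, 1)
        T = np.r_[np.zeros(10, int), np.ones(10, int)]
        res = GeneStateLogit(Phi, T).fit()
        assert res.separation
        with pytest.raises(SeparationError):
            _ = res.zvalues

    def test_gene_order_permutation_leaves_fit_unchanged(self, small_features, small_labels):
        Phi, T = small_features.Phi, small_labels.T
        res1 = fit_logistic(Phi, T)
        perm = np.random.default_rng(3).permutation(len(T))
        res2 = fit_logistic(Phi[perm], T[perm])
        assert np.allclose(res1.params, res2.params, rtol=1e-6)
        m1 = evaluate(res1, Phi, T)
        m2 = evaluate(res2, Phi[perm], T[perm])
        assert m1["auroc"] == pytest.approx(m2["auroc"], abs=1e-12)

    def test_summary_mentions_each_mark(self, fitted):
        text = fitted.summary()
        for mark in fitted.marks:
            assert mark in text


class TestEvaluate:
    def _results_with_identity_scores(self, scores):
        """A 1-feature model whose predicted probability is monotone in the
        feature, so ranking metrics see the raw scores."""
        Phi = np.asarray(scores, dtype=float).reshape(-1, 1)
        from markstate.model import GeneStateResults, GeneStateLogit

        model = GeneStateLogit(np.array([[0.0], [1.0], [2.0], [3.0]]),
                               np.array([0, 0, 1, 1]))
        return GeneStateResults(model=model, w=np.array([1.0]), b=0.0,
                                se=np.array([1.0]), se_b=1.0), Phi

    def test_perfect_ordering_gives_auroc_one(self):
        res, Phi = self._results_with_identity_scores([1, 2, 3, 4])
        assert evaluate(res, Phi, np.array([0, 0, 1, 1]))["auroc"] == 1.0

    def test_constant_scores_give_half_by_midranks(self):
        res, Phi = self._results_with_identity_scores([2, 2, 2, 2])
        assert evaluate(res, Phi, np.array([0, 1, 0, 1]))["auroc"] == 0.5

    def test_handcrafted_six_gene_concordance(self):
        scores = np.array([0.9, 0.1, 0.5, 0.5, 0.7, 0.2])
        labels = np.array([1, 0, 1, 0, 0, 1])
        res, Phi = self._results_with_identity_scores(scores)
        got = evaluate(res, Phi, labels)["auroc"]
        assert got == pytest.approx(brute_force_auroc(res.predict(Phi), labels))

    def test_matches_concordance_oracle_on_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            res, Phi = self._results_with_identity_scores(scores)
            got = evaluate(res, Phi, labels)["auroc"]
            assert got == pytest.approx(
                brute_force_auroc(res.predict(Phi), labels), abs=1e-12
            )

    def test_single_class_test_reports_missing(self, caplog):
        res, Phi = self._results_with_identity_scores([1, 2, 3])
        with caplog.at_level("WARNING"):
            out = evaluate(res, Phi, np.array([1, 1, 1]))
        assert np.isnan(out["auroc"]) and np.isnan(out["aupr"])
        assert np.isfinite(out["f1"])


class TestHyperparameterSelection:
    def _features(self, informative, n=400, seed=0, marks=("h1",)):
        """One informative dialect, others pure noise, for each mark."""
        rng = np.random.default_rng(seed)
        T = rng.integers(0, 2, n)
        features = {}
        for m in marks:
            features[m] = {}
            for d in ("narrow", "broad", "gapped"):
                if d == informative:
                    col = T * rng.lognormal(1.0, 0.3, n) + rng.lognormal(0, 0.3, n) * 0.3
                else:
                    col = rng.lognormal(0.5, 0.5, n)
                features[m][d] = col
        return features, T

    def test_single_candidate_returned_without_search(self):
        features, T = self._features("narrow")
        features = {"h1": {"narrow": features["h1"]["narrow"]}}
        split = split_dataset(len(T), seed=1)
        H, _, _, n_eval = select_hyperparameters(features, T, split.train_idx, split.val_idx)
        assert H == {"h1": "narrow"} and n_eval == 1

    @pytest.mark.parametrize("informative", ["narrow", "broad", "gapped"])
    def test_planted_informative_dialect_selected(self, informative):
        features, T = self._features(informative, seed=5)
        split = split_dataset(len(T), seed=2)
        H, res, val_auroc, _ = select_hyperparameters(
            features, T, split.train_idx, split.val_idx
        )
        assert H == {"h1": informative}
        assert val_auroc > 0.8
        assert res.hyperparameters == H

    def test_exhaustive_mode_enumerates_the_product(self):
        features, T = self._features("narrow", n=150, marks=[f"h{i}" for i in range(3)])
        split = split_dataset(len(T), seed=3)
        _, _, _, n_eval = select_hyperparameters(
            features, T, split.train_idx, split.val_idx
        )
        assert n_eval == 3 ** 3

    def test_greedy_mode_agrees_on_planted_signal(self):
        features, T = self._features("gapped", seed=6)
        split = split_dataset(len(T), seed=4)
        H, _, _, n_eval = select_hyperparameters(
            features, T, split.train_idx, split.val_idx, search="greedy"
        )
        assert H == {"h1": "gapped"} and n_eval <= 3

    def test_missing_candidates_rejected(self):
        with pytest.raises(ValueError, match="candidate"):
            select_hyperparameters({"h1": {}}, np.array([0, 1]), np.array([0]), np.array([1]))

    def test_selection_never_beaten_by_another_candidate(self):
        features, T = self._features("broad", seed=9)
        split = split_dataset(len(T), seed=7)
        H, _, best, _ = select_hyperparameters(features, T, split.train_idx, split.val_idx)
        from markstate.pipeline import _assemble, _fit_and_score

        for d in ("narrow", "broad", "gapped"):
            _, auroc = _fit_and_score(
                _assemble(features, {"h1": d}, ["h1"]), T, ["h1"],
                split.train_idx, split.val_idx,
            )
            assert auroc <= best + 1e-12


class TestRunExperiment:
    def test_reports_k_splits_with_mean_and_sd(self, small_features, small_labels):
        report = run_experiment(small_features, small_labels.T, k=3, seed=21)
        assert report.k == 3
        aurocs = report.metric("auroc")
        assert ((0 <= aurocs) & (aurocs <= 1)).all()
        assert min(aurocs) <= report.mean("auroc") <= max(aurocs)
        assert report.sd("auroc") >= 0

    def test_k_one_reports_zero_sd(self, small_features, small_labels):
        report = run_experiment(small_features, small_labels.T, k=1, seed=2)
        assert report.sd("auroc") == 0.0

    def test_reproducible_from_master_seed(self, small_features, small_labels):
        r1 = run_experiment(small_features, small_labels.T, k=2, seed=5)
        r2 = run_experiment(small_features, small_labels.T, k=2, seed=5)
        assert r1.metric("auroc").tolist() == r2.metric("auroc").tolist()

    def test_label_permutation_destroys_signal(self, small_features, small_labels):
        rng = np.random.default_rng(0)
        permuted = rng.permutation(small_labels.T)
        report = run_experiment(small_features, permuted, k=5, seed=13)
        assert abs(report.mean("auroc") - 0.5) < 0.06

    def test_tuned_mode_selects_per_split(self, small_dataset, small_labels):
        features = small_dataset.feature_candidates()
        report = run_experiment(features, small_labels.T, k=2, seed=3,
                                marks=list(small_dataset.spec.marks), search="greedy")
        for s in report.splits:
            assert set(s["hyperparameters"]) == set(small_dataset.spec.marks)
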