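import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from ocmetab import (SampleMatrix, autoscale, fit_metabolic_model,
                     loocv_evaluate, metabolic_score, rfe,
                     select_optimal_panel, simulate_run_table,
                     train_linear_svm, curate)
from ocmetab.curation import CurationParams
from ocmetab.svm import RfeStep, RfeTrace, Scaling, SvmModel

from conftest import noise_matrix, separable_matrix, small_config


def _matrix(X, labels) -> SampleMatrix:
    X = np.asarray(X, dtype=float)
    ids = [f"S{i + 1}" for i in range(len(X))]
    return SampleMatrix(
        pd.DataFrame(X, index=ids,
                     columns=[f"f{j + 1}" for j in range(X.shape[1])]),
        pd.Series(list(labels), index=ids))


class TestAutoscale:
    def test_forced_arithmetic(self):
        m = _matrix([[1.0], [2.0], [3.0]], "CCN")
        out, scaling = autoscale(m)
        assert out.data["f1"].tolist() == [-1.0, 0.0, 1.0]
        assert scaling.mean[0] == 2.0 and scaling.sd[0] == 1.0

    def test_idempotent(self):
        m = separable_matrix()
        once, _ = autoscale(m)
        twice, _ = autoscale(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_constant_column_named(self):
        m = _matrix([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]], "CCN")
        with pytest.raises(ValueError, match="f2"):
            autoscale(m)


class TestTrainLinearSvm:
    def test_analytic_max_margin(self):
        # 1-D points at -1 (N) and +1 (C): the max-margin separator is
        # w = 1, b = 0 (margin boundaries through the points)
        m = _matrix([[1.0], [-1.0]], "CN")
        model = train_linear_svm(m, cost=1e6)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)

    def test_margin_constraints_on_separable_data(self):
        m = separable_matrix(gap=4.0, noise=0.2, seed=3)
        model = train_linear_svm(m, cost=1e6)
        margins = m.y * (m.X @ model.w + model.b)
        assert (margins >= 1.0 - 1e-6).all()

    def test_invariant_to_duplication(self):
        m = separable_matrix(seed=5)
        dup = SampleMatrix(
            pd.concat([m.data, m.data.set_axis([f"{i}b" for i in m.data.index])]),
            pd.concat([m.classes, m.classes.set_axis([f"{i}b" for i in m.data.index])]))
        a = train_linear_svm(m, cost=1e4)
        b = train_linear_svm(dup, cost=1e4)
        assert np.allclose(a.w, b.w, atol=1e-6)
        assert a.b == pytest.approx(b.b, abs=1e-6)

    def test_label_flip_antisymmetry(self):
        m = separable_matrix(seed=7)
        flipped = SampleMatrix(m.data.copy(),
                               m.classes.map({"C": "N", "N": "C"}))
        a = train_linear_svm(m)
        b = train_linear_svm(flipped)
        assert np.allclose(a.w, -b.w, atol=1e-8)
        assert a.b == pytest.approx(-b.b, abs=1e-8)

    def test_single_class_rejected(self):
        m = _matrix([[1.0], [2.0]], "CC")
        with pytest.raises(ValueError, match="single class"):
            train_linear_svm(m)


class TestMetabolicScore:
    def _model(self, w, b):
        ids = [f"f{i + 1}" for i in range(len(w))]
        return SvmModel(np.asarray(w, float), b, ids, Scaling.identity(ids), 1.0)

    def test_forced_arithmetic_and_sign_convention(self):
        score, cls = metabolic_score(self._model([1.0, -1.0], 0.0),
                                     np.array([2.0, 1.0]))
        assert score == pytest.approx(1.0)
        assert cls == "C"  # positive score = cancer

    def test_hyperplane_tie_classified_N_with_warning(self):
        with pytest.warns(UserWarning, match="hyperplane"):
            score, cls = metabolic_score(self._model([1.0], 0.0),
                                         np.array([0.0]))
        assert score == 0.0 and cls == "N"

    def test_score_flips_with_training_labels(self):
        m = separable_matrix(seed=2)
        flipped = SampleMatrix(m.data.copy(),
                               m.classes.map({"C": "N", "N": "C"}))
        a = fit_metabolic_model(m)
        b = fit_metabolic_model(flipped)
        x = m.data.iloc[0].to_numpy()
        # antisymmetry holds to solver tolerance
        assert metabolic_score(a, x)[0] == pytest.approx(
            -metabolic_score(b, x)[0], abs=2e-3)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="features"):
            metabolic_score(self._model([1.0, 2.0], 0.0), np.array([1.0]))


class TestLoocv:
    def test_separable_data_is_perfect(self):
        # a single informative feature, classes separated far beyond spread;
        # large cost keeps the 1-vs-2 training folds in the max-margin regime
        res = loocv_evaluate(separable_matrix(n_per_class=2, n_features=1,
                                              gap=10.0, noise=0.1), cost=100.0)
        assert (res.accuracy, res.sensitivity, res.specificity) == (100.0,) * 3

    @pytest.mark.parametrize("scaling_mode", ["global", "per_fold"])
    def test_matches_fold_enumeration_oracle(self, scaling_mode):
        """LOOCV equals an explicit enumeration of all n train/test splits."""
        m = noise_matrix(n=8, n_features=4, seed=4)
        X, y = m.X, m.y
        correct = []
        for i in range(len(y)):  # brute-force oracle
            tr = np.ones(len(y), bool)
            tr[i] = False
            if scaling_mode == "global":
                mu, sd = X.mean(0), X.std(0, ddof=1)
            else:
                mu, sd = X[tr].mean(0), X[tr].std(0, ddof=1)
            svc = SVC(kernel="linear", C=1.0).fit((X[tr] - mu) / sd, y[tr])
            pred = svc.predict(((X[i] - mu) / sd)[None, :])[0]
            correct.append(pred == y[i])
        expected = 100.0 * np.mean(correct)
        res = loocv_evaluate(m, scaling_mode=scaling_mode)
        assert res.accuracy == pytest.approx(expected)

    def test_gram_fast_path_matches_direct_loocv(self):
        """The precomputed-kernel RFE inner loop reproduces the plain LOOCV
        metrics at the full feature set."""
        m = noise_matrix(n=10, n_features=6, seed=9)
        trace = rfe(m, scaling_mode="global")
        res = loocv_evaluate(m, scaling_mode="global")
        first = trace.steps[0]
        assert (first.accuracy, first.sensitivity, first.specificity) == \
            (res.accuracy, res.sensitivity, res.specificity)

    def test_random_labels_score_at_chance(self):
        """Isotropic noise with arbitrary labels: mean LOOCV accuracy sits at
        the 50% chance level over 200 simulations — never above it beyond
        Monte-Carlo error, and below it only by the small pessimistic LOOCV
        bias (the held-out sample's class is the training minority)."""
        accs = [loocv_evaluate(noise_matrix(n=40, n_features=5, seed=s)).accuracy
                for s in range(200)]
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert mean <= 50.0 + 4 * se
        assert mean >= 44.0

    def test_too_few_per_class(self):
        m = _matrix([[0.0], [1.0], [2.0]], "CNN")
        with pytest.raises(ValueError, match=">= 2 samples"):
            loocv_evaluate(m)


class TestRfe:
    def test_pure_noise_feature_eliminated_first(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 5 + [-1] * 5)
        X = np.column_stack([
            y + 0.05 * rng.normal(size=10),
            y + 0.05 * rng.normal(size=10),
            rng.normal(size=10),
        ])
        m = _matrix(X, ["C"] * 5 + ["N"] * 5)
        trace = rfe(m)
        assert trace.steps[0].eliminated == "f3"

    def test_trace_structure(self):
        m = noise_matrix(n=8, n_features=5, seed=1)
        trace = rfe(m)
        sizes = [len(s.feature_ids) for s in trace.steps]
        assert sizes == [5, 4, 3, 2, 1]
        for a, b in zip(trace.steps, trace.steps[1:]):
            assert a.eliminated in a.feature_ids
            assert a.eliminated not in b.feature_ids
            assert set(b.feature_ids) < set(a.feature_ids)
        assert trace.steps[-1].eliminated is None

    def test_metrics_invariant_to_feature_permutation(self):
        m = noise_matrix(n=10, n_features=4, seed=3)
        perm = SampleMatrix(m.data[["f3", "f1", "f4", "f2"]].copy(),
                            m.classes.copy())
        t1 = rfe(m)
        t2 = rfe(perm)
        for s1, s2 in zip(t1.steps, t2.steps):
            assert s1.accuracy == pytest.approx(s2.accuracy)

    def test_planted_panel_recovered_on_medium_emulation(self):
        """On a scaled-down study emulation large enough for the signal to
        dominate selection noise, the selected panel classifies perfectly and
        is drawn (almost) entirely from the planted features."""
        hits = 0
        for seed in range(5):
            cfg = small_config(seed=seed + 60, n_case=24, n_control=24,
                               n_features=60, planted_panel_size=6,
                               effect_size_range=(1.8, 2.5))
            table, truth = simulate_run_table(cfg)
            matrix, _ = curate(table, CurationParams(min_runs=10))
            sel = select_optimal_panel(rfe(matrix))
            frac_planted = len(set(sel.feature_ids)
                               & set(truth.planted_feature_ids)) / sel.size
            if sel.accuracy == 100.0 and frac_planted >= 0.8:
                hits += 1
        assert hits >= 4

    def test_strict_scaling_does_not_beat_global_on_null_data(self):
        """Global (leaky) autoscaling inflates apparent accuracy on null
        data relative to fold-wise scaling, on average over seeds."""
        paper, strict = [], []
        for seed in range(12):
            m = noise_matrix(n=14, n_features=10, seed=seed + 100)
            paper.append(select_optimal_panel(
                rfe(m, scaling_mode="global")).accuracy)
            strict.append(select_optimal_panel(
                rfe(m, scaling_mode="per_fold")).accuracy)
        assert np.mean(strict) <= np.mean(paper)

    def test_needs_two_features(self):
        m = _matrix([[0.0], [1.0], [2.0], [3.0]], "CCNN")
        with pytest.raises(ValueError, match="2 features"):
            rfe(m)


class TestSelectOptimalPanel:
    def _trace(self, triples):
        steps = []
        sizes = range(len(triples), 0, -1)
        for size, (acc, sens, spec) in zip(sizes, triples):
            ids = [f"f{i}" for i in range(size)]
            steps.append(RfeStep(ids, np.zeros(size), acc, sens, spec,
                                 None if size == 1 else f"f{size - 1}"))
        return RfeTrace(steps)

    def test_minimum_panel_at_joint_maximum(self):
        # best triple at sizes 4..3, worse elsewhere: the smallest of those wins
        triples = [(90, 88, 92), (100, 100, 100), (100, 100, 100),
                   (95, 95, 95), (98, 98, 98)]
        sel = select_optimal_panel(self._trace(triples))
        assert sel.size == 3
        assert (sel.accuracy, sel.sensitivity, sel.specificity) == (100,) * 3

    def test_all_tied_selects_single_feature(self):
        sel = select_optimal_panel(self._trace([(80, 80, 80)] * 4))
        assert sel.size == 1

    def test_sensitivity_breaks_accuracy_ties(self):
        triples = [(90, 95, 85), (90, 80, 100)]
        sel = select_optimal_panel(self._trace(triples))
        assert sel.size == 2 and sel.sensitivity == 95

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_optimal_panel(RfeTrace([]))


class TestModelSerialization:
    def test_model_json_round_trip(self, tmp_path):
        model = fit_metabolic_model(separable_matrix(seed=8))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = SvmModel.from_json(path)
        assert np.allclose(back.w, model.w)
        assert back.b == model.b and back.feature_ids == model.feature_ids

    def test_trace_json_round_trip(self, tmp_path):
        trace = rfe(noise_matrix(n=8, n_features=3, seed=2))
        path = tmp_path / "trace.json"
        trace.to_json(path)
        back = RfeTrace.from_json(path)
        assert back.metrics_table().equals(trace.metrics_table())
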