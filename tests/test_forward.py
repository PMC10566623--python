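import numpy as np
import pytest

from fvsdecode import (
    Dataset,
    FvsConfig,
    SplitConfig,
    forward_select,
    make_split,
    score_candidate,
)
from fvsdecode._seeds import derive_seed
from fvsdecode.forward import CAP_REACHED, NO_IMPROVEMENT, partition_candidates
from fvsdecode.model_zoo import get_spec
from fvsdecode.tuning import is_better

RIDGE3 = {"ridge": {"param_space": {"alpha": [0.01, 1.0, 100.0]}}}


def _cfg(**kw):
    base = dict(model_name="ridge", master_seed=1, registry_overrides=RIDGE3)
    base.update(kw)
    return FvsConfig(**base)


class TestForwardSelect:
    def test_exact_feature_selected_first(self, rng):
        """f3 == y exactly: brute force confirms it minimizes test MSE."""
        X = rng.standard_normal((60, 6))
        y = X[:, 3].copy()
        ds = Dataset(X=X, y=y, feature_names=[f"f{j}" for j in range(6)],
                     task="regression")
        trace = forward_select(ds, _cfg(n_selected_features=1))
        assert trace.steps[0].feature == "f3"
        assert trace.steps[0].score < 1e-6

    def test_first_feature_matches_single_feature_argmax(self, sim_regression):
        """First pick equals the argmin over all m single-feature pipelines."""
        ds, _ = sim_regression
        config = _cfg(n_selected_features=1)
        trace = forward_select(ds, config)

        spec = get_spec("ridge", "regression", RIDGE3)
        split = make_split(ds, SplitConfig(seed=derive_seed(1, "split", 0),
                                           cv_folds=5))
        scores = {}
        for j, f in enumerate(ds.feature_names):
            seed = derive_seed(1, 0, j)
            scores[f], _ = score_candidate(ds, [], f, spec, split, seed)
        assert trace.steps[0].feature == min(scores, key=scores.get)
        assert trace.steps[0].score == pytest.approx(min(scores.values()))

    def test_cap_reached(self, sim_regression):
        ds, _ = sim_regression
        trace = forward_select(ds, _cfg(n_selected_features=2))
        assert len(trace.steps) <= 2
        if len(trace.steps) == 2:
            assert trace.stop_reason == CAP_REACHED

    def test_pure_noise_stops_early_with_exhaustive_rescoring(self, rng):
        """On noise, selection stops; every remaining candidate fails to
        improve at the stopping iteration (exhaustive rescoring oracle)."""
        X = rng.standard_normal((80, 8))
        y = rng.standard_normal(80)
        ds = Dataset(X=X, y=y, feature_names=[f"f{j}" for j in range(8)],
                     task="regression")
        config = _cfg(master_seed=5)
        trace = forward_select(ds, config)
        assert trace.stop_reason == NO_IMPROVEMENT
        assert len(trace.steps) < 8

        # oracle: rescore all remaining candidates at the stop iteration
        t = len(trace.steps)
        spec = get_spec("ridge", "regression", RIDGE3)
        split = make_split(ds, SplitConfig(seed=derive_seed(5, "split", t)))
        selected = trace.selected_features
        prev = trace.steps[-1].score if trace.steps else np.inf
        feat_idx = {f: j for j, f in enumerate(ds.feature_names)}
        for f in ds.feature_names:
            if f in selected:
                continue
            s, _ = score_candidate(ds, selected, f, spec, split,
                                   derive_seed(5, t, feat_idx[f]))
            assert not is_better(s, prev, "mse")

    def test_monotone_trace(self, sim_regression):
        ds, _ = sim_regression
        trace = forward_select(ds, _cfg(n_selected_features=6))
        scores = [s.score for s in trace.steps]
        assert all(b < a for a, b in zip(scores, scores[1:]))

    def test_greedy_oracle_equivalence_stepwise(self, sim_regression):
        """Each selection equals exhaustive search over remaining candidates
        given the same split (fixed-split mode)."""
        ds, _ = sim_regression
        config = _cfg(n_selected_features=4, resplit_each_iteration=False,
                      master_seed=9)
        trace = forward_select(ds, config)

        spec = get_spec("ridge", "regression", RIDGE3)
        split = make_split(ds, SplitConfig(seed=derive_seed(9, "split", 0)))
        feat_idx = {f: j for j, f in enumerate(ds.feature_names)}
        selected = []
        for step in trace.steps:
            best_f, best_s = None, np.inf
            for f in ds.feature_names:
                if f in selected:
                    continue
                s, _ = score_candidate(ds, selected, f, spec, split,
                                       derive_seed(9, step.iteration, feat_idx[f]))
                if s < best_s:
                    best_f, best_s = f, s
            assert step.feature == best_f
            assert step.score == pytest.approx(best_s)
            selected.append(best_f)

    def test_classification_selection(self, sim_classification):
        ds, truth = sim_classification
        config = FvsConfig(model_name="naive_bayes", n_selected_features=4,
                           master_seed=2)
        trace = forward_select(ds, config)
        assert trace.criterion == "accuracy"
        assert len(trace.steps) >= 1
        scores = [s.score for s in trace.steps]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_auc_criterion(self, sim_classification):
        ds, _ = sim_classification
        config = FvsConfig(model_name="naive_bayes", n_selected_features=2,
                           master_seed=2, criterion="auc")
        trace = forward_select(ds, config)
        assert all(0.0 <= s.score <= 1.0 for s in trace.steps)

    def test_zero_cap_fatal(self):
        with pytest.raises(ValueError, match="n_selected_features"):
            FvsConfig(model_name="ridge", n_selected_features=0)

    def test_parallel_trace_identical_to_serial(self, sim_regression):
        ds, _ = sim_regression
        kw = dict(n_selected_features=3, master_seed=4)
        serial = forward_select(ds, _cfg(n_workers=1, **kw))
        parallel = forward_select(ds, _cfg(n_workers=3, **kw))
        assert serial.selected_features == parallel.selected_features
        assert [s.score for s in serial.steps] == [s.score for s in parallel.steps]
        assert [s.params for s in serial.steps] == [s.params for s in parallel.steps]
        assert serial.stop_reason == parallel.stop_reason

    def test_tune_every_reuses_params(self, sim_regression):
        ds, _ = sim_regression
        trace = forward_select(ds, _cfg(n_selected_features=3, tune_every=3))
        assert len({repr(s.params) for s in trace.steps[1:]}) <= 2


class TestScoreCandidate:
    def test_exact_fit_limit(self, rng):
        X = rng.standard_normal((60, 4))
        y = X[:, 2].copy()
        ds = Dataset(X=X, y=y, feature_names=list("abcd"), task="regression")
        spec = get_spec("ridge", "regression", RIDGE3)
        split = make_split(ds, SplitConfig(seed=0))
        s, params = score_candidate(ds, [], "c", spec, split, seed=0)
        assert s < 1e-6

    def test_invariant_to_selected_order(self, sim_regression):
        ds, _ = sim_regression
        spec = get_spec("ridge", "regression", RIDGE3)
        split = make_split(ds, SplitConfig(seed=0))
        names = ds.feature_names
        s1, _ = score_candidate(ds, [names[0], names[4]], names[7], spec, split, 3)
        s2, _ = score_candidate(ds, [names[4], names[0]], names[7], spec, split, 3)
        assert s1 == s2

    def test_equals_independent_pipeline(self, sim_regression):
        """Independently coded split -> CV-tune -> refit -> score."""
        from sklearn.linear_model import Ridge
        from sklearn.metrics import mean_squared_error
        from sklearn.model_selection import KFold

        ds, _ = sim_regression
        spec = get_spec("ridge", "regression", RIDGE3)
        split = make_split(ds, SplitConfig(seed=0))
        seed = 17
        cols = [1, 5]
        got, got_params = score_candidate(
            ds, [ds.feature_names[1]], ds.feature_names[5], spec, split, seed
        )

        Xs = ds.X[:, cols]
        Xtr, ytr = Xs[split.train_idx], ds.y[split.train_idx]
        Xte, yte = Xs[split.test_idx], ds.y[split.test_idx]
        folds = list(KFold(5, shuffle=True, random_state=seed).split(Xtr))
        best_a, best_mse = None, np.inf
        for a in [0.01, 1.0, 100.0]:
            ms = []
            for tr, va in folds:
                est = Ridge(alpha=a, random_state=seed).fit(Xtr[tr], ytr[tr])
                ms.append(mean_squared_error(ytr[va], est.predict(Xtr[va])))
            if np.mean(ms) < best_mse:
                best_a, best_mse = a, float(np.mean(ms))
        est = Ridge(alpha=best_a, random_state=seed).fit(Xtr, ytr)
        expected = mean_squared_error(yte, est.predict(Xte))
        assert got_params == {"alpha": best_a}
        assert got == pytest.approx(expected, abs=1e-12)

    def test_candidate_already_selected_fatal(self, sim_regression):
        ds, _ = sim_regression
        spec = get_spec("ridge", "regression")
        split = make_split(ds, SplitConfig(seed=0))
        with pytest.raises(ValueError):
            score_candidate(ds, [ds.feature_names[0]], ds.feature_names[0],
                            spec, split, 0)


class TestPartitionCandidates:
    def test_balanced_sizes(self):
        queues = partition_candidates(list(range(10)), 3, seed=0)
        assert sorted(len(q) for q in queues) == [3, 3, 4]

    def test_single_worker(self):
        queues = partition_candidates(list("abcde"), 1, seed=0)
        assert len(queues) == 1
        assert sorted(queues[0]) == list("abcde")

    def test_disjoint_and_exhaustive(self):
        cands = [f"f{i}" for i in range(23)]
        queues = partition_candidates(cands, 4, seed=5)
        flat = [c for q in queues for c in q]
        assert sorted(flat) == sorted(cands)
        assert len(flat) == len(set(flat))

    def test_reproducible(self):
        a = partition_candidates(list(range(17)), 4, seed=9)
        b = partition_candidates(list(range(17)), 4, seed=9)
        assert a == b

    def test_empty(self):
        assert partition_candidates([], 3, seed=0) == []

    def test_more_workers_than_candidates(self):
        queues = partition_candidates([1, 2], 5, seed=0)
        assert sorted(len(q) for q in queues) == [1, 1]
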