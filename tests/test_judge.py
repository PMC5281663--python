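import numpy as np
import pytest

from breathomix import Hyperparams, MLPModel, train_mlp
from breathomix.judge import (
    AnnPool,
    InnerFoldFeatures,
    JudgeModel,
    PoolMember,
    brute_force_select,
    build_pool,
    judge_predict,
)

from oracles import oracle_best_assembly_score


def _const_model(value: float, k: int = 2) -> MLPModel:
    """Network that outputs tanh(atanh(value)) = value for every input."""
    h = 1
    return MLPModel(
        w1=np.zeros((k, h)), b1=np.zeros(h),
        w2=np.zeros((h, 1)), b2=np.array([np.arctanh(value)]),
        seed=0, hyperparams=Hyperparams(hidden=h),
    )


def _judge(gate_v, pos_vs, neg_vs):
    return JudgeModel(
        gate=_const_model(gate_v),
        positive_committee=[_const_model(v) for v in pos_vs],
        negative_committee=[_const_model(v) for v in neg_vs],
        config_name="c", provenance={},
    )


class TestJudgePredict:
    def test_committee_mean(self):
        j = _judge(0.5, (0.2, 0.4, 0.6), (-0.9, -0.9, -0.9))
        assert judge_predict(j, np.zeros(2)) == pytest.approx(0.4)

    def test_gate_routes_negative_branch(self):
        j = _judge(-0.5, (0.9, 0.9, 0.9), (-0.2, -0.4, -0.6))
        assert judge_predict(j, np.zeros(2)) == pytest.approx(-0.4)

    def test_gate_zero_ties_to_positive_branch(self):
        j = _judge(0.0, (0.3, 0.3, 0.3), (-0.3, -0.3, -0.3))
        assert judge_predict(j, np.zeros(2)) == pytest.approx(0.3)

    def test_identical_members_reduce_to_single_net(self, rng):
        X = rng.standard_normal((10, 3))
        y = np.r_[-np.ones(5), np.ones(5)]
        net = train_mlp(X, y, seed=0)
        j = JudgeModel(gate=net, positive_committee=[net] * 3,
                       negative_committee=[net] * 3, config_name="c", provenance={})
        from breathomix.ann import predict
        assert np.allclose(judge_predict(j, X), predict(net, X))

    def test_output_bounded(self):
        j = _judge(0.9, (1.0 - 1e-9, 0.9, 0.8), (-0.9, -0.9, -0.9))
        v = judge_predict(j, np.ones(2) * 1e9)
        assert -1.0 <= v <= 1.0

    def test_committee_size_enforced(self):
        with pytest.raises(ValueError, match="three"):
            JudgeModel(gate=_const_model(0.1), positive_committee=[_const_model(0.1)] * 2,
                       negative_committee=[_const_model(0.1)] * 3, config_name="c", provenance={})


class TestBuildPool:
    def test_pool_size_is_grid_product(self, rng):
        X = rng.standard_normal((16, 3))
        y = np.r_[-np.ones(8), np.ones(8)]
        pool = build_pool({"a": (X, y), "b": (X, y), "c": (X, y)},
                          hidden_sizes=[4, 8], seeds=[0, 1])
        assert len(pool.members) == 12
        assert len({m.tag for m in pool.members}) == 12

    def test_empty_seed_list_rejected(self, rng):
        X = rng.standard_normal((8, 2))
        y = np.r_[-np.ones(4), np.ones(4)]
        with pytest.raises(ValueError, match="seed"):
            build_pool({"a": (X, y)}, hidden_sizes=[4], seeds=[])

    def test_reproducible_pool(self, rng):
        X = rng.standard_normal((12, 3))
        y = np.r_[-np.ones(6), np.ones(6)]
        p1 = build_pool({"a": (X, y)}, hidden_sizes=[4], seeds=[0, 1])
        p2 = build_pool({"a": (X, y)}, hidden_sizes=[4], seeds=[0, 1])
        for m1, m2 in zip(p1.members, p2.members):
            assert m1.tag == m2.tag
            assert np.array_equal(m1.model.w1, m2.model.w1)

    def test_failed_candidate_excluded_and_recorded(self, rng):
        X = rng.standard_normal((8, 2))
        y_ok = np.r_[-np.ones(4), np.ones(4)]
        y_bad = np.ones(8)  # single class: training must fail
        pool = build_pool({"good": (X, y_ok), "bad": (X, y_bad)},
                          hidden_sizes=[4], seeds=[0])
        assert len(pool.members) == 1
        assert len(pool.failures) == 1 and pool.failures[0][0][0] == "bad"


def _inner_fold_data(rng, n=24, k=3, n_folds=3, separation=4.0):
    """Simple separable inner-fold features in one config."""
    X = np.vstack([rng.normal(-separation / 2, 1.0, size=(n // 2, k)),
                   rng.normal(separation / 2, 1.0, size=(n // 2, k))])
    y = np.r_[-np.ones(n // 2), np.ones(n // 2)]
    perm = rng.permutation(n)
    X, y = X[perm], y[perm]
    folds = []
    idx = np.arange(n)
    for f in range(n_folds):
        val = idx[f::n_folds]
        tr = np.setdiff1d(idx, val)
        folds.append(InnerFoldFeatures(X[tr], y[tr], X[val], y[val], val))
    return X, y, folds


class TestBruteForceSelect:
    def test_single_member_pool_with_reuse(self, rng):
        X, y, folds = _inner_fold_data(rng)
        pool = build_pool({"c": (X, y)}, hidden_sizes=[4], seeds=[0])
        judge = brute_force_select(pool, {"c": folds}, allow_reuse=True)
        tag = ("c", 4, 0)
        assert judge.provenance["gate"] == list(tag)
        assert judge.provenance["positive_committee"] == [list(tag)] * 3

    def test_selected_score_matches_independent_full_enumeration(self, rng):
        # pool of 10 nets, enumeration bound m=5: package argmax must equal
        # a plain-loop full enumeration over the same candidate set
        X, y, folds = _inner_fold_data(rng, n=30, separation=1.0)
        pool = build_pool({"c": (X, y)}, hidden_sizes=[2, 3, 4, 5, 6], seeds=[0, 1])
        assert len(pool.members) == 10
        judge = brute_force_select(pool, {"c": folds}, top_m=5)

        # recompute candidate out-of-fold predictions exactly as selection does
        from breathomix.ann import predict
        from breathomix.judge import mcc_from_predictions
        members = pool.by_config()["c"]
        n_val = sum(len(f.val_idx) for f in folds)
        P = np.empty((n_val, len(members)))
        truth = np.empty(n_val, dtype=bool)
        fold_id = np.empty(n_val, dtype=int)
        row = 0
        for fi, f in enumerate(folds):
            for j, mem in enumerate(members):
                mdl = train_mlp(f.X_train, f.y_train, mem.model.hyperparams,
                                seed=mem.model.seed)
                P[row:row + len(f.val_idx), j] = predict(mdl, f.X_val)
            truth[row:row + len(f.val_idx)] = f.y_val > 0
            fold_id[row:row + len(f.val_idx)] = fi
            row += len(f.val_idx)
        indiv = [mcc_from_predictions(P[:, j] >= 0, truth) for j in range(len(members))]
        order = sorted(range(len(members)), key=lambda j: (-indiv[j], members[j].tag))
        committee_idx = sorted(order[:5])
        best = oracle_best_assembly_score(P, truth, fold_id, committee_idx,
                                          range(len(members)))
        assert judge.inner_score == pytest.approx(best, abs=1e-12)

    def test_planted_perfect_net_is_selected_as_gate(self, rng):
        X, y, folds = _inner_fold_data(rng, n=30, separation=6.0)
        # one strong candidate (enough epochs) among weak ones (0 epochs)
        pool_members = []
        strong = Hyperparams(hidden=4, learning_rate=0.05, epochs=1500)
        weak = Hyperparams(hidden=4, learning_rate=0.0, epochs=0)
        pool_members.append(PoolMember(("c", 4, 0), train_mlp(X, y, strong, seed=0)))
        for si in range(1, 10):
            pool_members.append(PoolMember(("c", 4, si), train_mlp(X, y, weak, seed=si)))
        pool = AnnPool(members=pool_members)

        def train_candidate(tag, Xt, yt):
            hp = strong if tag[2] == 0 else weak
            return train_mlp(Xt, yt, hp, seed=tag[2])

        judge = brute_force_select(pool, {"c": folds}, top_m=4,
                                   train_candidate=train_candidate)
        # the planted net separates perfectly, so it must appear in the
        # selected assembly and the gate must route through it or a committee
        # containing it with perfect inner MCC
        assert judge.inner_score == pytest.approx(1.0)
        used = [tuple(judge.provenance["gate"])]
        used += [tuple(t) for t in judge.provenance["positive_committee"]]
        used += [tuple(t) for t in judge.provenance["negative_committee"]]
        assert ("c", 4, 0) in used

    def test_deterministic_tie_break_prefers_lexicographic_provenance(self, rng):
        # all candidates identical (same seed/hyperparams): every assembly
        # scores the same, so the lexicographically first must be returned
        X, y, folds = _inner_fold_data(rng)
        hp = Hyperparams(hidden=4, epochs=200)
        members = [PoolMember(("c", 4, si), train_mlp(X, y, hp, seed=0)) for si in range(5)]
        pool = AnnPool(members=members)

        def train_candidate(tag, Xt, yt):
            return train_mlp(Xt, yt, hp, seed=0)

        judge = brute_force_select(pool, {"c": folds}, top_m=5,
                                   train_candidate=train_candidate)
        assert judge.provenance["gate"] == ["c", 4, 0]
        assert judge.provenance["positive_committee"] == [["c", 4, 0], ["c", 4, 1], ["c", 4, 2]]
        assert judge.provenance["negative_committee"] == [["c", 4, 0], ["c", 4, 1], ["c", 4, 2]]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty pool|no valid"):
            brute_force_select(AnnPool(members=[]), {})
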