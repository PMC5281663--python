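"""Gated committee ensemble ("judge model") with brute-force selection.

One gating network routes each sample to a positive or a negative group;
each group is judged by a committee of three networks whose outputs are
averaged, giving the final predictive value in [-1, 1].  The best
(gate, committee, committee) assembly is found by exhaustive search over a
bounded candidate set, scored by mean inner-cross-validation Matthews
correlation of the assembled judge.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .ann import Hyperparams, MLPModel, predict, train_mlp

__all__ = [
    "JudgeModel",
    "AnnPool",
    "PoolMember",
    "InnerFoldFeatures",
    "judge_predict",
    "build_pool",
    "brute_force_select",
    "mcc_from_predictions",
]

#: Provenance tag: (feature-config name, hidden size, weight seed index).
Tag = tuple[str, int, int]


@dataclass
class PoolMember:
    tag: Tag
    model: MLPModel


@dataclass
class AnnPool:
    """Trained candidate networks, each tagged with unique provenance."""

    members: list[PoolMember]
    failures: list[tuple[Tag, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        tags = [m.tag for m in self.members]
        if len(set(tags)) != len(tags):
            raise ValueError("pool provenance tags must be unique")

    def by_config(self) -> dict[str, list[PoolMember]]:
        out: dict[str, list[PoolMember]] = {}
        for m in sorted(self.members, key=lambda m: m.tag):
            out.setdefault(m.tag[0], []).append(m)
        return out


@dataclass
class JudgeModel:
    """A gate plus two three-member committees sharing one feature space."""

    gate: MLPModel
    positive_committee: list[MLPModel]
    negative_committee: list[MLPModel]
    config_name: str
    provenance: dict
    inner_score: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.positive_committee) != 3 or len(self.negative_committee) != 3:
            raise ValueError("each committee must have exactly three networks")
        sizes = {self.gate.n_inputs}
        sizes |= {m.n_inputs for m in self.positive_committee}
        sizes |= {m.n_inputs for m in self.negative_committee}
        if len(sizes) != 1:
            raise ValueError("all member networks must share one input size")

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_name": self.config_name,
                "provenance": self.provenance,
                "inner_score": self.inner_score,
                "gate": json.loads(self.gate.to_json()),
                "positive_committee": [json.loads(m.to_json()) for m in self.positive_committee],
                "negative_committee": [json.loads(m.to_json()) for m in self.negative_committee],
            }
        )


def judge_predict(judge: JudgeModel, features: np.ndarray) -> np.ndarray:
    """Predictive value(s) of the judge for one vector or an (n, k) matrix.

    Gate output >= 0 routes to the positive committee (ties positive); the
    routed committee's three outputs are averaged.
    """
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    gate_vals = predict(judge.gate, X)
    pos = np.mean([predict(m, X) for m in judge.positive_committee], axis=0)
    neg = np.mean([predict(m, X) for m in judge.negative_committee], axis=0)
    out = np.where(gate_vals >= 0, pos, neg)
    return float(out[0]) if single else out


def build_pool(
    features_by_config: Mapping[str, tuple[np.ndarray, np.ndarray]],
    hidden_sizes: Sequence[int],
    seeds: Sequence[int],
    base_hyperparams: Hyperparams = Hyperparams(),
) -> AnnPool:
    """Train one candidate per (feature config, hidden size, seed).

    ``features_by_config`` maps a provenance name to (X, y) with labels in
    -1/+1.  A candidate whose training raises is excluded and recorded in
    ``failures``.
    """
    if not features_by_config or not hidden_sizes:
        raise ValueError("non-empty feature configs and hidden sizes required")
    if not seeds:
        raise ValueError("at least one weight seed required")
    members: list[PoolMember] = []
    failures: list[tuple[Tag, str]] = []
    for cfg_name in sorted(features_by_config):
        X, y = features_by_config[cfg_name]
        for h in hidden_sizes:
            for si, seed in enumerate(seeds):
                tag: Tag = (cfg_name, int(h), int(si))
                hp = Hyperparams(
                    hidden=int(h),
                    learning_rate=base_hyperparams.learning_rate,
                    epochs=base_hyperparams.epochs,
                    init_scale=base_hyperparams.init_scale,
                )
                try:
                    model = train_mlp(X, y, hp, seed=int(seed))
                except Exception as exc:  # noqa: BLE001 - candidate exclusion is the contract
                    failures.append((tag, str(exc)))
                    continue
                members.append(PoolMember(tag=tag, model=model))
    return AnnPool(members=members, failures=failures)


@dataclass
class InnerFoldFeatures:
    """Per-inner-fold training/validation features for one feature config."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    val_idx: np.ndarray  # indices into the outer-training set


def mcc_from_predictions(pred_pos: np.ndarray, truth_pos: np.ndarray) -> float:
    """Matthews correlation from boolean predicted/true positives; 0 when a
    denominator factor vanishes."""
    pred_pos = np.asarray(pred_pos, bool)
    truth_pos = np.asarray(truth_pos, bool)
    tp = float(np.sum(pred_pos & truth_pos))
    fp = float(np.sum(pred_pos & ~truth_pos))
    fn = float(np.sum(~pred_pos & truth_pos))
    tn = float(np.sum(~pred_pos & ~truth_pos))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def _assembly_scores_for_gate(
    gate_col: np.ndarray,
    comb_means: np.ndarray,
    pair_pos: np.ndarray,
    pair_neg: np.ndarray,
    truth_pos: np.ndarray,
    fold_id: np.ndarray,
) -> np.ndarray:
    """Mean per-inner-fold MCC for every (pos, neg) committee pair under one
    gate, vectorized over assemblies."""
    route_pos = gate_col >= 0
    vals = np.where(route_pos[:, None], comb_means[:, pair_pos], comb_means[:, pair_neg])
    pred_pos = vals >= 0
    n_assy = vals.shape[1]
    scores = np.zeros(n_assy)
    folds = np.unique(fold_id)
    for f in folds:
        mask = fold_id == f
        p = pred_pos[mask]
        t = truth_pos[mask][:, None]
        tp = np.sum(p & t, axis=0, dtype=float)
        fp = np.sum(p & ~t, axis=0, dtype=float)
        fn = np.sum(~p & t, axis=0, dtype=float)
        tn = np.sum(~p & ~t, axis=0, dtype=float)
        denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        mcc = np.zeros(n_assy)
        ok = denom > 0
        mcc[ok] = (tp[ok] * tn[ok] - fp[ok] * fn[ok]) / np.sqrt(denom[ok])
        scores += mcc
    return scores / len(folds)


def brute_force_select(
    pool: AnnPool,
    inner_folds: Mapping[str, Sequence[InnerFoldFeatures]],
    *,
    top_m: int = 8,
    allow_reuse: bool = False,
    metric: str = "mcc",
    train_candidate: Callable[[Tag, np.ndarray, np.ndarray], MLPModel] | None = None,
) -> JudgeModel:
    """Exhaustively search (gate, positive committee, negative committee)
    assemblies and return the argmax by mean inner-fold MCC.

    For every pool candidate, an out-of-fold prediction is computed by
    retraining that candidate's configuration on each inner-training split
    (via ``train_candidate``, defaulting to the candidate's own
    hyperparameters and seed) and predicting its validation split.
    Committees are drawn from the ``top_m`` candidates of each feature
    config by individual inner MCC; the gate ranges over all candidates of
    that config.  Ties break to the lexicographically earliest provenance.
    Members may be reused between gate and committees; within a committee
    the three networks are distinct unless ``allow_reuse``.
    """
    if metric not in ("mcc", "accuracy"):
        raise ValueError("metric must be 'mcc' or 'accuracy'")
    if not pool.members:
        raise ValueError("empty pool: no valid assembly exists")
    groups = pool.by_config()

    best: tuple[float, tuple, JudgeModel] | None = None
    for cfg_name, members in groups.items():
        if cfg_name not in inner_folds:
            continue
        folds = inner_folds[cfg_name]
        if not folds:
            continue
        n_val = sum(len(f.val_idx) for f in folds)
        c = len(members)
        P = np.empty((n_val, c))
        truth = np.empty(n_val, dtype=bool)
        fold_id = np.empty(n_val, dtype=int)
        row = 0
        for fi, f in enumerate(folds):
            nv = len(f.val_idx)
            for j, member in enumerate(members):
                if train_candidate is not None:
                    mdl = train_candidate(member.tag, f.X_train, f.y_train)
                else:
                    mdl = train_mlp(
                        f.X_train, f.y_train, member.model.hyperparams, seed=member.model.seed
                    )
                P[row : row + nv, j] = predict(mdl, f.X_val)
            truth[row : row + nv] = f.y_val > 0
            fold_id[row : row + nv] = fi
            row += nv
        if metric == "accuracy":
            indiv = [float(np.mean((P[:, j] >= 0) == truth)) for j in range(c)]
        else:
            indiv = [mcc_from_predictions(P[:, j] >= 0, truth) for j in range(c)]
        order = sorted(range(c), key=lambda j: (-indiv[j], members[j].tag))
        m_eff = min(top_m, c)
        committee_pool = sorted(order[:m_eff], key=lambda j: members[j].tag)
        if allow_reuse:
            combos = list(itertools.combinations_with_replacement(committee_pool, 3))
        else:
            if len(committee_pool) < 3:
                continue
            combos = list(itertools.combinations(committee_pool, 3))
        if not combos:
            continue
        comb_means = np.stack([P[:, list(cmb)].mean(axis=1) for cmb in combos], axis=1)
        K = len(combos)
        pair_pos = np.repeat(np.arange(K), K)
        pair_neg = np.tile(np.arange(K), K)
        for g in range(c):  # members are already provenance-sorted
            if metric == "mcc":
                scores = _assembly_scores_for_gate(
                    P[:, g], comb_means, pair_pos, pair_neg, truth, fold_id
                )
            else:
                route = (P[:, g] >= 0)[:, None]
                vals = np.where(route, comb_means[:, pair_pos], comb_means[:, pair_neg])
                scores = np.mean((vals >= 0) == truth[:, None], axis=0)
            a = int(np.argmax(scores))  # first occurrence = provenance-lex earliest
            score = float(scores[a])
            key = (
                members[g].tag,
                tuple(members[j].tag for j in combos[pair_pos[a]]),
                tuple(members[j].tag for j in combos[pair_neg[a]]),
            )
            if best is None or score > best[0] + 0.0 or (score == best[0] and key < best[1]):
                pos_idx = list(combos[pair_pos[a]])
                neg_idx = list(combos[pair_neg[a]])
                judge = JudgeModel(
                    gate=members[g].model,
                    positive_committee=[members[j].model for j in pos_idx],
                    negative_committee=[members[j].model for j in neg_idx],
                    config_name=cfg_name,
                    provenance={
                        "gate": list(members[g].tag),
                        "positive_committee": [list(members[j].tag) for j in pos_idx],
                        "negative_committee": [list(members[j].tag) for j in neg_idx],
                    },
                    inner_score=score,
                )
                best = (score, key, judge)
    if best is None:
        raise ValueError("no valid assembly could be enumerated")
    return best[2]
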