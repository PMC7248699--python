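"""Metric oracles: brute-force auROC, hand-enumerated ranking metrics,
random-distance chance levels, and scenario/observation-time machinery."""

import numpy as np
import pytest

from simatch.encoders import pairwise_sq_distances
from simatch.evaluation import (
    EXPERIMENTS,
    EvalReport,
    ScenarioConfig,
    assignment_accuracy,
    auroc_by_negative_type,
    clip_embeddings,
    evaluate_model,
    map_score,
    observation_time_curve,
    roc,
    scenario_experiment,
    temporal_trace,
)
from simatch.triplets import NegativeType


def _brute_force_auroc(pos, neg):
    """P(pos distance < neg distance), ties one half — O(n^2) oracle."""
    wins = sum((p < q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


def test_roc_matches_brute_force_200():
    rng = np.random.default_rng(0)
    pos = list(rng.normal(1.0, 0.7, size=100) ** 2)
    neg = list(rng.normal(1.8, 0.7, size=100) ** 2)
    r = roc(pos, neg)
    assert r.auroc == pytest.approx(_brute_force_auroc(pos, neg), abs=1e-12)


def test_roc_with_ties_matches_brute_force():
    pos = [1.0, 1.0, 2.0, 0.5]
    neg = [1.0, 2.0, 3.0]
    assert roc(pos, neg).auroc == pytest.approx(_brute_force_auroc(pos, neg), abs=1e-12)


def test_roc_perfect_and_inverted():
    assert roc([0.1, 0.2], [0.9, 1.0]).auroc == 1.0
    assert roc([0.9, 1.0], [0.1, 0.2]).auroc == 0.0


def test_roc_optimal_tau_separates():
    r = roc([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
    # declaring matches at distance < optimal_tau achieves TPR 1, FPR 0
    assert 0.3 <= r.optimal_tau < 0.7


def test_roc_empty_raises():
    with pytest.raises(ValueError):
        roc([], [1.0])


def test_map_score_hand_enumerated():
    # row 0: true col 0 at distance 1 ranks 1st -> 1
    # row 1: true col 2 at distance 5 ranks 3rd -> 1/3
    # row 2: true col 1 ties with col 0; pessimistic -> rank 2 -> 1/2
    D = np.array([
        [1.0, 2.0, 3.0],
        [1.0, 2.0, 5.0],
        [4.0, 4.0, 9.0],
    ])
    assert map_score(D, [0, 2, 1]) == pytest.approx((1 + 1 / 3 + 1 / 2) / 3)


def test_assignment_accuracy_hand_enumerated():
    D = np.array([
        [0.1, 5.0, 5.0],  # correct
        [5.0, 0.2, 5.0],  # correct
        [0.3, 5.0, 0.4],  # argmin col 0, true col 2 -> wrong
    ])
    assert assignment_accuracy(D, [0, 1, 2]) == pytest.approx(2 / 3)
    assert assignment_accuracy(D, {0: 0, 1: 1, 2: 2}) == pytest.approx(2 / 3)


def test_true_columns_validation():
    D = np.ones((2, 2))
    with pytest.raises(ValueError):
        map_score(D, [0])  # wrong length
    with pytest.raises(ValueError):
        assignment_accuracy(D, [0, 5])  # out of range


def test_random_distances_chance_levels():
    # random embeddings: assignment accuracy ~ 1/N, auROC ~ 0.5
    rng = np.random.default_rng(1)
    N, reps = 5, 400
    correct = 0
    for _ in range(reps):
        D = rng.random((N, N))
        correct += int(np.sum(D.argmin(axis=1) == np.arange(N)))
    acc = correct / (reps * N)
    assert acc == pytest.approx(1.0 / N, abs=0.03)
    r = roc(list(rng.random(500)), list(rng.random(500)))
    assert r.auroc == pytest.approx(0.5, abs=0.05)


def test_auroc_by_negative_type_keys(tiny_net, tiny_clips):
    rng = np.random.default_rng(0)
    out = auroc_by_negative_type(tiny_net, tiny_clips, rng)
    assert {"DSDA", "DSSA", "SSSA", "OVLP", "AVG"} <= set(out)
    per_type = [v for k, v in out.items() if k != "AVG"]
    assert out["AVG"] == pytest.approx(np.mean(per_type))
    assert all(0.0 <= v <= 1.0 for v in out.values())


def test_auroc_by_negative_type_subset_and_embeddings(tiny_net, tiny_clips):
    rng = np.random.default_rng(0)
    emb = clip_embeddings(tiny_net, tiny_clips)
    out = auroc_by_negative_type(
        tiny_net, tiny_clips, rng, types=[NegativeType.DSDA], embeddings=emb
    )
    assert set(out) == {"DSDA", "AVG"}
    assert out["AVG"] == out["DSDA"]


def test_clip_embeddings_shapes(tiny_net, tiny_clips):
    e_v, e_a = clip_embeddings(tiny_net, tiny_clips[:6])
    assert e_v.shape == (6, tiny_net.cfg.embed_dim)
    assert e_a.shape == (6, tiny_net.cfg.embed_dim)


def test_temporal_trace(tiny_net, tiny_clips):
    subs = sorted({c.meta.subject_id for c in tiny_clips})
    a = [c for c in tiny_clips if c.meta.subject_id == subs[0]][:5]
    b = [c for c in tiny_clips if c.meta.subject_id == subs[1]][:5]
    tr = temporal_trace(tiny_net, a, b)
    assert len(tr["time_s"]) == len(tr["matching"]) == len(tr["nonmatching"]) == 5
    tr2 = temporal_trace(tiny_net, a, b, window=3)
    assert len(tr2["matching"]) == 3  # valid convolution shortens the trace


def test_scenario_config_validation():
    with pytest.raises(ValueError):
        ScenarioConfig(n_vid=2, n_acc=2, n_sync=3)
    assert ScenarioConfig(n_vid=4, n_acc=2, n_sync=2).n_guest == 2


def test_scenario_experiment_chance_level_random_embeddings(tiny_clips):
    # random (untrained-like) embeddings: all_sync accuracy ~ 1/N, so the
    # curve must stay well below a good model's and decay with N
    rng = np.random.default_rng(2)
    n = len(tiny_clips)
    emb = (rng.normal(size=(n, 8)), rng.normal(size=(n, 8)))
    res = scenario_experiment(
        tiny_clips, "all_sync", rng, embeddings=emb, n_values=[2, 4], n_reps=60
    )
    assert res.metric == "accuracy"
    assert res.mean[0] == pytest.approx(1 / 2, abs=0.12)
    assert res.mean[1] == pytest.approx(1 / 4, abs=0.12)


@pytest.mark.parametrize("experiment", EXPERIMENTS)
def test_scenario_experiment_runs(experiment, tiny_net, tiny_clips):
    rng = np.random.default_rng(0)
    res = scenario_experiment(
        tiny_clips, experiment, rng, net=tiny_net, n_values=[2, 3], n_reps=3
    )
    assert res.values.shape == (3, 2)
    assert (res.values >= 0).all() and (res.values <= 1).all()
    assert res.metric == ("accuracy" if experiment == "all_sync" else "mAP")


def test_scenario_experiment_validation(tiny_clips):
    with pytest.raises(ValueError, match="experiment"):
        scenario_experiment(tiny_clips, "nope", np.random.default_rng(0), embeddings=(None, None))
    with pytest.raises(ValueError, match="net or precomputed"):
        scenario_experiment(tiny_clips, "all_sync", np.random.default_rng(0))


def test_observation_time_curve_perfect_embeddings(tiny_clips):
    # give every subject a unique constant embedding shared by both halves:
    # assignment is perfect at every k
    subs = sorted({c.meta.subject_id for c in tiny_clips})
    n = len(tiny_clips)
    e = np.zeros((n, 4))
    for i, c in enumerate(tiny_clips):
        e[i, subs.index(c.meta.subject_id)] = 1.0
    out = observation_time_curve(
        tiny_clips, np.random.default_rng(0), embeddings=(e, e), ks=(1, 2, 4), n_reps=4
    )
    np.testing.assert_array_equal(out["k"], [1, 2, 4])
    np.testing.assert_allclose(out["accuracy"], 1.0)


def test_observation_time_curve_drops_oversized_k(tiny_clips):
    out = observation_time_curve(
        tiny_clips, np.random.default_rng(0),
        embeddings=(np.zeros((len(tiny_clips), 2)), np.zeros((len(tiny_clips), 2))),
        ks=(1, 10_000), n_reps=2,
    )
    np.testing.assert_array_equal(out["k"], [1])


def test_evaluate_model_report(tiny_net, tiny_clips):
    rng = np.random.default_rng(0)
    rep = evaluate_model(tiny_net, tiny_clips[:30], rng, n_people=2, n_reps=3)
    assert isinstance(rep, EvalReport)
    d = rep.to_dict()
    assert 0.0 <= d["auroc_5050"] <= 1.0
    assert 0.0 <= d["assignment_accuracy"] <= 1.0
    assert "AVG" in d["auroc"]
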