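"""Negative taxonomy, mixtures, and triplet sampling."""

import numpy as np
import pytest

from simatch.core_io import LabeledClipPair, StreamMeta
from simatch.triplets import (
    OVLP_MAX_OFFSET,
    STRATEGIES,
    NegativeType,
    StrategyMixture,
    _sample_ovlp,
    build_epoch,
    classify_negative,
    eval_negatives,
    sample_negative,
)


def _clip(subject, activity, session="s0", start=0, length=10, n_frames=40, tag=0.0):
    sil = np.zeros((length, 8, 8), dtype=np.uint8)
    bb = np.zeros((length, 4))
    src = np.full((n_frames, 3), tag, dtype=float) + np.arange(n_frames)[:, None]
    return LabeledClipPair(
        sil, bb, src[start : start + length],
        StreamMeta(subject, activity, session), start, source_accel=src
    )


def test_mixture_validation():
    with pytest.raises(ValueError):
        StrategyMixture({NegativeType.DSDA: 0.7})
    with pytest.raises(ValueError):
        StrategyMixture({NegativeType.DSDA: 1.5, NegativeType.DSSA: -0.5})


def test_named_strategies_sum_to_one():
    for name, mix in STRATEGIES.items():
        assert abs(sum(mix.weights.values()) - 1.0) < 1e-9, name
    assert STRATEGIES["easy_hard"].weights[NegativeType.SSSA] == 0.5
    assert STRATEGIES["all"].weights[NegativeType.OVLP] == pytest.approx(1 / 3)


@pytest.mark.parametrize(
    "anchor,cand,expected",
    [
        (("A", "walk", "s0", (0, 10)), ("B", "run", "s0", (0, 10)), NegativeType.DSDA),
        (("A", "walk", "s0", (0, 10)), ("B", "walk", "s0", (0, 10)), NegativeType.DSSA),
        (("A", "walk", "s0", (0, 10)), ("A", "run", "s0", (0, 10)), NegativeType.SSDA),
        (("A", "walk", "s0", (0, 10)), ("A", "walk", "s1", (0, 10)), NegativeType.SSSA),
        (("A", "walk", "s0", (0, 10)), ("A", "walk", "s0", (20, 30)), NegativeType.SSSA),
        (("A", "walk", "s0", (0, 10)), ("A", "walk", "s0", (5, 15)), NegativeType.OVLP),
        (("A", "walk", "s0", (0, 10)), ("A", "walk", "s0", (0, 10)), "positive"),
        # half-open windows: sharing only an endpoint is disjoint
        (("A", "walk", "s0", (0, 10)), ("A", "walk", "s0", (10, 20)), NegativeType.SSSA),
    ],
)
def test_classify_negative(anchor, cand, expected):
    am = StreamMeta(anchor[0], anchor[1], anchor[2])
    cm = StreamMeta(cand[0], cand[1], cand[2])
    assert classify_negative(am, anchor[3], cm, cand[3]) == expected


def test_sample_ovlp_offset_bounds():
    anchor = _clip("A", "walk", start=15, length=10, n_frames=40)
    rng = np.random.default_rng(0)
    offsets = set()
    for _ in range(300):
        acc, off = _sample_ovlp(anchor, rng)
        assert off != 0 and abs(off) <= OVLP_MAX_OFFSET
        np.testing.assert_array_equal(acc, anchor.source_accel[15 + off : 25 + off])
        offsets.add(off)
    # both directions and the extremes are reachable from a centred window
    assert min(offsets) == -OVLP_MAX_OFFSET and max(offsets) == OVLP_MAX_OFFSET


def test_sample_ovlp_respects_stream_bounds():
    # anchor at the very start: only positive offsets fit
    anchor = _clip("A", "walk", start=0, length=10, n_frames=15)
    rng = np.random.default_rng(0)
    for _ in range(50):
        _, off = _sample_ovlp(anchor, rng)
        assert 1 <= off <= 5


def test_sample_ovlp_no_source():
    c = LabeledClipPair(
        np.zeros((4, 8, 8), dtype=np.uint8), np.zeros((4, 4)), np.zeros((4, 3)),
        StreamMeta("A", "walk"), 0
    )
    with pytest.raises(ValueError, match="source_accel"):
        _sample_ovlp(c, np.random.default_rng(0))


def test_sample_negative_type_first():
    pool = [
        _clip("A", "walk", start=0),
        _clip("A", "walk", start=20),  # SSSA for the first
        _clip("B", "walk", tag=100.0),  # DSSA
        _clip("B", "run", tag=200.0),  # DSDA
    ]
    anchor = pool[0]
    rng = np.random.default_rng(0)
    counts = {t: 0 for t in NegativeType}
    for _ in range(400):
        neg, t, off = sample_negative(anchor, pool, STRATEGIES["easy_hard"], rng)
        counts[t] += 1
        if t == NegativeType.SSSA:
            np.testing.assert_array_equal(neg, pool[1].acc)
        assert (off is not None) == (t == NegativeType.OVLP)
    assert counts[NegativeType.SSSA] / 400 == pytest.approx(0.5, abs=0.08)
    assert counts[NegativeType.SSDA] == counts[NegativeType.OVLP] == 0


def test_sample_negative_renormalizes(caplog):
    # no same-subject clips at all -> SSSA impossible, falls back to easy types
    pool = [_clip("A", "walk"), _clip("B", "walk", tag=100.0), _clip("B", "run", tag=200.0)]
    rng = np.random.default_rng(0)
    with caplog.at_level("WARNING"):
        for _ in range(30):
            _, t, _ = sample_negative(pool[0], pool, STRATEGIES["easy_hard"], rng)
            assert t in (NegativeType.DSDA, NegativeType.DSSA)
    assert any("renormalizing" in r.message for r in caplog.records)


def test_sample_negative_exhausted():
    pool = [_clip("A", "walk")]
    with pytest.raises(ValueError, match="no eligible negative"):
        sample_negative(pool[0], pool, STRATEGIES["easy"], np.random.default_rng(0))


def test_build_epoch_one_per_anchor(tiny_clips):
    rng = np.random.default_rng(0)
    trips = build_epoch(tiny_clips, STRATEGIES["all"], rng)
    assert len(trips) == len(tiny_clips)
    for tr in trips:
        np.testing.assert_array_equal(tr.positive, tr.anchor.acc)
        assert tr.negative.shape == tr.positive.shape
        if tr.neg_type == NegativeType.OVLP:
            assert tr.ovlp_offset is not None and tr.ovlp_offset != 0


def test_build_epoch_separate_pool():
    # anchors without same-stream companions in the anchor list still get
    # SSSA negatives when the pool supplies them
    pool = [_clip("A", "walk", start=s) for s in (0, 20)] + [_clip("B", "walk", tag=9.0)]
    anchors = pool[:1]
    rng = np.random.default_rng(0)
    types = {t for _ in range(50) for t in [build_epoch(anchors, STRATEGIES["hard"], rng, pool=pool)[0].neg_type]}
    assert types == {NegativeType.SSSA}


def test_build_epoch_deterministic(tiny_clips):
    t1 = build_epoch(tiny_clips[:20], STRATEGIES["easy_hard"], np.random.default_rng(5), pool=tiny_clips)
    t2 = build_epoch(tiny_clips[:20], STRATEGIES["easy_hard"], np.random.default_rng(5), pool=tiny_clips)
    for a, b in zip(t1, t2):
        assert a.neg_type == b.neg_type
        np.testing.assert_array_equal(a.negative, b.negative)


def test_eval_negatives_easy_only(tiny_clips):
    rng = np.random.default_rng(0)
    main = eval_negatives(tiny_clips, rng)
    assert len(main) == len(tiny_clips)
    kinds = {t for _, _, t in main}
    assert kinds <= {NegativeType.DSDA, NegativeType.DSSA}


def test_eval_negatives_diagnostic(tiny_clips):
    rng = np.random.default_rng(0)
    main, diag = eval_negatives(tiny_clips, rng, diagnostic=True)
    assert {t for _, _, t in diag[NegativeType.SSSA]} == {NegativeType.SSSA}
    assert {t for _, _, t in diag[NegativeType.OVLP]} == {NegativeType.OVLP}
    assert {t for _, _, t in main} <= {NegativeType.DSDA, NegativeType.DSSA}


def test_eval_negatives_needs_two_subjects():
    pool = [_clip("A", "walk", start=s) for s in (0, 20)]
    with pytest.raises(ValueError, match="two subjects"):
        eval_negatives(pool, np.random.default_rng(0))
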