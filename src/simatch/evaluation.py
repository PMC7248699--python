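"""Verification and assignment metrics.

Verification: a (video, accelerometer) pair is declared matching when the
squared embedding distance is below a threshold tau; sweeping tau yields the
ROC curve, summarised by its area (auROC), computed separately for each
negative type because different negatives are differently hard to reject.
Assignment: with N videos and N accelerometers, each video is assigned to
its minimum-distance accelerometer (accuracy = fraction correct); retrieval
variants report the mean reciprocal rank (mAP) of the true accelerometer.
Multi-occupancy scenes are simulated with virtual streams: clips cut from
different single-person recordings are treated as simultaneous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .core_io import LabeledClipPair
from .encoders import ThreeStreamNet, pairwise_sq_distances
from .triplets import NegativeType, classify_negative, _sample_ovlp

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    thresholds: np.ndarray  # sorted distance thresholds tau
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    optimal_tau: float  # Youden: maximizes TPR - FPR


def roc(pos_dists: Sequence[float], neg_dists: Sequence[float]) -> RocResult:
    """ROC over the declaration rule ``distance < tau``.

    auROC is the exact rank statistic (ties counted one half), equal to the
    probability that a random positive pair has smaller distance than a
    random negative pair.
    """
    pos = np.asarray(pos_dists, dtype=float)
    neg = np.asarray(neg_dists, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("roc needs non-empty positive and negative distance lists")
    scores = -np.concatenate([pos, neg])  # smaller distance = higher score
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    auroc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    taus = -thr  # back to the distance scale
    order = np.argsort(taus)
    taus, fpr, tpr = taus[order], fpr[order], tpr[order]
    best = int(np.argmax(tpr - fpr))
    return RocResult(thresholds=taus, tpr=tpr, fpr=fpr, auroc=auroc,
                     optimal_tau=float(taus[best]))


# ---------------------------------------------------------------------------
# auROC per negative type


def clip_embeddings(
    net: ThreeStreamNet, clips: Sequence[LabeledClipPair]
) -> tuple[np.ndarray, np.ndarray]:
    """Inference-mode embeddings of every clip's video and accel halves."""
    sil = np.stack([c.sil for c in clips])
    bb = np.stack([c.bb for c in clips])
    acc = np.stack([c.acc for c in clips])
    return net.encode_video(sil, bb), net.encode_accel(acc)


def auroc_by_negative_type(
    net: ThreeStreamNet,
    clips: Sequence[LabeledClipPair],
    rng: np.random.Generator,
    types: Iterable[NegativeType] = (
        NegativeType.DSDA,
        NegativeType.DSSA,
        NegativeType.SSSA,
        NegativeType.OVLP,
    ),
    embeddings: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, float]:
    """One auROC per negative type, plus their unweighted mean under 'AVG'.

    The positive set (each clip against its own acceleration) is shared by
    all types; per type, one negative is drawn per anchor where the type is
    feasible.  Returns only the feasible types (at least two subjects are
    required for the DS types).
    """
    types = list(types)
    e_v, e_a = clip_embeddings(net, clips) if embeddings is None else embeddings
    pos = ((e_v - e_a) ** 2).sum(axis=1)
    d_all = pairwise_sq_distances(e_v, e_a)
    n = len(clips)
    out: dict[str, float] = {}
    for t in types:
        neg_d = []
        if t == NegativeType.OVLP:
            ovlp_accs, anchors = [], []
            for i, c in enumerate(clips):
                try:
                    acc, _ = _sample_ovlp(c, rng)
                except ValueError:
                    continue
                ovlp_accs.append(acc)
                anchors.append(i)
            if ovlp_accs:
                e_neg = net.encode_accel(np.stack(ovlp_accs))
                neg_d = ((e_v[anchors] - e_neg) ** 2).sum(axis=1).tolist()
        else:
            for i, a in enumerate(clips):
                elig = [
                    j
                    for j in range(n)
                    if classify_negative(a.meta, a.window, clips[j].meta, clips[j].window) == t
                ]
                if elig:
                    j = elig[int(rng.integers(len(elig)))]
                    neg_d.append(d_all[i, j])
        if neg_d:
            out[t.value] = roc(pos, neg_d).auroc
    if out:
        out["AVG"] = float(np.mean([v for k, v in out.items() if k != "AVG"]))
    return out


# ---------------------------------------------------------------------------
# temporal traces


def temporal_trace(
    net: ThreeStreamNet,
    clips_a: Sequence[LabeledClipPair],
    clips_b: Sequence[LabeledClipPair],
    window: int = 1,
) -> dict[str, np.ndarray]:
    """Distance-versus-time curves for a matching and a non-matching pair.

    ``clips_a`` provide both the video and the accelerometer of the
    monitored subject; ``clips_b`` provide the video of the other subject
    (a potential guest).  Per-clip squared distances are optionally summed
    over a sliding window of ``window`` clips.
    """
    m = min(len(clips_a), len(clips_b))
    a, b = clips_a[:m], clips_b[:m]
    e_va, e_aa = clip_embeddings(net, a)
    e_vb = net.encode_video(np.stack([c.sil for c in b]), np.stack([c.bb for c in b]))
    d_match = ((e_va - e_aa) ** 2).sum(axis=1)
    d_non = ((e_vb - e_aa) ** 2).sum(axis=1)
    if window > 1:
        kern = np.ones(window)
        d_match = np.convolve(d_match, kern, mode="valid")
        d_non = np.convolve(d_non, kern, mode="valid")
    t = np.array([c.start_frame / c.meta.fps for c in a])[: len(d_match)]
    return {"time_s": t, "matching": d_match, "nonmatching": d_non}


# ---------------------------------------------------------------------------
# ranking metrics


def _true_columns(D: np.ndarray, true_pairs) -> np.ndarray:
    n = D.shape[0]
    if isinstance(true_pairs, dict):
        cols = np.array([true_pairs.get(i, -1) for i in range(n)])
    else:
        cols = np.asarray(true_pairs, dtype=int)
    if cols.shape != (n,) or (cols < 0).any() or (cols >= D.shape[1]).any():
        raise ValueError("every row needs a valid true column index")
    return cols


def map_score(D: np.ndarray, true_pairs) -> float:
    """Mean reciprocal rank of the true accelerometer per video row.

    Rank ties are broken pessimistically (the true column gets the worst
    rank among equal distances).
    """
    D = np.asarray(D, dtype=float)
    cols = _true_columns(D, true_pairs)
    d_true = D[np.arange(D.shape[0]), cols]
    ranks = (D <= d_true[:, None]).sum(axis=1)  # counts itself: rank >= 1
    return float(np.mean(1.0 / ranks))


def assignment_accuracy(D: np.ndarray, true_pairs) -> float:
    """Fraction of rows whose minimum-distance column is the true one.

    Ties resolve to the lowest column index (logged when they occur).
    """
    D = np.asarray(D, dtype=float)
    cols = _true_columns(D, true_pairs)
    mins = D.min(axis=1, keepdims=True)
    if (np.isclose(D, mins).sum(axis=1) > 1).any():
        logger.info("distance ties in assignment; resolved to lowest column index")
    assigned = D.argmin(axis=1)
    return float(np.mean(assigned == cols))


# ---------------------------------------------------------------------------
# scenario experiments


@dataclass(frozen=True)
class ScenarioConfig:
    """Occupancy scenario: how many people the camera sees (N_vid), how many
    wearables exist (N_acc) and how many people are both visible and
    instrumented (N_sync); guests are visible but uninstrumented."""

    n_vid: int
    n_acc: int
    n_sync: int

    def __post_init__(self) -> None:
        if self.n_sync > min(self.n_vid, self.n_acc):
            raise ValueError("n_sync cannot exceed min(n_vid, n_acc)")
        if self.n_vid - self.n_sync < 0:
            raise ValueError("n_guest = n_vid - n_sync must be >= 0")

    @property
    def n_guest(self) -> int:
        return self.n_vid - self.n_sync


EXPERIMENTS = ("fix_sync_vary_acc", "fix_sync_vary_vid", "all_sync")


@dataclass
class ScenarioResult:
    experiment: str
    n_values: list[int]
    mean: np.ndarray
    var: np.ndarray
    values: np.ndarray = field(repr=False)  # n_reps x len(n_values)

    @property
    def metric(self) -> str:
        return "accuracy" if self.experiment == "all_sync" else "mAP"


def _compatible(a: LabeledClipPair, b: LabeledClipPair) -> bool:
    """Usable as distinct virtual people: not the same or an overlapping window."""
    c = classify_negative(a.meta, a.window, b.meta, b.window)
    return c not in ("positive", NegativeType.OVLP)


def _sample_virtual_people(
    clips: Sequence[LabeledClipPair], n: int, rng: np.random.Generator
) -> list[int]:
    order = rng.permutation(len(clips))
    chosen: list[int] = []
    for i in order:
        if all(_compatible(clips[i], clips[j]) for j in chosen):
            chosen.append(int(i))
            if len(chosen) == n:
                return chosen
    raise ValueError(f"cannot assemble {n} mutually-compatible virtual people")


def scenario_experiment(
    clips: Sequence[LabeledClipPair],
    experiment: str,
    rng: np.random.Generator,
    net: ThreeStreamNet | None = None,
    embeddings: tuple[np.ndarray, np.ndarray] | None = None,
    n_values: Sequence[int] = tuple(range(2, 11)),
    n_reps: int = 20,
) -> ScenarioResult:
    """Metric curve versus the number of people, averaged over seeded
    resamplings of virtual multi-occupancy scenes.

    fix_sync_vary_acc : one visible instrumented person, N wearables -> mAP
    fix_sync_vary_vid : one wearable, N visible people -> mAP
    all_sync          : N people all visible and instrumented -> accuracy
    """
    if experiment not in EXPERIMENTS:
        raise ValueError(f"experiment must be one of {EXPERIMENTS}")
    if embeddings is None:
        if net is None:
            raise ValueError("provide a net or precomputed embeddings")
        embeddings = clip_embeddings(net, clips)
    e_v, e_a = embeddings
    values = np.empty((n_reps, len(n_values)))
    for r in range(n_reps):
        for k, n in enumerate(n_values):
            ScenarioConfig(
                n_vid=n if experiment != "fix_sync_vary_acc" else 1,
                n_acc=n if experiment != "fix_sync_vary_vid" else 1,
                n_sync=1 if experiment != "all_sync" else n,
            )
            idx = _sample_virtual_people(clips, n, rng)
            if experiment == "all_sync":
                D = pairwise_sq_distances(e_v[idx], e_a[idx])
                values[r, k] = assignment_accuracy(D, np.arange(n))
            elif experiment == "fix_sync_vary_acc":
                D = pairwise_sq_distances(e_v[idx[:1]], e_a[idx])
                values[r, k] = map_score(D, [0])
            else:  # fix_sync_vary_vid: rank of the true video for one wearable
                D = pairwise_sq_distances(e_a[idx[:1]], e_v[idx])
                values[r, k] = map_score(D, [0])
    return ScenarioResult(
        experiment=experiment,
        n_values=list(n_values),
        mean=values.mean(axis=0),
        var=values.var(axis=0),
        values=values,
    )


# ---------------------------------------------------------------------------
# variable observation time


def observation_time_curve(
    clips: Sequence[LabeledClipPair],
    rng: np.random.Generator,
    net: ThreeStreamNet | None = None,
    embeddings: tuple[np.ndarray, np.ndarray] | None = None,
    ks: Sequence[int] = (1, 2, 5, 10, 20, 40),
    n_reps: int = 20,
) -> dict[str, np.ndarray]:
    """Assignment accuracy when distances are averaged over k consecutive
    clips before assigning, for increasing k.

    All subjects present in ``clips`` are treated as simultaneously visible
    and instrumented; per repetition a random window of k consecutive clips
    is taken from each subject's clip sequence.
    """
    if embeddings is None:
        if net is None:
            raise ValueError("provide a net or precomputed embeddings")
        embeddings = clip_embeddings(net, clips)
    e_v, e_a = embeddings
    by_subject: dict[str, list[int]] = {}
    for i, c in enumerate(clips):
        by_subject.setdefault(c.meta.subject_id, []).append(i)
    for s in by_subject:
        by_subject[s].sort(key=lambda i: (clips[i].meta.activity, clips[i].start_frame))
    subjects = sorted(by_subject)
    if len(subjects) < 2:
        raise ValueError("observation-time curve needs at least two subjects")
    m = min(len(v) for v in by_subject.values())
    ks = [k for k in ks if k <= m]
    n = len(subjects)
    acc = np.empty((n_reps, len(ks)))
    for r in range(n_reps):
        for ki, k in enumerate(ks):
            starts = {s: int(rng.integers(0, m - k + 1)) for s in subjects}
            D = np.empty((n, n))
            for i, si in enumerate(subjects):
                vi = by_subject[si][starts[si] : starts[si] + k]
                for j, sj in enumerate(subjects):
                    aj = by_subject[sj][starts[sj] : starts[sj] + k]
                    D[i, j] = np.mean(
                        [((e_v[p] - e_a[q]) ** 2).sum() for p, q in zip(vi, aj)]
                    )
            acc[r, ki] = assignment_accuracy(D, np.arange(n))
    return {"k": np.array(ks), "accuracy": acc.mean(axis=0), "var": acc.var(axis=0)}


# ---------------------------------------------------------------------------
# report


@dataclass
class EvalReport:
    """Summary of a model evaluation on a clip set."""

    aurocs: dict[str, float]
    roc_5050: RocResult
    map_all_sync: float | None = None
    assignment: float | None = None

    def to_dict(self) -> dict:
        return {
            "auroc": self.aurocs,
            "optimal_tau": self.roc_5050.optimal_tau,
            "auroc_5050": self.roc_5050.auroc,
            "mAP": self.map_all_sync,
            "assignment_accuracy": self.assignment,
        }


def evaluate_model(
    net: ThreeStreamNet,
    clips: Sequence[LabeledClipPair],
    rng: np.random.Generator,
    n_people: int = 2,
    n_reps: int = 20,
) -> EvalReport:
    """Full verification + assignment evaluation of a trained model."""
    from .triplets import eval_negatives

    emb = clip_embeddings(net, clips)
    aurocs = auroc_by_negative_type(net, clips, rng, embeddings=emb)
    e_v, e_a = emb
    pos = ((e_v - e_a) ** 2).sum(axis=1)
    pairs = eval_negatives(clips, rng)
    idx = {id(c): i for i, c in enumerate(clips)}
    e_neg = net.encode_accel(np.stack([nacc for _, nacc, _ in pairs]))
    anchor_rows = np.array([idx[id(a)] for a, _, _ in pairs])
    neg = ((e_v[anchor_rows] - e_neg) ** 2).sum(axis=1)
    roc_5050 = roc(pos, neg)
    sc = scenario_experiment(
        clips, "all_sync", rng, embeddings=emb, n_values=[n_people], n_reps=n_reps
    )
    return EvalReport(
        aurocs=aurocs,
        roc_5050=roc_5050,
        map_all_sync=None,
        assignment=float(sc.mean[0]),
    )
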