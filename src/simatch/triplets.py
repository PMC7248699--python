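"""Triplet construction under the negative-type taxonomy.

A training triplet is (anchor video clip, its own time-synchronised
acceleration, a non-matching acceleration).  Negatives are classified by how
hard they are to reject:

====== ============================================== =========
type   definition                                     difficulty
====== ============================================== =========
DSDA   different subject, different activity          easy
DSSA   different subject, same activity               easy
SSDA   same subject, different activity               easy
SSSA   same subject, same activity, disjoint window   hard
OVLP   same stream, overlapping but shifted window    very hard
====== ============================================== =========

Training strategies are probability mixtures over these types; at inference
only DSDA and DSSA can occur (one person cannot appear in two places), so
evaluation negatives are drawn 50/50 from those two types, with SSSA/OVLP
available separately for diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Literal, Sequence

import numpy as np

from .core_io import LabeledClipPair, StreamMeta

logger = logging.getLogger(__name__)

#: Out-of-sync shift range (frames) for overlapping negatives: the negative
#: acceleration is the anchor's own stream shifted by a nonzero offset in
#: [-10, 10].
OVLP_MAX_OFFSET = 10


class NegativeType(str, Enum):
    DSDA = "DSDA"
    DSSA = "DSSA"
    SSDA = "SSDA"
    SSSA = "SSSA"
    OVLP = "OVLP"


@dataclass(frozen=True)
class StrategyMixture:
    """Probability mixture over negative types."""

    weights: dict[NegativeType, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("mixture weights must be nonnegative")

    @property
    def types(self) -> list[NegativeType]:
        return sorted(self.weights, key=lambda t: t.value)

    def probabilities(self) -> tuple[list[NegativeType], np.ndarray]:
        types = self.types
        return types, np.array([self.weights[t] for t in types])


#: Named training strategies (easy / hard / very-hard mixtures).
STRATEGIES: dict[str, StrategyMixture] = {
    "easy": StrategyMixture({NegativeType.DSDA: 0.5, NegativeType.DSSA: 0.5}),
    "easy_hard": StrategyMixture(
        {NegativeType.DSDA: 0.25, NegativeType.DSSA: 0.25, NegativeType.SSSA: 0.5}
    ),
    "hard": StrategyMixture({NegativeType.SSSA: 1.0}),
    "hard_veryh": StrategyMixture({NegativeType.SSSA: 0.5, NegativeType.OVLP: 0.5}),
    "veryh": StrategyMixture({NegativeType.OVLP: 1.0}),
    # printed as 11/11/11/33/33 percent; implemented exactly
    "all": StrategyMixture(
        {
            NegativeType.DSDA: 1 / 9,
            NegativeType.DSSA: 1 / 9,
            NegativeType.SSDA: 1 / 9,
            NegativeType.SSSA: 1 / 3,
            NegativeType.OVLP: 1 / 3,
        }
    ),
}


@dataclass
class Triplet:
    anchor: LabeledClipPair
    positive: np.ndarray  # L x 3 acceleration, the anchor's own
    negative: np.ndarray  # L x 3 acceleration
    neg_type: NegativeType
    ovlp_offset: int | None = None  # frames, only for OVLP negatives


def classify_negative(
    anchor_meta: StreamMeta,
    anchor_window: tuple[int, int],
    cand_meta: StreamMeta,
    cand_window: tuple[int, int],
) -> NegativeType | Literal["positive"]:
    """Classify a candidate clip relative to an anchor clip.

    Windows are half-open frame ranges and are only comparable within the
    same stream (same subject, activity and session).
    """
    if anchor_meta.subject_id != cand_meta.subject_id:
        if anchor_meta.activity == cand_meta.activity:
            return NegativeType.DSSA
        return NegativeType.DSDA
    if anchor_meta.activity != cand_meta.activity:
        return NegativeType.SSDA
    if anchor_meta.session != cand_meta.session:
        return NegativeType.SSSA  # different recording, windows incomparable
    a0, a1 = anchor_window
    c0, c1 = cand_window
    if (a0, a1) == (c0, c1):
        return "positive"
    if a0 < c1 and c0 < a1:  # overlapping but shifted
        return NegativeType.OVLP
    return NegativeType.SSSA


def _eligible(
    anchor: LabeledClipPair, pool: Sequence[LabeledClipPair], neg_type: NegativeType
) -> list[LabeledClipPair]:
    return [
        c
        for c in pool
        if classify_negative(anchor.meta, anchor.window, c.meta, c.window) == neg_type
    ]


def _sample_ovlp(
    anchor: LabeledClipPair, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Cut an overlapping negative from the anchor's own accel stream,
    shifted by a nonzero offset of at most OVLP_MAX_OFFSET frames."""
    if anchor.source_accel is None:
        raise ValueError("anchor has no source_accel; overlap negatives unavailable")
    n = anchor.source_accel.shape[0]
    L = anchor.length
    start = anchor.start_frame
    offsets = [
        o
        for o in range(-OVLP_MAX_OFFSET, OVLP_MAX_OFFSET + 1)
        if o != 0 and 0 <= start + o and start + o + L <= n
    ]
    if not offsets:
        raise ValueError("no valid overlap offset for this anchor window")
    o = int(rng.choice(offsets))
    return anchor.source_accel[start + o : start + o + L], o


def sample_negative(
    anchor: LabeledClipPair,
    pool: Sequence[LabeledClipPair],
    mixture: StrategyMixture,
    rng: np.random.Generator,
) -> tuple[np.ndarray, NegativeType, int | None]:
    """Draw one negative acceleration for an anchor.

    The type is drawn from the mixture first, then a clip uniformly among
    the eligible candidates of that type.  If the drawn type has no eligible
    candidate, the mixture is renormalized over the remaining types (with a
    warning); if no type is feasible, an error is raised.
    """
    weights = dict(mixture.weights)
    while weights:
        types = sorted(weights, key=lambda t: t.value)
        probs = np.array([weights[t] for t in types], dtype=float)
        probs /= probs.sum()
        neg_type = types[rng.choice(len(types), p=probs)]
        if neg_type == NegativeType.OVLP:
            try:
                acc, off = _sample_ovlp(anchor, rng)
                return acc, neg_type, off
            except ValueError:
                candidates = []
        else:
            candidates = _eligible(anchor, pool, neg_type)
        if candidates:
            cand = candidates[int(rng.integers(len(candidates)))]
            return cand.acc, neg_type, None
        logger.warning(
            "no eligible %s negative for anchor %s; renormalizing mixture",
            neg_type.value,
            anchor.meta.stream_key,
        )
        del weights[neg_type]
    raise ValueError("no eligible negative of any type for this anchor")


def build_epoch(
    clips: Sequence[LabeledClipPair],
    mixture: StrategyMixture,
    rng: np.random.Generator,
    pool: Sequence[LabeledClipPair] | None = None,
) -> list[Triplet]:
    """One triplet per anchor clip; positives are always the anchor's own
    acceleration.  Negatives are drawn from ``pool`` (default: the anchors
    themselves).  Deterministic under the generator's state."""
    if pool is None:
        pool = clips
    triplets = []
    for anchor in clips:
        neg, neg_type, off = sample_negative(anchor, pool, mixture, rng)
        triplets.append(Triplet(anchor, anchor.acc, neg, neg_type, off))
    return triplets


def eval_negatives(
    clips: Sequence[LabeledClipPair],
    rng: np.random.Generator,
    diagnostic: bool = False,
) -> (
    list[tuple[LabeledClipPair, np.ndarray, NegativeType]]
    | tuple[
        list[tuple[LabeledClipPair, np.ndarray, NegativeType]],
        dict[NegativeType, list[tuple[LabeledClipPair, np.ndarray, NegativeType]]],
    ]
):
    """Inference-realistic negatives: a 50/50 DSDA/DSSA mixture, one per
    anchor.  With ``diagnostic=True``, also return separate SSSA and OVLP
    negative lists (never mixed into the 50/50 set)."""
    subjects = {c.meta.subject_id for c in clips}
    if len(subjects) < 2:
        raise ValueError("eval negatives need at least two subjects (DSDA/DSSA impossible)")
    mixture = STRATEGIES["easy"]
    main = []
    for anchor in clips:
        neg, neg_type, _ = sample_negative(anchor, clips, mixture, rng)
        main.append((anchor, neg, neg_type))
    if not diagnostic:
        return main
    diag: dict[NegativeType, list] = {}
    for t in (NegativeType.SSSA, NegativeType.OVLP):
        single = StrategyMixture({t: 1.0})
        entries = []
        for anchor in clips:
            try:
                neg, neg_type, _ = sample_negative(anchor, clips, single, rng)
            except ValueError:
                continue
            entries.append((anchor, neg, neg_type))
        diag[t] = entries
    return main, diag
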