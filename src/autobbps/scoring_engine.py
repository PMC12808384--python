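"""The AutoBBPS streaming scoring state machine.

Scoring starts only once the colonoscope reaches the ileocecal region: a
qualifying ileocecal observation (confidence at or above the engine
threshold, sustained for a configurable run of consecutive frames, one by
default) arms the counter, and every subsequent frame is tallied by
predicted category.  Frames predicted below the confidence threshold are
excluded from both numerator and denominator (tracked separately for
audit); instrument-operation frames are counted but subtracted from the
denominator, so they never dilute the cleanliness fractions.  The
cumulative score is the weighted sum of counted-frame fractions

    score = 9 * f3 + 6 * f2 + 3 * f1,   f_k = n_k / (total - n_instrument)

which spans the familiar 0-9 Boston scale range (9 = every counted frame
rated BBPS 3).  The engine is a pure fold: streaming updates and batch
scoring agree by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .stream_model import (
    BBPS1,
    BBPS2,
    BBPS3,
    ILEOCECAL,
    INSTRUMENT,
    VOCABULARY,
    FrameObservation,
)

__all__ = [
    "EngineConfig",
    "ScoringState",
    "CumulativeScore",
    "new_state",
    "update",
    "cumulative_score",
    "score_stream",
    "categorize_video",
]


@dataclass(frozen=True)
class EngineConfig:
    """Engine knobs.

    confidence_threshold
        Minimum per-frame confidence for an observation to count (and for
        an ileocecal frame to arm the trigger).  Default 0.80, the value
        selected by the kappa-based threshold sweep.
    trigger_run_length
        Number of consecutive qualifying ileocecal frames required to arm
        scoring.  Default 1 (a single detection arms the engine).
    frame_stride
        Process every ``frame_stride``-th frame (by frame index); skipped
        frames touch no counter.  Default 1 (every frame).
    strict
        When true, out-of-order frame indices and undefined final scores
        raise instead of being tolerated.
    """

    confidence_threshold: float = 0.80
    trigger_run_length: int = 1
    frame_stride: int = 1
    strict: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must be in [0, 1]")
        if self.trigger_run_length < 1:
            raise ValueError("trigger_run_length must be >= 1")
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


@dataclass(frozen=True)
class ScoringState:
    """Accumulator: trigger flag plus per-category counted-frame tallies."""

    ileocecal_reached: bool = False
    counts: tuple[int, ...] = (0,) * len(VOCABULARY)  # by vocabulary index
    total_counted: int = 0
    below_threshold_count: int = 0
    frames_seen: int = 0
    trigger_run: int = 0           # consecutive qualifying ileocecal frames so far
    last_frame_index: int = -1

    @property
    def instrument_count(self) -> int:
        return self.counts[INSTRUMENT.index]

    def count_of(self, category) -> int:
        return self.counts[category.index]

    def counts_by_name(self) -> dict[str, int]:
        return {c.name: self.counts[c.index] for c in VOCABULARY}


@dataclass(frozen=True)
class CumulativeScore:
    """The 0-9 weighted score with its component fractions.

    ``defined`` is false exactly when no countable (non-instrument) frame
    has been seen since the trigger; ``value`` is then NaN rather than a
    number, so an unscored video can never masquerade as score 0.
    """

    value: float
    fractions: tuple[float, float, float]  # f1, f2, f3 for BBPS 1/2/3
    denominator: int
    defined: bool

    UNDEFINED_SENTINEL = "--"

    def display(self, places: int = 2) -> str:
        return f"{self.value:.{places}f}" if self.defined else self.UNDEFINED_SENTINEL


def new_state() -> ScoringState:
    return ScoringState()


def update(state: ScoringState, obs: FrameObservation,
           config: EngineConfig = EngineConfig()) -> ScoringState:
    """Fold one observation into the state.

    Before the trigger nothing is counted; a qualifying ileocecal run arms
    the engine and counting begins with the next frame.  After the trigger,
    sub-threshold observations only increment the audit counter; everything
    else increments its category tally.
    """
    if obs.frame_index <= state.last_frame_index:
        if config.strict:
            raise ValueError(
                f"out-of-order frame index {obs.frame_index} "
                f"(last seen {state.last_frame_index})"
            )
    if obs.frame_index % config.frame_stride != 0:
        return state  # strided out: untouched, not even frames_seen
    qualifies = obs.confidence >= config.confidence_threshold

    if not state.ileocecal_reached:
        if obs.category is ILEOCECAL and qualifies:
            run = state.trigger_run + 1
            return replace(
                state,
                frames_seen=state.frames_seen + 1,
                last_frame_index=obs.frame_index,
                trigger_run=run,
                ileocecal_reached=run >= config.trigger_run_length,
            )
        return replace(
            state,
            frames_seen=state.frames_seen + 1,
            last_frame_index=obs.frame_index,
            trigger_run=0,
        )

    if not qualifies:
        return replace(
            state,
            frames_seen=state.frames_seen + 1,
            last_frame_index=obs.frame_index,
            below_threshold_count=state.below_threshold_count + 1,
        )
    counts = list(state.counts)
    counts[obs.category.index] += 1
    return replace(
        state,
        frames_seen=state.frames_seen + 1,
        last_frame_index=obs.frame_index,
        counts=tuple(counts),
        total_counted=state.total_counted + 1,
    )


def cumulative_score(state: ScoringState) -> CumulativeScore:
    """Weighted frame-fraction score of the current state."""
    denom = state.total_counted - state.instrument_count
    if denom <= 0:
        return CumulativeScore(math.nan, (0.0, 0.0, 0.0), 0, defined=False)
    f1 = state.counts[BBPS1.index] / denom
    f2 = state.counts[BBPS2.index] / denom
    f3 = state.counts[BBPS3.index] / denom
    return CumulativeScore(9.0 * f3 + 6.0 * f2 + 3.0 * f1, (f1, f2, f3),
                           denom, defined=True)


def score_stream(
    observations: Iterable[FrameObservation],
    config: EngineConfig = EngineConfig(),
) -> tuple[CumulativeScore, list[tuple[int, CumulativeScore]], ScoringState]:
    """Fold a whole stream; returns (final score, per-frame trace, state).

    The trace holds ``(frame_index, running score)`` after every processed
    frame; the final score equals the last trace entry, and equals
    :func:`cumulative_score` of the returned state (streaming/batch
    equivalence).
    """
    state = new_state()
    trace: list[tuple[int, CumulativeScore]] = []
    for obs in observations:
        nxt = update(state, obs, config)
        if nxt is not state:  # strided-out frames leave no trace entry
            trace.append((obs.frame_index, cumulative_score(nxt)))
        state = nxt
    final = cumulative_score(state)
    if config.strict and not final.defined:
        raise ValueError("stream produced no countable frames (score undefined)")
    return final, trace, state


def categorize_video(score: CumulativeScore) -> int:
    """Map a defined cumulative score to a video-level class in {0, 1, 2, 3}.

    ``round(value / 3)`` with half rounded away from zero (7.5 -> class 3),
    clipped to [0, 3].  This mapping is a repository convention: video-level
    labels exist in the evaluation design, but no explicit mapping from the
    continuous 0-9 score is prescribed.
    """
    if not score.defined:
        raise ValueError("cannot categorize an undefined score")
    cls = int(math.floor(score.value / 3.0 + 0.5))
    return min(3, max(0, cls))
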