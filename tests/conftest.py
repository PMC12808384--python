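import numpy as np
import pytest

from autobbps import (
    CLEANLINESS,
    ILEOCECAL,
    INSTRUMENT,
    EngineConfig,
    FrameObservation,
    canonical_category,
)

BBPS = {k: canonical_category(f"BBPS {k}") for k in range(4)}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def obs(i, category, confidence=1.0):
    """Shorthand FrameObservation constructor used across the suite."""
    return FrameObservation(i, canonical_category(category), confidence)


def stream(categories, confidences=None, start=0):
    """Build an observation list from category shorthand."""
    confidences = confidences or [1.0] * len(categories)
    return [obs(start + i, c, p) for i, (c, p) in
            enumerate(zip(categories, confidences))]


def brute_force_score(observations, threshold=0.80, trigger_run=1):
    """Independent recomputation of the cumulative score from raw counts.

    Walks the stream with plain Python: finds the ileocecal trigger (a run
    of qualifying landmark frames), then tallies every subsequent frame at
    or above the threshold and applies the weighted-fraction formula
    directly.  Shares no code with the engine.
    """
    run = 0
    triggered_at = None
    for k, o in enumerate(observations):
        if o.category.name == "ileocecal part" and o.confidence >= threshold:
            run += 1
            if run >= trigger_run:
                triggered_at = k
                break
        else:
            run = 0
    if triggered_at is None:
        return None
    tally = {}
    for o in observations[triggered_at + 1:]:
        if o.confidence >= threshold:
            tally[o.category.name] = tally.get(o.category.name, 0) + 1
    denom = sum(tally.values()) - tally.get("instrument", 0)
    if denom <= 0:
        return None
    num = (3 * tally.get("BBPS 1", 0) + 6 * tally.get("BBPS 2", 0)
           + 9 * tally.get("BBPS 3", 0))
    return num / denom


def random_stream(rng, max_frames=50):
    """A random observation stream over the full vocabulary."""
    n = int(rng.integers(1, max_frames + 1))
    cats = [CLEANLINESS + (ILEOCECAL, INSTRUMENT)][0]
    out = []
    for i in range(n):
        c = cats[int(rng.integers(0, 6))]
        conf = float(rng.uniform(0, 1))
        out.append(FrameObservation(i, c, conf))
    return out
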