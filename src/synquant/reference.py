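"""Slow, independent reference implementations used for validation.

These deliberately naive routines (explicit Python loops, exhaustive
enumeration) re-derive the same quantities as the vectorized production code
through a different mechanism, and serve as oracles in the test suite.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations

import numpy as np

__all__ = [
    "windowed_rms_reference",
    "segment_envelope_reference",
    "hypergeom_tail_enumeration",
]


def windowed_rms_reference(values, window_samples: int) -> np.ndarray:
    """Centered sliding-window RMS computed sample by sample."""
    values = np.asarray(values, dtype=float)
    x = values - values.mean()
    n = x.size
    w = window_samples
    out = np.empty(n)
    for i in range(n):
        lo = max(i - (w - 1) // 2, 0)
        hi = min(i + w // 2, n - 1)
        acc = 0.0
        for j in range(lo, hi + 1):
            acc += x[j] * x[j]
        out[i] = math.sqrt(acc / (hi - lo + 1))
    return out


def segment_envelope_reference(
    env,
    sampling_rate_hz: float,
    threshold: float,
    min_above_ms: float = 100.0,
    merge_gap_ms: float = 600.0,
) -> list[tuple[int, int]]:
    """Per-sample state machine applying the UP-state rules.

    Returns half-open ``(start, end)`` sample index pairs. Semantics: runs of
    ``env > threshold``; runs shorter than ``min_above_ms`` dropped; then a
    gap of at most ``merge_gap_ms`` between surviving runs keeps the event
    open. Durations round half up to sample counts, as in production.
    """
    env = np.asarray(env, dtype=float)
    fs = sampling_rate_hz
    min_n = max(1, int(math.floor(min_above_ms / 1000.0 * fs + 0.5)))
    gap_n = int(math.floor(merge_gap_ms / 1000.0 * fs + 0.5))

    # pass 1: collect maximal supra-threshold runs, one sample at a time
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for i, v in enumerate(env):
        if v > threshold and not in_run:
            in_run, start = True, i
        elif v <= threshold and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, env.size))

    # pass 2: minimum-duration rule
    survivors = []
    for s, e in runs:
        if e - s >= min_n:
            survivors.append((s, e))

    # pass 3: merge across short gaps
    events: list[tuple[int, int]] = []
    for s, e in survivors:
        if events and s - events[-1][1] <= gap_n:
            events[-1] = (events[-1][0], e)
        else:
            events.append((s, e))
    return events


def hypergeom_tail_enumeration(
    n_background: int, n_external: int, n_internal: int, k_observed: int
) -> Fraction:
    """P(overlap >= k) by exhaustive enumeration of all internal-set draws.

    Counts, over every possible draw of ``n_internal`` items from a
    background of ``n_background`` containing ``n_external`` marked items,
    the fraction of draws sharing at least ``k_observed`` items with the
    marked set. Exact rational arithmetic; only feasible for tiny universes.
    """
    population = range(n_background)
    external = set(range(n_external))
    total = 0
    hits = 0
    for draw in combinations(population, n_internal):
        total += 1
        if len(external.intersection(draw)) >= k_observed:
            hits += 1
    return Fraction(hits, total)
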