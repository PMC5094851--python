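"""Event detection for extracellular and voltage-clamp recordings.

UP-state segmentation follows the classic slice-physiology rules: an epoch
begins when the activity envelope stays above threshold for at least 100 ms,
ends only after the envelope has remained below threshold for more than
600 ms, and two epochs within 600 ms are one UP state. Miniature
postsynaptic currents are detected with the field's standard amplitude /
area criteria (defaults 7 pA and 10 pA·ms).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .types import EventSummary, MiniEvent, RecordingTrace, UpStateEvent

__all__ = [
    "envelope",
    "segment_envelope",
    "detect_up_states",
    "up_state_stats",
    "detect_minis",
    "mini_stats",
    "auto_threshold",
]


def _ms_to_samples(ms: float, fs: float) -> int:
    """Duration in ms -> sample count, rounding half up."""
    return int(math.floor(ms / 1000.0 * fs + 0.5))


def envelope(trace: RecordingTrace | np.ndarray, window_ms: float = 10.0,
             sampling_rate_hz: float | None = None) -> np.ndarray:
    """Sliding-window RMS amplitude of the mean-subtracted trace.

    The window is centered on each sample and truncated at the record edges,
    so the output has the same length as the input.
    """
    if isinstance(trace, RecordingTrace):
        values, fs = trace.values, trace.sampling_rate_hz
    else:
        if sampling_rate_hz is None:
            raise ValueError("sampling_rate_hz required for bare arrays")
        values, fs = np.asarray(trace, dtype=float), sampling_rate_hz
    if window_ms <= 0:
        raise ValueError("window_ms must be positive")
    w = max(2, _ms_to_samples(window_ms, fs))
    n = values.size
    if w > n:
        raise ValueError(f"window of {w} samples exceeds trace length {n}")
    sq = (values - values.mean()) ** 2
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    idx = np.arange(n)
    lo = np.maximum(idx - (w - 1) // 2, 0)
    hi = np.minimum(idx + w // 2, n - 1)
    means = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return np.sqrt(means)


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    padded = np.concatenate([[False], above, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment_envelope(
    env: np.ndarray,
    sampling_rate_hz: float,
    threshold: float,
    *,
    min_above_ms: float = 100.0,
    merge_gap_ms: float = 600.0,
    amplitude_mode: str = "mean",
) -> list[UpStateEvent]:
    """Apply the UP-state onset/offset/merge rules to an amplitude envelope.

    Candidate epochs are maximal runs of ``env > threshold``. Runs shorter
    than ``min_above_ms`` are discarded; surviving runs separated by a gap of
    at most ``merge_gap_ms`` are merged into one event (equivalently, an
    event only ends once the envelope stays below threshold for longer than
    the gap). Minimum duration is applied before merging. All durations are
    converted to sample counts by rounding half up; "at least 100 ms" means
    >= that many samples. A run still open at the record end is emitted with
    ``truncated=True``.
    """
    env = np.asarray(env, dtype=float)
    fs = sampling_rate_hz
    if min_above_ms <= 0 or merge_gap_ms <= 0:
        raise ValueError("durations must be positive")
    min_n = max(1, _ms_to_samples(min_above_ms, fs))
    gap_n = _ms_to_samples(merge_gap_ms, fs)

    runs = [(s, e) for s, e in _runs_above(env > threshold) if e - s >= min_n]
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    events = []
    for s, e in merged:
        seg = env[s:e]
        amp = float(seg.mean()) if amplitude_mode == "mean" else float(seg.max())
        events.append(
            UpStateEvent(
                start_s=s / fs, end_s=e / fs, amplitude=amp, truncated=(e == env.size)
            )
        )
    return events


def auto_threshold(env: np.ndarray, n_mads: float = 5.0) -> float:
    """Robust envelope threshold: median + ``n_mads`` scaled MADs.

    Median/MAD statistics are insensitive to the event epochs themselves as
    long as events occupy well under half the record, which makes the
    threshold stable on event-rich traces. Fails on a flat envelope (no
    baseline variance to set a scale).
    """
    env = np.asarray(env, dtype=float)
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    if mad == 0:
        raise ValueError("envelope has no baseline variance; supply an explicit threshold")
    return med + n_mads * 1.4826 * mad


def detect_up_states(
    trace: RecordingTrace,
    threshold: float | str = "auto",
    *,
    min_above_ms: float = 100.0,
    merge_gap_ms: float = 600.0,
    envelope_window_ms: float = 50.0,
    amplitude_mode: str = "mean",
) -> list[UpStateEvent]:
    """Detect UP states on a recording via its RMS envelope.

    ``threshold="auto"`` derives a robust threshold from the envelope
    (median + 5 scaled MADs); pass a number for an absolute threshold in
    envelope units. The 50 ms default envelope window trades temporal
    resolution for a stable within-event envelope so that brief dips do not
    fragment epochs below the 100 ms minimum.
    """
    env = envelope(trace, envelope_window_ms)
    thr = auto_threshold(env) if threshold == "auto" else float(threshold)
    return segment_envelope(
        env,
        trace.sampling_rate_hz,
        thr,
        min_above_ms=min_above_ms,
        merge_gap_ms=merge_gap_ms,
        amplitude_mode=amplitude_mode,
    )


def up_state_stats(events: list[UpStateEvent], record_duration_s: float) -> EventSummary:
    """Frequency (events/min), mean duration and mean amplitude of UP states."""
    if record_duration_s <= 0:
        raise ValueError("record_duration_s must be positive")
    n = len(events)
    freq = n / (record_duration_s / 60.0)
    if n == 0:
        return EventSummary(0, 0.0, "events/min")
    return EventSummary(
        n_events=n,
        frequency=freq,
        frequency_unit="events/min",
        mean_amplitude=float(np.mean([ev.amplitude for ev in events])),
        mean_duration_s=float(np.mean([ev.duration_s for ev in events])),
    )


def detect_minis(
    trace: RecordingTrace,
    amp_threshold_pA: float = 7.0,
    area_threshold_pA_ms: float = 10.0,
    *,
    baseline_window_ms: float = 500.0,
    refractory_ms: float = 5.0,
    smoothing_ms: float = 2.0,
    boundary_fraction: float = 0.1,
    valley_fraction: float = 0.5,
) -> list[MiniEvent]:
    """Detect miniature postsynaptic currents on a voltage-clamp record.

    The trace is oriented so events are positive deflections, a running
    median over ``baseline_window_ms`` is subtracted as the local baseline
    (the window is long relative to a single transient so the median is not
    pulled up by the event being measured), and candidate peaks are local
    maxima of the lightly smoothed residual exceeding ``amp_threshold_pA``,
    separated by at least ``refractory_ms``. Consecutive candidates with no
    intervening trough below ``valley_fraction`` of the smaller peak are one
    transient and are collapsed onto the larger peak. Event amplitude is the
    raw baseline-subtracted value at the peak; onset and offset are the
    last/first crossings of ``boundary_fraction`` x peak around it (the
    offset is capped at the next event's onset); the event area is the
    integral of the residual between them in pA·ms. Candidates below either
    threshold are rejected.
    """
    if trace.modality != "voltage-clamp":
        raise ValueError("mini detection requires a voltage-clamp recording")
    if amp_threshold_pA <= 0 or area_threshold_pA_ms <= 0:
        raise ValueError("thresholds must be positive")
    fs = trace.sampling_rate_hz
    x = -trace.values if trace.polarity == "inward" else trace.values.copy()

    w_base = max(3, _ms_to_samples(baseline_window_ms, fs) | 1)  # odd window
    baseline = (
        pd.Series(x).rolling(w_base, center=True, min_periods=1).median().to_numpy()
    )
    d = x - baseline
    w_smooth = max(1, _ms_to_samples(smoothing_ms, fs))
    ds = uniform_filter1d(d, size=w_smooth) if w_smooth > 1 else d

    distance = max(1, _ms_to_samples(refractory_ms, fs))
    candidates, _ = find_peaks(ds, height=amp_threshold_pA, distance=distance)

    # collapse candidates that ride on one transient (no trough between them)
    peaks: list[int] = []
    for p in candidates:
        if peaks:
            prev = peaks[-1]
            valley = float(ds[prev : p + 1].min())
            if valley > valley_fraction * min(ds[prev], ds[p]):
                if ds[p] > ds[prev]:
                    peaks[-1] = int(p)
                continue
        peaks.append(int(p))
    peaks = np.asarray(peaks, dtype=int)

    events: list[MiniEvent] = []
    n = d.size
    for j, p in enumerate(peaks):
        amp = float(d[p])
        if amp < amp_threshold_pA:
            continue
        level = boundary_fraction * ds[p]
        below_left = np.flatnonzero(ds[:p] <= level)
        onset = int(below_left[-1]) if below_left.size else 0
        below_right = np.flatnonzero(ds[p + 1 :] <= level)
        offset = int(p + 1 + below_right[0]) if below_right.size else n - 1
        if j + 1 < len(peaks):
            offset = min(offset, int(peaks[j + 1]))
        area = float(np.trapezoid(d[onset : offset + 1]) / fs * 1000.0)
        if area < area_threshold_pA_ms:
            continue
        events.append(
            MiniEvent(
                peak_time_s=p / fs,
                amplitude_pA=amp,
                area_pA_ms=area,
                onset_s=onset / fs,
                offset_s=offset / fs,
            )
        )
    return events


def mini_stats(events: list[MiniEvent], record_duration_s: float) -> EventSummary:
    """Frequency (Hz) and mean amplitude (pA) of accepted minis."""
    if record_duration_s <= 0:
        raise ValueError("record_duration_s must be positive")
    n = len(events)
    if n == 0:
        return EventSummary(0, 0.0, "events/s")
    return EventSummary(
        n_events=n,
        frequency=n / record_duration_s,
        frequency_unit="events/s",
        mean_amplitude=float(np.mean([ev.amplitude_pA for ev in events])),
    )
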