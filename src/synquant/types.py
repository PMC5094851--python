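"""Shared container types for images, traces, events and gene sets.

All containers are plain dataclasses around numpy arrays / pandas frames so
that they serialize cleanly to the text formats used by :mod:`synquant.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: channel roles recognized in a fluorescence field
CHANNEL_ROLES = ("cellfill", "presynaptic", "postsynaptic")


@dataclass
class FluorescenceField:
    """One imaged neuron: co-registered 2-D channel images plus pixel size.

    Parameters
    ----------
    channels
        Mapping from channel role (``cellfill`` | ``presynaptic`` |
        ``postsynaptic``) to a 2-D non-negative intensity array. All arrays
        must share one shape.
    pixel_size_um
        Lateral pixel size in micrometres per pixel.
    bit_depth
        Acquisition bit depth; intensities must fit ``[0, 2**bit_depth - 1]``.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FluorescenceField requires at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {sorted(shapes)}")
        for role, arr in self.channels.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 2:
                raise ValueError(f"channel {role!r} is not 2-D")
            if arr.min() < 0 or arr.max() > 2**self.bit_depth - 1:
                raise ValueError(
                    f"channel {role!r} intensities outside [0, 2^{self.bit_depth}-1]"
                )
            self.channels[role] = arr
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class ImageGroundTruth:
    """Planted truth accompanying a synthetic fluorescence field."""

    coloc_centers: list[tuple[int, int]]
    pre_only_centers: list[tuple[int, int]]
    post_only_centers: list[tuple[int, int]]
    neuron_mask: np.ndarray
    soma_mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.neuron_mask = np.asarray(self.neuron_mask, dtype=bool)
        self.soma_mask = np.asarray(self.soma_mask, dtype=bool)
        if self.soma_mask.shape != self.neuron_mask.shape:
            raise ValueError("soma/neuron mask shape mismatch")
        if np.any(self.soma_mask & ~self.neuron_mask):
            raise ValueError("soma_mask must be a subset of neuron_mask")
        nr, nc = self.neuron_mask.shape
        for name in ("coloc_centers", "pre_only_centers", "post_only_centers"):
            for r, c in getattr(self, name):
                if not (0 <= r < nr and 0 <= c < nc):
                    raise ValueError(f"{name} contains out-of-bounds center ({r}, {c})")
        for r, c in self.coloc_centers:
            if not self.neuron_mask[r, c]:
                raise ValueError("coloc centers must lie inside the neuron mask")


@dataclass
class RecordingTrace:
    """Uniformly sampled 1-D electrophysiology signal.

    ``values`` are in µV for extracellular records and pA under voltage
    clamp. ``polarity`` only applies to voltage-clamp records and states
    whether synaptic events deflect the trace inward (negative) or outward.
    """

    values: np.ndarray
    sampling_rate_hz: float
    modality: str  # "extracellular" | "voltage-clamp"
    polarity: str | None = None  # "inward" | "outward" (voltage-clamp only)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.modality not in ("extracellular", "voltage-clamp"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "voltage-clamp":
            if self.polarity not in ("inward", "outward"):
                raise ValueError("voltage-clamp traces need polarity inward|outward")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.sampling_rate_hz


@dataclass
class TraceGroundTruth:
    """Planted truth for a synthetic recording.

    Exactly one of ``event_intervals`` (UP-state epochs, in seconds) or
    ``event_times``/``amplitudes_pA`` (minis) is populated.
    """

    sampling_rate_hz: float
    noise_sd: float
    event_intervals: list[tuple[float, float]] = field(default_factory=list)
    event_times: list[float] = field(default_factory=list)
    amplitudes_pA: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        ivals = sorted(self.event_intervals)
        for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError("event intervals overlap")
        for s, e in ivals:
            if e <= s:
                raise ValueError("interval end must exceed start")
        if any(a <= 0 for a in self.amplitudes_pA):
            raise ValueError("mini amplitudes must be positive")
        if len(self.event_times) != len(self.amplitudes_pA):
            raise ValueError("event_times and amplitudes_pA lengths differ")


@dataclass
class UpStateEvent:
    """A segmented epoch of elevated network activity."""

    start_s: float
    end_s: float
    amplitude: float
    truncated: bool = False

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class MiniEvent:
    """A detected miniature postsynaptic current."""

    peak_time_s: float
    amplitude_pA: float
    area_pA_ms: float
    onset_s: float
    offset_s: float


@dataclass
class EventSummary:
    """Per-record event statistics.

    ``frequency`` is events/s for minis and events/min for UP states (the
    field's customary units). Means are ``None`` when no event was accepted.
    """

    n_events: int
    frequency: float
    frequency_unit: str
    mean_amplitude: float | None = None
    mean_duration_s: float | None = None


@dataclass
class GeneSetCollection:
    """Named gene sets over a background universe.

    Symbols are uppercase-normalized and de-duplicated (first occurrence
    wins) at construction time.
    """

    sets: dict[str, list[str]]
    background: list[str]
    expressed_universe: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sets = {name: normalize_symbols(genes) for name, genes in self.sets.items()}
        self.background = normalize_symbols(self.background)
        self.expressed_universe = normalize_symbols(self.expressed_universe)


@dataclass
class UniverseGroundTruth:
    """Planted truth for a synthetic gene universe."""

    background_genes: list[str]
    internal_set: list[str]
    external_set: list[str]
    planted_overlap: int
    enrichment_factor: float

    def __post_init__(self) -> None:
        bg = set(self.background_genes)
        if not set(self.internal_set) <= bg or not set(self.external_set) <= bg:
            raise ValueError("internal/external sets must be subsets of background")
        k = len(set(self.internal_set) & set(self.external_set))
        if k != self.planted_overlap:
            raise ValueError(
                f"planted_overlap={self.planted_overlap} but realized overlap is {k}"
            )


@dataclass
class OverlapResult:
    """Hypergeometric + permutation statistics for one set pair."""

    set_name: str
    n_internal: int
    n_external: int
    n_background: int
    k_overlap: int
    p_hypergeom: float
    p_bh: float | None
    p_perm_external: float | None
    p_perm_internal: float | None
    n_perm: int
    seed: int | None
    warning: str | None = None


def normalize_symbols(symbols: Sequence[str]) -> list[str]:
    """Uppercase gene symbols and drop duplicates, preserving order.

    Idempotent: applying it twice equals applying it once.
    """
    seen: dict[str, None] = {}
    for s in symbols:
        seen.setdefault(str(s).strip().upper(), None)
    seen.pop("", None)
    return list(seen)
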