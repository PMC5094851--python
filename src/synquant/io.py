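"""Readers and writers for the pipeline's text and TIFF formats.

All tabular output is tab-delimited UTF-8 with '.' decimals and a fixed
column order; floats are written at full precision so that write -> read
round-trips losslessly. Images travel as multi-page TIFF (one 16-bit page
per channel, channel roles recorded in the image description); traces as
two-column delimited text with a JSON metadata sidecar; gene sets as GMT;
ground truth as JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    CHANNEL_ROLES,
    FluorescenceField,
    ImageGroundTruth,
    MiniEvent,
    RecordingTrace,
    TraceGroundTruth,
    UniverseGroundTruth,
    UpStateEvent,
)

__all__ = [
    "write_field_tiff",
    "read_tiff",
    "write_trace",
    "read_trace",
    "read_gmt",
    "write_gmt",
    "write_table",
    "read_table",
    "events_to_frame",
    "write_json",
    "read_json",
    "image_truth_to_dict",
    "image_truth_from_dict",
    "trace_truth_to_dict",
    "trace_truth_from_dict",
    "universe_truth_to_dict",
    "universe_truth_from_dict",
]


def write_field_tiff(field: FluorescenceField, path) -> Path:
    """Write one field as a multi-page 16-bit TIFF (one page per channel)."""
    path = Path(path)
    roles = [r for r in CHANNEL_ROLES if r in field.channels] + [
        r for r in field.channels if r not in CHANNEL_ROLES
    ]
    stack = np.stack(
        [np.clip(np.round(field.channels[r]), 0, 2**16 - 1).astype(np.uint16) for r in roles]
    )
    meta = {"roles": roles, "pixel_size_um": field.pixel_size_um, "bit_depth": field.bit_depth}
    tifffile.imwrite(
        path, stack, photometric="minisblack", description=json.dumps(meta)
    )
    return path


def read_tiff(
    path, role_map: dict[str, int] | None = None, pixel_size_um: float | None = None
) -> FluorescenceField:
    """Read a multi-page TIFF back into a :class:`FluorescenceField`.

    Channel roles come from the embedded description written by
    :func:`write_field_tiff`; ``role_map`` (role -> page index) overrides it
    for third-party files. Pages with mismatched shapes fail with the page
    number.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        pages = [p.asarray() for p in tf.pages]
        desc = tf.pages[0].tags.get("ImageDescription")
        meta = {}
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if not pages:
        raise ValueError(f"{path}: TIFF contains no pages")
    shape = pages[0].shape
    for i, p in enumerate(pages):
        if p.shape != shape:
            raise ValueError(f"{path}: page {i} shape {p.shape} != page 0 shape {shape}")
    if role_map is None:
        roles = meta.get("roles")
        if roles is None:
            raise ValueError(f"{path}: no channel-role metadata; supply role_map")
        role_map = {r: i for i, r in enumerate(roles)}
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{path}: no pixel size in metadata; supply pixel_size_um")
    channels = {role: pages[i].astype(float) for role, i in role_map.items()}
    return FluorescenceField(channels=channels, pixel_size_um=float(px),
                             bit_depth=int(meta.get("bit_depth", 16)))


def write_trace(trace: RecordingTrace, path) -> Path:
    """Write a trace as (time_s, value) columns plus a JSON sidecar."""
    path = Path(path)
    t = np.arange(trace.values.size) / trace.sampling_rate_hz
    np.savetxt(path, np.column_stack([t, trace.values]), fmt="%.17g", delimiter="\t")
    sidecar = {
        "sampling_rate_hz": trace.sampling_rate_hz,
        "modality": trace.modality,
        "polarity": trace.polarity,
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_trace(path, sampling_rate_hz: float | None = None,
               modality: str | None = None, polarity: str | None = None) -> RecordingTrace:
    """Read a two-column (time_s, value) trace; metadata from the sidecar.

    Explicit arguments override sidecar values, which allows reading bare
    value files from other tools.
    """
    path = Path(path)
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    fs = sampling_rate_hz or meta.get("sampling_rate_hz")
    if data.shape[1] >= 2:
        values = data[:, 1]
        if fs is None:
            dt = np.diff(data[:, 0])
            if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError(f"{path}: non-uniform time column and no sampling rate given")
            fs = 1.0 / dt[0]
    else:
        values = data[:, 0]
        if fs is None:
            raise ValueError(f"{path}: single-column trace needs a sampling rate")
    return RecordingTrace(
        values=values,
        sampling_rate_hz=float(fs),
        modality=modality or meta.get("modality", "extracellular"),
        polarity=polarity or meta.get("polarity"),
    )


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file: one set per line as name, description, symbols."""
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "") -> Path:
    path = Path(path)
    lines = ["\t".join([name, description, *genes]) for name, genes in sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def write_table(df: pd.DataFrame, path, *, index: bool = False) -> Path:
    """Tab-delimited UTF-8 table with full-precision floats."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_table(path, *, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def events_to_frame(events) -> pd.DataFrame:
    """Events (UP states or minis) as a tidy one-row-per-event table."""
    if not events:
        return pd.DataFrame()
    rows = []
    for ev in events:
        d = asdict(ev)
        if isinstance(ev, UpStateEvent):
            d["duration_s"] = ev.duration_s
        rows.append(d)
    return pd.DataFrame(rows)


def write_json(obj, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=_json_default))
    return path


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _mask_to_rle(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate([[0], changes + 1, [flat.size]])
    runs = np.diff(bounds)
    return {
        "shape": list(mask.shape),
        "first": bool(flat[0]) if flat.size else False,
        "runs": runs.tolist(),
    }


def _mask_from_rle(d: dict) -> np.ndarray:
    vals = []
    v = bool(d["first"])
    for r in d["runs"]:
        vals.append(np.full(int(r), v, dtype=bool))
        v = not v
    flat = np.concatenate(vals) if vals else np.zeros(0, dtype=bool)
    return flat.reshape(d["shape"])


def image_truth_to_dict(t: ImageGroundTruth) -> dict:
    return {
        "coloc_centers": [list(p) for p in t.coloc_centers],
        "pre_only_centers": [list(p) for p in t.pre_only_centers],
        "post_only_centers": [list(p) for p in t.post_only_centers],
        "neuron_mask": _mask_to_rle(t.neuron_mask),
        "soma_mask": _mask_to_rle(t.soma_mask),
        "pixel_size_um": t.pixel_size_um,
    }


def image_truth_from_dict(d: dict) -> ImageGroundTruth:
    return ImageGroundTruth(
        coloc_centers=[tuple(p) for p in d["coloc_centers"]],
        pre_only_centers=[tuple(p) for p in d["pre_only_centers"]],
        post_only_centers=[tuple(p) for p in d["post_only_centers"]],
        neuron_mask=_mask_from_rle(d["neuron_mask"]),
        soma_mask=_mask_from_rle(d["soma_mask"]),
        pixel_size_um=d["pixel_size_um"],
    )


def trace_truth_to_dict(t: TraceGroundTruth) -> dict:
    return {
        "sampling_rate_hz": t.sampling_rate_hz,
        "noise_sd": t.noise_sd,
        "event_intervals": [list(iv) for iv in t.event_intervals],
        "event_times": list(t.event_times),
        "amplitudes_pA": list(t.amplitudes_pA),
    }


def trace_truth_from_dict(d: dict) -> TraceGroundTruth:
    return TraceGroundTruth(
        sampling_rate_hz=d["sampling_rate_hz"],
        noise_sd=d["noise_sd"],
        event_intervals=[tuple(iv) for iv in d["event_intervals"]],
        event_times=d["event_times"],
        amplitudes_pA=d["amplitudes_pA"],
    )


def universe_truth_to_dict(t: UniverseGroundTruth) -> dict:
    return asdict(t)


def universe_truth_from_dict(d: dict) -> UniverseGroundTruth:
    return UniverseGroundTruth(**d)
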