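"""Image quantification: thresholding, triple colocalization, densities, Sholl.

The per-neuron procedure mirrors the field's standard particle-analysis
workflow: each channel of a maximum-intensity projection is thresholded at
its whole-field mean + SD, binarized (strict ``>``), and regions where all
three masks coincide — at least one pixel in size — are counted as
structural synapses. Synapse density is that count divided by the dendritic
(cell fill minus soma) or somatic area, and experiment-level values are
normalized to each experiment's control mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label
from skimage.morphology import opening as binary_opening, disk as disk_selem

from .types import FluorescenceField

__all__ = [
    "ChannelThreshold",
    "SynapseDensityRecord",
    "ShollProfile",
    "max_project",
    "compute_threshold",
    "binarize",
    "triple_colocalize",
    "soma_segment",
    "synapse_density",
    "normalize_densities",
    "sholl_intersections",
    "reporter_ratio",
    "quantify_field",
]


@dataclass(frozen=True)
class ChannelThreshold:
    channel_role: str
    mean: float
    sd: float

    @property
    def threshold(self) -> float:
        return self.mean + self.sd


@dataclass
class SynapseDensityRecord:
    """Per-neuron colocalization count and areas, with derived densities."""

    n_coloc: int
    dendritic_area_um2: float
    soma_area_um2: float
    dendritic_density_per_um2: float
    somatic_density_per_um2: float
    condition_label: str = ""
    experiment_label: str = ""


@dataclass
class ShollProfile:
    center: tuple[int, int]
    radii_um: list[float]
    intersections: list[int]
    clipped: bool = False  # some circles extended beyond the image


def max_project(stack) -> np.ndarray:
    """Maximum-intensity projection of a z-stack (elementwise max)."""
    slices = [np.asarray(s, dtype=float) for s in stack]
    if not slices:
        raise ValueError("stack must contain at least one slice")
    shape = slices[0].shape
    if any(s.shape != shape for s in slices):
        raise ValueError("stack slices have mismatched shapes")
    return np.maximum.reduce(slices)


def compute_threshold(
    channel: np.ndarray, role: str = "", *, sample_sd: bool = False
) -> ChannelThreshold:
    """Per-channel threshold: mean + SD over all pixels of the field.

    Population SD (``ddof=0``) by default, matching histogram-based image
    statistics; set ``sample_sd`` for the n-1 flavor.
    """
    arr = np.asarray(channel, dtype=float)
    if arr.size == 0:
        raise ValueError("channel is empty")
    return ChannelThreshold(
        channel_role=role,
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1 if sample_sd else 0)),
    )


def binarize(channel: np.ndarray, threshold: float) -> np.ndarray:
    """Mask of pixels strictly above the threshold."""
    thr = threshold.threshold if isinstance(threshold, ChannelThreshold) else threshold
    return np.asarray(channel, dtype=float) > thr


def triple_colocalize(
    cellfill_mask: np.ndarray,
    pre_mask: np.ndarray,
    post_mask: np.ndarray,
    *,
    connectivity: int = 2,
) -> tuple[np.ndarray, int]:
    """Connected components of the three-way mask intersection.

    Every component of size >= 1 px counts as one colocalization region.
    ``connectivity`` follows scikit-image (2 = 8-connected, the default of
    the original macro environment; 1 = 4-connected).
    """
    masks = [np.asarray(m, dtype=bool) for m in (cellfill_mask, pre_mask, post_mask)]
    if len({m.shape for m in masks}) != 1:
        raise ValueError("masks have mismatched shapes")
    overlap = masks[0] & masks[1] & masks[2]
    labels, n = cc_label(overlap, connectivity=connectivity, return_num=True)
    return labels, int(n)


def soma_segment(cellfill_mask: np.ndarray, opening_radius_px: int = 5) -> np.ndarray:
    """Heuristic cell-body mask: largest component surviving a disc opening.

    Morphological opening with a disc of ``opening_radius_px`` strips thin
    dendrites; the largest surviving component is taken as the soma. Radius 0
    returns the mask unchanged. When a manually drawn or ground-truth soma
    mask exists it should be used verbatim instead of this heuristic.
    """
    mask = np.asarray(cellfill_mask, dtype=bool)
    if not mask.any():
        raise ValueError("cell-fill mask is empty")
    if opening_radius_px == 0:
        return mask
    opened = binary_opening(mask, disk_selem(opening_radius_px))
    labels, n = cc_label(opened, connectivity=2, return_num=True)
    if n == 0:
        raise ValueError(
            "opening removed the whole mask; retry with a smaller opening_radius_px"
        )
    sizes = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(sizes)) + 1)


def synapse_density(
    count: int,
    cellfill_mask: np.ndarray,
    soma_mask: np.ndarray,
    pixel_size_um: float,
    mode: str = "dendritic",
) -> float:
    """Synapse count divided by the mode-appropriate area in µm².

    ``dendritic`` uses the cell-fill mask minus the cell body; ``somatic``
    uses the cell-body mask alone.
    """
    cellfill_mask = np.asarray(cellfill_mask, dtype=bool)
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if np.any(soma_mask & ~cellfill_mask):
        raise ValueError("soma mask must be a subset of the cell-fill mask")
    if mode == "dendritic":
        n_px = int(np.count_nonzero(cellfill_mask & ~soma_mask))
    elif mode == "somatic":
        n_px = int(np.count_nonzero(soma_mask))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    area = n_px * pixel_size_um**2
    if area <= 0:
        raise ValueError(f"{mode} area is zero; cannot form a density")
    return count / area


def normalize_densities(
    records: pd.DataFrame,
    control_label: str,
    *,
    value_column: str = "dendritic_density_per_um2",
) -> pd.DataFrame:
    """Per-experiment normalization of condition means to the control mean.

    ``records`` needs columns ``experiment_label``, ``condition_label`` and
    ``value_column``. Within each experiment the mean value of every
    condition is divided by that experiment's control mean, so the control
    normalizes to 1 by construction. This cancels experiment-to-experiment
    variation in staining intensity and neuron density.
    """
    required = {"experiment_label", "condition_label", value_column}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rows = []
    for exp, grp in records.groupby("experiment_label", sort=True):
        ctrl = grp.loc[grp["condition_label"] == control_label, value_column]
        if ctrl.empty:
            raise ValueError(f"experiment {exp!r} has no {control_label!r} records")
        ctrl_mean = float(ctrl.mean())
        if ctrl_mean == 0:
            raise ValueError(f"experiment {exp!r} has zero control mean")
        for cond, sub in grp.groupby("condition_label", sort=True):
            rows.append(
                {
                    "experiment_label": exp,
                    "condition_label": cond,
                    "mean_density": float(sub[value_column].mean()),
                    "normalized": float(sub[value_column].mean()) / ctrl_mean,
                    "n_fields": int(len(sub)),
                }
            )
    return pd.DataFrame(rows)


def _circle_perimeter_by_angle(
    center: tuple[int, int], radius_px: float
) -> np.ndarray:
    """Integer pixels of a 1-px-wide circle, ordered by angle.

    Midpoint-style rasterization: for a dense sweep of angles take the
    nearest pixel, then drop consecutive duplicates. Ordering by angle means
    consecutive entries are spatial neighbors, so runs along the array are
    connected arcs of the circle.
    """
    n = max(int(np.ceil(2 * np.pi * radius_px * 4)), 16)
    theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = np.round(center[0] + radius_px * np.sin(theta)).astype(int)
    cc = np.round(center[1] + radius_px * np.cos(theta)).astype(int)
    pts = np.column_stack([rr, cc])
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(pts[1:] != pts[:-1], axis=1)
    pts = pts[keep]
    if len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    return pts


def sholl_intersections(
    skeleton: np.ndarray,
    center: tuple[int, int],
    *,
    n_circles: int = 11,
    spacing_um: float = 10.0,
    pixel_size_um: float = 1.0,
) -> ShollProfile:
    """Count dendrite crossings of concentric circles around the soma.

    Circles are rasterized at 1-px line width; the intersection count per
    circle is the number of connected runs of skeleton pixels lying on it
    (with circular wrap-around). Default geometry: 11 circles spaced 10 µm
    apart. Circles extending beyond the image are counted over the in-image
    arc and flagged via ``clipped``.
    """
    skel = np.asarray(skeleton, dtype=bool)
    nr, nc = skel.shape
    if not (0 <= center[0] < nr and 0 <= center[1] < nc):
        raise ValueError("center must lie inside the image")
    radii_um = [spacing_um * (i + 1) for i in range(n_circles)]
    counts: list[int] = []
    clipped = False
    for radius_um in radii_um:
        pts = _circle_perimeter_by_angle(center, radius_um / pixel_size_um)
        inb = (pts[:, 0] >= 0) & (pts[:, 0] < nr) & (pts[:, 1] >= 0) & (pts[:, 1] < nc)
        if not inb.all():
            clipped = True
        hits = np.zeros(len(pts), dtype=bool)
        hits[inb] = skel[pts[inb, 0], pts[inb, 1]]
        if hits.all():
            counts.append(1 if len(hits) else 0)
            continue
        starts = int(np.sum(hits & ~np.roll(hits, 1)))
        counts.append(starts)
    return ShollProfile(
        center=tuple(center), radii_um=radii_um, intersections=counts, clipped=clipped
    )


def reporter_ratio(signal: float, reference: float):
    """Reporter activity normalized to a co-expressed reference (signal/reference)."""
    signal = np.asarray(signal, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if np.any(reference <= 0):
        raise ValueError("reference must be strictly positive")
    out = signal / reference
    return float(out) if out.ndim == 0 else out


def score_detection(
    labels: np.ndarray,
    n_regions: int,
    true_centers,
    radius_px: int = 3,
) -> dict[str, float]:
    """Match detected colocalization regions to planted puncta centers.

    A planted center is recovered when a labeled region lies within
    ``radius_px`` of it; a region is a true positive when it matches at least
    one center. Returns recall, precision and the raw counts.
    """
    matched: set[int] = set()
    hits = 0
    nr, nc = labels.shape
    for r, c in true_centers:
        window = labels[max(r - radius_px, 0) : r + radius_px + 1,
                        max(c - radius_px, 0) : c + radius_px + 1]
        vals = window[window > 0]
        if vals.size:
            hits += 1
            matched.update(int(v) for v in np.unique(vals))
    n_true = len(list(true_centers))
    return {
        "n_true": n_true,
        "n_detected": n_regions,
        "n_recovered": hits,
        "n_matched_regions": len(matched),
        "recall": hits / n_true if n_true else 1.0,
        "precision": len(matched) / n_regions if n_regions else 1.0,
    }


def quantify_field(
    field: FluorescenceField,
    *,
    soma_mask: np.ndarray | None = None,
    opening_radius_px: int = 5,
    connectivity: int = 2,
    sample_sd: bool = False,
    condition_label: str = "",
    experiment_label: str = "",
) -> tuple[SynapseDensityRecord, dict[str, ChannelThreshold]]:
    """Full per-neuron quantification of one three-channel field.

    Thresholds each channel at mean + SD, counts triple-colocalized regions,
    segments the cell body (or uses ``soma_mask`` verbatim when supplied) and
    reports dendritic and somatic synapse densities per µm².
    """
    thresholds = {
        role: compute_threshold(img, role, sample_sd=sample_sd)
        for role, img in field.channels.items()
    }
    masks = {
        role: binarize(field.channels[role], thresholds[role]) for role in field.channels
    }
    _, n_coloc = triple_colocalize(
        masks["cellfill"], masks["presynaptic"], masks["postsynaptic"],
        connectivity=connectivity,
    )
    cellfill = masks["cellfill"]
    if soma_mask is None:
        soma = soma_segment(cellfill, opening_radius_px) & cellfill
    else:
        soma = np.asarray(soma_mask, dtype=bool) & cellfill
    px_area = field.pixel_size_um**2
    dend_px = int(np.count_nonzero(cellfill & ~soma))
    soma_px = int(np.count_nonzero(soma))
    record = SynapseDensityRecord(
        n_coloc=n_coloc,
        dendritic_area_um2=dend_px * px_area,
        soma_area_um2=soma_px * px_area,
        dendritic_density_per_um2=n_coloc / (dend_px * px_area) if dend_px else float("nan"),
        somatic_density_per_um2=n_coloc / (soma_px * px_area) if soma_px else float("nan"),
        condition_label=condition_label,
        experiment_label=experiment_label,
    )
    return record, thresholds
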