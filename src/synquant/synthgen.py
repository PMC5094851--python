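"""Synthetic ground-truth generators for every pipeline input.

The generators emulate the four kinds of raw data the analysis stages
consume: (i) a GFP-filled cortical neuron with partially colocalized
pre-/postsynaptic puncta channels, (ii) extracellular records carrying
discrete elevated-activity epochs in noise, (iii) voltage-clamp records with
Poisson-timed biexponential miniature synaptic currents, and (iv) gene
universes with planted set overlaps plus negative-binomial count matrices
with planted fold changes. Every generator is a pure function of its
parameters and ``seed`` (no global RNG state) and returns a machine-readable
ground-truth object alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.morphology import dilation as binary_dilation, disk as disk_selem

from .types import (
    FluorescenceField,
    GeneSetCollection,
    ImageGroundTruth,
    RecordingTrace,
    TraceGroundTruth,
    UniverseGroundTruth,
)

__all__ = [
    "NeuronGeometry",
    "PackingError",
    "gen_synapse_image",
    "gen_lfp_trace",
    "gen_mini_trace",
    "gen_gene_universe",
    "gen_count_matrix",
]


class PackingError(ValueError):
    """Requested puncta cannot be placed within the packing tolerance."""


@dataclass(frozen=True)
class NeuronGeometry:
    """Simple neuron shape: a filled soma disc plus straight dendrites.

    Defaults: soma radius 10 px, 4-6 branches of 3 px width radiating from
    the soma — deliberately minimal, but sufficient for density and Sholl
    quantification.
    """

    soma_radius_px: int = 10
    n_branches: int | None = None  # None -> drawn uniformly from [4, 6]
    branch_half_width_px: int = 1  # 3 px total width
    branch_length_px: tuple[int, int] = (60, 110)


def _build_neuron_mask(
    shape: tuple[int, int], geometry: NeuronGeometry, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    nr, nc = shape
    center = (nr // 2, nc // 2)
    soma = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk(center, geometry.soma_radius_px, shape=shape)
    soma[rr, cc] = True

    n_branches = geometry.n_branches
    if n_branches is None:
        n_branches = int(rng.integers(4, 7))
    if n_branches < 1:
        raise ValueError("geometry must yield at least one dendrite branch")

    # evenly spread base angles with random jitter keeps branches distinct
    base = rng.uniform(0, 2 * math.pi)
    angles = base + np.arange(n_branches) * 2 * math.pi / n_branches
    angles = angles + rng.uniform(-0.25, 0.25, size=n_branches)

    branch_lines = np.zeros(shape, dtype=bool)
    lo, hi = geometry.branch_length_px
    margin = 3
    for ang in angles:
        length = rng.uniform(lo, hi)
        r1 = int(round(center[0] + length * math.sin(ang)))
        c1 = int(round(center[1] + length * math.cos(ang)))
        r1 = min(max(r1, margin), nr - 1 - margin)
        c1 = min(max(c1, margin), nc - 1 - margin)
        rr, cc = draw_line(center[0], center[1], r1, c1)
        branch_lines[rr, cc] = True
    branches = binary_dilation(branch_lines, disk_selem(geometry.branch_half_width_px))
    return soma | branches, soma, center


def _sample_separated(
    candidates: np.ndarray,
    n: int,
    min_separation_px: float,
    rng: np.random.Generator,
    existing: np.ndarray | None = None,
) -> np.ndarray:
    """Greedily pick ``n`` points from ``candidates`` with pairwise spacing."""
    if n == 0:
        return np.empty((0, 2), dtype=int)
    order = rng.permutation(len(candidates))
    accepted: list[np.ndarray] = []
    anchor = [] if existing is None else [existing]
    min_sq = min_separation_px**2
    for idx in order:
        p = candidates[idx]
        blocks = anchor + [np.asarray(accepted)] if accepted else anchor
        ok = True
        for block in blocks:
            if len(block) and np.min(np.sum((block - p) ** 2, axis=1)) < min_sq:
                ok = False
                break
        if ok:
            accepted.append(p)
            if len(accepted) == n:
                return np.asarray(accepted, dtype=int)
    raise PackingError(
        f"could only place {len(accepted)}/{n} puncta at "
        f"min separation {min_separation_px} px; reduce counts or separation"
    )


def _render_spots(
    shape: tuple[int, int],
    centers: np.ndarray,
    peak: float,
    psf_sigma_px: float,
) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    if len(centers):
        amp = peak * 2 * math.pi * max(psf_sigma_px, 1e-12) ** 2
        np.add.at(img, (centers[:, 0], centers[:, 1]), amp)
    if psf_sigma_px > 0:
        img = gaussian_filter(img, psf_sigma_px, truncate=4.0)
    elif len(centers):
        # degenerate PSF: keep single-pixel spots at the requested peak
        img[img > 0] = peak
    return img


def gen_synapse_image(
    n_coloc: int,
    n_pre_only: int = 0,
    n_post_only: int = 0,
    *,
    shape: tuple[int, int] = (256, 256),
    geometry: NeuronGeometry | None = None,
    psf_sigma_px: float = 1.5,
    peak_intensity: float = 500.0,
    fill_intensity: float = 1500.0,
    baseline: float = 200.0,
    noise_sd: float = 0.0,
    n_distractors: int = 500,
    pixel_size_um: float = 0.5,
    min_separation_px: float = 8.0,
    geometry_seed: int | None = None,
    seed: int = 0,
) -> tuple[FluorescenceField, ImageGroundTruth]:
    """Simulate one immunostained, GFP-filled neuron.

    ``geometry_seed``, when given, draws the neuron shape from its own RNG so
    that paired conditions can share identical morphology (and hence areas)
    while puncta placement and noise still vary with ``seed``.

    Three co-registered channels are produced: a cell fill (``cellfill``), a
    presynaptic marker and a postsynaptic marker. ``n_coloc`` puncta appear
    at identical coordinates in both marker channels inside the neuron mask
    (true synapses); ``n_pre_only``/``n_post_only`` puncta appear on the
    neuron in a single channel. ``n_distractors`` additional puncta per
    marker channel — staining of synapses on unlabeled neighboring neurons —
    are scattered off the cell; they dominate the channel histogram exactly
    as dense neuropil staining does in real fields, which is what makes a
    mean+SD threshold sit well above the noise floor.

    Puncta are Gaussian spots (``psf_sigma_px``) of peak ``peak_intensity``
    on a camera ``baseline`` offset, with optional additive Gaussian noise;
    intensities are quantized to the integer ADC grid and clipped to the
    16-bit range. On-cell puncta are placed with a pairwise spacing of
    ``min_separation_px``; a :class:`PackingError` is raised when the
    requested counts do not fit.
    """
    if min(n_coloc, n_pre_only, n_post_only, n_distractors) < 0:
        raise ValueError("puncta counts must be non-negative")
    if psf_sigma_px < 0 or noise_sd < 0:
        raise ValueError("psf_sigma_px and noise_sd must be non-negative")
    geometry = geometry or NeuronGeometry()
    rng = np.random.default_rng(seed)
    geom_rng = np.random.default_rng(geometry_seed) if geometry_seed is not None else rng

    neuron_mask, soma_mask, _ = _build_neuron_mask(shape, geometry, geom_rng)

    on_cell = np.argwhere(neuron_mask)
    n_on = n_coloc + n_pre_only + n_post_only
    placed = _sample_separated(on_cell, n_on, min_separation_px, rng)
    coloc = placed[:n_coloc]
    pre_only = placed[n_coloc : n_coloc + n_pre_only]
    post_only = placed[n_coloc + n_pre_only :]

    # distractors live strictly off the cell so they can never triple-colocalize
    off_margin = max(4, int(math.ceil(min_separation_px / 2)))
    off_cell = np.argwhere(~binary_dilation(neuron_mask, disk_selem(off_margin)))
    if len(off_cell) == 0 and n_distractors > 0:
        raise PackingError("no off-cell area available for distractor puncta")
    pre_distr = off_cell[rng.integers(0, len(off_cell), size=n_distractors)]
    post_distr = off_cell[rng.integers(0, len(off_cell), size=n_distractors)]

    pre_img = _render_spots(
        shape, np.vstack([coloc, pre_only, pre_distr]), peak_intensity, psf_sigma_px
    )
    post_img = _render_spots(
        shape, np.vstack([coloc, post_only, post_distr]), peak_intensity, psf_sigma_px
    )
    fill_img = fill_intensity * neuron_mask.astype(float)
    if psf_sigma_px > 0:
        fill_img = gaussian_filter(fill_img, psf_sigma_px, truncate=4.0)

    channels = {}
    for role, img in (
        ("cellfill", fill_img),
        ("presynaptic", pre_img),
        ("postsynaptic", post_img),
    ):
        img = img + baseline
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=shape)
        channels[role] = np.clip(np.round(img), 0, 2**16 - 1)

    field = FluorescenceField(channels=channels, pixel_size_um=pixel_size_um)
    truth = ImageGroundTruth(
        coloc_centers=[tuple(map(int, p)) for p in coloc],
        pre_only_centers=[tuple(map(int, p)) for p in pre_only],
        post_only_centers=[tuple(map(int, p)) for p in post_only],
        neuron_mask=neuron_mask,
        soma_mask=soma_mask,
        pixel_size_um=pixel_size_um,
    )
    return field, truth


def _place_intervals(
    duration_s: float,
    n_events: int,
    event_duration_s: float,
    min_gap_s: float,
    edge_s: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    slack = duration_s - 2 * edge_s - n_events * event_duration_s - (n_events - 1) * min_gap_s
    if slack < 0:
        raise ValueError("requested events do not fit in the record")
    extra = rng.dirichlet(np.ones(n_events + 1)) * slack
    intervals = []
    t = edge_s + extra[0]
    for i in range(n_events):
        intervals.append((t, t + event_duration_s))
        t += event_duration_s + min_gap_s + extra[i + 1]
    return intervals


def gen_lfp_trace(
    duration_s: float,
    *,
    event_intervals: list[tuple[float, float]] | None = None,
    n_events: int | None = None,
    event_duration_s: float = 1.0,
    min_gap_s: float = 2.0,
    event_amplitude: float = 5.0,
    noise_sd: float = 1.0,
    sampling_rate_hz: float = 2500.0,
    lowpass_hz: float = 100.0,
    seed: int = 0,
) -> tuple[RecordingTrace, TraceGroundTruth]:
    """Simulate an extracellular record with elevated-activity epochs.

    Epochs are specified either explicitly (``event_intervals``, seconds) or
    by count: ``n_events`` epochs of ``event_duration_s`` placed at random
    with gaps of at least ``min_gap_s``. Inside each epoch the trace carries
    band-limited activity — white noise low-pass filtered at ``lowpass_hz``
    and rescaled so its RMS equals ``event_amplitude`` — added on top of the
    broadband baseline noise (``noise_sd`` RMS) that spans the whole record.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    rng = np.random.default_rng(seed)
    if event_intervals is None:
        if n_events:
            event_intervals = _place_intervals(
                duration_s, n_events, event_duration_s, min_gap_s, 0.2, rng
            )
        else:
            event_intervals = []
    event_intervals = sorted((float(s), float(e)) for s, e in event_intervals)
    prev_end = 0.0
    for s, e in event_intervals:
        if s < prev_end:
            raise ValueError("event intervals overlap")
        if s < 0 or e > duration_s or e <= s:
            raise ValueError("event intervals must lie within the record")
        prev_end = e

    n = int(round(duration_s * sampling_rate_hz))
    values = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)

    sos = None
    if lowpass_hz and lowpass_hz < sampling_rate_hz / 2:
        sos = sps.butter(4, lowpass_hz, btype="low", fs=sampling_rate_hz, output="sos")
    for s, e in event_intervals:
        i0, i1 = int(round(s * sampling_rate_hz)), int(round(e * sampling_rate_hz))
        if i1 <= i0:
            continue
        burst = rng.normal(0.0, 1.0, size=i1 - i0)
        if sos is not None:
            burst = sps.sosfiltfilt(sos, burst)
        rms = float(np.sqrt(np.mean(burst**2)))
        if rms > 0:
            burst = burst * (event_amplitude / rms)
        values[i0:i1] += burst

    trace = RecordingTrace(values, sampling_rate_hz, "extracellular")
    truth = TraceGroundTruth(
        sampling_rate_hz=sampling_rate_hz, noise_sd=noise_sd, event_intervals=event_intervals
    )
    return trace, truth


def biexp_kernel(
    tau_rise_ms: float, tau_decay_ms: float, sampling_rate_hz: float
) -> np.ndarray:
    """Unit-peak biexponential transient sampled on the trace grid."""
    if tau_rise_ms <= 0 or tau_decay_ms <= 0:
        raise ValueError("time constants must be positive")
    if tau_rise_ms >= tau_decay_ms:
        raise ValueError("tau_rise must be smaller than tau_decay (degenerate kinetics)")
    tr, td = tau_rise_ms / 1000.0, tau_decay_ms / 1000.0
    t_end = td * 8
    t = np.arange(0, t_end, 1.0 / sampling_rate_hz)
    k = np.exp(-t / td) - np.exp(-t / tr)
    t_peak = tr * td / (td - tr) * math.log(td / tr)
    k_peak = math.exp(-t_peak / td) - math.exp(-t_peak / tr)
    return k / k_peak


def _draw_amplitudes(
    spec: tuple, n: int, rng: np.random.Generator
) -> np.ndarray:
    kind = spec[0]
    if kind == "constant":
        amps = np.full(n, float(spec[1]))
    elif kind == "normal":
        mean, sd = float(spec[1]), float(spec[2])
        amps = rng.normal(mean, sd, size=n)
        while np.any(amps <= 0):  # resample to keep amplitudes strictly positive
            bad = amps <= 0
            amps[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    elif kind == "lognormal":
        amps = rng.lognormal(float(spec[1]), float(spec[2]), size=n)
    else:
        raise ValueError(f"unknown amplitude distribution {kind!r}")
    if np.any(amps <= 0):
        raise ValueError("amplitudes must be strictly positive")
    return amps


def gen_mini_trace(
    duration_s: float,
    rate_hz: float,
    *,
    amp_distribution: tuple = ("normal", 20.0, 3.0),
    tau_rise_ms: float = 1.0,
    tau_decay_ms: float = 8.0,
    polarity: str = "inward",
    noise_sd_pA: float = 0.0,
    sampling_rate_hz: float = 10000.0,
    seed: int = 0,
) -> tuple[RecordingTrace, TraceGroundTruth]:
    """Simulate a voltage-clamp record with miniature synaptic currents.

    Event times follow a homogeneous Poisson process at ``rate_hz``; each
    event is a biexponential transient whose peak magnitude is drawn from
    ``amp_distribution`` (``("constant", a)``, ``("normal", mean, sd)``
    truncated to positive, or ``("lognormal", mu, sigma)``). Default polarity
    is inward (negative deflection), as for currents recorded at -70 mV.
    """
    if duration_s <= 0 or rate_hz < 0:
        raise ValueError("duration_s must be positive and rate_hz non-negative")
    if polarity not in ("inward", "outward"):
        raise ValueError("polarity must be 'inward' or 'outward'")
    rng = np.random.default_rng(seed)
    kernel = biexp_kernel(tau_rise_ms, tau_decay_ms, sampling_rate_hz)

    n_samples = int(round(duration_s * sampling_rate_hz))
    n_events = rng.poisson(rate_hz * duration_s)
    times = np.sort(rng.uniform(0.0, duration_s, size=n_events))
    amps = _draw_amplitudes(amp_distribution, n_events, rng)

    values = np.zeros(n_samples)
    for t, a in zip(times, amps):
        i0 = int(round(t * sampling_rate_hz))
        seg = kernel[: n_samples - i0]
        values[i0 : i0 + len(seg)] += a * seg
    if polarity == "inward":
        values = -values
    if noise_sd_pA > 0:
        values = values + rng.normal(0.0, noise_sd_pA, size=n_samples)

    trace = RecordingTrace(values, sampling_rate_hz, "voltage-clamp", polarity=polarity)
    truth = TraceGroundTruth(
        sampling_rate_hz=sampling_rate_hz,
        noise_sd=noise_sd_pA,
        event_times=[float(t) for t in times],
        amplitudes_pA=[float(a) for a in amps],
    )
    return trace, truth


def gen_gene_universe(
    n_background: int,
    n_internal: int,
    n_external: int,
    enrichment_factor: float = 1.0,
    seed: int = 0,
) -> tuple[GeneSetCollection, UniverseGroundTruth]:
    """Simulate a gene universe with a planted internal/external overlap.

    ``enrichment_factor`` scales the expected overlap relative to the
    hypergeometric expectation ``n_internal * n_external / n_background``.
    At exactly 1 the external set is drawn uniformly from the background (a
    pure hypergeometric null); otherwise ``enrichment_factor * expectation``
    genes (stochastically rounded) are planted in the intersection.
    """
    if not (0 <= n_internal <= n_background and 0 <= n_external <= n_background):
        raise ValueError("set sizes must be within the background size")
    if enrichment_factor < 0:
        raise ValueError("enrichment_factor must be non-negative")
    rng = np.random.default_rng(seed)
    background = [f"G{i:06d}" for i in range(n_background)]
    bg_arr = np.asarray(background, dtype=object)
    internal = list(rng.choice(bg_arr, size=n_internal, replace=False))

    if enrichment_factor == 1.0:
        external = list(rng.choice(bg_arr, size=n_external, replace=False))
    else:
        expected = enrichment_factor * n_internal * n_external / max(n_background, 1)
        if expected > min(n_internal, n_external) + 1e-9:
            raise ValueError(
                f"requested expected overlap {expected:.2f} exceeds "
                f"min(set sizes) = {min(n_internal, n_external)}"
            )
        k = int(math.floor(expected))
        k += int(rng.random() < expected - k)
        k = min(k, n_internal, n_external)
        overlap = rng.choice(np.asarray(internal, dtype=object), size=k, replace=False)
        rest_pool = np.asarray(sorted(set(background) - set(internal)), dtype=object)
        if n_external - k > len(rest_pool):
            raise ValueError("background too small for the requested external set")
        rest = rng.choice(rest_pool, size=n_external - k, replace=False)
        external = list(overlap) + list(rest)

    truth = UniverseGroundTruth(
        background_genes=background,
        internal_set=list(internal),
        external_set=list(external),
        planted_overlap=len(set(internal) & set(external)),
        enrichment_factor=enrichment_factor,
    )
    collection = GeneSetCollection(
        sets={"internal": list(internal), "external": list(external)},
        background=background,
        expressed_universe=background,
    )
    return collection, truth


def gen_count_matrix(
    n_genes: int,
    n_per_group: int,
    *,
    gene_lengths: np.ndarray | None = None,
    dispersion: float = 0.1,
    planted_lfc: np.ndarray | None = None,
    baseline_mean: float = 100.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Simulate a two-group RNA-seq count matrix with planted fold changes.

    Counts are negative-binomial with mean proportional to gene length
    (so length-normalized expression is flat at ``baseline_mean`` per kb in
    the control group) and variance ``mu + dispersion * mu**2``; dispersion
    below 1e-8 falls back to Poisson. Returns ``(counts, truth, group_labels)``
    where ``counts`` has a ``length_bp`` column plus one column per sample,
    and ``truth`` records the planted log2 fold changes.
    """
    if n_genes <= 0 or n_per_group <= 0 or baseline_mean <= 0 or dispersion < 0:
        raise ValueError("all generator parameters must be positive")
    rng = np.random.default_rng(seed)
    if gene_lengths is None:
        gene_lengths = rng.integers(500, 5001, size=n_genes).astype(float)
    gene_lengths = np.asarray(gene_lengths, dtype=float)
    if planted_lfc is None:
        planted_lfc = np.zeros(n_genes)
    planted_lfc = np.asarray(planted_lfc, dtype=float)
    if len(planted_lfc) != n_genes or len(gene_lengths) != n_genes:
        raise ValueError("gene_lengths and planted_lfc must have length n_genes")

    genes = [f"G{i:06d}" for i in range(n_genes)]
    mu_ctrl = baseline_mean * gene_lengths / 1000.0
    mu_trt = mu_ctrl * 2.0**planted_lfc

    def _sample(mu: np.ndarray) -> np.ndarray:
        if dispersion <= 1e-8:
            return rng.poisson(mu)
        size = 1.0 / dispersion
        p = size / (size + mu)
        return rng.negative_binomial(size, p)

    data: dict[str, np.ndarray] = {"length_bp": gene_lengths}
    labels: list[str] = []
    for i in range(n_per_group):
        data[f"control_{i + 1}"] = _sample(mu_ctrl)
        labels.append("control")
    for i in range(n_per_group):
        data[f"treatment_{i + 1}"] = _sample(mu_trt)
        labels.append("treatment")

    counts = pd.DataFrame(data, index=pd.Index(genes, name="gene"))
    truth = pd.DataFrame(
        {
            "length_bp": gene_lengths,
            "true_log2fc": planted_lfc,
            "baseline_mean_per_kb": baseline_mean,
        },
        index=pd.Index(genes, name="gene"),
    )
    return counts, truth, labels
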