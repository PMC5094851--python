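"""Ground-truth recovery benchmarks for every pipeline stage.

Each function runs a self-contained validation experiment on synthetic data
with known truth — detector-vs-oracle agreement, planted-event recovery,
analytic cross-checks — and returns its metrics as a plain dict. They back
both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools

import numpy as np

from . import ephys, genesets, puncta, synthgen
from .reference import hypergeom_tail_enumeration, segment_envelope_reference

__all__ = [
    "upstate_rule_agreement",
    "upstate_recovery",
    "mini_recovery_noise_free",
    "mini_recovery_noisy",
    "puncta_recovery",
    "hypergeom_enumeration_check",
    "permutation_convergence",
    "permutation_floor",
    "density_ratio_recovery",
]


def upstate_rule_agreement(n_envelopes: int = 1000, seed: int = 0) -> dict:
    """Compare the vectorized UP-state segmenter against the per-sample
    state machine on random block-structured envelopes, plus four
    constructed edge cases of the 100 ms / 600 ms rules (1 kHz grid)."""
    rng = np.random.default_rng(seed)
    fs = 1000.0
    agree = 0
    for _ in range(n_envelopes):
        n_blocks = int(rng.integers(2, 12))
        lens = rng.integers(20, 900, size=n_blocks)
        levels = rng.random(n_blocks)
        env = np.concatenate([np.full(l, v) for l, v in zip(lens, levels)])
        thr = float(rng.uniform(0.2, 0.8))
        got = [
            (round(ev.start_s * fs), round(ev.end_s * fs))
            for ev in ephys.segment_envelope(env, fs, thr)
        ]
        agree += got == segment_envelope_reference(env, fs, thr)

    def n_events(spans, total=5000):
        env = np.zeros(total)
        for s, e in spans:
            env[s:e] = 1.0
        return len(ephys.segment_envelope(env, fs, 0.5))

    edge_results = [
        n_events([(1000, 1080)]) == 0,           # 80 ms run: too short
        n_events([(1000, 1150)]) == 1,           # 150 ms run: one event
        n_events([(1000, 1200), (1500, 1700)]) == 1,   # 300 ms gap: merged
        n_events([(1000, 1200), (1900, 2100)]) == 2,   # 700 ms gap: separate
    ]
    return {
        "n_envelopes": n_envelopes,
        "agreement_fraction": agree / n_envelopes,
        "edge_cases_passed": int(sum(edge_results)),
        "edge_cases_total": len(edge_results),
    }


def upstate_recovery(seed: int = 0, n_records: int = 5) -> dict:
    """Planted-epoch recovery on records at SNR 5 (amplitude 5x noise)."""
    n_found = 0
    n_planted = 0
    dur_errs = []
    for i in range(n_records):
        trace, truth = synthgen.gen_lfp_trace(
            60.0, n_events=5, event_amplitude=5.0, noise_sd=1.0, seed=seed + i
        )
        events = ephys.detect_up_states(trace)
        n_found += len(events)
        n_planted += len(truth.event_intervals)
        planted_mean = np.mean([e - s for s, e in truth.event_intervals])
        detected_mean = np.mean([ev.duration_s for ev in events]) if events else np.nan
        dur_errs.append(abs(detected_mean - planted_mean) / planted_mean)
    return {
        "n_planted": n_planted,
        "n_detected": n_found,
        "mean_duration_error_fraction": float(np.mean(dur_errs)),
    }


def _isolated(times, gap_s: float) -> np.ndarray:
    """Indices of events whose nearest neighbor is at least ``gap_s`` away."""
    t = np.asarray(times)
    keep = np.ones(t.size, dtype=bool)
    if t.size > 1:
        gaps_prev = np.diff(t)
        keep[1:] &= gaps_prev >= gap_s
        keep[:-1] &= gaps_prev >= gap_s
    return np.flatnonzero(keep)


def mini_recovery_noise_free(seed: int = 0, duration_s: float = 120.0) -> dict:
    """Noise-free recovery: every isolated planted 20 pA event found with its
    amplitude within 5%, every detection near a planted event, and sub-7 pA
    events always rejected.

    Per-event amplitude accuracy is assessed on events whose nearest neighbor
    is >= 50 ms away — superposed Poisson coincidences form one compound
    transient and carry no single well-defined amplitude.
    """
    trace, truth = synthgen.gen_mini_trace(
        duration_s, 1.0, amp_distribution=("constant", 20.0), seed=seed
    )
    events = ephys.detect_minis(trace)
    det_t = np.array([ev.peak_time_s for ev in events])
    det_a = np.array([ev.amplitude_pA for ev in events])
    true_t = np.asarray(truth.event_times)

    iso = _isolated(true_t, 0.05)
    amp_errs = []
    hits = 0
    for i in iso:
        d = np.abs(det_t - true_t[i])
        if d.size and d.min() <= 0.01:
            hits += 1
            amp_errs.append(abs(det_a[int(np.argmin(d))] - 20.0) / 20.0)
    # every detection must sit on some planted event (no spurious events)
    true_pos = sum(1 for t in det_t if np.abs(true_t - t).min() <= 0.02)

    sub_trace, sub_truth = synthgen.gen_mini_trace(
        duration_s, 0.5, amp_distribution=("constant", 6.0), seed=seed + 1
    )
    sub_detected = len(ephys.detect_minis(sub_trace))
    return {
        "n_planted": len(truth.event_times),
        "n_isolated": int(iso.size),
        "n_detected": len(events),
        "recall": hits / iso.size if iso.size else 1.0,
        "precision": true_pos / len(events) if events else 1.0,
        "max_amplitude_error_fraction": float(np.max(amp_errs)) if amp_errs else 0.0,
        "n_subthreshold_planted": len(sub_truth.event_times),
        "n_subthreshold_detected": sub_detected,
    }


def mini_recovery_noisy(seed: int = 0, duration_s: float = 300.0) -> dict:
    """Rate and mean-amplitude recovery at SNR 5 (20 pA events, 4 pA noise)."""
    trace, truth = synthgen.gen_mini_trace(
        duration_s, 1.0, amp_distribution=("normal", 20.0, 3.0),
        noise_sd_pA=4.0, seed=seed,
    )
    events = ephys.detect_minis(trace)
    true_rate = len(truth.event_times) / duration_s
    est_rate = len(events) / duration_s
    true_amp = float(np.mean(truth.amplitudes_pA))
    est_amp = float(np.mean([ev.amplitude_pA for ev in events]))
    return {
        "n_planted": len(truth.event_times),
        "n_detected": len(events),
        "rate_error_fraction": abs(est_rate - true_rate) / true_rate,
        "amplitude_error_fraction": abs(est_amp - true_amp) / true_amp,
    }


def puncta_recovery(n_fields: int = 50, seed: int = 0) -> dict:
    """Colocalization recovery over random synthetic fields.

    Noise-free fields must reproduce the planted count exactly; at noise
    equal to 10% of the puncta peak, pooled recall and precision are
    reported; channel-scale invariance is checked with an exact x2 rescale.
    """
    exact = 0
    for i in range(n_fields):
        field, truth = synthgen.gen_synapse_image(12, 3, 3, noise_sd=0.0,
                                                  seed=seed + i)
        rec, _ = puncta.quantify_field(field)
        exact += rec.n_coloc == len(truth.coloc_centers)

    tot = {"n_true": 0, "n_detected": 0, "n_recovered": 0, "n_matched_regions": 0}
    for i in range(n_fields):
        field, truth = synthgen.gen_synapse_image(
            12, 3, 3, noise_sd=50.0, seed=seed + 10_000 + i  # 10% of 500 peak
        )
        thr = {r: puncta.compute_threshold(img, r) for r, img in field.channels.items()}
        masks = {r: puncta.binarize(field.channels[r], thr[r]) for r in field.channels}
        labels, n = puncta.triple_colocalize(
            masks["cellfill"], masks["presynaptic"], masks["postsynaptic"]
        )
        score = puncta.score_detection(labels, n, truth.coloc_centers)
        for key in tot:
            tot[key] += score[key]

    field, _ = synthgen.gen_synapse_image(12, 3, 3, noise_sd=50.0, seed=seed)
    base, _ = puncta.quantify_field(field)
    scaled_masks = {
        r: puncta.binarize(2.0 * img, puncta.compute_threshold(2.0 * img))
        for r, img in field.channels.items()
    }
    _, n_scaled = puncta.triple_colocalize(
        scaled_masks["cellfill"], scaled_masks["presynaptic"],
        scaled_masks["postsynaptic"],
    )
    return {
        "n_fields": n_fields,
        "exact_recovery_fraction": exact / n_fields,
        "noisy_recall": tot["n_recovered"] / tot["n_true"],
        "noisy_precision": tot["n_matched_regions"] / tot["n_detected"],
        "scale_invariant": n_scaled == base.n_coloc,
    }


def hypergeom_enumeration_check(max_background: int = 12) -> dict:
    """Exact agreement with exhaustive enumeration for every small universe.

    Sweeps every (background size, external size, internal size, overlap)
    combination with background <= ``max_background`` and compares the
    hypergeometric tail with the enumerated fraction of draws.
    """
    max_err = 0.0
    n_checked = 0
    for n_bg in range(2, max_background + 1):
        bg = [f"g{i}" for i in range(n_bg)]
        for n_ext, n_int in itertools.product(range(1, n_bg + 1), repeat=2):
            for k in range(max(0, n_int + n_ext - n_bg), min(n_int, n_ext) + 1):
                outside = [g for g in bg if g not in bg[:n_ext]]
                internal = bg[:k] + outside[: n_int - k]
                if len(internal) < n_int:
                    continue
                got_k, got_p, _ = genesets.hypergeom_overlap(internal, bg[:n_ext], bg)
                assert got_k == k
                want = float(hypergeom_tail_enumeration(n_bg, n_ext, n_int, k))
                max_err = max(max_err, abs(got_p - want))
                n_checked += 1
    bg10 = [f"g{i}" for i in range(10)]
    _, p_example, _ = genesets.hypergeom_overlap(bg10[:4], bg10[:5], bg10)
    return {
        "n_universes_checked": n_checked,
        "max_abs_error": max_err,
        "worked_example_p": p_example,  # 5 / 210
    }


def permutation_convergence(
    seed: int = 0, n_perms=(100, 1000, 10000), n_seeds: int = 50
) -> dict:
    """Mean absolute error of the permutation p against the analytic
    hypergeometric p on a fixed universe, as the replicate count grows."""
    bg = [f"g{i:04d}" for i in range(1000)]
    external = bg[:50]
    internal = bg[:5] + bg[50:105]  # observed overlap 5, expectation 3
    _, p_hyp, _ = genesets.hypergeom_overlap(internal, external, bg)
    seed_seq = np.random.SeedSequence(seed)
    sub_seeds = seed_seq.generate_state(n_seeds * len(n_perms)) % 2**31
    mae = {}
    idx = 0
    for n_perm in n_perms:
        errs = []
        for _ in range(n_seeds):
            p = genesets.permute_external(internal, external, bg, n_perm,
                                          int(sub_seeds[idx]))
            idx += 1
            errs.append(abs(p - p_hyp))
        mae[int(n_perm)] = float(np.mean(errs))
    return {"p_hypergeom": p_hyp, "mae_by_n_perm": mae, "n_seeds": n_seeds}


def permutation_floor(seed: int = 0, n_perm: int = 1000) -> dict:
    """A maximally enriched overlap: the observed count exceeds every
    replicate, so the permutation p reports the reciprocal floor."""
    collection, truth = synthgen.gen_gene_universe(
        200, 20, 20, enrichment_factor=10.0, seed=seed
    )
    p = genesets.permute_external(
        collection.sets["internal"], collection.sets["external"],
        collection.background, n_perm=n_perm, seed=seed + 1,
    )
    return {"planted_overlap": truth.planted_overlap, "n_perm": n_perm, "p_perm": p}


def density_ratio_recovery(seed: int = 0, n_fields: int = 10,
                           noise_sd: float = 50.0) -> dict:
    """Two synthetic groups with a true dendritic density ratio of 2.0.

    Control fields carry 8 colocalized puncta, experimental fields 16, on
    pairwise-identical neuron shapes; the normalized experimental group value
    should recover the planted ratio.
    """
    import pandas as pd

    rows = []
    for i in range(n_fields):
        for ci, (label, n_coloc) in enumerate(
            [("control", 8), ("experimental", 16)]
        ):
            field, _ = synthgen.gen_synapse_image(
                n_coloc, 3, 3, noise_sd=noise_sd,
                geometry_seed=seed + i, seed=seed + 1000 * i + ci,
            )
            rec, _ = puncta.quantify_field(field, condition_label=label,
                                           experiment_label="exp1")
            rows.append(vars(rec))
    norm = puncta.normalize_densities(pd.DataFrame(rows), "control")
    ratio = float(
        norm.loc[norm["condition_label"] == "experimental", "normalized"].iloc[0]
    )
    return {"n_fields_per_group": n_fields, "true_ratio": 2.0,
            "normalized_ratio": ratio}
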