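"""Simulation studies quantifying pipeline performance on known ground truth.

Each benchmark generates synthetic recordings under the standard study
conditions (2 Hz secretion recordings with stimulus-locked events and
shot + read noise; 5-min-interval RUSH traces with 5% noise; 0.5 Hz
transport movies with constant-velocity particles), runs the corresponding
analysis chain, and reports recovery statistics against the ground truth.
All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .fusion import detect_events, extract_trace
from .io import PipelineConfig, run_pipeline
from .kymo import build_kymograph, classify_tracks, trace_tracks
from .rush import fit_golgi_kinetics, golgi_trace
from .simulate import (
    EventSpec,
    SimConfig,
    generate_fusion_movie,
    generate_kymo_movie,
    generate_rush_movie,
)
from .stats import superplot_compare

_MOD = 2**31 - 1


def _sub_seed(seed: int, stream: int, i: int) -> int:
    return (seed * 100_003 + stream * 1_009 + i) % _MOD


def fusion_recall_benchmark(
    n_movies: int = 50,
    seed: int = 0,
    events_per_movie: int = 5,
    peak_ratio: float = 2.0,
) -> dict:
    """Recall of trace-level event detection on stimulus-locked events.

    Each movie carries one event per punctum (amplitude well above four
    baseline SD in F/F0 units) with onsets inside the stimulation window.
    An event counts as detected when an accepted event's peak lies within
    two seconds of the true peak.
    """
    detected = total = 0
    for i in range(n_movies):
        s = _sub_seed(seed, 1, i)
        rng = np.random.default_rng(_sub_seed(seed, 11, i))
        events = tuple(
            EventSpec(pid, float(rng.uniform(31.0, 53.0)), peak_ratio, 0.25, 5.0)
            for pid in range(events_per_movie)
        )
        cfg = SimConfig(
            n_puncta=events_per_movie,
            punctum_min_separation=10.0,
            events=events,
            noise_gaussian_sd=3.0,
            noise_poisson_scale=2.0,
            rng_seed=s,
        )
        movie, truth = generate_fusion_movie(cfg)
        for pid, pos in enumerate(truth.puncta_positions):
            center = tuple(int(round(v)) for v in pos)
            found = detect_events(extract_trace(movie, center))
            ev = truth.events[pid]
            peak_frame = int(round((ev.onset_time + ev.rise_time) / cfg.frame_interval))
            total += 1
            detected += any(abs(e.peak_frame - peak_frame) <= 4 for e in found)
    return {"recall": detected / total, "n_events": total}


def fusion_specificity_benchmark(
    n_movies: int = 50, seed: int = 0, puncta_per_movie: int = 5
) -> dict:
    """Mean false-positive count per 240-frame trace on event-free movies."""
    counts = []
    for i in range(n_movies):
        s = _sub_seed(seed, 2, i)
        cfg = SimConfig(
            n_puncta=puncta_per_movie,
            punctum_min_separation=10.0,
            noise_gaussian_sd=3.0,
            noise_poisson_scale=2.0,
            rng_seed=s,
        )
        movie, truth = generate_fusion_movie(cfg)
        for pos in truth.puncta_positions:
            center = tuple(int(round(v)) for v in pos)
            counts.append(len(detect_events(extract_trace(movie, center))))
    return {"fp_per_trace": float(np.mean(counts)), "n_traces": len(counts)}


def released_fraction_benchmark(
    n_seeds: int = 20,
    seed: int = 0,
    pool_size: int = 25,
    n_events: int = 2,
) -> dict:
    """Full-pipeline recovery of a configured released fraction.

    The configured fraction is ``n_events / pool_size`` (default 0.08, the
    order of magnitude typical for strong stimulation); recovery runs the
    whole chain including automatic ROI placement and the NH4Cl pool count.
    """
    import tempfile

    target = n_events / pool_size
    fractions = []
    for i in range(n_seeds):
        s = _sub_seed(seed, 3, i)
        rng = np.random.default_rng(_sub_seed(seed, 13, i))
        pids = rng.choice(pool_size, size=n_events, replace=False)
        events = tuple(
            EventSpec(int(pid), float(rng.uniform(31.0, 53.0)), 2.0, 0.25, 5.0)
            for pid in pids
        )
        cfg = SimConfig(
            n_puncta=pool_size,
            punctum_min_separation=8.0,
            image_shape=(96, 96),
            nh4cl_window=(110.0, 120.0),
            dequench_factor=5.0,
            noise_gaussian_sd=3.0,
            noise_poisson_scale=2.0,
            events=events,
            rng_seed=s,
        )
        movie, _ = generate_fusion_movie(cfg)
        with tempfile.TemporaryDirectory() as tmp:
            result = run_pipeline(PipelineConfig(), movie, tmp)
        if result.get("released_fraction") is not None:
            fractions.append(result["released_fraction"])
    mean_fraction = float(np.mean(fractions))
    return {
        "target_fraction": target,
        "mean_fraction": mean_fraction,
        "relative_error": abs(mean_fraction - target) / target,
        "n_seeds": len(fractions),
    }


def rush_recovery_benchmark(
    n_traces: int = 50,
    seed: int = 0,
    k_true: float = 0.1,
    t_peak_true: float = 45.0,
    noise_sd: float = 0.05,
) -> dict:
    """Recovery of the Golgi export rate constant and time-to-peak."""
    k_errs, tp_errs, ks = [], [], []
    for i in range(n_traces):
        s = _sub_seed(seed, 4, i)
        movie, truth = generate_rush_movie(
            k_true, t_peak_true, noise_sd=noise_sd, rng_seed=s
        )
        kin = fit_golgi_kinetics(golgi_trace(movie, truth.golgi_mask, 3))
        ks.append(kin.k)
        k_errs.append(abs(kin.k - k_true) / k_true)
        tp_errs.append(abs(kin.t_peak - t_peak_true))
    return {
        "k_true": k_true,
        "median_k": float(np.median(ks)),
        "median_k_rel_error": float(np.median(k_errs)),
        "median_t_peak_error_min": float(np.median(tp_errs)),
        "n_traces": n_traces,
    }


def kymo_recovery_benchmark(
    n_movies: int = 250,
    seed: int = 0,
    particles_per_movie: int = 1,
    anterograde_prob: float = 2.0 / 3.0,
) -> dict:
    """Direction-fraction and speed recovery of constant-velocity particles.

    The default anterograde probability of 2/3 mirrors the predominance of
    outward transport of newly made vesicles in axons.  Movies are sparsely
    labelled (one vesicle per neurite recording by default), so recovery
    errors reflect the tracer itself rather than particle collisions;
    crowded variants are available via ``particles_per_movie``.
    """
    truth_a = truth_r = rec_a = rec_r = 0
    speed_errs = []
    # stratified design: the realized composition matches anterograde_prob
    # exactly, so the recovered fraction is not blurred by binomial noise
    n_total = n_movies * particles_per_movie
    n_antero = int(round(anterograde_prob * n_total))
    flags = np.zeros(n_total, dtype=bool)
    flags[:n_antero] = True
    flags = np.random.default_rng(_sub_seed(seed, 6, 0)).permutation(flags)
    for i in range(n_movies):
        s = _sub_seed(seed, 5, i)
        rng = np.random.default_rng(_sub_seed(seed, 15, i))
        outward = flags[i * particles_per_movie : (i + 1) * particles_per_movie]
        speeds = rng.uniform(0.5, 1.5, particles_per_movie)
        velocities = np.where(outward, speeds, -speeds)
        movie, _ = generate_kymo_movie(
            particles_per_movie, list(velocities), noise_sd=0.05, rng_seed=s
        )
        mid = movie.shape[1] // 2
        path = np.array([[mid, 0], [mid, movie.shape[2] - 1]], dtype=float)
        tracks, summary = classify_tracks(trace_tracks(build_kymograph(movie, path)))
        truth_a += int(outward.sum())
        truth_r += particles_per_movie - int(outward.sum())
        rec_a += summary["counts"]["anterograde"]
        rec_r += summary["counts"]["retrograde"]
        for tr in tracks:
            if tr.direction == "stationary":
                continue
            v_est = abs(tr.net_displacement) / tr.duration
            sign = 1.0 if tr.direction == "anterograde" else -1.0
            candidates = [abs(v_est - abs(v)) / abs(v) for v in velocities if np.sign(v) == sign]
            if candidates:
                speed_errs.append(min(candidates))
    return {
        "true_anterograde_fraction": truth_a / (truth_a + truth_r),
        "recovered_anterograde_fraction": rec_a / (rec_a + rec_r),
        "median_speed_rel_error": float(np.median(speed_errs)),
        "n_particles": truth_a + truth_r,
    }


def superplot_null_calibration(n_sims: int = 1000, seed: int = 0) -> dict:
    """Type-I error of the replicate-mean t-test under the null."""
    rng = np.random.default_rng(seed % _MOD)
    hits = 0
    for _ in range(n_sims):
        rows = []
        for g, rep0 in (("a", 0), ("b", 10)):
            for rep in range(3):
                for v in rng.normal(0.0, 1.0, 8):
                    rows.append({"group": g, "replicate": rep0 + rep, "value": v})
        res = superplot_compare(pd.DataFrame(rows), "a", "b")
        hits += res.p < 0.05
    return {"type_i_error": hits / n_sims, "n_sims": n_sims}
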