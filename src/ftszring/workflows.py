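"""End-to-end validation experiments on synthetic data.

Each function runs one self-contained experiment — simulate with known
ground truth, analyse with the measurement pipeline, compare — and returns
plain dictionaries / DataFrames. The numbered scripts under ``analysis/``
and the acceptance harness are thin wrappers over these.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ftszring import kymo, quantify, simulate, smtrack

__all__ = [
    "analytic_identities",
    "velocity_recovery_experiment",
    "residence_recovery_experiment",
    "bleach_calibration_experiment",
    "ring_size_experiment",
]


def analytic_identities() -> dict:
    """Closed-form identities tying the headline numbers together.

    Angular-to-linear conversion at the typical 500-nm ring radius, the mean
    filament length from speed x residence time, the photobleaching
    timescale, and the speed ratio between the FtsA-anchored vortices
    (108 nm/s) and the membrane-targeted construct (34 nm/s).
    """
    v = quantify.angular_to_linear(3.9, 500.0)
    length = quantify.filament_length(34.0, 11.5)
    return {
        "v_from_angular_nm_s": v,
        "v_slow_from_angular_nm_s": quantify.angular_to_linear(2.8, 500.0),
        "mean_filament_length_nm": length.mean_length_nm,
        "filament_n_monomers": length.n_monomers,
        "bleach_timescale_s": 1.0 / smtrack.DEFAULT_KP,
        "ftsa_speed_ratio": 108.0 / 34.0,
    }


def _analyse_one_ring(movie, truth) -> kymo.VelocityResult:
    pre = kymo.preprocess(movie, mean_filter_size=3)
    cx, cy = truth["center_px"]
    r = truth["radius_px"]
    roi = kymo.fit_ring(pre, ((cx - r, cy), (cx + r, cy)))
    return kymo.estimate_slope(kymo.extract_kymograph(pre, roi))


def velocity_recovery_experiment(
    seed: int,
    speeds_nm_s: tuple[float, ...] = (25.0, 34.0, 108.0),
    n_rings_per_condition: int = 20,
    n_static: int = 20,
    snr: float = 3.0,
    n_frames: int = 100,
    frame_interval_s: float = 3.0,
    ring_radius_um: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Velocity/chirality recovery on simulated treadmilling rings.

    For every signed speed condition (both chiralities of each entry in
    ``speeds_nm_s``) the stated number of rings is simulated at the given
    SNR, analysed blind, and compared with ground truth; a static-ring
    condition checks the quality gates (the GTPase-dead analogue).

    Returns the per-ring table and a summary with the accepted-ring median
    relative speed error, chirality accuracy, and static rejection rate.
    """
    rng = np.random.default_rng(seed)
    photon = simulate.photon_scale_for_snr(snr)
    rows = []
    conditions = [s * sign for s in speeds_nm_s for sign in (+1, -1)]
    conditions += [0.0] * (1 if n_static else 0)
    for speed in conditions:
        n = n_static if speed == 0 else n_rings_per_condition
        for _ in range(n):
            cfg = simulate.RingSimConfig(
                linear_speed_nm_s=speed,
                ring_radius_um=ring_radius_um,
                n_frames=n_frames,
                frame_interval_s=frame_interval_s,
                photon_scale=photon,
                phase_offset_rad=rng.uniform(0, 2 * np.pi),
                seed=int(rng.integers(2**31 - 1)),
            )
            movie, truth = simulate.simulate_ring_movie(cfg)
            res = _analyse_one_ring(movie, truth)
            true_chir = (
                "static" if speed == 0 else ("clockwise" if speed > 0 else "counterclockwise")
            )
            rows.append(
                {
                    "true_v_nm_s": speed,
                    "true_chirality": true_chir,
                    "v_nm_s": res.v_nm_s,
                    "chirality": res.chirality,
                    "peak_ratio": res.peak_ratio,
                    "r2": res.r_squared,
                    "accepted": res.accepted,
                }
            )
    table = pd.DataFrame(rows)

    moving = table[table.true_v_nm_s != 0]
    acc = moving[moving.accepted]
    rel_err = np.abs(acc.v_nm_s - acc.true_v_nm_s.abs()) / acc.true_v_nm_s.abs()
    static = table[table.true_v_nm_s == 0]
    summary = {
        "n_moving": int(len(moving)),
        "n_accepted": int(len(acc)),
        "median_rel_error_pct": float(100 * np.median(rel_err)) if len(acc) else float("nan"),
        "chirality_accuracy_pct": (
            float(100 * (acc.chirality == acc.true_chirality).mean()) if len(acc) else float("nan")
        ),
        "static_rejection_pct": (
            float(100 * (~static.accepted).mean()) if len(static) else float("nan")
        ),
    }
    for s in speeds_nm_s:
        sub = acc[acc.true_v_nm_s.abs() == s]
        summary[f"v_mean_recovered_{s:g}_nm_s"] = (
            float(sub.v_nm_s.mean()) if len(sub) else float("nan")
        )
    return table, summary


def residence_recovery_experiment(
    seed: int,
    k_true: float,
    fps: float,
    n_events: int = 5000,
    bleach_fraction: float = 0.22,
    kp_true: float = 0.031,
    kp_mode: str = "fixed",
) -> dict:
    """Residence-time recovery from simulated disappearance events.

    Events are drawn from the two-population mixture, discretised onto the
    frame grid (a molecule is seen in the frames its dwell spans), the
    sub-2-frame exclusion applied, and the constrained double-exponential
    survival fit run with kp fixed at its true value.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    # spread births over a window long enough that few events are censored
    t_total = max(50.0 / min(k_true, kp_true), 1000 * dt)
    n_frames = int(np.ceil(t_total / dt)) + 1
    dwell, cause = simulate.sample_dwell_times(n_events, k_true, kp_true, bleach_fraction, rng)
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "birth_time_s": rng.uniform(0, t_total - 1, n_events),
            "dwell_s": dwell,
            "cause": cause,
        }
    )
    vis = simulate.discretize_dwells(events, dt, n_frames)
    usable = vis[~vis.censored & (vis.n_frames_present >= 2)]
    rs = smtrack.ResidenceSet(usable.residence_s.to_numpy(), dt)
    fit = smtrack.fit_survival(rs, kp_mode=kp_mode, kp0=kp_true)
    return {
        "t_r_s": fit.t_r,
        "t_r_true_s": 1.0 / k_true,
        "rel_error_pct": 100 * abs(fit.t_r - 1.0 / k_true) * k_true,
        "B": fit.B,
        "kp_s": fit.kp,
        "n_events": rs.n_events,
    }


def bleach_calibration_experiment(
    seed: int, kp_true: float = 0.031, n_events: int = 3000, fps: float = 1.0
) -> dict:
    """Photobleaching-rate calibration from a simulated immobilised control."""
    rng = np.random.default_rng(seed)
    dt = 1.0 / fps
    t_total = 50.0 / kp_true
    n_frames = int(np.ceil(t_total / dt)) + 1
    events = pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "birth_time_s": rng.uniform(0, t_total - 1, n_events),
            "dwell_s": rng.exponential(1.0 / kp_true, n_events),
            "cause": "bleach",
        }
    )
    vis = simulate.discretize_dwells(events, dt, n_frames)
    usable = vis[~vis.censored & (vis.n_frames_present >= 2)]
    rs = smtrack.ResidenceSet(usable.residence_s.to_numpy(), dt)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kp = smtrack.calibrate_photobleaching(rs)
    return {"kp_s": kp, "kp_true_s": kp_true, "bleach_timescale_s": 1.0 / kp}


def ring_size_experiment(
    seed: int,
    n_rings: int = 140,
    mean_diameter_um: float = 0.94,
    sd_diameter_um: float = 0.16,
    n_frames: int = 5,
) -> dict:
    """Ring-diameter statistics measured through the circle-fitting step.

    Static rings with diameters drawn from the stated population are
    rendered and re-measured by :func:`ftszring.kymo.fit_ring` from noisy
    diametral seed points; the recovered distribution is summarised.
    """
    rng = np.random.default_rng(seed)
    rois = []
    pixel_size = 0.042
    for _ in range(n_rings):
        d = max(rng.normal(mean_diameter_um, sd_diameter_um), 0.35)
        cfg = simulate.RingSimConfig(
            image_size=int(np.ceil(d / pixel_size)) + 16,
            ring_radius_um=d / 2,
            linear_speed_nm_s=0.0,
            n_frames=n_frames,
            photon_scale=simulate.photon_scale_for_snr(5.0),
            seed=int(rng.integers(2**31 - 1)),
        )
        movie, truth = simulate.simulate_ring_movie(cfg)
        pre = kymo.preprocess(movie, mean_filter_size=3)
        cx, cy = truth["center_px"]
        r = truth["radius_px"]
        # seed points a user would click: diametral, ~1 px of error
        x1, y1 = cx - r + rng.normal(0, 1), cy + rng.normal(0, 1)
        x2, y2 = cx + r + rng.normal(0, 1), cy + rng.normal(0, 1)
        rois.append(kymo.fit_ring(pre, ((x1, y1), (x2, y2))))
    stats = quantify.ring_size_stats(rois, pixel_size)
    return {
        "mean_diameter_um": stats.mean_um,
        "sd_diameter_um": stats.sd_um,
        "n": stats.n,
        "true_mean_um": mean_diameter_um,
    }
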