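"""Derived metrics and population summaries.

Unit conversions between linear and angular treadmilling speed, the mean
filament length implied by speed and residence time (l = v * t_r, with a
5 nm monomer giving the subunit count), protein-density regime
classification from surface mean intensity, time-course synchronisation at
a fixed intensity threshold, ring-size statistics and velocity-population
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ftszring.kymo import RingROI, VelocityResult

__all__ = [
    "DerivedLength",
    "RingSizeStats",
    "angular_to_linear",
    "linear_to_angular",
    "filament_length",
    "classify_density",
    "synchronize_trace",
    "ring_size_stats",
    "velocity_population",
]

MONOMER_LENGTH_NM = 5.0
SYNC_THRESHOLD_AU = 200.0
DENSITY_LOW_MAX_AU = 450.0
DENSITY_RING_MAX_AU = 1000.0


@dataclass
class DerivedLength:
    """Mean treadmilling filament length implied by speed and residence time."""

    mean_length_nm: float
    n_monomers: int
    monomer_length_nm: float
    v_nm_s: float
    t_r_s: float


@dataclass
class RingSizeStats:
    diameters_um: np.ndarray
    mean_um: float
    sd_um: float  # sample SD; NaN for a single ring
    n: int


def angular_to_linear(omega_deg_s: float, radius_nm: float) -> float:
    """Angular speed (deg/s) to linear circumferential speed (nm/s)."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    return omega_deg_s * np.pi / 180.0 * radius_nm


def linear_to_angular(v_nm_s: float, radius_nm: float) -> float:
    """Linear circumferential speed (nm/s) to angular speed (deg/s)."""
    if radius_nm <= 0:
        raise ValueError("radius must be positive")
    return v_nm_s / radius_nm * 180.0 / np.pi


def filament_length(
    v_nm_s: float, t_r_s: float, monomer_length_nm: float = MONOMER_LENGTH_NM
) -> DerivedLength:
    """Mean filament length l = v * t_r and the implied monomer count.

    A filament treadmilling at speed v whose subunits stay bound for t_r on
    average spans v * t_r from growing to shrinking end.
    """
    if v_nm_s < 0:
        raise ValueError("speed must be non-negative")
    if t_r_s <= 0:
        raise ValueError("residence time must be positive")
    length = v_nm_s * t_r_s
    return DerivedLength(
        mean_length_nm=length,
        n_monomers=int(round(length / monomer_length_nm)),
        monomer_length_nm=monomer_length_nm,
        v_nm_s=v_nm_s,
        t_r_s=t_r_s,
    )


def classify_density(
    mean_intensity_au: float,
    low_max_au: float = DENSITY_LOW_MAX_AU,
    ring_max_au: float = DENSITY_RING_MAX_AU,
) -> str:
    """Protein surface-density regime from surface mean intensity.

    Below ``low_max_au``: sparse filaments ("low"); between the boundaries
    (both included): dynamic vortices ("ring-forming"); above: isotropic
    bundles ("bundled"). Boundaries follow the closed interval convention.
    """
    if mean_intensity_au < 0:
        raise ValueError("intensity must be non-negative")
    if low_max_au >= ring_max_au:
        raise ValueError("regime boundaries must be ordered")
    if mean_intensity_au < low_max_au:
        return "low"
    if mean_intensity_au <= ring_max_au:
        return "ring-forming"
    return "bundled"


def synchronize_trace(
    trace_au: np.ndarray, threshold_au: float = SYNC_THRESHOLD_AU
) -> int:
    """Index of time zero: first frame with mean intensity >= threshold.

    Acquisitions started at different absolute times are aligned by the
    frame at which the surface mean intensity first reaches the threshold.
    """
    trace_au = np.asarray(trace_au)
    if trace_au.size == 0:
        raise ValueError("empty trace")
    above = np.flatnonzero(trace_au >= threshold_au)
    if above.size == 0:
        raise ValueError("threshold never reached")
    return int(above[0])


def ring_size_stats(rois: list[RingROI], pixel_size_um: float) -> RingSizeStats:
    """Diameter distribution of fitted rings (2 r, in micrometres)."""
    if not rois:
        raise ValueError("need at least one ring")
    diameters = np.array([2.0 * roi.radius_px * pixel_size_um for roi in rois])
    sd = float(np.std(diameters, ddof=1)) if diameters.size > 1 else float("nan")
    return RingSizeStats(
        diameters_um=diameters,
        mean_um=float(diameters.mean()),
        sd_um=sd,
        n=diameters.size,
    )


def velocity_population(
    results: list[VelocityResult], n_bins: int = 10
) -> dict:
    """Summary of accepted per-ring velocity estimates.

    Returns overall mean/SD/N, a histogram of |v|, and per-chirality means.
    Rejected rings are ignored; an all-rejected input is an error.
    """
    accepted = [r for r in results if r.accepted]
    if not accepted:
        raise ValueError("no accepted velocity results")
    v = np.array([r.v_nm_s for r in accepted])
    counts, edges = np.histogram(v, bins=n_bins)
    by_chirality = {}
    for chir in ("clockwise", "counterclockwise"):
        sub = v[[r.chirality == chir for r in accepted]]
        if sub.size:
            by_chirality[chir] = {"mean_nm_s": float(sub.mean()), "n": int(sub.size)}
    return {
        "mean_nm_s": float(v.mean()),
        "sd_nm_s": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
        "n": int(v.size),
        "histogram": {
            "bin_left": edges[:-1].tolist(),
            "bin_right": edges[1:].tolist(),
            "count": counts.tolist(),
        },
        "by_chirality": by_chirality,
    }
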