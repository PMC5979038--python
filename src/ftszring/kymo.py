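"""Circular kymographs and Fourier-phase treadmilling velocity estimation.

A ring is defined from two user-supplied seed points, refined to a circle,
and unrolled into a kymograph (arc position x time) by averaging three
concentric sampling circles of radii r-1, r, r+1 px. A pattern that travels
along the circumference appears as tilted stripes; its speed is measured in
the Fourier domain: the dominant temporal frequency f* is found from the
mean spectrum over arc positions, and the phase of the transform at f* as a
function of arc position is a line whose slope is the spatial wavenumber q.
The linear speed is then v = 2*pi*f* / |q| * arc_step, and the sign of q
gives the chirality. Blocks with a weak spectral peak (< 10-fold the mean)
or a poor phase line (R^2 < 0.95) are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal
from skimage import exposure
from skimage.registration import phase_cross_correlation

from ftszring.io import Movie

logger = logging.getLogger(__name__)

__all__ = [
    "RingROI",
    "Kymograph",
    "VelocityResult",
    "preprocess",
    "estimate_drift",
    "fit_ring",
    "extract_kymograph",
    "estimate_slope",
]

PEAK_RATIO_MIN = 10.0
R_SQUARED_MIN = 0.95


@dataclass
class RingROI:
    """A fitted circle on which kymographs are extracted."""

    center: tuple[float, float]  # (x, y), subpixel
    radius_px: float
    seed_points: tuple[tuple[float, float], tuple[float, float]] | None = None
    refined: bool = True

    def __post_init__(self) -> None:
        if self.radius_px < 3:
            raise ValueError("ring radius must be >= 3 px (needs r-1, r, r+1 circles)")


@dataclass
class Kymograph:
    """Circular kymograph: rows are arc positions, columns are time."""

    values: np.ndarray  # (n_arc, n_time)
    arc_step_nm: float
    frame_interval_s: float
    roi: RingROI
    pixel_size_um: float

    @property
    def n_arc(self) -> int:
        return self.values.shape[0]

    @property
    def n_time(self) -> int:
        return self.values.shape[1]


@dataclass
class VelocityResult:
    """Per-ring treadmilling estimate with quality metrics."""

    f_star_hz: float
    q_rad_per_sample: float
    r_squared: float
    peak_ratio: float
    v_nm_s: float
    omega_deg_s: float
    chirality: str  # "clockwise" | "counterclockwise" | "static/rejected"
    accepted: bool
    n_blocks_accepted: int = 0
    n_blocks_total: int = 0


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def estimate_drift(data: np.ndarray) -> np.ndarray:
    """Integer-pixel (row, col) drift of every frame relative to frame 0.

    Returns the per-frame shift that, applied to the frame, registers it
    onto frame 0 (phase correlation).
    """
    ref = data[0]
    shifts = np.zeros((len(data), 2), dtype=int)
    for i in range(1, len(data)):
        shift, _, _ = phase_cross_correlation(ref, data[i], upsample_factor=1)
        shifts[i] = np.round(shift).astype(int)
    return shifts


def preprocess(movie: Movie, mean_filter_size: int = 3, drift: bool = False) -> Movie:
    """Mean-filter each frame and optionally drift-correct the stack.

    Drift correction registers every frame to frame 0 by integer-pixel phase
    correlation. A shift larger than 25% of the frame triggers a warning but
    is still applied.
    """
    if mean_filter_size < 1 or mean_filter_size % 2 == 0:
        raise ValueError("mean_filter_size must be odd and >= 1")
    data = movie.data.astype(np.float64)
    if mean_filter_size > 1:
        data = np.stack([ndimage.uniform_filter(f, size=mean_filter_size) for f in data])
    if drift:
        shifts = estimate_drift(data)
        fill = float(np.median(data[0]))
        limit = 0.25 * min(data[0].shape)
        out = [data[0]]
        for i in range(1, len(data)):
            if np.abs(shifts[i]).max() > limit:
                logger.warning("frame %d: drift %s exceeds 25%% of frame", i, shifts[i].tolist())
            out.append(ndimage.shift(data[i], shifts[i], order=0, cval=fill))
        data = np.stack(out)
    return movie.with_data(data)


# ---------------------------------------------------------------------------
# Ring fitting
# ---------------------------------------------------------------------------


def _circle_mean_intensity(
    img: np.ndarray, cx: float, cy: float, r: float, n_samples: int
) -> float:
    theta = 2 * np.pi * np.arange(n_samples) / n_samples
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    vals = ndimage.map_coordinates(img, np.vstack([y, x]), order=1, mode="nearest")
    return float(vals.mean())


def fit_ring(
    movie: Movie,
    seed_points: tuple[tuple[float, float], tuple[float, float]],
    search_box_px: float = 5.0,
) -> RingROI:
    """Fit a circle to a ring from two seed points.

    The initial circle has the seed segment as its diameter; it is refined by
    maximising the mean time-averaged intensity along the circle over
    (center, radius), constrained to within ``search_box_px`` of the initial
    guess. If the optimum escapes the box, or the image gives the optimiser
    nothing to improve (featureless field), the initial circle is returned
    with ``refined=False``.
    """
    (x1, y1), (x2, y2) = seed_points
    if x1 == x2 and y1 == y2:
        raise ValueError("seed points must be distinct")
    cx0, cy0 = (x1 + x2) / 2.0, (y1 + y2) / 2.0
    r0 = 0.5 * np.hypot(x2 - x1, y2 - y1)
    if r0 < 3:
        raise ValueError("seed points imply a ring radius < 3 px")

    avg = movie.data.mean(axis=0)
    avg = ndimage.gaussian_filter(avg, 0.8)  # smooth objective for the optimiser
    n_samples = max(int(round(2 * np.pi * r0)), 8)

    def negobj(p: np.ndarray) -> float:
        return -_circle_mean_intensity(avg, p[0], p[1], max(p[2], 3.0), n_samples)

    f0 = negobj(np.array([cx0, cy0, r0]))
    res = optimize.minimize(
        negobj,
        x0=np.array([cx0, cy0, r0]),
        method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 1e-8, "maxiter": 400},
    )
    cx, cy, r = res.x
    inside = (
        abs(cx - cx0) <= search_box_px
        and abs(cy - cy0) <= search_box_px
        and abs(r - r0) <= search_box_px
    )
    improved = (f0 - res.fun) > 1e-9 * max(abs(f0), 1.0)
    if not inside or not improved:
        if not inside:
            logger.info("ring refinement left the +/-%g px search box; keeping seed circle", search_box_px)
        return RingROI((cx0, cy0), r0, seed_points=seed_points, refined=False)
    return RingROI((float(cx), float(cy)), float(r), seed_points=seed_points, refined=True)


# ---------------------------------------------------------------------------
# Kymograph extraction
# ---------------------------------------------------------------------------


def extract_kymograph(movie: Movie, roi: RingROI) -> Kymograph:
    """Sample the movie along three concentric circles and average them.

    For every frame, intensities are bilinearly interpolated at
    ``round(2*pi*r)`` equally spaced angles on circles of radius r-1, r and
    r+1 px; the three angular profiles are averaged. One arc sample then
    corresponds to roughly one pixel of arc (``arc_step = pixel_size``).
    """
    cx, cy = roi.center
    r = roi.radius_px
    n_rows, n_cols = movie.data.shape[1:]
    if (
        cx - (r + 1) < 0
        or cy - (r + 1) < 0
        or cx + (r + 1) > n_cols - 1
        or cy + (r + 1) > n_rows - 1
    ):
        raise ValueError("sampling circles touch the image border")

    n_samples = int(round(2 * np.pi * r))
    theta = 2 * np.pi * np.arange(n_samples) / n_samples
    coords = []
    for radius in (r - 1, r, r + 1):
        x = cx + radius * np.cos(theta)
        y = cy + radius * np.sin(theta)
        coords.append(np.vstack([y, x]))
    coords = np.concatenate(coords, axis=1)  # (2, 3*n_samples)

    kym = np.empty((n_samples, movie.n_frames))
    for t in range(movie.n_frames):
        vals = ndimage.map_coordinates(movie.data[t], coords, order=1)
        kym[:, t] = vals.reshape(3, n_samples).mean(axis=0)

    return Kymograph(
        values=kym,
        arc_step_nm=movie.pixel_size_um * 1000.0,
        frame_interval_s=movie.frame_interval_s,
        roi=roi,
        pixel_size_um=movie.pixel_size_um,
    )


# ---------------------------------------------------------------------------
# Fourier-phase slope estimation
# ---------------------------------------------------------------------------


def _enhance(kym: np.ndarray, savgol_window: int, clahe_clip: float, clahe_tiles: int) -> np.ndarray:
    """Savitzky-Golay smoothing along time, then CLAHE."""
    n_arc, n_time = kym.shape
    win = min(savgol_window, n_time if n_time % 2 == 1 else n_time - 1)
    if win >= 3:
        kym = signal.savgol_filter(kym, window_length=win, polyorder=2, axis=1)
    lo, hi = kym.min(), kym.max()
    if hi - lo <= 0:
        return np.zeros_like(kym)
    norm = (kym - lo) / (hi - lo)
    kernel = (max(n_arc // clahe_tiles, 1), max(n_time // clahe_tiles, 1))
    return exposure.equalize_adapthist(norm, kernel_size=kernel, clip_limit=clahe_clip)


def _fit_phase_line(phase: np.ndarray) -> tuple[float, float]:
    """Least-squares line through unwrapped phase; returns (slope, R^2)."""
    s = np.arange(phase.size, dtype=float)
    slope, intercept = np.polyfit(s, phase, 1)
    pred = slope * s + intercept
    ss_res = float(np.sum((phase - pred) ** 2))
    ss_tot = float(np.sum((phase - phase.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(slope), r2


def estimate_slope(
    kym: Kymograph,
    band_size: int = 50,
    savgol_window: int = 7,
    clahe_clip: float = 0.01,
    clahe_tiles: int = 8,
    peak_ratio_min: float = PEAK_RATIO_MIN,
    r_squared_min: float = R_SQUARED_MIN,
    pad_factor: int = 4,
) -> VelocityResult:
    """Estimate treadmilling speed and chirality from a circular kymograph.

    The kymograph is smoothed (Savitzky-Golay, order 2, along time) and
    contrast-enhanced (CLAHE), then analysed in contiguous blocks of
    ``band_size`` arc samples. Per block: the temporal FFT is taken per arc
    position, f* is the frequency of the maximal mean magnitude (DC excluded,
    search limited to half the Nyquist frequency), and the unwrapped phase at
    f* versus arc position is fitted with a line. A block is accepted when
    its spectral peak is at least ``peak_ratio_min`` times the mean magnitude
    and the phase line has R^2 >= ``r_squared_min``. The ring estimate is the
    peak-ratio-weighted mean of accepted blocks, with
    ``v = 2*pi*f*/|q| * arc_step`` recomputed from the pooled f* and q.

    Sign convention: q is the traveling-wave wavenumber; q > 0 means the
    pattern advances toward increasing arc index, i.e. clockwise in displayed
    image coordinates.
    """
    n_arc, n_time = kym.values.shape
    dt = kym.frame_interval_s
    enhanced = _enhance(kym.values, savgol_window, clahe_clip, clahe_tiles)

    # zero-padding interpolates the spectrum so the peak is located off the
    # coarse bin grid (avoids scalloping loss on short acquisitions)
    n_pad = pad_factor * n_time
    freqs = np.fft.rfftfreq(n_pad, d=dt)
    spectra = np.fft.rfft(enhanced - enhanced.mean(axis=1, keepdims=True), n=n_pad, axis=1)
    # search below half Nyquist; the treadmilling band sits far under it
    searchable = np.flatnonzero((freqs > 0) & (freqs <= freqs[-1] / 2))
    if searchable.size == 0:
        return _rejected(n_blocks_total=0)

    if n_arc < band_size:
        blocks = [slice(0, n_arc)]
    else:
        blocks = [slice(i * band_size, (i + 1) * band_size) for i in range(n_arc // band_size)]

    rows = []
    for blk in blocks:
        mag = np.abs(spectra[blk]).mean(axis=0)
        nondc_mean = mag[1:].mean()
        if nondc_mean <= 0:
            rows.append({"peak_ratio": 0.0, "r2": 0.0, "f": 0.0, "q": 0.0, "ok": False})
            continue
        peak_bin = searchable[np.argmax(mag[searchable])]
        peak_ratio = float(mag[peak_bin] / nondc_mean)
        phase = np.unwrap(np.angle(spectra[blk, peak_bin]))
        slope, r2 = _fit_phase_line(phase)
        q = -slope  # wavenumber of the traveling wave
        ok = peak_ratio >= peak_ratio_min and r2 >= r_squared_min and q != 0.0
        rows.append(
            {"peak_ratio": peak_ratio, "r2": r2, "f": float(freqs[peak_bin]), "q": q, "ok": ok}
        )

    accepted = [r for r in rows if r["ok"]]
    if not accepted:
        best = max(rows, key=lambda r: r["peak_ratio"], default=None)
        return _rejected(
            f_star=best["f"] if best else 0.0,
            q=best["q"] if best else 0.0,
            r2=best["r2"] if best else 0.0,
            peak_ratio=best["peak_ratio"] if best else 0.0,
            n_blocks_total=len(rows),
        )

    w = np.array([r["peak_ratio"] for r in accepted])
    f_star = float(np.average([r["f"] for r in accepted], weights=w))
    q = float(np.average([r["q"] for r in accepted], weights=w))
    r2 = float(np.average([r["r2"] for r in accepted], weights=w))
    peak_ratio = float(np.average(w, weights=w))
    v = 2 * np.pi * f_star / abs(q) * kym.arc_step_nm
    radius_nm = kym.roi.radius_px * kym.pixel_size_um * 1000.0
    omega_deg_s = v / radius_nm * 180.0 / np.pi
    chirality = "clockwise" if q > 0 else "counterclockwise"
    return VelocityResult(
        f_star_hz=f_star,
        q_rad_per_sample=q,
        r_squared=r2,
        peak_ratio=peak_ratio,
        v_nm_s=float(v),
        omega_deg_s=float(omega_deg_s),
        chirality=chirality,
        accepted=True,
        n_blocks_accepted=len(accepted),
        n_blocks_total=len(rows),
    )


def _rejected(
    f_star: float = 0.0,
    q: float = 0.0,
    r2: float = 0.0,
    peak_ratio: float = 0.0,
    n_blocks_total: int = 0,
) -> VelocityResult:
    return VelocityResult(
        f_star_hz=f_star,
        q_rad_per_sample=q,
        r_squared=r2,
        peak_ratio=peak_ratio,
        v_nm_s=0.0,
        omega_deg_s=0.0,
        chirality="static/rejected",
        accepted=False,
        n_blocks_accepted=0,
        n_blocks_total=n_blocks_total,
    )
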