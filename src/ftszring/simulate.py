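"""Seeded generators for synthetic TIRF data with known ground truth.

Three kinds of data are emulated:

1. **Ring movies** — a ~1 um diameter ring of membrane-bound filaments whose
   intensity pattern translates along the circumference (treadmilling) at a
   signed linear speed, rendered through a Gaussian PSF with Poisson shot
   noise, Gaussian read noise and a constant background.
2. **Adsorption traces** — the frame-mean intensity of a bilayer during
   protein adsorption: a saturating ramp with additive noise, used to test
   time-zero synchronisation.
3. **Single-molecule movies / event tables** — sparse immobile fluorescent
   spots that appear as a Poisson process and disappear after an
   exponentially distributed dwell, terminated either by unbinding or by
   photobleaching.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ftszring.io import Movie

__all__ = [
    "RingSimConfig",
    "SmSimConfig",
    "simulate_ring_movie",
    "simulate_adsorption_trace",
    "simulate_sm_events",
    "simulate_sm_movie",
    "discretize_dwells",
    "sample_dwell_times",
    "photon_scale_for_snr",
]


def photon_scale_for_snr(
    snr: float, background_level: float = 200.0, read_noise_sd: float = 3.0
) -> float:
    """Signal amplitude (A.U.) giving a target peak SNR on a noisy background.

    SNR is defined as peak signal amplitude over the total noise standard
    deviation at the peak, ``a / sqrt(background + a + read^2)`` (Poisson shot
    noise on background plus signal, plus Gaussian read noise). Solving for
    ``a`` gives a closed form.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    var0 = background_level + read_noise_sd**2
    s2 = snr**2
    return 0.5 * (s2 + np.sqrt(s2**2 + 4.0 * s2 * var0))


# ---------------------------------------------------------------------------
# Ring movies
# ---------------------------------------------------------------------------


@dataclass
class RingSimConfig:
    """Parameters of a synthetic treadmilling-ring movie.

    ``linear_speed_nm_s`` is signed: positive means clockwise rotation in
    displayed image coordinates (row index increasing downward). Angles are
    measured from the +x axis toward +y (down), so increasing angle is
    clockwise on screen.
    """

    image_size: int = 48
    pixel_size_um: float = 0.042
    frame_interval_s: float = 3.0
    n_frames: int = 100
    ring_center: tuple[float, float] | None = None  # (x, y) px; default = centre
    ring_radius_um: float = 0.5
    linear_speed_nm_s: float = 34.0
    # two arcs give a kymograph dominated by the second spatial harmonic,
    # whose temporal frequency at 34 nm/s (~0.02 Hz) matches observed rings
    n_filaments: int = 2
    filament_length_nm: float = 390.0
    psf_sigma_px: float = 1.3
    background_level: float = 200.0
    photon_scale: float = 300.0
    read_noise_sd: float = 3.0
    shot_noise: bool = True
    phases: str = "even"  # "even" (mirror-symmetric layout) or "random"
    phase_jitter_sd_rad: float = 0.0  # seeded jitter around the even layout
    phase_offset_rad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ring_radius_um <= 0:
            raise ValueError("ring_radius_um must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.phases not in ("even", "random"):
            raise ValueError("phases must be 'even' or 'random'")
        circumference_nm = 2 * np.pi * self.ring_radius_um * 1000.0
        if self.filament_length_nm > circumference_nm:
            raise ValueError(
                f"filament_length_nm={self.filament_length_nm} exceeds ring "
                f"circumference {circumference_nm:.0f} nm"
            )

    @property
    def radius_px(self) -> float:
        return self.ring_radius_um / self.pixel_size_um

    @property
    def angular_speed_rad_s(self) -> float:
        """Signed angular speed; positive = clockwise on screen."""
        return self.linear_speed_nm_s / (self.ring_radius_um * 1000.0)

    @property
    def center(self) -> tuple[float, float]:
        if self.ring_center is not None:
            return self.ring_center
        c = self.image_size // 2
        return (float(c), float(c))


def _deposit_bilinear(img: np.ndarray, x: np.ndarray, y: np.ndarray, w: np.ndarray) -> None:
    """Accumulate point masses onto a grid with bilinear splatting (in place)."""
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    h, wd = img.shape
    for dy, dx, ww in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        yy = y0 + dy
        xx = x0 + dx
        ok = (yy >= 0) & (yy < h) & (xx >= 0) & (xx < wd)
        np.add.at(img, (yy[ok], xx[ok]), (w * ww)[ok])


def _initial_angles(cfg: RingSimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.phases == "even":
        # evenly spaced with one arc centred at pi/2: the set is invariant
        # under the mirror map theta -> pi - theta, so column-flipping a
        # noiseless movie exactly reverses its chirality (jitter = 0)
        base = np.pi / 2 + 2 * np.pi * np.arange(cfg.n_filaments) / cfg.n_filaments
        if cfg.phase_jitter_sd_rad > 0:
            base = base + rng.normal(0.0, cfg.phase_jitter_sd_rad, size=cfg.n_filaments)
        return base
    return rng.uniform(0, 2 * np.pi, size=cfg.n_filaments)


def simulate_ring_movie(cfg: RingSimConfig) -> tuple[Movie, dict]:
    """Render a treadmilling ring and return the movie plus ground truth.

    Filaments are drawn as thin arcs of uniform linear density on the ring
    circle, advanced rigidly by the configured angular speed each frame,
    blurred by the PSF, scaled so the brightest noiseless pixel equals
    ``photon_scale``, then Poisson-sampled and corrupted with Gaussian read
    noise over a constant background.

    Returns
    -------
    movie, truth
        ``truth`` holds the signed angular speed (rad/s), ring geometry,
        initial arc angles and the noiseless stack (background included).
    """
    rng = np.random.default_rng(cfg.seed)
    r_px = cfg.radius_px
    cx, cy = cfg.center
    half_arc = 0.5 * cfg.filament_length_nm / (cfg.ring_radius_um * 1000.0)  # rad
    omega = cfg.angular_speed_rad_s
    dt = cfg.frame_interval_s
    n = cfg.image_size

    theta0 = _initial_angles(cfg, rng) + cfg.phase_offset_rad
    # sub-pixel sampling along each arc (~5 samples per pixel of arc)
    n_pts = max(int(np.ceil(2 * half_arc * r_px * 5)), 2)
    rel = np.linspace(-half_arc, half_arc, n_pts)
    weight = np.full(n_pts, 1.0 / n_pts)

    density = np.zeros((cfg.n_frames, n, n))
    for t in range(cfg.n_frames):
        frame = density[t]
        for th0 in theta0:
            theta = th0 + omega * t * dt + rel
            x = cx + r_px * np.cos(theta)
            y = cy + r_px * np.sin(theta)
            _deposit_bilinear(frame, x, y, weight)
        density[t] = ndimage.gaussian_filter(frame, cfg.psf_sigma_px)

    peak = density.max()
    if peak > 0:
        density *= cfg.photon_scale / peak
    noiseless = density + cfg.background_level

    if cfg.shot_noise:
        stack = rng.poisson(np.clip(noiseless, 0, None)).astype(np.float64)
    else:
        stack = noiseless.copy()
    if cfg.read_noise_sd > 0:
        stack += rng.normal(0.0, cfg.read_noise_sd, size=stack.shape)
    stack = np.clip(stack, 0, None)

    movie = Movie(stack, pixel_size_um=cfg.pixel_size_um, frame_interval_s=dt)
    truth = {
        "angular_speed_rad_s": omega,
        "linear_speed_nm_s": cfg.linear_speed_nm_s,
        "center_px": (cx, cy),
        "radius_px": r_px,
        "initial_angles_rad": theta0,
        "noiseless": noiseless,
    }
    return movie, truth


# ---------------------------------------------------------------------------
# Adsorption traces
# ---------------------------------------------------------------------------


def simulate_adsorption_trace(
    rate_au_per_min: float,
    plateau_au: float,
    n_frames: int,
    frame_interval_s: float = 10.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    shape: str = "linear",
) -> np.ndarray:
    """Frame-mean intensity of a bilayer during protein adsorption.

    The noiseless curve rises from zero and saturates at ``plateau_au``:
    ``min(rate * t, plateau)`` for ``shape='linear'`` or
    ``plateau * (1 - exp(-rate * t / plateau))`` for ``shape='exponential'``.
    Gaussian noise of ``noise_sd`` is added per frame.
    """
    if plateau_au <= 0:
        raise ValueError("plateau_au must be positive")
    t_min = np.arange(n_frames) * frame_interval_s / 60.0
    if shape == "linear":
        trace = np.minimum(rate_au_per_min * t_min, plateau_au)
    elif shape == "exponential":
        trace = plateau_au * (1.0 - np.exp(-rate_au_per_min * t_min / plateau_au))
    else:
        raise ValueError("shape must be 'linear' or 'exponential'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=n_frames)
    return trace


# ---------------------------------------------------------------------------
# Single-molecule channel
# ---------------------------------------------------------------------------


@dataclass
class SmSimConfig:
    """Parameters of a synthetic single-molecule (nanobody channel) movie.

    Disappearance follows a two-population mixture: a fraction
    ``bleach_fraction`` of molecules photobleach (dwell ~ Exp(kp_true)), the
    rest unbind (dwell ~ Exp(k_true)) — the form of the double-exponential
    survival model fitted downstream. ``mode='competing'`` instead draws both
    clocks for every molecule and keeps the minimum.
    """

    field_size: int = 128
    pixel_size_um: float = 0.042
    frame_interval_s: float = 1.0
    n_frames: int = 300
    appearance_rate: float = 5.0  # events/s over the whole field
    k_true: float = 1.0 / 11.5  # unbinding rate, 1/s
    kp_true: float = 0.031  # photobleaching rate, 1/s
    bleach_fraction: float = 0.22
    spot_amplitude: float = 150.0
    noise_sd: float = 30.0  # SNR = spot_amplitude / noise_sd
    background_level: float = 100.0
    psf_sigma_px: float = 1.3
    margin_px: float = 5.0
    mode: str = "mixture"  # or "competing"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_true, self.kp_true, self.appearance_rate) < 0:
            raise ValueError("rates must be non-negative")
        if not 0.0 <= self.bleach_fraction <= 1.0:
            raise ValueError("bleach_fraction must lie in [0, 1]")
        if self.k_true == 0 and self.kp_true == 0:
            raise ValueError("no disappearance mechanism: both rates are zero")
        if self.mode not in ("mixture", "competing"):
            raise ValueError("mode must be 'mixture' or 'competing'")


def sample_dwell_times(
    n: int,
    k: float,
    kp: float,
    bleach_fraction: float,
    rng: np.random.Generator,
    mode: str = "mixture",
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` dwell times and their termination causes.

    Returns ``(dwell_s, cause)`` where cause is ``'unbind'`` or ``'bleach'``.
    """
    if mode == "mixture":
        is_bleach = rng.uniform(size=n) < bleach_fraction
        dwell = np.where(
            is_bleach,
            rng.exponential(1.0 / kp if kp > 0 else np.inf, size=n),
            rng.exponential(1.0 / k if k > 0 else np.inf, size=n),
        )
    elif mode == "competing":
        t_u = rng.exponential(1.0 / k, size=n) if k > 0 else np.full(n, np.inf)
        t_b = rng.exponential(1.0 / kp, size=n) if kp > 0 else np.full(n, np.inf)
        is_bleach = t_b < t_u
        dwell = np.minimum(t_u, t_b)
    else:
        raise ValueError("mode must be 'mixture' or 'competing'")
    cause = np.where(is_bleach, "bleach", "unbind")
    return dwell, cause


def simulate_sm_events(cfg: SmSimConfig) -> pd.DataFrame:
    """Ground-truth event table: Poisson appearances with mixture dwells.

    Columns: ``event_id, birth_time_s, dwell_s, cause, x_px, y_px``.
    """
    rng = np.random.default_rng(cfg.seed)
    total_time = cfg.n_frames * cfg.frame_interval_s
    n_events = rng.poisson(cfg.appearance_rate * total_time)
    birth = np.sort(rng.uniform(0.0, total_time, size=n_events))
    dwell, cause = sample_dwell_times(
        n_events, cfg.k_true, cfg.kp_true, cfg.bleach_fraction, rng, cfg.mode
    )
    lo, hi = cfg.margin_px, cfg.field_size - 1 - cfg.margin_px
    x = rng.uniform(lo, hi, size=n_events)
    y = rng.uniform(lo, hi, size=n_events)
    return pd.DataFrame(
        {
            "event_id": np.arange(n_events),
            "birth_time_s": birth,
            "dwell_s": dwell,
            "cause": cause,
            "x_px": x,
            "y_px": y,
        }
    )


def discretize_dwells(
    events: pd.DataFrame, frame_interval_s: float, n_frames: int
) -> pd.DataFrame:
    """Map continuous events onto the frame grid as a tracker would see them.

    A molecule is visible in frame ``i`` when ``birth <= i*dt < birth+dwell``.
    Adds ``n_frames_present``, ``residence_s`` (first-to-last detection,
    ``(m-1)*dt``) and ``censored`` (visible in the first or last frame);
    events visible in no frame are dropped.
    """
    dt = frame_interval_s
    birth = events["birth_time_s"].to_numpy()
    death = birth + events["dwell_s"].to_numpy()
    first = np.ceil(birth / dt).astype(int)
    first = np.maximum(first, 0)
    # last visible frame index: largest i with i*dt < death
    last = np.ceil(death / dt).astype(int) - 1
    last_clip = np.minimum(last, n_frames - 1)
    visible = (last_clip >= first) & (first < n_frames)
    out = events.loc[visible].copy()
    f = first[visible]
    l = last_clip[visible]
    out["first_frame"] = f
    out["last_frame"] = l
    out["n_frames_present"] = l - f + 1
    out["residence_s"] = (l - f) * dt
    out["censored"] = (f == 0) | (last[visible] >= n_frames - 1)
    return out.reset_index(drop=True)


def simulate_sm_movie(cfg: SmSimConfig) -> tuple[Movie, pd.DataFrame]:
    """Render the single-molecule channel and return the movie plus events.

    Each molecule is an immobile 2-D Gaussian of ``psf_sigma_px`` at its
    ground-truth position for every frame of its dwell; frames get a constant
    background and i.i.d. Gaussian noise.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # independent of event draws
    events = simulate_sm_events(cfg)
    vis = discretize_dwells(events, cfg.frame_interval_s, cfg.n_frames)

    n = cfg.field_size
    stack = np.full((cfg.n_frames, n, n), float(cfg.background_level))
    half = int(np.ceil(4 * cfg.psf_sigma_px))
    win = np.arange(-half, half + 1)
    gx, gy = np.meshgrid(win, win)
    for row in vis.itertuples():
        xi, yi = int(round(row.x_px)), int(round(row.y_px))
        dx, dy = row.x_px - xi, row.y_px - yi
        spot = cfg.spot_amplitude * np.exp(
            -((gx - dx) ** 2 + (gy - dy) ** 2) / (2 * cfg.psf_sigma_px**2)
        )
        ys = slice(max(yi - half, 0), min(yi + half + 1, n))
        xs = slice(max(xi - half, 0), min(xi + half + 1, n))
        sy = slice(ys.start - (yi - half), spot.shape[0] - ((yi + half + 1) - ys.stop))
        sx = slice(xs.start - (xi - half), spot.shape[1] - ((xi + half + 1) - xs.stop))
        stack[row.first_frame : row.last_frame + 1, ys, xs] += spot[sy, sx]

    if cfg.noise_sd > 0:
        stack += rng.normal(0.0, cfg.noise_sd, size=stack.shape)
    stack = np.clip(stack, 0, None)
    movie = Movie(stack, pixel_size_um=cfg.pixel_size_um, frame_interval_s=cfg.frame_interval_s)
    return movie, events
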