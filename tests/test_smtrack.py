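"""Spot detection, linking, residence collection and survival fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage
from scipy.spatial import cKDTree

from ftszring import simulate, smtrack


def _dog_peak(amplitude, psf_sigma=1.3, low=1.0, high=4.0):
    """Filtered peak height of a rendered spot — used to set thresholds."""
    yy, xx = np.mgrid[-20:21, -20:21]
    spot = amplitude * np.exp(-(xx**2 + yy**2) / (2 * psf_sigma**2))
    bp = ndimage.gaussian_filter(spot, low) - ndimage.gaussian_filter(spot, high)
    return bp.max()


class TestDetect:
    def test_noiseless_integer_spot_localised_exactly(self, gaussian_spot_frame):
        spots = smtrack.detect_spots(gaussian_spot_frame(12, 9), threshold=20)
        assert len(spots) == 1
        assert spots.x[0] == pytest.approx(12.0, abs=1e-3)
        assert spots.y[0] == pytest.approx(9.0, abs=1e-3)

    def test_subpixel_localization_at_snr5(self, gaussian_spot_frame):
        """Mean position over 100 renders within 0.15 px; scatter near the
        background-noise information bound (~0.16 px per axis)."""
        rng = np.random.default_rng(7)
        est = []
        for _ in range(100):
            frame = gaussian_spot_frame(10.3, 7.6, noise_sd=30.0, rng=rng)
            spots = smtrack.detect_spots(frame, threshold=20)
            assert len(spots) >= 1
            j = np.hypot(spots.x - 10.3, spots.y - 7.6).idxmin()
            est.append((spots.x[j], spots.y[j]))
        est = np.array(est)
        bias = np.hypot(*(est.mean(axis=0) - (10.3, 7.6)))
        assert bias < 0.15
        assert est.std(axis=0).max() < 0.25

    def test_recall_at_snr2(self):
        """50 spots at SNR 2 on a noisy field: recall >= 0.95."""
        rng = np.random.default_rng(3)
        size, noise_sd, amplitude = 200, 30.0, 60.0
        pos = rng.uniform(10, size - 10, (50, 2))
        yy, xx = np.mgrid[0:size, 0:size]
        img = np.full((size, size), 100.0)
        for x, y in pos:
            img += amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 1.3**2))
        img += rng.normal(0, noise_sd, img.shape)
        spots = smtrack.detect_spots(img, threshold=0.5 * _dog_peak(amplitude))
        d, _ = cKDTree(spots[["x", "y"]].to_numpy()).query(pos)
        assert (d < 2).mean() >= 0.95

    def test_nonpositive_threshold_rejected(self, gaussian_spot_frame):
        with pytest.raises(ValueError):
            smtrack.detect_spots(gaussian_spot_frame(10, 10), threshold=0)


class TestLink:
    @staticmethod
    def _spots(rows):
        return pd.DataFrame(rows, columns=["frame", "x", "y", "brightness"])

    def test_single_immobile_molecule_residence(self):
        spots = self._spots([(f, 20.0, 20.0, 1.0) for f in range(3, 13)])
        _, tracks = smtrack.link_tracks(spots, n_frames=20, frame_interval_s=1.0)
        assert len(tracks) == 1
        assert tracks.residence_s[0] == 9.0
        assert not tracks.censored[0]

    def test_distant_molecules_never_merged(self):
        rows = [(f, 10.0, 10.0, 1.0) for f in range(5)]
        rows += [(f, 40.0, 10.0, 1.0) for f in range(5)]
        _, tracks = smtrack.link_tracks(self._spots(rows), n_frames=10, frame_interval_s=1.0)
        assert len(tracks) == 2
        assert (tracks.n_frames == 5).all()

    def test_gap_ends_track(self):
        rows = [(0, 5.0, 5.0, 1.0), (1, 5.0, 5.0, 1.0), (3, 5.0, 5.0, 1.0)]
        _, tracks = smtrack.link_tracks(self._spots(rows), n_frames=10, frame_interval_s=1.0)
        assert len(tracks) == 2

    def test_boundary_tracks_censored(self):
        rows = [(0, 5.0, 5.0, 1.0), (1, 5.0, 5.0, 1.0)]
        rows += [(8, 30.0, 5.0, 1.0), (9, 30.0, 5.0, 1.0)]
        _, tracks = smtrack.link_tracks(self._spots(rows), n_frames=10, frame_interval_s=1.0)
        assert tracks.censored.all()

    def test_ground_truth_dwells_recovered_on_sparse_field(self):
        """>= 95% of usable simulated dwells match a track within one frame.

        Sparse field (0.005 appearance events per px^2 over a 10-min, 1-fps
        acquisition); residual mismatches come from molecules overlapping in
        space and time.
        """
        ok = total = 0
        for seed in range(3):
            field, n_frames = 192, 600
            cfg = simulate.SmSimConfig(
                field_size=field,
                n_frames=n_frames,
                appearance_rate=0.005 * field**2 / n_frames,
                seed=seed,
            )
            movie, events = simulate.simulate_sm_movie(cfg)
            thr = 0.4 * _dog_peak(cfg.spot_amplitude, cfg.psf_sigma_px)
            spots = smtrack.detect_movie(movie.data, thr)
            _, tracks = smtrack.link_tracks(spots, n_frames, cfg.frame_interval_s)
            vis = simulate.discretize_dwells(events, cfg.frame_interval_s, n_frames)
            usable = vis[~vis.censored & (vis.n_frames_present >= 3)]
            d, idx = cKDTree(tracks[["x", "y"]].to_numpy()).query(
                usable[["x_px", "y_px"]].to_numpy()
            )
            matched = (d < 3) & (
                np.abs(tracks.iloc[idx].residence_s.to_numpy() - usable.residence_s.to_numpy())
                <= cfg.frame_interval_s
            )
            ok += matched.sum()
            total += len(usable)
        assert ok / total >= 0.95


class TestResidences:
    @staticmethod
    def _tracks(lengths, n_frames=100, start=10):
        rows = []
        for i, n in enumerate(lengths):
            rows.append((i, start, start + n - 1, n, 0.0, 0.0, float(n - 1), False))
        return pd.DataFrame(
            rows,
            columns=["track_id", "start_frame", "end_frame", "n_frames", "x", "y", "residence_s", "censored"],
        )

    def test_sub_two_frame_events_excluded(self):
        """Tracks of 1, 2 and 5 frames at 1 fps: the 1-frame event is dropped."""
        rs = smtrack.collect_residences(self._tracks([1, 2, 5]), 1.0)
        assert sorted(rs.residences_s) == [1.0, 4.0]
        assert rs.n_excluded_short == 1

    def test_all_censored_is_an_error(self):
        tracks = self._tracks([5, 6])
        tracks["censored"] = True
        with pytest.raises(ValueError, match="no usable events"):
            smtrack.collect_residences(tracks, 1.0)

    def test_censored_kept_when_requested(self):
        tracks = self._tracks([5, 6])
        tracks["censored"] = True
        rs = smtrack.collect_residences(tracks, 1.0, drop_censored=False)
        assert rs.n_events == 2

    def test_empirical_survival_is_monotone_and_starts_at_one(self):
        rng = np.random.default_rng(0)
        res = np.round(rng.exponential(10, 500)) + 1
        t, surv = smtrack.empirical_survival(smtrack.ResidenceSet(res, 1.0))
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 0).all()


class TestSurvivalFit:
    def test_exact_model_curve_self_consistent(self):
        """Fitting the noiseless model curve returns its own parameters."""
        b, k, kp = 0.22, 0.087, 0.031
        t = np.arange(0, 120.0)
        surv = (1 - b) * np.exp(-k * t) + b * np.exp(-kp * t)
        fit = smtrack.fit_survival_curve(t, surv, kp_mode="free", kp0=0.02)
        assert fit.B == pytest.approx(b, abs=1e-4)
        assert fit.k == pytest.approx(k, rel=1e-4)
        assert fit.kp == pytest.approx(kp, rel=1e-3)
        assert fit.t_r == pytest.approx(1 / k, rel=1e-4)

    def test_parameter_recovery_from_simulated_events(self):
        from ftszring import workflows

        out = workflows.residence_recovery_experiment(seed=5, k_true=1 / 11.5, fps=1.0)
        assert out["t_r_s"] == pytest.approx(11.5, rel=0.10)

    def test_single_exponential_limit_matches_mle_mean(self):
        """With kp = k the fitted 1/k agrees with the ML mean dwell within 5%."""
        rng = np.random.default_rng(8)
        k, dt = 0.5, 0.1
        res = dt * np.ceil(rng.exponential(1 / k, 4000) / dt) + dt  # >= 2 frames
        rs = smtrack.ResidenceSet(res, dt)
        fit = smtrack.fit_survival(rs, kp_mode="fixed", kp0=k)
        mle_mean = (res - res.min()).mean() + dt / 2  # discretisation midpoint
        assert fit.t_r == pytest.approx(mle_mean, rel=0.05)

    def test_short_event_cut_biases_mean_but_not_fitted_rate(self):
        """The <2-frame cut inflates the naive mean; the fit stays consistent."""
        out = []
        rng = np.random.default_rng(9)
        k, dt = 1 / 5.0, 1.0
        dwell = rng.exponential(1 / k, 8000)
        events = pd.DataFrame(
            {
                "event_id": np.arange(dwell.size),
                "birth_time_s": rng.uniform(0, 1e5, dwell.size),
                "dwell_s": dwell,
                "cause": "unbind",
            }
        )
        vis = simulate.discretize_dwells(events, dt, 100001)
        usable = vis[~vis.censored & (vis.n_frames_present >= 2)]
        naive_mean = usable.residence_s.mean()
        assert naive_mean > 1 / k  # truncation bias
        rs = smtrack.ResidenceSet(usable.residence_s.to_numpy(), dt)
        fit = smtrack.fit_survival(rs, kp_mode="fixed", kp0=k)  # degenerate mixture
        assert fit.t_r == pytest.approx(1 / k, rel=0.10)

    def test_frame_rate_consistency(self):
        """Fits at 1 fps and 3 fps agree within 10% when k << frame rate."""
        from ftszring import workflows

        slow = workflows.residence_recovery_experiment(seed=6, k_true=1 / 11.5, fps=1.0)
        fast = workflows.residence_recovery_experiment(seed=6, k_true=1 / 11.5, fps=3.0)
        assert fast["t_r_s"] == pytest.approx(slow["t_r_s"], rel=0.10)

    def test_small_sample_warns(self):
        rng = np.random.default_rng(1)
        rs = smtrack.ResidenceSet(np.ceil(rng.exponential(10, 50)), 1.0)
        with pytest.warns(UserWarning, match="events"):
            smtrack.fit_survival(rs)


class TestPhotobleachingCalibration:
    def test_exact_exponential_recovered(self):
        t = np.arange(0, 200.0)
        fitted = []
        surv = np.exp(-0.031 * t)
        # route through a ResidenceSet built so its survival equals the curve
        rng = np.random.default_rng(2)
        res = np.ceil(rng.exponential(1 / 0.031, 20000))
        kp = smtrack.calibrate_photobleaching(smtrack.ResidenceSet(res, 1.0))
        assert kp == pytest.approx(0.031, rel=0.05)

    def test_simulated_immobilised_control(self):
        from ftszring import workflows

        out = workflows.bleach_calibration_experiment(seed=3)
        assert out["kp_s"] == pytest.approx(0.031, rel=0.10)

    def test_contaminated_control_warns(self):
        rng = np.random.default_rng(4)
        res = np.concatenate(
            [np.ceil(rng.exponential(5, 3000)), np.ceil(rng.exponential(120, 3000))]
        )
        with pytest.warns(UserWarning, match="single exponential"):
            smtrack.calibrate_photobleaching(smtrack.ResidenceSet(res, 1.0))
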