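"""Simulator ground truth: closed-form limits, determinism, allocation."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synapsekit import SynapseGeometry, simulate
from synapsekit.simulate import (
    largest_remainder_allocation,
    render_movie,
    render_synapse_channels,
    simulate_screen_dataset,
    simulate_trackset,
    simulate_trajectory,
)
from synapsekit.screen import fit_4pl, four_param_logistic
from synapsekit.types import MODE_CONFINED, MODES, TrackSet


class TestSimulateTrajectory:
    def test_zero_diffusion_is_stationary(self):
        traj = simulate_trajectory("normal", n_frames=20, D=0.0, start=(2.0, 3.0), seed=0)
        assert np.all(traj.positions == (2.0, 3.0))

    def test_pure_drift_is_ballistic(self):
        # 19 steps of v*dt = 0.025 um along the drift direction
        traj = simulate_trajectory(
            "active", n_frames=20, dt=0.05, D=0.0, v=0.5,
            direction=(1.0, 0.0), start=(0.0, 0.0), seed=0,
        )
        net = traj.positions[-1] - traj.positions[0]
        assert net == pytest.approx([0.475, 0.0], abs=1e-12)

    def test_brownian_one_frame_msd_matches_closed_form(self):
        # Monte-Carlo vs 4*D*dt, tolerance 3 standard errors
        D, dt = 0.1, 0.05
        traj = simulate_trajectory("normal", n_frames=10_001, dt=dt, D=D, seed=7)
        sq = (np.diff(traj.positions, axis=0) ** 2).sum(axis=1)
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 4 * D * dt) < 3 * se

    def test_confined_never_leaves_corral(self):
        R = 0.15
        traj = simulate_trajectory(
            "confined", n_frames=500, D=0.1, corral_radius=R, start=(5.0, 5.0), seed=3,
        )
        d = np.hypot(traj.positions[:, 0] - 5.0, traj.positions[:, 1] - 5.0)
        assert d.max() <= R + 1e-12

    def test_deterministic_given_seed(self):
        a = simulate_trajectory("normal", n_frames=50, D=0.2, seed=11)
        b = simulate_trajectory("normal", n_frames=50, D=0.2, seed=11)
        assert np.array_equal(a.positions, b.positions)

    @pytest.mark.parametrize(
        "kwargs, message",
        [
            (dict(mode="ballistic", n_frames=5), "unknown mode"),
            (dict(mode="normal", n_frames=5, dt=0.0), "dt"),
            (dict(mode="confined", n_frames=5, corral_radius=0.0), "corral"),
            (dict(mode="normal", n_frames=1), "n_frames"),
        ],
    )
    def test_invalid_inputs_raise(self, kwargs, message):
        mode = kwargs.pop("mode")
        with pytest.raises(ValueError, match=message):
            simulate_trajectory(mode, **kwargs)


class TestLargestRemainder:
    def test_forced_allocation(self):
        assert list(largest_remainder_allocation(300, (0.6, 0.2, 0.2))) == [180, 60, 60]

    @settings(derandomize=True, max_examples=50)
    @given(
        n=st.integers(1, 500),
        weights=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=5),
    )
    def test_conserves_total(self, n, weights):
        p = np.asarray(weights) / np.sum(weights)
        assert largest_remainder_allocation(n, p).sum() == n

    def test_rejects_bad_proportions(self):
        with pytest.raises(ValueError):
            largest_remainder_allocation(10, (0.5, 0.6))


class TestSimulateTrackset:
    def test_single_mode_proportions(self, geometry):
        ts = simulate_trackset(geometry, (1.0, 0.0, 0.0), 20, n_frames=10, seed=0)
        assert all(t.true_mode == "normal" for t in ts)

    def test_mode_counts_follow_allocation(self, geometry):
        ts = simulate_trackset(geometry, (0.6, 0.2, 0.2), 300, n_frames=5, seed=0)
        counts = {m: sum(t.true_mode == m for t in ts) for m in MODES}
        assert counts == {"normal": 180, "active": 60, "confined": 60}

    def test_confined_tracks_bounded_and_starts_inside_contact(self, geometry):
        ts = simulate_trackset(geometry, (0.0, 0.0, 1.0), 10, n_frames=100, seed=1)
        cx, cy = geometry.center
        for t in ts:
            start = t.positions[0]
            assert np.hypot(start[0] - cx, start[1] - cy) <= geometry.r_contact
            d = np.hypot(*(t.positions - start).T)
            assert d.max() <= 0.15 + 1e-12


class TestRenderSynapseChannels:
    def test_uniform_spec_gives_uniform_contact(self, geometry):
        spec = {"receptor": lambda r: np.where(np.asarray(r) < geometry.r_contact, 50.0, 2.0)}
        img = render_synapse_channels(geometry, spec, noise="none")
        r = geometry.radius_map()
        inside = img["receptor"][r < geometry.r_contact - 0.1]
        assert np.all(inside == 50.0)

    def test_pixel_value_equals_spec_at_pixel_radius(self, geometry):
        spec = {"receptor": lambda r: 10.0 + np.asarray(r) ** 2}
        img = render_synapse_channels(geometry, spec, noise="none")
        r = geometry.radius_map()
        assert np.allclose(img["receptor"], 10.0 + r**2)

    def test_poisson_mean_matches_clean_value(self):
        geo = SynapseGeometry(center=(1.6, 1.6), r_csmac=0.4, r_psmac=0.8,
                              r_contact=1.2, pixel_size=0.1, image_shape=(32, 32))
        spec = {"receptor": lambda r: np.full_like(np.asarray(r, dtype=float), 40.0)}
        clean = render_synapse_channels(geo, spec, noise="none")["receptor"]
        stack = np.stack([
            render_synapse_channels(geo, spec, noise="poisson", seed=s)["receptor"]
            for s in range(200)
        ])
        se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
        within = np.abs(stack.mean(axis=0) - clean) < 3.0 * se
        # per-pixel agreement at the ~3-sigma level across the whole image
        assert within.mean() > 0.985
        grand_se = clean.std() / np.sqrt(clean.size * stack.shape[0])
        assert abs(stack.mean() - clean.mean()) < max(3 * grand_se, 0.05)

    def test_negative_spec_rejected(self, geometry):
        with pytest.raises(ValueError, match="negative"):
            render_synapse_channels(geometry, {"receptor": lambda r: np.asarray(r) - 100.0})


class TestRenderMovie:
    def _single_spot_movie(self, x_px, y_px, **kwargs):
        from synapsekit.types import Trajectory

        traj = Trajectory(
            track_id=0, frames=[0],
            positions=[[(x_px + 0.5) * 0.1, (y_px + 0.5) * 0.1]], dt=0.05,
        )
        return render_movie(TrackSet(tracks=[traj], dt=0.05), shape=(64, 64), **kwargs)

    def test_argmax_pixel_contains_true_position(self):
        movie = self._single_spot_movie(10, 20, noise="none")
        i, j = np.unravel_index(np.argmax(movie.frames[0]), movie.frames[0].shape)
        assert (i, j) == (20, 10)

    def test_spot_mass_conservation(self):
        movie = self._single_spot_movie(30, 30, noise="none", background=5.0,
                                        photons_per_spot=500.0)
        total = (movie.frames[0] - 5.0).sum()
        assert total == pytest.approx(500.0, rel=0.01)

    def test_out_of_bounds_position_warns_and_flags(self):
        from synapsekit.types import Trajectory

        traj = Trajectory(track_id=0, frames=[0], positions=[[-1.0, 2.0]], dt=0.05)
        with pytest.warns(UserWarning, match="clip"):
            movie = render_movie(TrackSet(tracks=[traj], dt=0.05), shape=(32, 32))
        assert movie.meta["clipped"]


class TestSimulateScreenDataset:
    def test_baseline_at_zero_concentration(self):
        params = {"KO1": {"baseline": 0.07, "top": 0.5, "log_ec50": 0.0, "hill": 1.0}}
        ds = simulate_screen_dataset(params, noise_sd=0.0, n_donors=2, seed=0)
        zero = ds.table[ds.table["conc_ng_ml"] == 0]
        assert np.allclose(zero["frac_pos"], 0.07)

    def test_noise_free_curve_recovered_by_fit(self):
        params = {"KO1": {"baseline": 0.05, "top": 0.5, "log_ec50": 0.3, "hill": 1.2}}
        ds = simulate_screen_dataset(params, noise_sd=0.0, n_donors=1, seed=0)
        sub = ds.table[ds.table["conc_ng_ml"] > 0]
        # responses on the fraction scale, baseline subtracted
        fit = fit_4pl(sub["conc_ng_ml"], sub["frac_pos"] - 0.05)
        assert fit.log_ec50 == pytest.approx(0.3, abs=1e-4)
        assert fit.hill == pytest.approx(1.2, abs=1e-4)

    def test_log_ec50_recovered_under_donor_noise(self):
        params = {"KO1": {"baseline": 0.05, "top": 0.5, "log_ec50": 0.3, "hill": 1.0}}
        errors = []
        for seed in range(20):
            ds = simulate_screen_dataset(params, noise_sd=0.02, n_donors=6, seed=seed)
            sub = ds.table[ds.table["conc_ng_ml"] > 0]
            fit = fit_4pl(sub["conc_ng_ml"], sub["frac_pos"] - 0.05)
            errors.append(abs(fit.log_ec50 - 0.3))
        assert max(errors) < 0.2

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_screen_dataset(noise_sd=-0.1)
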