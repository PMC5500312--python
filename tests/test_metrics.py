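import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendrospt.geometry import DendriteGeometry, Synapse, SynapseMap
from dendrospt.metrics import (
    EXTRASYNAPTIC,
    InsufficientDataError,
    analyze_tracks,
    classify_points,
    compute_msd,
    detect_transitions,
    dwell_episodes,
    fit_diffusion_msd,
    msd_steady_state,
)
from dendrospt.simulate import SimulationParams, simulate_trajectory

from oracles import brute_force_msd, disk_membership_raster, transitions_by_enumeration


class TestComputeMSD:
    def test_stationary_trajectory_msd_zero(self, traj_factory):
        traj = traj_factory(range(10), [1.0] * 10, [2.0] * 10)
        curve = compute_msd(traj, dt=0.05)
        np.testing.assert_allclose(curve.msd, 0.0, atol=1e-15)

    def test_uniform_steps_single_lag_value(self, traj_factory):
        # steps of 0.1 μm per frame along x: msd(1 frame) = 0.01 μm²
        xs = np.arange(6) * 0.1
        traj = traj_factory(range(6), xs, np.zeros(6))
        curve = compute_msd(traj, max_lag=1, dt=0.05)
        assert curve.lags[0] == pytest.approx(0.05)
        assert curve.msd[0] == pytest.approx(0.01)
        assert curve.n_pairs[0] == 5

    def test_too_few_points_raises(self, traj_factory):
        traj = traj_factory(range(4), np.zeros(4), np.zeros(4))
        with pytest.raises(InsufficientDataError):
            compute_msd(traj)

    def test_matches_double_loop_on_toy_trajectory(self, traj_factory):
        frames = [0, 1, 2, 3, 4, 5]
        xs = [0.0, 0.1, 0.05, 0.2, 0.15, 0.3]
        ys = [0.0, -0.05, 0.1, 0.0, 0.2, 0.1]
        traj = traj_factory(frames, xs, ys)
        curve = compute_msd(traj, max_lag=4, dt=0.05)
        xy = list(zip(xs, ys))
        for k, lag in enumerate([1, 2, 3, 4]):
            expect, n = brute_force_msd(frames, xy, lag)
            assert curve.msd[k] == pytest.approx(expect)
            assert curve.n_pairs[k] == n

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_double_loop_on_random_gapped_trajectories(self, seed):
        """Frame-indexed MSD equals brute-force evaluation over all pairs,
        including trajectories with blink gaps."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 25))
        frames = np.sort(rng.choice(60, size=n, replace=False))
        xy = rng.normal(0, 0.3, size=(n, 2))
        traj = pd.DataFrame(
            {"frame": frames, "x_um": xy[:, 0], "y_um": xy[:, 1]}
        )
        max_lag = int(frames[-1] - frames[0])
        curve = compute_msd(traj, max_lag=max_lag, dt=0.05)
        for k, lag in enumerate(range(1, max_lag + 1)):
            expect, npairs = brute_force_msd(frames, xy, lag)
            assert curve.n_pairs[k] == npairs
            if npairs:
                assert curve.msd[k] == pytest.approx(expect)
            else:
                assert np.isnan(curve.msd[k])


class TestFitDiffusion:
    def test_exact_line_recovers_slope_over_four(self):
        from dendrospt.metrics import MSDCurve

        curve = MSDCurve(
            lags=np.array([0.05, 0.10, 0.15, 0.20]),
            msd=np.array([0.01, 0.02, 0.03, 0.04]),
            n_pairs=np.array([10, 9, 8, 7]),
            dt=0.05,
        )
        est = fit_diffusion_msd(curve)
        assert est.D == pytest.approx(0.05)  # slope 0.2 μm²/s over 4
        assert not est.confined

    def test_flat_msd_clamps_to_zero_with_confined_flag(self):
        from dendrospt.metrics import MSDCurve

        curve = MSDCurve(
            lags=np.array([0.05, 0.10, 0.15, 0.20]),
            msd=np.full(4, 0.05),
            n_pairs=np.array([10, 9, 8, 7]),
            dt=0.05,
        )
        est = fit_diffusion_msd(curve)
        assert est.D == 0.0
        assert est.confined

    def test_intercept_absorbs_localization_noise_offset(self, wide_geometry):
        """Static 40 nm noise adds ≈ 4σ² to every MSD value; the intercept
        takes it and the slope-based D stays calibrated."""
        p = SimulationParams(
            D_long=0.05, D_trans=0.05, n_frames=1200, loc_noise_sd=0.04, seed=33
        )
        rng = np.random.default_rng(17)
        Ds, intercepts = [], []
        for _ in range(60):
            locs, _ = simulate_trajectory(wide_geometry, None, p, rng=rng, start_uv=(100.0, 0.0))
            est = fit_diffusion_msd(compute_msd(locs, max_lag=4, dt=0.05))
            Ds.append(est.D)
            intercepts.append(est.intercept)
        assert np.median(Ds) == pytest.approx(0.05, rel=0.15)
        assert np.median(intercepts) == pytest.approx(4 * 0.04**2, rel=0.5)

    def test_parameter_recovery_at_published_median(self, wide_geometry):
        """Free diffusion at D = 0.066 μm²/s is recovered by the MSD fit."""
        D = 0.066
        p = SimulationParams(
            D_long=D, D_trans=D, n_frames=1200, loc_noise_sd=0.0, seed=1
        )
        rng = np.random.default_rng(5)
        Ds = []
        for _ in range(100):
            locs, _ = simulate_trajectory(
                wide_geometry, None, p, rng=rng, start_uv=(100.0, 0.0)
            )
            Ds.append(fit_diffusion_msd(compute_msd(locs, max_lag=4, dt=0.05)).D)
        assert np.median(Ds) == pytest.approx(D, rel=0.10)


class TestClassifyPoints:
    def test_center_point_is_synaptic(self, traj_factory, two_synapse_map):
        traj = traj_factory([0], [3.0], [0.0])
        assert classify_points(traj, two_synapse_map)[0] == 0

    def test_far_point_is_extrasynaptic(self, traj_factory, two_synapse_map):
        traj = traj_factory([0], [3.0], [5.0])
        assert classify_points(traj, two_synapse_map)[0] == EXTRASYNAPTIC

    def test_boundary_point_is_synaptic_inclusive(self, traj_factory):
        m = SynapseMap(synapses=[Synapse(0, "inhibitory", (0.0, 0.0), 0.2)])
        r_eff = 0.2 + 2 * 0.16
        traj = traj_factory([0], [r_eff], [0.0])
        assert classify_points(traj, m)[0] == 0
        just_out = traj_factory([0], [r_eff + 1e-6], [0.0])
        assert classify_points(just_out, m)[0] == EXTRASYNAPTIC

    def test_membership_agrees_with_raster_oracle(self, traj_factory):
        m = SynapseMap(synapses=[Synapse(0, "inhibitory", (1.0, -0.5), 0.25)])
        r_eff = 0.25 + 0.32
        rng = np.random.default_rng(2)
        pts = rng.uniform([-0.2, -1.7], [2.2, 0.7], size=(200, 2))
        # keep points away from the boundary shell where raster resolution matters
        d = np.hypot(pts[:, 0] - 1.0, pts[:, 1] + 0.5)
        pts = pts[np.abs(d - r_eff) > 1e-3]
        traj = traj_factory(range(len(pts)), pts[:, 0], pts[:, 1])
        labels = classify_points(traj, m)
        for p, lab in zip(pts, labels):
            assert (lab == 0) == disk_membership_raster(p, (1.0, -0.5), r_eff)

    def test_overlap_resolved_by_nearest_center(self, traj_factory):
        m = SynapseMap(
            synapses=[
                Synapse(0, "inhibitory", (0.0, 0.0), 0.5),
                Synapse(1, "inhibitory", (1.0, 0.0), 0.5),
            ]
        )
        traj = traj_factory([0, 1], [0.4, 0.6], [0.0, 0.0])
        labels = classify_points(traj, m)
        assert labels.tolist() == [0, 1]


class TestTransitionsAndDwell:
    DT = 0.05

    def test_endpoint_convention_four_frame_transition(self):
        labels = np.array([0, 0, -1, -1, -1, 1])
        frames = np.arange(6)
        events = detect_transitions(labels, frames, dt=self.DT)
        assert len(events) == 1
        e = events[0]
        assert (e.source_id, e.target_id) == (0, 1)
        assert (e.exit_frame, e.entry_frame) == (1, 5)
        assert e.transition_time == pytest.approx(0.20)

    def test_single_compartment_no_events(self):
        labels = np.zeros(10, dtype=int)
        assert detect_transitions(labels, np.arange(10), dt=self.DT) == []

    def test_self_reentry_emits_nothing_but_a_to_b_does(self):
        labels = np.array([0, -1, 0, -1, 1])
        events = detect_transitions(labels, np.arange(5), dt=self.DT)
        assert len(events) == 1
        assert events[0].source_id == 0 and events[0].target_id == 1
        assert events[0].exit_frame == 2

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.integers(-1, 2), min_size=1, max_size=40))
    def test_transitions_match_run_length_enumeration(self, labels):
        frames = np.arange(len(labels))
        got = detect_transitions(np.array(labels), frames, dt=self.DT)
        expect = transitions_by_enumeration(labels, list(frames), self.DT)
        assert [
            (e.source_id, e.target_id, e.exit_frame, e.entry_frame, e.transition_time)
            for e in got
        ] == expect

    def test_no_third_synapse_inside_any_event_interval(self):
        rng = np.random.default_rng(0)
        labels = rng.choice([-1, 0, 1, 2], size=300, p=[0.55, 0.15, 0.15, 0.15])
        frames = np.arange(300)
        for e in detect_transitions(labels, frames, dt=self.DT):
            inner = labels[e.exit_frame + 1 : e.entry_frame]
            third = set(inner) - {-1, e.source_id, e.target_id}
            assert not third
            # and strictly: no synaptic frame at all strictly inside
            assert (inner == -1).all()

    def test_dwell_durations_count_run_length(self):
        labels = np.array([-1] + [0] * 26 + [-1])
        frames = np.arange(len(labels))
        eps = dwell_episodes(labels, frames, dt=self.DT)
        assert len(eps) == 1
        assert eps[0].duration == pytest.approx(1.3)

    def test_no_synaptic_frames_empty_dwells(self):
        labels = np.full(10, -1)
        assert dwell_episodes(labels, np.arange(10), dt=self.DT) == []

    def test_alternating_labels_single_frame_episodes(self):
        labels = np.array([0, -1] * 5)
        eps = dwell_episodes(labels, np.arange(10), dt=self.DT)
        assert len(eps) == 5
        assert all(e.duration == pytest.approx(0.05) for e in eps)

    def test_dwell_plus_extrasynaptic_time_conserved(self):
        rng = np.random.default_rng(4)
        labels = rng.choice([-1, 0, 1], size=200)
        frames = np.arange(200)
        eps = dwell_episodes(labels, frames, dt=self.DT)
        syn_time = sum(e.duration for e in eps)
        extra_time = (labels == -1).sum() * self.DT
        assert syn_time + extra_time == pytest.approx(len(labels) * self.DT)

    def test_enlarging_regions_never_shrinks_dwell_durations(self, wide_geometry):
        p = SimulationParams(D_long=0.05, D_trans=0.05, n_frames=500, loc_noise_sd=0.0, seed=3)
        locs, _ = simulate_trajectory(wide_geometry, None, p, start_uv=(100.0, 0.0))
        frames = locs["frame"].to_numpy()
        center = (locs["x_um"].median(), locs["y_um"].median())
        totals = []
        for radius in (0.3, 0.6, 1.2):
            m = SynapseMap(synapses=[Synapse(0, "inhibitory", center, radius)])
            eps = dwell_episodes(classify_points(locs, m), frames, dt=self.DT)
            totals.append(sum(e.duration for e in eps))
        assert totals[0] <= totals[1] <= totals[2]


class TestSteadyState:
    def make_curve(self, msd):
        from dendrospt.metrics import MSDCurve

        n = len(msd)
        return MSDCurve(
            lags=(np.arange(n) + 1) * 0.05,
            msd=np.asarray(msd, dtype=float),
            n_pairs=np.arange(n, 0, -1),
            dt=0.05,
        )

    def test_constant_msd_plateau_value(self):
        value, plateau = msd_steady_state(self.make_curve([0.05] * 40))
        assert value == pytest.approx(0.05)
        assert plateau

    def test_linear_msd_flagged_non_plateau(self):
        value, plateau = msd_steady_state(self.make_curve(np.arange(1, 41) * 0.01))
        assert not plateau

    def test_confined_steady_state_below_free(self, straight_geometry, wide_geometry):
        """Same D: confinement in a tight trap caps the MSD plateau."""
        tight = SynapseMap(synapses=[Synapse(0, "inhibitory", (6.0, 0.0), 0.05)])
        p_conf = SimulationParams(
            D_long=0.08, D_trans=0.08, n_frames=800, loc_noise_sd=0.0,
            trap_D_factor=0.02, trap_escape_prob=0.0, seed=8,
        )
        locs_c, _ = simulate_trajectory(straight_geometry, tight, p_conf, start_uv=(6.0, 0.0))
        p_free = SimulationParams(
            D_long=0.08, D_trans=0.08, n_frames=800, loc_noise_sd=0.0, seed=8
        )
        locs_f, _ = simulate_trajectory(wide_geometry, None, p_free, start_uv=(100.0, 0.0))
        ss_c, _ = msd_steady_state(compute_msd(locs_c, max_lag=100, dt=0.05))
        ss_f, _ = msd_steady_state(compute_msd(locs_f, max_lag=100, dt=0.05))
        assert ss_c < ss_f


class TestAnalyzeTracks:
    def test_tables_schema_and_consistency(self, straight_geometry, two_synapse_map):
        p = SimulationParams(
            D_long=0.1, D_trans=0.02, n_frames=600, loc_noise_sd=0.02,
            trap_D_factor=0.3, trap_escape_prob=0.05, seed=10,
        )
        from dendrospt.simulate import simulate_many

        locs, _ = simulate_many(8, straight_geometry, two_synapse_map, p)
        tables = analyze_tracks(locs, two_synapse_map, dt=0.05)
        tracks = tables["tracks"]
        assert {"track_id", "D_msd_um2s", "confined_flag", "n_transitions"} <= set(tracks.columns)
        assert (tracks["D_msd_um2s"] >= 0).all()
        if not tables["transitions"].empty:
            per_track = tables["transitions"].groupby("track_id").size()
            for tid, n in per_track.items():
                assert tracks.loc[tracks["track_id"] == tid, "n_transitions"].iloc[0] == n
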