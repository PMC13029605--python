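import numpy as np
import pytest

from acoustopiv.metrics import MeanVelocityTrace, amplitude_spectrum, dominant_peak
from acoustopiv.protocol import amp_high_protocol, amp_low_protocol
from acoustopiv.synthdata import (
    ChannelGeometry,
    ExperimentCondition,
    default_camera,
    default_geometry,
    mean_channel_velocity,
    particle_mass,
    render_frames,
    silica_beads,
    simulate_flow_sensor,
    simulate_trajectories,
    yeast_cells,
    _profile,
)


class TestParticleMass:
    @pytest.mark.parametrize(
        "radius, density, expected",
        [
            (3.0e-6, 1200.0, 1.36e-13),  # silica bead
            (2.5e-6, 1126.0, 7.37e-14),  # yeast cell
        ],
    )
    def test_spherical_mass_values(self, radius, density, expected):
        assert particle_mass(radius, density) == pytest.approx(expected, rel=5e-3)

    def test_zero_radius(self):
        assert particle_mass(0.0, 1200.0) == 0.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            particle_mass(-1e-6, 1000.0)

    def test_preset_masses(self):
        assert silica_beads().mass == pytest.approx(1.36e-13, rel=5e-3)
        assert yeast_cells().mass == pytest.approx(7.37e-14, rel=5e-3)


class TestMeanChannelVelocity:
    def test_derived_values(self):
        geom = default_geometry()  # 0.40 x 0.40 mm cross-section
        assert mean_channel_velocity(1e-3, geom) == pytest.approx(0.1042, abs=1e-4)
        assert mean_channel_velocity(1e-4, geom) == pytest.approx(0.01042, abs=1e-5)

    def test_linear_in_flow_rate(self):
        geom = default_geometry()
        assert mean_channel_velocity(2e-3, geom) == pytest.approx(
            2.0 * mean_channel_velocity(1e-3, geom)
        )

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            ChannelGeometry(width_mm=0.0)


class TestTrajectories:
    def test_steady_advection_is_exact(self):
        # no stimulation, no diffusion: per-frame x-step is v_base*profile(y)/fps
        cond = ExperimentCondition(silica_beads(), 1e-3, None, 0)
        cam = default_camera()
        geom = default_geometry()
        traj = simulate_trajectories(
            cond, geom, cam, n_particles=20, seed=3, duration=0.5, diffusion_px=0.0
        )
        v_base = mean_channel_velocity(1e-3, geom)
        y0 = traj.positions_um[0, :, 1]
        expected_step_um = v_base * _profile(y0, geom, cam) * 1000.0 / cam.frame_rate
        step = traj.positions_um[1, :, 0] - traj.positions_um[0, :, 0]
        np.testing.assert_allclose(step, expected_step_um, rtol=1e-12)
        assert np.all(traj.positions_um[1, :, 1] == y0)  # no transverse motion

    def test_ground_truth_mean_matches_profile_average(self):
        cond = ExperimentCondition(yeast_cells(), 1e-3, None, 0)
        cam, geom = default_camera(), default_geometry()
        traj = simulate_trajectories(
            cond, geom, cam, n_particles=50, seed=1, duration=0.2, diffusion_px=0.0
        )
        v_base = mean_channel_velocity(1e-3, geom)
        expected = v_base * _profile(traj.positions_um[0, :, 1], geom, cam).mean()
        got = traj.velocities_mm_s[0, :, 0].mean()
        assert got == pytest.approx(expected, rel=1e-9)

    def test_modulated_ground_truth_peaks_at_half_hz(self):
        # ON/OFF gating of the stimulus puts the fundamental at 0.5 Hz
        cond = ExperimentCondition(silica_beads(), 1e-4, amp_low_protocol(20.0), 0)
        traj = simulate_trajectories(cond, seed=0, duration=20.0)
        gt = traj.velocities_mm_s[:, :, 0].mean(axis=1)
        trace = MeanVelocityTrace("x", gt, traj.camera.frame_rate)
        _, freq = dominant_peak(amplitude_spectrum(trace), (0.0, 2.0))
        assert freq == pytest.approx(0.5, abs=trace.sample_rate / len(gt))

    def test_particles_stay_inside_roi(self):
        cond = ExperimentCondition(yeast_cells(), 5e-3, amp_high_protocol(5.0), 0)
        traj = simulate_trajectories(cond, seed=2, duration=5.0, n_particles=30)
        w, h = traj.roi_size_um
        assert traj.positions_um.shape[1] == 30  # count conserved every frame
        assert np.all(traj.positions_um[:, :, 0] >= 0)
        assert np.all(traj.positions_um[:, :, 0] < w)
        assert np.all(traj.positions_um[:, :, 1] >= 0)
        assert np.all(traj.positions_um[:, :, 1] < h)

    def test_deterministic_under_seed(self):
        cond = ExperimentCondition(yeast_cells(), 1e-3, amp_low_protocol(2.0), 7)
        t1 = simulate_trajectories(cond, seed=7, duration=2.0, n_particles=10)
        t2 = simulate_trajectories(cond, seed=7, duration=2.0, n_particles=10)
        np.testing.assert_array_equal(t1.positions_um, t2.positions_um)

    def test_invalid_particle_count(self):
        cond = ExperimentCondition(yeast_cells(), 1e-3, None, 0)
        with pytest.raises(ValueError):
            simulate_trajectories(cond, n_particles=0, duration=1.0)


class TestGroundTruthTrends:
    """The generator encodes the rigid-bead vs compliant-cell contrast in
    its ground-truth velocities, before any image processing."""

    @staticmethod
    def _gt_range(particle, flow, protocol_factory, duration=10.0):
        cond = ExperimentCondition(particle, flow, protocol_factory(duration), 0)
        traj = simulate_trajectories(cond, seed=5, duration=duration, diffusion_px=0.0)
        gt = traj.velocities_mm_s[:, :, 0].mean(axis=1)
        return float(gt.max() - gt.min())

    def test_bead_range_invariant_across_conditions(self):
        ranges = [
            self._gt_range(silica_beads(), q, proto)
            for q in (1e-4, 1e-3)
            for proto in (amp_low_protocol, amp_high_protocol)
        ]
        assert (max(ranges) - min(ranges)) / np.mean(ranges) < 0.10

    def test_yeast_range_increases_with_flow_and_octave(self):
        for proto in (amp_low_protocol, amp_high_protocol):
            r = [self._gt_range(yeast_cells(), q, proto) for q in (1e-4, 1e-3, 5e-3)]
            assert r[0] < r[1] < r[2]
        for q in (1e-4, 1e-3):
            assert self._gt_range(yeast_cells(), q, amp_low_protocol) < self._gt_range(
                yeast_cells(), q, amp_high_protocol
            )

    def test_bead_has_no_transverse_response(self):
        cond = ExperimentCondition(silica_beads(), 1e-3, amp_high_protocol(5.0), 0)
        traj = simulate_trajectories(cond, seed=0, duration=5.0, diffusion_px=0.0)
        assert np.all(traj.velocities_mm_s[:, :, 1] == 0.0)

    def test_yeast_has_transverse_response(self):
        cond = ExperimentCondition(yeast_cells(), 1e-3, amp_high_protocol(5.0), 0)
        traj = simulate_trajectories(cond, seed=0, duration=5.0, diffusion_px=0.0)
        assert np.abs(traj.velocities_mm_s[:, :, 1]).max() > 0.0


class TestRenderFrames:
    def test_single_particle_centroid(self, quiet_camera):
        from acoustopiv.synthdata import Trajectories

        pitch = quiet_camera.pixel_pitch_um
        pos = np.array([[[80.3, 60.7]]]) * pitch  # one frame, one particle
        traj = Trajectories(
            positions_um=pos,
            velocities_mm_s=np.zeros_like(pos),
            times=np.zeros(1),
            roi_size_um=(180 * pitch, 140 * pitch),
            camera=quiet_camera,
        )
        seq = render_frames(traj, quiet_camera, seed=0)
        img = seq.frames[0].astype(float) - quiet_camera.background_level
        yy, xx = np.mgrid[0:140, 0:180]
        cx = (img * xx).sum() / img.sum()
        cy = (img * yy).sum() / img.sum()
        assert cx == pytest.approx(80.3, abs=0.05)
        assert cy == pytest.approx(60.7, abs=0.05)

    def test_bit_identical_under_seed(self):
        cond = ExperimentCondition(yeast_cells(), 1e-3, amp_low_protocol(2.0), 0)
        traj = simulate_trajectories(cond, seed=1, duration=1.0, n_particles=15)
        a = render_frames(traj, seed=9)
        b = render_frames(traj, seed=9)
        np.testing.assert_array_equal(a.frames, b.frames)

    def test_metadata_embedded(self):
        cond = ExperimentCondition(yeast_cells(), 1e-3, amp_low_protocol(2.0), 0)
        traj = simulate_trajectories(cond, seed=1, duration=1.0, n_particles=5)
        seq = render_frames(traj, seed=0)
        assert seq.frame_rate == pytest.approx(57.0)
        assert seq.pixel_pitch_um == pytest.approx(0.74)
        assert seq.meta["particle"] == "yeast_cells"


class TestFlowSensor:
    def test_no_stimulation_gives_constant_baseline(self):
        p = amp_low_protocol(20.0)
        df = simulate_flow_sensor(p, baseline=1e-3, on_amplitude=0.0, relaxation_tau=0.2)
        np.testing.assert_allclose(df["flow_mL_min"], 1e-3)

    def test_fast_relaxation_returns_to_baseline(self):
        # tau << off duration: each OFF phase decays back within ~5 tau
        p = amp_low_protocol(20.0)
        tau = 0.05
        df = simulate_flow_sensor(
            p, baseline=1e-3, on_amplitude=5e-4, relaxation_tau=tau, sample_rate=200.0
        )
        t = df["time_s"].to_numpy()
        f = df["flow_mL_min"].to_numpy()
        tail = (np.mod(t, 2.0) >= 1.0 + 5 * tau) & (np.mod(t, 2.0) < 2.0)
        assert np.all(f[tail] - 1e-3 < 0.01 * 5e-4)

    def test_slow_relaxation_leaves_residual(self):
        # tau > off duration: the signal never gets back to baseline
        p = amp_low_protocol(20.0)
        df = simulate_flow_sensor(
            p, baseline=1e-3, on_amplitude=5e-4, relaxation_tau=3.0,
            residual_offset=1e-4, sample_rate=200.0,
        )
        t = df["time_s"].to_numpy()
        f = df["flow_mL_min"].to_numpy()
        late_off = (t > 10.0) & (np.mod(t, 2.0) >= 1.8)
        assert f[late_off].min() > 1e-3

    def test_parameter_validation(self):
        p = amp_low_protocol(20.0)
        with pytest.raises(ValueError):
            simulate_flow_sensor(p, baseline=1e-3, on_amplitude=1e-4, relaxation_tau=0.0)
        with pytest.raises(ValueError):
            simulate_flow_sensor(
                p, baseline=1e-3, on_amplitude=1e-4, relaxation_tau=0.2, sample_rate=0.5
            )
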