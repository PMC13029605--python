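"""Synthetic microchannel particle videos and flow-sensor traces.

The generator emulates the measurement situation the analysis pipeline is
built for: micrometre-scale particles (rigid silica beads or compliant yeast
cells) advected by a steady syringe-pump flow through a 0.40 mm-wide
channel, imaged at 57 FPS through a 10x objective onto a 7.4 um-pixel
sensor, while an acousto-mechanical perturbation (a speaker-driven tubing
vibration, gated by a 1 s ON / 1 s OFF protocol) superposes a periodic
velocity modulation.

The two particle presets encode the qualitative contrast the pipeline must
resolve:

* **silica beads** respond with a fixed-amplitude longitudinal modulation,
  independent of flow rate and drive tone, and show no transverse response;
* **yeast cells** couple more strongly the faster the flow and the higher
  the drive octave, and oscillate transversally as well as longitudinally.

Drive tones above the camera's 28.5 Hz Nyquist limit cannot be imaged
directly, so the stimulus injects its high-frequency signature as spectral
lines inside the resolvable 10-28 Hz band (``hf_line_amplitudes``) rather
than modelling aliasing physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import FrameSequence
from .protocol import AMP_LOW, StimulusProtocol, modulation_fundamental

__all__ = [
    "ParticleType",
    "ChannelGeometry",
    "CameraModel",
    "ExperimentCondition",
    "Trajectories",
    "particle_mass",
    "mean_channel_velocity",
    "simulate_trajectories",
    "render_frames",
    "simulate_flow_sensor",
    "silica_beads",
    "yeast_cells",
    "default_geometry",
    "default_camera",
    "REFERENCE_FLOW_RATE",
    "REFERENCE_TONE_HZ",
]

#: Reference condition at which particle couplings are quoted:
#: lowest campaign flow rate, low-octave G# drive.
REFERENCE_FLOW_RATE = 1e-4  # mL/min
REFERENCE_TONE_HZ = AMP_LOW


def particle_mass(radius: float, density: float) -> float:
    """Mass in kg of a homogeneous sphere, ``(4/3) pi r^3 rho``."""
    if radius < 0 or density < 0:
        raise ValueError("radius and density must be non-negative")
    return (4.0 / 3.0) * math.pi * radius**3 * density


@dataclass(frozen=True)
class ParticleType:
    """A suspended micro-particle population and its stimulus coupling.

    ``coupling_longitudinal`` is the mean added x-velocity (mm/s) during the
    ON phase at the reference condition; ``hf_line_amplitudes`` are
    (frequency Hz, amplitude mm/s) sinusoids injected while ON, all scaled
    by the same flow/tone gain.  ``coupling_transverse`` is the fraction of
    the high-frequency amplitude that appears on the transverse (y) axis.
    """

    name: str
    radius: float  # m
    density: float  # kg/m^3
    coupling_longitudinal: float = 0.0  # mm/s at reference condition
    coupling_transverse: float = 0.0  # dimensionless fraction for y
    coupling_flow_exponent: float = 0.0
    coupling_tone_exponent: float = 0.0
    hf_line_amplitudes: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.density <= 0:
            raise ValueError("radius and density must be positive")

    @property
    def mass(self) -> float:
        """Spherical mass in kg."""
        return particle_mass(self.radius, self.density)

    def gain(self, flow_rate: float, tone_frequency: float) -> float:
        """Dimensionless coupling gain relative to the reference condition.

        ``(Q/Q_ref)**flow_exponent * (f/f_ref)**tone_exponent`` — unity for
        the rigid-bead preset by construction.
        """
        return (flow_rate / REFERENCE_FLOW_RATE) ** self.coupling_flow_exponent * (
            tone_frequency / REFERENCE_TONE_HZ
        ) ** self.coupling_tone_exponent


def silica_beads() -> ParticleType:
    """Rigid 3 um-radius silica beads: stable, flow/tone-independent
    longitudinal response, no transverse response."""
    return ParticleType(
        name="silica_beads",
        radius=3.0e-6,
        density=1200.0,
        coupling_longitudinal=0.12,
        coupling_transverse=0.0,
        coupling_flow_exponent=0.0,
        coupling_tone_exponent=0.0,
        hf_line_amplitudes=((12.5, 0.020), (20.5, 0.015), (25.5, 0.012)),
    )


def yeast_cells() -> ParticleType:
    """Compliant 2.5 um-radius yeast cells: coupling grows with flow rate
    and drive octave, with a transverse oscillatory component."""
    return ParticleType(
        name="yeast_cells",
        radius=2.5e-6,
        density=1126.0,
        coupling_longitudinal=0.022,
        coupling_transverse=0.6,
        coupling_flow_exponent=0.5,
        coupling_tone_exponent=0.3,
        hf_line_amplitudes=((12.5, 0.006), (20.5, 0.005), (25.5, 0.004)),
    )


@dataclass(frozen=True)
class ChannelGeometry:
    """Microchannel footprint and observation window.

    The channel depth is not part of the imaging geometry and is taken equal
    to the width (square cross-section) for the flow-rate-to-velocity
    conversion.
    """

    length_mm: float = 45.0
    width_mm: float = 0.40
    depth_mm: float = 0.40
    roi_offset_mm: float = 22.0
    roi_size_px: Tuple[int, int] = (180, 140)  # (width, height)

    def __post_init__(self) -> None:
        if self.width_mm <= 0 or self.depth_mm <= 0:
            raise ValueError("channel cross-section must be positive")
        if min(self.roi_size_px) <= 0:
            raise ValueError("ROI must be non-empty")

    @property
    def cross_section_mm2(self) -> float:
        return self.width_mm * self.depth_mm


@dataclass(frozen=True)
class CameraModel:
    """Acquisition model: CCD at 57 FPS, 7.4 um pixels behind a 10x objective."""

    frame_rate: float = 57.0
    sensor_pixel_um: float = 7.4
    magnification: float = 10.0
    frame_size: Tuple[int, int] = (640, 480)
    exposure_ms: float = 17.438
    noise_sigma: float = 2.0  # additive read noise, grey levels
    particle_spot_sigma: float = 1.2  # px, rendered Gaussian spot
    background_level: float = 20.0  # grey levels

    def __post_init__(self) -> None:
        if self.frame_rate <= 0 or self.sensor_pixel_um <= 0 or self.magnification <= 0:
            raise ValueError("frame_rate, sensor_pixel and magnification must be positive")

    @property
    def pixel_pitch_um(self) -> float:
        """Object-plane pixel pitch, sensor pixel / magnification."""
        return self.sensor_pixel_um / self.magnification

    @property
    def nyquist_hz(self) -> float:
        return self.frame_rate / 2.0


def default_geometry() -> ChannelGeometry:
    return ChannelGeometry()


def default_camera() -> CameraModel:
    return CameraModel()


@dataclass(frozen=True)
class ExperimentCondition:
    """One run of the campaign: particle type, flow rate, protocol, seed."""

    particle: ParticleType
    flow_rate: float  # mL/min
    protocol: Optional[StimulusProtocol]  # None = NO-AMP control
    replicate_seed: int = 0

    def __post_init__(self) -> None:
        if self.flow_rate <= 0:
            raise ValueError("flow_rate must be positive")

    @property
    def label(self) -> str:
        mode = "no-amp" if self.protocol is None else (
            self.protocol.label or f"amp-{self.protocol.tone_frequency:.2f}Hz"
        )
        return f"{self.particle.name}_Q{self.flow_rate:g}_{mode}_s{self.replicate_seed}"


def mean_channel_velocity(flow_rate: float, geometry: ChannelGeometry) -> float:
    """Cross-section transport speed in mm/s for a flow rate in mL/min.

    1 mL/min = 1000 mm^3 / 60 s, divided by the width x depth cross-section.
    """
    if flow_rate <= 0:
        raise ValueError("flow_rate must be positive")
    area = geometry.cross_section_mm2
    if area <= 0:
        raise ValueError("zero cross-section area")
    return flow_rate * (1000.0 / 60.0) / area


@dataclass
class Trajectories:
    """Per-frame particle positions (object-plane um) and ground-truth
    deterministic velocities (mm/s), on the ROI coordinate frame
    (x = flow-parallel image axis, y = transverse)."""

    positions_um: np.ndarray  # (n_frames, n_particles, 2) -> (x, y)
    velocities_mm_s: np.ndarray  # (n_frames, n_particles, 2)
    times: np.ndarray  # (n_frames,)
    roi_size_um: Tuple[float, float]
    camera: CameraModel
    condition: Optional[ExperimentCondition] = None

    @property
    def n_particles(self) -> int:
        return self.positions_um.shape[1]

    @property
    def n_frames(self) -> int:
        return self.positions_um.shape[0]


def _envelope(t: np.ndarray, protocol: StimulusProtocol, rise_time: float, decay_tau: float) -> np.ndarray:
    """Stateless ON-OFF envelope in [0, 1]: linear ramp over ``rise_time``
    after each ON onset, exponential decay with ``decay_tau`` after OFF."""
    t_in = np.mod(t, protocol.period)
    on = t_in < protocol.on_duration
    env = np.empty_like(np.asarray(t, dtype=float))
    if rise_time > 0:
        env_on = np.minimum(1.0, t_in / rise_time)
    else:
        env_on = np.ones_like(t_in)
    peak = min(1.0, protocol.on_duration / rise_time) if rise_time > 0 else 1.0
    env_off = peak * np.exp(-(t_in - protocol.on_duration) / max(decay_tau, 1e-12))
    env = np.where(on, env_on, env_off)
    return env


def _profile(y_um: np.ndarray, geometry: ChannelGeometry, camera: CameraModel) -> np.ndarray:
    """Poiseuille-like parabola across the channel width, normalised to 1 at
    the centerline; the ROI is assumed centred on the channel axis."""
    roi_h_um = geometry.roi_size_px[1] * camera.pixel_pitch_um
    half_w_um = geometry.width_mm * 1000.0 / 2.0
    y_center = roi_h_um / 2.0
    rel = (y_um - y_center) / half_w_um
    return np.clip(1.0 - rel**2, 0.0, None)


def simulate_trajectories(
    condition: ExperimentCondition,
    geometry: Optional[ChannelGeometry] = None,
    camera: Optional[CameraModel] = None,
    n_particles: int = 80,
    seed: Optional[int] = None,
    duration: Optional[float] = None,
    rise_time: float = 0.3,
    decay_tau: float = 0.3,
    diffusion_px: float = 0.05,
) -> Trajectories:
    """Advance particles through the ROI under steady flow plus the gated
    acousto-mechanical modulation.

    Per frame each particle moves by ``v(t) * dt``:

    * x: ``v_base * profile(y)`` steady transport plus, while the stimulus
      envelope is up, the gained ON-boost and the in-band sinusoid lines;
    * y: the gained transverse fraction of the sinusoid lines;
    * both axes: isotropic Gaussian jitter of ``diffusion_px`` px/frame
      (not part of the recorded ground-truth velocity).

    Particles leaving the ROI wrap to the opposite edge, keeping seeding
    density constant.
    """
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    geometry = geometry or default_geometry()
    camera = camera or default_camera()
    protocol = condition.protocol
    if duration is None:
        duration = protocol.total_duration if protocol is not None else 60.0
    seed = condition.replicate_seed if seed is None else seed
    rng = np.random.default_rng(seed)

    dt = 1.0 / camera.frame_rate
    n_frames = int(round(duration * camera.frame_rate))
    pitch = camera.pixel_pitch_um
    roi_w_um = geometry.roi_size_px[0] * pitch
    roi_h_um = geometry.roi_size_px[1] * pitch

    v_base = mean_channel_velocity(condition.flow_rate, geometry)
    particle = condition.particle
    if protocol is not None:
        gain = particle.gain(condition.flow_rate, protocol.tone_frequency)
        times = np.arange(n_frames) * dt
        env = _envelope(times, protocol, rise_time, decay_tau)
        freqs = np.array([f for f, _ in particle.hf_line_amplitudes])
        amps = np.array([a for _, a in particle.hf_line_amplitudes]) * gain
        if freqs.size:
            lines = np.sin(2.0 * np.pi * freqs[None, :] * times[:, None]) @ amps
        else:
            lines = np.zeros(n_frames)
        carrier_x = env * (gain * particle.coupling_longitudinal + lines)
        carrier_y = env * particle.coupling_transverse * lines
    else:
        carrier_x = np.zeros(n_frames)
        carrier_y = np.zeros(n_frames)

    pos = np.empty((n_frames, n_particles, 2))
    vel = np.empty((n_frames, n_particles, 2))
    xy = np.column_stack(
        [rng.uniform(0, roi_w_um, n_particles), rng.uniform(0, roi_h_um, n_particles)]
    )
    diff_um = diffusion_px * pitch
    for k in range(n_frames):
        prof = _profile(xy[:, 1], geometry, camera)
        vx = v_base * prof + carrier_x[k]  # mm/s
        vy = np.full(n_particles, carrier_y[k])
        pos[k] = xy
        vel[k, :, 0] = vx
        vel[k, :, 1] = vy
        step_um = np.column_stack([vx, vy]) * 1000.0 * dt
        if diff_um > 0:
            step_um = step_um + rng.normal(0.0, diff_um, (n_particles, 2))
        xy = xy + step_um
        xy[:, 0] %= roi_w_um
        xy[:, 1] %= roi_h_um

    return Trajectories(
        positions_um=pos,
        velocities_mm_s=vel,
        times=np.arange(n_frames) * dt,
        roi_size_um=(roi_w_um, roi_h_um),
        camera=camera,
        condition=condition,
    )


def render_frames(
    trajectories: Trajectories,
    camera: Optional[CameraModel] = None,
    seed: int = 0,
    spot_amplitude: float = 110.0,
) -> FrameSequence:
    """Render trajectories into an 8-bit grayscale ROI stack.

    Each particle becomes an isotropic Gaussian spot of the camera's
    ``particle_spot_sigma`` on a uniform background, with additive Gaussian
    read noise, quantised to uint8. Identical inputs and seed give
    bit-identical stacks.
    """
    camera = camera or trajectories.camera
    if trajectories.n_particles < 1:
        raise ValueError("empty trajectory set")
    rng = np.random.default_rng(seed)
    pitch = camera.pixel_pitch_um
    w = int(round(trajectories.roi_size_um[0] / pitch))
    h = int(round(trajectories.roi_size_um[1] / pitch))
    sigma = camera.particle_spot_sigma
    half = max(3, int(math.ceil(4.0 * sigma)))
    offs = np.arange(-half, half + 1)

    n_frames = trajectories.n_frames
    stack = np.empty((n_frames, h, w), dtype=np.uint8)
    for k in range(n_frames):
        img = np.full((h, w), float(camera.background_level))
        px = trajectories.positions_um[k, :, 0] / pitch
        py = trajectories.positions_um[k, :, 1] / pitch
        cx = np.round(px).astype(int)
        cy = np.round(py).astype(int)
        rows = cy[:, None, None] + offs[None, :, None]  # (n, P, 1)
        cols = cx[:, None, None] + offs[None, None, :]  # (n, 1, P)
        dy = rows - py[:, None, None]
        dx = cols - px[:, None, None]
        vals = spot_amplitude * np.exp(-(dx**2 + dy**2) / (2.0 * sigma**2))
        inside = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rows_b, cols_b, vals_b = np.broadcast_arrays(rows, cols, vals)
        np.add.at(
            img, (rows_b[inside], cols_b[inside]), vals_b[inside]
        )
        if camera.noise_sigma > 0:
            img += rng.normal(0.0, camera.noise_sigma, img.shape)
        stack[k] = np.clip(np.round(img), 0, 255).astype(np.uint8)

    cond = trajectories.condition
    meta = {"seed": seed, "generator": "acoustopiv.synthdata"}
    if cond is not None:
        meta.update(
            condition=cond.label,
            particle=cond.particle.name,
            flow_rate_mL_min=cond.flow_rate,
            protocol=None if cond.protocol is None else cond.protocol.to_dict(),
        )
    return FrameSequence(stack, camera.frame_rate, pitch, meta)


def simulate_flow_sensor(
    protocol: StimulusProtocol,
    baseline: float,
    on_amplitude: float,
    relaxation_tau: float,
    residual_offset: float = 0.0,
    noise_sigma: float = 0.0,
    sample_rate: float = 50.0,
    seed: int = 0,
    rise_tau: float = 0.1,
) -> pd.DataFrame:
    """Emulate the outlet flow-sensor reading under cyclic stimulation.

    The modulation ``g(t)`` follows first-order kinetics: it relaxes toward
    1 with time constant ``rise_tau`` while ON and decays toward 0 with
    ``relaxation_tau`` while OFF, so a relaxation slower than the OFF window
    leaves the signal above baseline between pulses.  When that is the case
    an additional slowly accumulating offset of asymptotic size
    ``residual_offset`` models a persistent mechanical excitation.

    Returns a DataFrame with columns ``time_s`` and ``flow_mL_min``.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if relaxation_tau <= 0:
        raise ValueError("relaxation_tau must be positive")
    if sample_rate <= 2.0 * modulation_fundamental(protocol):
        raise ValueError("sample_rate must exceed twice the modulation fundamental")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate
    times = np.arange(0.0, protocol.total_duration, dt)
    on = protocol.state(times)

    g = np.empty_like(times)
    state = 0.0
    for i, is_on in enumerate(on):
        if is_on:
            state += (1.0 - state) * (1.0 - math.exp(-dt / rise_tau))
        else:
            state *= math.exp(-dt / relaxation_tau)
        g[i] = state

    trace = baseline + on_amplitude * g
    if relaxation_tau > protocol.off_duration:
        # persistent excitation builds up over a couple of periods
        trace = trace + residual_offset * (1.0 - np.exp(-times / (2.0 * protocol.period)))
    if noise_sigma > 0:
        trace = trace + rng.normal(0.0, noise_sigma, trace.shape)
    return pd.DataFrame({"time_s": times, "flow_mL_min": trace})
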