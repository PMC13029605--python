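"""Response metrics for ON-OFF stimulated velocity records.

Three quantities summarise each record:

* the **velocity range** ``r = max - min`` of the spatially averaged
  velocity component over the recording (time domain);
* the **dominant spectral peak** ``fp``: the largest non-DC amplitude of
  the one-sided spectrum inside a low-frequency band (default 0-2 Hz,
  where the 1 s ON / 1 s OFF protocol puts its 0.5 Hz fundamental);
* **band integrals** ``A[f1, f2)``: sums of spectral amplitude over
  higher-frequency bands (presets 10-15, 18-23, 23-28 Hz) carrying the
  acoustic signature of the drive tone.

Replicates are aggregated as mean +/- SEM with the sample standard
deviation (ddof=1).  The calibration helpers quantify ON/OFF flow-rate
modulation and incomplete OFF-phase relaxation in flow-sensor traces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .dpiv import VelocityFieldSeries
from .protocol import StimulusProtocol

__all__ = [
    "MeanVelocityTrace",
    "SpectralResponse",
    "ResponseSummary",
    "ReplicateAggregate",
    "BAND_PRESETS",
    "spatial_mean",
    "velocity_range",
    "amplitude_spectrum",
    "dominant_peak",
    "band_integral",
    "aggregate_replicates",
    "calibration_metrics",
    "summarize_series",
]

logger = logging.getLogger(__name__)

#: Higher-frequency analysis bands in Hz (half-open [f1, f2)).
BAND_PRESETS: Tuple[Tuple[float, float], ...] = ((10.0, 15.0), (18.0, 23.0), (23.0, 28.0))


@dataclass
class MeanVelocityTrace:
    """Spatially averaged velocity component, uniformly sampled in mm/s."""

    component: str  # "x" | "y"
    values: np.ndarray
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be 1-D")
        if not np.isfinite(self.values).all():
            raise ValueError("trace must be finite")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.sample_rate

    @property
    def duration(self) -> float:
        return len(self.values) / self.sample_rate


@dataclass
class SpectralResponse:
    """One-sided amplitude spectrum of a mean-velocity trace (mm/s per bin)."""

    component: str
    frequencies: np.ndarray
    amplitudes: np.ndarray
    resolution: float  # Hz, 1/duration

    def __post_init__(self) -> None:
        if self.frequencies.shape != self.amplitudes.shape:
            raise ValueError("frequency and amplitude axes must match")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def nyquist(self) -> float:
        return float(self.frequencies[-1])


@dataclass
class ResponseSummary:
    """Per-record metrics for one velocity component.

    ``hf_peak_*`` describe the strongest spectral line inside the
    higher-frequency analysis window (10-28 Hz by default) and
    ``hf_floor`` its median in-band amplitude, so a line can be judged
    against the local noise floor.
    """

    component: str
    r: float  # velocity range, mm/s
    fp_amplitude: float
    fp_frequency: float
    band_areas: Dict[Tuple[float, float], float]
    hf_peak_amplitude: float = np.nan
    hf_peak_frequency: float = np.nan
    hf_floor: float = np.nan
    #: amplitude of THIS component's spectrum at the bin where the
    #: longitudinal (x) component has its in-band line; lets a transverse
    #: spectrum be tested for a co-located stimulus line against hf_floor
    hf_amp_at_x_line: float = np.nan


@dataclass
class ReplicateAggregate:
    """Mean +/- SEM over independent replicates (sample std, ddof=1)."""

    n: int
    mean: float
    sem: float


def spatial_mean(
    series: VelocityFieldSeries, roi_mask: Optional[np.ndarray] = None
) -> Tuple[MeanVelocityTrace, MeanVelocityTrace]:
    """Average valid vectors over space, per frame pair, for both components.

    Frame pairs with no valid vector inside the mask are linearly
    interpolated from neighbouring pairs (and logged) so the trace stays
    uniformly sampled for the DFT.
    """
    valid = series.valid
    if roi_mask is not None:
        valid = valid & roi_mask[None, :, :]
    counts = valid.sum(axis=(1, 2))
    if not (counts > 0).any():
        raise ValueError("no frame pair has a valid vector inside the ROI")
    traces = []
    for comp, arr in (("x", series.vx), ("y", series.vy)):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(valid, arr, 0.0).sum(axis=(1, 2)) / np.where(counts > 0, counts, 1)
        empty = counts == 0
        if empty.any():
            logger.info("interpolating %d frame pairs with zero valid vectors", int(empty.sum()))
            idx = np.arange(len(mean))
            mean[empty] = np.interp(idx[empty], idx[~empty], mean[~empty])
        traces.append(
            MeanVelocityTrace(comp, mean, series.sample_rate, meta=dict(series.meta))
        )
    return traces[0], traces[1]


def velocity_range(trace: MeanVelocityTrace) -> float:
    """Max minus min of the trace, in mm/s."""
    if len(trace.values) == 0:
        raise ValueError("empty trace")
    return float(trace.values.max() - trace.values.min())


def amplitude_spectrum(trace: MeanVelocityTrace, window: str = "rectangular") -> SpectralResponse:
    """One-sided amplitude spectrum with mean removal.

    Non-DC bins carry ``2|X_k|/N`` (the Nyquist bin of an even-length
    record carries ``|X_k|/N``, being its own mirror); the DC bin is 0
    after mean removal.  A Hann taper is available for records that do not
    hold an integer number of modulation periods.
    """
    x = trace.values
    n = len(x)
    if n < 16:
        raise ValueError("trace too short for a meaningful spectrum (need >= 16)")
    x = x - x.mean()
    if window == "hann":
        w = np.hanning(n)
        x = x * w
        norm = w.sum()
    elif window == "rectangular":
        norm = float(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(x)
    amps = np.abs(spec) * 2.0 / norm
    amps[0] = 0.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / trace.sample_rate)
    return SpectralResponse(
        component=trace.component,
        frequencies=freqs,
        amplitudes=amps,
        resolution=trace.sample_rate / n,
    )


def dominant_peak(
    spectrum: SpectralResponse, band: Tuple[float, float] = (0.0, 2.0)
) -> Tuple[float, float]:
    """Largest non-DC amplitude in ``band`` and its bin frequency.

    Ties break toward the lower frequency.  The DC bin is excluded: with
    mean removal the steady-flow term would otherwise trivially dominate.
    """
    f1, f2 = band
    if not (0.0 <= f1 < f2):
        raise ValueError("band must satisfy 0 <= f1 < f2")
    if f2 > spectrum.nyquist + 1e-12:
        raise ValueError("band exceeds the Nyquist frequency")
    sel = (spectrum.frequencies >= f1) & (spectrum.frequencies <= f2) & (
        spectrum.frequencies > 0
    )
    if not sel.any():
        raise ValueError("no non-DC bin inside the requested band")
    idx = np.flatnonzero(sel)
    k = idx[int(np.argmax(spectrum.amplitudes[idx]))]
    return float(spectrum.amplitudes[k]), float(spectrum.frequencies[k])


def band_integral(spectrum: SpectralResponse, f1: float, f2: float) -> float:
    """Sum of spectral amplitudes over the half-open band ``f1 <= f < f2``.

    Half-open bins make touching presets (18-23 and 23-28 Hz) exactly
    additive without double-counting the shared edge.
    """
    if not f1 < f2:
        raise ValueError("band must satisfy f1 < f2")
    if f2 > spectrum.nyquist + spectrum.resolution:
        raise ValueError("band exceeds the Nyquist frequency")
    sel = (spectrum.frequencies >= f1) & (spectrum.frequencies < f2)
    return float(spectrum.amplitudes[sel].sum())


def aggregate_replicates(values: Sequence[float]) -> ReplicateAggregate:
    """Mean and SEM (= sample std / sqrt(n)) over replicate metric values."""
    vals = np.asarray(list(values), dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("SEM undefined for fewer than two replicates")
    return ReplicateAggregate(n=n, mean=float(vals.mean()), sem=float(vals.std(ddof=1) / np.sqrt(n)))


def summarize_series(
    series: VelocityFieldSeries,
    bands: Sequence[Tuple[float, float]] = BAND_PRESETS,
    peak_band: Tuple[float, float] = (0.0, 2.0),
    hf_band: Tuple[float, float] = (10.0, 28.0),
    window: str = "rectangular",
) -> Dict[str, ResponseSummary]:
    """Full metric set (range, dominant peak, band areas) per component."""
    tx, ty = spatial_mean(series)
    out: Dict[str, ResponseSummary] = {}
    specs = {t.component: amplitude_spectrum(t, window=window) for t in (tx, ty)}
    for trace in (tx, ty):
        spec = specs[trace.component]
        amp, freq = dominant_peak(spec, peak_band)
        areas = {
            (f1, f2): band_integral(spec, f1, f2)
            for (f1, f2) in bands
            if f2 <= spec.nyquist + spec.resolution
        }
        hf_amp = hf_freq = hf_floor = hf_at_x = np.nan
        f1, f2 = hf_band
        if f2 <= spec.nyquist + 1e-9:
            hf_amp, hf_freq = dominant_peak(spec, hf_band)
            sel = (spec.frequencies >= f1) & (spec.frequencies <= f2)
            hf_floor = float(np.median(spec.amplitudes[sel]))
            _, x_line = dominant_peak(specs["x"], hf_band)
            k = int(np.argmin(np.abs(spec.frequencies - x_line)))
            hf_at_x = float(spec.amplitudes[k])
        out[trace.component] = ResponseSummary(
            component=trace.component,
            r=velocity_range(trace),
            fp_amplitude=amp,
            fp_frequency=freq,
            band_areas=areas,
            hf_peak_amplitude=hf_amp,
            hf_peak_frequency=hf_freq,
            hf_floor=hf_floor,
            hf_amp_at_x_line=hf_at_x,
        )
    return out


def calibration_metrics(
    times: np.ndarray,
    flow: np.ndarray,
    protocol: StimulusProtocol,
    baseline: Optional[float] = None,
    tail_fraction: float = 0.2,
) -> Dict[str, float]:
    """Quantify ON/OFF flow-rate modulation in a flow-sensor trace.

    Returns ``mean_on``/``mean_off`` (phase-conditioned averages),
    ``modulation_amplitude`` (their difference) and ``residual_offset``:
    the average over the final ``tail_fraction`` of each OFF phase minus
    the reference level (``baseline`` if given, else the first OFF-phase
    tail), measuring incomplete relaxation between pulses.
    """
    times = np.asarray(times, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if times.shape != flow.shape or times.ndim != 1:
        raise ValueError("times and flow must be matching 1-D arrays")
    period = protocol.period
    if times[-1] - times[0] < 3.0 * period:
        raise ValueError("trace must cover at least 3 full protocol periods")
    t_in = np.mod(times, period)
    on = t_in < protocol.on_duration
    mean_on = float(flow[on].mean())
    mean_off = float(flow[~on].mean())

    # tail of each OFF phase: last tail_fraction of the OFF window
    off_start = protocol.on_duration
    tail_lo = off_start + (1.0 - tail_fraction) * protocol.off_duration
    in_tail = (~on) & (t_in >= tail_lo)
    cycle = np.floor(times / period).astype(int)
    tail_means = [
        float(flow[in_tail & (cycle == c)].mean())
        for c in np.unique(cycle[in_tail])
        if (in_tail & (cycle == c)).any()
    ]
    if not tail_means:
        raise ValueError("no samples in OFF-phase tails; sample rate too low")
    ref = float(baseline) if baseline is not None else tail_means[0]
    residual = float(np.mean(tail_means)) - ref
    return {
        "mean_on": mean_on,
        "mean_off": mean_off,
        "modulation_amplitude": mean_on - mean_off,
        "residual_offset": residual,
    }
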