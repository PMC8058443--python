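"""Synthetic voltage traces, fluorescence traces, line-scans and cell images.

Every generator draws from a single :class:`numpy.random.Generator` seeded
from its spec and returns machine-readable ground truth next to the data,
so each downstream estimator can be scored exactly.

The action-potential template is piecewise analytic (linear upstroke of a
stated dV/dt, linear repolarization), which makes the true APD50/APD90 of
every beat available in closed form.  Ca2+ release events (transients,
waves, sparks, caffeine responses) use the standard simulation kernel of
the spark literature: a spatial Gaussian multiplied by a linear rise
followed by a mono-exponential decay in time, so FWHM = 2*sigma*sqrt(2 ln 2)
and the decay half-time is tau*ln 2 by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import CellImage, FluorescenceTrace, LineScanImage, VoltageTrace

__all__ = [
    "APTrainSpec",
    "APTrainTruth",
    "gen_ap_train",
    "CaTraceTruth",
    "WaveEvent",
    "gen_ca_trace",
    "SparkGroundTruth",
    "LineScanSpec",
    "gen_linescan",
    "random_spark_population",
    "StriationImageSpec",
    "gen_striation_image",
]

LN2 = math.log(2.0)
GAUSS_FWHM = 2.0 * math.sqrt(2.0 * LN2)  # FWHM = 2.3548 * sigma


# ---------------------------------------------------------------------------
# Action-potential trains
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class APTrainSpec:
    """Geometry of a paced action-potential train (current-clamp style).

    The default emulates 1 Hz pacing of an adult ventricular myocyte:
    resting potential -80 mV, overshoot +40 mV, APD90 around 250 ms.
    ``apd90_sd`` sets the beat-to-beat APD variability; ``dad_probability``
    is the per-diastole chance of inserting one delayed
    afterdepolarization of ``dad_amplitude`` mV.
    """

    n_beats: int = 30
    pacing_rate: float = 1.0  # Hz
    apd90_mean: float = 250.0  # ms
    apd90_sd: float = 0.0  # ms, beat-to-beat
    diastolic_potential: float = -80.0  # mV
    peak_potential: float = 40.0  # mV
    dad_probability: float = 0.0
    dad_amplitude: float = 3.0  # mV
    sampling_rate: float = 10.0  # kHz
    dvdt_max: float = 150.0  # V/s during the upstroke
    noise_sd: float = 0.0  # mV additive white noise
    lead_in: float = 200.0  # ms of diastole before the first beat
    plateau_ms: float = 0.0  # optional flat plateau after a phase-1 notch
    notch_drop: float = 15.0  # mV below peak where the plateau sits
    seed: int = 0

    def __post_init__(self):
        if self.n_beats < 1:
            raise ValueError("n_beats must be >= 1")
        if self.apd90_sd < 0:
            raise ValueError("apd90_sd must be >= 0")
        if not 0.0 <= self.dad_probability <= 1.0:
            raise ValueError("dad_probability must lie in [0, 1]")
        if self.peak_potential <= self.diastolic_potential:
            raise ValueError("peak_potential must exceed diastolic_potential")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive (kHz)")
        if self.pacing_rate <= 0:
            raise ValueError("pacing_rate must be positive (Hz)")
        if self.dvdt_max <= 0:
            raise ValueError("dvdt_max must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.plateau_ms < 0:
            raise ValueError("plateau_ms must be >= 0")
        if self.plateau_ms > 0 and not 0 < self.notch_drop < 0.4 * (
            self.peak_potential - self.diastolic_potential
        ):
            raise ValueError("notch_drop must lie in (0, 0.4 * AP amplitude)")


@dataclass
class APTrainTruth:
    """Ground truth accompanying a generated AP train."""

    take_off_times: np.ndarray  # ms, one per beat
    apd90: np.ndarray  # ms, per beat
    apd50: np.ndarray  # ms, per beat
    dad_times: np.ndarray  # ms, at the hump peak
    dad_amplitudes: np.ndarray  # mV
    upstroke_duration: float  # ms


def gen_ap_train(spec: APTrainSpec) -> tuple[VoltageTrace, APTrainTruth]:
    """Generate a paced AP train with closed-form per-beat APD ground truth.

    Each beat rises linearly from the diastolic potential to the peak at
    ``dvdt_max`` (upstroke duration t_up = dV/dvdt_max), then repolarizes
    linearly back to the diastolic potential.  With a linear decline of
    duration D the x% repolarization level is crossed at t_up + x*D, so
    D = (APD90 - t_up)/0.9 and APD50 = t_up + 0.5*D exactly.

    DADs are smooth Gaussian humps centred in the diastolic interval.
    """
    rng = np.random.default_rng(spec.seed)
    v_dia, v_peak = spec.diastolic_potential, spec.peak_potential
    amp = v_peak - v_dia
    t_up = amp / spec.dvdt_max  # mV / (mV/ms) = ms
    period = 1000.0 / spec.pacing_rate

    notch_ms = 5.0 if spec.plateau_ms > 0 else 0.0
    plateau_level = v_peak - spec.notch_drop if spec.plateau_ms > 0 else v_peak
    head = t_up + notch_ms + spec.plateau_ms  # from take-off to decline start

    apd90 = np.full(spec.n_beats, spec.apd90_mean, dtype=float)
    if spec.apd90_sd > 0:
        apd90 = rng.normal(spec.apd90_mean, spec.apd90_sd, spec.n_beats)
    apd90 = np.maximum(apd90, head + 10.0)
    # linear decline from plateau_level to v_dia over D; the x% level
    # (peak - x * amp) is crossed at head + D*(plateau_level - level_x)/
    # (plateau_level - v_dia), which inverts to closed-form D and APD50
    level90 = v_dia + 0.1 * amp
    level50 = v_dia + 0.5 * amp
    decline = (apd90 - head) * (plateau_level - v_dia) / (plateau_level - level90)
    apd50 = head + decline * (plateau_level - level50) / (plateau_level - v_dia)
    if np.any(head + decline + 100.0 > period):
        raise ValueError(
            "pacing period shorter than AP duration plus diastolic margin; "
            "lower pacing_rate or apd90_mean"
        )

    take_off = spec.lead_in + period * np.arange(spec.n_beats)
    duration = spec.lead_in + period * spec.n_beats
    n = int(round(duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    v = np.full(n, v_dia, dtype=float)

    for k in range(spec.n_beats):
        t0 = take_off[k]
        rel = t - t0
        up = (rel >= 0) & (rel < t_up)
        v[up] = v_dia + spec.dvdt_max * rel[up]
        if spec.plateau_ms > 0:
            notch = (rel >= t_up) & (rel < t_up + notch_ms)
            v[notch] = v_peak - spec.notch_drop * (rel[notch] - t_up) / notch_ms
            flat = (rel >= t_up + notch_ms) & (rel < head)
            v[flat] = plateau_level
        down = (rel >= head) & (rel < head + decline[k])
        v[down] = plateau_level - (plateau_level - v_dia) * (rel[down] - head) / decline[k]

    # DADs: one optional Gaussian hump per diastolic interval
    dad_times, dad_amps = [], []
    if spec.dad_probability > 0:
        for k in range(spec.n_beats):
            dia_start = take_off[k] + head + decline[k] + 30.0
            dia_end = take_off[k] + period - 30.0
            if dia_end - dia_start < 60.0:
                continue
            if rng.random() <= spec.dad_probability:
                center = 0.5 * (dia_start + dia_end)
                sigma = min(25.0, (dia_end - dia_start) / 8.0)
                v += spec.dad_amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)
                dad_times.append(center)
                dad_amps.append(spec.dad_amplitude)

    if spec.noise_sd > 0:
        v += rng.normal(0.0, spec.noise_sd, n)

    trace = VoltageTrace(v, spec.sampling_rate, stimulus_times=take_off.tolist())
    truth = APTrainTruth(
        take_off_times=take_off,
        apd90=apd90,
        apd50=apd50,
        dad_times=np.asarray(dad_times),
        dad_amplitudes=np.asarray(dad_amps),
        upstroke_duration=t_up,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Fluorescence traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WaveEvent:
    """A spontaneous resting Ca2+ event to be injected into a trace.

    Waves propagate slowly, so the default kernel is broad: 200 ms linear
    rise and 500 ms exponential decay.
    """

    time: float  # ms, at the kernel peak
    amplitude: float  # dF/F0
    rise: float = 200.0  # ms
    decay: float = 500.0  # ms


@dataclass
class CaTraceTruth:
    stim_times: np.ndarray  # ms
    amplitude: float  # dF/F0 per evoked transient
    decay_tau: float  # ms
    t_half: float  # ms = decay_tau * ln 2
    caffeine_time: Optional[float]
    caffeine_amplitude: Optional[float]
    caffeine_tau: Optional[float]
    wave_times: np.ndarray
    wave_amplitudes: np.ndarray
    f0: float
    background: float


def _rise_decay_kernel(rel: np.ndarray, rise: float, tau: float) -> np.ndarray:
    """Unit-amplitude kernel: linear rise over `rise` ms peaking at rel=0,
    then exp(-rel/tau)."""
    out = np.zeros_like(rel)
    up = (rel >= -rise) & (rel < 0)
    out[up] = 1.0 + rel[up] / rise
    down = rel >= 0
    out[down] = np.exp(-rel[down] / tau)
    return out


def gen_ca_trace(
    stim_rate: float,
    transient_amplitude: float = 1.0,
    decay_tau: float = 200.0,
    duration: float = 10_000.0,
    caffeine_time: Optional[float] = None,
    caffeine_amplitude: float = 0.8,
    caffeine_tau: float = 800.0,
    wave_events: Sequence[WaveEvent] = (),
    noise_sd: float = 0.0,
    f0: float = 1000.0,
    background: float = 50.0,
    sampling_rate: float = 2000.0,
    rise_ms: float = 10.0,
    first_stim: float = 500.0,
    seed: int = 0,
) -> tuple[FluorescenceTrace, CaTraceTruth]:
    """Generate a raw fluorescence trace with evoked transients, an
    optional caffeine pulse and optional resting events.

    ``stim_rate`` is in Hz; 0 means a resting (unstimulated) recording.
    Amplitudes are ground-truth dF/F0; ``noise_sd`` is additive Gaussian
    noise in dF/F0 units.  The raw trace is
    ``background + f0 * (1 + sum of events + noise)``.
    """
    if stim_rate < 0:
        raise ValueError("stim_rate must be 0 (resting) or positive")
    if transient_amplitude < 0:
        raise ValueError("transient_amplitude must be >= 0")
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    if caffeine_time is not None and not 0 < caffeine_time < duration:
        raise ValueError("caffeine_time must fall inside the trace")

    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sampling_rate
    rel_signal = np.zeros(n)  # in dF/F0 units

    stim_times = np.array([])
    if stim_rate > 0 and transient_amplitude > 0:
        period = 1000.0 / stim_rate
        stop = caffeine_time - period if caffeine_time is not None else duration
        stim_times = np.arange(first_stim, stop - decay_tau, period)
        for t0 in stim_times:
            # t0 is the stimulus; peak at t0 + rise_ms
            rel_signal += transient_amplitude * _rise_decay_kernel(
                t - (t0 + rise_ms), rise_ms, decay_tau
            )

    caf_amp = caf_tau = None
    if caffeine_time is not None:
        caf_amp, caf_tau = caffeine_amplitude, caffeine_tau
        rel_signal += caffeine_amplitude * _rise_decay_kernel(
            t - (caffeine_time + 50.0), 50.0, caffeine_tau
        )

    wave_times, wave_amps = [], []
    for ev in wave_events:
        ev = ev if isinstance(ev, WaveEvent) else WaveEvent(*ev)
        rel_signal += ev.amplitude * _rise_decay_kernel(t - ev.time, ev.rise, ev.decay)
        wave_times.append(ev.time)
        wave_amps.append(ev.amplitude)

    if noise_sd > 0:
        rel_signal += rng.normal(0.0, noise_sd, n)

    raw = background + f0 * (1.0 + rel_signal)
    trace = FluorescenceTrace(
        raw,
        sampling_rate,
        background=background,
        stim_times=stim_times.tolist() if stim_times.size else None,
        caffeine_time=caffeine_time,
    )
    truth = CaTraceTruth(
        stim_times=stim_times,
        amplitude=transient_amplitude,
        decay_tau=decay_tau,
        t_half=decay_tau * LN2,
        caffeine_time=caffeine_time,
        caffeine_amplitude=caf_amp,
        caffeine_tau=caf_tau,
        wave_times=np.asarray(wave_times),
        wave_amplitudes=np.asarray(wave_amps),
        f0=f0,
        background=background,
    )
    return trace, truth


# ---------------------------------------------------------------------------
# Line-scan images with Ca2+ sparks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SparkGroundTruth:
    """One simulated spark: separable Gaussian(space) x rise/decay(time)."""

    x_um: float  # spatial centre
    t_ms: float  # time of peak
    amplitude: float  # dF/F0
    sigma_um: float  # spatial Gaussian sigma
    rise_ms: float  # linear rise duration
    tau_ms: float  # exponential decay constant

    @property
    def fwhm_um(self) -> float:
        return GAUSS_FWHM * self.sigma_um

    @property
    def fdhm_ms(self) -> float:
        # half-max is crossed at rise/2 before the peak and tau*ln2 after
        return self.rise_ms / 2.0 + self.tau_ms * LN2


@dataclass(frozen=True)
class LineScanSpec:
    """Geometry and content of a synthetic line-scan acquisition.

    Defaults mirror a 0.5 kHz confocal line-scan (2 ms per line) of
    512 x 512 pixels.
    """

    n_lines: int = 512
    n_pixels: int = 512
    pixel_size: float = 0.2  # um
    line_period: float = 2.0  # ms
    baseline_f0: float = 1000.0
    noise_sd: float = 0.0  # raw fluorescence units
    background: float = 0.0
    sparks: Sequence[SparkGroundTruth] = ()
    quantize: bool = True  # round to integer counts (16-bit style)
    seed: int = 0

    def __post_init__(self):
        if self.pixel_size <= 0 or self.line_period <= 0:
            raise ValueError("pixel_size and line_period must be positive")
        if self.baseline_f0 <= 0:
            raise ValueError("baseline_f0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for s in self.sparks:
            if s.amplitude < 0:
                raise ValueError("spark amplitudes must be >= 0")


def gen_linescan(spec: LineScanSpec) -> tuple[LineScanImage, pd.DataFrame]:
    """Render sparks onto a noisy baseline line-scan.

    Returns the image and a ground-truth table with one row per spark
    (x_um, t_ms, amplitude, sigma_um, rise_ms, tau_ms, fwhm_um, fdhm_ms).
    """
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.n_pixels) * spec.pixel_size
    t = np.arange(spec.n_lines) * spec.line_period
    rel = np.zeros((spec.n_lines, spec.n_pixels))

    length = spec.n_pixels * spec.pixel_size
    duration = spec.n_lines * spec.line_period
    for s in spec.sparks:
        if not (0 <= s.x_um <= length) or not (0 <= s.t_ms <= duration):
            raise ValueError(f"spark centred outside the image: {s}")
        gx = np.exp(-0.5 * ((x - s.x_um) / s.sigma_um) ** 2)
        ht = _rise_decay_kernel(t - s.t_ms, s.rise_ms, s.tau_ms)
        rel += s.amplitude * np.outer(ht, gx)

    raw = spec.background + spec.baseline_f0 * (1.0 + rel)
    if spec.noise_sd > 0:
        raw = raw + rng.normal(0.0, spec.noise_sd, raw.shape)
    if spec.quantize:
        raw = np.clip(np.rint(raw), 0, 65535)

    image = LineScanImage(raw, spec.pixel_size, spec.line_period, spec.background)
    truth = pd.DataFrame(
        {
            "x_um": [s.x_um for s in spec.sparks],
            "t_ms": [s.t_ms for s in spec.sparks],
            "amplitude": [s.amplitude for s in spec.sparks],
            "sigma_um": [s.sigma_um for s in spec.sparks],
            "rise_ms": [s.rise_ms for s in spec.sparks],
            "tau_ms": [s.tau_ms for s in spec.sparks],
            "fwhm_um": [s.fwhm_um for s in spec.sparks],
            "fdhm_ms": [s.fdhm_ms for s in spec.sparks],
        }
    )
    return image, truth


def random_spark_population(
    n: int,
    rng: np.random.Generator,
    *,
    length_um: float,
    duration_ms: float,
    amplitude_range: tuple[float, float] = (0.5, 1.0),
    sigma_range: tuple[float, float] = (0.7, 1.2),
    rise_range: tuple[float, float] = (8.0, 14.0),
    tau_range: tuple[float, float] = (25.0, 45.0),
    margin_um: float = 6.0,
    margin_ms: float = 80.0,
    min_separation_um: float = 8.0,
    min_separation_ms: float = 150.0,
) -> list[SparkGroundTruth]:
    """Draw ``n`` well-separated sparks with realistic parameter ranges.

    Events are rejected-sampled so no two sparks overlap in both space and
    time, keeping the ground-truth matching unambiguous.
    """
    sparks: list[SparkGroundTruth] = []
    attempts = 0
    while len(sparks) < n and attempts < 100 * max(n, 1):
        attempts += 1
        x = rng.uniform(margin_um, length_um - margin_um)
        t = rng.uniform(margin_ms, duration_ms - margin_ms)
        clash = any(
            abs(x - s.x_um) < min_separation_um and abs(t - s.t_ms) < min_separation_ms
            for s in sparks
        )
        if clash:
            continue
        sparks.append(
            SparkGroundTruth(
                x_um=x,
                t_ms=t,
                amplitude=rng.uniform(*amplitude_range),
                sigma_um=rng.uniform(*sigma_range),
                rise_ms=rng.uniform(*rise_range),
                tau_ms=rng.uniform(*tau_range),
            )
        )
    if len(sparks) < n:
        raise RuntimeError("could not place the requested number of sparks")
    return sparks


# ---------------------------------------------------------------------------
# Striated cell images (T-tubule pattern)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StriationImageSpec:
    """A striated cell image: bright transverse bands at the sarcomere
    spacing, optionally jittered, dropped out and embedded in an
    elliptical cell silhouette.

    The default 2.0 um spacing puts the fundamental spatial frequency at
    0.5 um^-1; the default pixel pitch is 78/1024 um on a 1024 x 1024
    frame.
    """

    width: int = 1024
    height: int = 1024
    pixel_size: float = 78.0 / 1024.0  # um
    sarcomere_spacing: float = 2.0  # um
    jitter_sd: float = 0.0  # um, per-band positional noise
    dropout_fraction: float = 0.0
    noise_sd: float = 0.0  # intensity units (8-bit scale)
    band_sigma: float = 0.25  # um, Gaussian band half-width
    band_intensity: float = 120.0
    background_intensity: float = 20.0
    segment_px: int = 64  # vertical granularity of dropout
    cell_axes: Optional[tuple[float, float]] = None  # (length, width) um ellipse
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sarcomere_spacing <= 0:
            raise ValueError("sarcomere_spacing must be positive")
        if not 0.0 <= self.dropout_fraction <= 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1]")
        if self.sarcomere_spacing < 2 * self.pixel_size:
            raise ValueError("sarcomere_spacing below 2 pixels is unresolvable")


def gen_striation_image(spec: StriationImageSpec) -> tuple[CellImage, dict]:
    """Render vertical striation bands (periodic along x) and return the
    image plus ground truth (true spacing, band positions kept)."""
    rng = np.random.default_rng(spec.seed)
    x = np.arange(spec.width) * spec.pixel_size
    img = np.full((spec.height, spec.width), spec.background_intensity)

    extent = spec.width * spec.pixel_size
    n_bands = int(extent / spec.sarcomere_spacing) + 1
    centers = spec.sarcomere_spacing * (0.5 + np.arange(n_bands))
    if spec.jitter_sd > 0:
        centers = centers + rng.normal(0.0, spec.jitter_sd, n_bands)

    n_seg = max(1, int(np.ceil(spec.height / spec.segment_px)))
    kept = rng.random((n_bands, n_seg)) >= spec.dropout_fraction

    for b, cx in enumerate(centers):
        profile = spec.band_intensity * np.exp(-0.5 * ((x - cx) / spec.band_sigma) ** 2)
        if not profile.any():
            continue
        for s in range(n_seg):
            if kept[b, s]:
                r0, r1 = s * spec.segment_px, min((s + 1) * spec.segment_px, spec.height)
                img[r0:r1, :] += profile

    if spec.cell_axes is not None:
        half_len, half_wid = spec.cell_axes[0] / 2.0, spec.cell_axes[1] / 2.0
        cy, cx0 = spec.height / 2.0 * spec.pixel_size, spec.width / 2.0 * spec.pixel_size
        yy = np.arange(spec.height) * spec.pixel_size
        inside = ((x[None, :] - cx0) / half_len) ** 2 + ((yy[:, None] - cy) / half_wid) ** 2 <= 1.0
        img = np.where(inside, img, 2.0)

    if spec.rotation_deg != 0.0:
        from scipy.ndimage import rotate

        img = rotate(img, spec.rotation_deg, reshape=False, order=1, cval=2.0)

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)

    img = np.clip(np.rint(img), 0, 255)
    truth = {
        "spacing_um": spec.sarcomere_spacing,
        "frequency_um": 1.0 / spec.sarcomere_spacing,
        "band_centers_um": centers,
        "kept_segments": kept,
        "rotation_deg": spec.rotation_deg,
    }
    return CellImage(img, spec.pixel_size), truth
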