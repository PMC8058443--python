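"""Action-potential feature extraction and repolarization variability.

Implements the current-clamp analysis layer: beat segmentation, APD at
configurable repolarization fractions (APD50/APD90 by default), diastolic
potential, maximal upstroke velocity, delayed/early afterdepolarization
detection, and the short-term variability (STV) of APD — the mean
orthogonal deviation of consecutive APDs from the Poincaré identity line,

    STV = sum(|APD_{n+1} - APD_n|) / (n_beats * sqrt(2)).

Some labs divide by ``n_beats * 2`` instead; that variant is available via
``denominator="two"``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats

from .datatypes import APFeatures, BVRResult, DADEvent, VoltageTrace

__all__ = [
    "APSegment",
    "segment_aps",
    "ap_features",
    "detect_dads",
    "detect_eads",
    "stv",
    "stv_apd_regression",
    "analyze_ap_trace",
]

logger = logging.getLogger(__name__)


@dataclass
class APSegment:
    """One beat: samples from shortly before take-off to the next beat."""

    samples: np.ndarray
    sampling_rate: float  # kHz
    t_start: float  # ms, absolute time of samples[0] in the parent trace
    take_off_index: int  # index of take-off within `samples`

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    @property
    def take_off_time(self) -> float:
        return self.t_start + self.take_off_index * self.dt

    @property
    def times(self) -> np.ndarray:
        return self.t_start + np.arange(self.samples.size) * self.dt


def _dvdt(samples: np.ndarray, rate_khz: float, smooth_window: Optional[int] = None) -> np.ndarray:
    """dV/dt in mV/ms (numerically equal to V/s)."""
    v = samples
    if smooth_window and smooth_window >= 5:
        v = signal.savgol_filter(v, smooth_window, 3)
    return np.gradient(v) * rate_khz


def segment_aps(
    trace: VoltageTrace,
    dvdt_threshold: float = 20.0,
    refractory: float = 100.0,
    lead: float = 60.0,
    smooth_window: Optional[int] = None,
) -> list[APSegment]:
    """Split a voltage trace into one segment per beat.

    Uses ``trace.stimulus_times`` when present (take-off = dV/dt maximum
    within 10 ms of each annotation); otherwise detects upward crossings
    of ``dvdt_threshold`` (V/s) separated by at least ``refractory`` ms.
    Each segment starts ``lead`` ms before take-off so a diastolic window
    is available for the diastolic-potential estimate.
    """
    dvdt = _dvdt(trace.samples, trace.sampling_rate, smooth_window)
    n = trace.samples.size
    dt = trace.dt

    take_offs: list[int] = []
    if trace.stimulus_times:
        w = max(1, int(round(10.0 / dt)))
        for ts in trace.stimulus_times:
            i0 = max(0, int(round((ts - 1.0) / dt)))
            i1 = min(n, i0 + w + int(round(1.0 / dt)))
            if i1 - i0 < 2:
                continue
            take_offs.append(i0 + int(np.argmax(dvdt[i0:i1])))
    else:
        above = dvdt > dvdt_threshold
        crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
        refr = int(round(refractory / dt))
        last = -refr - 1
        for c in crossings:
            if c - last < refr:
                continue
            i1 = min(n, c + int(round(5.0 / dt)))
            take_offs.append(c + int(np.argmax(dvdt[c:i1])))
            last = c
    if not take_offs:
        logger.warning("no action potentials found in trace")
        return []

    lead_n = int(round(lead / dt))
    segments = []
    for k, idx in enumerate(take_offs):
        start = max(0, idx - lead_n)
        stop = take_offs[k + 1] - lead_n if k + 1 < len(take_offs) else n
        stop = max(stop, idx + 2)
        segments.append(
            APSegment(
                samples=trace.samples[start:stop].copy(),
                sampling_rate=trace.sampling_rate,
                t_start=start * dt,
                take_off_index=idx - start,
            )
        )
    return segments


def ap_features(
    segment: APSegment,
    repolarization_fractions: Sequence[float] = (0.5, 0.9),
    ediast_window: tuple[float, float] = (-55.0, -5.0),
    smooth_window: Optional[int] = None,
) -> APFeatures:
    """Measure per-beat AP features.

    APD_x runs from the take-off (time of dV/dt max) to the first
    interpolated crossing of ``peak - x*(peak - E_diast)`` after the peak.
    E_diast is the mean over a diastolic window (default 50 ms ending 5 ms
    before take-off); when no pre-take-off samples exist the tail of the
    segment is used instead.  An AP that never repolarizes to a level
    inside its segment gets NaN for that APD rather than an extrapolation.
    """
    v = segment.samples
    dt = segment.dt
    dvdt = _dvdt(v, segment.sampling_rate, smooth_window)
    i_take = segment.take_off_index
    # refine: dV/dt max near the annotated take-off
    lo = max(0, i_take - int(round(2.0 / dt)))
    hi = min(v.size, i_take + int(round(5.0 / dt)))
    i_take = lo + int(np.argmax(dvdt[lo:hi]))
    dvdt_max = float(dvdt[i_take])

    w0 = i_take + int(round(ediast_window[0] / dt))
    w1 = i_take + int(round(ediast_window[1] / dt))
    if w1 > w0 >= 0:
        e_diast = float(np.mean(v[w0:w1]))
    else:
        tail = v[-max(2, int(round(50.0 / dt))):]
        e_diast = float(np.mean(tail))
        logger.debug("no pre-take-off diastole; used segment tail for E_diast")

    i_peak = i_take + int(np.argmax(v[i_take:]))
    peak = float(v[i_peak])

    # take-off refined by extrapolating the maximal-slope tangent back to
    # E_diast (phase-0 foot); exact for a linear upstroke, where the time
    # of dV/dt max is ambiguous within the ramp
    t_take = i_take * dt
    if dvdt_max > 0:
        foot = t_take - (v[i_take] - e_diast) / dvdt_max
        t_take = float(np.clip(foot, t_take - 2.0, t_take))

    apds = {}
    for frac in repolarization_fractions:
        level = peak - frac * (peak - e_diast)
        below = np.flatnonzero(v[i_peak:] <= level)
        if below.size == 0:
            apds[frac] = float("nan")
            logger.debug("AP never repolarized to the %.0f%% level", 100 * frac)
            continue
        j = i_peak + below[0]
        if j == 0 or v[j] == v[j - 1]:
            t_cross = j * dt
        else:
            # linear interpolation between the bracketing samples
            f = (v[j - 1] - level) / (v[j - 1] - v[j])
            t_cross = (j - 1 + f) * dt
        apds[frac] = t_cross - t_take

    return APFeatures(
        apd50=apds.get(0.5, float("nan")),
        apd90=apds.get(0.9, float("nan")),
        e_diast=e_diast,
        dvdt_max=dvdt_max,
        peak=peak,
        take_off_time=segment.t_start + t_take,
    )


def detect_dads(
    trace: VoltageTrace,
    segments: Sequence[APSegment],
    features: Optional[Sequence[APFeatures]] = None,
    min_amplitude: float = 1.0,
    margin: float = 20.0,
    smooth_ms: float = 2.0,
) -> list[DADEvent]:
    """Find delayed afterdepolarizations in the diastolic intervals.

    A DAD is a depolarizing deflection occurring after APD90 completion
    and before the next take-off, with baseline-to-peak amplitude of at
    least ``min_amplitude`` mV (inclusive; default 1 mV).  The amplitude
    reference is the median of the surrounding diastole.  A short boxcar
    (default 2 ms) suppresses sample noise before peak picking.
    """
    if features is None:
        features = [ap_features(s) for s in segments]
    dt = trace.dt
    v = trace.samples
    if smooth_ms > 0:
        w = max(1, int(round(smooth_ms / dt)))
        vs = np.convolve(v, np.ones(w) / w, mode="same")
    else:
        vs = v

    events: list[DADEvent] = []
    for k, (seg, ft) in enumerate(zip(segments, features)):
        apd90 = ft.apd90 if math.isfinite(ft.apd90) else ft.apd50
        if not math.isfinite(apd90):
            continue
        dia_start = ft.take_off_time + apd90 + margin
        if k + 1 < len(segments):
            dia_end = features[k + 1].take_off_time - margin
        else:
            dia_end = seg.t_start + seg.samples.size * dt - margin
        i0, i1 = int(round(dia_start / dt)), int(round(dia_end / dt))
        i0, i1 = max(0, i0), min(v.size, i1)
        if i1 - i0 < 5:
            continue
        dia = vs[i0:i1]
        baseline = float(np.median(dia))
        peaks, _ = signal.find_peaks(dia, prominence=0.3 * min_amplitude)
        for p in peaks:
            amp = float(dia[p] - baseline)
            # 1e-3 mV slack absorbs sampling/smoothing attenuation at the
            # inclusive >= 1 mV boundary
            if amp >= min_amplitude - 1e-3:
                events.append(DADEvent(time=(i0 + p) * dt, amplitude=amp))
    return events


def detect_eads(
    segment: APSegment,
    min_deflection: float = 1.0,
    features: Optional[APFeatures] = None,
) -> list[float]:
    """Flag early afterdepolarizations: secondary depolarizations during
    repolarization, before the APD90 crossing.

    Returns the times (ms, absolute) of secondary peaks whose prominence
    exceeds ``min_deflection`` mV.  A monotonically repolarizing AP yields
    an empty list.
    """
    if features is None:
        features = ap_features(segment)
    if not math.isfinite(features.apd90):
        return []
    dt = segment.dt
    v = segment.samples
    i_take = int(round((features.take_off_time - segment.t_start) / dt))
    i_peak = i_take + int(np.argmax(v[i_take:]))
    i_end = i_take + int(round(features.apd90 / dt))
    repol = v[i_peak:min(i_end, v.size)]
    if repol.size < 5:
        return []
    peaks, _ = signal.find_peaks(repol, prominence=min_deflection)
    return [segment.t_start + (i_peak + p) * dt for p in peaks]


def stv(apd_sequence: Sequence[float], denominator: str = "sqrt2") -> BVRResult:
    """Short-term variability of an APD sequence.

    STV = sum(|APD_{n+1} - APD_n|) / (n_beats * sqrt(2)), the mean
    orthogonal deviation from the Poincaré identity line.  Pass
    ``denominator="two"`` for the n_beats*2 variant.
    """
    apds = np.asarray(apd_sequence, dtype=float)
    if apds.size < 2:
        raise ValueError("STV requires at least 2 APD values")
    if not np.all(np.isfinite(apds)):
        raise ValueError("APD sequence contains non-finite values")
    if denominator == "sqrt2":
        denom = apds.size * math.sqrt(2.0)
    elif denominator == "two":
        denom = apds.size * 2.0
    else:
        raise ValueError("denominator must be 'sqrt2' or 'two'")
    total = float(np.sum(np.abs(np.diff(apds))))
    pairs = list(zip(apds[:-1].tolist(), apds[1:].tolist()))
    return BVRResult(stv=total / denom, poincare_pairs=pairs, n_beats=int(apds.size))


def stv_apd_regression(cells: Sequence[tuple[float, float]]):
    """Ordinary least squares of per-cell STV on APD90.

    ``cells`` is a sequence of (APD90, STV) pairs; returns
    (slope, intercept, r).  The slope of this relation is expected to be
    conserved across treatment groups when variability scales with APD.
    """
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (APD90, STV) pairs")
    apd, s = arr[:, 0], arr[:, 1]
    if np.ptp(apd) == 0:
        raise ValueError("degenerate regression: all APD90 values equal")
    res = stats.linregress(apd, s)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def analyze_ap_trace(trace: VoltageTrace, denominator: str = "sqrt2") -> dict:
    """Convenience per-cell pipeline: segment, featurize, STV, DAD flag."""
    segments = segment_aps(trace)
    feats = [ap_features(s) for s in segments]
    apd90s = [f.apd90 for f in feats if math.isfinite(f.apd90)]
    result = {
        "n_beats": len(segments),
        "features": feats,
        "apd50_mean": float(np.nanmean([f.apd50 for f in feats])) if feats else float("nan"),
        "apd90_mean": float(np.mean(apd90s)) if apd90s else float("nan"),
    }
    if len(apd90s) >= 2:
        result["bvr"] = stv(apd90s, denominator=denominator)
    dads = detect_dads(trace, segments, feats)
    result["dads"] = dads
    result["has_dads"] = len(dads) > 0
    return result
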