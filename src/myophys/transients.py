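"""Ca2+ transient analysis: F/F0 normalization, evoked-transient kinetics,
caffeine-pulse SR-content estimation, and resting SR-instability events.

The normalization convention is (F - background) / (F0 - background) with
F0 the diastolic fluorescence, so a quiescent cell sits at 1 and transient
amplitudes are dF/F0.  Decay speed is reported as the half-time T0.5 (for
a mono-exponential decay T0.5 = tau * ln 2) and, for caffeine responses,
as the fitted mono-exponential constant, which reflects Na+/Ca2+ exchange
when SR reuptake is disabled.
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .datatypes import CaffeineResult, FluorescenceTrace, RestingEvent, TransientFeatures

__all__ = [
    "FitError",
    "normalize_f",
    "transient_features",
    "steady_state_summary",
    "caffeine_analysis",
    "detect_resting_events",
    "normalize_to_ctrl",
]

logger = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Raised when a kinetic fit fails or yields a non-physical result."""


def _estimate_f0(trace: FluorescenceTrace) -> float:
    """Diastolic fluorescence.

    With stimulus annotations: the median over the last 20 % of each
    inter-stimulus cycle (pre-caffeine only).  Without: the median after
    two rounds of excluding samples more than 3 robust SDs above it.
    """
    x = trace.samples
    dt = trace.dt
    stims = sorted(trace.stim_times) if trace.stim_times else []
    if trace.caffeine_time is not None:
        stims = [s for s in stims if s < trace.caffeine_time]
    if len(stims) >= 2:
        vals = []
        for a, b in zip(stims[:-1], stims[1:]):
            w0 = a + 0.8 * (b - a)
            i0, i1 = int(round(w0 / dt)), int(round(b / dt))
            if i1 > i0:
                vals.append(x[max(0, i0):i1])
        # pre-stimulation baseline is diastolic too
        i_first = int(round(stims[0] / dt))
        if i_first > 2:
            vals.append(x[: i_first])
        return float(np.median(np.concatenate(vals)))
    included = x.copy()
    for _ in range(2):
        med = np.median(included)
        sd = 1.4826 * np.median(np.abs(included - med))
        if sd == 0:
            break
        included = included[included <= med + 3 * sd]
    return float(np.median(included))


def normalize_f(trace: FluorescenceTrace) -> tuple[FluorescenceTrace, float]:
    """Background-subtract and normalize a raw trace to F/F0.

    Returns the normalized trace and the raw diastolic fluorescence F0.
    Raises ``ValueError`` when the background is at or above the diastolic
    level (non-physical: there would be no dye signal left).
    """
    f0 = _estimate_f0(trace)
    if trace.background >= f0:
        raise ValueError(
            f"background ({trace.background}) >= diastolic fluorescence ({f0}); "
            "check background measurement"
        )
    norm = (trace.samples - trace.background) / (f0 - trace.background)
    out = FluorescenceTrace(
        norm,
        trace.sampling_rate,
        background=0.0,
        stim_times=list(trace.stim_times) if trace.stim_times else None,
        caffeine_time=trace.caffeine_time,
        normalized=True,
    )
    return out, f0


def _half_decay_time(x: np.ndarray, dt: float, i_peak: int, dia: float, i_stop: int) -> Optional[float]:
    """Interpolated time (ms) from the peak to 50 % amplitude decay."""
    amp = x[i_peak] - dia
    level = dia + 0.5 * amp
    seg = x[i_peak:i_stop]
    below = np.flatnonzero(seg <= level)
    if below.size == 0:
        return None
    j = below[0]
    if j == 0:
        return 0.0
    f = (seg[j - 1] - level) / (seg[j - 1] - seg[j])
    return (j - 1 + f) * dt


def transient_features(
    trace: FluorescenceTrace,
    stim_times: Optional[Sequence[float]] = None,
    pre_window: float = 50.0,
    min_amplitude: float = 0.05,
    fit_tau: bool = False,
) -> list[TransientFeatures]:
    """Per-transient amplitude, time-to-peak and decay half-time.

    ``trace`` must be normalized (F/F0).  Amplitude is peak minus the
    pre-stimulus diastolic level; T0.5 is the interpolated time from peak
    to 50 % decay and is left ``None`` (flagged missing) when the signal
    does not fall below 50 % before the next stimulus.  Transients whose
    amplitude is below ``min_amplitude`` dF/F0 are skipped.
    """
    stims = list(stim_times) if stim_times is not None else (trace.stim_times or [])
    if not stims:
        raise ValueError("no stimulus times available")
    stims = sorted(stims)
    x = trace.samples
    dt = trace.dt
    end_limit = trace.caffeine_time if trace.caffeine_time is not None else trace.duration

    out: list[TransientFeatures] = []
    for k, t0 in enumerate(stims):
        t1 = stims[k + 1] if k + 1 < len(stims) else min(t0 + 3000.0, end_limit)
        i0, i1 = int(round(t0 / dt)), min(int(round(t1 / dt)), x.size)
        if i1 - i0 < 3:
            continue
        ip0 = max(0, i0 - int(round(pre_window / dt)))
        dia = float(np.mean(x[ip0:i0])) if i0 > ip0 else float(x[i0])
        i_peak = i0 + int(np.argmax(x[i0:i1]))
        amp = float(x[i_peak] - dia)
        if amp < min_amplitude:
            logger.debug("stimulus at %.1f ms evoked no transient", t0)
            continue
        t_half = _half_decay_time(x, dt, i_peak, dia, i1)
        tau = None
        if fit_tau:
            try:
                tau, _ = _fit_exponential(x[i_peak:i1], dt, dia)
            except FitError:
                tau = None
        out.append(
            TransientFeatures(
                amplitude=amp,
                t_half_decay=t_half,
                time_to_peak=(i_peak - i0) * dt,
                decay_tau=tau,
                stim_time=float(t0),
            )
        )
    return out


def steady_state_summary(features: Sequence[TransientFeatures], last_k: int = 5) -> dict:
    """Mean amplitude/T0.5 over the last ``last_k`` transients."""
    feats = list(features)[-last_k:]
    if not feats:
        return {"amplitude": float("nan"), "t_half_decay": float("nan"), "n": 0}
    halves = [f.t_half_decay for f in feats if f.t_half_decay is not None]
    return {
        "amplitude": float(np.mean([f.amplitude for f in feats])),
        "t_half_decay": float(np.mean(halves)) if halves else float("nan"),
        "n": len(feats),
    }


def _fit_exponential(seg: np.ndarray, dt: float, offset_guess: float) -> tuple[float, float]:
    """Least-squares fit of A*exp(-t/tau)+C to a decay segment.

    Returns (tau_ms, rmse); raises FitError on failure or tau <= 0.
    """
    t = np.arange(seg.size) * dt
    a0 = seg[0] - offset_guess
    if a0 <= 0:
        raise FitError("decay segment does not start above the offset")
    head = float(np.mean(seg[: max(1, seg.size // 10)]))
    tail = float(np.mean(seg[-max(1, seg.size // 10):]))
    if tail >= head:
        raise FitError("segment does not decay; refusing to fit an exponential")
    tau0 = max(t[-1] / 3.0, dt)

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    try:
        popt, _ = curve_fit(
            model,
            t,
            seg,
            p0=(a0, tau0, offset_guess),
            bounds=([0.0, dt * 0.1, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy message path
        raise FitError(f"mono-exponential fit failed: {exc}") from exc
    a, tau, c = popt
    if not np.isfinite(tau) or tau <= 0 or a <= 0:
        raise FitError("mono-exponential fit returned a non-decaying solution")
    rmse = float(np.sqrt(np.mean((model(t, *popt) - seg) ** 2)))
    return float(tau), rmse


def caffeine_analysis(
    trace: FluorescenceTrace,
    caffeine_time: Optional[float] = None,
    search_window: float = 1500.0,
    fit_fraction: float = 0.95,
) -> CaffeineResult:
    """Quantify a caffeine-pulse response on a normalized trace.

    CaSR is the caffeine-transient amplitude (dF/F0, peak minus the
    pre-pulse diastolic level); the decay from the peak over
    ``fit_fraction`` of the remaining record is fitted with
    A*exp(-t/tau)+C, whose tau indexes NCX-mediated extrusion.  A
    non-decaying segment raises :class:`FitError` — there is no silent
    fallback.
    """
    t_caf = caffeine_time if caffeine_time is not None else trace.caffeine_time
    if t_caf is None:
        raise ValueError("caffeine_time not given and absent from trace metadata")
    if not 0 <= t_caf < trace.duration:
        raise ValueError("caffeine_time outside the trace")
    x = trace.samples
    dt = trace.dt
    i_caf = int(round(t_caf / dt))
    ip0 = max(0, i_caf - int(round(200.0 / dt)))
    dia = float(np.mean(x[ip0:i_caf])) if i_caf > ip0 else float(x[0])
    i_hi = min(x.size, i_caf + int(round(search_window / dt)))
    i_peak = i_caf + int(np.argmax(x[i_caf:i_hi]))
    casr = float(x[i_peak] - dia)
    i_end = i_peak + int(round(fit_fraction * (x.size - i_peak)))
    if i_end - i_peak < 10:
        raise FitError("caffeine decay segment too short to fit")
    tau, rmse = _fit_exponential(x[i_peak:i_end], dt, dia)
    return CaffeineResult(casr=casr, ncx_tau=tau, peak_time=i_peak * dt, fit_rmse=rmse)


def _iterative_rest_stats(x: np.ndarray, n_rounds: int = 2, k: float = 3.0) -> tuple[float, float]:
    """Resting level and SD with iterative exclusion of event samples."""
    included = x
    mu = float(np.median(included))
    sd = float(np.std(included))
    for _ in range(n_rounds):
        if sd == 0:
            break
        included = included[included <= mu + k * sd]
        if included.size < 10:
            break
        mu = float(np.median(included))
        sd = float(np.std(included))
    return mu, sd


def detect_resting_events(
    trace: FluorescenceTrace,
    sd_cutoff: float = 3.0,
    min_run: int = 3,
    smooth_ms: float = 50.0,
    resting_cat_threshold: float = 0.5,
    paced_amplitude: Optional[float] = None,
) -> list[RestingEvent]:
    """Detect spontaneous Ca2+ events in an unstimulated, normalized trace.

    The resting level F_rest and its SD come from the raw samples after
    two rounds of excluding values more than 3 SD above the running
    estimate (events inflate a naive SD).  Candidate excursions are runs
    of at least ``min_run`` samples on a boxcar-smoothed copy exceeding
    F_rest + 1.5 SD; a candidate becomes an event when its smoothed peak
    amplitude strictly exceeds ``sd_cutoff`` SD over F_rest.

    Events are labelled ``resting_transient`` when their dF/F0 amplitude
    reaches 50 % of the cell's paced transient amplitude (when supplied)
    or ``resting_cat_threshold`` otherwise; smaller events are waves.
    """
    x = trace.samples
    dt = trace.dt
    mu, sd = _iterative_rest_stats(x)
    if sd == 0:
        sd = 1e-12  # flat baseline: any excursion counts, a flat trace yields none
    w = max(1, int(round(smooth_ms / dt)))
    xs = np.convolve(x, np.ones(w) / w, mode="same") if w > 1 else x

    candidate = xs > mu + 1.5 * sd
    events: list[RestingEvent] = []
    # contiguous runs of candidate samples
    edges = np.flatnonzero(np.diff(np.concatenate(([0], candidate.view(np.int8), [0]))))
    big_cut = 0.5 * paced_amplitude if paced_amplitude is not None else resting_cat_threshold
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a < min_run:
            continue
        i_peak = a + int(np.argmax(xs[a:b]))
        amp = float(xs[i_peak] - mu)
        if amp <= sd_cutoff * sd:
            continue
        kind = "resting_transient" if amp >= big_cut else "wave"
        events.append(
            RestingEvent(kind=kind, time=i_peak * dt, amplitude_sd=amp / sd, amplitude_df=amp)
        )
    return events


def normalize_to_ctrl(
    group_values: pd.DataFrame,
    ctrl_values: pd.DataFrame,
    by: str = "cycle_length",
    value: str = "value",
) -> pd.DataFrame:
    """Normalize a treated group's per-cycle-length means to control.

    Both inputs need columns ``by`` and ``value``.  Output has one row per
    cycle length with the treated/ctrl mean ratio and the standard error
    propagated as ratio * sqrt((se_t/m_t)^2 + (se_c/m_c)^2).
    """
    def _summ(df):
        g = df.groupby(by)[value]
        return pd.DataFrame({"mean": g.mean(), "se": g.sem(), "n": g.size()})

    gs, cs = _summ(group_values), _summ(ctrl_values)
    missing = sorted(set(gs.index) - set(cs.index))
    if missing:
        raise ValueError(f"no control values at cycle length(s): {missing}")
    cs = cs.loc[gs.index]
    ratio = gs["mean"] / cs["mean"]
    se = ratio.abs() * np.sqrt((gs["se"] / gs["mean"]) ** 2 + (cs["se"] / cs["mean"]) ** 2)
    out = pd.DataFrame(
        {
            "ratio": ratio,
            "se": se,
            "n_group": gs["n"],
            "n_ctrl": cs["n"],
            "group_mean": gs["mean"],
            "ctrl_mean": cs["mean"],
        }
    )
    out.index.name = by
    return out.reset_index()
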