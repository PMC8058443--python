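"""Core in-memory containers shared across the analysis modules.

Conventions
-----------
* Voltage traces are in mV and sampled at a rate given in kHz (so the
  sample interval in ms is ``1 / sampling_rate``).
* Fluorescence traces are in arbitrary detector units and sampled at a
  rate given in Hz.  After normalization the samples are F/F0 with a
  diastolic baseline of ~1.
* Line-scan (xt) images are stored with time along axis 0 (one row per
  scanned line) and space along axis 1.
* All times are milliseconds, all lengths micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "VoltageTrace",
    "FluorescenceTrace",
    "LineScanImage",
    "CellImage",
    "APFeatures",
    "DADEvent",
    "BVRResult",
    "TransientFeatures",
    "CaffeineResult",
    "RestingEvent",
    "Spark",
    "SparkSummary",
    "TTPowerResult",
]


def _as_float_array(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("trace samples must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError("trace samples must be finite")
    return arr


@dataclass
class VoltageTrace:
    """Sampled membrane potential (mV) with optional stimulus annotations.

    Parameters
    ----------
    samples : array of mV values
    sampling_rate : kHz
    stimulus_times : optional list of stimulus (or take-off) times in ms
    """

    samples: np.ndarray
    sampling_rate: float  # kHz
    stimulus_times: Optional[Sequence[float]] = None

    def __post_init__(self):
        self.samples = _as_float_array(self.samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive (kHz)")
        if self.stimulus_times is not None:
            self.stimulus_times = list(map(float, self.stimulus_times))

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Time axis in ms."""
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


@dataclass
class FluorescenceTrace:
    """Sampled fluorescence signal (arbitrary units, rate in Hz)."""

    samples: np.ndarray
    sampling_rate: float  # Hz
    background: float = 0.0
    stim_times: Optional[Sequence[float]] = None  # ms
    caffeine_time: Optional[float] = None  # ms
    normalized: bool = False

    def __post_init__(self):
        self.samples = _as_float_array(self.samples)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive (Hz)")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.stim_times is not None:
            self.stim_times = list(map(float, self.stim_times))

    @property
    def dt(self) -> float:
        """Sample interval in ms."""
        return 1000.0 / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) * self.dt

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt


@dataclass
class LineScanImage:
    """Confocal line-scan (xt) image: rows are time lines, columns space."""

    matrix: np.ndarray
    pixel_size: float  # um per pixel along the scanned line
    line_period: float  # ms per line
    background: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("line-scan matrix must be 2-D (time x space)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um)")
        if self.line_period <= 0:
            raise ValueError("line_period must be positive (ms)")

    @property
    def n_lines(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]

    @property
    def duration_s(self) -> float:
        """Total scan duration in seconds."""
        return self.n_lines * self.line_period / 1000.0

    @property
    def line_length_um(self) -> float:
        return self.n_pixels * self.pixel_size


@dataclass
class CellImage:
    """2-D confocal cell image (8-bit style gray intensities)."""

    matrix: np.ndarray
    pixel_size: float = 78.0 / 1024.0  # um per pixel
    roi: Optional[tuple] = None  # (row0, row1, col0, col1)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("cell image must be 2-D single channel")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive (um)")
        if self.roi is not None:
            r0, r1, c0, c1 = self.roi
            if not (0 <= r0 < r1 <= self.matrix.shape[0] and 0 <= c0 < c1 <= self.matrix.shape[1]):
                raise ValueError("roi out of image bounds or empty")

    def roi_view(self) -> np.ndarray:
        if self.roi is None:
            return self.matrix
        r0, r1, c0, c1 = self.roi
        return self.matrix[r0:r1, c0:c1]


# ---------------------------------------------------------------------------
# Result records
# ---------------------------------------------------------------------------

@dataclass
class APFeatures:
    """Per-beat action-potential features.

    apd50/apd90 are measured from the take-off (time of dV/dt max) to the
    interpolated crossing of the 50 % / 90 % repolarization level; NaN when
    the AP never reaches the level inside its segment.
    """

    apd50: float  # ms
    apd90: float  # ms
    e_diast: float  # mV
    dvdt_max: float  # V/s
    peak: float  # mV
    take_off_time: float  # ms, absolute within the parent trace


@dataclass
class DADEvent:
    """A delayed afterdepolarization: diastolic deflection >= 1 mV."""

    time: float  # ms
    amplitude: float  # mV above local diastolic baseline


@dataclass
class BVRResult:
    """Beat-to-beat variability of repolarization summary."""

    stv: float  # ms
    poincare_pairs: list  # [(APD_n, APD_n+1), ...]
    n_beats: int


@dataclass
class TransientFeatures:
    """One evoked Ca2+ transient."""

    amplitude: float  # dF/F0
    t_half_decay: Optional[float]  # ms; None if decay never reaches 50 %
    time_to_peak: float  # ms
    decay_tau: Optional[float] = None  # ms
    stim_time: Optional[float] = None  # ms


@dataclass
class CaffeineResult:
    """Caffeine-pulse readout: SR content and NCX-dominated decay."""

    casr: float  # dF/F0 amplitude of the caffeine transient
    ncx_tau: float  # ms, mono-exponential decay constant
    peak_time: float = float("nan")
    fit_rmse: float = float("nan")


@dataclass
class RestingEvent:
    """A spontaneous diastolic Ca2+ event (wave or resting transient)."""

    kind: str  # "wave" | "resting_transient"
    time: float  # ms, at event peak
    amplitude_sd: float  # multiples of resting-fluorescence SD
    amplitude_df: float  # dF/F0


@dataclass
class Spark:
    """One detected Ca2+ release event on a line-scan with its parameters."""

    x_center: float  # um
    t_center: float  # ms
    amplitude: float  # dF/F0
    fwhm: float  # um
    fdhm: float  # ms
    fw: float  # um
    fd: float  # ms
    ttp: float  # ms
    tau_decay: float  # ms (NaN when the fit fails)
    mass: float  # dF/F0 * um^3
    in_focus: bool
    is_ember: bool
    partial: bool = False  # touches the image edge / incomplete profiles


@dataclass
class SparkSummary:
    """Per-cell spark statistics and derived SR-leak index."""

    frequency: float  # events / s / 100 um
    mean_mass: float
    leak: float  # mean_mass * frequency
    ember_count: int
    ember_fraction: float
    n_sparks: int
    has_embers: bool = False


@dataclass
class TTPowerResult:
    """Normalized spatial power spectrum and the T-tubule band-power index."""

    frequencies: np.ndarray = field(repr=False)  # um^-1
    power: np.ndarray = field(repr=False)  # normalized to the central peak
    tt_index: float = float("nan")
    band: tuple = (0.3, 0.7)
    peak_frequency: float = float("nan")  # um^-1, dominant non-DC peak
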