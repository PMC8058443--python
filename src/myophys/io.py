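"""Readers/writers for traces (delimited text), images (TIFF) and run
manifests.

Trace files are two-column tab-delimited text (time_ms, value) with a
``#``-prefixed header carrying the trace kind, sampling rate (with unit),
and optional metadata (background, stimulus times, caffeine time), so a
file round-trips into the same typed object it was written from.
"""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

import numpy as np
import tifffile

from .datatypes import CellImage, FluorescenceTrace, LineScanImage, VoltageTrace

__all__ = ["read_trace", "write_trace", "read_image", "write_image", "write_manifest"]


def write_trace(path, trace: Union[VoltageTrace, FluorescenceTrace]) -> None:
    path = Path(path)
    lines = []
    if isinstance(trace, VoltageTrace):
        lines.append("# kind: voltage")
        lines.append(f"# sampling_rate: {trace.sampling_rate} kHz")
        lines.append("# units: mV")
        if trace.stimulus_times:
            lines.append("# stimulus_times_ms: " + ",".join(f"{t:g}" for t in trace.stimulus_times))
        dt = trace.dt
    else:
        lines.append("# kind: fluorescence")
        lines.append(f"# sampling_rate: {trace.sampling_rate} Hz")
        lines.append("# units: au")
        lines.append(f"# background: {trace.background:g}")
        if trace.normalized:
            lines.append("# normalized: true")
        if trace.stim_times:
            lines.append("# stimulus_times_ms: " + ",".join(f"{t:g}" for t in trace.stim_times))
        if trace.caffeine_time is not None:
            lines.append(f"# caffeine_time_ms: {trace.caffeine_time:g}")
        dt = trace.dt
    lines.append("time_ms\tvalue")
    t = np.arange(trace.samples.size) * dt
    body = "\n".join(f"{ti:.6g}\t{vi:.10g}" for ti, vi in zip(t, trace.samples))
    path.write_text("\n".join(lines) + "\n" + body + "\n")


def _parse_rate(text: str) -> tuple[float, str]:
    parts = text.split()
    value = float(parts[0])
    unit = parts[1].lower() if len(parts) > 1 else ""
    return value, unit


def read_trace(path) -> Union[VoltageTrace, FluorescenceTrace]:
    """Read a delimited trace file written by :func:`write_trace` (or any
    file following the same header convention).

    Malformed data rows raise a ``ValueError`` naming the line number; a
    missing sampling-rate header is an error.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    values = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    key, _, val = line.lstrip("# ").partition(":")
                    meta[key.strip().lower()] = val.strip()
                continue
            fields = line.replace(",", "\t").split()
            if fields[0].lower().startswith("time"):
                continue
            try:
                values.append(float(fields[1]) if len(fields) > 1 else float(fields[0]))
            except (ValueError, IndexError):
                raise ValueError(f"{path.name}: malformed data row at line {lineno}: {line!r}")
    if "sampling_rate" not in meta:
        raise ValueError(f"{path.name}: missing '# sampling_rate:' header")
    rate, unit = _parse_rate(meta["sampling_rate"])
    kind = meta.get("kind", "voltage").lower()
    samples = np.asarray(values, dtype=float)
    stim = None
    if "stimulus_times_ms" in meta:
        stim = [float(s) for s in meta["stimulus_times_ms"].split(",") if s]

    if kind == "voltage":
        rate_khz = rate / 1000.0 if unit == "hz" else rate  # canonical kHz
        return VoltageTrace(samples, rate_khz, stimulus_times=stim)
    rate_hz = rate * 1000.0 if unit == "khz" else rate  # canonical Hz
    caf = float(meta["caffeine_time_ms"]) if "caffeine_time_ms" in meta else None
    return FluorescenceTrace(
        samples,
        rate_hz,
        background=float(meta.get("background", 0.0)),
        stim_times=stim,
        caffeine_time=caf,
        normalized=meta.get("normalized", "").lower() == "true",
    )


def write_image(path, image: Union[LineScanImage, CellImage]) -> None:
    """Write a single-channel TIFF: 8-bit for cell images, 16-bit for
    line-scans."""
    path = Path(path)
    if isinstance(image, CellImage):
        tifffile.imwrite(path, np.clip(image.matrix, 0, 255).astype(np.uint8))
    else:
        tifffile.imwrite(path, np.clip(image.matrix, 0, 65535).astype(np.uint16))


def read_image(
    path,
    kind: str,
    pixel_size: float | None = None,
    line_period: float | None = None,
    background: float = 0.0,
) -> Union[LineScanImage, CellImage]:
    """Read a single-channel TIFF as a typed image.

    ``kind`` is ``"linescan"`` or ``"cell"``.  Multi-frame line-scan
    stacks (e.g. 10 xt frames from one cell) are concatenated along the
    time axis, so the scan duration is n_frames x frame duration.
    Multi-channel images are rejected with instructions to extract one
    channel first.
    """
    arr = tifffile.imread(Path(path))
    if pixel_size is None or pixel_size <= 0:
        raise ValueError("pixel_size (um) is required to calibrate the image")
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError("multi-channel image: extract a single channel before analysis")
    if kind == "linescan":
        if line_period is None or line_period <= 0:
            raise ValueError("line_period (ms) is required for line-scan images")
        if arr.ndim == 3:  # frame stack -> concatenate in time
            arr = arr.reshape(-1, arr.shape[-1])
        elif arr.ndim != 2:
            raise ValueError(f"unsupported line-scan dimensionality: {arr.ndim}")
        return LineScanImage(arr.astype(float), pixel_size, line_period, background)
    if kind == "cell":
        if arr.ndim != 2:
            raise ValueError("cell images must be single 2-D frames")
        return CellImage(arr.astype(float), pixel_size)
    raise ValueError(f"unknown image kind {kind!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: list | None = None) -> dict:
    """Write a JSON run manifest (config, input hashes, versions)."""
    import numpy
    import scipy

    from . import __version__

    manifest = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "inputs": [
            {"path": str(p), "sha256": _sha256(Path(p))} for p in (inputs or []) if Path(p).exists()
        ],
        "versions": {
            "myophys": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
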