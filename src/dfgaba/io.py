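"""Readers and writers for traces, recordings and run records.

Conventions are centralised here and in the type containers: times in
seconds, voltages in mV, frames indexed from 0, windows half-open
[start, end).  Every file the package writes can be read back by the
package.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from dfgaba.traces import FluorescenceRecording, TraceError

RATE_MISMATCH_TOL = 0.01


class FormatError(ValueError):
    """Raised for malformed input files."""


def read_trace_table(path: str | Path) -> FluorescenceRecording:
    """Read a CSV/TSV trace table (columns: time, roi, background).

    A sidecar ``<stem>.json`` file, when present, supplies frame rate,
    stimulus windows and other metadata; the frame rate inferred from the
    time column is cross-checked against it (>1% mismatch is an error).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = {"time", "roi", "background"} - set(df.columns)
    if missing:
        raise FormatError(f"trace table {path.name} lacks columns: {sorted(missing)}")
    times = df["time"].to_numpy(dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        raise FormatError("time column must be strictly increasing")

    meta: dict[str, Any] = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    inferred = 1.0 / float(np.median(np.diff(times))) if len(times) > 1 else meta.get(
        "frame_rate_hz", 0.0
    )
    declared = meta.get("frame_rate_hz")
    if declared is not None and len(times) > 1:
        if abs(inferred - declared) / declared > RATE_MISMATCH_TOL:
            raise FormatError(
                f"frame rate mismatch: metadata says {declared} Hz but the time "
                f"column implies {inferred:.4g} Hz"
            )
    windows = [tuple(w) for w in meta.get("stimulus_windows", [])]
    try:
        return FluorescenceRecording(
            times=times,
            roi=df["roi"].to_numpy(dtype=float),
            background=df["background"].to_numpy(dtype=float),
            stimulus_windows=[(float(a), float(b), str(k)) for a, b, k in windows],
            frame_rate_hz=float(declared or inferred),
            exposure_ms=meta.get("exposure_ms"),
            metadata={k: v for k, v in meta.items() if k not in
                      ("frame_rate_hz", "stimulus_windows", "exposure_ms")},
        )
    except TraceError as exc:
        raise FormatError(str(exc)) from exc


def write_trace_table(rec: FluorescenceRecording, path: str | Path) -> None:
    """Write a recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(
        {"time": rec.times, "roi": rec.roi, "background": rec.background}
    ).to_csv(path, index=False)
    meta = {
        "frame_rate_hz": rec.frame_rate_hz,
        "exposure_ms": rec.exposure_ms,
        "stimulus_windows": [list(w) for w in rec.stimulus_windows],
        **rec.metadata,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_tiff_stack(
    path: str | Path,
    roi_mask_path: str | Path,
    frame_rate_hz: float,
    roi_label: int = 1,
    background_label: int = 2,
    stimulus_windows: list[tuple[float, float, str]] | None = None,
) -> FluorescenceRecording:
    """Extract ROI and background traces from a multi-frame TIFF stack.

    The mask TIFF labels pixels: ``roi_label`` marks the cell ROI and
    ``background_label`` the background region; traces are the per-frame
    mean pixel brightness (integrated density) over each region.
    """
    import tifffile

    stack = np.asarray(tifffile.imread(str(path)), dtype=float)
    if stack.ndim == 2:
        stack = stack[None, ...]
    mask = np.asarray(tifffile.imread(str(roi_mask_path)))
    if mask.shape != stack.shape[1:]:
        raise FormatError(
            f"mask shape {mask.shape} does not match frame shape {stack.shape[1:]}"
        )
    roi_px = mask == roi_label
    bg_px = mask == background_label
    if not roi_px.any():
        raise FormatError(f"mask contains no pixels with ROI label {roi_label}")
    if not bg_px.any():
        raise FormatError(f"mask contains no pixels with background label {background_label}")
    n = stack.shape[0]
    return FluorescenceRecording(
        times=np.arange(n) / frame_rate_hz,
        roi=stack[:, roi_px].mean(axis=1),
        background=stack[:, bg_px].mean(axis=1),
        stimulus_windows=stimulus_windows or [],
        frame_rate_hz=frame_rate_hz,
        metadata={"source": str(path)},
    )


def write_tiff_stack(frames: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), np.asarray(frames))


def write_run_record(
    out_dir: str | Path, subcommand: str, config: dict[str, Any], seed: int | None = None
) -> Path:
    """Write the reproducibility record every run leaves behind."""
    from dfgaba import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "subcommand": subcommand,
        "config": _jsonable(config),
        "seed": seed,
        "version": __version__,
    }
    path = out_dir / "run_record.json"
    path.write_text(json.dumps(record, indent=1))
    return path


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj
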