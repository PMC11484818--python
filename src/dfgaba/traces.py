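"""Fluorescence trace analysis: from ROI time series to DF_GABAA in mV.

The pipeline mirrors the all-optical workflow: background subtraction
(optionally with a heavily smoothed background), polynomial detrending
with the stimulus response excluded from the fit, light smoothing,
dF/F0 extraction (epoch-averaged, extremum, or neuropil-corrected), and
linear conversion of dF/F0 to a voltage deflection through a per-dye
calibration slope.

Sign conventions.  The voltage indicator brightens when the cell
hyperpolarizes, so a positive dF/F0 maps to a negative voltage
deflection.  The reported ``df_gabaa`` is that measured deflection
DeltaV = E_GABAA - Vm: negative values mean anion influx and
hyperpolarization, matching how optically estimated driving forces are
conventionally quoted.  (The biophysical model reports
DF = Vm - E_GABAA, the same quantity with opposite sign.)

Also here: threshold/duration event detection on voltage traces
(seizure-like events, network bursts) and the peri-event rules for
choosing uncontaminated measurement windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Literal, Sequence

import numpy as np
import pandas as pd

from dfgaba.params import ParameterError

Window = tuple[float, float]


class TraceError(ValueError):
    """Raised for malformed traces or analysis windows."""


@dataclass
class FluorescenceRecording:
    """A sampled fluorescence recording with its stimulus bookkeeping.

    ``times`` in seconds; ``roi`` and ``background`` are mean-pixel
    brightness (integrated density) per frame in arbitrary units;
    ``stimulus_windows`` are half-open [start, end) intervals in seconds
    with a kind of ``"optogenetic"`` or ``"agonist_puff"``.
    """

    times: np.ndarray
    roi: np.ndarray
    background: np.ndarray
    stimulus_windows: list[tuple[float, float, str]] = field(default_factory=list)
    frame_rate_hz: float = 0.0
    exposure_ms: float | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.roi = np.asarray(self.roi, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.frame_rate_hz == 0.0 and len(self.times) > 1:
            self.frame_rate_hz = 1.0 / float(np.median(np.diff(self.times)))
        self.validate()

    def validate(self) -> None:
        if not (len(self.times) == len(self.roi) == len(self.background)):
            raise TraceError("times, roi and background must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise TraceError("frame times must be strictly increasing")
        if self.frame_rate_hz <= 0:
            raise TraceError("frame rate must be > 0")
        t0, t1 = self.times[0], self.times[-1]
        for start, end, kind in self.stimulus_windows:
            if start >= end:
                raise TraceError(f"empty stimulus window ({start}, {end})")
            if start < t0 or end > t1 + 1.0 / self.frame_rate_hz:
                raise TraceError(
                    f"stimulus window ({start}, {end}) outside the recording span"
                )
            if kind not in ("optogenetic", "agonist_puff"):
                raise TraceError(f"unknown stimulus kind {kind!r}")

    def window_mask(self, window: Window) -> np.ndarray:
        """Boolean frame mask for a half-open [start, end) time window."""
        return (self.times >= window[0]) & (self.times < window[1])

    def windows_of_kind(self, kind: str | None = None) -> list[Window]:
        return [
            (s, e) for s, e, k in self.stimulus_windows if kind is None or k == kind
        ]


@dataclass
class Calibration:
    """Linear fluorescence-voltage calibration for one indicator/dye pair.

    ``slope_percent_per_mV`` is the regression slope of dF/F0 (in %)
    against the voltage step magnitude; the bundled default is the
    published JF608 value (0.1845 %/mV, i.e. ~5.42 mV per percent).
    ``brighter_when_hyperpolarized`` records the indicator's sign.
    """

    slope_percent_per_mV: float = 0.1845
    brighter_when_hyperpolarized: bool = True

    def __post_init__(self) -> None:
        if self.slope_percent_per_mV == 0:
            raise ParameterError("calibration slope must be non-zero")


@dataclass
class DfEstimate:
    """Result of one driving-force estimation."""

    dff: float                    # fractional dF/F0
    delta_v_mV: float             # measured voltage deflection
    df_gabaa_mV: float            # = delta_v (negative -> hyperpolarizing influx)
    mode: str
    windows: dict[str, Any] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "dff": self.dff,
            "delta_v_mV": self.delta_v_mV,
            "df_gabaa_mV": self.df_gabaa_mV,
            "mode": self.mode,
            "windows": self.windows,
        }


# ---------------------------------------------------------------------------
# elementary trace operations
# ---------------------------------------------------------------------------

def moving_average(trace: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks at the edges.

    ``window = 1`` is the identity.
    """
    if window < 1:
        raise TraceError("smoothing window must be >= 1")
    if window == 1:
        return np.asarray(trace, dtype=float).copy()
    s = pd.Series(np.asarray(trace, dtype=float))
    return s.rolling(window, center=True, min_periods=1).mean().to_numpy()


def subtract_background(
    roi_trace: np.ndarray, background_trace: np.ndarray, smooth_window: int = 1
) -> np.ndarray:
    """Subtract the (optionally smoothed) background trace element-wise.

    ``smooth_window = 1`` subtracts the raw background (the agonist-puff
    pipeline); the all-optical pipeline smooths the background with a
    window of 100 frames first.
    """
    roi_trace = np.asarray(roi_trace, dtype=float)
    background_trace = np.asarray(background_trace, dtype=float)
    if roi_trace.shape != background_trace.shape:
        raise TraceError("roi and background traces must have equal length")
    return roi_trace - moving_average(background_trace, smooth_window)


def detrend_polynomial(
    trace: np.ndarray,
    order: int,
    exclude_mask: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Remove bleaching/drift by least-squares polynomial subtraction.

    The fit uses only samples where ``exclude_mask`` is False (stimulus
    responses are excluded so the signal survives); the fitted polynomial
    is evaluated and subtracted over the whole trace.  The residual mean
    over the fitted samples is zero by construction.
    """
    trace = np.asarray(trace, dtype=float)
    n = len(trace)
    if order < 0:
        raise TraceError("polynomial order must be >= 0")
    x = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    fit_mask = np.ones(n, dtype=bool) if exclude_mask is None else ~np.asarray(exclude_mask, dtype=bool)
    n_fit = int(fit_mask.sum())
    if n_fit < order + 2:
        raise TraceError(
            f"underdetermined detrend: order {order} needs at least {order + 2} "
            f"fitted samples, got {n_fit}"
        )
    poly = np.polynomial.Polynomial.fit(x[fit_mask], trace[fit_mask], deg=order)
    return trace - poly(x)


def dff_event(
    trace: np.ndarray,
    baseline_mask: np.ndarray,
    response_mask: np.ndarray,
    mode: Literal["extremum", "mean"] = "extremum",
) -> float:
    """dF/F0 of one event: response vs baseline-mean, as a fraction.

    ``extremum`` picks the response sample of largest absolute deviation
    from the baseline mean (signed); ``mean`` uses the response mean.
    """
    trace = np.asarray(trace, dtype=float)
    baseline_mask = np.asarray(baseline_mask, dtype=bool)
    response_mask = np.asarray(response_mask, dtype=bool)
    if not baseline_mask.any() or not response_mask.any():
        raise TraceError("baseline and response windows must be non-empty")
    if (baseline_mask & response_mask).any():
        raise TraceError("baseline and response windows must be disjoint")
    f0 = trace[baseline_mask].mean()
    if f0 == 0:
        raise TraceError("zero baseline mean: dF/F0 undefined")
    dev = trace[response_mask] - f0
    if mode == "mean":
        df = dev.mean()
    elif mode == "extremum":
        df = dev[np.argmax(np.abs(dev))]
    else:
        raise TraceError(f"unknown dff mode {mode!r}")
    return float(df / f0)


def average_epochs(
    trace: np.ndarray,
    stimulus_slices: Sequence[tuple[int, int]],
    baseline_slices: Sequence[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample-wise average across repeated stimulation epochs.

    Each stimulus slice [i0, i1) must have the same length; baselines
    default to the window of equal length immediately preceding each
    stimulus.  Returns (averaged stimulus segment, averaged baseline
    segment).
    """
    trace = np.asarray(trace, dtype=float)
    if not stimulus_slices:
        raise TraceError("at least one stimulation epoch is required")
    lengths = {i1 - i0 for i0, i1 in stimulus_slices}
    if len(lengths) != 1:
        raise TraceError(f"unequal epoch lengths: {sorted(lengths)}")
    span = lengths.pop()
    if span <= 0:
        raise TraceError("empty stimulation epoch")
    if baseline_slices is None:
        baseline_slices = [(i0 - span, i0) for i0, _ in stimulus_slices]
    if {i1 - i0 for i0, i1 in baseline_slices} != {span}:
        raise TraceError("baseline segments must match the epoch length")
    for i0, i1 in list(stimulus_slices) + list(baseline_slices):
        if i0 < 0 or i1 > len(trace):
            raise TraceError("epoch slice outside the trace")
    stim = np.mean([trace[i0:i1] for i0, i1 in stimulus_slices], axis=0)
    base = np.mean([trace[i0:i1] for i0, i1 in baseline_slices], axis=0)
    return stim, base


def in_vivo_dff(
    roi_trace: np.ndarray,
    background_trace: np.ndarray,
    stim_mask: np.ndarray,
    flank_mask: np.ndarray,
) -> float:
    """Neuropil-corrected dF/F0 for one stimulus.

    dF_S = mean(roi, stim) - mean(roi, flank); the equivalent background
    change dF_BG is subtracted (shared contamination cancels exactly);
    the result is normalised by F0S = mean(roi, flank).
    """
    roi_trace = np.asarray(roi_trace, dtype=float)
    background_trace = np.asarray(background_trace, dtype=float)
    stim_mask = np.asarray(stim_mask, dtype=bool)
    flank_mask = np.asarray(flank_mask, dtype=bool)
    if roi_trace.shape != background_trace.shape:
        raise TraceError("roi and background traces must have equal length")
    if stim_mask.sum() == 0 or flank_mask.sum() == 0:
        raise TraceError("stimulus and flank windows must be non-empty")
    if abs(int(stim_mask.sum()) - int(flank_mask.sum())) > 1:
        raise TraceError("stimulus and flank windows must have equal duration")
    f0s = roi_trace[flank_mask].mean()
    if f0s == 0:
        raise TraceError("zero F0S: dF/F0 undefined")
    df_s = roi_trace[stim_mask].mean() - f0s
    df_bg = background_trace[stim_mask].mean() - background_trace[flank_mask].mean()
    return float((df_s - df_bg) / f0s)


def dff_to_voltage(dff: float, cal: Calibration) -> float:
    """Convert a fractional dF/F0 to a voltage deflection in mV.

    |DeltaV| = (dff * 100) / slope; with an indicator that brightens on
    hyperpolarization a positive dF/F0 is a negative (hyperpolarizing)
    deflection.
    """
    dv = dff * 100.0 / cal.slope_percent_per_mV
    return -dv if cal.brighter_when_hyperpolarized else dv


# ---------------------------------------------------------------------------
# the composed estimator
# ---------------------------------------------------------------------------

DEFAULT_BACKGROUND_SMOOTH = 100
DEFAULT_DISPLAY_SMOOTH = 7
DEFAULT_DETREND_ORDER = 9


def estimate_df_gabaa(
    rec: FluorescenceRecording,
    cal: Calibration | None = None,
    mode: Literal["in-vitro", "puff", "in-vivo"] = "in-vitro",
    detrend_order: int = DEFAULT_DETREND_ORDER,
    background_smooth: int | None = None,
    smooth_window: int = DEFAULT_DISPLAY_SMOOTH,
    flank_side: Literal["before", "after"] = "before",
) -> DfEstimate:
    """Estimate the GABA_A driving force (mV) from a fluorescence recording.

    Modes
    -----
    ``in-vitro``
        All-optical protocol: smoothed-background subtraction, polynomial
        detrend (stimuli excluded), average of the strobed stimulation
        epochs against equal-length preceding baselines, mean-mode dF/F0.
    ``puff``
        Agonist-puff protocol: raw background subtraction, detrend,
        7-frame smoothing, extremum-mode dF/F0 against the pre-puff
        baseline.
    ``in-vivo``
        Single-stimulus neuropil-corrected dF/F0 using an equal-length
        flank window on one side of the stimulus; no detrending (the
        adjacent flank controls for slow drift).

    Returns a :class:`DfEstimate`; ``df_gabaa_mV`` is the measured
    deflection (negative = hyperpolarizing anion influx).
    """
    cal = cal or Calibration()
    windows = rec.windows_of_kind()
    if not windows:
        raise TraceError("recording has no stimulus windows")
    exclude = np.zeros(len(rec.times), dtype=bool)
    for wdw in windows:
        exclude |= rec.window_mask(wdw)

    if mode == "in-vitro":
        bg_smooth = DEFAULT_BACKGROUND_SMOOTH if background_smooth is None else background_smooth
        corrected = subtract_background(rec.roi, rec.background, bg_smooth)
        detrended = detrend_polynomial(corrected, detrend_order, exclude, rec.times)
        # restore the DC level removed with the trend so F0 keeps its scale
        detrended = detrended + corrected[~exclude].mean()
        slices = [_window_slice(rec, wdw) for wdw in windows]
        span = min(i1 - i0 for i0, i1 in slices)
        slices = [(i0, i0 + span) for i0, _ in slices]
        stim_avg, base_avg = average_epochs(detrended, slices)
        f0 = base_avg.mean()
        if f0 == 0:
            raise TraceError("zero baseline mean: dF/F0 undefined")
        dff = float((stim_avg.mean() - f0) / f0)
        used = {"stimulus_windows": windows, "n_epochs": len(windows)}
        est_mode = "epoch-average"
    elif mode == "puff":
        bg_smooth = 1 if background_smooth is None else background_smooth
        corrected = subtract_background(rec.roi, rec.background, bg_smooth)
        detrended = detrend_polynomial(corrected, detrend_order, exclude, rec.times)
        detrended = detrended + corrected[~exclude].mean()
        smoothed = moving_average(detrended, smooth_window)
        start, end = windows[0]
        response = rec.window_mask((start, end))
        baseline = rec.window_mask((max(rec.times[0], start - (end - start)), start))
        dff = dff_event(smoothed, baseline, response, mode="extremum")
        used = {"response_window": windows[0], "mode": "extremum"}
        est_mode = "extremum"
    elif mode == "in-vivo":
        start, end = windows[0]
        span = end - start
        stim_mask = rec.window_mask((start, end))
        if flank_side == "before":
            flank = (start - span, start)
        else:
            flank = (end, end + span)
        flank_mask = rec.window_mask(flank)
        dff = in_vivo_dff(rec.roi, rec.background, stim_mask, flank_mask)
        used = {"stimulus_window": windows[0], "flank_window": flank, "side": flank_side}
        est_mode = "in-vivo-corrected"
    else:
        raise TraceError(f"unknown analysis mode {mode!r}")

    dv = dff_to_voltage(dff, cal)
    return DfEstimate(dff=dff, delta_v_mV=dv, df_gabaa_mV=dv, mode=est_mode, windows=used)


def _window_slice(rec: FluorescenceRecording, window: Window) -> tuple[int, int]:
    idx = np.nonzero(rec.window_mask(window))[0]
    if idx.size == 0:
        raise TraceError(f"stimulus window {window} contains no frames")
    return int(idx[0]), int(idx[-1]) + 1


# ---------------------------------------------------------------------------
# voltage-trace event detection
# ---------------------------------------------------------------------------

def _contiguous_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.nonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))[0]
    return list(zip(idx[0::2], idx[1::2]))


def detect_sle(
    vm_trace: np.ndarray,
    rate_hz: float,
    baseline_span: Window | None = None,
    n_sd: float = 2.0,
    min_duration_s: float = 5.0,
) -> list[Window]:
    """Seizure-like events: |Vm - baseline| > n_sd*SD sustained >= 5 s.

    Baseline statistics come from ``baseline_span`` (seconds; defaults to
    the first 10 s of the trace), which must itself be quiet enough to
    define a resting potential.
    """
    vm_trace = np.asarray(vm_trace, dtype=float)
    if rate_hz <= 0:
        raise TraceError("sampling rate must be > 0")
    if len(vm_trace) / rate_hz <= min_duration_s:
        raise TraceError(f"trace shorter than the {min_duration_s} s duration rule")
    t = np.arange(len(vm_trace)) / rate_hz
    span = baseline_span or (0.0, min(10.0, t[-1] / 2))
    base = vm_trace[(t >= span[0]) & (t < span[1])]
    if base.size < 2:
        raise TraceError("no valid baseline segment for SLE detection")
    mu, sd = base.mean(), base.std()
    above = np.abs(vm_trace - mu) > n_sd * sd
    min_len = int(np.ceil(min_duration_s * rate_hz))
    return [
        (i0 / rate_hz, i1 / rate_hz)
        for i0, i1 in _contiguous_runs(above)
        if i1 - i0 >= min_len
    ]


def detect_network_burst(
    vm_trace: np.ndarray,
    rate_hz: float,
    baseline_span: Window | None = None,
    threshold_mV: float = 10.0,
    min_duration_s: float = 0.250,
) -> list[Window]:
    """Network bursts: depolarisation > 10 mV above baseline for > 250 ms."""
    vm_trace = np.asarray(vm_trace, dtype=float)
    if rate_hz <= 0:
        raise TraceError("sampling rate must be > 0")
    t = np.arange(len(vm_trace)) / rate_hz
    span = baseline_span or (0.0, min(10.0, t[-1] / 2))
    base = vm_trace[(t >= span[0]) & (t < span[1])]
    if base.size < 1:
        raise TraceError("no valid baseline segment for burst detection")
    above = (vm_trace - base.mean()) > threshold_mV
    min_len = int(np.floor(min_duration_s * rate_hz)) + 1   # strictly longer
    return [
        (i0 / rate_hz, i1 / rate_hz)
        for i0, i1 in _contiguous_runs(above)
        if i1 - i0 >= min_len
    ]


def select_peri_sle_probe(
    stim_windows: Sequence[Window],
    sle_intervals: Sequence[Window],
    phase: Literal["pre", "during", "post"],
    contaminated_intervals: Sequence[Window] | None = None,
    max_gap_s: float = 15.0,
) -> Window | None:
    """Choose the stimulation window for a peri-event driving-force probe.

    ``pre``: window ending < 15 s before event onset; ``during``: window
    inside the event, < 15 s before its cessation; ``post``: window
    starting < 15 s after cessation.  The window and its equal-length
    preceding baseline must not overlap any event or contaminated
    interval.  Returns ``None`` when no window qualifies — absence is a
    valid result, not an error.
    """
    if not sle_intervals:
        raise TraceError("at least one seizure-like event is required")
    contaminated = list(contaminated_intervals or [])
    onset, cessation = sle_intervals[0][0], sle_intervals[0][1]

    def overlaps(w: Window, intervals: Sequence[Window]) -> bool:
        return any(w[0] < b and a < w[1] for a, b in intervals)

    for start, end in stim_windows:
        span = end - start
        baseline = (start - span, start)
        if phase == "pre":
            ok = end <= onset and onset - end < max_gap_s
            clean = not overlaps((start, end), sle_intervals) and not overlaps(
                baseline, sle_intervals
            )
        elif phase == "during":
            ok = start >= onset and end <= cessation and cessation - end < max_gap_s
            clean = True
        elif phase == "post":
            ok = start >= cessation and start - cessation < max_gap_s
            clean = not overlaps((start, end), sle_intervals) and not overlaps(
                baseline, sle_intervals
            )
        else:
            raise TraceError(f"unknown phase {phase!r}")
        if ok and clean and not overlaps((start, end), contaminated) and not overlaps(
            baseline, contaminated
        ):
            return (start, end)
    return None
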