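"""Photon-budget design for shot-noise-limited voltage imaging.

With dark and read noise negligible, the only noise is Poisson shot
noise with standard deviation sqrt(F0) photons, so detecting a
fractional change dF/F0 at signal-to-noise ratio S requires

    F0 = (S / (dF/F0))^2

collected photons.  A camera pixel well of ``well_depth`` electrons at
quantum efficiency QE yields well_depth/QE photoelectron-equivalents per
frame, which sets how many frames (hence how long a stimulation at a
given frame rate) are needed to reach the budget.  SNR grows as the
square root of the number of averaged frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from dfgaba.params import ParameterError
from dfgaba.traces import Calibration


@dataclass
class AcquisitionSpec:
    """Camera and protocol parameters for SNR design.

    Defaults describe the published setup: 30000 e- well depth, 82%
    quantum efficiency, 25 Hz frame rate, 1% target dF/F0 at SNR 10.
    """

    well_depth: float = 30000.0
    quantum_efficiency: float = 0.82
    frame_rate_hz: float = 25.0
    stimulus_duration_s: float = 1.0
    target_dff: float = 0.01
    target_snr: float = 10.0
    extra_variance_per_frame: float = 0.0   # optional dark/read-noise hook

    def __post_init__(self) -> None:
        if not 0.0 < self.quantum_efficiency <= 1.0:
            raise ParameterError("quantum efficiency must lie in (0, 1]")
        for name in ("well_depth", "frame_rate_hz", "stimulus_duration_s"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.extra_variance_per_frame < 0:
            raise ParameterError("extra variance must be >= 0")


def electrons_per_frame(spec: AcquisitionSpec) -> float:
    """Photoelectron budget per frame: well_depth / quantum_efficiency."""
    return spec.well_depth / spec.quantum_efficiency


def required_f0(target_snr: float, target_dff: float) -> float:
    """Baseline photon count needed for ``target_snr`` at ``target_dff``.

    F0 = (SNR / dff)^2, from SNR = dF/sqrt(F0) with dF = dff * F0.
    """
    if target_dff <= 0:
        raise ParameterError("target dF/F0 must be > 0")
    return (target_snr / target_dff) ** 2


def frames_required(required_f0_photons: float, epf: float) -> tuple[float, int]:
    """Frames needed to accumulate ``required_f0_photons`` at ``epf`` e-/frame.

    Returns the exact (unrounded) value and its ceiling.
    """
    if epf <= 0:
        raise ParameterError("electrons per frame must be > 0")
    exact = required_f0_photons / epf
    return exact, math.ceil(exact)


def snr_for_stimulation(spec: AcquisitionSpec) -> float:
    """Expected SNR of one stimulation epoch at the spec's dF/F0.

    Single-frame SNR is dff*sqrt(epf); averaging the
    frame_rate * stimulus_duration frames of the epoch scales it by the
    square root of that count.  The optional per-frame variance term
    (default 0) models non-negligible dark/read noise.
    """
    epf = electrons_per_frame(spec)
    n_frames = spec.frame_rate_hz * spec.stimulus_duration_s
    noise = math.sqrt(epf + spec.extra_variance_per_frame)
    return spec.target_dff * epf / noise * math.sqrt(n_frames)


def predicted_df_sd(
    epf: float,
    n_stim_frames: int,
    n_baseline_frames: int,
    cal: Calibration | None = None,
    background_fraction: float = 0.0,
    background_smooth: int = 1,
) -> float:
    """Shot-noise-limited SD of an estimated driving force, in mV.

    Propagates Poisson noise through the dF/F0 estimator
    (stim mean - baseline mean)/baseline mean: the variance of each mean
    is F0/N, so SD(dff) = sqrt((1/N_stim + 1/N_base)/F0).  A background
    ROI carrying ``background_fraction`` of the signal budget and
    smoothed over ``background_smooth`` frames before subtraction adds
    its (much smaller) share.  The voltage SD follows through the
    calibration slope.
    """
    cal = cal or Calibration()
    if epf <= 0:
        raise ParameterError("electrons per frame must be > 0")
    if n_stim_frames < 1 or n_baseline_frames < 1:
        raise ParameterError("frame counts must be >= 1")
    per_window = 1.0 / n_stim_frames + 1.0 / n_baseline_frames
    var_dff = per_window / epf
    if background_fraction > 0:
        var_dff += background_fraction * per_window / (epf * background_smooth)
    return math.sqrt(var_dff) * 100.0 / abs(cal.slope_percent_per_mV)


def predicted_df_sd_pipeline(
    frame_times,
    stimulus_windows,
    epf: float,
    cal: Calibration | None = None,
    background_photons: float = 0.0,
    bleach_rate_per_s: float = 0.0,
    detrend_order: int = 9,
    background_smooth: int = 100,
) -> float:
    """Shot-noise SD (mV) of the epoch-averaged estimator, exactly propagated.

    The composed estimator — smoothed-background subtraction, polynomial
    detrend fitted outside the stimulus windows, epoch/baseline means —
    is linear in the photon counts, so its shot-noise variance follows in
    closed form from the Poisson variance of each frame.  This is the
    quantity a Monte-Carlo over seeds should reproduce; the plain
    :func:`predicted_df_sd` is the floor without the detrending term.
    """
    import numpy as np

    cal = cal or Calibration()
    t = np.asarray(frame_times, dtype=float)
    n = len(t)
    exclude = np.zeros(n, dtype=bool)
    stim_weight = np.zeros(n)
    base_weight = np.zeros(n)
    for start, end in stimulus_windows:
        in_stim = (t >= start) & (t < end)
        exclude |= in_stim
        span = end - start
        in_base = (t >= start - span) & (t < start)
        stim_weight[in_stim] += 1.0
        base_weight[in_base] += 1.0
    if stim_weight.sum() == 0 or base_weight.sum() == 0:
        raise ParameterError("windows contain no frames")
    stim_weight /= stim_weight.sum()
    base_weight /= base_weight.sum()
    a = stim_weight - base_weight   # the DC add-back cancels in this contrast

    # hat matrix of the polynomial fit on non-excluded frames
    x = 2.0 * (t - t[0]) / (t[-1] - t[0]) - 1.0
    V = np.polynomial.legendre.legvander(x, detrend_order)
    Vm_fit = V[~exclude]
    # w = (I - H)^T a with H = V pinv(V_fit) E_fit
    beta = V.T @ a                        # (p+1,)
    coef = np.linalg.lstsq(Vm_fit.T @ Vm_fit, beta, rcond=None)[0]
    w = a.copy()
    w[~exclude] -= Vm_fit @ coef

    bleach = np.exp(-bleach_rate_per_s * t)
    var_roi = epf * bleach + background_photons * bleach
    var_bg = background_photons * bleach
    # background smoothed by a centred shrinking-window moving average
    if background_smooth > 1:
        half = background_smooth // 2
        sw = np.zeros(n)
        counts = np.array([min(i + half, n - 1) - max(i - half, 0) + 1 for i in range(n)])
        for i in range(n):
            lo, hi = max(i - half, 0), min(i + half, n - 1)
            sw[lo : hi + 1] += w[i] / counts[i]
        w_bg = sw
    else:
        w_bg = w
    var = float(w**2 @ var_roi + w_bg**2 @ var_bg)
    # the estimator's F0 is the restored DC of the background-subtracted
    # trace: the mean expected signal over the fitted (non-stimulus) frames
    f0 = float(np.mean(epf * bleach[~exclude]))
    sd_dff = np.sqrt(var) / f0
    return sd_dff * 100.0 / abs(cal.slope_percent_per_mV)


def design_report(spec: AcquisitionSpec) -> dict:
    """The full design chain for one acquisition spec, as plain numbers."""
    epf = electrons_per_frame(spec)
    f0 = required_f0(spec.target_snr, spec.target_dff)
    frames_exact, frames_ceil = frames_required(f0, epf)
    return {
        "electrons_per_frame": epf,
        "required_f0": f0,
        "frames_required_exact": frames_exact,
        "frames_required": frames_ceil,
        "expected_snr": snr_for_stimulation(spec),
        "frame_rate_hz": spec.frame_rate_hz,
        "stimulus_duration_s": spec.stimulus_duration_s,
        "target_dff": spec.target_dff,
        "target_snr": spec.target_snr,
    }
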