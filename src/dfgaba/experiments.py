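"""Scripted in-silico experiments probing what sets the GABA_A driving force.

Two classic manipulations are reproduced as turnkey protocols:

* KCC2 blockade — ramp the KCC2 conductance from its default (20 uS/cm^2)
  to zero over minutes 41-50.  Chloride accumulates, E_GABAA collapses
  toward (and past) the resting potential, and the synaptic GABA response
  flips from hyperpolarizing to depolarising.

* Impermeant-anion charge shift — ramp the mean impermeant charge z_i
  from -0.85 to -1.05 over the same window.  Vm and E_GABAA drop roughly
  in tandem, chloride falls, and the driving force (hence the GABA
  response) is left comparatively unchanged.

Each experiment delivers one synaptic GABA_A pulse before (40 min) and one
after (70 min) the manipulation and reports equilibrium values plus the
peak voltage responses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from dfgaba.model import SimulationResult, simulate
from dfgaba.params import ModelParams, ParameterError
from dfgaba.protocols import GabaPulse, ParameterRamp, StimulusProtocol

MIN = 60.0


@dataclass
class ExperimentReport:
    """Baseline vs post-manipulation summary of one in-silico experiment."""

    baseline: dict[str, float]
    post: dict[str, float]
    response_peak_baseline_mV: float
    response_peak_post_mV: float
    polarity_baseline: str
    polarity_post: str
    manipulation: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for peak, label in (
            (self.response_peak_baseline_mV, self.polarity_baseline),
            (self.response_peak_post_mV, self.polarity_post),
        ):
            expected = "hyperpolarizing" if peak < 0 else "depolarising"
            if label != expected:
                raise ParameterError(
                    f"polarity label {label!r} inconsistent with peak {peak:+.3f} mV"
                )

    @property
    def delta(self) -> dict[str, float]:
        return {k: self.post[k] - self.baseline[k] for k in self.baseline}

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def _snapshot(result: SimulationResult, t_probe: float) -> dict[str, float]:
    i = int(np.searchsorted(result.t, t_probe))
    i = min(i, len(result.t) - 1)
    return {
        "Vm_mV": float(result.Vm[i]),
        "E_GABAA_mV": float(result.E_GABAA[i]),
        "E_Cl_mV": float(result.E_Cl[i]),
        "Cl_i_mM": float(result.Cl_i[i]),
        "DF_GABAA_mV": float(result.df_gabaa[i]),
        "w_pL": float(result.w[i]),
    }


def _response_peak(result: SimulationResult, t_onset: float, span: float = 5.0) -> float:
    """Peak Vm deflection (mV, signed) within ``span`` s of a pulse onset."""
    pre = np.searchsorted(result.t, t_onset) - 1
    v0 = result.Vm[max(pre, 0)]
    mask = (result.t >= t_onset) & (result.t <= t_onset + span)
    dv = result.Vm[mask] - v0
    return float(dv[np.argmax(np.abs(dv))])


def _run_two_pulse(
    params: ModelParams,
    ramp: ParameterRamp,
    t_pulse_pre: float,
    t_pulse_post: float,
    duration: float,
) -> tuple[SimulationResult, ExperimentReport]:
    protocol = StimulusProtocol(
        events=[
            GabaPulse(t_onset=t_pulse_pre, tau_ms=params.tau_ms, g_max_nS=params.g_GABAA_max),
            ramp,
            GabaPulse(t_onset=t_pulse_post, tau_ms=params.tau_ms, g_max_nS=params.g_GABAA_max),
        ]
    )
    result = simulate(params, protocol, duration=duration)
    baseline = _snapshot(result, t_pulse_pre - 30.0)
    post = _snapshot(result, t_pulse_post - 30.0)
    peak_pre = _response_peak(result, t_pulse_pre)
    peak_post = _response_peak(result, t_pulse_post)
    report = ExperimentReport(
        baseline=baseline,
        post=post,
        response_peak_baseline_mV=peak_pre,
        response_peak_post_mV=peak_post,
        polarity_baseline="hyperpolarizing" if peak_pre < 0 else "depolarising",
        polarity_post="hyperpolarizing" if peak_post < 0 else "depolarising",
        manipulation={
            "symbol": ramp.symbol,
            "start": ramp.start,
            "end": ramp.end,
            "t_start_s": ramp.t_start,
            "t_end_s": ramp.t_end,
        },
    )
    return result, report


def kcc2_block_experiment(
    params: ModelParams | None = None,
    g_end: float = 0.0,
    t_pulse_pre: float = 40.0 * MIN,
    t_pulse_post: float = 70.0 * MIN,
    duration: float = 75.0 * MIN,
    return_result: bool = False,
):
    """Simulated KCC2 blockade: g_KCC2 ramped to ``g_end`` over min 41-50."""
    params = params or _default_params()
    ramp = ParameterRamp("g_KCC2", params.g_KCC2, g_end, 41.0 * MIN, 50.0 * MIN)
    result, report = _run_two_pulse(params, ramp, t_pulse_pre, t_pulse_post, duration)
    return (report, result) if return_result else report


def impermeant_anion_experiment(
    params: ModelParams | None = None,
    z_end: float = -1.05,
    t_pulse_pre: float = 40.0 * MIN,
    t_pulse_post: float = 70.0 * MIN,
    duration: float = 75.0 * MIN,
    return_result: bool = False,
):
    """Impermeant-anion addition emulated as a ramp of z_i (default -0.85 -> -1.05).

    The amount of X is fixed; only its average charge ramps, so total
    impermeant charge changes smoothly across the stated window.
    """
    params = params or _default_params()
    ramp = ParameterRamp("z_i", params.z_i, z_end, 41.0 * MIN, 50.0 * MIN)
    result, report = _run_two_pulse(params, ramp, t_pulse_pre, t_pulse_post, duration)
    return (report, result) if return_result else report


def df_timecourse(result: SimulationResult, probe_times) -> np.ndarray:
    """DF_GABAA (mV) sampled at ``probe_times`` by linear interpolation."""
    probe_times = np.asarray(probe_times, dtype=float)
    if probe_times.size and (
        probe_times.min() < result.t[0] or probe_times.max() > result.t[-1]
    ):
        raise ParameterError("probe time outside the simulated range")
    return np.interp(probe_times, result.t, result.df_gabaa)


def _default_params() -> ModelParams:
    from dfgaba.params import table1_defaults

    return table1_defaults()
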