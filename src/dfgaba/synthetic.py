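"""Ground-truth-labelled synthetic voltage-imaging recordings.

The generator emulates the statistical structure the analysis pipeline
assumes: a baseline fluorescence level with slow monoexponential
photobleaching, step-like voltage deflections during stimulation epochs
converted through the linear fluorescence-voltage gain (fluorescence
rises when voltage falls), Poisson shot noise at a stated photon budget,
background/neuropil contamination shared between ROI and background
traces, and optional seizure-like high-amplitude excursions.

``true_df_mV`` uses the measurement convention: it is the voltage
deflection during stimulation (Vm moves from rest to rest + true_df), so
negative values are hyperpolarizing anion influx.  In mechanistic mode
the voltage trace is produced by the biophysical model instead, with a
sustained anion conductance during each epoch pulling Vm toward the
model's own E_GABAA.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np

from dfgaba.params import ModelParams, ParameterError
from dfgaba.traces import Calibration, FluorescenceRecording


@dataclass
class SyntheticScenario:
    """Everything needed to render one synthetic recording.

    Defaults are the published acquisition conditions: five 2-s strobed
    stimulation epochs every 5 s at 25 Hz in a 25-s recording, a photon
    budget of 36585 photoelectrons per frame, ~5% bleaching over the
    recording, and a typical hyperpolarizing driving force of -6 mV.
    """

    true_df_mV: float = -6.0
    vm_rest_mV: float = -67.2
    n_epochs: int = 5
    epoch_duration_s: float = 2.0
    epoch_period_s: float = 5.0
    first_onset_s: float = 2.5
    duration_s: float = 25.0
    frame_rate_hz: float = 25.0
    tau_on_s: float = 0.05        # neuron preset; astrocytes respond ~10x slower
    tau_off_s: float = 0.05
    calibration: Calibration = field(default_factory=Calibration)
    photons_per_frame: float = 36585.37
    background_photons: float = 3658.5
    bleach_rate_per_s: float = -float(np.log(0.95)) / 25.0
    artefact_amplitude: float = 0.0   # shared additive contamination (photons)
    artefact_window: tuple[float, float] | None = None
    sle_amplitude_mV: float = 0.0     # optional seizure-like excursion
    sle_window: tuple[float, float] | None = None
    shot_noise: bool = True
    stimulus_kind: str = "optogenetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_per_frame <= 0:
            raise ParameterError("photon budget must be > 0")
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ParameterError("frame rate and duration must be > 0")
        last_end = (
            self.first_onset_s
            + (self.n_epochs - 1) * self.epoch_period_s
            + self.epoch_duration_s
        )
        if self.n_epochs > 0 and last_end > self.duration_s:
            raise ParameterError("stimulus schedule extends beyond the recording")

    @classmethod
    def astrocyte(cls, **kwargs: Any) -> "SyntheticScenario":
        """Preset with the slower astrocytic voltage response."""
        kwargs.setdefault("tau_on_s", 0.5)
        kwargs.setdefault("tau_off_s", 0.5)
        return cls(**kwargs)

    @property
    def frame_times(self) -> np.ndarray:
        n = int(round(self.duration_s * self.frame_rate_hz))
        return np.arange(n) / self.frame_rate_hz

    @property
    def stimulus_windows(self) -> list[tuple[float, float, str]]:
        return [
            (
                self.first_onset_s + k * self.epoch_period_s,
                self.first_onset_s + k * self.epoch_period_s + self.epoch_duration_s,
                self.stimulus_kind,
            )
            for k in range(self.n_epochs)
        ]


@dataclass
class GroundTruthManifest:
    """Generative parameters and per-epoch truths; for scoring only."""

    scenario: dict[str, Any]
    seed: int
    true_df_mV: float
    per_epoch_delta_v_mV: list[float]
    per_epoch_dff: list[float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthManifest":
        return cls(**json.loads(text))


def generate_vm_trace(
    scenario: SyntheticScenario,
    params: ModelParams | None = None,
) -> np.ndarray:
    """Membrane-potential trace (mV) at the scenario's frame times.

    Kinetic mode (default): during each stimulation epoch Vm relaxes
    exponentially from rest toward rest + true_df with time constant
    ``tau_on_s`` and decays back with ``tau_off_s`` afterwards.
    Mechanistic mode (``params`` given): the pump-leak model is driven by
    a sustained anion conductance during each epoch, so the plateau is
    set by the model's E_GABAA rather than by ``true_df_mV``.
    """
    t = scenario.frame_times
    if params is not None:
        return _mechanistic_vm(scenario, params, t)
    vm = _sequential_vm(scenario, t)
    if scenario.sle_window is not None and scenario.sle_amplitude_mV != 0.0:
        s0, s1 = scenario.sle_window
        vm[(t >= s0) & (t < s1)] += scenario.sle_amplitude_mV
    return vm


def _sequential_vm(scenario: SyntheticScenario, t: np.ndarray) -> np.ndarray:
    """Exact piecewise-exponential evaluation, robust to overlap/slow decay."""
    events = sorted((s, e) for s, e, _ in scenario.stimulus_windows)
    vm = np.full_like(t, scenario.vm_rest_mV)
    level = 0.0
    edges: list[tuple[float, bool]] = []
    for s, e in events:
        edges.append((s, True))
        edges.append((e, False))
    edges.sort()
    seg_start = t[0] if len(t) else 0.0
    active = False
    for edge_t, turning_on in edges + [(np.inf, False)]:
        mask = (t >= seg_start) & (t < edge_t)
        tau = scenario.tau_on_s if active else scenario.tau_off_s
        target = scenario.true_df_mV if active else 0.0
        dt = t[mask] - seg_start
        vm[mask] = scenario.vm_rest_mV + target + (level - target) * np.exp(
            -dt / max(tau, 1e-9)
        )
        if np.isfinite(edge_t):
            level = target + (level - target) * np.exp(
                -(edge_t - seg_start) / max(tau, 1e-9)
            )
            seg_start = edge_t
            active = turning_on
    return vm


def _mechanistic_vm(
    scenario: SyntheticScenario, params: ModelParams, t: np.ndarray
) -> np.ndarray:
    from dfgaba.model import simulate, steady_state
    from dfgaba.protocols import SquareConductance, StimulusProtocol

    state0 = steady_state(params)
    protocol = StimulusProtocol(
        events=[
            SquareConductance(t_on=s, t_off=e, g_nS=params.g_GABAA_max)
            for s, e, _ in scenario.stimulus_windows
        ]
    )
    result = simulate(
        params,
        protocol,
        duration=float(scenario.duration_s),
        initial_state=state0,
        dt_out=0.2,
        dt_fine=0.005,
    )
    return np.interp(t, result.t, result.Vm)


def vm_to_fluorescence(
    vm_trace: np.ndarray, scenario: SyntheticScenario
) -> np.ndarray:
    """Expected ROI photon count per frame for a voltage trace.

    F(t) = F0 * bleach(t) * (1 + slope/100 * (V_rest - Vm(t))) plus any
    shared additive artefact; the indicator brightens as Vm falls.
    """
    cal = scenario.calibration
    if cal.slope_percent_per_mV == 0:
        raise ParameterError("calibration slope must be non-zero")
    t = scenario.frame_times
    vm_trace = np.asarray(vm_trace, dtype=float)
    sign = 1.0 if cal.brighter_when_hyperpolarized else -1.0
    gain = 1.0 + sign * cal.slope_percent_per_mV / 100.0 * (
        scenario.vm_rest_mV - vm_trace
    )
    expected = scenario.photons_per_frame * np.exp(-scenario.bleach_rate_per_s * t) * gain
    expected = expected + _artefact(scenario, t)
    if np.any(expected <= 0):
        raise ParameterError("expected fluorescence must be strictly positive")
    return expected


def _artefact(scenario: SyntheticScenario, t: np.ndarray) -> np.ndarray:
    out = np.zeros_like(t)
    if scenario.artefact_amplitude != 0.0 and scenario.artefact_window is not None:
        a0, a1 = scenario.artefact_window
        out[(t >= a0) & (t < a1)] = scenario.artefact_amplitude
    return out


def add_shot_noise(expected_counts: np.ndarray, seed: int) -> np.ndarray:
    """Independent Poisson draw per frame; reproducible for a given seed."""
    expected_counts = np.asarray(expected_counts, dtype=float)
    if np.any(expected_counts < 0):
        raise ParameterError("expected counts must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.poisson(expected_counts).astype(float)


def render_recording(
    scenario: SyntheticScenario,
    params: ModelParams | None = None,
) -> tuple[FluorescenceRecording, GroundTruthManifest]:
    """Render one recording (ROI + background traces) with its manifest.

    Deterministic for a given scenario seed.  The background trace is the
    configured background level under the same bleaching, plus the shared
    artefact, with its own shot noise.
    """
    t = scenario.frame_times
    vm = generate_vm_trace(scenario, params=params)
    bg_floor = scenario.background_photons * np.exp(-scenario.bleach_rate_per_s * t)
    # the ROI sits on the background floor; the shared artefact (inside
    # vm_to_fluorescence) appears once in each trace so subtraction cancels it
    roi_expected = vm_to_fluorescence(vm, scenario) + bg_floor
    bg_expected = bg_floor + _artefact(scenario, t)
    if scenario.shot_noise:
        roi = add_shot_noise(roi_expected, scenario.seed)
        bg = add_shot_noise(bg_expected, scenario.seed + 1)
    else:
        roi, bg = roi_expected, bg_expected

    rec = FluorescenceRecording(
        times=t,
        roi=roi,
        background=bg,
        stimulus_windows=scenario.stimulus_windows,
        frame_rate_hz=scenario.frame_rate_hz,
        metadata={"synthetic": True, "seed": scenario.seed},
    )

    cal = scenario.calibration
    per_epoch_dv: list[float] = []
    per_epoch_dff: list[float] = []
    sign = 1.0 if cal.brighter_when_hyperpolarized else -1.0
    for start, end, _ in scenario.stimulus_windows:
        mask = (t >= start) & (t < end)
        dv = float((vm[mask] - scenario.vm_rest_mV).mean()) if mask.any() else 0.0
        per_epoch_dv.append(dv)
        per_epoch_dff.append(-sign * cal.slope_percent_per_mV / 100.0 * dv)

    scen_dict = asdict(scenario)
    scen_dict["calibration"] = asdict(scenario.calibration)
    manifest = GroundTruthManifest(
        scenario=scen_dict,
        seed=scenario.seed,
        true_df_mV=scenario.true_df_mV,
        per_epoch_delta_v_mV=per_epoch_dv,
        per_epoch_dff=per_epoch_dff,
    )
    return rec, manifest
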