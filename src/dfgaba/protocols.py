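"""Timed intervention protocols for the compartment model.

A protocol is an ordered list of events:

* :class:`GabaPulse` — an alpha-shaped synaptic GABA_A conductance;
* :class:`SquareConductance` — a sustained anion conductance (the optical
  anion-channel analogue: constant g, Cl-/HCO3- partitioned like GABA_A);
* :class:`ParameterRamp` — linear ramp of a named model parameter
  (e.g. ``g_KCC2`` or ``z_i``) between two times;
* :class:`ParameterSet` — an instantaneous parameter change.

Parameter ramps/sets act on ``ModelParams`` attribute names and are
evaluated lazily at each integrator step, so a ramp of the impermeant
anion charge ``z_i`` changes total impermeant charge continuously (the
amount of X is conserved; its average valence shifts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Union

from dfgaba.gaba import GabaStimulus, alpha_conductance
from dfgaba.params import ModelParams, ParameterError


@dataclass
class GabaPulse:
    """Synaptic GABA_A activation at ``t_onset`` (s)."""

    t_onset: float
    tau_ms: float = 250.0
    g_max_nS: float = 10.0

    @property
    def stimulus(self) -> GabaStimulus:
        return GabaStimulus(self.t_onset, self.tau_ms, self.g_max_nS)

    def conductance(self, t: float) -> float:
        return alpha_conductance(t, self.stimulus)

    # alpha tail is negligible ~8 tau after onset
    @property
    def t_end(self) -> float:
        return self.t_onset + 8.0 * self.tau_ms * 1e-3


@dataclass
class SquareConductance:
    """Constant anion conductance between ``t_on`` and ``t_off`` (s)."""

    t_on: float
    t_off: float
    g_nS: float = 10.0

    def __post_init__(self) -> None:
        if self.t_off <= self.t_on:
            raise ParameterError("SquareConductance requires t_on < t_off")
        if self.g_nS < 0:
            raise ParameterError("conductance must be >= 0")

    def conductance(self, t: float) -> float:
        return self.g_nS if self.t_on < t <= self.t_off else 0.0

    @property
    def t_onset(self) -> float:
        return self.t_on

    @property
    def t_end(self) -> float:
        return self.t_off


@dataclass
class ParameterRamp:
    """Linear ramp of ``symbol`` from ``start`` to ``end`` over [t_start, t_end]."""

    symbol: str
    start: float
    end: float
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ParameterError("ramp requires t_start < t_end")

    def value(self, t: float) -> float:
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        frac = min(max(frac, 0.0), 1.0)
        return self.start + (self.end - self.start) * frac


@dataclass
class ParameterSet:
    """Set ``symbol`` to ``value`` at time ``t`` (s)."""

    symbol: str
    value: float
    t: float


Event = Union[GabaPulse, SquareConductance, ParameterRamp, ParameterSet]

_EVENT_TYPES = {
    "gaba_pulse": GabaPulse,
    "square_conductance": SquareConductance,
    "parameter_ramp": ParameterRamp,
    "parameter_set": ParameterSet,
}


@dataclass
class StimulusProtocol:
    """Ordered collection of timed interventions."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for ev in self.events:
            if isinstance(ev, ParameterRamp) and ev.t_end <= ev.t_start:
                raise ParameterError("ramp requires t_start < t_end")

    # -- evaluation ---------------------------------------------------------
    def parameter_overrides(self, t: float, params: ModelParams) -> dict[str, float]:
        """Current values of every protocol-controlled parameter at time t."""
        out: dict[str, float] = {}
        for ev in self.events:
            if isinstance(ev, ParameterRamp) and t >= ev.t_start:
                out[ev.symbol] = ev.value(t)
            elif isinstance(ev, ParameterSet) and t >= ev.t:
                out[ev.symbol] = ev.value
        for sym in out:
            if not hasattr(params, sym):
                raise ParameterError(f"unknown model parameter {sym!r}")
        return out

    def gabaa_conductance(self, t: float) -> float:
        """Total chloride/bicarbonate-permeable conductance (nS) at time t.

        Overlapping events sum additively.
        """
        return sum(
            ev.conductance(t)
            for ev in self.events
            if isinstance(ev, (GabaPulse, SquareConductance))
        )

    def boundary_times(self) -> list[float]:
        """Times at which the right-hand side changes character."""
        times: set[float] = set()
        for ev in self.events:
            if isinstance(ev, (GabaPulse, SquareConductance)):
                times.update((ev.t_onset, ev.t_end))
            elif isinstance(ev, ParameterRamp):
                times.update((ev.t_start, ev.t_end))
            elif isinstance(ev, ParameterSet):
                times.add(ev.t)
        return sorted(times)

    def conductance_windows(self) -> list[tuple[float, float]]:
        return [
            (ev.t_onset, ev.t_end)
            for ev in self.events
            if isinstance(ev, (GabaPulse, SquareConductance))
        ]

    def last_event_time(self) -> float:
        times = self.boundary_times()
        return times[-1] if times else 0.0

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out = []
        for ev in self.events:
            kind = next(k for k, cls in _EVENT_TYPES.items() if isinstance(ev, cls))
            out.append({"kind": kind, **asdict(ev)})
        return {"events": out}

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StimulusProtocol":
        events: list[Event] = []
        for entry in d.get("events", []):
            entry = dict(entry)
            kind = entry.pop("kind")
            try:
                ev_cls = _EVENT_TYPES[kind]
            except KeyError:
                raise ParameterError(f"unknown protocol event kind {kind!r}") from None
            events.append(ev_cls(**entry))
        return cls(events=events)

    @classmethod
    def from_file(cls, path: str | Path) -> "StimulusProtocol":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))
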