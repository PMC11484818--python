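"""Parameter and state containers for the pump-leak compartment model.

Interface units follow electrophysiological convention (mM, mV, pL,
uS/cm^2, ms); internally everything is converted once to a coherent
SI-decimetre system (M, V, dm, dm^2, dm^3 = L, S/dm^2, s) so that flux
bookkeeping needs no scattered factors.  Conversion happens only through
the properties defined here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from pathlib import Path
from typing import Any

# unit conversions (interface -> internal)
UM_TO_DM = 1e-5
MM_TO_M = 1e-3          # millimolar -> molar
MV_TO_V = 1e-3
PL_TO_L = 1e-12
US_PER_CM2_TO_S_PER_DM2 = 1e-4   # 1 uS/cm^2 = 1e-6 S / 1e-2 dm^2
F_PER_CM2_TO_F_PER_DM2 = 1e2
NS_TO_S = 1e-9


class ParameterError(ValueError):
    """Raised when a parameter set violates its physical constraints."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants; defaults are the model's standard values."""

    F: float = 96485.33      # Faraday constant, C/mol
    R: float = 8.31446       # gas constant, J/(K mol)
    T: float = 310.15        # absolute temperature, K (37 C)

    def __post_init__(self) -> None:
        if self.F <= 0 or self.R <= 0 or self.T <= 0:
            raise ParameterError("physical constants must be strictly positive")

    @property
    def rtf(self) -> float:
        """R*T/F in volts (~26.7 mV at 37 C)."""
        return self.R * self.T / self.F


@dataclass
class ModelParams:
    """Every constant of the single-compartment model, in interface units.

    Defaults reproduce the published parameter table bit-for-bit (see the
    bundled ``data/table1_defaults.json``).  Geometry is a cylinder; only
    the lateral surface participates in transport.
    """

    radius_um: float = 5.0
    length_um: float = 25.0
    Cm: float = 2e-6                 # F/cm^2
    g_Na: float = 25.0               # uS/cm^2
    g_K: float = 70.0
    g_Cl: float = 20.0
    g_HCO3: float = 4.0
    g_KCC2: float = 20.0
    vw: float = 0.018                # dm^3/mol, partial molar volume of water
    pw: float = 0.0015               # dm/s, osmotic permeability
    P: float = 0.1                   # C/(dm^2 s), ATPase pump rate constant
    PCO2: float = 0.05               # atm
    kH: float = 0.031                # M/atm
    Kf: float = 1.0e3                # 1/s
    Kr: float = 2.539e9              # 1/(s M)
    g_GABAA_max: float = 10.0        # nS, whole-cell
    tau_ms: float = 250.0            # alpha-function time constant
    pKa: float = 6.1
    pH_o: float = 7.4
    pH_i: float = 7.2
    K_o: float = 3.5                 # mM
    Na_o: float = 145.0
    Cl_o: float = 110.0
    HCO3_o: float = 31.0
    H2CO3_o: float = 1.55
    H2CO3_i: float = 1.55
    X_o: float = 7.5
    z_o: float = -1.0
    z_i: float = -0.85
    constants: PhysicalConstants = field(default_factory=PhysicalConstants)
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("g_Na", "g_K", "g_Cl", "g_HCO3", "g_KCC2", "g_GABAA_max"):
            if getattr(self, name) < 0:
                raise ParameterError(f"conductance {name} must be >= 0")
        for name in ("K_o", "Na_o", "Cl_o", "HCO3_o", "H2CO3_o", "H2CO3_i", "X_o"):
            if getattr(self, name) < 0:
                raise ParameterError(f"concentration {name} must be >= 0")
        for name in ("kH", "PCO2", "Kf", "Kr", "tau_ms", "radius_um", "length_um", "Cm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("pH_o", "pH_i"):
            if not 0.0 < getattr(self, name) < 14.0:
                raise ParameterError(f"{name} must lie in (0, 14)")

    # -- geometry ----------------------------------------------------------
    @property
    def surface_area_dm2(self) -> float:
        """Lateral cylinder surface area, dm^2."""
        r = self.radius_um * UM_TO_DM
        length = self.length_um * UM_TO_DM
        sa = 2.0 * math.pi * r * length
        if sa <= 0:
            raise ParameterError("zero membrane surface area")
        return sa

    @property
    def volume_litre(self) -> float:
        """Geometric cylinder volume, dm^3 (litres)."""
        r = self.radius_um * UM_TO_DM
        return math.pi * r * r * self.length_um * UM_TO_DM

    @property
    def volume_pl(self) -> float:
        return self.volume_litre / PL_TO_L

    # -- internal-unit views ----------------------------------------------
    @property
    def cm_si(self) -> float:
        """Membrane capacitance, F/dm^2."""
        return self.Cm * F_PER_CM2_TO_F_PER_DM2

    def g_si(self, name: str) -> float:
        """Leak/transporter conductance ``g_<name>`` in S/dm^2."""
        return getattr(self, f"g_{name}") * US_PER_CM2_TO_S_PER_DM2

    @property
    def h_i(self) -> float:
        """Intracellular [H+] in M (pH clamped)."""
        return 10.0 ** (-self.pH_i)

    @property
    def h2co3_i_molar(self) -> float:
        return self.H2CO3_i * MM_TO_M

    @property
    def osmolarity_out_molar(self) -> float:
        """Total extracellular solute concentration (M), impermeants included."""
        return (self.Na_o + self.K_o + self.Cl_o + self.HCO3_o + self.X_o) * MM_TO_M

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["constants"] = asdict(self.constants)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        d = dict(d)
        const = d.pop("constants", {})
        if not isinstance(const, PhysicalConstants):
            const = PhysicalConstants(**const)
        return cls(constants=const, **d)

    def with_overrides(self, **kwargs: float) -> "ModelParams":
        return replace(self, **kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "ModelParams":
        """Load parameters from a JSON or YAML file.

        Accepts either the flat ``to_dict`` layout or the symbol-keyed
        layout of the bundled defaults file.
        """
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if "parameters" in raw:
            return _params_from_table(raw)
        return cls.from_dict(raw)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))


_TABLE_KEY_MAP = {
    "radius": "radius_um",
    "length": "length_um",
    "tau": "tau_ms",
}


def _params_from_table(raw: dict[str, Any]) -> ModelParams:
    const = {k: v["value"] for k, v in raw.get("constants", {}).items()}
    kwargs: dict[str, Any] = {}
    for key, entry in raw["parameters"].items():
        kwargs[_TABLE_KEY_MAP.get(key, key)] = entry["value"]
    params = ModelParams(constants=PhysicalConstants(**const), **kwargs)
    params.metadata["initial_state"] = {
        k: v["value"] for k, v in raw.get("initial_state", {}).items()
    }
    return params


def table1_defaults() -> ModelParams:
    """The published default parameter set, loaded from the bundled file."""
    with resources.files("dfgaba.data").joinpath("table1_defaults.json").open() as fh:
        return _params_from_table(json.load(fh))


@dataclass
class IonState:
    """Intracellular state of the compartment at one instant.

    Concentrations in mM, membrane potential in mV, volume in pL, time in
    seconds.  ``Vm`` is derived (charge-difference method) but carried so
    a state is self-describing.
    """

    Na_i: float
    K_i: float
    Cl_i: float
    HCO3_i: float
    X_i: float
    Vm: float
    w: float
    t: float = 0.0

    def __post_init__(self) -> None:
        for name in ("Na_i", "K_i", "Cl_i", "HCO3_i", "X_i"):
            if getattr(self, name) < 0:
                raise ParameterError(f"concentration {name} must be >= 0")
        if self.w <= 0:
            raise ParameterError("volume w must be > 0")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @property
    def osmolarity(self) -> float:
        """Total intracellular solute concentration, mM."""
        return self.Na_i + self.K_i + self.Cl_i + self.HCO3_i + self.X_i


@dataclass(frozen=True)
class ReversalPotentials:
    """Nernst/weighted reversal potentials in mV."""

    E_Cl: float
    E_HCO3: float
    E_K: float
    E_Na: float
    E_GABAA: float
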