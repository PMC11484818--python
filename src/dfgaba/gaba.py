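"""GABA_A conductance kinetics and the carbonate/pH subsystem.

The synaptic conductance is an alpha function.  GABA_A current is split
between Cl- and HCO3- by the fraction ``chi`` so that the combined
current reverses exactly at the 4:1 permeability-weighted reversal
potential E_GABAA.

Intracellular pH is clamped: every proton produced by CO2 hydration is
instantaneously exchanged for a sodium ion by the Na+/H+ exchanger
(electroneutral 1:1), so the carbonate reaction feeds both the HCO3- and
the Na+ balance but never moves net charge across the membrane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from dfgaba.params import ModelParams, ParameterError


class DegenerateGradientError(ValueError):
    """E_HCO3 equals E_Cl: the Cl-/HCO3- split is undefined."""


@dataclass
class GabaStimulus:
    """One synaptic GABA_A activation: an alpha-shaped conductance.

    tau in ms, g_max in nS, onset in seconds.
    """

    t_onset: float
    tau_ms: float = 250.0
    g_max_nS: float = 10.0

    def __post_init__(self) -> None:
        if self.tau_ms <= 0:
            raise ParameterError("alpha-function tau must be > 0")
        if self.g_max_nS < 0:
            raise ParameterError("g_max must be >= 0")


def alpha_conductance(t: float, stim: GabaStimulus) -> float:
    """GABA_A conductance (nS) at time ``t`` (s).

    g(t) = g_max * ((t-t0)/tau) * exp(-(t-t0-tau)/tau) for t > t0, else 0;
    the peak equals g_max at t0 + tau.
    """
    tau = stim.tau_ms * 1e-3
    dt = t - stim.t_onset
    if dt <= 0.0:
        return 0.0
    return stim.g_max_nS * (dt / tau) * math.exp(-(dt - tau) / tau)


def chi_fraction(E_HCO3: float, E_GABAA: float, E_Cl: float) -> float:
    """Fraction of the GABA_A current carried by Cl- (potentials in mV).

    chi = (E_HCO3 - E_GABAA) / (E_HCO3 - E_Cl).  Values outside [0, 1]
    indicate E_GABAA outside the interval spanned by the two ionic
    reversals; they are reported with a warning rather than clipped
    silently.
    """
    denom = E_HCO3 - E_Cl
    if denom == 0.0:
        raise DegenerateGradientError(
            "E_HCO3 == E_Cl: chi is undefined for identical gradients"
        )
    chi = (E_HCO3 - E_GABAA) / denom
    if not 0.0 <= chi <= 1.0:
        warnings.warn(
            f"chi = {chi:.4f} outside [0, 1]; E_GABAA lies outside "
            "the E_Cl..E_HCO3 interval",
            stacklevel=2,
        )
    return chi


def gabaa_currents(
    Vm: float, g_now_nS: float, chi: float, E_Cl: float, E_HCO3: float
) -> tuple[float, float]:
    """Cl- and HCO3- components of the GABA_A current.

    Inputs in mV and nS; returns (I_Cl, I_HCO3) in pA (nS * mV).  With chi
    taken from :func:`chi_fraction` the sum vanishes at Vm = E_GABAA.
    """
    if g_now_nS < 0:
        raise ParameterError("GABA_A conductance must be >= 0")
    i_cl = chi * g_now_nS * (Vm - E_Cl)
    i_hco3 = (1.0 - chi) * g_now_nS * (Vm - E_HCO3)
    return i_cl, i_hco3


def h2co3_concentration(PCO2_atm: float, kH_M_per_atm: float) -> float:
    """Dissolved H2CO3 (mM) from Henry's law: kH * PCO2."""
    if PCO2_atm < 0 or kH_M_per_atm < 0:
        raise ParameterError("PCO2 and kH must be >= 0")
    return kH_M_per_atm * PCO2_atm * 1e3


def equilibrium_hco3(h2co3_mM: float, pH: float, pKa: float = 6.1) -> float:
    """Henderson-Hasselbalch equilibrium [HCO3-] (mM): h2co3 * 10^(pH - pKa)."""
    if h2co3_mM < 0:
        raise ParameterError("H2CO3 concentration must be >= 0")
    return h2co3_mM * 10.0 ** (pH - pKa)


def carbonate_rates(hco3_i_mM: float, params: ModelParams) -> tuple[float, float]:
    """Net intracellular HCO3- production rate and matched H+ rate (mM/s).

    rate = Kf*[H2CO3]_i - Kr*[H+]_i*[HCO3-]_i, with [H2CO3]_i held at its
    Henry's-law value and [H+]_i fixed by the clamped pH.  H+ is produced
    mole-for-mole with HCO3-, so both returned rates are equal.
    """
    if hco3_i_mM < 0:
        raise ParameterError("HCO3 concentration must be >= 0")
    forward = params.Kf * params.h2co3_i_molar          # M/s
    reverse = params.Kr * params.h_i * hco3_i_mM * 1e-3
    net = (forward - reverse) * 1e3                     # mM/s
    return net, net


def nhe_sodium_flux(h_production_rate: float) -> float:
    """Na+ influx rate (mM/s) driven by Na+/H+ exchange.

    Each proton produced is exported in exchange for one sodium ion, so
    the adjustment equals the H+ production rate exactly.
    """
    return h_production_rate
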