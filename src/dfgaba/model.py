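"""Single-compartment pump-leak model of ion, voltage and volume dynamics.

The compartment exchanges Na+, K+, Cl- and HCO3- with an infinite bath
through ohmic leak channels, a 3:2 Na+/K+-ATPase whose rate scales with
the cubed sodium gradient, an electroneutral KCC2 cotransporter driven by
(E_K - E_Cl), and (when a protocol schedules them) GABA_A-type anion
conductances.  Impermeant anions X (average charge z_i) are trapped;
water follows the osmotic gradient.

Membrane potential is not integrated as its own ODE: it is computed from
the accumulated intracellular charge (charge-difference formulation),

    Vm = F * w * sum_i(z_i * c_i) / (Cm * SA),

so charge and concentration bookkeeping can never diverge.  The carbonate
buffer (fast, ~160 1/s at defaults) makes the system stiff; the default
integrator is adaptive-step implicit (LSODA), with a fixed-step explicit
RK4 in :func:`step` as an independent reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from dfgaba.gaba import carbonate_rates, chi_fraction, nhe_sodium_flux
from dfgaba.params import (
    MM_TO_M,
    MV_TO_V,
    NS_TO_S,
    PL_TO_L,
    IonState,
    ModelParams,
    ParameterError,
    ReversalPotentials,
)
from dfgaba.protocols import StimulusProtocol


class IntegrationError(RuntimeError):
    """The integrator produced an invalid state (e.g. negative concentration)."""


class SteadyStateError(RuntimeError):
    """Steady-state search failed to converge within its budget."""


# ---------------------------------------------------------------------------
# elementary electrochemistry
# ---------------------------------------------------------------------------

def nernst_potential(c_in: float, c_out: float, valence: int, const=None) -> float:
    """Nernst reversal potential in mV for concentrations in mM.

    E = (R*T)/(valence*F) * ln(c_out/c_in); for a monovalent anion this is
    (RT/F)*ln(c_in/c_out).
    """
    from dfgaba.params import PhysicalConstants

    const = const or PhysicalConstants()
    if valence == 0:
        raise ParameterError("valence must be non-zero")
    if c_in <= 0 or c_out <= 0:
        side = "intracellular" if c_in <= 0 else "extracellular"
        raise ParameterError(
            f"non-positive {side} concentration ({c_in if c_in <= 0 else c_out} mM) "
            "in Nernst potential"
        )
    return const.rtf / valence * math.log(c_out / c_in) / MV_TO_V


def gabaa_reversal(
    Cl_i: float, Cl_o: float, HCO3_i: float, HCO3_o: float, const=None
) -> float:
    """Permeability-weighted GABA_A reversal potential (mV).

    The receptor passes Cl- and HCO3- with 4:1 permeability, so

        E_GABAA = (RT/F) * ln((0.8*Cl_i + 0.2*HCO3_i) / (0.8*Cl_o + 0.2*HCO3_o)).
    """
    from dfgaba.params import PhysicalConstants

    const = const or PhysicalConstants()
    for name, c in (("Cl_i", Cl_i), ("Cl_o", Cl_o), ("HCO3_i", HCO3_i), ("HCO3_o", HCO3_o)):
        if c <= 0:
            raise ParameterError(f"non-positive concentration {name} = {c} mM")
    num = 0.8 * Cl_i + 0.2 * HCO3_i
    den = 0.8 * Cl_o + 0.2 * HCO3_o
    return const.rtf * math.log(num / den) / MV_TO_V


def reversal_potentials(state: IonState, params: ModelParams) -> ReversalPotentials:
    const = params.constants
    return ReversalPotentials(
        E_Cl=nernst_potential(state.Cl_i, params.Cl_o, -1, const),
        E_HCO3=nernst_potential(state.HCO3_i, params.HCO3_o, -1, const),
        E_K=nernst_potential(state.K_i, params.K_o, +1, const),
        E_Na=nernst_potential(state.Na_i, params.Na_o, +1, const),
        E_GABAA=gabaa_reversal(state.Cl_i, params.Cl_o, state.HCO3_i, params.HCO3_o, const),
    )


def membrane_voltage(state: IonState, params: ModelParams, z_i: float | None = None) -> float:
    """Membrane potential (mV) from the intracellular charge imbalance."""
    z = params.z_i if z_i is None else z_i
    charge_molar = (
        state.Na_i + state.K_i - state.Cl_i - state.HCO3_i + z * state.X_i
    ) * MM_TO_M
    sa = params.surface_area_dm2
    w = state.w * PL_TO_L
    return params.constants.F * w * charge_molar / (params.cm_si * sa) / MV_TO_V


# ---------------------------------------------------------------------------
# fluxes and derivatives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FluxReport:
    """Per-species transmembrane molar fluxes (mol/s, influx positive)."""

    Na: float
    K: float
    Cl: float
    HCO3: float
    X: float
    pump_current_density: float    # Jp, C/(dm^2 s)
    kcc2_current_density: float    # g_KCC2*(E_K - E_Cl), C/(dm^2 s)
    total_current: float           # net outward membrane current, A


def transmembrane_fluxes(
    state: IonState,
    params: ModelParams,
    g_gabaa_now_nS: float = 0.0,
    chi_now: float | None = None,
) -> FluxReport:
    """Molar flux of each species across the membrane (influx positive).

    Components: ohmic leaks, the 3:2 ATPase with Jp = P*(Na_i/Na_o)^3,
    KCC2 moving K+ and Cl- together down (E_K - E_Cl), and the
    chi-partitioned GABA_A anion conductance.  Impermeant X never moves.
    The carbonate reaction and Na+/H+ exchange are bulk processes handled
    in the full derivative, not here.
    """
    if g_gabaa_now_nS < 0:
        raise ParameterError("GABA_A conductance must be >= 0")
    const = params.constants
    F = const.F
    sa = params.surface_area_dm2
    rev = reversal_potentials(state, params)
    vm = state.Vm * MV_TO_V
    e_na, e_k = rev.E_Na * MV_TO_V, rev.E_K * MV_TO_V
    e_cl, e_hco3 = rev.E_Cl * MV_TO_V, rev.E_HCO3 * MV_TO_V

    jp = params.P * (state.Na_i / params.Na_o) ** 3
    jkcc2 = params.g_si("KCC2") * (e_k - e_cl)

    i_na = params.g_si("Na") * (vm - e_na) + 3.0 * jp          # C/(dm^2 s), outward +
    i_k = params.g_si("K") * (vm - e_k) - 2.0 * jp - jkcc2
    i_cl = params.g_si("Cl") * (vm - e_cl) + jkcc2
    i_hco3 = params.g_si("HCO3") * (vm - e_hco3)

    g_gaba = g_gabaa_now_nS * NS_TO_S                          # whole-cell, S
    i_gaba_cl = i_gaba_hco3 = 0.0
    if g_gaba > 0.0:
        if chi_now is None:
            chi_now = chi_fraction(rev.E_HCO3, rev.E_GABAA, rev.E_Cl)
        if not 0.0 <= chi_now <= 1.0:
            raise ParameterError("chi must lie in [0, 1]")
        i_gaba_cl = chi_now * g_gaba * (vm - e_cl)             # A, outward +
        i_gaba_hco3 = (1.0 - chi_now) * g_gaba * (vm - e_hco3)

    # cations: outward current removes ions; anions: outward current adds them
    flux_na = -i_na * sa / F
    flux_k = -i_k * sa / F
    flux_cl = (i_cl * sa + i_gaba_cl) / F
    flux_hco3 = (i_hco3 * sa + i_gaba_hco3) / F
    total_current = (i_na + i_k + i_cl + i_hco3) * sa + i_gaba_cl + i_gaba_hco3
    return FluxReport(
        Na=flux_na,
        K=flux_k,
        Cl=flux_cl,
        HCO3=flux_hco3,
        X=0.0,
        pump_current_density=jp,
        kcc2_current_density=jkcc2,
        total_current=total_current,
    )


def volume_derivative(state: IonState, params: ModelParams) -> float:
    """Osmotic volume change dw/dt in pL/s.

    dw/dt = pw * vw * SA * (Pi_i - Pi_o) with Pi the total solute
    concentrations (impermeants included) on each side.
    """
    pi_i = state.osmolarity * MM_TO_M
    dw = params.pw * params.vw * params.surface_area_dm2 * (pi_i - params.osmolarity_out_molar)
    return dw / PL_TO_L


# internal packed vector: amounts of Na, K, Cl, HCO3 (mol) and volume (L);
# the amount of X is conserved and carried separately.
def _pack(state: IonState) -> tuple[np.ndarray, float]:
    w = state.w * PL_TO_L
    y = np.array(
        [
            state.Na_i * MM_TO_M * w,
            state.K_i * MM_TO_M * w,
            state.Cl_i * MM_TO_M * w,
            state.HCO3_i * MM_TO_M * w,
            w,
        ]
    )
    return y, state.X_i * MM_TO_M * w


def _unpack(y: np.ndarray, n_x: float, params: ModelParams, t: float, z_i: float) -> IonState:
    n_na, n_k, n_cl, n_hco3, w = y
    conc = np.array([n_na, n_k, n_cl, n_hco3, n_x]) / w / MM_TO_M
    state = IonState(
        Na_i=conc[0], K_i=conc[1], Cl_i=conc[2], HCO3_i=conc[3], X_i=conc[4],
        Vm=0.0, w=w / PL_TO_L, t=t,
    )
    state.Vm = membrane_voltage(state, params, z_i=z_i)
    return state


def _derivatives(
    t: float,
    y: np.ndarray,
    n_x: float,
    params: ModelParams,
    protocol: StimulusProtocol | None,
) -> np.ndarray:
    if np.any(y[:4] < 0.0) or y[4] <= 0.0:
        raise IntegrationError(
            "negative amount or volume during integration; reduce the step size"
        )
    overrides: dict[str, float] = {}
    g_gaba = 0.0
    if protocol is not None:
        overrides = protocol.parameter_overrides(t, params)
        g_gaba = protocol.gabaa_conductance(t)
    p = params.with_overrides(**overrides) if overrides else params
    z_i = p.z_i
    state = _unpack(y, n_x, p, t, z_i)
    flux = transmembrane_fluxes(state, p, g_gabaa_now_nS=g_gaba)
    # carbonate production and its electroneutral Na+/H+ counterflux (mol/s)
    hco3_rate, h_rate = carbonate_rates(state.HCO3_i, p)
    w = y[4]
    reaction = hco3_rate * MM_TO_M * w
    na_nhe = nhe_sodium_flux(h_rate) * MM_TO_M * w
    dw = volume_derivative(state, p) * PL_TO_L
    return np.array(
        [
            flux.Na + na_nhe,
            flux.K,
            flux.Cl,
            flux.HCO3 + reaction,
            dw,
        ]
    )


# ---------------------------------------------------------------------------
# integrators
# ---------------------------------------------------------------------------

def step(
    state: IonState,
    params: ModelParams,
    dt: float,
    protocol: StimulusProtocol | None = None,
) -> IonState:
    """Advance one fixed explicit RK4 step of length ``dt`` seconds.

    Reference integrator: slow but scheme-independent of the adaptive
    implicit default.  The carbonate kinetics bound stability at roughly
    dt < 2.8/(Kr*[H+]_i) (~17 ms at default parameters).
    """
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    y, n_x = _pack(state)
    t = state.t
    f = lambda tt, yy: _derivatives(tt, yy, n_x, params, protocol)
    k1 = f(t, y)
    k2 = f(t + dt / 2, y + dt / 2 * k1)
    k3 = f(t + dt / 2, y + dt / 2 * k2)
    k4 = f(t + dt, y + dt * k3)
    y_new = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if np.any(y_new[:4] < 0.0) or y_new[4] <= 0.0:
        raise IntegrationError("negative concentration after step; reduce dt")
    z_i = params.z_i
    if protocol is not None:
        z_i = protocol.parameter_overrides(t + dt, params).get("z_i", z_i)
    return _unpack(y_new, n_x, params, t + dt, z_i)


@dataclass
class SimulationResult:
    """Trajectory of a compartment-model simulation.

    All per-step arrays share the time grid.  ``df_gabaa`` is
    Vm - E_GABAA in mV (positive when anion influx hyperpolarizes).
    """

    t: np.ndarray
    Na_i: np.ndarray
    K_i: np.ndarray
    Cl_i: np.ndarray
    HCO3_i: np.ndarray
    X_i: np.ndarray
    w: np.ndarray
    Vm: np.ndarray
    E_Cl: np.ndarray
    E_HCO3: np.ndarray
    E_K: np.ndarray
    E_Na: np.ndarray
    E_GABAA: np.ndarray
    df_gabaa: np.ndarray
    event_log: list[dict[str, Any]] = field(default_factory=list)
    params: ModelParams | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("time grid must be strictly increasing")
        n = len(self.t)
        for name in ("Na_i", "K_i", "Cl_i", "HCO3_i", "X_i", "w", "Vm", "df_gabaa"):
            if len(getattr(self, name)) != n:
                raise ParameterError(f"trajectory field {name} has inconsistent length")

    def state_at(self, index: int) -> IonState:
        return IonState(
            Na_i=float(self.Na_i[index]),
            K_i=float(self.K_i[index]),
            Cl_i=float(self.Cl_i[index]),
            HCO3_i=float(self.HCO3_i[index]),
            X_i=float(self.X_i[index]),
            Vm=float(self.Vm[index]),
            w=float(self.w[index]),
            t=float(self.t[index]),
        )

    def final_state(self) -> IonState:
        return self.state_at(len(self.t) - 1)

    def to_frame(self):
        """Tidy table, one row per time point."""
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "Na_i_mM": self.Na_i,
                "K_i_mM": self.K_i,
                "Cl_i_mM": self.Cl_i,
                "HCO3_i_mM": self.HCO3_i,
                "X_i_mM": self.X_i,
                "w_pL": self.w,
                "Vm_mV": self.Vm,
                "E_Cl_mV": self.E_Cl,
                "E_HCO3_mV": self.E_HCO3,
                "E_K_mV": self.E_K,
                "E_Na_mV": self.E_Na,
                "E_GABAA_mV": self.E_GABAA,
                "DF_GABAA_mV": self.df_gabaa,
            }
        )


def balanced_initial_state(
    params: ModelParams, vm_target_mV: float = -67.2, w_pL: float | None = None
) -> IonState:
    """Initial state from the published defaults, charge-consistent.

    The printed concentrations are rounded to 0.1 mM while the
    charge-difference Vm is sensitive to ~0.005 mM of net charge, so the
    raw column is electrically meaningless.  Startup therefore adjusts the
    most abundant cation (K+) by a fraction of the rounding error so the
    initial Vm equals the printed value exactly.
    """
    init = params.metadata.get("initial_state", {})
    na = init.get("Na_i", 15.0)
    k = init.get("K_i", 122.6)
    cl = init.get("Cl_i", 5.3)
    hco3 = init.get("HCO3_i", 9.7)
    x = init.get("X_i", 144.4)
    w = w_pL if w_pL is not None else params.volume_pl
    # net charge (mM-equivalents) required for the target Vm
    target = (
        vm_target_mV
        * MV_TO_V
        * params.cm_si
        * params.surface_area_dm2
        / (params.constants.F * w * PL_TO_L)
        / MM_TO_M
    )
    k_adj = target - (na - cl - hco3 + params.z_i * x)
    return IonState(Na_i=na, K_i=k_adj, Cl_i=cl, HCO3_i=hco3, X_i=x,
                    Vm=vm_target_mV, w=w, t=0.0)


def simulate(
    params: ModelParams,
    protocol: StimulusProtocol | None = None,
    duration: float = 3600.0,
    initial_state: IonState | None = None,
    dt_out: float = 1.0,
    dt_fine: float = 0.02,
    rtol: float = 1e-10,
    atol: float = 1e-18,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model for ``duration`` seconds under a protocol.

    The integration is split at protocol boundary times; output is sampled
    on a coarse grid everywhere and a fine grid around conductance events
    so brief synaptic responses are resolved.  Deterministic: identical
    inputs give identical trajectories.
    """
    protocol = protocol or StimulusProtocol()
    if protocol.events and protocol.last_event_time() > duration:
        raise ParameterError("protocol events extend beyond the simulation duration")
    state0 = initial_state or balanced_initial_state(params)
    y0, n_x = _pack(state0)

    # output grid: coarse everywhere, fine around conductance windows
    grid = np.arange(0.0, duration + dt_out / 2, dt_out)
    fine_blocks = [
        np.arange(max(0.0, on - 1.0), min(duration, off + 2.0), dt_fine)
        for on, off in protocol.conductance_windows()
    ]
    t_eval = np.unique(np.concatenate([grid, *fine_blocks])) if fine_blocks else grid
    t_eval = t_eval[(t_eval >= 0.0) & (t_eval <= duration)]

    boundaries = [b for b in protocol.boundary_times() if 0.0 < b < duration]
    seg_edges = [0.0, *boundaries, duration]

    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = y0.copy()
    for a, b in zip(seg_edges[:-1], seg_edges[1:]):
        if b - a <= 0:
            continue
        pts = t_eval[(t_eval >= a) & (t_eval <= b)]
        if len(pts) == 0 or pts[0] > a:
            pts = np.concatenate([[a], pts])
        if pts[-1] < b:
            pts = np.concatenate([pts, [b]])
        sol = solve_ivp(
            _derivatives,
            (a, b),
            y,
            method=method,
            t_eval=pts,
            rtol=rtol,
            atol=atol,
            args=(n_x, params, protocol),
        )
        if not sol.success:
            raise IntegrationError(f"integration failed in [{a}, {b}]: {sol.message}")
        y = sol.y[:, -1]
        ts.append(sol.t)
        ys.append(sol.y)

    t = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, y_all = t[keep], y_all[:, keep]

    w = y_all[4]
    conc = y_all[:4] / w / MM_TO_M
    x_i = n_x / w / MM_TO_M
    z = np.array([
        protocol.parameter_overrides(tt, params).get("z_i", params.z_i) for tt in t
    ])
    charge = (conc[0] + conc[1] - conc[2] - conc[3] + z * x_i) * MM_TO_M
    vm = (
        params.constants.F * w * charge / (params.cm_si * params.surface_area_dm2)
    ) / MV_TO_V

    rtf_mv = params.constants.rtf / MV_TO_V
    e_cl = rtf_mv * np.log(conc[2] / params.Cl_o)
    e_hco3 = rtf_mv * np.log(conc[3] / params.HCO3_o)
    e_k = rtf_mv * np.log(params.K_o / conc[1])
    e_na = rtf_mv * np.log(params.Na_o / conc[0])
    e_gaba = rtf_mv * np.log(
        (0.8 * conc[2] + 0.2 * conc[3]) / (0.8 * params.Cl_o + 0.2 * params.HCO3_o)
    )

    log = [{"t": float(bt), "event": "protocol boundary"} for bt in protocol.boundary_times()]
    return SimulationResult(
        t=t,
        Na_i=conc[0], K_i=conc[1], Cl_i=conc[2], HCO3_i=conc[3],
        X_i=x_i, w=w / PL_TO_L, Vm=vm,
        E_Cl=e_cl, E_HCO3=e_hco3, E_K=e_k, E_Na=e_na, E_GABAA=e_gaba,
        df_gabaa=vm - e_gaba,
        event_log=log,
        params=params,
    )


def steady_state(
    params: ModelParams,
    initial_state: IonState | None = None,
    t_relax: float = 7200.0,
    tol: float = 1e-8,
) -> IonState:
    """Resting state of the model: all derivatives vanish.

    Long implicit integration from the (charge-balanced) published initial
    state, followed by a damped Newton refinement on the packed amounts.
    Raises :class:`SteadyStateError` with the residuals if neither
    converges.
    """
    state0 = initial_state or balanced_initial_state(params)
    y0, n_x = _pack(state0)
    sol = solve_ivp(
        _derivatives, (0.0, t_relax), y0, method="LSODA",
        rtol=1e-11, atol=1e-19, args=(n_x, params, None),
    )
    if not sol.success:
        raise SteadyStateError(f"relaxation failed: {sol.message}")
    y = sol.y[:, -1]

    scale = np.abs(y)
    res = root(lambda u: _derivatives(0.0, u * scale, n_x, params, None) / scale,
               y / scale, method="hybr", tol=1e-12)
    if res.success and np.all(res.x * scale > 0):
        y = res.x * scale
    resid = _derivatives(0.0, y, n_x, params, None)
    # fractional change per second of each amount; << 1/t_relax means converged
    rel = np.max(np.abs(resid) / np.maximum(np.abs(y), 1e-30))
    if rel > tol:
        raise SteadyStateError(
            f"no steady state within budget; max relative residual {rel:.3e}/s "
            f"(residuals {resid})"
        )
    return _unpack(y, n_x, params, 0.0, params.z_i)
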