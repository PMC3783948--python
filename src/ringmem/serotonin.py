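"""Serotonin receptor gating and the downstream currents it modulates.

Tonic 5-HT acts through two receptor types.  5-HT1A receptors on pyramidal
cells gate a hyperpolarizing potassium current I_K1A.  5-HT2A receptors are
depolarizing: on pyramidal cells they suppress the calcium-dependent
afterhyperpolarization current I_KCa, drive a slow calcium influx, and
thereby recruit the calcium-activated non-selective cation current I_Can; on
interneurons they shrink the leak conductance.

Receptor gates follow first-order kinetics driven by the 5-HT concentration:

    ds1A/dt = -s1A/tau1A + alpha1A * [5-HT]
    ds2A/dt = -s2A/tau2A + alpha2A * [5-HT] * (1 - s2A)

Agonist/antagonist manipulations are represented by per-receptor multipliers
on the concentration *inside that receptor's kinetic equation only*, leaving
the other receptor at its physiological activation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import NM_TO_UM


@dataclass(frozen=True)
class SerotoninSpec:
    """Receptor kinetics, downstream current parameters and the tonic level.

    Rates ``alpha_*`` are in kHz/uM (equivalently 1/(ms*uM)); the baseline
    concentration is quoted in nM and converted once, internally, to uM.
    ``gamma_5ht`` (calcium flux through 5-HT2A receptors) is quoted in nM/ms
    and likewise converted to uM/ms where used.
    """

    tau_1A: float = 30.0  # ms
    tau_2A: float = 120.0  # ms
    alpha_1A: float = 1.8  # kHz/uM
    alpha_2A_E: float = 2.25  # kHz/uM, pyramidal 5-HT2A affinity
    alpha_2A_I: float = 11.0  # kHz/uM, interneuron 5-HT2A affinity
    baseline_5ht_nM: float = 10.0  # nM, physiological tonic level
    g_K1A: float = 29.7  # nS
    V_K: float = -70.0  # mV
    gamma_5ht: float = 0.41  # nM/ms
    alpha_Ca: float = 0.1  # uM influx per spike
    tau_Ca: float = 240.0  # ms
    g_KCa: float = 703.0  # nS
    K_D: float = 30.0  # uM, I_KCa half-saturation
    g_Can: float = 36.0  # nS
    V_Can: float = -20.0  # mV
    alpha_Can: float = 0.0056  # 1/(ms*uM)
    beta_Can: float = 0.002  # 1/ms
    alpha_h: float = 3.0  # uM, h_Ca slope
    beta_h: float = 5.0  # uM, h_Ca midpoint
    concentration_scale_1A: float = 1.0
    concentration_scale_2A: float = 1.0

    def __post_init__(self):
        if self.concentration_scale_1A <= 0 or self.concentration_scale_2A <= 0:
            raise ValueError("receptor concentration scales must be positive")
        for name in ("tau_1A", "tau_2A", "alpha_1A", "alpha_2A_E", "alpha_2A_I",
                     "baseline_5ht_nM", "g_K1A", "gamma_5ht", "alpha_Ca", "tau_Ca",
                     "g_KCa", "K_D", "g_Can", "alpha_Can", "beta_Can", "alpha_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    # -- effective concentrations (uM) seen by each receptor equation --

    @property
    def baseline_uM(self) -> float:
        return self.baseline_5ht_nM * NM_TO_UM

    @property
    def conc_1A(self) -> float:
        return self.baseline_uM * self.concentration_scale_1A

    @property
    def conc_2A(self) -> float:
        return self.baseline_uM * self.concentration_scale_2A

    # -- analytic steady states of the gating equations --

    def s1A_steady(self, conc: float | None = None) -> float:
        c = self.conc_1A if conc is None else conc
        return self.tau_1A * self.alpha_1A * c

    def s2A_steady(self, alpha_2A: float, conc: float | None = None) -> float:
        c = self.conc_2A if conc is None else conc
        a = alpha_2A * c
        return a / (1.0 / self.tau_2A + a)

    def s2A_steady_E(self, conc: float | None = None) -> float:
        return self.s2A_steady(self.alpha_2A_E, conc)

    def s2A_steady_I(self, conc: float | None = None) -> float:
        return self.s2A_steady(self.alpha_2A_I, conc)

    def Ca_steady(self, s2A_E: float | None = None) -> float:
        """Fixed point of the calcium equation in the absence of spiking (uM)."""
        s = self.s2A_steady_E() if s2A_E is None else s2A_E
        return self.tau_Ca * self.gamma_5ht * NM_TO_UM * s


@dataclass
class ReceptorState:
    """Receptor gates for one neuron (or an array of neurons).

    Calcium and the I_Can activation gate exist only on pyramidal cells;
    interneuron instances carry ``s_2A`` alone.  ``h_Ca`` is an instantaneous
    function of calcium and is not stored.
    """

    s_1A: float | np.ndarray = 0.0
    s_2A: float | np.ndarray = 0.0
    Ca: float | np.ndarray = 0.0
    m_Ca: float | np.ndarray = 0.0


def step_receptor_gates(state: ReceptorState, spec: SerotoninSpec, dt: float,
                        alpha_2A: float | None = None) -> ReceptorState:
    """Advance s_1A and s_2A one RK2 step under the configured tonic level.

    The concentration entering each gate equation is baseline times that
    receptor's manipulation scale.  The saturating form of the s_2A kinetics
    keeps the gate in [0, 1] for any non-negative concentration.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    c1, c2 = spec.conc_1A, spec.conc_2A
    if c1 < 0 or c2 < 0:
        raise ValueError("concentration must be non-negative")
    a2 = spec.alpha_2A_E if alpha_2A is None else alpha_2A

    def f1(s):
        return -s / spec.tau_1A + spec.alpha_1A * c1

    def f2(s):
        return -s / spec.tau_2A + a2 * c2 * (1.0 - s)

    k1 = f1(state.s_1A)
    s1 = state.s_1A + 0.5 * dt * (k1 + f1(state.s_1A + dt * k1))
    k1 = f2(state.s_2A)
    s2 = state.s_2A + 0.5 * dt * (k1 + f2(state.s_2A + dt * k1))
    return ReceptorState(s_1A=s1, s_2A=s2, Ca=state.Ca, m_Ca=state.m_Ca)


def current_K1A(spec: SerotoninSpec, s_1A, V):
    """5-HT1A-gated potassium current (nA), outward-positive.

    I_K1A = g_K1A * s_1A * (V - V_K); pyramidal cells only.
    """
    from .units import NS_MV_TO_NA
    return spec.g_K1A * np.asarray(s_1A) * (np.asarray(V) - spec.V_K) * NS_MV_TO_NA


def step_calcium(Ca, spec: SerotoninSpec, s_2A, dt: float, spike_now=False):
    """Advance intracellular calcium one step (uM).

    Between spikes calcium follows the linear ODE
    dCa/dt = -Ca/tau_Ca + gamma * s_2A, advanced with the exact exponential
    update; a spike adds alpha_Ca = 0.1 uM instantaneously afterwards.
    """
    Ca = np.asarray(Ca, dtype=float)
    if np.any(Ca < 0):
        raise ValueError("calcium concentration must be non-negative")
    target = spec.tau_Ca * spec.gamma_5ht * NM_TO_UM * np.asarray(s_2A)
    decay = math.exp(-dt / spec.tau_Ca)
    out = target + (Ca - target) * decay
    return out + spec.alpha_Ca * np.asarray(spike_now, dtype=float)


def h_Ca(spec: SerotoninSpec, Ca):
    """Instantaneous inactivation factor of I_Can."""
    return 1.0 / (1.0 + np.exp((np.asarray(Ca) - spec.beta_h) / spec.alpha_h))


def m_inf(spec: SerotoninSpec, Ca):
    a = spec.alpha_Can * np.asarray(Ca)
    return a / (a + spec.beta_Can)


def tau_Can(spec: SerotoninSpec, Ca):
    return 1.0 / (spec.alpha_Can * np.asarray(Ca) + spec.beta_Can)


def step_m_Ca(m, spec: SerotoninSpec, Ca, dt: float):
    """Relax the I_Can activation gate toward m_inf(Ca) over one step."""
    tau = tau_Can(spec, Ca)
    return m_inf(spec, Ca) + (np.asarray(m) - m_inf(spec, Ca)) * np.exp(-dt / tau)


def current_KCa(spec: SerotoninSpec, Ca, s_2A, V):
    """Calcium-dependent potassium (AHP) current (nA), suppressed by 5-HT2A.

    I_KCa = g_KCa * (1 - s_2A) * Ca/(Ca + K_D) * (V - V_K).
    """
    from .units import NS_MV_TO_NA
    Ca = np.asarray(Ca)
    sat = Ca / (Ca + spec.K_D)
    return spec.g_KCa * (1.0 - np.asarray(s_2A)) * sat * (np.asarray(V) - spec.V_K) * NS_MV_TO_NA


def current_Can(spec: SerotoninSpec, Ca, m_Ca, V):
    """Calcium-activated non-selective cation current (nA).

    I_Can = g_Can * m_Ca**2 * h_Ca(Ca) * (V - V_Can); depolarizing at rest.
    """
    from .units import NS_MV_TO_NA
    return (spec.g_Can * np.asarray(m_Ca) ** 2 * h_Ca(spec, Ca)
            * (np.asarray(V) - spec.V_Can) * NS_MV_TO_NA)


def interneuron_leak(g_L_star: float, s_2A):
    """Effective interneuron leak conductance g_L* (1 - s_2A), in nS."""
    return g_L_star * (1.0 - np.asarray(s_2A))


def steady_state(spec: SerotoninSpec) -> dict:
    """All tonic-condition fixed points used to initialize simulations."""
    s2A_E = spec.s2A_steady_E()
    Ca = spec.Ca_steady(s2A_E)
    return {
        "s1A": spec.s1A_steady(),
        "s2A_E": s2A_E,
        "s2A_I": spec.s2A_steady_I(),
        "Ca": Ca,
        "m_Ca": float(m_inf(spec, Ca)),
    }
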