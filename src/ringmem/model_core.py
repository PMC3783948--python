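"""Network architecture: populations, intrinsic parameters, synapses and the
tuned ring connectivity.

The circuit is a ring of leaky integrate-and-fire neurons — excitatory
pyramidal cells and inhibitory interneurons in a 4:1 ratio — each labelled by
a preferred angle.  Connection strength between two cells depends only on the
(circular) difference of their preferred angles through a kernel

    W(dtheta) = J_minus + (J_plus - J_minus) * exp(-dtheta**2 / (2 sigma**2))

where ``J_plus`` and ``sigma`` are given per projection class (EE, EI, IE,
II) and ``J_minus`` is fixed by the normalization condition that the mean of
``W`` over the presynaptic ring equals 1, so that total recurrent drive per
neuron is independent of the kernel shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

PROJECTION_CLASSES = ("EE", "EI", "IE", "II")

#: Receptor classes carried by each projection (excitatory projections carry
#: both AMPA and NMDA; inhibitory projections are GABA_A only).
PROJECTION_RECEPTORS = {
    "EE": ("AMPA", "NMDA"),
    "EI": ("AMPA", "NMDA"),
    "IE": ("GABA",),
    "II": ("GABA",),
}


def wrap_angle(delta):
    """Wrap angle differences (degrees) to the interval [-180, 180)."""
    return (np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0


def preferred_angles(n: int) -> np.ndarray:
    """Preferred angles of ``n`` neurons uniformly spaced on the ring.

    A half-offset grid is used, ``theta_i = -180 + (i + 0.5) * 360 / n``, so
    that no neuron sits exactly at the +-180 deg seam and excitatory and
    inhibitory grids interleave symmetrically.
    """
    if n <= 0:
        raise ValueError("population size must be positive")
    return -180.0 + (np.arange(n) + 0.5) * 360.0 / n


@dataclass(frozen=True)
class PopulationSpec:
    """Sizes and ring geometry of the two populations."""

    n_excitatory: int = 1024
    n_inhibitory: int = 256

    def __post_init__(self):
        if self.n_excitatory <= 0 or self.n_inhibitory <= 0:
            raise ValueError("population sizes must be positive")

    @property
    def angles_e(self) -> np.ndarray:
        return preferred_angles(self.n_excitatory)

    @property
    def angles_i(self) -> np.ndarray:
        return preferred_angles(self.n_inhibitory)


@dataclass(frozen=True)
class IntrinsicParams:
    """Leaky integrate-and-fire constants for one population.

    For interneurons ``g_L`` is the *pre-modulation* leak conductance
    (g_L-star); the effective leak is scaled down by 5-HT2A activation at
    run time.
    """

    C_m: float  # nF
    g_L: float  # nS
    E_L: float  # mV
    V_th: float  # mV
    V_res: float  # mV
    tau_ref: float  # ms
    nu_ext: float  # Hz, external Poisson rate
    g_ext: float  # nS, external AMPA conductance

    def __post_init__(self):
        if self.V_res >= self.V_th:
            raise ValueError("V_res must lie below V_th")
        for name in ("C_m", "g_L", "g_ext"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class SynapseParams:
    """Receptor kinetics and peak conductances.

    Decay constants: AMPA 2 ms, NMDA 100 ms, GABA_A 10 ms.  NMDA channels
    have a 2 ms rise (tau_x), saturate with alpha_s = 0.5 kHz and are subject
    to a magnesium block evaluated at the postsynaptic voltage.
    """

    tau_ampa: float = 2.0  # ms
    tau_nmda: float = 100.0  # ms
    tau_gaba: float = 10.0  # ms
    tau_x: float = 2.0  # ms, NMDA rise
    alpha_s: float = 0.5  # kHz (= 1/ms), NMDA saturation
    mg_concentration: float = 1.0  # mM
    V_exc: float = 0.0  # mV, AMPA/NMDA reversal
    V_inh: float = -70.0  # mV, GABA_A reversal
    # peak conductances, nS
    G_EE_AMPA: float = 0.14
    G_EE_NMDA: float = 2.1
    G_EI_AMPA: float = 0.72
    G_EI_NMDA: float = 1.9
    G_IE: float = 7.8
    G_II: float = 4.4

    def __post_init__(self):
        for name in ("G_EE_AMPA", "G_EE_NMDA", "G_EI_AMPA", "G_EI_NMDA",
                     "G_IE", "G_II"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def peak_conductance(self, cls: str, receptor: str) -> float:
        if cls in ("IE", "II"):
            return getattr(self, f"G_{cls}")
        return getattr(self, f"G_{cls}_{receptor}")

    def mg_block(self, V):
        """Voltage-dependent NMDA magnesium-block factor."""
        return 1.0 / (1.0 + self.mg_concentration * np.exp(-0.062 * np.asarray(V)) / 3.57)


def _presyn_angle_offsets(pop: PopulationSpec, cls: str) -> np.ndarray:
    """Wrapped angle differences (postsyn neuron 0) minus (presynaptic ring).

    The set is independent of which postsynaptic neuron is chosen, by
    translation invariance of the half-offset grids.
    """
    if cls == "EE":
        post, pre = pop.angles_e[:1], pop.angles_e
    elif cls == "EI":
        post, pre = pop.angles_i[:1], pop.angles_e
    elif cls == "IE":
        post, pre = pop.angles_e[:1], pop.angles_i
    elif cls == "II":
        post, pre = pop.angles_i[:1], pop.angles_i
    else:
        raise ValueError(f"unknown projection class {cls!r}")
    return wrap_angle(post[0] - pre)


def solve_j_minus(j_plus: float, sigma: float, deltas: np.ndarray) -> float:
    """Solve the normalization condition mean(W) = 1 over the presynaptic ring.

    With f = mean of the unit Gaussian over the discrete angle differences,
    mean(W) = J_minus + (J_plus - J_minus) * f = 1, giving

        J_minus = (1 - J_plus * f) / (1 - f).
    """
    f = float(np.mean(np.exp(-np.asarray(deltas) ** 2 / (2.0 * sigma**2))))
    if not f < 1.0:
        raise ValueError("Gaussian footprint covers the whole ring; cannot normalize")
    return (1.0 - j_plus * f) / (1.0 - f)


@dataclass(frozen=True)
class ConnectivityKernel:
    """Ring connectivity profile per projection class.

    ``j_minus`` is derived from the normalization condition and filled in by
    :meth:`resolve`; it depends on the discrete ring through the population
    sizes.
    """

    j_plus: dict = field(default_factory=lambda: {"EE": 2.0, "EI": 0.5, "IE": 1.4, "II": 1.9})
    sigma: float = 14.4  # degrees, shared by all classes
    j_minus: dict | None = None

    def resolve(self, pop: PopulationSpec) -> "ConnectivityKernel":
        jm = {
            cls: solve_j_minus(self.j_plus[cls], self.sigma, _presyn_angle_offsets(pop, cls))
            for cls in PROJECTION_CLASSES
        }
        return replace(self, j_minus=jm)


def kernel_value(kernel: ConnectivityKernel, delta_angle, cls: str):
    """Evaluate W(delta_angle) for one projection class.

    ``delta_angle`` (degrees) is wrapped to [-180, 180) before evaluating the
    Gaussian, making W even and 360-periodic.
    """
    if cls not in PROJECTION_CLASSES:
        raise ValueError(f"unknown projection class {cls!r}")
    if kernel.j_minus is None:
        raise ValueError("kernel not resolved; call ConnectivityKernel.resolve(pop)")
    jp, jm = kernel.j_plus[cls], kernel.j_minus[cls]
    d = wrap_angle(delta_angle)
    return jm + (jp - jm) * np.exp(-d**2 / (2.0 * kernel.sigma**2))


@dataclass(frozen=True)
class NetworkSpec:
    """Complete immutable description of a network realization."""

    pop: PopulationSpec = field(default_factory=PopulationSpec)
    excitatory: IntrinsicParams = field(default_factory=lambda: IntrinsicParams(
        C_m=0.5, g_L=27.4, E_L=-70.0, V_th=-50.0, V_res=-60.0,
        tau_ref=2.0, nu_ext=1650.0, g_ext=5.0))
    inhibitory: IntrinsicParams = field(default_factory=lambda: IntrinsicParams(
        C_m=0.2, g_L=26.0, E_L=-70.0, V_th=-50.0, V_res=-60.0,
        tau_ref=1.0, nu_ext=1800.0, g_ext=1.8))
    synapses: SynapseParams = field(default_factory=SynapseParams)
    kernel: ConnectivityKernel = field(default_factory=ConnectivityKernel)
    scale: float = 1.0

    def __post_init__(self):
        if self.kernel.j_minus is None:
            object.__setattr__(self, "kernel", self.kernel.resolve(self.pop))

    @classmethod
    def reference(cls) -> "NetworkSpec":
        """The full-size network with the reference parameter set."""
        return cls()


def weight_matrix(spec: NetworkSpec, cls: str) -> np.ndarray:
    """Dense dimensionless weight matrix W[post, pre] for one projection."""
    pop = spec.pop
    post = {"EE": pop.angles_e, "EI": pop.angles_i,
            "IE": pop.angles_e, "II": pop.angles_i}[cls]
    pre = {"EE": pop.angles_e, "EI": pop.angles_e,
           "IE": pop.angles_i, "II": pop.angles_i}[cls]
    return kernel_value(spec.kernel, post[:, None] - pre[None, :], cls)


def build_weight_matrices(spec: NetworkSpec) -> dict:
    """Per-projection conductance matrices g_syn[post, pre] = W * G_syn (nS).

    Keys are (projection class, receptor) pairs, e.g. ``("EE", "NMDA")``.
    Matrices are circulant within each class (translation invariance on the
    ring) and every row sums to N_pre * G_syn by the normalization of W.
    """
    out = {}
    for cls in PROJECTION_CLASSES:
        W = weight_matrix(spec, cls)
        for receptor in PROJECTION_RECEPTORS[cls]:
            out[(cls, receptor)] = W * spec.synapses.peak_conductance(cls, receptor)
    return out


def make_fixture_network(scale: float) -> NetworkSpec:
    """A reduced network preserving total recurrent drive per neuron.

    Population sizes are multiplied by ``scale`` (E:I ratio preserved) and
    every recurrent peak conductance by ``1/scale``, so the summed recurrent
    conductance each neuron receives matches the reference network.  External
    drive parameters are per neuron and are left untouched.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    ref = NetworkSpec.reference()
    n_e = ref.pop.n_excitatory * scale
    if abs(n_e - round(n_e)) > 1e-9 or round(n_e) % 4:
        raise ValueError("scaled N_E must be an integer divisible by 4")
    n_e = int(round(n_e))
    if n_e < 32:
        raise ValueError("scaled network too small to tile the ring (N_E < 32)")
    if scale == 1.0:
        return ref
    g = 1.0 / scale
    syn = replace(
        ref.synapses,
        G_EE_AMPA=ref.synapses.G_EE_AMPA * g,
        G_EE_NMDA=ref.synapses.G_EE_NMDA * g,
        G_EI_AMPA=ref.synapses.G_EI_AMPA * g,
        G_EI_NMDA=ref.synapses.G_EI_NMDA * g,
        G_IE=ref.synapses.G_IE * g,
        G_II=ref.synapses.G_II * g,
    )
    pop = PopulationSpec(n_excitatory=n_e, n_inhibitory=n_e // 4)
    return NetworkSpec(pop=pop, excitatory=ref.excitatory, inhibitory=ref.inhibitory,
                       synapses=syn, kernel=ConnectivityKernel().resolve(pop), scale=scale)
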