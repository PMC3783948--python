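"""Trial simulation engine.

Advances the full network through the task protocol with a second-order
Runge-Kutta step at dt = 0.02 ms.  External Poisson arrivals and recurrent
spikes are applied as discrete gate jumps at step boundaries around the
deterministic update; recurrent conductance sums are evaluated once per
step from the post-jump gates (they decay by at most ~1% within a step).

The engine integrates a *batch* of trials at once (state arrays are
``(n_trials, N)``), which amortizes the per-step cost of the ring
convolutions; a single trial is just a batch of one.  Every trial owns a
named random stream derived from ``(master_seed, trial_index)``, so results
are bit-identical regardless of how trials are grouped into batches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import serotonin as sero_mod
from ._kernels import (PE_ACAN, PE_AH, PE_BCAN, PE_BH, PE_CM, PE_EL, PE_GCAN,
                       PE_GEEA, PE_GEEN, PE_GEXT, PE_GIE, PE_GK1A, PE_GKCA1,
                       PE_GL, PE_KD, PE_TREF, PE_VCAN, PE_VINH, PE_VK,
                       PE_VRES, PE_VTH, PI_CM, PI_EL, PI_GEIA, PI_GEIN,
                       PI_GEXT, PI_GII, PI_GL, PI_TREF, PI_VINH, PI_VRES,
                       PI_VTH, PK_ACA, PK_ALPHAS, PK_CATARGET, PK_DA, PK_DCA,
                       PK_DG, PK_DX, PK_TAUN, step_once)
from .model_core import NetworkSpec, kernel_value, weight_matrix
from .serotonin import SerotoninSpec
from .units import NM_TO_UM


@dataclass(frozen=True)
class StimulusSpec:
    """Spatially tuned current injection used for cue and distractor.

    I_s(theta_i) = I_1 * exp[mu_stim * (cos(theta_i - theta_s) - 1)], applied
    to excitatory neurons only.
    """

    theta_s: float = 0.0  # degrees
    I_1: float = 0.235  # nA
    mu_stim: float = 10.0
    duration: float = 250.0  # ms

    def current(self, angles_deg: np.ndarray, theta: float | np.ndarray) -> np.ndarray:
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        d = np.deg2rad(angles_deg[None, :] - th[:, None])
        return self.I_1 * np.exp(self.mu_stim * (np.cos(d) - 1.0))


@dataclass(frozen=True)
class TrialProtocol:
    """Ordered task periods; each is (name, duration_ms, stimulus_role)."""

    periods: tuple

    def __post_init__(self):
        roles = [p[2] for p in self.periods]
        if roles.count("cue") != 1:
            raise ValueError("protocol must contain exactly one cue period")
        if any(p[1] <= 0 for p in self.periods):
            raise ValueError("period durations must be positive")

    @classmethod
    def standard(cls, delay_ms: float = 3000.0, fixation_ms: float = 3000.0,
                 cue_ms: float = 250.0) -> "TrialProtocol":
        """Fixation, cue, delay — the delay length is the sweep variable.

        The long default fixation is deliberate: spontaneous (emergent)
        bumps need time to form before the cue.
        """
        return cls(periods=(("fixation", fixation_ms, None),
                            ("cue", cue_ms, "cue"),
                            ("delay", delay_ms, None)))

    @classmethod
    def distractor(cls, fixation_ms: float = 750.0, cue_ms: float = 250.0,
                   delay1_ms: float = 1750.0, distractor_ms: float = 250.0,
                   delay2_ms: float = 1750.0) -> "TrialProtocol":
        return cls(periods=(("fixation", fixation_ms, None),
                            ("cue", cue_ms, "cue"),
                            ("delay1", delay1_ms, None),
                            ("distractor", distractor_ms, "distractor"),
                            ("delay2", delay2_ms, None)))

    @property
    def total_duration(self) -> float:
        return float(sum(p[1] for p in self.periods))

    @property
    def has_distractor(self) -> bool:
        return any(p[2] == "distractor" for p in self.periods)

    def period_edges(self, dt: float):
        """(start_step, end_step, role) per period, on the dt grid."""
        edges, start = [], 0
        for name, dur, role in self.periods:
            n = int(round(dur / dt))
            edges.append((start, start + n, role))
            start += n
        return edges

    @property
    def cue_onset(self) -> float:
        t = 0.0
        for name, dur, role in self.periods:
            if role == "cue":
                return t
            t += dur
        raise AssertionError

    @property
    def cue_offset(self) -> float:
        t = 0.0
        for name, dur, role in self.periods:
            t += dur
            if role == "cue":
                return t
        raise AssertionError


@dataclass
class SpikeRaster:
    """Spike events of one trial: times (ms), neuron indices, population tag.

    ``population`` holds "E"/"I" strings; times are nondecreasing.
    """

    times: np.ndarray
    neuron: np.ndarray
    population: np.ndarray

    def __len__(self):
        return len(self.times)

    def select(self, pop: str, t0: float = -np.inf, t1: float = np.inf):
        m = (self.population == pop) & (self.times > t0) & (self.times <= t1)
        return self.times[m], self.neuron[m]


@dataclass
class NetworkState:
    """Snapshot of the time-evolving state (end of simulation)."""

    t: float
    V_e: np.ndarray
    V_i: np.ndarray
    s_ampa_ext_e: np.ndarray
    s_ampa_ext_i: np.ndarray
    s_ampa_rec: np.ndarray
    s_nmda: np.ndarray
    x_nmda: np.ndarray
    s_gaba: np.ndarray
    Ca: np.ndarray
    m_Ca: np.ndarray
    s_1A: float
    s_2A_E: float
    s_2A_I: float
    refractory_until_e: np.ndarray  # ms
    refractory_until_i: np.ndarray  # ms


@dataclass
class BatchResult:
    """Windowed spike statistics for a batch of trials, plus bookkeeping."""

    theta_s: float
    theta_d: np.ndarray | None
    decode_counts: np.ndarray  # (B, N_E), last 50 ms of the delay
    precue_counts: np.ndarray  # (B, N_E), 50 ms before cue onset
    delay_counts: np.ndarray  # (B, N_E), cue offset to end of trial
    delay_duration: float  # ms
    angles_e: np.ndarray
    trial_indices: np.ndarray
    master_seed: int
    dt: float
    protocol: TrialProtocol
    rasters: list | None = None
    final_state: NetworkState | None = None


def _param_vectors(spec: NetworkSpec, sero: SerotoninSpec, dt: float):
    ss = sero_mod.steady_state(sero)
    e, i, syn = spec.excitatory, spec.inhibitory, spec.synapses
    pe = np.zeros(21)
    pe[PE_CM] = e.C_m; pe[PE_GL] = e.g_L; pe[PE_EL] = e.E_L
    pe[PE_VTH] = e.V_th; pe[PE_VRES] = e.V_res
    pe[PE_TREF] = round(e.tau_ref / dt)  # refractory clock in steps
    pe[PE_GEXT] = e.g_ext
    pe[PE_GEEA] = syn.G_EE_AMPA; pe[PE_GEEN] = syn.G_EE_NMDA
    pe[PE_GIE] = syn.G_IE
    pe[PE_GK1A] = sero.g_K1A * ss["s1A"]
    pe[PE_VK] = sero.V_K
    pe[PE_GKCA1] = sero.g_KCa * (1.0 - ss["s2A_E"])
    pe[PE_KD] = sero.K_D
    pe[PE_GCAN] = sero.g_Can; pe[PE_VCAN] = sero.V_Can
    pe[PE_ACAN] = sero.alpha_Can; pe[PE_BCAN] = sero.beta_Can
    pe[PE_AH] = sero.alpha_h; pe[PE_BH] = sero.beta_h
    pe[PE_VINH] = syn.V_inh

    pi = np.zeros(11)
    pi[PI_CM] = i.C_m
    pi[PI_GL] = sero_mod.interneuron_leak(i.g_L, ss["s2A_I"])
    pi[PI_EL] = i.E_L; pi[PI_VTH] = i.V_th; pi[PI_VRES] = i.V_res
    pi[PI_TREF] = round(i.tau_ref / dt)
    pi[PI_GEXT] = i.g_ext
    pi[PI_GEIA] = syn.G_EI_AMPA; pi[PI_GEIN] = syn.G_EI_NMDA
    pi[PI_GII] = syn.G_II
    pi[PI_VINH] = syn.V_inh

    pk = np.zeros(8)
    pk[PK_DA] = math.exp(-dt / syn.tau_ampa)
    pk[PK_DG] = math.exp(-dt / syn.tau_gaba)
    pk[PK_DX] = math.exp(-dt / syn.tau_x)
    pk[PK_TAUN] = syn.tau_nmda
    pk[PK_ALPHAS] = syn.alpha_s
    pk[PK_CATARGET] = sero.tau_Ca * sero.gamma_5ht * NM_TO_UM * ss["s2A_E"]
    pk[PK_DCA] = math.exp(-dt / sero.tau_Ca)
    pk[PK_ACA] = sero.alpha_Ca
    return pe, pi, pk, ss


class _RingConv:
    """Recurrent conductance sums Sum_j W(theta_i - theta_j) s_j.

    The projections from the excitatory ring (E->E and E->I) exploit the
    circulant kernel with a single real FFT over the stacked AMPA/NMDA gate
    block (both receptors share W): the E->I result is evaluated on the
    interneuron grid by folding the half-offset between the two rings into
    the kernel row and subsampling.  The small projections from the
    interneuron ring use dense products.  A dense path for the E-side
    projections backs the equivalence contract.
    """

    def __init__(self, spec: NetworkSpec, method: str = "fft"):
        if method not in ("fft", "dense"):
            raise ValueError("conv method must be 'fft' or 'dense'")
        self.method = method
        n_e, n_i = spec.pop.n_excitatory, spec.pop.n_inhibitory
        self.n_e, self.n_i = n_e, n_i
        self.ratio = n_e // n_i
        delta = 360.0 / n_e
        m = np.arange(n_e)
        self._kee_hat = np.fft.rfft(kernel_value(spec.kernel, m * delta, "EE"))
        # E->I: postsyn interneuron k sits (ratio-1)/2 E-grid steps above
        # E index ratio*k, so shift the kernel row and subsample
        off = (self.ratio - 1) / 2.0
        self._kei_hat = np.fft.rfft(
            kernel_value(spec.kernel, (m + off) * delta, "EI"))
        self._W_EE = weight_matrix(spec, "EE") if method == "dense" else None
        self._W_EI = weight_matrix(spec, "EI") if method == "dense" else None
        self._M_IE = np.ascontiguousarray(weight_matrix(spec, "IE").T)  # (NI, NE)
        self._M_II = np.ascontiguousarray(weight_matrix(spec, "II").T)  # (NI, NI)

    def e_side(self, gates_en: np.ndarray):
        """(S_EE, S_EI) from the stacked (2B, N_E) AMPA/NMDA gate block."""
        if self.method == "dense":
            return gates_en @ self._W_EE.T, gates_en @ self._W_EI.T
        spec_hat = np.fft.rfft(gates_en, axis=1)
        s_ee = np.fft.irfft(spec_hat * self._kee_hat, n=self.n_e, axis=1)
        s_ei = np.fft.irfft(spec_hat * self._kei_hat, n=self.n_e,
                            axis=1)[:, ::self.ratio]
        return s_ee, np.ascontiguousarray(s_ei)

    def ie(self, s: np.ndarray) -> np.ndarray:
        return s @ self._M_IE

    def ii(self, s: np.ndarray) -> np.ndarray:
        return s @ self._M_II


def trial_rng(master_seed: int, trial_index: int) -> np.random.Generator:
    """The named random stream of one trial."""
    return np.random.default_rng(np.random.SeedSequence((master_seed, trial_index)))


def _fill_poisson_block(rng, out, m, lam, n):
    """Poisson counts for ``m`` steps x ``n`` neurons, by event thinning.

    The total event count over the block is Poisson(m*n*lam) and positions
    are uniform, which is distributionally identical to i.i.d. per-cell
    draws but touches ~30x fewer random numbers at the rates used here.
    """
    n_ev = rng.poisson(lam * m * n)
    pos = rng.integers(0, m * n, n_ev)
    out[:m] = np.bincount(pos, minlength=m * n).reshape(m, n)


def run_trials(spec: NetworkSpec, sero: SerotoninSpec, protocol: TrialProtocol,
               master_seed: int, n_trials: int = 1, *,
               stimulus: StimulusSpec = StimulusSpec(),
               theta_d=None, dt: float = 0.02, conv_method: str = "fft",
               record_raster: bool = False, noise_block: int = 250,
               drive_rotation: int = 0, trial_indices=None,
               keep_final_state: bool = False) -> BatchResult:
    """Integrate a batch of independent trials under one condition.

    Parameters
    ----------
    theta_d : scalar, array of length ``n_trials``, or None
        Distractor locations (degrees); required iff the protocol has a
        distractor period.
    drive_rotation : int
        Rotate the external-noise assignment and initial voltages by this
        many grid steps (used by the ring-symmetry tests).
    """
    if dt <= 0 or dt > 0.05:
        raise ValueError("dt must be positive and at most 0.05 ms")
    if protocol.has_distractor != (theta_d is not None):
        raise ValueError("theta_d must be given exactly when the protocol has "
                         "a distractor period")
    n_e, n_i = spec.pop.n_excitatory, spec.pop.n_inhibitory
    angles_e = spec.pop.angles_e
    if trial_indices is None:
        trial_indices = np.arange(n_trials)
    trial_indices = np.asarray(trial_indices)
    B = len(trial_indices)

    pe, pi, pk, ss = _param_vectors(spec, sero, dt)
    conv = _RingConv(spec, conv_method)

    edges = protocol.period_edges(dt)
    n_steps = edges[-1][1]
    n_dec = int(round(50.0 / dt))
    cue_start = next(a for a, b, r in edges if r == "cue")
    cue_end = next(b for a, b, r in edges if r == "cue")

    # stimulus currents per role (nA), broadcast over the batch
    zero_stim = np.zeros((B, n_e))
    cue_stim = np.broadcast_to(
        stimulus.current(angles_e, stimulus.theta_s), (B, n_e)).copy()
    if theta_d is not None:
        theta_d = np.broadcast_to(np.asarray(theta_d, dtype=float), (B,)).copy()
        dist_stim = stimulus.current(angles_e, theta_d)
    else:
        dist_stim = zero_stim
    role_stim = {None: zero_stim, "cue": cue_stim, "distractor": dist_stim}

    # state; the recurrent AMPA and NMDA gates live in one stacked block so
    # both E-side convolutions ride a single FFT
    e, i = spec.excitatory, spec.inhibitory
    rngs = [trial_rng(master_seed, int(ti)) for ti in trial_indices]
    VE = np.empty((B, n_e))
    VI = np.empty((B, n_i))
    for b, rng in enumerate(rngs):
        VE[b] = rng.uniform(e.E_L, e.V_th - 5.0, n_e)
        VI[b] = rng.uniform(i.E_L, i.V_th - 5.0, n_i)
    rot_i = drive_rotation * n_i // n_e
    if drive_rotation:
        VE = np.roll(VE, drive_rotation, axis=1)
        VI = np.roll(VI, rot_i, axis=1)
    gates_en = np.zeros((2 * B, n_e))
    sA, sN = gates_en[:B], gates_en[B:]
    xN = np.zeros((B, n_e))
    sExtE = np.zeros((B, n_e)); sExtI = np.zeros((B, n_i))
    sG = np.zeros((B, n_i))
    Ca = np.full((B, n_e), ss["Ca"]); mCa = np.full((B, n_e), ss["m_Ca"])
    refE = np.full((B, n_e), -1.0); refI = np.full((B, n_i), -1.0)
    spkE = np.zeros((B, n_e)); spkI = np.zeros((B, n_i))

    lam_e = e.nu_ext * 1e-3 * dt
    lam_i = i.nu_ext * 1e-3 * dt
    blockE = np.zeros((noise_block, B, n_e), dtype=np.int64)
    blockI = np.zeros((noise_block, B, n_i), dtype=np.int64)

    decode_counts = np.zeros((B, n_e))
    precue_counts = np.zeros((B, n_e))
    delay_counts = np.zeros((B, n_e))
    raster_chunks = [] if record_raster else None

    period_idx = 0
    stim = role_stim[edges[0][2]]
    for k in range(n_steps):
        if k % noise_block == 0:
            m = min(noise_block, n_steps - k)
            for b, rng in enumerate(rngs):
                _fill_poisson_block(rng, blockE[:, b, :], m, lam_e, n_e)
                _fill_poisson_block(rng, blockI[:, b, :], m, lam_i, n_i)
            if drive_rotation:
                blockE[:m] = np.roll(blockE[:m], drive_rotation, axis=2)
                blockI[:m] = np.roll(blockI[:m], rot_i, axis=2)
        while k >= edges[period_idx][1]:
            period_idx += 1
            stim = role_stim[edges[period_idx][2]]

        s_ee, s_ei = conv.e_side(gates_en)
        SIE = conv.ie(sG)
        SII = conv.ii(sG)

        # voltage/calcium exponentials, SIMD-vectorized outside the kernel
        eVE = np.exp(-0.062 * VE) * (1.0 / 3.57)
        eVI = np.exp(-0.062 * VI) * (1.0 / 3.57)
        hcaE = 1.0 / (1.0 + np.exp((Ca - sero.beta_h) / sero.alpha_h))

        step_once(VE, VI, sExtE, sExtI, sA, xN, sN, sG, Ca, mCa, refE, refI,
                  spkE, spkI, s_ee[:B], s_ee[B:], SIE, s_ei[:B], s_ei[B:], SII,
                  blockE[k % noise_block], blockI[k % noise_block], stim,
                  eVE, hcaE, eVI, float(k), dt, pe, pi, pk,
                  decode_counts, precue_counts, delay_counts,
                  1.0 if k >= n_steps - n_dec else 0.0,
                  1.0 if cue_start - n_dec <= k < cue_start else 0.0,
                  1.0 if k >= cue_end else 0.0)

        if record_raster:
            be, ne_idx = np.nonzero(spkE)
            bi, ni_idx = np.nonzero(spkI)
            if len(be) or len(bi):
                raster_chunks.append((k, be, ne_idx, bi, ni_idx))
        if k % 5000 == 0 and not (np.isfinite(VE).all() and np.isfinite(VI).all()):
            raise RuntimeError(
                f"non-finite state at t={k * dt:.2f} ms "
                f"(max |V_e|={np.nanmax(np.abs(VE)):.3g})")

    rasters = None
    if record_raster:
        rasters = _assemble_rasters(raster_chunks, B, dt)

    final_state = None
    if keep_final_state:
        final_state = NetworkState(
            t=n_steps * dt, V_e=VE, V_i=VI, s_ampa_ext_e=sExtE,
            s_ampa_ext_i=sExtI, s_ampa_rec=sA.copy(), s_nmda=sN.copy(),
            x_nmda=xN, s_gaba=sG,
            Ca=Ca, m_Ca=mCa, s_1A=ss["s1A"], s_2A_E=ss["s2A_E"],
            s_2A_I=ss["s2A_I"], refractory_until_e=refE * dt,
            refractory_until_i=refI * dt)

    return BatchResult(
        theta_s=stimulus.theta_s, theta_d=theta_d,
        decode_counts=decode_counts, precue_counts=precue_counts,
        delay_counts=delay_counts,
        delay_duration=(n_steps - cue_end) * dt,
        angles_e=angles_e, trial_indices=trial_indices,
        master_seed=master_seed, dt=dt, protocol=protocol,
        rasters=rasters, final_state=final_state)


def _assemble_rasters(chunks, B, dt):
    """Per-trial SpikeRaster objects from per-step nonzero records."""
    times = [[] for _ in range(B)]
    neurons = [[] for _ in range(B)]
    pops = [[] for _ in range(B)]
    for k, be, ne_idx, bi, ni_idx in chunks:
        t = (k + 1) * dt
        for b, n in zip(be, ne_idx):
            times[b].append(t); neurons[b].append(n); pops[b].append("E")
        for b, n in zip(bi, ni_idx):
            times[b].append(t); neurons[b].append(n); pops[b].append("I")
    out = []
    for b in range(B):
        out.append(SpikeRaster(times=np.array(times[b], dtype=float),
                               neuron=np.array(neurons[b], dtype=int),
                               population=np.array(pops[b], dtype="U1")))
    return out


def run_trial(spec: NetworkSpec, sero: SerotoninSpec, protocol: TrialProtocol,
              seed: int, *, trial_index: int = 0, theta_d=None,
              stimulus: StimulusSpec = StimulusSpec(), dt: float = 0.02,
              conv_method: str = "fft", record_raster: bool = True,
              c_thresh: float = 0.3):
    """Run one trial and decode it; returns (SpikeRaster, TrialResult)."""
    from .decoding import decode_batch
    batch = run_trials(spec, sero, protocol, seed, 1, stimulus=stimulus,
                       theta_d=theta_d, dt=dt, conv_method=conv_method,
                       record_raster=record_raster,
                       trial_indices=[trial_index])
    result = decode_batch(batch, c_thresh=c_thresh)[0]
    raster = batch.rasters[0] if record_raster else None
    return raster, result
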