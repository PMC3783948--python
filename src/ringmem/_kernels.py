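"""Compiled inner loop of the network integrator.

One call advances every neuron of every trial in a batch by a single time
step.  The ring convolutions (recurrent conductance sums) and the Poisson
draws for external drive are performed by the caller; this kernel handles
the per-neuron updates: RK2 voltage integration with the synaptic
conductances held constant over the step, threshold/reset with an absolute
refractory clamp (tracked in integer steps, so refractory windows are
exact), exact exponential decay of the linear synaptic gates, RK2 for the
saturating NMDA gate, and the calcium / I_Can dynamics of pyramidal cells.

The magnesium-block factor at the second RK2 stage is obtained from the
first-stage value through a second-order expansion of
exp(-0.062 * dt * k1) (the exponent is below 1e-2 at dt = 0.02 ms), which
preserves the order of the scheme while halving the exp count.

Spikes detected in this step are folded into the presynaptic gates here
(decay-then-jump), so the caller's convolution at the next step sees them;
this is identical to applying the jump at the start of the next step.

Parameter vectors (see index constants below) are plain float64 arrays so
the kernel compiles once and is reused across serotonin conditions.
"""

import math

from numba import njit

# pyramidal parameter vector indices (TREF is in *steps*)
PE_CM, PE_GL, PE_EL, PE_VTH, PE_VRES, PE_TREF, PE_GEXT, PE_GEEA, PE_GEEN, \
    PE_GIE, PE_GK1A, PE_VK, PE_GKCA1, PE_KD, PE_GCAN, PE_VCAN, PE_ACAN, \
    PE_BCAN, PE_AH, PE_BH, PE_VINH = range(21)

# interneuron parameter vector indices (GL is the 5-HT2A-reduced effective leak)
PI_CM, PI_GL, PI_EL, PI_VTH, PI_VRES, PI_TREF, PI_GEXT, PI_GEIA, PI_GEIN, \
    PI_GII, PI_VINH = range(11)

# kinetic constants vector indices
PK_DA, PK_DG, PK_DX, PK_TAUN, PK_ALPHAS, PK_CATARGET, PK_DCA, PK_ACA = range(8)

U = 1e-3  # nA per nS*mV


@njit(cache=True, fastmath=True)
def step_once(VE, VI, sExtE, sExtI, sA, xN, sN, sG, Ca, mCa, refE, refI,
              spkE, spkI, SEE_A, SEE_N, SIE, SEI_A, SEI_N, SII,
              extE, extI, stim, eVE, hcaE, eVI, kstep, dt, pe, pi, pk,
              acc_decode, acc_precue, acc_delay, f_decode, f_precue, f_delay):
    B, NE = VE.shape
    NI = VI.shape[1]

    CmE = pe[PE_CM]; gLE = pe[PE_GL]; ELE = pe[PE_EL]
    VthE = pe[PE_VTH]; VresE = pe[PE_VRES]; trefE = pe[PE_TREF]
    gextE = pe[PE_GEXT]; GEEA = pe[PE_GEEA]; GEEN = pe[PE_GEEN]
    GIE = pe[PE_GIE]; gk1a = pe[PE_GK1A]; VK = pe[PE_VK]
    gkca1 = pe[PE_GKCA1]; KD = pe[PE_KD]; gCan = pe[PE_GCAN]
    VCan = pe[PE_VCAN]; aCan = pe[PE_ACAN]; bCan = pe[PE_BCAN]
    ah = pe[PE_AH]; bh = pe[PE_BH]; VinhE = pe[PE_VINH]

    CmI = pi[PI_CM]; gLI = pi[PI_GL]; ELI = pi[PI_EL]
    VthI = pi[PI_VTH]; VresI = pi[PI_VRES]; trefI = pi[PI_TREF]
    gextI = pi[PI_GEXT]; GEIA = pi[PI_GEIA]; GEIN = pi[PI_GEIN]
    GII = pi[PI_GII]; VinhI = pi[PI_VINH]

    dA = pk[PK_DA]; dG = pk[PK_DG]; dX = pk[PK_DX]
    tauN = pk[PK_TAUN]; alphas = pk[PK_ALPHAS]
    caT = pk[PK_CATARGET]; dCa = pk[PK_DCA]; aCa = pk[PK_ACA]

    iCmE = U / CmE; iCmE_s = 1.0 / CmE
    iCmI = U / CmI
    itauN = 1.0 / tauN

    for b in range(B):
        for i in range(NE):
            se = sExtE[b, i] + extE[b, i]
            V = VE[b, i]
            spike = 0.0
            ca0 = Ca[b, i]
            d3 = aCan * ca0 + bCan
            if kstep >= refE[b, i]:
                gA = GEEA * SEE_A[b, i]
                gN = GEEN * SEE_N[b, i]
                gG = GIE * SIE[b, i]
                # one reciprocal serves the two calcium-side denominators;
                # h_Ca arrives precomputed (SIMD exp in the caller)
                d1 = ca0 + KD
                r = 1.0 / (d1 * d3)
                gkca = gkca1 * ca0 * (r * d3)
                minf = aCan * ca0 * (r * d1)
                gcan = gCan * mCa[b, i] * mCa[b, i] * hcaE[b, i]
                Ist = stim[b, i] * iCmE_s
                # two-stage RK2 with conductances frozen over the step
                eV = eVE[b, i]
                I1 = (gLE * (V - ELE) + gextE * se * V + gA * V
                      + gG * (V - VinhE) + gk1a * (V - VK) + gkca * (V - VK)
                      + gcan * (V - VCan))
                mg = 1.0 / (1.0 + eV)
                k1 = Ist - (I1 + gN * mg * V) * iCmE
                Vp = V + dt * k1
                z = -0.062 * dt * k1
                eVp = eV * (1.0 + z * (1.0 + 0.5 * z))
                I2 = (gLE * (Vp - ELE) + gextE * se * Vp + gA * Vp
                      + gG * (Vp - VinhE) + gk1a * (Vp - VK) + gkca * (Vp - VK)
                      + gcan * (Vp - VCan))
                mg = 1.0 / (1.0 + eVp)
                k2 = Ist - (I2 + gN * mg * Vp) * iCmE
                V = V + 0.5 * dt * (k1 + k2)
                if V >= VthE:
                    spike = 1.0
                    V = VresE
                    refE[b, i] = kstep + 1.0 + trefE
            else:
                minf = aCan * ca0 / d3
            VE[b, i] = V
            spkE[b, i] = spike
            if f_decode == 1.0:
                acc_decode[b, i] += spike
            if f_precue == 1.0:
                acc_precue[b, i] += spike
            if f_delay == 1.0:
                acc_delay[b, i] += spike

            # synaptic gates: exact exponential decay of the linear gates
            # (decay-then-jump for this step's spike), RK2 for the
            # saturating NMDA gate driven by x(t) and x(t+dt)
            sExtE[b, i] = se * dA
            x0 = xN[b, i]
            x1 = x0 * dX
            s = sN[b, i]
            k1 = -s * itauN + alphas * x0 * (1.0 - s)
            sp = s + dt * k1
            k2 = -sp * itauN + alphas * x1 * (1.0 - sp)
            sN[b, i] = s + 0.5 * dt * (k1 + k2)
            sA[b, i] = sA[b, i] * dA + spike
            xN[b, i] = x1 + spike

            # calcium: exact update of the linear ODE, then the spike jump;
            # I_Can activation relaxes toward m_inf(Ca) (relaxation factor
            # poly-expanded: dt/tau_m ~ 1e-4, truncation error O(1e-12))
            z = dt * d3
            decay_m = 1.0 - z * (1.0 - 0.5 * z)
            mCa[b, i] = minf + (mCa[b, i] - minf) * decay_m
            c = caT + (ca0 - caT) * dCa
            if spike == 1.0:
                c += aCa
            Ca[b, i] = c

        for j in range(NI):
            se = sExtI[b, j] + extI[b, j]
            V = VI[b, j]
            spike = 0.0
            if kstep >= refI[b, j]:
                gA = GEIA * SEI_A[b, j]
                gN = GEIN * SEI_N[b, j]
                gG = GII * SII[b, j]
                eV = eVI[b, j]
                mg = 1.0 / (1.0 + eV)
                I1 = (gLI * (V - ELI) + gextI * se * V + (gA + gN * mg) * V
                      + gG * (V - VinhI))
                k1 = -I1 * iCmI
                Vp = V + dt * k1
                z = -0.062 * dt * k1
                mg = 1.0 / (1.0 + eV * (1.0 + z * (1.0 + 0.5 * z)))
                I2 = (gLI * (Vp - ELI) + gextI * se * Vp + (gA + gN * mg) * Vp
                      + gG * (Vp - VinhI))
                k2 = -I2 * iCmI
                V = V + 0.5 * dt * (k1 + k2)
                if V >= VthI:
                    spike = 1.0
                    V = VresI
                    refI[b, j] = kstep + 1.0 + trefI
            VI[b, j] = V
            spkI[b, j] = spike
            sExtI[b, j] = se * dA
            sG[b, j] = sG[b, j] * dG + spike
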