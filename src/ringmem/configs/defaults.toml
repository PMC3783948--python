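# Reference parameter set: full-size network, physiological serotonin level.
# Units: mV, ms, nS, nA, nF, uM (concentrations quoted in nM where noted).

[population]
n_excitatory = 1024
n_inhibitory = 256

[excitatory]
C_m = 0.5        # nF
g_L = 27.4       # nS
E_L = -70.0      # mV
V_th = -50.0     # mV
V_res = -60.0    # mV
tau_ref = 2.0    # ms
nu_ext = 1650.0  # Hz
g_ext = 5.0      # nS

[inhibitory]
C_m = 0.2
g_L = 26.0       # nS, pre-modulation value g_L*
E_L = -70.0
V_th = -50.0
V_res = -60.0
tau_ref = 1.0
nu_ext = 1800.0
g_ext = 1.8

[synapses]
tau_ampa = 2.0    # ms
tau_nmda = 100.0  # ms
tau_gaba = 10.0   # ms
tau_x = 2.0       # ms, NMDA rise
alpha_s = 0.5     # kHz, NMDA saturation
mg_concentration = 1.0  # mM
V_exc = 0.0       # mV
V_inh = -70.0     # mV
G_EE_AMPA = 0.14  # nS
G_EE_NMDA = 2.1
G_EI_AMPA = 0.72
G_EI_NMDA = 1.9
G_IE = 7.8
G_II = 4.4

[kernel]
sigma = 14.4      # degrees
J_plus_EE = 2.0
J_plus_EI = 0.5
J_plus_IE = 1.4
J_plus_II = 1.9

[serotonin]
tau_1A = 30.0        # ms
tau_2A = 120.0       # ms
alpha_1A = 1.8       # kHz/uM
alpha_2A_E = 2.25    # kHz/uM
alpha_2A_I = 11.0    # kHz/uM
baseline_5ht_nM = 10.0
g_K1A = 29.7         # nS
V_K = -70.0          # mV
gamma_5ht = 0.41     # nM/ms
alpha_Ca = 0.1       # uM per spike
tau_Ca = 240.0       # ms
g_KCa = 703.0        # nS
K_D = 30.0           # uM
g_Can = 36.0         # nS
V_Can = -20.0        # mV
alpha_Can = 0.0056   # 1/(ms*uM)
beta_Can = 0.002     # 1/ms
alpha_h = 3.0        # uM
beta_h = 5.0         # uM
concentration_scale_1A = 1.0
concentration_scale_2A = 1.0

[stimulus]
I_1 = 0.235       # nA
mu_stim = 10.0
duration = 250.0  # ms

[integration]
dt = 0.02         # ms
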