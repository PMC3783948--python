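"""Unit conventions used throughout the package.

All quantities are kept in a single consistent system: millivolts (mV),
milliseconds (ms), nanosiemens (nS), nanoamperes (nA), nanofarads (nF) and
micromolar (uM).  In this system ``g [nS] * V [mV]`` is in picoamperes, so a
single factor converts conductance-driven currents to nA, and
``I [nA] / C [nF]`` is exactly in mV/ms.
"""

#: nA per (nS * mV); the only place this conversion lives.
NS_MV_TO_NA = 1e-3

#: uM per nM (serotonin concentrations are quoted in nM, calcium in uM).
NM_TO_UM = 1e-3
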