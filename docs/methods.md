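# Methods

`ringmem` simulates a local prefrontal microcircuit that stores a spatial
angle as a bump of persistent spiking on a ring of neurons, and asks how
tonic serotonin, acting through 5-HT1A and 5-HT2A receptors, reshapes the
behavior this circuit supports: accuracy of the memory report, the type of
error committed, sensitivity to delay length, resistance to intervening
distractors, and the shape of delay-period tuning curves.

## The circuit model

Two populations of leaky integrate-and-fire neurons — N_E = 1024 pyramidal
cells and N_I = 256 interneurons in the reference configuration — are
labelled by preferred angles uniformly spaced on (−180°, 180°] (half-offset
grid, so no neuron sits on the ±180° seam).  The membrane equation is

    C_m dV/dt = −I_L − I_syn,e − I_syn,i − I_ext + I_s − I_5-HT

with threshold −50 mV, reset −60 mV, and absolute refractory periods of
2 ms (E) and 1 ms (I).  Recurrent synapses are conductance-based AMPA
(τ = 2 ms), NMDA (τ_s = 100 ms, rise τ_x = 2 ms, saturation α_s = 0.5 kHz,
magnesium block 1/(1 + [Mg]e^(−0.062V)/3.57) at the postsynaptic voltage)
and GABA_A (τ = 10 ms, reversal −70 mV).  External drive is an independent
Poisson train per neuron (1650 Hz through 5 nS AMPA for E, 1800 Hz through
1.8 nS for I).

Connectivity depends only on the difference of preferred angles through

    W(Δθ) = J⁻ + (J⁺ − J⁻) exp(−Δθ²/2σ²),  σ = 14.4°,

with J⁺ = 2 (E→E), 0.5 (E→I), 1.4 (I→E), 1.9 (I→I).  J⁻ is fixed per
projection by requiring the mean of W over the discrete presynaptic ring to
equal 1, solved in closed form as J⁻ = (1 − J⁺f)/(1 − f) with f the ring
average of the unit Gaussian.  The normalization is computed on the
discrete ring rather than the continuous circle; the difference is O(1/N)
and the discrete choice makes the row sums of the weight matrices exactly
uniform, which the stepper exploits.

## Serotonin model

Tonic [5-HT] (10 nM physiological) gates two receptor variables with
first-order kinetics; at constant concentration they sit at their fixed
points (s₁A* = 0.54, s₂A,E* ≈ 0.730, s₂A,I* ≈ 0.930 at 10 nM), which is how
the simulator treats them — gates are initialized at the fixed point, which
the constant-concentration ODE never leaves.  Downstream, 5-HT1A gates a
potassium current I_K1A = g_K1A·s₁A·(V−V_K) on pyramidal cells
(hyperpolarizing, ~16 nS at baseline); 5-HT2A suppresses the
calcium-dependent AHP current I_KCa by (1−s₂A), feeds calcium at
γ·s₂A, and thereby drives the calcium-activated cation current
I_Can = g_Can·m²·h_Ca·(V−V_Can); on interneurons 5-HT2A shrinks the leak to
g_L*(1−s₂A).  Receptor-specific agonists/antagonists are modelled exactly
as concentration multipliers inside one receptor's kinetic equation,
leaving the other at the physiological level; setting both multipliers to c
is algebraically identical to scaling the baseline concentration by c.

### Operating-point calibration

Implemented literally, the quoted constants do not produce a functioning
working-memory regime at 10 nM: the tonic hyperpolarizing load (I_K1A plus
the GABA tone of the leak-reduced, integrator-like interneurons) holds the
excitatory ring at V ≈ −59 mV, the cue cannot ignite a bump, and even
artificially ignited bumps collapse within ~300 ms — while the same code
at [5-HT] ≲ 5 nM shows the expected spontaneous state and stable bumps.
The published network demonstrably had a stable regime at 10 nM (its
receptor affinities were optimized for exactly that), so one constant was
recalibrated: the I_Can activation rate α_Can, from 0.0056 to
0.035 (ms·µM)⁻¹ (`ringmem.calibration`).  With the quoted value,
m_∞(Ca_rest) ≈ 0.17 and I_Can contributes ~1 nS — the depolarizing arm of
5-HT2A is inert, which both starves the baseline state and inverts the
5-HT2A axis (the interneuron-leak arm then dominates, so 2A agonists would
*reduce* network excitability, contrary to the model's documented
phenomenology).  At 0.035 the current supplies ~12 nS of tonic
depolarization and grows on active neurons, and the model reproduces the
full directional pattern: stable baseline bumps, emergent-bump errors for
reduced [5-HT] or 5-HT1A activation, decaying-bump errors for raised
[5-HT] or 5-HT1A, and the mirrored pattern for 5-HT2A.  The calibration
was selected on this qualitative regime only.  `SerotoninSpec` keeps the
quoted default, so the printed parameter set remains retrievable; the
experiment drivers and CLI use the calibrated value.

The distractor-task stimulus intensity is calibrated by the model's own
stated rule: the cue/distractor current (shared intensity) is set so that,
at physiological [5-HT], reports after a distant distractor (≥ 90°) fall
near the cue and near the distractor in similar proportion.  With the
α_Can calibration the quoted 0.235 nA no longer satisfies this (the
entrenched bump never yields); the balance point of the calibrated
quarter-scale network, 0.70 nA, is used instead
(`STIMULUS_I1_CALIBRATED`), derived on the baseline condition only so that
all serotonin manipulations of the distractor task remain predictions.
The calibrated intensity is scoped to the distractor task (where cue and
distractor share it, as the task requires); the no-distractor task keeps
the quoted 0.235 nA, under which the calibrated network already shows the
documented standard-task behavior.  The cost of this scoping is that the
stimulus intensity is no longer identical across the two task variants.

## Numerical scheme

Second-order Runge–Kutta at dt = 0.02 ms.  Within a step the synaptic
conductance sums are held constant (they change by ≤ 1%/step); the linear
gates (AMPA, GABA_A, NMDA-x, calcium) use exact exponential updates, so a
gate trajectory between spikes matches the closed form to machine
precision; the saturating NMDA gate uses RK2 driven by x(t) and x(t+dt);
the I_Can activation relaxes exactly toward m_∞(Ca) with its Ca-dependent
time constant (the relaxation factor is expanded to second order in
dt/τ_m ≈ 10⁻⁴).  External Poisson arrivals and recurrent spikes enter as
gate jumps at step boundaries; spike times are resolved at step boundaries
(no interpolation), threshold crossings reset V and start an integer-step
refractory clock during which the voltage is clamped and inputs ignored.
The second magnesium-block evaluation inside RK2 reuses the first through
a second-order expansion of exp(−0.062·dt·k₁) (exponent < 10⁻²), which
preserves the order of the scheme.

Recurrent drive uses the circulant structure of the ring: the E-side
projections (E→E and E→I) ride one real FFT of the stacked AMPA/NMDA gate
block, with the E→I result read on the interneuron grid by folding the
half-offset between the rings into the kernel row and subsampling; the
small I-side projections are dense products.  A dense path for the E-side
is kept and the two are equivalence-tested to 10⁻¹⁰.

External Poisson counts are drawn per trial in blocks by event thinning
(total count ~ Poisson(λ·steps·N), positions uniform), which is
distributionally identical to per-cell draws.  Every trial owns a named
stream seeded by SeedSequence((master_seed, trial_index)), so any trial is
bit-reproducible regardless of batch composition.  Initial voltages are
uniform on [E_L, V_th − 5 mV]; synaptic gates start at zero; receptor
gates, calcium and m_Ca start at their tonic fixed points (the model is
silent on initialization; starting at the fixed points avoids long
equilibration transients).  The 3-s fixation is retained in full because
spontaneous (emergent) bumps need time to form before the cue.

## Behavioral read-out

The report θ_R and coherence C are the angle and modulus of the normalized
population vector of excitatory spike counts in the last 50 ms of the
delay (right-closed).  A trial is correct when the circular distance
|θ_R − θ_S| < 22.5°.  Errors split by late-delay coherence: *decaying-bump*
errors have no coherent signal, *emergent-bump* errors carry a confident
but misaligned bump.  "Coherent" requires both C ≥ 0.3 and a Rayleigh
statistic N·C² ≥ 6 (N = spikes in the window): the modulus of a
near-silent window is biased upward as 1/√N, so a bare modulus threshold
would label silent windows as bumps.  Under the uniform null N·C² is
approximately Exp(1), so the floor of 6 keeps false coherence below 0.3%
at any spike count; windows with literally zero (or exactly cancelling)
counts get a uniformly random report from the trial's own stream and are
classed as decaying unless the draw lands in the response window.  Both
thresholds are exposed in the API.

## Experiments

Condition sweeps fix the cue at 0° (the ring is homogeneous; an exact
rotation test backs the reduction).  Performance summaries report the
correct/decaying/emergent fractions with Wilson intervals.  The delay
sweep runs delays of 1–3 s.  The distractor task (fixation 0.75 s, cue
0.25 s, delay 1.75 s, distractor 0.25 s, delay 1.75 s) probes distances
0–180° in 11.25° steps; the headline statistic is the fraction of trials
with |θ_R − θ_S| < 22.5° among distances ≥ 90° *inclusive* (nine
distances).  Report displacements are binned signed-positive toward the
distractor side.  Tuning curves average per-neuron delay rates after
rotating each trial so the cue (or the decoded report) maps to 0° (nearest
grid step), bin at 45° with bins centered on 0°, and fit
baseline + amplitude·exp(−θ²/2w²) by unweighted least squares
(width bounded below by a quarter bin so the fit cannot chase single-bin
noise); "sharpness" is amplitude/width.

## Problem sizes

The full-size experiments (≥ 900–1000 trials per condition at N = 1280
neurons) are not desk-scale.  The shipped tests and the acceptance script
run the quarter-scale fixture network (N_E = 256, N_I = 64; per-projection
conductances scaled by 1/scale so the summed recurrent drive per neuron is
preserved) at the production dt = 0.02 ms, with 8–34 trials per condition
in the test suite and 18 distractor trials per condition (two per distance)
in the acceptance script.  At these sizes the binomial standard error of a
fraction is 7–12 percentage points, and the quarter-scale ring has ~4×
larger finite-size fluctuations than the reference network — faster bump
diffusion along the ring and easier spontaneous bump nucleation — so
fractions should be read as scaled-down reproductions of the full-size
statistics, not precise recoveries.  The clearest example is baseline
standard-task accuracy: the quarter-scale fixture loses ~20% of trials to
spontaneous pre-cue bumps, while a 12-trial run at the reference size
scored 12/12 correct with no emergent errors — the reduced ring nucleates
spurious bumps that the full ring suppresses.

## Known limitations

* Two constants are calibrated rather than quoted (α_Can and the
  distractor-task stimulus intensity); see above for the rationale and
  the calibration criteria.
* The quarter-scale network's sharper competition makes the
  distractor-displacement transition steeper than a large ring's, so
  distraction fractions depend more strongly on stimulus intensity than
  they would at full size.
* Phasic serotonin transients, 5-HT receptors on synaptic transmission,
  5-HT3/5-HT2C receptors, dendritic receptor segregation and an explicit
  response period are all outside the model's scope.
* Receptor gates are population-wide scalars (tonic, spatially uniform
  5-HT); per-neuron receptor state would only matter for phasic or
  spatially structured neuromodulation.
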