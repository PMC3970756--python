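# Methods

## The model

`afferentsim` simulates the soma of a myelinated dorsal-root-ganglion
(DRG) afferent as a hybrid conductance-based membrane model: a
two-variable Morris–Lecar (ML) spike generator plus additive
Hodgkin–Huxley-style subthreshold conductances that bias the competition
between net fast inward and net slower outward current near threshold.

The ML core (potential `V`, recovery `w`) is

    C dV/dt = I_stim − gbar_fast·m_inf(V)(V−E_Na) − gbar_slow·w(V−E_K)
              − g_leak(V−E_leak) − Σ I_channel − I_AHP
    dw/dt   = phi_w · (w_inf(V) − w) / tau_w(V)

with the standard hyperbolic-tangent gating

    m_inf(V) = 0.5·[1 + tanh((V−beta_m)/gamma_m)]
    w_inf(V) = 0.5·[1 + tanh((V−beta_w)/gamma_w)]
    tau_w(V) = 1 / cosh((V−beta_w)/(2·gamma_w))

This particular two-variable formulation is a deliberate design choice:
the parameter names (`beta_m`, `gamma_m`, `beta_w`, `gamma_w`, `phi_w`)
fix the functional form up to convention, and the chosen convention
reproduces the expected behavior of the default cell (rest near −70 mV,
spike threshold near −35 mV, onset-only spiking).

Default core parameters (densities): C = 2 µF/cm², E_Na = 50 mV,
E_K = −100 mV, E_leak = −70 mV, phi_w = 0.15, gbar_fast = 20 mS/cm²,
gbar_slow = 20 mS/cm², g_leak = 2 mS/cm², beta_m = −1.2 mV,
gamma_m = 14 mV, beta_w = −10 mV, gamma_w = 10 mV. These are held fixed
throughout; every excitability manipulation acts on the added channels.

### Added subthreshold channels

Each added channel is first order (activation exponent 1, no
inactivation), with linoid/exponential rates

    alpha(V) = k_a · x/(e^x − 1),  x = (V − V_a)/s_a
    beta(V)  = k_b · e^((V − V_b)/s_b)
    dm/dt    = alpha(1 − m) − beta·m,     I = gbar·m·(V − E_rev)

Defaults V_a = V_b = −24 mV, s_a = s_b = −17 mV, k_a = k_b = 1 ms⁻¹
place half-activation at −24 mV with tau ≈ 0.5 ms there — fast,
perithreshold activation. The exponent arguments are taken as the
dimensionless (V−V_a)/s_a (alpha) and, for the AHP gate below,
(beta_z−V)/gamma_z; these are the only dimensionally consistent
readings. The rate constant k is exposed in configuration (physiological
range roughly 1–1.5 ms⁻¹; default 1). A channel is "Na-like" or
"K-like" purely through its reversal potential (+50 / −100 mV); the
kinetics are identical.

### AHP (adaptation) current

    I_AHP = gbar_AHP · z · (V − E_K),
    dz/dt = (z_inf(V) − z)/tau_z,  z_inf(V) = 1/(1 + e^((beta_z−V)/gamma_z))

with beta_z = 0 mV (suprathreshold, so z integrates spikes),
gamma_z = 5 mV, tau_z = 300 ms. The default density gbar_AHP = 2 mS/cm²
was chosen by measurement: it is near the minimum at which the
adaptation current can sweep the reference neuropathic cell's effective
stimulus across its bistable window (≈54–61 µA/cm²), the prerequisite
for hysteresis bursting. Weaker adaptation merely slows tonic firing.

### Noise

Stochastic runs add zero-mean Gaussian current noise with SD
0.3 µA/cm². Only the SD and mean are physically constrained, so the
discretization is a package choice: the noise current is held
piecewise-constant per integration step, with the SD referred to
dt_ref = 0.1 ms and rescaled by sqrt(dt_ref/dt) at other step sizes, so
voltage statistics are dt-invariant. An Ornstein–Uhlenbeck mode
(stationary SD `sigma`, correlation time `tau_corr`) is available;
white is the default.

## Numerics

* Deterministic integration: fixed-step classical RK4, default
  dt = 0.02 ms (spike counts are converged: halving dt leaves them
  unchanged). Stochastic integration: Euler–Maruyama at dt = 0.05 ms.
  Gating variables are clipped to [0, 1] against integrator overshoot.
  The integration kernels are numba-compiled.
* Initial conditions default to the relaxed rest state under the
  holding current (1 s noise-free settle), so step responses are free of
  onset transients.
* Equilibria are roots of the scalar stationary current balance
  I_stim = I_ss(V) (every gate at its voltage-dependent steady state);
  roots are bracketed by a dense 0.1 mV scan and polished with Brent's
  method. Stability comes from the eigenvalues of a central
  finite-difference Jacobian (step 1e−6, relative).
* The linoid alpha(V) has a removable singularity at V = V_a; it is
  evaluated by a quadratic expansion for |x| < 1e−4.

## Bifurcation analysis without continuation

Instead of numerical continuation, the equilibrium branch is
parametrized by V: each V indexes one equilibrium with stimulus
I_ss(V). The Hopf stimulus I* is located by bisection on the leading
eigenvalue real part along the branch (tolerance 0.01 µA/cm²), with the
destabilizing pair verified complex. Subcriticality is established
constructively: a state on the spiking attractor is obtained just above
I*, and the attractor's persistence is tested just below I* where the
equilibrium is still stable — coexistence means bistability, hence a
subcritical Hopf. The saddle-node of limit cycles (SNLC, lower edge of
the bistable window) is bisected on persistence of the spiking
attractor. Unstable limit-cycle branches are not computed; this is a
documented simplification.

### The scanned stimulus range

Regime classification asks whether a Hopf exists for some I_stim in a
bounded range, default (0, 70) µA/cm². The cap matters: at
≈74 µA/cm² the bare ML core's own equilibrium destabilizes (a
high-stimulus instability adjacent to depolarization block), so an
unbounded scan would classify even the channel-free cell as
repetitive-spiking-capable. The cap is set just below that value so
that classification reflects the added-conductance tipping point:
within (0, 70), the base cell and the normal reference cell
(gNa = 2.0, gK = 2.5 mS/cm²) have no Hopf, while the neuropathic
reference cell (gNa = 2.5, gK = 2.0) has a subcritical Hopf at
I* ≈ 60.8 µA/cm² with a bistable window down to ≈54.1. The
classification ladder's stimulus cap is aligned at the same 70 µA/cm².
(All added-conductance settings are on the mS/cm² scale of the core
conductances, consistent with the 1 nS/pF ≡ 1 mS/cm² dynamic-clamp
convention; the simulation oracle confirms the two reference settings
behave as intended on this scale.) One consequence: the normal
reference cell's single-spike
rheobase (≈72 µA/cm²) lies just above the cap, so it is classified
onset-only with a no-spike flag rather than by an observed onset spike.

A cell whose Hopf lies below the bottom of the range (very large gNa)
has an unstable equilibrium from the start; `hopf_bearing` classifies
it as repetitive-capable even though no in-range crossing exists, and
the tipping map stores the bottom of the range as its I*.

### The two-parameter tipping map

Each (gbar_Na, gbar_K) grid cell is classified Hopf-bearing or not; the
boundary is the gbar_Na at which each gK row first becomes bearing
(mid-point interpolation, optionally refined by bisection). The
boundary is monotone increasing in gbar_K and moves as expected with
context parameters: larger g_leak and hyperpolarizing activation shifts
push it to larger gbar_Na; depolarizing shifts and depolarized E_K pull
it down.

### Two notions of "can spike repetitively"

The eigenvalue criterion (Hopf in range) and the step-protocol
criterion (≥3 spikes during a sustained step at some tested amplitude)
agree except in a narrow band where the bistable window, but not the
Hopf itself, dips below the stimulus cap: there the step-onset
transient can recruit the spiking attractor by hard excitation
(quasi-separatrix crossing into the cycle), so the simulation
classifier flips slightly earlier along a titration than the eigenvalue
classifier (≈0.4 mS/cm² of added Na for the normal reference cell).
Both classifiers are exposed (`classifier="simulate" | "hopf"`);
agreement between eigenvalue-detected I* and simulated spiking onset is
asserted from perturbed-equilibrium initial conditions, where onset is
sharp at I* (full-height spikes develop within ~2 µA/cm² above the
crossing, since the just-destabilized focus can first settle on a
subthreshold cycle).

## Phenotype detection

* **Spikes**: upward crossings of 0 mV with a 2 ms refractory gap —
  neither value is dictated by the source experiments; both are
  configurable. Repetitive spiking is defined as at least three spikes
  during the sustained step (≥500 ms; default 1 s).
* **Classification ladder**: the minimal step amplitude evoking ≥1
  spike is found by doubling and bisection (0.1 µA/cm²); the cell is
  probed at that rheobase times (1, 1.5, 2, 3), capped at 70 µA/cm².
* **MPOs**: ≥5 s of subthreshold voltage with noise; spikes excised
  with ±10 ms margins; Welch periodograms (1 s segments, 50% overlap,
  linear detrend) averaged over spike-free stretches, lightly smoothed
  (5-bin boxcar). The background is a median filter across frequency
  with ±40 Hz half-width — much wider than the broad (~30 Hz) resonance
  so it does not absorb the peak. MPOs are present iff a local peak at
  ≥5 Hz exceeds the background 3-fold. The band, estimator and factor
  are package defaults (the qualitative target is "a broad spectral
  peak"), all configurable. Near the Hopf the reference cell shows
  ratios ≈3–7 at ~85 Hz; far below, ≈1.5–2.
* **Bursts**: maximal runs of ≥2 spikes with ISI < 50 ms, flanked by
  gaps > 150 ms; bursting requires ≥2 such bursts and at least 6
  spikes. Thresholds are ISI-based for transparency and configurable.
* **Titration**: bisection (tolerance 0.005 mS/cm²) on the added
  (or removed) conductance density until the classification flips;
  reported in mS/cm² and in nS/pF via the capacitance convention
  g[mS/cm²] = g[nS/pF]·C_spec[µF/cm²].

## Spike-initiation voltage

The operational threshold measurement bisects a 500 ms step to the
minimal spiking amplitude (0.1 µA/cm²) and reads the membrane potential
at which dV/dt crosses the 5 mV/ms criterion into the threshold crawl.
Under step stimulation the criterion must be applied on the
*deceleration* flank: the stimulus onset itself drives dV/dt to
I/C ≈ 33 mV/ms, so the first upward crossing of 5 mV/ms is an artifact
of the protocol, and the re-acceleration into the spike occurs only at
≈−21 mV, well above threshold. The deceleration crossing is stable at
−37.0 mV and brackets the instantaneous I–V knee of the model (≈−34 mV)
— the regenerative takeoff a slow approach would expose. For the base
cell this yields −36.95 mV.

## Synthetic cohorts

Cohorts draw each cell's added-Na density, added-K density, leak and
capacitance from log-normal distributions (median, CV; default
CV = 0.3 for conductances, 0.1 for passive parameters). Log-normals
guarantee positivity and right-skewed between-cell variability.
Defaults (mS/cm² medians): naive cutaneous gK = 2.5, naive muscle
gK = 1.0 — their ratio anchored to the measured ≈2.5:1 ratio of
perithreshold K-current densities in cutaneous vs muscle afferents —
and gNa = 0.3 for both. Against the measured boundary this puts the
median muscle cell 0.86 mS/cm² (0.43 nS/pF) from its tipping point and
the median cutaneous cell 2.71 mS/cm² (1.36 nS/pF) — both comfortably
below the boundary (naive cohorts essentially never convert
spontaneously), with muscle markedly closer, matching the ordering of
the recorded dynamic-clamp titrations.

The injury transform removes a log-normal fraction of each cell's
added-K conductance (median 0.5) and adds a log-normal Na density
(median 0.17 nS/pF); both draws are per-cell independent, and both
moves are monotone toward the Hopf-bearing regime, so no cell's
distance to tipping increases. The magnitudes are calibrated (see
`scripts/calibrate_cohorts.py`) so the median injured muscle cell lands
on its boundary — roughly half of an injured muscle cohort converts,
while injured cutaneous cohorts rarely convert but move measurably
closer to their tipping point. These defaults emulate the *directions
and orderings* of the recorded cohorts, not their per-cell conductance
values (which are not published); passing cohort-level tests shows the
pipeline recovers orderings under realistic heterogeneity, not that
real afferents carry these densities.

## Exact statistics

Fisher's exact test enumerates the hypergeometric support with
big-integer binomials and exact rational arithmetic; the two-sided p
sums all tables (fixed margins) whose point probability does not exceed
the observed one. Sidedness is not stated by the source experiments;
the two-sided point-probability convention is adopted because it
reproduces the printed p = 0.28 for the 1-of-9 vs 0-of-23 comparison
(0.28125; simple doubling would give 0.56). The Mann–Whitney U test
uses midranks, exact enumeration for pooled n ≤ 12 and the
tie-corrected normal approximation with continuity correction beyond;
the approximation tracks the exact branch to ≈0.02 at the crossover
(and matches the standard asymptotic implementation exactly). The
recorded conversion-count tables ship as named fixtures
(`stats.conversion_tables`); for the 6-of-9 vs 1-of-9 comparison the
exact two-sided p evaluates to 0.0498.

## Problem sizes

Default analysis sizes are desk-scale by design: bifurcation scans use
~80 stimulus samples with 1–1.2 s simulations for cycle measurements;
tipping maps default to modest grids (refinable by bisection to
0.01 mS/cm²); cohort demonstrations use 10–27 cells (the recorded
cohort sizes) with the eigenvalue classifier, and power-style replicate
checks use 100 replicates. All are parameters, not limits.

## Known limitations

* Single-compartment, density-based model: no axon, no morphology, no
  channel kinetics beyond first-order activation; pharmacology is
  represented purely as conductance scaling.
* Unstable limit-cycle branches are inferred, not computed; the
  bistable window's lower edge comes from attractor persistence at
  finite simulation length (1.2 s), which can misplace the SNLC by a
  fraction of the bisection tolerance for extremely long transients.
* The stimulus-range cap that defines "repetitive spiking possible" is
  a modeling convention (see above); conclusions near the cap inherit
  it.
* The normal-approximation branch of the Mann–Whitney test is the
  standard one; exactness holds only for pooled n ≤ 12.
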