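# Methods

This note documents the models and procedures implemented in `fetalmn`,
their assumptions, the parameters that matter, and the choices made where
the design was genuinely open.

## Scope and intent

The package reproduces, as testable code, the computational chain used to
study GABA/glycine inhibition of fetal (E17.5) mouse spinal motoneurons in
the SOD1^G93A ALS model: chloride physiology arithmetic, IPSC event
analysis, fictive-locomotion rhythm statistics, biophysical WT-like and
SOD-like motoneuron models with inhibitory train protocols, and a
half-center CPG model. Synthetic-data generators supply every input the
analysis stages need, with ground truth, so recovery can be quantified.

## Chloride homeostasis

The chloride reversal potential follows the Nernst relation for a
monovalent anion, `E_Cl = (RT/F) ln([Cl-]_i/[Cl-]_o)`, with defaults
`[Cl-]_o = 123.5 mM` (the summed chloride of the recording aCSF) and
`T = 303.15 K` (30 °C bath), giving RT/F ≈ 26.12 mV. A pure-chloride
assumption is used throughout: no bicarbonate term enters the GABA_A
reversal. Driving force is reported with the depolarizing convention
`DF = E_GABAAR − E_m`, so the fetal values are positive (22.6 mV SOD-type,
12.1 mV WT-type from the mean potentials). E_GABAAR from an agonist I/V
series is the zero-current crossing of an ordinary least-squares line; the
ramp-subtraction E_Cl is the linearly interpolated zero crossing of the
agonist-minus-control ramp current, with explicit errors for "no
crossing" and "multiple crossings" (all crossings reported). A
liquid-junction correction (3.3 mV in the reference chain) is never
applied implicitly; callers subtract it from voltages when appropriate.

Mean per-genotype intracellular chloride values reported for cohorts are
averages of per-cell Nernst inversions; since per-cell values are not
available they are treated as descriptive only, never as recovery targets.

## IPSC event analysis

Events are downward deflections in voltage-clamp at −70 mV; amplitudes are
reported as positive magnitudes. The detection baseline is a running
median over 200 ms; an onset is the first sample more than `threshold`
(default 15 pA) below it, with a 5 ms refractory and a hysteresis re-arm
at half the threshold so noise on a decay tail cannot re-trigger. The
decay time constant is a least-squares single-exponential fit; the fit
segment starts 2.5 ms (≈ two rise constants) after the peak because the
rising exponential biases a fit begun exactly at the peak by ≈ +0.3 ms,
an order of magnitude more than the fit's noise floor on clean events.
Fit quality `r_fit` is the Pearson correlation between fitted and observed
decay. The rising phase is fitted with a single-exponential approach to
peak, and the 10–90% rise time is exported as a robustness fallback.
Charge is reported only for well-fitted events (r_fit > 0.98) as
`A·(τ_d − τ_r)/norm`, the exact integral of the peak-normalized
dual-exponential template (`norm` is the template's raw peak value).
Events whose decay window contains the next onset are truncated there and
flagged. Population comparisons use the two-sample Kolmogorov-Smirnov test
(asymptotic p) for distributions and Mann-Whitney U for means.

## Locomotor rhythm analysis

The floating mean spike frequency is a centred sliding-window rate
(default window 0.5 s) that conserves total spike count. Burst starts are
upward crossings of `min + frac·(max − min)` (default frac 0.3) with 10%
hysteresis; the trough-crossing convention is ours, since the reference
analysis names no algorithm. Cycle period is the mean of successive
burst-start differences. Left-right phase assigns each right start the
fractional position within its containing left cycle; the circular mean
and resultant length r are summarized with the Rayleigh statistic
`Z = n r²` and the small-sample corrected tail probability
`p = exp(−Z)(1 + (2Z − Z²)/(4n))`. The correction term is an asymptotic
series; where it would turn negative (large Z) it is dropped, leaving the
exact leading term `exp(−Z)`.

## Motoneuron models

### Architecture

Each canonical cell is a tree of cylindrical sections: soma, four
symmetric dendrites (a primary plus a terminal section each), an axon
initial segment (AIS), and a long axon fixed at 750 segments. All other
sections are discretized by the d-lambda rule at 100 Hz (d_lambda = 0.1),
which always yields an odd compartment count. The SOD-like cell is
identical except its terminal dendrites are 60% of the WT length, which
raises its input resistance (the "more excitable" phenotype).

Passive properties: Rm = 21200 Ω·cm², E_leak = −73 mV everywhere,
Ra = 100 Ω·cm and cm = 1 µF/cm² (unstated in the reference; standard
values, exposed in config).

Channels: Hodgkin-Huxley Na/K on the axon (0.012 / 0.0036 S/cm²) and at
high density on the AIS (0.5 / 0.15 S/cm²); a Connor-Stevens A-current on
the AIS (0.0033 S/cm²); on the soma a high-threshold (L-type) Ca current
(8e-5 S/cm²), a Ca-dependent K current I_C (0.0025 S/cm²) and the calcium
pool. Equations are the canonical forms of each mechanism:

* HH rates are the classical squid functions with per-gate voltage shifts
  (m +3, h +5, n +10 mV): independent shifts let Na stay available at the
  depolarized operating point of a slowly firing cell while spike
  initiation remains near the measured −48 mV threshold — the standard
  adaptation when moving squid kinetics onto a motoneuron. E_Na = +50,
  E_K = −77 mV.
* I_A uses the Connor-Stevens a³b kinetics, reversing at E_K.
* I_L has one sigmoid activation gate (V½ −20 mV, slope 6, τ 2 ms) and an
  ohmic driving force with E_Ca from the pool via the Nernst relation.
* I_C activation is a first-order variable (τ 70 ms) relaxing to a Hill-4
  function of pool calcium (half-activation 1.5 µM). It produces the
  medium AHP that sets the slow (≈12.5 Hz) repetitive firing range; its
  two constants were calibrated to that operating point.

Calcium pool: a shell of depth 0.17 µm under the somatic membrane;
`d[Ca]/dt = −I_Ca/(2F·depth·area) − pump + ([Ca]_inf − [Ca])/τ_r` with
τ_r = 1e10 ms (leak-back effectively off), [Ca]_inf = 2e-4 mM, initial
[Ca] = 2.4e-4 mM, [Ca]_o = 3 mM. The Michaelis-Menten pump
(kt = 2.5e-4 mM/ms, kd = 1e-4 mM) acts on the *excess* over the resting
concentration, i.e. it is balanced by background influx at rest: with no
Ca current the pool stays exactly at its initial value, and any loaded
calcium is extruded at the stated saturating rate. (A pump acting on the
raw concentration would empty the pool at rest on a millisecond time
scale, contradicting the stated resting calcium.)

Synapses are conductance-based dual exponentials, peak-normalized so one
event reaches exactly `g_max`; events sum linearly. GABA/glycine kinetics:
τ_rise 0.3 ms, τ_decay 15–25 ms depending on protocol; excitatory kinetics
(0.1 / 10 ms) are available for the CPG followers.

### Numerical scheme

A theta-weighted implicit voltage step (theta = 0.5, Crank-Nicolson) with
a direct Hines (tree-tridiagonal) solve; gates advance with exact
exponential updates using the pre-step voltage (the staggered
interpretation that makes the pair second-order accurate), and the
calcium pool advances after the solve using the midpoint voltage.  The
scheme is unconditionally stable; at the fixed default dt = 0.025 ms,
halving dt shifts the early spike times of the standard discharge by
well under 0.1 ms (the residual ≈3e-4 relative period error accumulates
as phase drift over long trains, as for any fixed-step integrator).
Rate functions are evaluated through lookup tables on a 0.05 mV grid with
linear interpolation. No temperature (Q10) scaling is applied. The
integration kernel is numba-compiled; a divergence check rejects
non-finite voltages.

### Calibration

The reference morphometry is not published, so the canonical tree is
parameterized and was calibrated once against the printed constraints,
then frozen in the config defaults:

1. terminal dendrite length set so WT somatic input resistance is 120 MΩ
   (−10 pA step, steady-state ratio) — 418 µm at the default diameters;
2. AIS Na/K densities fixed at the printed 0.5 / 0.15 S/cm²; AIS geometry
   (50 × 4 µm) and the HH m-shift set so the slow-ramp spike threshold
   (first dV/dt = 10 mV/ms crossing, 0→400 pA over 2 s) is ≈ −48 mV;
3. the I_C constants set so 250 pA drives the WT cell at ≈ 12.5 Hz, the
   locomotor firing rate (200 pA for the SOD cell follows from its
   morphology; see Limitations);
4. the unitary GABA/glycine conductance `g_gaba_max` calibrated on the WT
   model against the reference train figure: the smallest conductance on
   a 0.001 µS grid for which the 71 Hz, τ_decay 25 ms, E −50 mV train
   silences the discharge completely *and* the matching τ_decay 20 ms
   train is inhibitory (below baseline). The minimal silencing
   conductance alone leaves the 20 ms train excitatory in this model,
   contradicting the reference behaviour (partial inhibition), so the
   second, qualitative condition is part of the calibration. The result,
   0.046 µS, is frozen and reused for both genotypes and all protocols.

### Train protocols

Tonic somatic current runs for the whole simulation; the periodic somatic
GABA/glycine train starts at t = 2 s (after rate stabilization) and lasts
4 s; rates are measured on [2.5 s, 6 s] and "silenced" means zero spikes
there. `calibrate_tonic` bisects the injected current to a target steady
rate (measured on [1, 2] s, 0.25 Hz tolerance). The cut-off frequency is
found on a coarse 5 Hz grid refined to 1 Hz; because silencing is monotone
in train frequency in every configuration examined, the default search
bisects both grids (identical result, about one third of the
simulations); `method="scan"` evaluates the full grid and warns if the
monotonicity assumption fails. Effect classification uses a ±0.5 Hz
neutral band around the no-train baseline. Trains are strictly periodic;
jittered trains are deliberately out of scope.

## Half-center CPG

Each half-center is a single-compartment pacemaker: fast Na (instantaneous
m∞³, inactivation slaved to the K gate as 1 − n), delayed-rectifier K, a
persistent Na current with slow inactivation (V½ −48 mV, slope 6,
τ_max 10 s), and a Ca-pool-driven K(Ca) current (Hill-2,
half-activation 1 µM, τ_pool 300 ms) fed by a high-threshold Ca current.
Cm 21 pF, g_leak 2.8 nS, E_leak −58 mV, E_K −85 mV. The constants the
reference leaves unstated were chosen so a single uncoupled cell bursts
with a period near 2 s — the scale of the biological rhythm
(1.88–2.01 s), used only for calibration, never as validation. Reciprocal
inhibition uses the same peak-normalized dual-exponential conductance,
triggered on presynaptic upward 0 mV crossings (2 ms refractory); followers
are optional single-compartment spiking cells receiving fast excitation
and are excluded from period measurement. Asymmetric initial conditions
select the anti-phase attractor; the integration (backward-Euler voltage,
exponential gates, dt 0.05 ms) is fully deterministic. Period is the mean
left-cell inter-burst-onset interval after discarding the first five
bursts (burst onset = first spike after ≥ 0.3 s silence).

At E_Cl = −60 mV the rhythm slows monotonically as the IPSC τ_decay grows
from 15 to 30 ms, for both 0.04 and 0.2 µS coupling; at E_Cl = −50 mV the
slope collapses to roughly a tenth of the −60 mV value. Phase locks at
0.50 at −60 mV; with the depolarized, weakly inhibiting synapse
(−50 mV / 0.2 µS) the locking deviates from exact anti-phase (≈ 0.3), a
known behaviour of weakly coupled half-centers.

## Synthetic data

The IPSC generator emulates the recording chain: Poisson event times
(exponential IEIs), lognormal amplitudes (only means are constrained; CV
default 0.4), fixed dual-exponential kinetics per preset, Gaussian noise,
20 kHz sampling and a 2 kHz 4-pole Butterworth (zero-phase) filter, plus
optional tonic holding-current steps. Presets carry the measured summary
statistics of WT/SOD miniature and spontaneous IPSCs and of the
locomotor rhythm (periods 1.88/2.01 s, phase ≈ 0.5). The burst generator
jitters cycle starts with Gaussian noise (default 2% of the period). All
generators are seed-deterministic. What the generators do *not* emulate:
electrode/series-resistance artifacts, amplitude-kinetics correlations,
event rundown, bursty (non-Poisson) event timing and non-stationary
rhythms — so recovery results bound pipeline error under the stated
model, not under every pathology of real recordings.

## Problem sizes

Default analysis checks use 100 s synthetic traces (≈ 113–120 events at
miniature-IPSC rates), 50–100 noise seeds for Monte-Carlo recovery, 60 s
CPG runs (≈ 25–30 cycles), and 6 s motoneuron train simulations; these
sizes give stable estimates for every quantity tested while keeping a
full run of the suite practical on one CPU.

## Known limitations

* The reference model's morphometry and full rate equations are not
  published; this implementation uses the canonical mechanism forms with
  its own calibrated morphometry. Printed emergent quantities (train
  rates, cut-off frequencies) are reproduced within tolerance bands, not
  exactly.
* The SOD model under the fixed 200 pA drive fires ≈ 10.5–11 Hz rather
  than 12.5 Hz: with all shared parameters frozen by WT constraints, the
  terminal-dendrite scaling alone does not make the SOD cell excitable
  enough for the printed current to reach the printed rate while the
  train responses stay in their bands. The discrepancy and the trade-off
  are deliberate; see the repository's test suite for the exact bands.
* Low-frequency hyperpolarizing trains (E −60 mV at 15–20 Hz) slow this
  model strongly but do not silence it completely: the soma recovers
  between events (τ_m ≈ 21 ms against ≈ 45 ms of free gap), so the
  cut-off frequency at E −60 mV is ≈ 40 Hz rather than ≤ 20 Hz. Making
  sodium-inactivation accommodation strong enough to hold the silenced
  state also abolishes the 12.5 Hz baseline under this channel family,
  so the slow-firing calibration was kept and the low-frequency blocking
  left as a known gap.
* Rate measurements quantize at 1/window (0.29 Hz for the 3.5 s train
  window), which bounds how precisely any rate target can be matched.
* The event detector is a threshold detector, not a matched filter; very
  small or strongly overlapping events are missed or truncated (flagged).
* The CPG is two cells, not a population network; its periods are
  model-intrinsic and are validated only through the property suite
  (alternation, monotone τ_decay dependence, attenuation at depolarized
  E_Cl).
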