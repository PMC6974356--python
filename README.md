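# fetalmn

Inhibition physiology of fetal spinal motoneurons, as reusable, tested
Python: chloride homeostasis arithmetic, GABA/glycine IPSC analysis,
fictive-locomotion rhythm statistics, biophysical WT-like and SOD1-like
motoneuron models with inhibitory-train protocols, and a half-center
locomotor CPG model — together with seeded synthetic-data generators for
every input the analyses consume.

## The scientific problem

In the SOD1^G93A mouse model of ALS, fetal (E17.5) spinal motoneurons show
a depolarized chloride reversal potential (E_GABAAR ≈ −50 mV vs −60 mV in
wild type, from reduced KCC2 efficacy) — which weakens GABA/glycine
inhibition — but also a *slower* IPSC decay (τ_decay ≈ 20.5 vs 16 ms).
The central question is quantitative: can slower synaptic decay compensate
for the weakened driving force? The package implements the computational
tools used to answer it:

* **Chloride arithmetic** — `E_Cl = (RT/F)·ln([Cl⁻]ᵢ/[Cl⁻]ₒ)` and its
  inverse, driving force `DF = E_GABAAR − E_m`, E_GABAAR from I/V linear
  fits, and E_Cl from ramp-subtraction protocols.
* **IPSC analysis** — event detection, single-exponential τ_rise/τ_decay
  fits, charge for well-fitted events (R > 0.98), tonic-current shifts,
  Kolmogorov-Smirnov / Mann-Whitney comparisons.
* **Locomotor rhythm** — floating mean spike frequency, burst starts,
  cycle period, left-right phase with the Rayleigh test
  (Z = n·r², small-sample corrected p).
* **Motoneuron models** — multi-compartment WT-like and SOD-like cells
  (identical except terminal dendrites at 60% length in SOD), HH Na/K
  axon/AIS, A-current, Ca pool with I_L and I_K(Ca), calibrated to
  Rin = 120 MΩ and spike threshold −48 mV (WT), integrated with an
  implicit Hines scheme (numba).
* **Inhibition protocols** — tonic-drive calibration to the 12.5 Hz
  locomotor rate, periodic GABA/Gly trains, event-rate/firing-rate
  curves, and the cut-off frequency (minimal train rate that silences
  the cell).
* **Half-center CPG** — two reciprocally inhibiting I_NaP/I_K(Ca)
  pacemakers; rhythm period as a function of IPSC τ_decay, E_Cl and
  coupling strength.

## Worked example

```python
import fetalmn as f

# Chloride physiology of the two genotypes.
for label, e_gaba, e_m in [("WT", -62.0, -74.1), ("SOD", -50.5, -73.1)]:
    print(label, round(f.cl_in_from_ecl(e_gaba), 1), "mM,",
          round(f.driving_force(e_gaba, e_m), 1), "mV")
# WT 11.5 mM, 12.1 mV
# SOD 17.9 mM, 22.6 mV

# IPSC analysis on a synthetic SOD-like recording.
trace, truth = f.synth.gen_ipsc_trace(
    f.synth.preset("SOD-mIPSC", seed=7, duration=100.0))
events = f.analyze_trace(trace)
print(round(events.to_frame().tau_decay_ms.median(), 2))   # 20.61
```

The analysis recovers the generating decay constant (20.53 ms) to within
half a percent on a clean 100 s trace. The `examples/` directory
holds one short narrative script per capability
(`chloride_physiology.py`, `ipsc_analysis.py`, `locomotor_rhythm.py`,
`mn_inhibition.py`, `cpg_rhythm.py`); each builds a small input, runs the
method and prints what the numbers mean. The biophysical examples take a
few minutes; the analysis examples run in seconds.

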