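"""Fictive-locomotion analysis: period, left-right phase, Rayleigh test.

Builds synthetic alternating left/right ventral-root spike trains with a
2.01 s cycle (the SOD-like rhythm) and runs the full analysis chain:
spike-frequency envelope, burst-start detection, cycle period and circular
phase statistics.
"""

import fetalmn as f

left_spikes, right_spikes, truth = f.synth.gen_burst_spike_trains(
    f.synth.preset("SOD-locomotion", seed=3, duration=100.0))

bursts = {}
for side, spikes in (("left", left_spikes), ("right", right_spikes)):
    env = f.mean_frequency_envelope(spikes, window=0.5)
    bursts[side] = f.detect_burst_starts(env, frac=0.3, side=side)

period, sd = f.cycle_period(bursts["left"])
res = f.phase_and_rayleigh(bursts["left"], bursts["right"])
print(f"cycle period : {period:.3f} ± {sd:.3f} s "
      f"(generator {truth['period']} s)")
print(f"L-R phase    : {res.mean_phase:.3f} (generator {truth['phase']}; "
      "0.5 = strict alternation)")
print(f"Rayleigh     : r = {res.r:.3f}, p = {res.rayleigh_p:.2e} over "
      f"{res.n} cycles")
# A phase near 0.5 with small Rayleigh p confirms significant left-right
# alternation, as seen in both genotypes.
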