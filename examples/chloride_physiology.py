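"""Chloride homeostasis arithmetic on synthetic recordings.

Converts measured GABA_A reversal potentials to intracellular chloride,
computes driving forces, and recovers reversal potentials from a synthetic
agonist I/V series and a voltage-ramp subtraction protocol.
"""

import fetalmn as f

ctx = f.ChlorideContext()           # 123.5 mM bath chloride, 30 °C

# Mean reversal potentials of fetal WT and SOD1 motoneurons.
for label, e_gaba, e_m in [("WT", -62.0, -74.1), ("SOD", -50.5, -73.1)]:
    cl_in = f.cl_in_from_ecl(e_gaba, ctx)
    df = f.driving_force(e_gaba, e_m)
    print(f"{label}: E_GABAAR {e_gaba:6.1f} mV -> [Cl-]i {cl_in:5.1f} mM, "
          f"driving force {df:+5.1f} mV")
# A positive driving force means GABA/glycine depolarizes the cell from
# rest; the SOD-type cell sits ~10 mV more depolarized.

iv = f.synth.gen_iv_series(e_rev=-61.4, slope=2.0,
                           holdings=[-70, -60, -50, -40],
                           noise_sd=2.0, seed=1)
print(f"I/V linear fit reversal: {f.fit_reversal(iv):.1f} mV "
      "(generator used -61.4 mV)")

ramp = f.synth.gen_ramp_pair(e_agonist=-49.0, noise_sd=0.0, seed=1)
print(f"Ramp-subtraction E_Cl: {f.ramp_subtraction_ecl(ramp):.1f} mV "
      "(pipette-imposed -49 mV)")
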