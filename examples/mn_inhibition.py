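"""Inhibitory-train protocol on the biophysical motoneuron models.

Builds the canonical WT-like and SOD-like motoneurons, verifies their
passive calibration, then delivers the reference 71 Hz GABA/glycine train
(tau_decay 20 vs 25 ms, E_GABAAR -50 mV) on top of the ~12.5 Hz locomotor
discharge.  Slower IPSC decay turns a partial rate reduction into complete
blockade — the compensation effect.

Runtime: a few minutes (eight 6-second biophysical simulations).
"""

import fetalmn as f
from fetalmn.protocols import TrainProtocol, rate_under_train

models = {"WT": (f.build_canonical_mn("WT"), 250.0),
          "SOD": (f.build_canonical_mn("SOD"), 200.0)}

for name, (model, tonic) in models.items():
    rin = f.measure_rin(model)
    print(f"{name}: input resistance {rin:.0f} MOhm", end="")
    if name == "WT":
        print(f", spike threshold {f.measure_spike_threshold(model):.1f} mV")
    else:
        print()

for name, (model, tonic) in models.items():
    base = rate_under_train(model, TrainProtocol(
        freq=0.0, tonic_current=tonic))
    print(f"\n{name} at {tonic:.0f} pA: baseline discharge {base:.1f} Hz")
    for tau in (20.0, 25.0):
        rate = rate_under_train(model, TrainProtocol(
            freq=71.0, tau_decay=tau, e_gaba=-50.0, tonic_current=tonic))
        label = "silenced" if rate == 0 else f"{rate:.2f} Hz"
        print(f"  71 Hz train, tau_decay {tau:.0f} ms, E -50 mV -> {label}")
# Increasing tau_decay from 20 to 25 ms strengthens inhibition enough to
# block the discharge completely despite the depolarized reversal.
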