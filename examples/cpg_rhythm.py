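"""Half-center CPG: locomotor period as a function of IPSC decay.

Two reciprocally inhibiting I_NaP/I_K(Ca) pacemakers alternate in
anti-phase.  Slowing the IPSC decay lengthens the locomotor period when
E_Cl is hyperpolarized (-60 mV); with a depolarized E_Cl (-50 mV) the same
change has a much smaller effect.
"""

from fetalmn.cpg import build_halfcenter, period_vs_taudecay

TAUS = [15, 20, 25, 30]

for g_inh, e_cl in [(0.04, -60.0), (0.2, -60.0), (0.2, -50.0)]:
    net = build_halfcenter(g_inh=g_inh, e_cl=e_cl)
    results = period_vs_taudecay(net, TAUS, tstop=60)
    print(f"g_inh {g_inh} µS, E_Cl {e_cl:.0f} mV:")
    for tau, r in zip(TAUS, results):
        print(f"  tau_decay {tau:2d} ms -> period {r.period:.2f} s, "
              f"phase {r.phase:.2f}")
    slope = results[-1].period - results[0].period
    print(f"  period change across 15->30 ms: {slope:+.3f} s")
# The period grows with tau_decay at E_Cl -60 mV for both conductances;
# at -50 mV the slope collapses to a small fraction of the -60 mV value.
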