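"""Implicit compartmental integrator (numba kernel).

Each step advances the cable equation on the whole tree with a
theta-weighted implicit scheme (theta = 0.5, Crank-Nicolson, by default;
theta = 1 gives backward Euler): gating variables and the somatic calcium
pool are updated first from the current voltage (exponential updates,
exact for frozen rates), then all membrane currents are linearized about
the new states and the voltage system — symmetric, tridiagonal on the
tree — is solved directly with the two-pass Hines elimination.  The
scheme is unconditionally stable; at theta = 0.5 the voltage step is
second-order accurate, which keeps spike-time drift under dt refinement
far below the spike width.

Units: mV, ms, nF, µS, nA, MΩ, mM.  Conductance densities are converted to
absolute µS per compartment before entering the kernel.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .channels import VMIN, VSTEP

__all__ = ["integrate"]

FARADAY = 96485.332  # C/mol
RT2F_30C = 13.061    # RT/2F at 303.15 K, mV


@njit(cache=True, fastmath=True)
def _lookup(tab, v):
    idx = (v - VMIN) / VSTEP
    i = int(idx)
    if i < 0:
        i = 0
    if i > tab.size - 2:
        i = tab.size - 2
    f = idx - i
    if f < 0.0:
        f = 0.0
    if f > 1.0:
        f = 1.0
    return tab[i] + f * (tab[i + 1] - tab[i])


@njit(cache=True, fastmath=True)
def _kernel(nsteps, dt, theta,
            parent, g_ax, cm, gl, el,
            gna, gk, gia, gic, gil,
            ca_gain, kt, kd, ca0, cainf, taur, cao, kc, tau_o,
            ena, ek,
            m_inf, m_fac, h_inf, h_fac, n_inf, n_fac,
            a_inf, a_fac, b_inf, b_fac, l_inf, l_fac,
            syn_comp, syn_gw, syn_er, syn_ed, syn_e,
            ev_step, ev_syn, ev_w,
            inj_comp, inj,
            rec_comps, v_out, g_out, ca_out):
    n = parent.size
    ns = syn_comp.size
    ne = ev_step.size
    nr = rec_comps.size

    v = np.empty(n)
    m = np.zeros(n)
    h = np.zeros(n)
    nn = np.zeros(n)
    a = np.zeros(n)
    b = np.zeros(n)
    l = np.zeros(n)
    o = np.zeros(n)
    ca = np.empty(n)
    for i in range(n):
        v[i] = el
        m[i] = _lookup(m_inf, el)
        h[i] = _lookup(h_inf, el)
        nn[i] = _lookup(n_inf, el)
        a[i] = _lookup(a_inf, el)
        b[i] = _lookup(b_inf, el)
        l[i] = _lookup(l_inf, el)
        ca[i] = ca0
    sa = np.zeros(ns)
    sb = np.zeros(ns)
    o_fac = np.exp(-dt / tau_o)

    d = np.empty(n)
    rhs = np.empty(n)
    v_prev = np.empty(n)

    for r in range(nr):
        v_out[0, r] = v[rec_comps[r]]
    g_out[0] = 0.0
    ca_out[0] = ca0

    ev_ptr = 0
    for step in range(nsteps):
        # Scheduled synaptic events at the start of this step.
        while ev_ptr < ne and ev_step[ev_ptr] == step:
            k = ev_syn[ev_ptr]
            sa[k] += ev_w[ev_ptr]
            sb[k] += ev_w[ev_ptr]
            ev_ptr += 1
        for k in range(ns):
            sa[k] *= syn_er[k]
            sb[k] *= syn_ed[k]

        g_syn_rec = 0.0
        i_amp = inj[step]
        for i in range(n):
            v_prev[i] = v[i]

        for i in range(n):
            vi = v[i]
            # Gate updates (exponential, exact for frozen rates).
            if gna[i] > 0.0:
                fm = _lookup(m_fac, vi)
                m[i] = m[i] * fm + _lookup(m_inf, vi) * (1.0 - fm)
                fh = _lookup(h_fac, vi)
                h[i] = h[i] * fh + _lookup(h_inf, vi) * (1.0 - fh)
                fn = _lookup(n_fac, vi)
                nn[i] = nn[i] * fn + _lookup(n_inf, vi) * (1.0 - fn)
            if gia[i] > 0.0:
                fa = _lookup(a_fac, vi)
                a[i] = a[i] * fa + _lookup(a_inf, vi) * (1.0 - fa)
                fb = _lookup(b_fac, vi)
                b[i] = b[i] * fb + _lookup(b_inf, vi) * (1.0 - fb)

            gtot = gl[i]
            bb = cm[i] / dt * vi + gl[i] * el
            eca = 0.0

            if gil[i] > 0.0 or gic[i] > 0.0:
                fl = _lookup(l_fac, vi)
                l[i] = l[i] * fl + _lookup(l_inf, vi) * (1.0 - fl)
                eca = RT2F_30C * np.log(cao / ca[i])
                x = (ca[i] / kc) ** 4
                oinf = x / (1.0 + x)
                o[i] = o[i] * o_fac + oinf * (1.0 - o_fac)
                gi_l = gil[i] * l[i]
                gi_c = gic[i] * o[i]
                gtot += gi_l + gi_c
                bb += gi_l * eca + gi_c * ek
            if gna[i] > 0.0:
                g_na = gna[i] * m[i] * m[i] * m[i] * h[i]
                g_k = gk[i] * nn[i] ** 4
                gtot += g_na + g_k
                bb += g_na * ena + g_k * ek
            if gia[i] > 0.0:
                g_a = gia[i] * a[i] * a[i] * a[i] * b[i]
                gtot += g_a
                bb += g_a * ek

            d[i] = cm[i] / dt + theta * gtot
            rhs[i] = bb - (1.0 - theta) * gtot * vi

        for k in range(ns):
            gsk = syn_gw[k] * (sb[k] - sa[k])
            if gsk < 0.0:
                gsk = 0.0
            i = syn_comp[k]
            d[i] += theta * gsk
            rhs[i] += gsk * syn_e[k] - (1.0 - theta) * gsk * v[i]
            g_syn_rec += gsk

        if inj_comp >= 0:
            rhs[inj_comp] += i_amp

        # Axial coupling (theta-weighted implicit part plus the explicit
        # remainder evaluated at the old voltage) and Hines solve.
        for i in range(1, n):
            if g_ax[i] > 0.0:
                p = parent[i]
                ga = theta * g_ax[i]
                d[i] += ga
                d[p] += ga
                flow = (1.0 - theta) * g_ax[i] * (v[p] - v[i])
                rhs[i] += flow
                rhs[p] -= flow
        for i in range(n - 1, 0, -1):
            if g_ax[i] > 0.0:
                p = parent[i]
                ga = theta * g_ax[i]
                f = ga / d[i]
                d[p] -= f * ga
                rhs[p] += f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            if g_ax[i] > 0.0:
                v[i] = (rhs[i] + theta * g_ax[i] * v[parent[i]]) / d[i]
            else:
                v[i] = rhs[i] / d[i]

        # Calcium pool and AHP activation advance with the new voltage
        # (staggered with the voltage solve): influx from I_L, pump on the
        # excess over rest, slow leak toward cainf (off when taur is huge).
        for i in range(n):
            if gil[i] > 0.0 or gic[i] > 0.0:
                eca = RT2F_30C * np.log(cao / ca[i])
                v_mid = 0.5 * (v_prev[i] + v[i])
                i_l = gil[i] * l[i] * (v_mid - eca)       # nA, inward < 0
                drive = -ca_gain[i] * i_l
                if drive < 0.0:
                    drive = 0.0
                excess = ca[i] - ca0
                pump = 0.0
                if excess > 0.0:
                    pump = kt * excess / (excess + kd)
                ca[i] += dt * (drive - pump + (cainf - ca[i]) / taur)
                if ca[i] < 1e-12:
                    ca[i] = 1e-12

        for r in range(nr):
            v_out[step + 1, r] = v[rec_comps[r]]
        g_out[step + 1] = g_syn_rec
        ca_out[step + 1] = ca[0]

    return 0


def integrate(nsteps: int, dt: float, arrays: dict, tables: dict,
              synapses: dict, injection: dict, rec_comps) -> dict:
    """Run the compartmental kernel; see the module docstring for units.

    ``arrays`` carries the per-compartment tables, ``tables`` the gate
    lookup tables from :func:`..channels.build_gate_tables`, ``synapses``
    the event-driven dual-exponential synapse arrays and ``injection`` a
    per-step current waveform (nA) for one compartment.  Returns recorded
    voltages (mV), the total synaptic conductance (µS) and the calcium
    concentration of compartment 0's pool holder (mM).
    """
    rec_comps = np.asarray(rec_comps, dtype=np.int32)
    v_out = np.empty((nsteps + 1, rec_comps.size))
    g_out = np.empty(nsteps + 1)
    ca_out = np.empty(nsteps + 1)
    _kernel(
        nsteps, dt, arrays.get("theta", 0.5),
        arrays["parent"], arrays["g_ax"], arrays["cm"], arrays["gl"],
        arrays["el"],
        arrays["gna"], arrays["gk"], arrays["gia"], arrays["gic"],
        arrays["gil"],
        arrays["ca_gain"], arrays["kt"], arrays["kd"], arrays["ca0"],
        arrays["cainf"], arrays["taur"], arrays["cao"], arrays["kc"],
        arrays["tau_o"],
        arrays["ena"], arrays["ek"],
        tables["m"][0], tables["m"][1], tables["h"][0], tables["h"][1],
        tables["n"][0], tables["n"][1], tables["a"][0], tables["a"][1],
        tables["b"][0], tables["b"][1], tables["l"][0], tables["l"][1],
        synapses["comp"], synapses["gw"], synapses["er"], synapses["ed"],
        synapses["e"],
        synapses["ev_step"], synapses["ev_syn"], synapses["ev_w"],
        injection["comp"], injection["waveform"],
        rec_comps, v_out, g_out, ca_out)
    if not np.all(np.isfinite(v_out)):
        raise FloatingPointError("simulation diverged (non-finite voltage)")
    return {"v": v_out, "g_syn": g_out, "ca": ca_out}
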