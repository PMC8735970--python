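"""Numba core of the stochastic simulation engine.

One jitted direct-method (Gillespie) kernel serves every simulation mode:
grid sampling, stop-at-threshold shots for forward flux sampling, absorbing
OFF-state detection, and time-weighted accumulation of promoter occupancy
and mRNA profiles binned by total protein (transition-path statistics).

Channels are at most bimolecular with distinct reactants, so every propensity
is ``rate * count_A [* count_B]``.  The kernel seeds numba's RNG itself; the
Python wrappers derive independent sub-seeds per segment/run so ensembles are
reproducible and order-independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the kernel
REACHED_T_END = 0
HIT_LOW = 1        # order parameter (total protein) fell to c_lo (+ M==0 if required)
HIT_HIGH = 2       # order parameter rose back to c_hi
ABSORBED = 3       # total propensity zero
MAX_EVENTS = 4     # event budget exhausted (caller should continue)


@njit(cache=True)
def ssa_kernel(state, rates, re_idx, stoich, t0, t_end, seed,
               sample_times, sample_start, samples_out,
               w_prot, m_idx, stop_mode, c_lo, c_hi, require_m_zero,
               acc, acc_on, acc_binw, w_own, tgt_idx, max_events):
    """Run the direct method from ``t0`` until ``t_end`` or a stop condition.

    state        : int64[n_sp], modified in place
    rates        : float64[n_ch] rate constants (piecewise-constant segment)
    re_idx       : int64[n_ch, 2] reactant species indices (-1 = none)
    stoich       : int64[n_ch, n_sp]
    sample_times : float64[:] grid times inside [t0, t_end]; states recorded
                   into samples_out starting at row sample_start
    w_prot       : float64[n_sp]; total protein = w_prot . state
    stop_mode    : 0 none, 1 stop on total protein <= c_lo or >= c_hi
    require_m_zero : if nonzero, the low stop also requires state[m_idx] == 0
    acc          : float64[n_bins, 4] time-weighted (dt, own_occ*dt,
                   n_target_bound*dt, M*dt) per total-protein bin of width
                   acc_binw (only if acc_on)
    Returns (t, status, events, next_sample_index, min_protein).
    """
    np.random.seed(seed)
    n_ch = rates.shape[0]
    n_samp = sample_times.shape[0]
    k_samp = sample_start
    t = t0
    events = 0
    a = np.empty(n_ch)

    prot = 0.0
    for i in range(state.shape[0]):
        prot += w_prot[i] * state[i]
    min_prot = prot

    status = REACHED_T_END
    while True:
        # stop conditions evaluated on the current (post-event) state
        if stop_mode == 1:
            if prot <= c_lo and (require_m_zero == 0 or state[m_idx] == 0):
                status = HIT_LOW
                break
            if prot >= c_hi:
                status = HIT_HIGH
                break

        # propensities
        a_tot = 0.0
        for k in range(n_ch):
            ak = rates[k]
            i0 = re_idx[k, 0]
            if i0 >= 0:
                ak *= state[i0]
                i1 = re_idx[k, 1]
                if i1 >= 0:
                    ak *= state[i1]
            a[k] = ak
            a_tot += ak

        if a_tot <= 0.0:
            # absorbing: state constant for the rest of the segment
            while k_samp < n_samp:
                for i in range(state.shape[0]):
                    samples_out[k_samp, i] = state[i]
                k_samp += 1
            t = t_end
            status = ABSORBED
            break

        tau = -np.log(1.0 - np.random.random()) / a_tot
        t_new = t + tau
        if t_new >= t_end:
            # record remaining grid points with the current state
            while k_samp < n_samp and sample_times[k_samp] <= t_end:
                for i in range(state.shape[0]):
                    samples_out[k_samp, i] = state[i]
                k_samp += 1
            if acc_on == 1:
                b = int(prot / acc_binw)
                if b >= acc.shape[0]:
                    b = acc.shape[0] - 1
                dt = t_end - t
                own = 0.0
                for i in range(state.shape[0]):
                    own += w_own[i] * state[i]
                acc[b, 0] += dt
                acc[b, 1] += dt * own
                acc[b, 2] += dt * state[tgt_idx]
                acc[b, 3] += dt * state[m_idx]
            t = t_end
            status = REACHED_T_END
            break

        # grid samples inside [t, t_new)
        while k_samp < n_samp and sample_times[k_samp] < t_new:
            for i in range(state.shape[0]):
                samples_out[k_samp, i] = state[i]
            k_samp += 1

        if acc_on == 1:
            b = int(prot / acc_binw)
            if b >= acc.shape[0]:
                b = acc.shape[0] - 1
            own = 0.0
            for i in range(state.shape[0]):
                own += w_own[i] * state[i]
            acc[b, 0] += tau
            acc[b, 1] += tau * own
            acc[b, 2] += tau * state[tgt_idx]
            acc[b, 3] += tau * state[m_idx]

        # channel selection by cumulative sum
        r = np.random.random() * a_tot
        c = 0.0
        kk = n_ch - 1
        for k in range(n_ch):
            c += a[k]
            if r < c:
                kk = k
                break

        for i in range(state.shape[0]):
            state[i] += stoich[kk, i]
        t = t_new
        events += 1

        prot = 0.0
        for i in range(state.shape[0]):
            prot += w_prot[i] * state[i]
        if prot < min_prot:
            min_prot = prot

        if events >= max_events:
            status = MAX_EVENTS
            break

    return t, status, events, k_samp, min_prot
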