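"""Compiled trajectory kernel for the case-study fitting objective.

Basin-hopping least squares evaluates the model trajectory for hundreds of
thousands of parameter vectors, so the inner fixed-step RK4 loop is
compiled with numba when available.  The pure-numpy implementation in
``case_study`` remains the reference; the two paths are asserted equal in
the test suite.  The module layout is encoded positionally: per module a
target gene, up to ``P`` activator/deactivator inputs (padded, with counts),
the matching edge columns for the Michaelis-Menten constants, a type sign
and a binding mode.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@njit(cache=True)
def _rhs(state, alpha, rho, kvals, betas, delta, hill,
         mt, mc, mr, mb, a_idx, a_edge, a_n, d_idx, d_edge, d_n, deriv):
    S, n2 = state.shape
    n = alpha.size
    M = mt.size
    for s in range(S):
        # production rates accumulate in deriv[:, :n] before degradation
        for g in range(n):
            deriv[s, g] = alpha[g]
        for m in range(M):
            if mr[m] == 0:
                act = 1.0
                for p in range(a_n[m]):
                    y = state[s, n + a_idx[m, p]]
                    if y < 0.0:
                        y = 0.0
                    nu = (y / kvals[a_edge[m, p]]) ** hill
                    act *= nu / (1.0 + nu)
                for p in range(d_n[m]):
                    y = state[s, n + d_idx[m, p]]
                    if y < 0.0:
                        y = 0.0
                    nu = (y / kvals[d_edge[m, p]]) ** hill
                    act *= 1.0 / (1.0 + nu)
            else:
                p_a = 1.0
                for p in range(a_n[m]):
                    y = state[s, n + a_idx[m, p]]
                    if y < 0.0:
                        y = 0.0
                    p_a *= (y / kvals[a_edge[m, p]]) ** hill
                if d_n[m] == 0:
                    act = p_a / (1.0 + p_a)
                else:
                    p_d = 1.0
                    for p in range(d_n[m]):
                        y = state[s, n + d_idx[m, p]]
                        if y < 0.0:
                            y = 0.0
                        p_d *= (y / kvals[d_edge[m, p]]) ** hill
                    act = p_a / (1.0 + p_a + p_a * p_d)
            deriv[s, mt[m]] += mc[m] * betas[mb[m]] * act
        for g in range(n):
            rate = deriv[s, g]
            if rate < 0.0:
                rate = 0.0
            x = state[s, g]
            if x < 0.0:
                x = 0.0
            y = state[s, n + g]
            if y < 0.0:
                y = 0.0
            deriv[s, g] = rate - delta[g] * x
            deriv[s, n + g] = rho[g] * (x - y)


@njit(cache=True)
def simulate_rk4(ics, times, n_steps_per_unit, alpha, rho, kvals, betas, hill,
                 mt, mc, mr, mb, a_idx, a_edge, a_n, d_idx, d_edge, d_n):
    """Fixed-step RK4 trajectories for all sets; returns ``S x T x n`` mRNA."""
    S = ics.shape[0]
    n = alpha.size
    T = times.size
    delta = alpha.copy()
    for m in range(mt.size):
        delta[mt[m]] += betas[mb[m]]
    state = ics.copy()
    k1 = np.empty_like(state)
    k2 = np.empty_like(state)
    k3 = np.empty_like(state)
    k4 = np.empty_like(state)
    out = np.empty((S, T, n))
    for s in range(S):
        for g in range(n):
            v = state[s, g]
            out[s, 0, g] = v if v > 0.0 else 0.0
    t = times[0]
    for t_idx in range(1, T):
        span = times[t_idx] - t
        n_sub = int(np.ceil(span * n_steps_per_unit))
        if n_sub < 1:
            n_sub = 1
        h = span / n_sub
        for _ in range(n_sub):
            _rhs(state, alpha, rho, kvals, betas, delta, hill,
                 mt, mc, mr, mb, a_idx, a_edge, a_n, d_idx, d_edge, d_n, k1)
            _rhs(state + (h / 2.0) * k1, alpha, rho, kvals, betas, delta, hill,
                 mt, mc, mr, mb, a_idx, a_edge, a_n, d_idx, d_edge, d_n, k2)
            _rhs(state + (h / 2.0) * k2, alpha, rho, kvals, betas, delta, hill,
                 mt, mc, mr, mb, a_idx, a_edge, a_n, d_idx, d_edge, d_n, k3)
            _rhs(state + h * k3, alpha, rho, kvals, betas, delta, hill,
                 mt, mc, mr, mb, a_idx, a_edge, a_n, d_idx, d_edge, d_n, k4)
            state = state + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = times[t_idx]
        for s in range(S):
            for g in range(n):
                v = state[s, g]
                out[s, t_idx, g] = v if v > 0.0 else 0.0
    return out
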