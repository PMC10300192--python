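"""Independent numerical oracles used by the tests.

The fixed-step RK4 integrator re-implements the growth/death/consumption
equations directly in plain Python, deliberately sharing no code with the
package's solver path.
"""

from __future__ import annotations

import math


def rk4_simulate(n0, d0, g0, k_p, k_d, v, theta, g_star, g_min, k_bys, g_in,
                 t_end=4.0, dt=1e-4, sample_every=None):
    """Classic fixed-step 4th-order Runge-Kutta on the three-state system.

    Returns (times, N, D, G) lists sampled every ``sample_every`` steps
    (default: every 0.125 days).
    """
    if sample_every is None:
        sample_every = max(1, round(0.125 / dt))

    def deriv(t, n, d, g):
        n = max(n, 0.0)
        d = max(d, 0.0)
        g = max(g, 0.0)
        g_acs = g / (1.0 + g_in * n)
        s_d = (1.0 - g_acs / (g_acs + g_min)) * math.tanh(t)
        s_p = 1.0 - s_d
        total = n + d
        bys = d / total if total > 0 else 0.0
        death = k_d * n * s_d + k_bys * n * bys
        dn = k_p * n * (1.0 - n / theta) * s_p - death
        dd = death
        dg = -v * n * g_acs / (g_acs + g_star)
        return dn, dd, dg

    n, d, g = float(n0), float(d0), float(g0)
    t = 0.0
    n_steps = round(t_end / dt)
    times, ns, ds, gs = [0.0], [n], [d], [g]
    for step in range(1, n_steps + 1):
        k1 = deriv(t, n, d, g)
        k2 = deriv(t + dt / 2, n + dt / 2 * k1[0], d + dt / 2 * k1[1], g + dt / 2 * k1[2])
        k3 = deriv(t + dt / 2, n + dt / 2 * k2[0], d + dt / 2 * k2[1], g + dt / 2 * k2[2])
        k4 = deriv(t + dt, n + dt * k3[0], d + dt * k3[1], g + dt * k3[2])
        n += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        d += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        g += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        g = max(g, 0.0)
        t = step * dt
        if step % sample_every == 0:
            times.append(t)
            ns.append(n)
            ds.append(d)
            gs.append(g)
    return times, ns, ds, gs


def logistic(n0, k_p, theta, t):
    """Closed-form logistic growth N(t) = theta n0 e^{kt} / (theta + n0 (e^{kt} - 1))."""
    e = math.exp(k_p * t)
    return theta * n0 * e / (theta + n0 * (e - 1.0))
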