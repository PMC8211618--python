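"""Numba kernels for Euler-Maruyama diffusion walks.

All times are in seconds inside the kernels.  Each kernel seeds numba's
internal RNG from an explicit integer so that runs are reproducible and
subjects can receive independent substreams.

Absorption is detected both at step ends and *within* steps via the
Brownian-bridge crossing probability (exp(-2 d0 d1 / dt) for gap distances
d0, d1 to a boundary); without this the walk systematically overshoots
first-passage times by O(sqrt(dt)).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _absorb(x0, x1, a, dt):
    """0 = still diffusing, 1 = upper boundary, 2 = lower boundary."""
    if x1 >= a:
        return 1
    if x1 <= 0.0:
        return 2
    if np.random.random() < np.exp(-2.0 * (a - x0) * (a - x1) / dt):
        return 1
    if np.random.random() < np.exp(-2.0 * x0 * x1 / dt):
        return 2
    return 0


@njit(cache=True)
def fpt_batch(a, v, n, dt, cap, seed):
    """n independent first-passage draws from a/2 with boundaries {0, a}.

    Returns (times, hit_upper, flagged); flagged marks walks not absorbed
    within ``cap`` seconds (their time is set to cap).
    """
    np.random.seed(seed)
    times = np.empty(n)
    upper = np.zeros(n, dtype=np.bool_)
    flagged = np.zeros(n, dtype=np.bool_)
    sq = np.sqrt(dt)
    max_steps = int(cap / dt)
    for i in range(n):
        x = 0.5 * a
        steps = 0
        code = 0
        while steps < max_steps:
            x_new = x + v * dt + sq * np.random.normal()
            steps += 1
            code = _absorb(x, x_new, a, dt)
            if code != 0:
                break
            x = x_new
        times[i] = steps * dt
        if code == 1:
            upper[i] = True
        elif code == 0:
            flagged[i] = True
    return times, upper, flagged


@njit(cache=True)
def serial_walk(soas, e1, m1, a1, v1, e2, m2, a2, v2, dt, cap, seed):
    """Serial-bottleneck trials: Task-2 decision waits for Task-1 decision.

    rt1 = e1 + d1 + m1; Task-2 decision starts at max(soa + e2, e1 + d1) on
    the Task-1 clock; rt2 = (start - soa) + d2 + m2.
    """
    np.random.seed(seed)
    n = soas.shape[0]
    rt1 = np.empty(n)
    rt2 = np.empty(n)
    c1 = np.zeros(n, dtype=np.bool_)
    c2 = np.zeros(n, dtype=np.bool_)
    flagged = np.zeros(n, dtype=np.bool_)
    sq = np.sqrt(dt)
    max_steps = int(cap / dt)
    for i in range(n):
        d = np.empty(2)
        hit = np.zeros(2, dtype=np.bool_)
        for k in range(2):
            a = a1 if k == 0 else a2
            v = v1 if k == 0 else v2
            x = 0.5 * a
            steps = 0
            code = 0
            while steps < max_steps:
                x_new = x + v * dt + sq * np.random.normal()
                steps += 1
                code = _absorb(x, x_new, a, dt)
                if code != 0:
                    break
                x = x_new
            d[k] = steps * dt
            hit[k] = code == 1
            if code == 0:
                flagged[i] = True
        rt1[i] = e1 + d[0] + m1
        start2 = max(soas[i] + e2, e1 + d[0])
        rt2[i] = (start2 - soas[i]) + d[1] + m2
        c1[i] = hit[0]
        c2[i] = hit[1]
    return rt1, rt2, c1, c2, flagged


@njit(cache=True)
def parallel_walk(soas, e1, m1, a1, v1, e2, m2, a2, v2, share, dt, cap, seed):
    """Capacity-sharing trials: both decisions run concurrently on the Task-1
    clock; while both are active Task 1 accumulates at share*v1 and Task 2 at
    (1-share)*v2, otherwise each runs at full drift.  Task-2 decision onset is
    never postponed (it starts at soa + e2).
    """
    np.random.seed(seed)
    n = soas.shape[0]
    rt1 = np.empty(n)
    rt2 = np.empty(n)
    c1 = np.zeros(n, dtype=np.bool_)
    c2 = np.zeros(n, dtype=np.bool_)
    flagged = np.zeros(n, dtype=np.bool_)
    sq = np.sqrt(dt)
    for i in range(n):
        on1 = e1
        on2 = soas[i] + e2
        # each accumulator is capped ``cap`` seconds after its own onset
        t_end = max(on1, on2) + cap
        x1 = 0.5 * a1
        x2 = 0.5 * a2
        done1 = False
        done2 = False
        end1 = -1.0
        end2 = -1.0
        t = min(on1, on2)
        while t < t_end and not (done1 and done2):
            act1 = (t >= on1) and not done1
            act2 = (t >= on2) and not done2
            both = act1 and act2
            if act1:
                drift = share * v1 if both else v1
                x_new = x1 + drift * dt + sq * np.random.normal()
                code = _absorb(x1, x_new, a1, dt)
                if code != 0:
                    done1 = True
                    c1[i] = code == 1
                    end1 = t + dt
                else:
                    x1 = x_new
            if act2:
                drift = (1.0 - share) * v2 if both else v2
                x_new = x2 + drift * dt + sq * np.random.normal()
                code = _absorb(x2, x_new, a2, dt)
                if code != 0:
                    done2 = True
                    c2[i] = code == 1
                    end2 = t + dt
                else:
                    x2 = x_new
            t += dt
        if not done1:
            end1 = t_end
            flagged[i] = True
        if not done2:
            end2 = t_end
            flagged[i] = True
        rt1[i] = end1 + m1
        rt2[i] = (end2 - soas[i]) + m2
    return rt1, rt2, c1, c2, flagged
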