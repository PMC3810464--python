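"""Numba inner loops for the explicit-Euler reaction-diffusion integrator.

Both kernels share the exact floating-point expression order for the
reaction term so that the single-sex kernel reproduces the two-sex kernel
bit-for-bit under the symmetric reduction (r = 1/2, f = m = u).

Return codes:
    0  early persistence (mass growth + plateau at the persistence density)
    1  early extinction (peak total density below the extinction threshold)
    2  converged (max-norm time derivative below tolerance)
    3  step/time budget exhausted
    9  non-finite values encountered
"""

import numpy as np
from numba import njit


@njit(cache=True)
def run_two_sex(
    f,
    m,
    dx,
    dt,
    r,
    mu_f,
    mu_m,
    sigma,
    Df,
    Dm,
    absorbing,
    tol,
    t0,
    max_time,
    max_steps,
    check_every,
    ext_peak,
    persist_mass,
    peak_lo,
    peak_hi,
):
    n = f.shape[0]
    inv = 1.0 / (dx * dx)
    fn = np.empty(n)
    mn = np.empty(n)
    mass0 = 0.0
    for i in range(n):
        mass0 += f[i] + m[i]
    mass0 *= dx
    t = t0
    steps = 0
    code = 3
    maxd = 0.0
    while steps < max_steps and t < max_time - 1e-12 * max(1.0, max_time):
        check = (steps % check_every == check_every - 1) or (steps == max_steps - 1)
        maxd = 0.0
        for i in range(n):
            if i == 0:
                lapf = 2.0 * (f[1] - f[0]) * inv
                lapm = 2.0 * (m[1] - m[0]) * inv
            elif i == n - 1:
                lapf = 2.0 * (f[n - 2] - f[n - 1]) * inv
                lapm = 2.0 * (m[n - 2] - m[n - 1]) * inv
            else:
                lapf = (f[i - 1] - 2.0 * f[i] + f[i + 1]) * inv
                lapm = (m[i - 1] - 2.0 * m[i] + m[i + 1]) * inv
            birth = sigma * f[i] * m[i] * (1.0 - (f[i] + m[i]))
            df = Df * lapf + r * birth - mu_f * f[i]
            dm = Dm * lapm + (1.0 - r) * birth - mu_m * m[i]
            if check:
                ad = abs(df)
                if ad > maxd:
                    maxd = ad
                ad = abs(dm)
                if ad > maxd:
                    maxd = ad
            nf = f[i] + dt * df
            if nf < 0.0:
                nf = 0.0
            fn[i] = nf
            nm = m[i] + dt * dm
            if nm < 0.0:
                nm = 0.0
            mn[i] = nm
        if absorbing:
            fn[0] = 0.0
            fn[n - 1] = 0.0
            mn[0] = 0.0
            mn[n - 1] = 0.0
        tmp = f
        f = fn
        fn = tmp
        tmp = m
        m = mn
        mn = tmp
        t += dt
        steps += 1
        if check:
            if not np.isfinite(maxd):
                code = 9
                break
            peak = 0.0
            mass = 0.0
            for i in range(n):
                tot = f[i] + m[i]
                if tot > peak:
                    peak = tot
                mass += tot
            mass *= dx
            if peak < ext_peak:
                code = 1
                break
            if (
                persist_mass > 0.0
                and mass >= persist_mass
                and mass >= 1.5 * mass0
                and peak_lo <= peak <= peak_hi
            ):
                code = 0
                break
            if tol > 0.0 and maxd < tol:
                code = 2
                break
    return f, m, t, code, maxd, steps


@njit(cache=True)
def run_single_sex(
    u,
    dx,
    dt,
    mu,
    sigma,
    D,
    absorbing,
    tol,
    t0,
    max_time,
    max_steps,
    check_every,
    ext_peak,
    persist_mass,
    peak_lo,
    peak_hi,
):
    # peak/mass thresholds refer to the TOTAL density of both sexes (= 2u).
    n = u.shape[0]
    inv = 1.0 / (dx * dx)
    un = np.empty(n)
    mass0 = 0.0
    for i in range(n):
        mass0 += u[i] + u[i]
    mass0 *= dx
    t = t0
    steps = 0
    code = 3
    maxd = 0.0
    while steps < max_steps and t < max_time - 1e-12 * max(1.0, max_time):
        check = (steps % check_every == check_every - 1) or (steps == max_steps - 1)
        maxd = 0.0
        for i in range(n):
            if i == 0:
                lap = 2.0 * (u[1] - u[0]) * inv
            elif i == n - 1:
                lap = 2.0 * (u[n - 2] - u[n - 1]) * inv
            else:
                lap = (u[i - 1] - 2.0 * u[i] + u[i + 1]) * inv
            birth = sigma * u[i] * u[i] * (1.0 - (u[i] + u[i]))
            du = D * lap + 0.5 * birth - mu * u[i]
            if check:
                ad = abs(du)
                if ad > maxd:
                    maxd = ad
            nu = u[i] + dt * du
            if nu < 0.0:
                nu = 0.0
            un[i] = nu
        if absorbing:
            un[0] = 0.0
            un[n - 1] = 0.0
        tmp = u
        u = un
        un = tmp
        t += dt
        steps += 1
        if check:
            if not np.isfinite(maxd):
                code = 9
                break
            peak = 0.0
            mass = 0.0
            for i in range(n):
                tot = u[i] + u[i]
                if tot > peak:
                    peak = tot
                mass += tot
            mass *= dx
            if peak < ext_peak:
                code = 1
                break
            if (
                persist_mass > 0.0
                and mass >= persist_mass
                and mass >= 1.5 * mass0
                and peak_lo <= peak <= peak_hi
            ):
                code = 0
                break
            if tol > 0.0 and maxd < tol:
                code = 2
                break
    return u, t, code, maxd, steps
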