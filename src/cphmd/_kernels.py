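"""Compiled inner loop for the batched frozen-atom lambda sampler.

The kernel advances every walker by one chunk of leapfrog steps with
constraint projection and v-rescale thermostatting, consuming
pre-generated thermostat noise.  It covers the common campaign case
(quadratic Coulomb form, per-coordinate bias and pH step, no correction
polynomial); :func:`cphmd.dynamics.run_lambda_dynamics` falls back to
the pure-numpy loop whenever the kernel is unavailable or a correction
potential is active.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba ships with the environment
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def lambda_chunk(
    lam, vel, masses, H, g_lin, use_coulomb, barrier, gmask, dg, k1, x0, snorm,
    J, A, c, dt, cth, kbar, nf, r1, schi, use_thermo, frames, stride, frame0,
):
    """Advance all walkers by ``r1.shape[0]`` steps; returns frames written.

    ``lam``/``vel`` (B, K) are updated in place.  ``H``/``g_lin`` hold
    the quadratic Coulomb form, ``gmask`` marks titration coordinates
    that feel the bias, ``dg`` (B, K) the per-walker pH end-state free
    energies, ``snorm`` the step-normalization of the double logistic.
    ``J``/``A``/``c`` are the constraint Jacobian, mass-weighted
    projection matrix, and targets.  ``r1``/``schi`` (n_steps, B) are the
    thermostat noise streams; recorded frames go to ``frames`` starting
    at ``frame0``.
    """
    n_steps, B = r1.shape
    K = lam.shape[1]
    m = J.shape[0]
    fi = frame0
    grad = np.empty(K)
    resid = np.empty(m)
    for step in range(n_steps):
        for b in range(B):
            for i in range(K):
                g = 0.0
                if use_coulomb:
                    g += g_lin[i]
                    for j in range(K):
                        g += H[i, j] * lam[b, j]
                if gmask[i] and barrier != 0.0:
                    li = lam[b, i]
                    g += 32.0 * barrier * li * (1.0 - li) * (1.0 - 2.0 * li)
                d = dg[b, i]
                if d != 0.0:
                    li = lam[b, i]
                    ea = 1.0 / (1.0 + np.exp(-k1 * (li - x0)))
                    eb = 1.0 / (1.0 + np.exp(-k1 * (li - (1.0 - x0))))
                    g += d * 0.5 * k1 * (ea * (1.0 - ea) + eb * (1.0 - eb)) / snorm
                grad[i] = g
            for i in range(K):
                vel[b, i] += dt * (-grad[i]) / masses[i]
            for r in range(m):
                acc = -c[r]
                for i in range(K):
                    acc += J[r, i] * (lam[b, i] + dt * vel[b, i])
                resid[r] = acc
            kin = 0.0
            for i in range(K):
                new = lam[b, i] + dt * vel[b, i]
                for r in range(m):
                    new -= resid[r] * A[i, r]
                vel[b, i] = (new - lam[b, i]) / dt
                lam[b, i] = new
                kin += 0.5 * masses[i] * vel[b, i] * vel[b, i]
            if use_thermo:
                if kin < 1e-300:
                    kin = 1e-300
                rr = r1[step, b]
                s = schi[step, b]
                a2 = (
                    cth
                    + (1.0 - cth) * kbar * (rr * rr + s) / (nf * kin)
                    + 2.0 * rr * np.sqrt(cth * (1.0 - cth) * kbar / (nf * kin))
                )
                if a2 < 0.0:
                    a2 = 0.0
                fac = np.sqrt(a2)
                for i in range(K):
                    vel[b, i] *= fac
        if (step + 1) % stride == 0:
            for b in range(B):
                for i in range(K):
                    frames[fi, b, i] = lam[b, i]
            fi += 1
    return fi
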