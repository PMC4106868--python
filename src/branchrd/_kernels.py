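"""Numba kernels: explicit finite-difference integrators and ODE relaxation.

All lattice kernels use the four-point Laplacian with mirrored (no-flux)
boundary neighbours and a Jacobi update (every field advances from the same
time level).  The multi-step drivers swap ping-pong buffers internally and
return the arrays holding the final state.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def laplacian_noflux_inplace(F, out, dx):
    ny, nx = F.shape
    idx2 = 1.0 / (dx * dx)
    for i in range(ny):
        im = i - 1 if i > 0 else 0
        ip = i + 1 if i < ny - 1 else ny - 1
        for j in range(nx):
            jm = j - 1 if j > 0 else 0
            jp = j + 1 if j < nx - 1 else nx - 1
            out[i, j] = (
                F[im, j] + F[ip, j] + F[i, jm] + F[i, jp] - 4.0 * F[i, j]
            ) * idx2


@njit(cache=True)
def advance_full(
    A, H, S, Y, An, Hn, Sn, Yn, nsteps,
    Da, Dh, Ds, c, c0, gamma, mu, nu, rhoA, rhoH, eps, d, e, f,
    dx, dt, hfloor,
):
    """Advance the 4-variable model nsteps; returns the final-state arrays."""
    ny, nx = A.shape
    idx2 = 1.0 / (dx * dx)
    for _ in range(nsteps):
        for i in range(ny):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < ny - 1 else ny - 1
            for j in range(nx):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < nx - 1 else nx - 1
                a = A[i, j]
                h = H[i, j]
                s = S[i, j]
                y = Y[i, j]
                lapA = (A[im, j] + A[ip, j] + A[i, jm] + A[i, jp] - 4.0 * a) * idx2
                lapH = (H[im, j] + H[ip, j] + H[i, jm] + H[i, jp] - 4.0 * h) * idx2
                lapS = (S[im, j] + S[ip, j] + S[i, jm] + S[i, jp] - 4.0 * s) * idx2
                auto = c * s * a * a
                An[i, j] = a + dt * (auto / max(h, hfloor) - mu * a + rhoA * y + Da * lapA)
                Hn[i, j] = h + dt * (auto - nu * h + rhoH * y + Dh * lapH)
                Sn[i, j] = s + dt * (c0 - gamma * s - eps * y * s + Ds * lapS)
                Yn[i, j] = y + dt * (d * a - e * y + y * y / (1.0 + f * y * y))
        A, An = An, A
        H, Hn = Hn, H
        S, Sn = Sn, S
        Y, Yn = Yn, Y
    return A, H, S, Y


@njit(cache=True)
def advance_reduced(
    A, H, An, Hn, Yf, Sf, nsteps,
    Da, Dh, c, mu, nu, rhoA, rhoH,
    dx, dt, hfloor,
):
    """Advance the reduced A/H model with frozen Y, S fields."""
    ny, nx = A.shape
    idx2 = 1.0 / (dx * dx)
    for _ in range(nsteps):
        for i in range(ny):
            im = i - 1 if i > 0 else 0
            ip = i + 1 if i < ny - 1 else ny - 1
            for j in range(nx):
                jm = j - 1 if j > 0 else 0
                jp = j + 1 if j < nx - 1 else nx - 1
                a = A[i, j]
                h = H[i, j]
                lapA = (A[im, j] + A[ip, j] + A[i, jm] + A[i, jp] - 4.0 * a) * idx2
                lapH = (H[im, j] + H[ip, j] + H[i, jm] + H[i, jp] - 4.0 * h) * idx2
                auto = c * Sf[i, j] * a * a
                An[i, j] = a + dt * (
                    auto / max(h, hfloor) - mu * a + rhoA * Yf[i, j] + Da * lapA
                )
                Hn[i, j] = h + dt * (auto - nu * h + rhoH * Yf[i, j] + Dh * lapH)
        A, An = An, A
        H, Hn = Hn, H
    return A, H


@njit(cache=True)
def relax_ah(Sv, Yv, c, mu, nu, rhoA, rhoH, a0, h0, tmax, hfloor):
    """Damped time integration of the homogeneous A/H kinetics per point.

    Positivity-preserving Patankar-Euler (explicit production, implicit
    linear decay) with a step limited to 10% relative production change.
    Returns end points and a convergence flag per point.
    """
    n = Sv.size
    aout = np.empty(n)
    hout = np.empty(n)
    conv = np.zeros(n, dtype=np.uint8)
    dt_cap = 0.5 / max(mu, nu)
    for pidx in range(n):
        al = c * Sv[pidx]
        ry_a = rhoA * Yv[pidx]
        ry_h = rhoH * Yv[pidx]
        a = a0
        h = h0
        t = 0.0
        while t < tmax:
            auto = al * a * a
            pa = auto / max(h, hfloor) + ry_a
            ph = auto + ry_h
            fa = pa - mu * a
            fh = ph - nu * h
            ra = abs(fa) / max(a, 1e-9)
            rh = abs(fh) / max(h, 1e-9)
            if ra < 1e-11 and rh < 1e-11:
                conv[pidx] = 1
                break
            dt = dt_cap
            denom = max(pa / max(a, 1e-9), ph / max(h, 1e-9))
            if denom > 1e-30:
                lim = 0.1 / denom
                if lim < dt:
                    dt = lim
            a = (a + dt * pa) / (1.0 + dt * mu)
            h = (h + dt * ph) / (1.0 + dt * nu)
            t += dt
        aout[pidx] = a
        hout[pidx] = h
    return aout, hout, conv
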