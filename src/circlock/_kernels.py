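"""Compiled integration kernels.

Everything in this module is an implementation detail of the public modules
(:mod:`circlock.simulate`, :mod:`circlock.analysis`, ...).  The kernels exist
because the Monte-Carlo oscillation-region scans integrate tens of thousands
of small ODE systems; a compiled Dormand-Prince 5(4) driver brings one
integration down to well under a millisecond.

Right-hand sides are written against flat ``float64`` parameter vectors with
fixed layouts (documented per function).  The public modules own the mapping
from typed parameter objects to these vectors.
"""

from __future__ import annotations

import numba as nb
import numpy as np

# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def _free_activator(S, A_T, Kd):
    """Free activator left by a sequestrant S at total A_T and dissociation Kd.

    Numerically stable evaluation of the positive root of
    A**2 + (S - A_T + Kd)*A - Kd*A_T = 0.
    """
    q = A_T - S - Kd
    root = np.sqrt(q * q + 4.0 * Kd * A_T)
    if q >= 0.0:
        return 0.5 * (q + root)
    # cancellation-safe branch for q < 0
    denom = -q + root
    if denom == 0.0:
        return 0.0
    return 2.0 * Kd * A_T / denom


# ---------------------------------------------------------------------------
# model right-hand sides
# ---------------------------------------------------------------------------
# p layout for the three-phosphoform sequestration model:
#   p = [k1, k2, k3, k4, Kd, A_T, C_T];  y = [T, ST, S]


@nb.njit(cache=True)
def rhs_core(t, y, p, out):
    k1, k2, k3, k4, Kd, A_T, C_T = p[0], p[1], p[2], p[3], p[4], p[5], p[6]
    T, ST, S = y[0], y[1], y[2]
    f = _free_activator(S, A_T, Kd)
    U = C_T - T - ST - S
    out[0] = k1 * f * U - k2 * T
    out[1] = k2 * T - k3 * ST
    out[2] = k3 * ST - k4 * S


# p layout for the five-state transcription-coupled model:
#   p = [k1, k2, k3, k4, Kd, A_T, V_trsp, V_m, K_s, K_0, V_d, mode]
#   mode > 0.5 -> S-inhibited transcription; otherwise constitutive.
#   y = [M, U, T, ST, S]

TTFL_HILL = 4.0
TTFL_FOLD = 100.0


@nb.njit(cache=True)
def rhs_ttfl(t, y, p, out):
    k1, k2, k3, k4 = p[0], p[1], p[2], p[3]
    Kd, A_T = p[4], p[5]
    V_trsp, V_m, K_s, K_0, V_d, mode = p[6], p[7], p[8], p[9], p[10], p[11]
    M, U, T, ST, S = y[0], y[1], y[2], y[3], y[4]
    A = _free_activator(S, A_T, Kd)
    if mode > 0.5:
        x = S / K_0
        x2 = x * x
        transcription = V_trsp * TTFL_FOLD / (1.0 + x2 * x2)
    else:
        transcription = V_trsp
    out[0] = transcription - V_m * M
    out[1] = K_s * M - k1 * A * U + k4 * S - V_d * U
    out[2] = k1 * A * U - k2 * T - V_d * T
    out[3] = k2 * T - k3 * ST - V_d * ST
    out[4] = k3 * ST - k4 * S - V_d * S


# p layout for the activator/repressor transcription chain:
#   p = [a1, b1, a2, b2, a3, b3, A_T, K1, K2, K3, k4]
#   y = [M, r, R]
# The repression function is the closed-form free-activator expression with
# effective constants K1, K2, K3; k4 is the activator phospho/dephospho ratio
# (0 for the plain phospholock chain).  The simple titration chain is the
# special case K1 = K3, K2/K1 = Kd, k4 = 0 (with a1 pre-divided by A_T when a
# free-activator *fraction* is wanted).


@nb.njit(cache=True)
def repression_f(R, A_T, K1, K2, K3, k4):
    c = K2 * (1.0 + k4)
    num = K1 * A_T - K3 * R - c
    s = K1 * A_T + K3 * R + c
    disc = s * s - 4.0 * K1 * K3 * A_T * R
    if disc < 0.0:
        disc = 0.0
    root = np.sqrt(disc)
    denom = 2.0 * K1 * (1.0 + k4)
    if num >= 0.0:
        return (num + root) / denom
    # stable branch: (num + root) = (root^2 - num^2)/(root - num)
    alt = root - num
    if alt == 0.0:
        return 0.0
    return (disc - num * num) / alt / denom


@nb.njit(cache=True)
def rhs_chain(t, y, p, out):
    a1, b1, a2, b2, a3, b3 = p[0], p[1], p[2], p[3], p[4], p[5]
    A_T, K1, K2, K3, k4 = p[6], p[7], p[8], p[9], p[10]
    M, r, R = y[0], y[1], y[2]
    f = repression_f(R, A_T, K1, K2, K3, k4)
    out[0] = a1 * f - b1 * M
    out[1] = a2 * M - b2 * r
    out[2] = a3 * r - b3 * R


# p layout for the nine-species KaiABC cycle (see circlock.detailed_kaiabc):
#   p = [kUT, kTU, kTS, kSd, kSU, kB, kBSU, kseq, atp]
#   y = [A, U, T, ST, S, BST, BS, ABST, ABS]


@nb.njit(cache=True)
def rhs_detailed(t, y, p, out):
    kUT, kTU, kTS, kSd, kSU = p[0], p[1], p[2], p[3], p[4]
    kB, kBSU, kseq, atp = p[5], p[6], p[7], p[8]
    A, U, T, ST, S = y[0], y[1], y[2], y[3], y[4]
    BST, BS, ABST, ABS = y[5], y[6], y[7], y[8]
    vUT = kUT * atp * A * U
    vTU = kTU * T
    vTS = kTS * T
    vSd = kSd * ST
    vSU = kSU * S
    vB1 = kB * ST
    vB2 = kB * S
    vBSd = kSd * BST
    vBSU = kBSU * BS
    vq1 = kseq * A * BST
    vq2 = kseq * A * BS
    vABd = kSd * ABST
    vABU = kBSU * ABS
    out[0] = -vq1 - vq2 + vABU
    out[1] = -vUT + vTU + vSU + vBSU + vABU
    out[2] = vUT - vTU - vTS
    out[3] = vTS - vSd - vB1
    out[4] = vSd - vSU - vB2
    out[5] = vB1 - vBSd - vq1
    out[6] = vB2 + vBSd - vBSU - vq2
    out[7] = vq1 - vABd
    out[8] = vq2 + vABd - vABU


# generic mass-action network rhs; the network is packed into a flat vector:
#   p = [n_rxn, n_sp, r1[0..n), r2[0..n), k[0..n), net[0..n*n_sp) row-major]
# r1/r2 are reactant indices (-1 for absent second reactant).


def pack_network(r1, r2, rates, net):
    r1 = np.asarray(r1, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    rates = np.asarray(rates, dtype=np.float64)
    net = np.asarray(net, dtype=np.float64)
    n_rxn, n_sp = net.shape
    return np.concatenate(
        [[float(n_rxn), float(n_sp)], r1, r2, rates, net.ravel()]
    )


@nb.njit(cache=True)
def rhs_network(t, y, p, out):
    n_rxn = int(p[0])
    n_sp = int(p[1])
    for j in range(n_sp):
        out[j] = 0.0
    base = 2
    for i in range(n_rxn):
        i1 = int(p[base + i])
        i2 = int(p[base + n_rxn + i])
        v = p[base + 2 * n_rxn + i]
        if i1 >= 0:
            v *= y[i1]
        if i2 >= 0:
            v *= y[i2]
        off = base + 3 * n_rxn + i * n_sp
        for j in range(n_sp):
            out[j] += v * p[off + j]


# ---------------------------------------------------------------------------
# Dormand-Prince 5(4) drivers
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def _dp_step(rhs, t, y, h, p, k1, k2, k3, k4, k5, k6, k7, ytmp, y5, rtol, atol):
    """One trial step; returns scaled error norm, writes candidate into y5."""
    n = y.shape[0]
    for i in range(n):
        ytmp[i] = y[i] + h * 0.2 * k1[i]
    rhs(t + 0.2 * h, ytmp, p, k2)
    for i in range(n):
        ytmp[i] = y[i] + h * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
    rhs(t + 0.3 * h, ytmp, p, k3)
    for i in range(n):
        ytmp[i] = y[i] + h * (
            44.0 / 45.0 * k1[i] - 56.0 / 15.0 * k2[i] + 32.0 / 9.0 * k3[i]
        )
    rhs(t + 0.8 * h, ytmp, p, k4)
    for i in range(n):
        ytmp[i] = y[i] + h * (
            19372.0 / 6561.0 * k1[i]
            - 25360.0 / 2187.0 * k2[i]
            + 64448.0 / 6561.0 * k3[i]
            - 212.0 / 729.0 * k4[i]
        )
    rhs(t + 8.0 / 9.0 * h, ytmp, p, k5)
    for i in range(n):
        ytmp[i] = y[i] + h * (
            9017.0 / 3168.0 * k1[i]
            - 355.0 / 33.0 * k2[i]
            + 46732.0 / 5247.0 * k3[i]
            + 49.0 / 176.0 * k4[i]
            - 5103.0 / 18656.0 * k5[i]
        )
    rhs(t + h, ytmp, p, k6)
    for i in range(n):
        y5[i] = y[i] + h * (
            35.0 / 384.0 * k1[i]
            + 500.0 / 1113.0 * k3[i]
            + 125.0 / 192.0 * k4[i]
            - 2187.0 / 6784.0 * k5[i]
            + 11.0 / 84.0 * k6[i]
        )
    rhs(t + h, y5, p, k7)
    err = 0.0
    for i in range(n):
        e = h * (
            71.0 / 57600.0 * k1[i]
            - 71.0 / 16695.0 * k3[i]
            + 71.0 / 1920.0 * k4[i]
            - 17253.0 / 339200.0 * k5[i]
            + 22.0 / 525.0 * k6[i]
            - 1.0 / 40.0 * k7[i]
        )
        sc = atol + rtol * max(abs(y[i]), abs(y5[i]))
        err += (e / sc) ** 2
    return np.sqrt(err / n)


@nb.njit(cache=True)
def integrate_grid(rhs, p, y0, tgrid, rtol, atol, max_steps):
    """Adaptive DP5(4) integration recording the state at every grid time.

    Returns (Y, ok).  Steps never overshoot the next grid time, so grid
    values are exact solver states (no interpolation error on top of the
    local error control).
    """
    n = y0.shape[0]
    m = tgrid.shape[0]
    Y = np.empty((m, n))
    Y[0] = y0
    y = y0.copy()
    t = tgrid[0]
    h = (tgrid[-1] - tgrid[0]) / 1000.0
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n); y5 = np.empty(n)
    rhs(t, y, p, k1)
    gi = 1
    steps = 0
    while gi < m:
        if steps > max_steps:
            return Y, False
        tnext = tgrid[gi]
        if t + h > tnext:
            h = tnext - t
        err = _dp_step(rhs, t, y, h, p, k1, k2, k3, k4, k5, k6, k7, ytmp, y5,
                       rtol, atol)
        steps += 1
        accepted = err <= 1.0
        if accepted:
            t = t + h
            for i in range(n):
                y[i] = y5[i]
                k1[i] = k7[i]
            if t >= tnext:
                Y[gi] = y
                gi += 1
        if err > 0.0:
            fac = 0.9 * err ** (-0.2)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h = h * fac
        if h <= 1e-13:
            return Y, False
    return Y, True


@nb.njit(cache=True)
def _hermite_scalar(theta, h, y0, y1, d0, d1):
    t2 = theta * theta
    t3 = t2 * theta
    return (
        (2.0 * t3 - 3.0 * t2 + 1.0) * y0
        + (t3 - 2.0 * t2 + theta) * h * d0
        + (-2.0 * t3 + 3.0 * t2) * y1
        + (t3 - t2) * h * d1
    )


@nb.njit(cache=True)
def upward_crossings(rhs, p, y0, t0, t_end, level, comp, rtol, atol,
                     max_steps, out_times):
    """Integrate and record times where component `comp` crosses `level`
    upward.  Crossings are located inside accepted steps by bisection on the
    cubic Hermite interpolant (solution value and derivative at both step
    ends), mirroring an ODE solver's event machinery.

    Returns (n_events, ok).  At most out_times.shape[0] events are kept
    (oldest first; further events overwrite cyclically is NOT done -- extra
    events shift the window so the last three are always retained).
    """
    n = y0.shape[0]
    cap = out_times.shape[0]
    y = y0.copy()
    t = t0
    h = (t_end - t0) / 1000.0
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n); y5 = np.empty(n)
    rhs(t, y, p, k1)
    steps = 0
    nev = 0
    while t < t_end:
        if steps > max_steps:
            return nev, False
        if t + h > t_end:
            h = t_end - t
        err = _dp_step(rhs, t, y, h, p, k1, k2, k3, k4, k5, k6, k7, ytmp, y5,
                       rtol, atol)
        steps += 1
        if err <= 1.0:
            d0 = y[comp] - level
            d1v = y5[comp] - level
            if d0 < 0.0 and d1v >= 0.0:
                lo = 0.0
                hi = 1.0
                g0 = k1[comp]
                g1 = k7[comp]
                for _ in range(60):
                    mid = 0.5 * (lo + hi)
                    val = _hermite_scalar(mid, h, d0, d1v, g0, g1)
                    if val < 0.0:
                        lo = mid
                    else:
                        hi = mid
                tc = t + 0.5 * (lo + hi) * h
                if nev < cap:
                    out_times[nev] = tc
                    nev += 1
                else:
                    for j in range(cap - 1):
                        out_times[j] = out_times[j + 1]
                    out_times[cap - 1] = tc
            t = t + h
            for i in range(n):
                y[i] = y5[i]
                k1[i] = k7[i]
        if err > 0.0:
            fac = 0.9 * err ** (-0.2)
        else:
            fac = 5.0
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h = h * fac
        if h <= 1e-13:
            return nev, False
    return nev, True


@nb.njit(cache=True)
def series_mean(rhs, p, y0, t0, t_end, comp, dt, rtol, atol, max_steps):
    """Mean of one component sampled on a uniform grid (first scan pass)."""
    m = int((t_end - t0) / dt) + 1
    tgrid = np.empty(m)
    for i in range(m):
        tgrid[i] = t0 + i * dt
    Y, ok = integrate_grid(rhs, p, y0, tgrid, rtol, atol, max_steps)
    if not ok:
        return 0.0, False
    total = 0.0
    for i in range(m):
        total += Y[i, comp]
    return total / m, True


# ---------------------------------------------------------------------------
# stochastic simulation (direct method)
# ---------------------------------------------------------------------------


@nb.njit(cache=True)
def gillespie_direct(r1, r2, rates, net, x0, tgrid, omega, seed):
    """Exact SSA sample path recorded at the times in `tgrid`.

    r1/r2: reactant indices per reaction (-1 = absent); `net` is the integer
    net-stoichiometry matrix (n_rxn x n_species).  Bimolecular propensities
    scale with 1/omega; a doubled reactant uses x*(x-1)/2.
    """
    np.random.seed(seed)
    n_rxn = net.shape[0]
    n_sp = net.shape[1]
    m = tgrid.shape[0]
    X = np.empty((m, n_sp), dtype=np.int64)
    x = x0.copy()
    t = tgrid[0]
    X[0] = x
    gi = 1
    a = np.empty(n_rxn)
    while gi < m:
        a0 = 0.0
        for i in range(n_rxn):
            prop = rates[i]
            i1 = r1[i]
            i2 = r2[i]
            if i1 >= 0 and i2 >= 0:
                if i1 == i2:
                    prop *= x[i1] * (x[i1] - 1) / (2.0 * omega)
                else:
                    prop *= x[i1] * x[i2] / omega
            elif i1 >= 0:
                prop *= x[i1]
            a[i] = prop
            a0 += prop
        if a0 <= 0.0:
            for g in range(gi, m):
                X[g] = x
            return X
        tau = -np.log(np.random.random()) / a0
        t_new = t + tau
        while gi < m and tgrid[gi] <= t_new:
            X[gi] = x
            gi += 1
        if gi >= m:
            break
        t = t_new
        u = np.random.random() * a0
        acc = 0.0
        chosen = n_rxn - 1
        for i in range(n_rxn):
            acc += a[i]
            if u <= acc:
                chosen = i
                break
        for j in range(n_sp):
            x[j] += net[chosen, j]
    return X
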