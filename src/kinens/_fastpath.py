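"""Numba-compiled kernels for the steady-state hot path.

Everything here mirrors the pure-numpy implementations in
:mod:`kinens.kinetics`; the solver falls back to those when numba is
unavailable. Status codes returned by :func:`be_march`:
0 = residual below tolerance, 1 = diverged (concentration cap), 2 = failed.

Array contract: ``N_live`` is the live-row slice of the step
stoichiometric matrix (n_live x n_steps, C-contiguous) and ``pos`` maps a
full species index to its live position (-1 when clamped/dead).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - env-dependent
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _rates(ca, slots_r, slots_p, kf, kb):
    ns = slots_r.shape[0]
    out = np.empty(ns)
    for i in range(ns):
        pr = 1.0
        for j in range(slots_r.shape[1]):
            pr *= ca[slots_r[i, j]]
        pp = 1.0
        for j in range(slots_p.shape[1]):
            pp *= ca[slots_p[i, j]]
        out[i] = kf[i] * pr - kb[i] * pp
    return out


@njit(cache=True)
def _rhs_live(ca, x, slots_r, slots_p, kf, kb, N_live, live):
    for i in range(live.shape[0]):
        ca[live[i]] = x[i]
    rates = _rates(ca, slots_r, slots_p, kf, kb)
    return N_live @ rates


@njit(cache=True)
def _jac_live(ca, x, slots_r, slots_p, kf, kb, N_live, live, pos):
    for i in range(live.shape[0]):
        ca[live[i]] = x[i]
    ns = slots_r.shape[0]
    nl = live.shape[0]
    Jr = np.zeros((ns, nl))
    for i in range(ns):
        Lr = slots_r.shape[1]
        for j in range(Lr):
            col = pos[slots_r[i, j]]
            if col < 0:
                continue
            comp = kf[i]
            for l in range(Lr):
                if l != j:
                    comp *= ca[slots_r[i, l]]
            Jr[i, col] += comp
        Lp = slots_p.shape[1]
        for j in range(Lp):
            col = pos[slots_p[i, j]]
            if col < 0:
                continue
            comp = kb[i]
            for l in range(Lp):
                if l != j:
                    comp *= ca[slots_p[i, l]]
            Jr[i, col] -= comp
    return N_live @ Jr


@njit(cache=True)
def be_march(slots_r, slots_p, kf, kb, N_live, live, pos, c_full, tol,
             max_time, cap, max_steps):
    """Adaptive implicit-Euler march of the live subsystem to its
    attractor (fresh-factorization simplified Newton per step)."""
    nsp = c_full.shape[0]
    ca = np.empty(nsp + 1)
    ca[nsp] = 1.0
    for i in range(nsp):
        ca[i] = c_full[i]
    nl = live.shape[0]
    x = np.empty(nl)
    for i in range(nl):
        x[i] = c_full[live[i]]
    f = _rhs_live(ca, x, slots_r, slots_p, kf, kb, N_live, live)
    dt = 1e-2
    t_used = 0.0
    eye = np.eye(nl)
    J = np.zeros((nl, nl))
    Minv = np.zeros((nl, nl))
    j_fresh = False
    have_inv = False
    inv_dt = -1.0
    theta = 1.0
    for _step in range(max_steps):
        nf = 0.0
        for i in range(nl):
            a = abs(f[i])
            if a > nf:
                nf = a
        if nf < tol:
            return 0, x, t_used
        if not np.isfinite(nf):
            return 2, x, t_used
        if not have_inv:
            if not j_fresh:
                J = _jac_live(ca, x, slots_r, slots_p, kf, kb, N_live,
                              live, pos)
                j_fresh = True
            try:
                Minv = np.ascontiguousarray(np.linalg.inv(eye - dt * J))
            except Exception:
                return 2, x, t_used
            have_inv = True
            inv_dt = dt
        y = x + dt * f
        ok = False
        theta = 1.0
        prev = -1.0
        nx = np.linalg.norm(x)
        for _inner in range(10):
            fy = _rhs_live(ca, y, slots_r, slots_p, kf, kb, N_live, live)
            r = y - x - dt * fy
            finite = True
            for i in range(nl):
                if not np.isfinite(r[i]):
                    finite = False
                    break
            if not finite:
                break
            dy = -(Minv @ r)
            step = np.linalg.norm(dy)
            y = y + dy
            if prev > 0.0:
                theta = step / prev
            if theta > 0.9 and _inner >= 2:
                break
            prev = step
            if step <= 1e-10 * (1.0 + nx):
                ok = True
                break
        if not ok:
            if inv_dt != dt or not j_fresh:
                if not j_fresh:
                    J = _jac_live(ca, x, slots_r, slots_p, kf, kb, N_live,
                                  live, pos)
                    j_fresh = True
                have_inv = False  # rebuild the inverse at (J, dt)
                continue
            dt *= 0.25
            have_inv = False
            if dt < 1e-10:
                return 2, x, t_used
            continue
        for i in range(nl):
            if y[i] < 0.0:
                y[i] = 0.0
        x = y
        f = _rhs_live(ca, x, slots_r, slots_p, kf, kb, N_live, live)
        j_fresh = False
        t_used += dt
        mx = 0.0
        for i in range(nl):
            a = abs(x[i])
            if a > mx:
                mx = a
        if mx > cap:
            return 1, x, t_used
        if t_used > max_time:
            return 2, x, t_used
        # grow the pseudo-step while the inner iteration contracts well;
        # rebuild the preconditioner once it has drifted too far
        if theta < 0.5:
            dt = dt * 3.0
            if dt > 8.0 * inv_dt:
                have_inv = False
        elif theta < 0.8:
            dt = dt * 1.5
            if dt > 8.0 * inv_dt:
                have_inv = False
        if dt > 1e9:
            dt = 1e9
    return 2, x, t_used


@njit(cache=True)
def newton_polish(slots_r, slots_p, kf, kb, N_live, live, pos, piv, cons,
                  targets, c_full, x0, max_iter):
    """Damped Newton on the conservation-substituted system; returns
    (success, x)."""
    nsp = c_full.shape[0]
    ca = np.empty(nsp + 1)
    ca[nsp] = 1.0
    for i in range(nsp):
        ca[i] = c_full[i]
    x = x0.copy()
    nl = live.shape[0]
    npiv = piv.shape[0]

    f = _rhs_live(ca, x, slots_r, slots_p, kf, kb, N_live, live)
    for k in range(npiv):
        acc = -targets[k]
        for j in range(nl):
            acc += cons[k, j] * x[j]
        f[piv[k]] = acc
    nf = np.linalg.norm(f)
    for _it in range(max_iter):
        if nf < 1e-12:
            return True, x
        J = _jac_live(ca, x, slots_r, slots_p, kf, kb, N_live, live, pos)
        for k in range(npiv):
            for j in range(nl):
                J[piv[k], j] = cons[k, j]
        try:
            dx = np.linalg.solve(J, -f)
        except Exception:
            return False, x
        t = 1.0
        ok = False
        while t >= 1.0 / 1024.0:
            xn = x + t * dx
            fn = _rhs_live(ca, xn, slots_r, slots_p, kf, kb, N_live, live)
            for k in range(npiv):
                acc = -targets[k]
                for j in range(nl):
                    acc += cons[k, j] * xn[j]
                fn[piv[k]] = acc
            nfn = np.linalg.norm(fn)
            if np.isfinite(nfn) and nfn < nf:
                x = xn
                f = fn
                nf = nfn
                ok = True
                break
            t *= 0.5
        if not ok:
            return nf < 1e-10, x
    return nf < 1e-10, x
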