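"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's LP/QP and kinetics code paths:
vertex enumeration for linear programs over {S.v = 0, l <= v <= u},
active-set KKT enumeration for the MOMA quadratic program, and a symbolic
King-Altman steady state for small enzyme mechanisms.
"""

from __future__ import annotations

import itertools

import numpy as np


def polytope_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                      tol: float = 1e-9) -> list[np.ndarray]:
    """All vertices of {v : S v = 0, lb <= v <= ub} by enumerating active
    bound sets (n <= ~8 only)."""
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank  # number of bounds that must be active at a vertex
    verts: list[np.ndarray] = []
    for active in itertools.combinations(range(n), k):
        for signs in itertools.product((0, 1), repeat=k):
            A = [S[i] for i in range(m)]
            b = [0.0] * m
            for j, s in zip(active, signs):
                row = np.zeros(n)
                row[j] = 1.0
                A.append(row)
                b.append(ub[j] if s else lb[j])
            A = np.asarray(A)
            b = np.asarray(b)
            if np.linalg.matrix_rank(A) < n:
                continue
            v, *_ = np.linalg.lstsq(A, b, rcond=None)
            if np.max(np.abs(A @ v - b)) > tol:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                if not any(np.allclose(v, w, atol=1e-7) for w in verts):
                    verts.append(v)
    return verts


def fba_oracle(S, lb, ub, c) -> tuple[float, np.ndarray]:
    """max c.v over the flux polytope via vertex enumeration."""
    verts = polytope_vertices(S, lb, ub)
    if not verts:
        raise ValueError("infeasible or empty vertex set")
    vals = [float(np.dot(c, v)) for v in verts]
    i = int(np.argmax(vals))
    return vals[i], verts[i]


def fva_oracle(S, lb, ub) -> list[tuple[float, float]]:
    verts = polytope_vertices(S, lb, ub)
    V = np.array(verts)
    return [(float(V[:, j].min()), float(V[:, j].max()))
            for j in range(S.shape[1])]


def moma_oracle(S, lb, ub, ref, tol=1e-9) -> np.ndarray:
    """min ||v - ref||^2 via KKT enumeration over active bound sets."""
    m, n = S.shape
    best = None
    best_val = np.inf
    for k in range(n + 1):
        for active in itertools.combinations(range(n), k):
            for signs in itertools.product((0, 1), repeat=k):
                # KKT: v - ref + S^T mu + sum_j lam_j e_j = 0; S v = 0;
                # active bounds fixed. Solve the equality-constrained QP.
                fixed = {j: (ub[j] if s else lb[j])
                         for j, s in zip(active, signs)}
                free = [j for j in range(n) if j not in fixed]
                if not free:
                    v = np.array([fixed[j] for j in range(n)])
                    if np.max(np.abs(S @ v)) > 1e-7:
                        continue
                else:
                    # eliminate: v_free minimizes ||v-ref||^2 s.t.
                    # S_free v_free = -S_fixed v_fixed
                    Sf = S[:, free]
                    vfix = np.array([fixed[j] for j in sorted(fixed)])
                    rhs = -S[:, sorted(fixed)] @ vfix if fixed else \
                        np.zeros(m)
                    # projection of ref_free onto affine subspace
                    reff = ref[free]
                    # lstsq for particular solution + nullspace projection
                    p, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                    if np.max(np.abs(Sf @ p - rhs)) > 1e-7:
                        continue
                    from scipy.linalg import null_space
                    Nf = null_space(Sf)
                    if Nf.size:
                        z = Nf.T @ (reff - p)
                        v_free = p + Nf @ z
                    else:
                        v_free = p
                    v = np.zeros(n)
                    for j, val in fixed.items():
                        v[j] = val
                    for jj, j in enumerate(free):
                        v[j] = v_free[jj]
                if np.any(v < lb - tol) or np.any(v > ub + tol):
                    continue
                val = float(np.sum((v - ref) ** 2))
                if val < best_val - 1e-12:
                    best_val = val
                    best = v
    if best is None:
        raise ValueError("MOMA oracle found no feasible point")
    return best


def king_altman_uni_uni(k1, km1, k2, km2, k3, km3, a, b, e_total=1.0):
    """Symbolic steady-state flux of E+A<->EA<->EB<->E+B via sympy."""
    import sympy as sp

    E, EA, EB = sp.symbols("E EA EB", positive=True)
    r1 = k1 * E * a - km1 * EA
    r2 = k2 * EA - km2 * EB
    r3 = k3 * EB - km3 * E * b
    sol = sp.solve([sp.Eq(r1, r2), sp.Eq(r2, r3),
                    sp.Eq(E + EA + EB, e_total)], [E, EA, EB], dict=True)[0]
    return float(sp.simplify(r2.subs(sol)))


def briggs_haldane_constants(k1, km1, k2, km2, k3):
    """Apparent K_m and k_cat of the irreversible-product uni-uni cycle
    (product at zero), classic closed forms."""
    kcat = k2 * k3 / (k2 + km2 + k3)
    km = (km1 * km2 + km1 * k3 + k2 * k3) / (k1 * (k2 + km2 + k3))
    return km, kcat
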