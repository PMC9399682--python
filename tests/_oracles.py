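"""Independent oracles used by the test suite.

These deliberately avoid the code paths they certify: the solver oracle
minimises a smoothed surrogate with L-BFGS-B (epsilon-continuation), the
TV-prox oracle solves the box-constrained dual with lsq_linear, and hull
membership is a linear-programming feasibility check.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog, lsq_linear, minimize

from adcascade.tglasso import LongitudinalDesign, RegularizationParams, objective


def smoothed_min_objective(
    design: LongitudinalDesign,
    params: RegularizationParams,
    eps_seq=(1e-2, 1e-4, 1e-6, 1e-8, 1e-10),
) -> float:
    """Global minimum of the tgLASSO objective via smoothing + L-BFGS-B.

    Each nonsmooth term |.| or ||.||_2 is replaced by sqrt(. ^2 + eps^2);
    the surrogate overestimates the true objective by at most
    (lambda1 d + lambda2 d (T-1)) eps, so the final eps makes the gap
    negligible.  Warm-started continuation keeps L-BFGS-B on track.
    """
    d, T = design.d, design.T
    X, y = design.X, design.y

    def make(eps):
        def f(wvec):
            W = wvec.reshape(d, T)
            val = 0.0
            grad = np.zeros((d, T))
            for j in range(T):
                r = X[j] @ W[:, j] - y[j]
                val += 0.5 * float(r @ r)
                grad[:, j] += X[j].T @ r
            rn = np.sqrt((W**2).sum(axis=1) + eps**2)
            val += params.lambda1 * float(rn.sum())
            grad += params.lambda1 * W / rn[:, None]
            if T >= 2:
                Dw = W[:, 1:] - W[:, :-1]
                sn = np.sqrt(Dw**2 + eps**2)
                val += params.lambda2 * float(sn.sum())
                g2 = params.lambda2 * Dw / sn
                grad[:, 1:] += g2
                grad[:, :-1] -= g2
                if params.lambda3 > 0:
                    for j in range(T - 1):
                        dv = X[j] @ W[:, j] - X[j + 1] @ W[:, j + 1]
                        val += params.lambda3 * float(dv @ dv)
                        grad[:, j] += 2 * params.lambda3 * X[j].T @ dv
                        grad[:, j + 1] -= 2 * params.lambda3 * X[j + 1].T @ dv
            return val, grad.ravel()

        return f

    w = np.zeros(d * T)
    for eps in eps_seq:
        res = minimize(
            make(eps), w, jac=True, method="L-BFGS-B",
            options=dict(maxiter=20000, ftol=1e-18, gtol=1e-14),
        )
        w = res.x
    return objective(design, w.reshape(d, T), params)


def tv_prox_oracle(v: np.ndarray, lam: float) -> np.ndarray:
    """TV prox via the box-constrained dual: x = v - D^T z*,
    z* = argmin ||D^T z - v||^2 over the box [-lam, lam]^(n-1)."""
    v = np.asarray(v, dtype=float)
    n = v.size
    if n <= 1 or lam <= 0:
        return v.copy()
    D = np.diff(np.eye(n), axis=0)
    res = lsq_linear(D.T, v, bounds=(-lam, lam), tol=1e-14, max_iter=5000)
    return v - D.T @ res.x


def in_convex_hull(point: np.ndarray, cloud: np.ndarray, tol: float = 1e-7) -> bool:
    """LP feasibility: does `point` lie in the convex hull of `cloud` rows?"""
    cloud = np.asarray(cloud, dtype=float)
    point = np.asarray(point, dtype=float)
    m = len(cloud)
    A_eq = np.vstack([cloud.T, np.ones(m)])
    b_eq = np.append(point, 1.0)
    res = linprog(np.zeros(m), A_eq=A_eq, b_eq=b_eq, bounds=[(0, None)] * m, method="highs")
    if not res.success:
        return False
    return bool(np.max(np.abs(A_eq @ res.x - b_eq)) < tol)


def brute_force_auc(scores, labels) -> float:
    """All-pairs Mann-Whitney AUC with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    pos = s[y]
    neg = s[~y]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_design(rng, d=None, T=None, n=None) -> LongitudinalDesign:
    d = d or int(rng.integers(2, 9))
    T = T or int(rng.integers(2, 4))
    n = n or int(rng.integers(3, 13))
    X = [rng.normal(size=(n, d)) for _ in range(T)]
    y = [rng.normal(size=n) * 3 for _ in range(T)]
    return LongitudinalDesign(X, y)
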