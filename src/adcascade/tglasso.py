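"""Temporally constrained group-sparse regression (tgLASSO).

Selects longitudinal imaging features by regressing per-visit cognitive
scores (MMSE) on per-visit feature matrices under three penalties:

* an L2,1 group penalty across visits (row-wise sparsity: a feature is
  selected jointly for all visits or not at all),
* a fused-lasso L1 penalty on adjacent-visit weight differences
  (piecewise-constant temporal weight profiles),
* a quadratic penalty on adjacent-visit fitted-output differences
  (smoothly varying predictions over time).

The objective is

    J(W) = 1/2 sum_j ||y_j - X_j w_j||^2
         + lambda1 * sum_rows ||W_row||_2
         + lambda2 * sum_j ||w_j - w_{j+1}||_1
         + lambda3 * sum_j ||X_j w_j - X_{j+1} w_{j+1}||^2

minimised over the d x T weight matrix W whose column j is w_j.  The
problem is convex; :func:`fit` solves it with consensus ADMM, splitting
the two nonsmooth penalties into separate blocks with closed-form
proximal maps (row-wise group soft-thresholding and an exact 1-D
total-variation prox).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "LongitudinalDesign",
    "RegularizationParams",
    "SolveReport",
    "loss",
    "group_penalty",
    "smooth_penalty",
    "objective",
    "lambda_zero_threshold",
    "fit",
    "standardize_design",
    "tv1d_prox",
]


@dataclass
class LongitudinalDesign:
    """Per-visit feature matrices X_j (n_j x d) and responses y_j (n_j,).

    Rows of adjacent X_j must correspond to the same subjects whenever the
    output-smoothness penalty (lambda3 > 0) is used.
    """

    X: list[np.ndarray]
    y: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise ValueError("X and y must have the same number of time points")
        if len(self.X) < 1:
            raise ValueError("a design needs at least one time point")
        self.X = [np.asarray(Xj, dtype=float) for Xj in self.X]
        self.y = [np.asarray(yj, dtype=float).ravel() for yj in self.y]
        d = self.X[0].shape[1]
        for j, (Xj, yj) in enumerate(zip(self.X, self.y)):
            if Xj.ndim != 2 or Xj.shape[1] != d:
                raise ValueError(f"X[{j}] must be 2-D with {d} columns")
            if Xj.shape[0] != yj.shape[0]:
                raise ValueError(f"X[{j}] has {Xj.shape[0]} rows but y[{j}] has {yj.shape[0]}")

    @property
    def T(self) -> int:
        return len(self.X)

    @property
    def d(self) -> int:
        return self.X[0].shape[1]

    @property
    def aligned(self) -> bool:
        n0 = self.X[0].shape[0]
        return all(Xj.shape[0] == n0 for Xj in self.X)


@dataclass
class RegularizationParams:
    """Penalty weights; defaults are the study's settings."""

    lambda1: float = 0.25
    lambda2: float = 0.08
    lambda3: float = 0.04

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SolveReport:
    """Result of :func:`fit`.

    ``objective_trace[k]`` is the best objective value found up to and
    including iteration k, so the trace is non-increasing by construction;
    ``W_hat`` is the iterate attaining the final trace value.
    """

    W_hat: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    iterations: int
    tolerance: float
    params: RegularizationParams = field(default_factory=RegularizationParams)


def _check_W(design: LongitudinalDesign, W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.shape != (design.d, design.T):
        raise ValueError(f"W must have shape ({design.d}, {design.T}), got {W.shape}")
    return W


def loss(design: LongitudinalDesign, W: np.ndarray) -> float:
    """Squared-error data term 1/2 sum_j ||y_j - X_j w_j||^2."""
    W = _check_W(design, W)
    total = 0.0
    for j in range(design.T):
        r = design.y[j] - design.X[j] @ W[:, j]
        total += 0.5 * float(r @ r)
    return total


def group_penalty(W: np.ndarray, lambda1: float) -> float:
    """L2,1 penalty: lambda1 * sum over feature rows of the row 2-norm."""
    if lambda1 < 0:
        raise ValueError("lambda1 must be >= 0")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    return lambda1 * float(np.linalg.norm(W, axis=1).sum())


def smooth_penalty(
    design: LongitudinalDesign, W: np.ndarray, lambda2: float, lambda3: float
) -> float:
    """Fused-L1 temporal penalty plus quadratic output-smoothness penalty.

    With a single time point both sums are empty and the penalty is 0.
    """
    if lambda2 < 0 or lambda3 < 0:
        raise ValueError("lambda2 and lambda3 must be >= 0")
    W = _check_W(design, W)
    if design.T < 2:
        return 0.0
    fused = float(np.abs(np.diff(W, axis=1)).sum())
    out = 0.0
    if lambda3 > 0:
        if not design.aligned:
            raise ValueError(
                "the output-smoothness penalty (lambda3 > 0) requires row-aligned "
                "designs with equal n_j at every time point"
            )
        for j in range(design.T - 1):
            dout = design.X[j] @ W[:, j] - design.X[j + 1] @ W[:, j + 1]
            out += float(dout @ dout)
    return lambda2 * fused + lambda3 * out


def objective(
    design: LongitudinalDesign, W: np.ndarray, params: RegularizationParams
) -> float:
    """Full tgLASSO objective J(W)."""
    return (
        loss(design, W)
        + group_penalty(W, params.lambda1)
        + smooth_penalty(design, W, params.lambda2, params.lambda3)
    )


def lambda_zero_threshold(design: LongitudinalDesign) -> float:
    """Smallest lambda1 (with lambda2 = lambda3 = 0) at which W = 0 is optimal.

    The zero matrix satisfies the L2,1 subgradient condition iff every row of
    the stacked correlations X_j^T y_j has Euclidean norm <= lambda1; the
    threshold is the maximum row norm.
    """
    B = np.column_stack([design.X[j].T @ design.y[j] for j in range(design.T)])
    return float(np.linalg.norm(B, axis=1).max(initial=0.0))


def tv1d_prox(v: np.ndarray, lam: float) -> np.ndarray:
    """Exact prox of lam * total variation in 1-D (Condat's direct algorithm).

    Returns argmin_x 1/2 ||x - v||^2 + lam * sum |x_{i+1} - x_i|.
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if n <= 1 or lam <= 0:
        return v.copy()
    x = np.empty(n)
    # indices are 0-based; [k0, km] / [k0, kp] are the candidate segments
    k = k0 = km = kp = 0
    vmin = v[0] - lam
    vmax = v[0] + lam
    umin = lam
    umax = -lam
    while True:
        if k == n - 1:
            if umin < 0.0:
                x[k0 : km + 1] = vmin
                k = k0 = km = km + 1
                kp = max(kp, k)
                vmin = v[k]
                umin = lam
                umax = v[k] + lam - vmax
            elif umax > 0.0:
                x[k0 : kp + 1] = vmax
                k = k0 = kp = kp + 1
                km = max(km, k)
                vmax = v[k]
                umax = -lam
                umin = v[k] - lam - vmin
            else:
                x[k0:n] = vmin + umin / (k - k0 + 1)
                return x
            if k == n - 1:
                x[k] = vmin + umin
                return x
            continue
        if v[k + 1] + umin < vmin - lam:
            # segment [k0, km] is final at value vmin
            x[k0 : km + 1] = vmin
            k = k0 = km = kp = km + 1
            vmin = v[k]
            vmax = v[k] + 2.0 * lam
            umin = lam
            umax = -lam
        elif v[k + 1] + umax > vmax + lam:
            # segment [k0, kp] is final at value vmax
            x[k0 : kp + 1] = vmax
            k = k0 = km = kp = kp + 1
            vmin = v[k] - 2.0 * lam
            vmax = v[k]
            umin = lam
            umax = -lam
        else:
            k += 1
            umin += v[k] - vmin
            umax += v[k] - vmax
            if umin >= lam:
                vmin += (umin - lam) / (k - k0 + 1)
                umin = lam
                km = k
            if umax <= -lam:
                vmax += (umax + lam) / (k - k0 + 1)
                umax = -lam
                kp = k


def _group_shrink(M: np.ndarray, thresh: float) -> np.ndarray:
    """Row-wise group soft-thresholding (prox of thresh * L2,1)."""
    norms = np.linalg.norm(M, axis=1)
    scale = np.zeros_like(norms)
    nz = norms > thresh
    scale[nz] = 1.0 - thresh / norms[nz]
    return M * scale[:, None]


def standardize_design(
    design: LongitudinalDesign,
) -> tuple[LongitudinalDesign, dict]:
    """Z-score feature columns and center responses, per time point.

    Returns the standardized design and the per-visit statistics
    (column means/SDs of X, mean of y).  Constant columns get unit scale.
    Used by the high-level selection pipeline; the penalties are
    scale-sensitive, so features are put on a common scale before fitting.
    """
    Xs, ys, stats = [], [], []
    for Xj, yj in zip(design.X, design.y):
        mu = Xj.mean(axis=0)
        sd = Xj.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        ym = yj.mean()
        Xs.append((Xj - mu) / sd)
        ys.append(yj - ym)
        stats.append({"x_mean": mu, "x_sd": sd, "y_mean": ym})
    return LongitudinalDesign(Xs, ys), {"per_visit": stats}


def fit(
    design: LongitudinalDesign,
    params: RegularizationParams | None = None,
    *,
    max_iter: int = 5000,
    tol: float = 1e-8,
    init: np.ndarray | None = None,
    rho: float | None = None,
) -> SolveReport:
    """Minimise the tgLASSO objective by consensus ADMM.

    The smooth part (squared loss + output smoothness) is handled by a
    linear solve against a cached Cholesky factor; the two nonsmooth
    penalties get separate consensus copies with closed-form proxes.
    Stops when the relative decrease of the best objective stalls below
    ``tol`` and the consensus residuals are small; otherwise runs to
    ``max_iter`` and reports ``converged=False``.
    """
    params = params or RegularizationParams()
    d, T = design.d, design.T
    for j in range(T):
        if not (np.isfinite(design.X[j]).all() and np.isfinite(design.y[j]).all()):
            raise ValueError(f"non-finite values in the design at time point {j}")
    if params.lambda3 > 0 and not design.aligned:
        raise ValueError(
            "the output-smoothness penalty (lambda3 > 0) requires row-aligned "
            "designs with equal n_j at every time point"
        )

    G = [design.X[j].T @ design.X[j] for j in range(T)]
    b = np.column_stack([design.X[j].T @ design.y[j] for j in range(T)])

    # the consensus penalty must sit on the scale of the data-term curvature,
    # otherwise the W-update all but ignores the Z copies
    if rho is None:
        curv = np.mean([np.trace(Gj) / d for Gj in G])
        rho = float(max(curv, 1.0))
    rho_bounds = (rho * 1e-6, rho * 1e6)

    # Block-tridiagonal Hessian of the smooth part, in time-major vec order.
    H0 = np.zeros((d * T, d * T))
    for j in range(T):
        c = (1 if j > 0 else 0) + (1 if j < T - 1 else 0)
        H0[j * d : (j + 1) * d, j * d : (j + 1) * d] = (1.0 + 2.0 * params.lambda3 * c) * G[j]
    if params.lambda3 > 0:
        for j in range(T - 1):
            C = -2.0 * params.lambda3 * (design.X[j].T @ design.X[j + 1])
            H0[j * d : (j + 1) * d, (j + 1) * d : (j + 2) * d] = C
            H0[(j + 1) * d : (j + 2) * d, j * d : (j + 1) * d] = C.T

    def factor(rho_val: float):
        return scipy.linalg.cho_factor(H0 + 2.0 * rho_val * np.eye(d * T))

    cho = factor(rho)

    W = np.zeros((d, T)) if init is None else _check_W(design, init).copy()
    Z1 = W.copy()
    Z2 = W.copy()
    U1 = np.zeros_like(W)
    U2 = np.zeros_like(W)

    def J(M: np.ndarray) -> float:
        return objective(design, M, params)

    best_J = J(Z1)
    best_W = Z1.copy()
    trace = [best_J]
    converged = False
    stall = 0
    it = 0

    for it in range(1, max_iter + 1):
        rhs = b + rho * ((Z1 - U1) + (Z2 - U2))
        W = scipy.linalg.cho_solve(cho, rhs.ravel(order="F")).reshape((d, T), order="F")

        Z1_old, Z2_old = Z1, Z2
        M1 = W + U1
        Z1 = _group_shrink(M1, params.lambda1 / rho) if params.lambda1 > 0 else M1.copy()
        M2 = W + U2
        if params.lambda2 > 0:
            Z2 = np.empty_like(M2)
            lam = params.lambda2 / rho
            for i in range(d):
                Z2[i] = tv1d_prox(M2[i], lam)
        else:
            Z2 = M2.copy()
        U1 = U1 + W - Z1
        U2 = U2 + W - Z2

        # track the group-sparse consensus copy: it carries exact zero rows
        prev_best = best_J
        Jc = J(Z1)
        if Jc < best_J:
            best_J = Jc
            best_W = Z1.copy()
        trace.append(best_J)

        r = np.sqrt(np.linalg.norm(W - Z1) ** 2 + np.linalg.norm(W - Z2) ** 2)
        s = rho * np.sqrt(
            np.linalg.norm(Z1 - Z1_old) ** 2 + np.linalg.norm(Z2 - Z2_old) ** 2
        )
        scale = max(np.linalg.norm(W), np.linalg.norm(Z1), np.linalg.norm(Z2), 1.0)

        rel_drop = (prev_best - best_J) / max(abs(prev_best), 1.0)
        stall = stall + 1 if rel_drop < tol else 0
        if stall >= 10 and r <= 1e-7 * scale and s <= 1e-7 * scale:
            converged = True
            break

        # residual balancing keeps the two consensus blocks progressing together
        if it % 25 == 0 and (r > 10.0 * s or s > 10.0 * r):
            new_rho = rho * 2.0 if r > 10.0 * s else rho / 2.0
            new_rho = float(np.clip(new_rho, *rho_bounds))
            if new_rho != rho:
                U1 *= rho / new_rho
                U2 *= rho / new_rho
                rho = new_rho
                cho = factor(rho)

    return SolveReport(
        W_hat=best_W,
        objective_trace=np.asarray(trace),
        converged=converged,
        iterations=it,
        tolerance=tol,
        params=params,
    )
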