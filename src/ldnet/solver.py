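"""Direct difference estimation by constrained l1 minimization.

Estimates Delta = Omega2 - Omega1, the difference of two groups'
latent precision matrices, without estimating either precision matrix:

    minimize |Delta|_1   subject to
    |S1 Delta S2 - S1 + S2|_inf <= lambda

with S1, S2 the two groups' (rank-based) correlation estimates.  In
symmetric-vectorized form (theta the p(p+1)/2 free parameters, Gamma the
duplication map) the constraint splits into an infinity-norm box:
off-diagonal coordinates of Gamma^T S Gamma theta - Gamma^T s bounded by
lambda, diagonal coordinates by lambda / 2.  The box constraint is
handled by ADMM: a projection z-update, an l1-penalized least-squares
theta-update (solved by FISTA), and an unscaled dual ascent step.

The Kronecker product S1 (x) S2 is never formed: each operator
application is the matrix sandwich S2 Delta(theta) S1 followed by the
Gamma^T projection, so memory stays O(p^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .vectorize import SymmetricVectorizer

__all__ = [
    "QuadraticOperator",
    "DifferenceProblem",
    "DifferenceEstimate",
    "apply_quadratic_operator",
    "project_z",
    "update_theta",
    "admm_solve",
    "solve_path",
    "threshold_support",
    "lambda_max",
]


class QuadraticOperator:
    """The symmetric linear map A(theta) = Gamma^T (S1 (x) S2) Gamma theta,
    applied Kronecker-free as Gamma^T vec(S2 Delta(theta) S1)."""

    def __init__(self, s1, s2, vectorizer=None):
        s1 = np.asarray(s1, dtype=float)
        s2 = np.asarray(s2, dtype=float)
        if s1.shape != s2.shape or s1.ndim != 2 or s1.shape[0] != s1.shape[1]:
            raise ValueError("s1 and s2 must be square matrices of equal size")
        self.s1 = s1
        self.s2 = s2
        self.vectorizer = vectorizer or SymmetricVectorizer(s1.shape[0])
        self._opnorm = None
        p = s1.shape[0]
        # scratch buffers: applications sit in the solver's innermost loop
        self._m = np.zeros((p, p))
        self._t1 = np.empty((p, p))
        self._t2 = np.empty((p, p))

    def __call__(self, theta):
        v = self.vectorizer
        m = self._m
        m[v.rows, v.cols] = theta
        m[v.cols, v.rows] = theta
        np.dot(self.s2, m, out=self._t1)
        np.dot(self._t1, self.s1, out=self._t2)
        w = self._t2
        out = w[v.rows, v.cols]
        out += w[v.cols, v.rows]
        out[v.is_diag] *= 0.5
        return out

    @property
    def opnorm(self):
        """Largest |eigenvalue| of the (symmetric) operator, by power
        iteration; cached."""
        if self._opnorm is None:
            rng = np.random.default_rng(0)
            x = rng.standard_normal(self.vectorizer.dim)
            x /= np.linalg.norm(x)
            lam = 0.0
            for _ in range(200):
                y = self(x)
                ny = np.linalg.norm(y)
                if ny == 0:
                    lam = 0.0
                    break
                x_new = y / ny
                if abs(ny - lam) < 1e-10 * max(ny, 1.0):
                    lam = ny
                    break
                lam = ny
                x = x_new
            self._opnorm = max(lam, 1e-12)
        return self._opnorm


def apply_quadratic_operator(vectorizer, s1, s2, theta):
    """Functional form of :class:`QuadraticOperator` application."""
    return QuadraticOperator(s1, s2, vectorizer)(theta)


@dataclass
class DifferenceProblem:
    """The data of one direct-difference problem: the two correlation
    estimates and their vectorized target Gamma^T vec(s1 - s2)."""

    s1: np.ndarray
    s2: np.ndarray
    vectorizer: SymmetricVectorizer = field(init=False)
    operator: QuadraticOperator = field(init=False)
    target: np.ndarray = field(init=False)

    def __post_init__(self):
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        self.vectorizer = SymmetricVectorizer(self.s1.shape[0])
        self.operator = QuadraticOperator(self.s1, self.s2, self.vectorizer)
        self.target = self.vectorizer.gamma_t(self.s1 - self.s2)

    @property
    def p(self):
        return self.s1.shape[0]


def lambda_max(problem: DifferenceProblem) -> float:
    """Smallest lambda at which theta = 0 is feasible (z = target lies in
    the box), i.e. max of off-diagonal |target| and 2x diagonal |target|."""
    t = problem.target
    d = problem.vectorizer.is_diag
    off = np.abs(t[~d]).max() if (~d).any() else 0.0
    dia = 2.0 * np.abs(t[d]).max() if d.any() else 0.0
    return float(max(off, dia, 1e-12))


@dataclass
class DifferenceEstimate:
    """One solution of the constrained problem at a fixed lambda."""

    delta: np.ndarray
    theta: np.ndarray
    lam: float
    rho: float
    iterations: int
    converged: bool
    primal_residuals: np.ndarray
    dual_residuals: np.ndarray
    dual: np.ndarray = None

    @property
    def n_nonzero(self):
        """|theta|_0 above numerical zero (1e-5), the AIC degrees of
        freedom."""
        return int(np.sum(np.abs(self.theta) > 1e-5))


def project_z(v, lam, vectorizer):
    """Project onto the split box: off-diagonal coordinates clipped to
    [-lambda, lambda], diagonal coordinates to [-lambda/2, lambda/2]."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    v = np.asarray(v, dtype=float)
    bound = np.where(vectorizer.is_diag, lam / 2.0, lam)
    return np.clip(v, -bound, bound)


def _soft(x, thr):
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def update_theta(operator, v, rho, theta0, inner_tol=1e-8, max_inner=500):
    """Solve  argmin_theta |A theta - v|_2^2 + (2/rho) |theta|_1  by FISTA.

    Gradient of the smooth part is 2 A(A theta - v); step 1/L with
    L = 2 ||A||_2^2 from the cached power-iteration norm.  Returns
    (theta, n_iterations, converged).
    """
    if rho <= 0:
        raise ValueError("rho must be positive")
    L = 2.0 * operator.opnorm**2
    step = 1.0 / L
    shrink = step * 2.0 / rho
    theta = np.asarray(theta0, dtype=float).copy()
    y = theta.copy()
    t_acc = 1.0
    for it in range(1, max_inner + 1):
        grad = 2.0 * operator(operator(y) - v)
        theta_new = _soft(y - step * grad, shrink)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_acc**2))
        y = theta_new + ((t_acc - 1.0) / t_new) * (theta_new - theta)
        change = np.max(np.abs(theta_new - theta))
        theta, t_acc = theta_new, t_new
        if change < inner_tol:
            return theta, it, True
    return theta, max_inner, False


def admm_solve(
    problem: DifferenceProblem,
    lam: float,
    rho: float = 1.0,
    max_iter: int = 5000,
    eps_abs: float = 1e-7,
    eps_rel: float = 1e-5,
    theta0=None,
    u0=None,
    inner_tol: float = 1e-8,
    max_inner: int = 100,
) -> DifferenceEstimate:
    """ADMM for the box-constrained l1 problem at one lambda.

    Iterates, for t = 0, 1, ...:
      z      <- clip(u/rho + c - A theta, box(lambda, lambda/2))
      theta  <- argmin |u/rho + c - A theta - z|^2 + 2 |theta|_1 / rho
      u      <- u + rho (c - A theta - z)
    with c = Gamma^T vec(s1 - s2).  The theta subproblem is solved
    inexactly (a few warm-started FISTA steps per sweep; the error
    vanishes as the outer iteration converges).  Stopping is on
    infinity-norm primal and dual residuals with combined
    absolute/relative tolerances

      |c - A theta - z|_inf      < eps_abs + eps_rel * max(|A theta|, |z|, |c|)_inf
      |rho A(theta - theta_old)|_inf < eps_abs + eps_rel * |A u|_inf,

    which adapts to the scale (and conditioning) of the correlation pair.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    op = problem.operator
    vzr = problem.vectorizer
    c = problem.target
    q = vzr.dim
    theta = np.zeros(q) if theta0 is None else np.asarray(theta0, float).copy()
    u = np.zeros(q) if u0 is None else np.asarray(u0, float).copy()
    prim_hist, dual_hist = [], []
    converged = False
    it = 0
    a_theta = op(theta)
    for it in range(1, max_iter + 1):
        z = project_z(u / rho + c - a_theta, lam, vzr)
        theta_old = theta
        theta, _, _ = update_theta(
            op, u / rho + c - z, rho, theta, inner_tol, max_inner
        )
        a_theta = op(theta)
        r = c - a_theta - z
        u = u + rho * r
        s = rho * op(theta - theta_old)
        prim = float(np.max(np.abs(r)))
        dual = float(np.max(np.abs(s)))
        prim_hist.append(prim)
        dual_hist.append(dual)
        eps_p = eps_abs + eps_rel * max(
            np.abs(a_theta).max(), np.abs(z).max(), np.abs(c).max()
        )
        eps_d = eps_abs + eps_rel * float(np.abs(op(u)).max())
        if prim < eps_p and dual < eps_d:
            converged = True
            break
    return DifferenceEstimate(
        delta=vzr.to_matrix(theta),
        theta=theta,
        lam=float(lam),
        rho=float(rho),
        iterations=it,
        converged=converged,
        primal_residuals=np.asarray(prim_hist),
        dual_residuals=np.asarray(dual_hist),
        dual=u,
    )


def default_lambda_grid(problem, n_lambda=50, ratio=0.01):
    """Log-spaced lambda grid strictly inside the nonempty region.

    `lambda_max(problem)` is the smallest lambda whose solution is
    exactly zero; as in lasso-path software, the trivial all-zero
    solution is excluded and the path starts one log-step inside it, so
    every grid point carries a nonzero estimate and a defined discovery
    rate.  n_lambda points span down to ratio * lambda_max.
    """
    lmax = lambda_max(problem)
    return np.geomspace(lmax, ratio * lmax, n_lambda + 1)[1:]


def solve_path(problem, lambda_grid=None, rho=1.0, stop_when=None, **kwargs):
    """Warm-started solutions along a decreasing lambda grid.

    Both theta and the dual variable are carried from one lambda to the
    next.  `stop_when`, if given, is called with the list of estimates
    so far and may return True to truncate the path early (used by the
    AIC search to skip the dense tail once the criterion has clearly
    passed its minimum).
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(problem)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    estimates = []
    theta = u = None
    for lam in lambda_grid:
        est = admm_solve(problem, lam, rho=rho, theta0=theta, u0=u, **kwargs)
        theta, u = est.theta, est.dual
        estimates.append(est)
        if stop_when is not None and stop_when(estimates):
            break
    return estimates


def threshold_support(delta_hat, tau_threshold=1e-5):
    """Zero out entries with |delta| <= tau_threshold, keeping signs of
    the survivors; the support-recovery hardening step."""
    if tau_threshold < 0:
        raise ValueError("threshold must be nonnegative")
    delta_hat = np.asarray(delta_hat, dtype=float)
    return np.where(np.abs(delta_hat) > tau_threshold, delta_hat, 0.0)
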