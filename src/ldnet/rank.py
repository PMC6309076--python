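"""Rank-based latent correlation estimation.

Estimates the correlation matrix of latent Gaussian-copula variables from
observed continuous, binary, or mixed data.  For continuous pairs the
classical sine transform of Kendall's tau applies; for pairs involving
dichotomized variables the population Kendall's tau is a "bridge" function
of the latent correlation and the (transformed) dichotomization cutoffs,
which is inverted numerically.

All Kendall's tau statistics here are the tau-a form

    tau_jk = 2 / (n (n - 1)) * sum_{i < i'} sign(x_ij - x_i'j) sign(x_ik - x_i'k),

i.e. tied pairs contribute zero and no tie correction is applied.  This is
the form the bridge functions assume: for binary data the attainable range
of tau-a shrinks with the cutoffs, and the bridges account for that
explicitly.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.stats import norm

from .data import DataMatrix

__all__ = [
    "kendall_tau",
    "kendall_tau_matrix",
    "npn_correlation_entry",
    "bvn_cdf",
    "bridge_F",
    "bridge_F_inverse",
    "bridge_H",
    "bridge_H_inverse",
    "estimate_cutoffs",
    "latent_correlation",
    "LatentCorrelation",
    "pearson_correlation",
]

# Latent correlations are kept strictly inside (-1, 1); bridge inversion
# brackets roots on [-1 + T_EPS, 1 - T_EPS].
T_EPS = 1e-6
_INV_TOL = 1e-8

# Gauss-Legendre rule for the bivariate-normal integral; 64 nodes give
# ~1e-14 accuracy on the smooth trigonometric form, well below the
# 1e-8 inversion tolerance.
_GL_NODES, _GL_WEIGHTS = leggauss(64)


def kendall_tau(x, y):
    """Kendall's tau-a between two equal-length samples.

    Ties contribute zero to the sum; the denominator is always n(n-1)/2
    pairs.  For binary 0/1 vectors this is NOT the tie-corrected tau-b.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("kendall_tau needs at least 2 observations")
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    # each unordered pair counted twice in the full sign-product sum
    return float(np.sum(sx * sy) / (n * (n - 1)))


def kendall_tau_matrix(values: np.ndarray) -> np.ndarray:
    """All pairwise Kendall tau-a statistics of the columns of `values`.

    Vectorized through the identity
        sum_{i,i'} sign(dx) sign(dy) = <vec(Sx), vec(Sy)>
    with Sx the n-by-n pairwise sign matrix of a column, so the whole
    matrix is a single GEMM on the stacked sign matrices.
    """
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    signs = np.sign(values[:, None, :] - values[None, :, :])  # (n, n, p)
    flat = signs.reshape(n * n, p)
    g = flat.T @ flat
    tau = g / (n * (n - 1))
    np.fill_diagonal(tau, 1.0)
    return tau


def npn_correlation_entry(tau):
    """Sine transform sin(pi * tau / 2) mapping Kendall's tau of a
    Gaussian-copula pair to its latent Pearson correlation."""
    tau = np.asarray(tau, dtype=float)
    if np.any(np.abs(tau) > 1):
        raise ValueError("|tau| must not exceed 1")
    out = np.sin(np.pi * tau / 2.0)
    return float(out) if out.ndim == 0 else out


def _bvn_integral(h, k, rho):
    """The correlation-dependent part of the bivariate normal CDF,

        Q(h, k, rho) = Phi2(h, k, rho) - Phi(h) Phi(k)
                     = 1/(2 pi) * int_0^{asin rho}
                         exp(-(h^2 + k^2 - 2 h k sin t) / (2 cos^2 t)) dt,

    evaluated with a fixed Gauss-Legendre rule.  Exactly zero at rho = 0,
    smooth up to |rho| = 1.  Broadcasts over array arguments.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    upper = np.arcsin(np.clip(rho, -1.0, 1.0))
    # map [-1, 1] nodes onto [0, upper]
    half = upper[..., None] / 2.0
    t = half * (_GL_NODES + 1.0)
    cos2 = np.cos(t) ** 2
    hh = h[..., None]
    kk = k[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        integrand = np.exp(-(hh**2 + kk**2 - 2.0 * hh * kk * np.sin(t)) / (2.0 * cos2))
    integrand = np.where(cos2 > 0, integrand, 0.0)
    return (integrand * _GL_WEIGHTS).sum(axis=-1) * half[..., 0] / (2.0 * np.pi)


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X1 < h, X2 < k) with correlation rho."""
    return norm.cdf(h) * norm.cdf(k) + _bvn_integral(h, k, rho)


def bridge_F(t, lam_j, lam_k):
    """Population Kendall's tau of two latent-Gaussian variables
    dichotomized at cutoffs lam_j, lam_k, as a function of their latent
    correlation t:  F(t) = 2 {Phi2(lam_j, lam_k, t) - Phi(lam_j) Phi(lam_k)}.

    Strictly increasing in t on (-1, 1) for fixed cutoffs.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.abs(t) >= 1):
        raise ValueError("|t| must be < 1")
    out = 2.0 * _bvn_integral(lam_j, lam_k, t)
    return float(out) if out.ndim == 0 else out


def bridge_H(t, lam_j):
    """Population Kendall's tau between a dichotomized (cutoff lam_j) and a
    continuous latent coordinate with latent correlation t:

        H(t) = 4 Phi2(lam_j, 0, t / sqrt(2)) - 2 Phi(lam_j).

    Strictly increasing in t on (-1, 1) for fixed lam_j.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.abs(t) >= 1):
        raise ValueError("|t| must be < 1")
    # Phi2(l, 0, r) = Phi(l)/2 + Q(l, 0, r), so the Phi terms cancel
    out = 4.0 * _bvn_integral(lam_j, 0.0, t / np.sqrt(2.0))
    return float(out) if out.ndim == 0 else out


def _bisect_bridge(bridge, tau, n_iter=60):
    """Vectorized monotone bisection of `bridge` on [-1+T_EPS, 1-T_EPS].

    `bridge` maps an array of t values to the corresponding taus; `tau`
    values outside the attainable range are clipped to the bracket
    endpoint.  60 halvings of the length-2 bracket reach ~2e-18, far
    below the 1e-8 target.
    """
    tau = np.asarray(tau, dtype=float)
    lo = np.full(tau.shape, -1.0 + T_EPS)
    hi = np.full(tau.shape, 1.0 - T_EPS)
    f_lo = bridge(lo)
    f_hi = bridge(hi)
    out_lo = tau <= f_lo
    out_hi = tau >= f_hi
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        f_mid = bridge(mid)
        take_hi = f_mid < tau
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    root = 0.5 * (lo + hi)
    root = np.where(out_lo, -1.0 + T_EPS, root)
    root = np.where(out_hi, 1.0 - T_EPS, root)
    resid = np.abs(bridge(root) - tau)
    ok = out_lo | out_hi | (np.abs(hi - lo) < 1e-12) | (resid < 1e-6)
    if not np.all(ok):
        bad = np.argwhere(~ok)
        raise FloatingPointError(
            f"bridge inversion failed to converge at entries {bad[:5].tolist()}"
        )
    return root


def bridge_F_inverse(tau, lam_j, lam_k):
    """Invert the binary-binary bridge: the latent correlation t with
    F(t; lam_j, lam_k) = tau.  Taus outside the attainable range are
    clipped to the nearest endpoint of [-1 + 1e-6, 1 - 1e-6]."""
    lam_j = np.asarray(lam_j, float)
    lam_k = np.asarray(lam_k, float)
    out = _bisect_bridge(lambda t: 2.0 * _bvn_integral(lam_j, lam_k, t), tau)
    return float(out) if out.ndim == 0 else out


def bridge_H_inverse(tau, lam_j):
    """Invert the binary-continuous bridge H(t; lam_j) = tau, with the same
    clipping convention as `bridge_F_inverse`."""
    lam_j = np.asarray(lam_j, float)
    out = _bisect_bridge(
        lambda t: 4.0 * _bvn_integral(lam_j, 0.0, t / np.sqrt(2.0)), tau
    )
    return float(out) if out.ndim == 0 else out


def estimate_cutoffs(data: DataMatrix) -> np.ndarray:
    """Estimate the transformed dichotomization cutoffs Lambda_j for the
    binary columns of `data` as Phi^{-1}(1 - mean(B_j)).

    Column means are clamped to [1/(2n), 1 - 1/(2n)] so that constant
    binary columns yield finite cutoffs.  Continuous columns get NaN.
    """
    values = data.values
    n = values.shape[0]
    lam = np.full(values.shape[1], np.nan)
    if data.n_binary:
        means = values[:, data.binary_mask].mean(axis=0)
        means = np.clip(means, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
        lam[data.binary_mask] = norm.ppf(1.0 - means)
    return lam


class LatentCorrelation:
    """A rank-based estimate of the latent correlation matrix.

    Attributes
    ----------
    matrix : (p, p) ndarray
        Symmetric with unit diagonal; off-diagonals in (-1, 1).
    source : str
        'npn' (all continuous), 'binary', 'mixed', or 'pearson'.
    cutoffs : ndarray or None
        Estimated transformed cutoffs for binary variables (NaN elsewhere).
    """

    def __init__(self, matrix, source, cutoffs=None, names=None):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("correlation matrix must be square")
        self.matrix = matrix
        self.source = source
        self.cutoffs = cutoffs
        self.names = list(names) if names is not None else None

    @property
    def p(self):
        return self.matrix.shape[0]

    def nearest_psd(self, eps=1e-8):
        """Optional projection to the nearest positive semidefinite
        correlation matrix (eigenvalue clipping + rediagonalization).
        The direct difference estimator does not require PSD input; this
        exists for downstream reuse of the correlation estimate."""
        w, v = np.linalg.eigh(self.matrix)
        if w.min() >= eps:
            return self
        w = np.clip(w, eps, None)
        m = (v * w) @ v.T
        d = np.sqrt(np.diag(m))
        m = m / np.outer(d, d)
        np.fill_diagonal(m, 1.0)
        return LatentCorrelation(m, self.source, self.cutoffs, self.names)


def pearson_correlation(data: DataMatrix) -> LatentCorrelation:
    """Sample Pearson correlation of the observed columns (the non-rank
    baseline plugged into the same direct difference estimator)."""
    corr = np.corrcoef(data.values, rowvar=False)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return LatentCorrelation(corr, "pearson", names=data.names)


def latent_correlation(data: DataMatrix, clip_eps: float = T_EPS,
                       psd: object = "auto") -> LatentCorrelation:
    """Rank-based latent correlation matrix of one group.

    Dispatches per pair of column types: sine transform for
    continuous-continuous, inverse-F bridge for binary-binary, inverse-H
    bridge for binary-continuous.  The result is exactly symmetric with
    unit diagonal; off-diagonals are clipped into
    [-1 + clip_eps, 1 - clip_eps].

    psd : 'auto', True or False
        Whether to project the result to the nearest positive
        semidefinite correlation matrix.  Entrywise bridge inversion can
        produce severely indefinite matrices when cutoffs are extreme
        (the flat bridge tails amplify tau noise, occasionally clipping
        an entry near +/-1), which both misleads the downstream
        difference estimator and wrecks its conditioning; the projection
        is the standard regularization for plugging latent-copula
        estimates into matrix procedures.  'auto' projects exactly when
        any binary column is present — the all-continuous sine estimate
        does not suffer from inversion blow-ups and is left as computed.
    """
    values = data.values
    p = values.shape[1]
    tau = kendall_tau_matrix(values)
    lam = estimate_cutoffs(data)
    bmask = data.binary_mask

    corr = np.eye(p)
    iu, ju = np.triu_indices(p, k=1)
    pair_bb = bmask[iu] & bmask[ju]
    pair_cc = ~bmask[iu] & ~bmask[ju]
    pair_mix = ~(pair_bb | pair_cc)

    est = np.empty(iu.size)
    if pair_cc.any():
        est[pair_cc] = np.sin(np.pi * tau[iu[pair_cc], ju[pair_cc]] / 2.0)
    if pair_bb.any():
        i, j = iu[pair_bb], ju[pair_bb]
        est[pair_bb] = bridge_F_inverse(tau[i, j], lam[i], lam[j])
    if pair_mix.any():
        i, j = iu[pair_mix], ju[pair_mix]
        # the H bridge takes the cutoff of whichever column is binary
        lam_bin = np.where(bmask[i], lam[i], lam[j])
        est[pair_mix] = bridge_H_inverse(tau[i, j], lam_bin)

    est = np.clip(est, -1.0 + clip_eps, 1.0 - clip_eps)
    corr[iu, ju] = est
    corr[ju, iu] = est

    if data.n_binary == 0:
        source = "npn"
    elif data.n_binary == p:
        source = "binary"
    else:
        source = "mixed"
    result = LatentCorrelation(corr, source, cutoffs=lam, names=data.names)
    if psd is True or (psd == "auto" and data.n_binary > 0):
        result = result.nearest_psd(eps=1e-4)
    return result
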