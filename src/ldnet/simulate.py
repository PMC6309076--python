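"""Synthetic two-group data with hub-structured differential networks.

The generator builds a pair of precision matrices that differ only in the
sign of all edges incident to two hub nodes, then draws nonparanormal
(Gaussian-copula) samples from the implied correlation matrices, with
optional dichotomization (binary and mixed designs) and outlier
contamination of the latent Gaussians.

Construction of one graph pair, for dimension p divisible by 5:

1. Partition the p variables into 5 equal blocks; in each block connect
   the smallest-index node (the hub) to every other block member.
2. Draw each hub-edge weight of Omega1 uniformly from
   [-0.75, -0.25] U [0.25, 0.75]; add (0.2 + |min eigenvalue|) I so the
   matrix is positive definite with minimum eigenvalue 0.2.
3. Pick 2 of the 5 hubs; Omega2 flips the sign of every off-diagonal
   entry in those hubs' rows/columns (a diagonal +/-1 similarity, so
   positive definiteness is preserved automatically).
4. Invert both, rescale the inverses to correlation matrices Sigma1 and
   Sigma2, and define the true differential network
   delta0 = Sigma2^{-1} - Sigma1^{-1} from the final correlations.

The sampling scenarios:

- 'copula'   : X = g(Z), Z ~ N(0, Sigma), g the moment-normalized
               standard-normal CDF applied coordinatewise,
               g(z) = sqrt(12)(Phi(z) - 1/2), which has mean 0 and
               variance 1 (any strictly increasing g gives the same
               ranks, hence the same rank-based estimates; the
               normalization keeps the observed scale comparable to the
               latent one, which matters for the Unif[0,1] cutoffs below
               and for the Pearson-based baselines).
- 's1_binary': all p coordinates of the copula sample dichotomized at
               cutoffs C_j ~ Unif[0, 1] on the observed scale (shared
               between groups).
- 's2_mixed' : first p/2 coordinates continuous, last p/2 dichotomized.
- 's3_outlier': Gaussian latent data (no copula transform) with a fixed
               number of entries per row replaced by +/-5 before
               dichotomizing every coordinate -- a misclassification
               robustness stress.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = [
    "GraphPair",
    "ScenarioSpec",
    "generate_hub_precision",
    "make_differential_pair",
    "sample_npn",
    "dichotomize",
    "contaminate",
    "make_scenario",
    "SCENARIOS",
]

SCENARIOS = ("copula", "s1_binary", "s2_mixed", "s3_outlier")


@dataclass
class GraphPair:
    """Ground truth for one differential-network experiment."""

    omega1: np.ndarray
    omega2: np.ndarray
    sigma1: np.ndarray
    sigma2: np.ndarray
    delta0: np.ndarray
    hub_ids: np.ndarray
    support: set = field(repr=False)  # ordered off-diagonal (i, j) pairs

    @property
    def p(self):
        return self.omega1.shape[0]


def _hub_edges(p):
    """Hub edge list: 5 equal blocks, each block's smallest index is its
    hub, wired to every other member.  At the degenerate minimum p = 5
    the five blocks would be singletons with no edges at all, so that
    case uses a single block spanning all five nodes (one hub with four
    spokes), keeping small instances usable."""
    n_blocks = 1 if p == 5 else 5
    block = p // n_blocks
    edges = []
    hubs = []
    for b in range(n_blocks):
        lo = b * block
        hubs.append(lo)
        for j in range(lo + 1, lo + block):
            edges.append((lo, j))
    return hubs, edges


def generate_hub_precision(p, seed=0):
    """Hub-structured positive-definite precision matrix.

    Returns (omega, edge_set).  Requires p divisible by 5.  Each of the 5
    blocks has its smallest-index node connected to all other members;
    weights are uniform on [-0.75, -0.25] U [0.25, 0.75]; the diagonal is
    shifted by 0.2 + |min eigenvalue| to guarantee positive definiteness.
    """
    if p % 5 != 0 or p < 5:
        raise ValueError("p must be a positive multiple of 5")
    rng = np.random.default_rng(seed)
    _, edges = _hub_edges(p)
    omega = np.zeros((p, p))
    for (i, j) in edges:
        mag = rng.uniform(0.25, 0.75)
        sign = rng.choice((-1.0, 1.0))
        omega[i, j] = omega[j, i] = sign * mag
    lam_min = np.linalg.eigvalsh(omega).min()
    omega += (0.2 + abs(lam_min)) * np.eye(p)
    return omega, edges


def _cov_to_corr(cov):
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def make_differential_pair(p, seed=0) -> GraphPair:
    """Generate the two-group ground truth (see module docstring).

    The sign flip is the similarity D Omega1 D with D = diag(+/-1)
    carrying -1 exactly at the two chosen hubs, so Omega2 shares Omega1's
    spectrum and needs no further diagonal repair; delta0 and its support
    are recomputed from the final correlation matrices.
    """
    omega1, _ = generate_hub_precision(p, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    hubs, _ = _hub_edges(p)
    if len(hubs) < 2:
        raise ValueError("differential pairs need p >= 10 (two hub blocks)")
    flipped = rng.choice(hubs, size=2, replace=False)
    d = np.ones(p)
    d[flipped] = -1.0
    omega2 = omega1 * np.outer(d, d)
    if np.linalg.eigvalsh(omega2).min() <= 0:  # defensive; cannot trigger
        lam_min = np.linalg.eigvalsh(omega2).min()
        omega2 = omega2 + (0.2 + abs(lam_min)) * np.eye(p)
    sigma1 = _cov_to_corr(np.linalg.inv(omega1))
    sigma2 = _cov_to_corr(np.linalg.inv(omega2))
    delta0 = np.linalg.inv(sigma2) - np.linalg.inv(sigma1)
    off = ~np.eye(p, dtype=bool)
    tol = 1e-8 * max(np.abs(delta0).max(), 1.0)
    support = {
        (i, j)
        for i, j in zip(*np.nonzero(off & (np.abs(delta0) > tol)))
    }
    return GraphPair(
        omega1=omega1,
        omega2=omega2,
        sigma1=sigma1,
        sigma2=sigma2,
        delta0=delta0,
        hub_ids=np.sort(flipped),
        support=support,
    )


def sample_npn(sigma, n, transform="gaussian_cdf", seed=0):
    """Draw n nonparanormal observations with latent correlation sigma.

    transform='gaussian_cdf' applies the standard-normal CDF to each
    coordinate of the latent Gaussian draw (a strictly increasing map, so
    Kendall's tau is unchanged); transform='id' returns the Gaussian draw
    itself.  Returns (observed, latent) arrays of shape (n, p).
    """
    sigma = np.asarray(sigma, dtype=float)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(sigma)  # raises LinAlgError if not PD
    z = rng.standard_normal((n, sigma.shape[0])) @ chol.T
    if transform == "id":
        return z.copy(), z
    if transform == "gaussian_cdf":
        from scipy.stats import norm

        # moment-normalized CDF transform: Phi(z) is Unif(0,1), so
        # sqrt(12)(Phi(z) - 1/2) has mean 0 and variance 1, keeping the
        # observed scale comparable to the latent one
        return np.sqrt(12.0) * (norm.cdf(z) - 0.5), z
    raise ValueError(f"unknown transform {transform!r}")


def dichotomize(values, cutoffs, columns=None):
    """Indicator transform 1{value > cutoff} on the selected columns.

    `cutoffs` is broadcast per column; non-selected columns pass through
    unchanged.
    """
    values = np.array(values, dtype=float)
    p = values.shape[1]
    columns = np.arange(p) if columns is None else np.asarray(columns)
    cutoffs = np.broadcast_to(np.asarray(cutoffs, dtype=float), (p,))
    values[:, columns] = (values[:, columns] > cutoffs[columns]).astype(float)
    return values


def contaminate(values, k, seed=0, magnitude=5.0):
    """Replace k randomly chosen entries per row by +/-magnitude
    (fair-coin sign), emulating gross outliers in the latent scale."""
    values = np.array(values, dtype=float)
    if k == 0:
        return values
    n, p = values.shape
    if k > p:
        raise ValueError("cannot contaminate more entries than columns")
    rng = np.random.default_rng(seed)
    for i in range(n):
        cols = rng.choice(p, size=k, replace=False)
        values[i, cols] = rng.choice((-magnitude, magnitude), size=k)
    return values


@dataclass
class ScenarioSpec:
    """Configuration of one simulated experiment."""

    p: int
    n1: int = 100
    n2: int = 100
    scenario: str = "copula"
    transform: str = "gaussian_cdf"
    contamination_count: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.p % 5 != 0:
            raise ValueError("p must be divisible by 5")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be at least 2")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.contamination_count > self.p:
            raise ValueError("contamination_count cannot exceed p")


def make_scenario(spec: ScenarioSpec, graph: GraphPair = None, data_seed=None):
    """Generate one replication of a scenario.

    Returns (data1, data2, graph, latent) where latent = (z1, z2) are the
    latent Gaussian draws, kept for the oracle baselines that pretend the
    latent variables are observed.  The graph pair is derived from
    `spec.seed` unless one is passed in (replication studies hold the
    graph fixed and redraw only data); `data_seed` defaults to spec.seed.
    """
    if graph is None:
        graph = make_differential_pair(spec.p, seed=spec.seed)
    data_seed = spec.seed if data_seed is None else data_seed
    ss = np.random.SeedSequence((data_seed, 2))
    s_x, s_y, s_cut, s_cont = [s.generate_state(1)[0] for s in ss.spawn(4)]
    p = spec.p

    if spec.scenario == "s3_outlier":
        # Gaussian latent data, contaminated, then fully dichotomized
        _, z1 = sample_npn(graph.sigma1, spec.n1, transform="id", seed=s_x)
        _, z2 = sample_npn(graph.sigma2, spec.n2, transform="id", seed=s_y)
        rng_c = np.random.default_rng(s_cut)
        cutoffs = rng_c.uniform(0.0, 1.0, size=p)
        x1 = contaminate(z1, spec.contamination_count, seed=s_cont)
        x2 = contaminate(z2, spec.contamination_count, seed=s_cont + 1)
        b1 = dichotomize(x1, cutoffs)
        b2 = dichotomize(x2, cutoffs)
        types = ["binary"] * p
        obs1, obs2 = b1, b2
        # the oracle baselines "observe" the latent data as they are —
        # including the outliers, which is the point of this design
        z1, z2 = x1, x2
    else:
        x1, z1 = sample_npn(graph.sigma1, spec.n1, spec.transform, seed=s_x)
        x2, z2 = sample_npn(graph.sigma2, spec.n2, spec.transform, seed=s_y)
        if spec.scenario == "copula":
            obs1, obs2 = x1, x2
            types = ["continuous"] * p
        else:
            rng_c = np.random.default_rng(s_cut)
            # Unif[0,1] cutoffs on the observed scale; with the normalized
            # CDF transform these land in the upper-middle of the observed
            # range, i.e. moderate latent cutoffs (same regime as the
            # Gaussian-scale cutoffs of the outlier scenario)
            cutoffs = rng_c.uniform(0.0, 1.0, size=p)
            if spec.scenario == "s1_binary":
                cols = np.arange(p)
                types = ["binary"] * p
            else:  # s2_mixed: second half dichotomized
                cols = np.arange(p // 2, p)
                types = ["continuous"] * (p // 2) + ["binary"] * (p - p // 2)
            obs1 = dichotomize(x1, cutoffs, columns=cols)
            obs2 = dichotomize(x2, cutoffs, columns=cols)

    data1 = DataMatrix(obs1, types=types, group_label="group1")
    data2 = DataMatrix(obs2, types=types, group_label="group2")
    return data1, data2, graph, (z1, z2)
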