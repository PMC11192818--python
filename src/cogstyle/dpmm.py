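"""Dirichlet-process Gaussian mixture over 2D tool placements.

Attempt "types" are defined nonparametrically: placements on a level are
modeled as a Dirichlet-process mixture of Gaussians with a conjugate
normal-inverse-Wishart (NIW) base measure, so the number of clusters is
inferred from the data.  Inference is a collapsed Gibbs sampler over the
partition (component means/covariances integrated out analytically); the
point estimate is the retained sweep with maximal joint log-probability,
which is reproducible and can be checked against exact enumeration of the
partition posterior at small n.

Model
-----
Partition prior: Chinese restaurant process with concentration ``alpha``.
Component likelihood: Gaussian with NIW(mu0, kappa0, nu0, psi0) prior, so
cluster marginal likelihoods and posterior-predictive densities (bivariate
Student-t) are available in closed form.

The Gibbs conditional for reassigning point i is

    P(z_i = k | rest) ∝ n_k^(-i) * t_k^(-i)(x_i)        (existing k)
    P(z_i = new)      ∝ alpha    * t_0(x_i)             (prior predictive)

where t_k^(-i) is the posterior predictive of cluster k with point i
removed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import lgamma, log, pi

import numpy as np
from scipy.special import gammaln, logsumexp

_D = 2  # placements are 2D
_LOG_PI = log(pi)

__all__ = [
    "NIWParams", "DirichletProcessMixture", "DPMMResults", "fit_dpmm",
    "map_labels", "partition_posterior_bruteforce", "canonical_partition",
    "crp_expected_clusters", "sample_crp_partition",
]


@dataclass(frozen=True)
class NIWParams:
    """Normal-inverse-Wishart base measure for a 2D Gaussian component.

    ``nu0 > 3`` (dimension + 1) so the prior covariance mean
    ``psi0 / (nu0 - 3)`` exists.
    """

    mu0: np.ndarray
    kappa0: float
    nu0: float
    psi0: np.ndarray

    def __post_init__(self) -> None:
        mu0 = np.asarray(self.mu0, dtype=float).reshape(_D)
        psi0 = np.asarray(self.psi0, dtype=float).reshape(_D, _D)
        object.__setattr__(self, "mu0", mu0)
        object.__setattr__(self, "psi0", psi0)
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.nu0 <= _D + 1:
            raise ValueError(f"nu0 must exceed {_D + 1}")
        if not np.allclose(psi0, psi0.T):
            raise ValueError("psi0 must be symmetric")
        if np.any(np.linalg.eigvalsh(psi0) <= 0):
            raise ValueError("psi0 must be positive definite")

    @classmethod
    def from_data(cls, points: np.ndarray, kappa0: float = 0.1,
                  nu0: float = 4.0) -> "NIWParams":
        """Data-scaled default: prior covariance mean matches the empirical
        per-dimension variances, prior mean is the empirical mean."""
        points = np.asarray(points, dtype=float).reshape(-1, _D)
        var = points.var(axis=0, ddof=0)
        var = np.where(var > 0, var, 1.0)
        return cls(mu0=points.mean(axis=0), kappa0=kappa0, nu0=nu0,
                   psi0=np.diag(var) * (nu0 - _D - 1))


def _lgamma2(a: float) -> float:
    """log of the bivariate multivariate gamma function."""
    return 0.5 * _LOG_PI + lgamma(a) + lgamma(a - 0.5)


class _Base:
    """Precomputed scalar form of the NIW base measure (hot path)."""

    __slots__ = ("m0", "m1", "kappa0", "nu0", "p00", "p01", "p11",
                 "ld0", "lg0", "lkappa0")

    def __init__(self, base: NIWParams):
        self.m0, self.m1 = float(base.mu0[0]), float(base.mu0[1])
        self.kappa0 = float(base.kappa0)
        self.nu0 = float(base.nu0)
        self.p00 = float(base.psi0[0, 0])
        self.p01 = float(base.psi0[0, 1])
        self.p11 = float(base.psi0[1, 1])
        self.ld0 = log(self.p00 * self.p11 - self.p01 * self.p01)
        self.lg0 = _lgamma2(self.nu0 / 2.0)
        self.lkappa0 = log(self.kappa0)


def _lml(n: int, s0: float, s1: float, q00: float, q01: float, q11: float,
         b: _Base) -> float:
    """Log NIW marginal likelihood of a block with raw sufficient stats
    (n, sum, sum of outer products); 0 for the empty block."""
    if n == 0:
        return 0.0
    kn = b.kappa0 + n
    nun = b.nu0 + n
    xb0, xb1 = s0 / n, s1 / n
    # scatter around the block mean
    S00 = q00 - n * xb0 * xb0
    S01 = q01 - n * xb0 * xb1
    S11 = q11 - n * xb1 * xb1
    d0, d1 = xb0 - b.m0, xb1 - b.m1
    c = b.kappa0 * n / kn
    a00 = b.p00 + S00 + c * d0 * d0
    a01 = b.p01 + S01 + c * d0 * d1
    a11 = b.p11 + S11 + c * d1 * d1
    ldn = log(a00 * a11 - a01 * a01)
    return (-n * _LOG_PI + _lgamma2(nun / 2.0) - b.lg0
            + 0.5 * b.nu0 * b.ld0 - 0.5 * nun * ldn
            + b.lkappa0 - log(kn))


def _pred(x0: float, x1: float, n: int, s0: float, s1: float,
          q00: float, q01: float, q11: float, b: _Base) -> float:
    """Posterior-predictive (Student-t) log density at (x0, x1), computed
    as a marginal-likelihood ratio."""
    return (_lml(n + 1, s0 + x0, s1 + x1, q00 + x0 * x0, q01 + x0 * x1,
                 q11 + x1 * x1, b)
            - _lml(n, s0, s1, q00, q01, q11, b))


def canonical_partition(labels) -> tuple[int, ...]:
    """Relabel to first-occurrence order (restricted growth string)."""
    seen: dict[int, int] = {}
    out = []
    for z in labels:
        z = int(z)
        if z not in seen:
            seen[z] = len(seen)
        out.append(seen[z])
    return tuple(out)


def _crp_log_prior(sizes: list[int], alpha: float) -> float:
    n = sum(sizes)
    return (len(sizes) * math.log(alpha)
            + sum(gammaln(s) for s in sizes)
            - sum(math.log(alpha + i) for i in range(n)))


class _SuffStats:
    """Per-cluster raw sufficient statistics for the Gibbs sweep."""

    __slots__ = ("n", "s0", "s1", "q00", "q01", "q11")

    def __init__(self):
        self.n = 0
        self.s0 = self.s1 = 0.0
        self.q00 = self.q01 = self.q11 = 0.0

    def add(self, x0: float, x1: float) -> None:
        self.n += 1
        self.s0 += x0
        self.s1 += x1
        self.q00 += x0 * x0
        self.q01 += x0 * x1
        self.q11 += x1 * x1

    def drop(self, x0: float, x1: float) -> None:
        self.n -= 1
        self.s0 -= x0
        self.s1 -= x1
        self.q00 -= x0 * x0
        self.q01 -= x0 * x1
        self.q11 -= x1 * x1


class DirichletProcessMixture:
    """DP Gaussian mixture over 2D points, fit by collapsed Gibbs sampling.

    Parameters
    ----------
    points : (n, 2) array
        Placements in pixel coordinates (used raw; the default base measure
        is scaled to the data instead of standardizing).
    alpha : float
        DP concentration (> 0).
    base : NIWParams, optional
        Base measure; defaults to :meth:`NIWParams.from_data`.
    """

    def __init__(self, points, alpha: float = 1.0,
                 base: NIWParams | None = None):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != _D:
            raise ValueError("points must be an (n, 2) array")
        if len(points) < 1:
            raise ValueError("need at least one point")
        if not np.all(np.isfinite(points)):
            raise ValueError("points must be finite")
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.points = points
        self.alpha = float(alpha)
        self.base = base if base is not None else NIWParams.from_data(points)
        self._b = _Base(self.base)

    # -- joint probability of a partition ---------------------------------

    def log_joint(self, labels) -> float:
        """CRP log prior of the partition plus per-block NIW marginals."""
        labels = np.asarray(labels)
        lp = _crp_log_prior(
            [int((labels == k).sum()) for k in np.unique(labels)], self.alpha)
        for k in np.unique(labels):
            pts = self.points[labels == k]
            s = pts.sum(axis=0)
            q = pts.T @ pts
            lp += _lml(len(pts), s[0], s[1], q[0, 0], q[0, 1], q[1, 1], self._b)
        return lp

    # -- collapsed Gibbs --------------------------------------------------

    def fit(self, n_sweeps: int = 500, burn_in: int = 250,
            seed: int | None = 0) -> "DPMMResults":
        """Run the collapsed Gibbs sampler and return the max-log-joint sweep.

        ``n_sweeps`` must exceed ``burn_in``; sweeps after burn-in are
        retained for diagnostics.  Deterministic given ``seed``.
        """
        if n_sweeps <= burn_in:
            raise ValueError("n_sweeps must exceed burn_in")
        rng = np.random.default_rng(seed)
        b = self._b
        n = len(self.points)
        xs = [(float(p[0]), float(p[1])) for p in self.points]
        # singleton start: collapsed Gibbs merges far more readily than it
        # splits, so begin maximally split
        labels = list(range(n))
        clusters = []
        for x0, x1 in xs:
            st = _SuffStats()
            st.add(x0, x1)
            clusters.append(st)
        log_alpha = math.log(self.alpha)

        retained_labels: list[tuple[int, ...]] = []
        retained_lj: list[float] = []
        best_labels: list[int] | None = None
        best_lj = -np.inf

        for sweep in range(n_sweeps):
            for i in range(n):
                x0, x1 = xs[i]
                k_old = labels[i]
                st = clusters[k_old]
                st.drop(x0, x1)
                if st.n == 0:
                    clusters.pop(k_old)
                    for j in range(n):
                        if labels[j] > k_old:
                            labels[j] -= 1
                K = len(clusters)
                logw = np.empty(K + 1)
                for k, c in enumerate(clusters):
                    logw[k] = log(c.n) + _pred(
                        x0, x1, c.n, c.s0, c.s1, c.q00, c.q01, c.q11, b)
                logw[K] = log_alpha + _pred(x0, x1, 0, 0.0, 0.0, 0.0, 0.0, 0.0, b)
                p = np.exp(logw - logw.max())
                u = rng.random() * p.sum()
                acc = 0.0
                knew = K
                for k in range(K + 1):
                    acc += p[k]
                    if u < acc:
                        knew = k
                        break
                if knew == K:
                    clusters.append(_SuffStats())
                clusters[knew].add(x0, x1)
                labels[i] = knew
            if sweep >= burn_in:
                lj = self.log_joint(np.asarray(labels))
                retained_labels.append(canonical_partition(labels))
                retained_lj.append(lj)
                if lj > best_lj:
                    best_lj = lj
                    best_labels = list(labels)

        assignments = np.asarray(canonical_partition(best_labels), dtype=int)
        resp = self._responsibilities(assignments)
        return DPMMResults(model=self, assignments=assignments,
                           log_joint=float(best_lj), responsibilities=resp,
                           retained_partitions=retained_labels,
                           retained_log_joints=np.asarray(retained_lj))

    def _responsibilities(self, labels: np.ndarray) -> np.ndarray:
        """Per-point cluster membership probabilities under a partition.

        Row i follows the Gibbs conditional with point i held out:
        n_k^(-i) times the leave-one-out posterior predictive for clusters
        that remain occupied, and alpha times the prior predictive for a
        cluster point i occupies alone; renormalized over the partition's
        clusters (no phantom new-cluster column, so K stays fixed for
        downstream label logic).
        """
        b = self._b
        K = int(labels.max()) + 1
        n = len(self.points)
        stats = [_SuffStats() for _ in range(K)]
        for i in range(n):
            stats[labels[i]].add(float(self.points[i, 0]), float(self.points[i, 1]))
        resp = np.empty((n, K))
        for i in range(n):
            x0, x1 = float(self.points[i, 0]), float(self.points[i, 1])
            zi = labels[i]
            logw = np.empty(K)
            for k in range(K):
                c = stats[k]
                if k == zi:
                    c.drop(x0, x1)
                if c.n == 0:
                    logw[k] = math.log(self.alpha) + _pred(
                        x0, x1, 0, 0.0, 0.0, 0.0, 0.0, 0.0, b)
                else:
                    logw[k] = log(c.n) + _pred(
                        x0, x1, c.n, c.s0, c.s1, c.q00, c.q01, c.q11, b)
                if k == zi:
                    c.add(x0, x1)
            resp[i] = np.exp(logw - logsumexp(logw))
            resp[i] /= resp[i].sum()
        return resp


@dataclass
class DPMMResults:
    """Fitted partition of placements into attempt-type clusters."""

    model: DirichletProcessMixture
    assignments: np.ndarray          # n labels, contiguous 0..K-1
    log_joint: float
    responsibilities: np.ndarray     # (n, K), rows on the simplex
    retained_partitions: list[tuple[int, ...]]
    retained_log_joints: np.ndarray

    @property
    def n_clusters(self) -> int:
        return int(self.assignments.max()) + 1

    def map_labels(self) -> np.ndarray:
        """Highest-responsibility cluster per point (ties to lowest index)."""
        return np.argmax(self.responsibilities, axis=1)

    def partition_frequencies(self) -> dict[tuple[int, ...], float]:
        """Empirical distribution of partitions across retained sweeps."""
        freq: dict[tuple[int, ...], float] = {}
        for p in self.retained_partitions:
            freq[p] = freq.get(p, 0.0) + 1.0
        total = len(self.retained_partitions)
        return {p: c / total for p, c in freq.items()}


def fit_dpmm(points, alpha: float = 1.0, base: NIWParams | None = None,
             n_sweeps: int = 500, burn_in: int = 250,
             seed: int | None = 0) -> DPMMResults:
    """Convenience wrapper: build the model and run the sampler."""
    return DirichletProcessMixture(points, alpha=alpha, base=base).fit(
        n_sweeps=n_sweeps, burn_in=burn_in, seed=seed)


def map_labels(state: DPMMResults) -> np.ndarray:
    """Highest-responsibility cluster per point (ties to lowest index)."""
    return state.map_labels()


# ---- exact small-n oracle ------------------------------------------------


def _set_partitions(n: int):
    """All partitions of range(n) as restricted growth strings."""
    def rec(i: int, labels: list[int], k: int):
        if i == n:
            yield tuple(labels)
            return
        for z in range(k + 1):
            labels.append(z)
            yield from rec(i + 1, labels, max(k, z + 1))
            labels.pop()
    yield from rec(0, [], 0)


def partition_posterior_bruteforce(points, alpha: float = 1.0,
                                   base: NIWParams | None = None
                                   ) -> dict[tuple[int, ...], float]:
    """Exact partition posterior by enumeration (n <= 8; Bell(8) = 4140).

    Returns a dict from canonical partition to posterior probability;
    probabilities sum to one.
    """
    points = np.asarray(points, dtype=float).reshape(-1, _D)
    n = len(points)
    if n > 8:
        raise ValueError("brute-force enumeration limited to n <= 8")
    model = DirichletProcessMixture(points, alpha=alpha, base=base)
    parts = list(_set_partitions(n))
    logp = np.array([model.log_joint(p) for p in parts])
    p = np.exp(logp - logsumexp(logp))
    p /= p.sum()
    return {part: float(pi) for part, pi in zip(parts, p)}


# ---- CRP helpers (prior checks) -----------------------------------------


def crp_expected_clusters(alpha: float, n: int) -> float:
    """E[number of clusters] under the CRP: sum_i alpha / (alpha + i - 1)."""
    return float(sum(alpha / (alpha + i) for i in range(n)))


def sample_crp_partition(rng: np.random.Generator, n: int,
                         alpha: float) -> np.ndarray:
    """One draw of a CRP partition by sequential seating."""
    labels = np.zeros(n, dtype=int)
    sizes: list[int] = []
    for i in range(n):
        w = np.array(sizes + [alpha], dtype=float)
        k = int(rng.choice(len(w), p=w / w.sum()))
        if k == len(sizes):
            sizes.append(1)
        else:
            sizes[k] += 1
        labels[i] = k
    return labels
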