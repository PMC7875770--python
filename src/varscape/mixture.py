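"""Exponential-mixture model of inter-singleton distances.

Nearest-neighbour distances between singletons of one individual are
modelled as a K-component mixture of exponentials,

    f(d) = sum_k lambda_k * (1/theta_k) * exp(-d / theta_k),

where theta_k is the component *mean* distance in bp (scale, not rate) and
lambda_k the proportion of singletons arising from component k.  Components
are reported in ascending theta order, so component 1 is always the
tightest-clustering process.  The number of components is chosen by fitting
K = 1, 2, ... and stopping when a likelihood-ratio test (chi-square, 2 df)
between K-1 and K components is no longer significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "MixtureFit", "ComponentAssignment", "mixture_density",
    "fit_exponential_mixture", "select_k", "classify_singletons",
]


@dataclass
class MixtureFit:
    K: int
    lam: np.ndarray      # component weights, sum to 1
    theta: np.ndarray    # component mean distances (bp), strictly ascending
    loglik: float
    n: int
    converged: bool
    n_iter: int
    seed: int | None = None
    lrt_pvalue: float | None = None  # set by select_k: P(K vs K+1) that stopped

    def __post_init__(self):
        self.lam = np.asarray(self.lam, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.isclose(self.lam.sum(), 1.0, atol=1e-9):
            raise ValueError(f"weights sum to {self.lam.sum()}, expected 1")
        if np.any(self.theta <= 0):
            raise ValueError("all scales must be positive")

    def to_dict(self) -> dict:
        return {
            "K": self.K, "lambda": self.lam.tolist(),
            "theta": self.theta.tolist(), "loglik": self.loglik,
            "n": self.n, "converged": self.converged,
            "n_iter": self.n_iter, "seed": self.seed,
        }


@dataclass
class ComponentAssignment:
    posterior: np.ndarray  # (n, K), rows sum to 1
    assigned: np.ndarray   # hard labels in 1..K (argmax, ties -> smallest k)


def _check_params(lam, theta):
    lam = np.atleast_1d(np.asarray(lam, dtype=float))
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    if lam.shape != theta.shape:
        raise ValueError("lambda and theta must have equal length")
    if np.any(theta <= 0) or np.any(lam <= 0):
        raise ValueError("parameters must be positive")
    if not np.isclose(lam.sum(), 1.0, atol=1e-6):
        raise ValueError("weights must sum to 1")
    return lam, theta


def mixture_density(d, lam, theta):
    """Mixture density f(d) = sum_k lambda_k exp(-d/theta_k)/theta_k for d >= 0."""
    lam, theta = _check_params(lam, theta)
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    dens = np.sum(lam / theta * np.exp(-d[..., None] / theta), axis=-1)
    return dens if dens.ndim else float(dens)


def _log_components(d, lam, theta):
    # (n, K) matrix of log(lambda_k) + log f_k(d)
    return np.log(lam) - np.log(theta) - d[:, None] / theta


def _loglik(d, lam, theta) -> float:
    return float(logsumexp(_log_components(d, lam, theta), axis=1).sum())


def _em(d, lam, theta, tol, max_iter):
    """Run EM from one start; log-likelihood is checked monotone each step."""
    n = len(d)
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # exponents are <= 0, so the weighted densities never overflow
        w = (lam / theta) * np.exp(-d[:, None] / theta)
        f = np.maximum(w.sum(axis=1), 1e-300)
        ll = float(np.log(f).sum())               # loglik at current params
        # EM guarantees ascent; tolerate only rounding-level jitter
        if ll < prev_ll - 1e-8 * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"log-likelihood decreased at iteration {it}: {prev_ll} -> {ll}"
            )
        if np.isfinite(prev_ll) and \
                abs(ll - prev_ll) <= tol * max(1.0, abs(ll)):
            converged = True
            break
        prev_ll = ll
        r = w / f[:, None]                        # responsibilities
        nk = np.maximum(r.sum(axis=0), 1e-300)
        lam = nk / n
        theta = np.maximum(r.T @ d / nk, 1e-12)
    ll = _loglik(d, lam, theta)
    return lam, theta, ll, converged, it


def fit_exponential_mixture(distances, K: int, tol: float = 1e-8,
                            max_iter: int = 2000, n_restarts: int = 5,
                            seed: int | None = None) -> MixtureFit:
    """Maximum-likelihood fit of a K-component exponential mixture by EM.

    The first start places theta geometrically between the 1st and 99th
    distance percentiles, so components whose scales differ by orders of
    magnitude (a few bp next to hundreds of kb) are all seen; the second
    start uses equal-count block means of the sorted distances; further
    restarts jitter the geometric scales multiplicatively by
    exp(N(0, 0.5^2)).  The best converged restart (by log-likelihood) is
    returned with components sorted by ascending theta.  K = 1 is the
    closed-form exponential MLE.
    """
    d = np.asarray(distances, dtype=float)
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(d) < 10 * K:
        raise ValueError(f"need at least {10 * K} distances to fit K={K}")
    if np.any(d <= 0):
        raise ValueError("distances must be strictly positive")

    if K == 1:
        theta = np.array([d.mean()])
        lam = np.array([1.0])
        return MixtureFit(1, lam, theta, _loglik(d, lam, theta), len(d),
                          True, 0, seed)

    rng = np.random.default_rng(seed)
    lo, hi = np.quantile(d, [0.01, 0.99])
    geo = np.geomspace(max(lo, 1e-12), max(hi, 2 * lo, 1e-9), K)
    blocks = np.array_split(np.sort(d), K)
    block_means = np.maximum([b.mean() for b in blocks], 1e-12)
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            th = geo
        elif restart == 1:
            th = block_means
        else:
            th = geo * np.exp(rng.normal(0, 0.5, K))
        lam, theta, ll, conv, it = _em(d, np.full(K, 1.0 / K), th.copy(),
                                       tol, max_iter)
        cand = (conv, ll, lam, theta, it)
        if best is None or (cand[0], cand[1]) > (best[0], best[1]):
            best = cand
    conv, ll, lam, theta, it = best
    order = np.argsort(theta, kind="stable")
    return MixtureFit(K, lam[order], theta[order], ll, len(d), conv, it, seed)


def select_k(distances, alpha: float = 0.01, k_max: int = 10,
             tol: float = 1e-8, max_iter: int = 2000, n_restarts: int = 5,
             seed: int | None = None) -> MixtureFit:
    """Choose K by iterative likelihood-ratio testing.

    Fits K = 1, 2, ...; at each step the statistic
    Lambda = 2 (loglik_K - loglik_{K-1}) is referred to a chi-square
    distribution with two degrees of freedom.  The search stops at the
    first K whose P value exceeds ``alpha`` and the K-1 fit is returned.
    If every test is significant up to ``k_max``, the k_max fit is
    returned (its ``lrt_pvalue`` is the last significant one).
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    prev = fit_exponential_mixture(distances, 1, tol, max_iter, n_restarts, seed)
    for k in range(2, k_max + 1):
        fit = fit_exponential_mixture(distances, k, tol, max_iter, n_restarts,
                                      seed)
        lrt = 2.0 * (fit.loglik - prev.loglik)
        p = float(stats.chi2.sf(max(lrt, 0.0), df=2))
        if p > alpha:
            prev.lrt_pvalue = p
            return prev
        prev = fit
        prev.lrt_pvalue = p
    return prev


def classify_singletons(fit: MixtureFit, distances) -> ComponentAssignment:
    """Posterior component membership and the argmax decision rule.

    p(k | d) = lambda_k f_k(d; theta_k) / sum_k lambda_k f_k(d; theta_k);
    the hard label is the posterior mode, ties resolved toward the smallest
    component index.  Zero distance is a valid observation (the density is
    finite at the origin); negative distances are rejected.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    logw = _log_components(d, fit.lam, fit.theta)
    posterior = np.exp(logw - logsumexp(logw, axis=1)[:, None])
    assigned = posterior.argmax(axis=1) + 1
    return ComponentAssignment(posterior, assigned)
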