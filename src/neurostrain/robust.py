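"""FAST-MCD robust location and scatter estimation.

The minimum covariance determinant (MCD) estimator seeks the h-point subset
of an n-point sample whose classical covariance matrix has the smallest
determinant; its mean and (consistency-rescaled) covariance are robust to up
to n − h arbitrary outliers.  The FAST-MCD algorithm approximates the
combinatorial search with many random (p+1)-point starts refined by
concentration steps (C-steps): given a candidate (mean, covariance), keep
the h points of smallest Mahalanobis distance and re-estimate.  Each C-step
can only decrease the determinant, so iteration converges; the best subset
over all starts is returned.

The raw covariance of an h-subset is biased low for normal data; it is
rescaled by the standard consistency factor
``(h/n) / P(χ²_{p+2} < χ²_{p, h/n} quantile)`` so that the estimate is
Fisher-consistent at the normal model.  No outlier-reweighting step is
applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = ["MCDFit", "fast_mcd", "exhaustive_mcd"]


@dataclass(frozen=True)
class MCDFit:
    """Result of an MCD fit.

    Attributes
    ----------
    location : (p,) array
        Robust mean (mean of the optimal h-subset).
    covariance : (p, p) array
        Consistency-rescaled covariance of the optimal h-subset.
    support : (h,) int array
        Indices of the selected subset, sorted.
    h : int
        Subset size.
    n : int
        Sample size.
    raw_covariance : (p, p) array
        Subset covariance before consistency rescaling.
    determinant : float
        det(raw_covariance) — the minimised objective.
    seed : int or None
        Seed used for the random subset starts.
    """

    location: np.ndarray
    covariance: np.ndarray
    support: np.ndarray
    h: int
    n: int
    raw_covariance: np.ndarray
    determinant: float
    seed: int | None = None

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distances under the robust estimate."""
        diff = np.atleast_2d(points) - self.location
        return np.einsum(
            "ni,ij,nj->n", diff, np.linalg.inv(self.covariance), diff
        )


def _subset_stats(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sub = X[idx]
    mean = sub.mean(axis=0)
    cov = np.cov(sub, rowvar=False, bias=False)
    return mean, np.atleast_2d(cov)


def _c_steps(
    X: np.ndarray,
    mean: np.ndarray,
    cov: np.ndarray,
    h: int,
    rtol: float = 1e-9,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Concentrate (mean, cov) until det converges; returns final subset."""
    det_prev = np.inf
    idx = None
    for _ in range(max_iter):
        try:
            inv = np.linalg.inv(cov)
        except np.linalg.LinAlgError:
            return mean, cov, idx if idx is not None else np.arange(h), np.inf
        diff = X - mean
        d2 = np.einsum("ni,ij,nj->n", diff, inv, diff)
        idx = np.argsort(d2, kind="stable")[:h]
        mean, cov = _subset_stats(X, idx)
        det = float(np.linalg.det(cov))
        if det <= 0:
            return mean, cov, idx, det
        if det_prev < np.inf and abs(det_prev - det) <= rtol * det_prev:
            break
        det_prev = det
    return mean, cov, idx, det


def consistency_factor(n: int, h: int, p: int) -> float:
    """Fisher-consistency rescaling for the raw MCD covariance."""
    alpha = h / n
    if alpha >= 1.0:
        return 1.0
    q = stats.chi2.ppf(alpha, p)
    return alpha / stats.chi2.cdf(q, p + 2)


def default_h(n: int) -> int:
    """Default subset size: ⌈(n + 3) / 2⌉ (breakdown ≈ 50%)."""
    return int(np.ceil((n + 3) / 2))


def fast_mcd(
    points: np.ndarray,
    h_fraction: float | None = None,
    seed: int | None = None,
    n_starts: int = 500,
    rtol: float = 1e-9,
) -> MCDFit:
    """Robust location and scatter by the FAST-MCD algorithm.

    Parameters
    ----------
    points : (n, p) array
        Sample; n >= 5 required.
    h_fraction : float, optional
        Subset proportion in [0.5, 1]. Defaults to ⌈(n+3)/2⌉ / n.
    seed : int, optional
        Seed for the random (p+1)-subset starts; fixing it makes the fit
        deterministic.
    n_starts : int
        Number of random elemental starts.
    rtol : float
        Relative determinant-change tolerance for C-step convergence.

    Raises
    ------
    ValueError
        If n < 5 or every candidate covariance is singular (e.g. more than
        h points on an exact line).
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, p = X.shape
    if n < 5:
        raise ValueError("MCD requires at least 5 points")
    if h_fraction is None:
        h = default_h(n)
    else:
        if not 0.5 <= h_fraction <= 1.0:
            raise ValueError("h_fraction must be in [0.5, 1]")
        h = min(n, max(p + 1, int(np.ceil(h_fraction * n))))

    if h == n:
        mean = X.mean(axis=0)
        cov = np.atleast_2d(np.cov(X, rowvar=False))
        det = float(np.linalg.det(cov))
        if det <= 0:
            raise ValueError("sample covariance is singular")
        return MCDFit(
            location=mean, covariance=cov, support=np.arange(n), h=h, n=n,
            raw_covariance=cov, determinant=det, seed=seed,
        )

    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray] | None = None
    for _ in range(n_starts):
        start = rng.choice(n, size=p + 1, replace=False)
        mean, cov = _subset_stats(X, start)
        if np.linalg.det(cov) <= 0:
            # degenerate elemental set: grow it until non-singular
            extra = p + 1
            while np.linalg.det(cov) <= 0 and extra < n:
                extra += 1
                start = rng.choice(n, size=extra, replace=False)
                mean, cov = _subset_stats(X, start)
            if np.linalg.det(cov) <= 0:
                continue
        mean, cov, idx, det = _c_steps(X, mean, cov, h, rtol=rtol)
        if not np.isfinite(det) or det <= 0:
            continue
        if best is None or det < best[0]:
            best = (det, mean, cov, idx)
    if best is None:
        raise ValueError("all candidate subset covariances were singular")

    det, mean, cov, idx = best
    factor = consistency_factor(n, h, p)
    return MCDFit(
        location=mean,
        covariance=cov * factor,
        support=np.sort(idx),
        h=h,
        n=n,
        raw_covariance=cov,
        determinant=det,
        seed=seed,
    )


def exhaustive_mcd(points: np.ndarray, h: int) -> MCDFit:
    """Exact MCD by enumerating all C(n, h) subsets.

    Feasible only for small n; used as an independent check of the
    stochastic search.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    n, p = X.shape
    best_det = np.inf
    best: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None
    for combo in combinations(range(n), h):
        idx = np.array(combo)
        mean, cov = _subset_stats(X, idx)
        det = float(np.linalg.det(cov))
        if 0 < det < best_det:
            best_det = det
            best = (mean, cov, idx)
    if best is None:
        raise ValueError("all h-subsets have singular covariance")
    mean, cov, idx = best
    factor = consistency_factor(n, h, p)
    return MCDFit(
        location=mean, covariance=cov * factor, support=idx, h=h, n=n,
        raw_covariance=cov, determinant=best_det, seed=None,
    )
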