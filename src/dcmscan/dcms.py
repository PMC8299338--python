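"""De-correlated composite of multiple selection signals (DCMS).

Each statistic is turned into a fractional-rank p-value with its own tail
direction; a robust (minimum covariance determinant) correlation matrix
between the statistics supplies de-correlation weights; the composite for
locus *l* is

    DCMS_l = sum_t w_t * log[(1 - p_lt) / p_lt],   w_t = 1 / sum_i |r_it|

so a statistic highly correlated with the others contributes less.  The
genome-wide DCMS values are fitted with a robust (Huber) normal location/
scale, converted to upper-tail normal p-values and then to
Benjamini-Hochberg q-values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class DCMSConfig:
    """Parameters of the composite step.

    mcd_alpha  : fraction of loci in the MCD subset (default 0.75).
    mcd_nsamp  : number of random initial subsets for FAST-MCD.
    huber_c    : Huber tuning constant for the normal location fit.
    use_storey : use Storey's pi0-adjusted q-values instead of plain BH.
    """

    mcd_alpha: float = 0.75
    mcd_nsamp: int = 50_000
    huber_c: float = 1.345
    use_storey: bool = False


def fractional_rank_pvalues(values: np.ndarray, tail: str) -> np.ndarray:
    """Fractional-rank empirical p-values.

    Average-on-ties ascending ranks r in [1, n]; left tail p = r/(n+1),
    right tail p = (n+1-r)/(n+1), two-sided p = 2*min(left, right) capped
    at n/(n+1).  Bounded inside (0, 1) by construction.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty value vector")
    r = sps.rankdata(values, method="average")
    left = r / (n + 1.0)
    right = (n + 1.0 - r) / (n + 1.0)
    if tail == "left":
        return left
    if tail == "right":
        return right
    if tail == "two":
        return np.minimum(2.0 * np.minimum(left, right), n / (n + 1.0))
    raise ValueError(f"unknown tail {tail!r}")


# -- FAST-MCD robust correlation --------------------------------------------

def _c_step(X: np.ndarray, subset: np.ndarray, h: int) -> np.ndarray:
    mu = X[subset].mean(axis=0)
    S = np.cov(X[subset], rowvar=False)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        return subset  # singular; caller handles
    d = X - mu
    md = np.einsum("ij,jk,ik->i", d, Sinv, d)
    return np.argsort(md, kind="stable")[:h]


def _subset_det(X: np.ndarray, subset: np.ndarray) -> float:
    S = np.cov(X[subset], rowvar=False)
    sign, logdet = np.linalg.slogdet(S)
    return logdet if sign > 0 else -np.inf


def _classical_corr(X: np.ndarray) -> np.ndarray:
    """Pearson correlation with zero-variance columns treated as
    uncorrelated (r = 0 off-diagonal, 1 on the diagonal)."""
    sd = X.std(axis=0)
    ok = sd > 0
    R = np.eye(X.shape[1])
    if ok.sum() >= 2:
        sub = np.corrcoef(X[:, ok], rowvar=False)
        R[np.ix_(ok, ok)] = sub
    return R


def robust_correlation_mcd(
    panel: np.ndarray,
    alpha: float = 0.75,
    nsamp: int = 50_000,
    seed: int | None = None,
) -> tuple[np.ndarray, dict]:
    """FAST-MCD robust correlation matrix of the statistic columns.

    Random (p+1)-subsets are each improved by two concentration steps; the
    ten best subsets are iterated to convergence and the covariance of the
    winner (consistency-corrected) is converted to a correlation matrix.
    A degenerate (singular) best subset falls back to the classical
    correlation with a logged warning.
    """
    X = np.asarray(panel, dtype=float)
    X = np.nan_to_num(X, nan=0.0)
    n, p = X.shape
    if n < 20:
        raise ValueError("need at least 20 loci for the MCD correlation")
    h = int(math.ceil(alpha * n))
    rng = np.random.default_rng(seed)
    meta = {"alpha": alpha, "nsamp": nsamp, "seed": seed, "h": h,
            "fallback_classical": False}

    trials: list[tuple[float, np.ndarray]] = []
    for _ in range(nsamp):
        init = rng.choice(n, size=p + 1, replace=False)
        subset = init
        for _ in range(2):
            subset = _c_step(X, subset, h)
        det = _subset_det(X, subset)
        trials.append((det, subset))
    trials.sort(key=lambda t: t[0])
    finite = [t for t in trials if np.isfinite(t[0])]
    if not finite:
        logger.warning("all MCD trial subsets singular; classical correlation used")
        meta["fallback_classical"] = True
        return _classical_corr(X), meta

    best_det, best_subset = np.inf, None
    for det, subset in finite[:10]:
        prev = np.inf
        for _ in range(100):
            subset = _c_step(X, subset, h)
            det = _subset_det(X, subset)
            if det >= prev - 1e-12:
                break
            prev = det
        if det < best_det:
            best_det, best_subset = det, subset

    S = np.cov(X[best_subset], rowvar=False)
    # consistency correction (scalar; cancels in the correlation)
    qa = sps.chi2.ppf(h / n, p)
    corr_factor = (h / n) / sps.chi2.cdf(qa, p + 2)
    S = S * corr_factor
    sd = np.sqrt(np.diag(S))
    if (sd <= 0).any() or not np.isfinite(best_det):
        logger.warning("singular MCD covariance; classical correlation used")
        meta["fallback_classical"] = True
        return _classical_corr(X), meta
    R = S / np.outer(sd, sd)
    R = np.clip(0.5 * (R + R.T), -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    meta["log_det"] = float(best_det)
    return R, meta


def dcms_combine(pvals: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Combine the per-statistic p-value panel into the composite.

    ``pvals`` is (n_loci, n_stats), ``corr`` the matching robust
    correlation matrix.  Weight for statistic t is 1 / sum_i |r_it|
    (the sum includes i = t), so mutually correlated statistics are not
    double-counted.
    """
    P = np.asarray(pvals, dtype=float)
    if P.ndim != 2 or P.shape[1] != corr.shape[0]:
        raise ValueError("p-value panel and correlation matrix disagree")
    if ((P <= 0.0) | (P >= 1.0)).any():
        raise ValueError("p-values must lie strictly inside (0, 1)")
    weights = 1.0 / np.abs(corr).sum(axis=0)
    logits = np.log((1.0 - P) / P)
    return logits @ weights


def robust_normal_fit(values: np.ndarray, huber_c: float = 1.345) -> tuple[float, float]:
    """Huber M-estimate of location with normalized-MAD scale.

    The scale is fixed at 1.4826 * MAD; the location is iterated (IRLS)
    to relative tolerance 1e-8.  Raises on zero spread.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 30:
        raise ValueError("need at least 30 values for the normal fit")
    med = np.median(x)
    sigma = 1.4826 * np.median(np.abs(x - med))
    if sigma <= 0:
        raise ValueError("zero spread: robust scale is 0")
    mu = med
    for _ in range(200):
        u = (x - mu) / sigma
        w = np.ones_like(u)
        big = np.abs(u) > huber_c
        w[big] = huber_c / np.abs(u[big])
        mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) <= 1e-8 * max(1.0, abs(mu)):
            mu = mu_new
            break
        mu = mu_new
    return float(mu), float(sigma)


def upper_tail_p(dcms: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """p = 1 - Phi((dcms - mu) / sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sps.norm.sf((np.asarray(dcms, dtype=float) - mu) / sigma)


def bh_qvalues(pvalues: np.ndarray, use_storey: bool = False) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (optionally Storey pi0-scaled)."""
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if use_storey:
        lam = 0.5
        pi0 = min(1.0, (p > lam).mean() / (1.0 - lam))
        q = np.minimum(q * pi0, 1.0)
    return q


def dcms_track(
    panel: np.ndarray,
    tails: list[str],
    config: DCMSConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Full composite step: rank p-values -> MCD correlation -> DCMS ->
    robust normal fit -> upper-tail p -> q.  Returns a dict of arrays and
    fit metadata."""
    config = config or DCMSConfig()
    X = np.nan_to_num(np.asarray(panel, dtype=float), nan=0.0)
    P = np.column_stack(
        [fractional_rank_pvalues(X[:, t], tail) for t, tail in enumerate(tails)]
    )
    R, meta = robust_correlation_mcd(
        X, alpha=config.mcd_alpha, nsamp=config.mcd_nsamp, seed=seed
    )
    dcms = dcms_combine(P, R)
    mu, sigma = robust_normal_fit(dcms, config.huber_c)
    p = upper_tail_p(dcms, mu, sigma)
    q = bh_qvalues(p, use_storey=config.use_storey)
    return {
        "stat_pvalues": P,
        "correlation": R,
        "correlation_meta": meta,
        "weights": 1.0 / np.abs(R).sum(axis=0),
        "dcms": dcms,
        "mu": mu,
        "sigma": sigma,
        "p": p,
        "q": q,
    }
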