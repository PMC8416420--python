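"""Inferential procedures used by the sampling analyses.

Self-contained implementations of the three tools the analyses need:

* the Wilcoxon matched-pairs signed-rank test (exact by enumeration for
  small samples, tie/continuity-corrected normal approximation otherwise),
* Poisson regression fitted by IRLS with sandwich (robust) standard errors,
  clustered by subject by default because overlap observations from one
  subject are dependent by design,
* the sign-flip permutation machinery that builds an empirical null for
  paired per-region differences by randomly negating whole subject rows.

Each is deliberately small and auditable; the test suite cross-checks them
against independent reference implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

# ------------------------------------------------------------------ Wilcoxon

#: largest sample size for which "auto" uses exact enumeration (2^m states)
EXACT_ENUMERATION_LIMIT = 12


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # pairs remaining after zero differences are dropped
    mode_used: str  # "exact" or "normal_approx"


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def wilcoxon_signed_rank(
    values_a, values_b=None, mode: str = "auto"
) -> WilcoxonResult:
    """Two-sided Wilcoxon matched-pairs signed-rank test.

    Accepts either paired vectors or (with ``values_b=None``) precomputed
    differences.  Zero differences are dropped; tied absolute differences
    receive mid-ranks.  ``mode='exact'`` enumerates all 2^m sign
    assignments; ``'normal_approx'`` uses the tie- and continuity-corrected
    Gaussian; ``'auto'`` picks exact for m <= 12.
    """
    a = np.asarray(values_a, dtype=float)
    d = a if values_b is None else a - np.asarray(values_b, dtype=float)
    if d.ndim != 1 or d.size < 1:
        raise ValueError("need a 1-D paired sample of length >= 1")
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        raise ValueError("all differences are zero")
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    total = m * (m + 1) / 2.0

    if mode == "auto":
        mode = "exact" if m <= EXACT_ENUMERATION_LIMIT else "normal_approx"
    if mode == "exact":
        # all 2^m sign assignments; the null distribution of W+ is symmetric
        # about total/2, so the two-sided p sums both tails by distance.
        bits = (np.arange(2**m)[:, None] >> np.arange(m)) & 1
        w_all = bits @ ranks
        dist = np.abs(w_all - total / 2.0)
        p = float(np.mean(dist >= abs(w_pos - total / 2.0) - 1e-9))
    elif mode == "normal_approx":
        mn = total / 2.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = float((counts**3 - counts).sum()) / 48.0
        se = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0 - tie_term)
        if se == 0:
            raise ValueError("zero variance (all absolute differences tied at one value)")
        dev = w_pos - mn
        dev -= 0.5 * np.sign(dev)  # continuity correction
        p = float(2.0 * sps.norm.sf(abs(dev) / se))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return WilcoxonResult(w_pos, p, m, mode)


# ----------------------------------------------------------- Poisson + robust


@dataclass
class GLMResult:
    """Fitted Poisson regression with robust standard errors."""

    terms: list[str]
    coefficients: np.ndarray
    robust_se: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    vcov: np.ndarray
    n_obs: int
    n_clusters: int | None
    cov_type: str
    n_iter: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "robust_se": self.robust_se,
                "z": self.z_values,
                "p": self.p_values,
            }
        )


def poisson_robust(
    counts,
    exposure,
    design=None,
    cluster=None,
    add_intercept: bool = True,
    cov_type: str = "cluster",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> GLMResult:
    """Poisson regression with a log(exposure) offset and sandwich SEs.

    The model is ``counts ~ Poisson(exposure * exp(X beta))``, fitted by
    iteratively reweighted least squares until the score (gradient) norm
    falls below ``tol``.  ``cov_type='cluster'`` (default) groups score
    contributions by ``cluster`` (e.g. subject id) with the G/(G-1)
    small-sample factor; ``'HC0'`` is the plain heteroskedasticity-robust
    sandwich.
    """
    y = np.asarray(counts, dtype=float)
    expo = np.asarray(exposure, dtype=float)
    if np.any(y < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(expo <= 0):
        raise ValueError("exposure must be strictly positive")
    if design is None:
        x = np.empty((y.size, 0))
        names: list[str] = []
    elif isinstance(design, pd.DataFrame):
        x = design.to_numpy(dtype=float)
        names = [str(c) for c in design.columns]
    else:
        x = np.atleast_2d(np.asarray(design, dtype=float))
        if x.shape[0] != y.size:
            x = x.T
        names = [f"x{j}" for j in range(x.shape[1])]
    if add_intercept:
        x = np.column_stack([np.ones(y.size), x])
        names = ["intercept"] + names
    n, k = x.shape
    if np.linalg.matrix_rank(x) < k:
        raise ValueError("rank-deficient design matrix")
    offset = np.log(expo)

    beta = np.zeros(k)
    if add_intercept:
        beta[0] = np.log(max(y.sum() / expo.sum(), 1e-12))
    converged = False
    for it in range(1, max_iter + 1):
        eta = x @ beta + offset
        mu = np.exp(eta)
        score = x.T @ (y - mu)
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        xtwx = x.T @ (x * mu[:, None])
        try:
            beta = beta + np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular weighted design during IRLS") from err
    if not converged:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations")

    mu = np.exp(x @ beta + offset)
    bread = np.linalg.inv(x.T @ (x * mu[:, None]))
    resid = y - mu
    n_clusters = None
    if cov_type == "cluster":
        if cluster is None:
            raise ValueError("cov_type='cluster' requires cluster ids")
        groups = np.asarray(cluster)
        uniq = np.unique(groups)
        n_clusters = uniq.size
        meat = np.zeros((k, k))
        for g in uniq:
            sg = x[groups == g].T @ resid[groups == g]
            meat += np.outer(sg, sg)
        # Stata-style small-sample factor: G/(G-1) * (N-1)/(N-k)
        meat *= (n_clusters / max(n_clusters - 1, 1)) * ((n - 1) / max(n - k, 1))
    elif cov_type == "HC0":
        meat = x.T @ (x * (resid**2)[:, None])
    else:
        raise ValueError(f"unknown cov_type {cov_type!r}")
    vcov = bread @ meat @ bread
    # rounding can leave tiny negative diagonal entries when residuals are
    # (near-)zero; clamp before the square root and reject true degeneracy
    se = np.sqrt(np.clip(np.diag(vcov), 0.0, None))
    if np.any(se <= 0):
        raise ValueError(
            "zero robust variance (saturated or degenerate data); "
            "no meaningful standard errors"
        )
    z = beta / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    return GLMResult(
        names, beta, se, z, p, vcov, n, n_clusters, cov_type, it, converged
    )


# ------------------------------------------------------- sign-flip machinery


@dataclass
class SignFlipResult:
    """Per-region empirical-threshold decisions from whole-row sign flips."""

    observed: np.ndarray
    lower: np.ndarray  # empirical alpha-quantile of the null statistic
    upper: np.ndarray  # empirical (1 - alpha)-quantile
    significant_up: np.ndarray
    significant_down: np.ndarray
    degenerate: np.ndarray  # all-zero delta columns, excluded from calls
    statistic: str
    n_perm: int

    def to_frame(self, region_ids=None) -> pd.DataFrame:
        ids = np.arange(self.observed.size) if region_ids is None else region_ids
        return pd.DataFrame(
            {
                "region": ids,
                "observed": self.observed,
                "lower": self.lower,
                "upper": self.upper,
                "significant_up": self.significant_up,
                "significant_down": self.significant_down,
                "degenerate": self.degenerate,
            }
        )


def sign_flip_null(
    deltas,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    statistic: str = "signed_count",
) -> SignFlipResult:
    """Empirical top/bottom-``alpha`` thresholds from subject-level sign flips.

    ``deltas`` is subjects x regions.  The observed per-region statistic is
    the number of subjects with a positive difference minus the number with a
    negative one (``statistic='signed_count'``) or the mean difference
    (``'mean'``).  The null flips the sign of each subject's entire row
    (preserving within-subject dependence across regions); a region is
    flagged when its observed statistic falls strictly outside the empirical
    [alpha, 1-alpha] quantiles of its null distribution.
    """
    d = np.asarray(deltas, dtype=float)
    if d.ndim != 2:
        raise ValueError("deltas must be a subjects x regions matrix")
    if not np.isfinite(d).all():
        raise ValueError("deltas must be finite")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n_subj, n_reg = d.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if statistic == "signed_count":
        basis = np.sign(d)
    elif statistic == "mean":
        basis = d / n_subj
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    observed = basis.sum(axis=0)
    flips = rng.integers(0, 2, size=(n_perm, n_subj)) * 2 - 1
    null = flips @ basis  # n_perm x regions
    lower = np.quantile(null, alpha, axis=0)
    upper = np.quantile(null, 1.0 - alpha, axis=0)
    degenerate = np.all(d == 0.0, axis=0)
    sig_up = (observed > upper) & ~degenerate
    sig_down = (observed < lower) & ~degenerate
    return SignFlipResult(
        observed, lower, upper, sig_up, sig_down, degenerate, statistic, n_perm
    )
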