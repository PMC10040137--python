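"""Surrogate variable estimation for EWAS outcome matrices.

Hidden structure in methylation data (plates, cell composition, ancestry)
confounds per-site regressions. This module estimates surrogate variables
(SVs) from the outcome matrix after removing known covariates, using an
iteratively re-weighted residual SVD: sites that look driven by the latent
structure (high F-statistic for the current SVs relative to the covariates)
get up-weighted before the next decomposition, so the recovered directions
concentrate on genuinely confounded sites.

The number of SVs is chosen by parallel analysis: residual singular values
are compared against the 95th percentile of singular values obtained after
permuting each residual row independently, and the count of leading
components exceeding their permutation threshold is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import subspace_angles
from sklearn.base import BaseEstimator


@dataclass
class SVMatrix:
    """Estimated surrogate variables with convergence diagnostics."""

    scores: pd.DataFrame  # samples x K, orthonormal columns
    n_iter: int
    converged: bool
    final_change: float

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self.scores.to_numpy()


def _as_design(design) -> np.ndarray:
    x = design.to_numpy(dtype=float) if hasattr(design, "to_numpy") else np.asarray(design, float)
    if x.ndim != 2:
        raise ValueError("covariate design must be 2-dimensional (samples x covariates)")
    return x


def _residualize(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(x, y.T, rcond=None)
    return y - (x @ coef).T


def _check_design(x: np.ndarray, n_samples: int) -> int:
    if x.shape[0] != n_samples:
        raise ValueError(f"design has {x.shape[0]} rows but outcome has {n_samples} samples")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError("covariate design is rank-deficient")
    if n_samples <= x.shape[1] + 2:
        raise ValueError("need more samples than covariates + 2")
    return rank


def estimate_n_sv(outcome, covariate_design, n_perm: int = 20, seed: int = 0) -> int:
    """Parallel-analysis estimate of the number of surrogate variables.

    Counts leading singular values of the covariate-residualized outcome that
    exceed the 95th percentile of the corresponding singular values under
    ``n_perm`` independent row-wise permutations of the residual matrix.
    """
    if n_perm < 1:
        raise ValueError(f"n_perm must be >= 1, got {n_perm}")
    y = outcome.to_numpy(dtype=float) if hasattr(outcome, "to_numpy") else np.asarray(outcome, float)
    if y.shape[0] < 50:
        raise ValueError(f"need >= 50 sites to estimate surrogate variables, got {y.shape[0]}")
    x = _as_design(covariate_design)
    _check_design(x, y.shape[1])

    resid = _residualize(y, x)
    sv_obs = np.linalg.svd(resid, compute_uv=False)

    rng = np.random.default_rng(seed)
    perm_sv = np.empty((n_perm, len(sv_obs)))
    for b in range(n_perm):
        perm_sv[b] = np.linalg.svd(rng.permuted(resid, axis=1), compute_uv=False)
    thresh = np.percentile(perm_sv, 95, axis=0)

    k = 0
    for obs, thr in zip(sv_obs, thresh):
        if obs > thr:
            k += 1
        else:
            break
    return k


def _rss_under(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    r = _residualize(y, x)
    return (r**2).sum(axis=1)


def estimate_svs(
    outcome,
    covariate_design,
    k: int,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> SVMatrix:
    """Iteratively re-weighted residual SVD returning ``k`` orthonormal SVs.

    Per-site weights w_j = F_sv / (F_sv + F_cov + 1), a bounded monotone
    score of how much a site loads on the current SVs relative to the known
    covariates; convergence is measured by the sine of the largest principal
    angle between successive SV subspaces.

    The iteration runs on covariate-residualized data (so true covariate and
    exposure effects cannot masquerade as latent structure), but the returned
    surrogate variables are rebuilt from the weighted, row-centred original
    outcome: a latent factor that happens to correlate with a design column
    in this finite sample is then captured in full, so adjusting for the SVs
    removes the whole nuisance direction rather than only its
    design-orthogonal part.
    """
    y = outcome.to_numpy(dtype=float) if hasattr(outcome, "to_numpy") else np.asarray(outcome, float)
    sample_ids = list(outcome.columns) if hasattr(outcome, "columns") else list(range(y.shape[1]))
    x = _as_design(covariate_design)
    rank = _check_design(x, y.shape[1])
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if k == 0:
        return SVMatrix(pd.DataFrame(index=pd.Index(sample_ids, name="sample_id")), 0, True, 0.0)
    n = y.shape[1]
    if k >= n - rank:
        raise ValueError(f"k={k} must be < samples - rank(design) = {n - rank}")

    resid = _residualize(y, x)
    scale = float(np.sqrt((resid**2).mean()))
    if scale < 1e-10 * max(1.0, float(np.sqrt((y**2).mean()))):
        raise ValueError("outcome equals the covariate fit exactly; no residual structure to decompose")

    p = x.shape[1]
    intercept = np.ones((n, 1))
    sv = _top_right_singular(resid, k)
    n_iter, change, converged = 0, np.inf, False
    for n_iter in range(1, max_iter + 1):
        xs = np.column_stack([x, sv])
        rss_x = _rss_under(y, x)
        rss_xs = _rss_under(y, xs)
        rss_1 = _rss_under(y, intercept)
        with np.errstate(divide="ignore", invalid="ignore"):
            f_sv = np.maximum((rss_x - rss_xs) / k, 0.0) / np.maximum(rss_xs / (n - p - k), 1e-300)
            if p > 1:
                f_cov = np.maximum((rss_1 - rss_x) / (p - 1), 0.0) / np.maximum(rss_x / (n - p), 1e-300)
            else:
                f_cov = np.zeros_like(f_sv)
        # bounded surrogate for "associated with the SVs AND not with the
        # design": the second factor suppresses sites carrying true covariate
        # or exposure signal so they cannot steer the decomposition
        w = np.clip(f_sv / (f_sv + 1.0), 0.0, 1.0) / (1.0 + f_cov)
        new_sv = _top_right_singular(w[:, None] * resid, k)
        angles = subspace_angles(sv, new_sv)
        change = float(np.sin(np.max(angles))) if len(angles) else 0.0
        sv = new_sv
        if change < tol:
            converged = True
            break
    # rebuild the returned SVs from the weighted, row-centred raw outcome
    centred = y - y.mean(axis=1, keepdims=True)
    sv = _top_right_singular(w[:, None] * centred, k)
    if not converged:
        warnings.warn(
            f"surrogate variable estimation did not converge in {max_iter} iterations "
            f"(final change {change:.2e}); returning best iterate",
            RuntimeWarning,
        )
    cols = [f"sv_{j + 1}" for j in range(k)]
    scores = pd.DataFrame(sv, index=pd.Index(sample_ids, name="sample_id"), columns=cols)
    return SVMatrix(scores, n_iter, converged, change)


def _top_right_singular(mat: np.ndarray, k: int) -> np.ndarray:
    _, _, vt = np.linalg.svd(mat, full_matrices=False)
    v = vt[:k].T
    # deterministic sign: largest-magnitude entry of each column positive
    for j in range(v.shape[1]):
        i = np.argmax(np.abs(v[:, j]))
        if v[i, j] < 0:
            v[:, j] = -v[:, j]
    return v


class SurrogateVariableAnalysis(BaseEstimator):
    """Sklearn-style wrapper around parallel-analysis SV-count selection and
    iteratively re-weighted SV estimation.

    Parameters
    ----------
    n_sv : int or "auto"
        Number of surrogate variables; "auto" uses parallel analysis.
    n_perm : int
        Permutations for parallel analysis (only used when n_sv="auto").
    max_iter, tol : convergence controls for the re-weighted SVD.
    random_state : seed for the parallel-analysis permutations.
    """

    def __init__(self, n_sv="auto", n_perm: int = 20, max_iter: int = 50, tol: float = 1e-4, random_state: int = 0):
        self.n_sv = n_sv
        self.n_perm = n_perm
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, outcome, covariate_design):
        """Estimate SVs from a sites x samples outcome matrix and known design."""
        if self.n_sv == "auto":
            k = estimate_n_sv(outcome, covariate_design, n_perm=self.n_perm, seed=self.random_state)
        else:
            k = int(self.n_sv)
        result = estimate_svs(outcome, covariate_design, k, max_iter=self.max_iter, tol=self.tol)
        self.n_sv_ = k
        self.svs_ = result.scores
        self.n_iter_ = result.n_iter
        self.converged_ = result.converged
        self.final_change_ = result.final_change
        return self

    def fit_transform(self, outcome, covariate_design):
        return self.fit(outcome, covariate_design).svs_
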