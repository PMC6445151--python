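"""Gene-gene association estimation within one group.

Two families of symmetric association measures are provided:

* marginal correlation (Pearson or Spearman), optionally passed through the
  WGCNA-style soft threshold |r|**beta or a hard threshold at gamma;
* partial correlation obtained by inverting a shrinkage covariance
  estimate, Sigma* = lambda* T + (1 - lambda*) Sigma_hat, where the target
  T = diag(Sigma_hat) encodes uncorrelated genes with unequal variances and
  lambda* is the analytically optimal (Ledoit-Wolf / Schafer-Strimmer)
  shrinkage intensity

      lambda* = sum_{i!=j} Var_hat(r_ij) / sum_{i!=j} r_ij^2,

  computed on standardized data and clipped to [0, 1]. Because lambda* > 0
  in any finite sample with noise, Sigma* is positive definite even when
  m > n or columns are collinear, which is what makes partial correlations
  usable on pathway-sized gene sets with few samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import rankdata

from .io import ExpressionMatrix

__all__ = [
    "AssociationMatrix",
    "ShrinkageFit",
    "marginal_correlation",
    "soft_threshold",
    "hard_threshold",
    "shrinkage_covariance",
    "partial_correlation_from_precision",
    "estimate_partial_correlation",
    "estimate_association",
    "MEASURES",
]

MEASURES = ("pearson", "spearman", "pearson_soft", "pearson_hard", "partial_shrinkage")


@dataclass
class AssociationMatrix:
    """Symmetric gene-gene association scores on a fixed gene order."""

    scores: np.ndarray
    gene_ids: list[str]
    measure: str

    def __post_init__(self) -> None:
        S = np.asarray(self.scores, dtype=float)
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise ValueError("scores must be square")
        if S.shape[0] != len(self.gene_ids):
            raise ValueError("gene_ids length must match matrix size")
        S = (S + S.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(S, 0.0)  # diagonal carries no connectivity
        self.scores = S

    @property
    def n_genes(self) -> int:
        return self.scores.shape[0]

    def to_edge_list(self):
        """Long-format (gene_i, gene_j, score) rows over i < j."""
        rows = []
        m = self.n_genes
        for i in range(m):
            for j in range(i + 1, m):
                rows.append((self.gene_ids[i], self.gene_ids[j], self.scores[i, j]))
        return rows


@dataclass
class ShrinkageFit:
    """A shrunk covariance Sigma* = lambda* T + (1-lambda*) Sigma_hat."""

    sigma_star: np.ndarray
    lambda_star: float
    target_description: str = "diagonal, unequal variances"


def _center(values: np.ndarray) -> np.ndarray:
    return values - values.mean(axis=0, keepdims=True)


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale columns by the ddof=1 standard deviation.

    Zero-variance columns are set to 0 (their correlations become 0) and a
    warning is recorded instead of aborting.
    """
    centered = _center(values)
    sd = centered.std(axis=0, ddof=1)
    degenerate = sd == 0
    if np.any(degenerate):
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance gene(s); their "
            "correlations are reported as 0",
            stacklevel=3,
        )
    safe = np.where(degenerate, 1.0, sd)
    std = centered / safe[np.newaxis, :]
    std[:, degenerate] = 0.0
    return std, degenerate


def marginal_correlation(X: ExpressionMatrix, method: str = "pearson") -> AssociationMatrix:
    """Pairwise marginal correlation r_ij = Sigma_ij / sqrt(Sigma_ii Sigma_jj).

    ``method`` is "pearson" (sample covariance on centered columns) or
    "spearman" (Pearson on column ranks). Zero-variance genes get r = 0
    with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples for correlation estimation")
    vals = X.values
    if method == "spearman":
        vals = np.apply_along_axis(rankdata, 0, vals)
    std, _ = _standardize(vals)
    n = std.shape[0]
    R = std.T @ std / (n - 1)
    R = np.clip(R, -1.0, 1.0)
    return AssociationMatrix(R, list(X.gene_ids), method)


def soft_threshold(R: AssociationMatrix, beta: float) -> AssociationMatrix:
    """WGCNA soft threshold: S_ij = |r_ij| ** beta, beta >= 1."""
    if beta < 1:
        raise ValueError("soft-threshold exponent beta must be >= 1")
    return AssociationMatrix(
        np.abs(R.scores) ** beta, list(R.gene_ids), f"{R.measure}_soft"
    )


def hard_threshold(R: AssociationMatrix, gamma: float) -> AssociationMatrix:
    """Hard threshold: keep r_ij (sign included) where |r_ij| > gamma."""
    if gamma <= 0:
        raise ValueError("hard-threshold gamma must be > 0")
    S = np.where(np.abs(R.scores) > gamma, R.scores, 0.0)
    return AssociationMatrix(S, list(R.gene_ids), f"{R.measure}_hard")


def shrinkage_covariance(X: ExpressionMatrix) -> ShrinkageFit:
    """Fit Sigma* = lambda* T + (1-lambda*) Sigma_hat with T = diag(Sigma_hat).

    lambda* = sum_{i!=j} Var_hat(r_ij) / sum_{i!=j} r_ij^2 on standardized
    columns, with Var_hat(r_ij) = n/(n-1)^3 * sum_s (w_sij - w_bar_ij)^2 and
    w_sij the per-sample cross-product of standardized columns; clipped to
    [0, 1]. Degenerate (zero-variance) genes contribute unit variance to the
    target so Sigma* stays positive definite.
    """
    n, m = X.values.shape
    if m == 1:
        var = X.values[:, 0].var(ddof=1) if n >= 2 else 1.0
        return ShrinkageFit(np.array([[var if var > 0 else 1.0]]), 0.0)
    if n < 3:
        raise ValueError("need at least 3 samples for shrinkage estimation")
    std, degenerate = _standardize(X.values)
    # w[s, i, j] = x_si * x_sj; r_ij = n/(n-1) * mean_s w[s, i, j]
    w_bar = std.T @ std / n
    R = w_bar * n / (n - 1)
    # Var_hat(r_ij) = n/(n-1)^3 sum_s (w_sij - w_bar_ij)^2
    sq = (std**2).T @ (std**2) / n  # mean_s w_sij^2
    var_r = n / (n - 1) ** 3 * n * (sq - w_bar**2)
    off = ~np.eye(m, dtype=bool)
    denom = float((R[off] ** 2).sum())
    numer = float(var_r[off].sum())
    lam = 1.0 if denom == 0 else float(np.clip(numer / denom, 0.0, 1.0))
    centered = _center(X.values)
    sigma_hat = centered.T @ centered / (n - 1)
    diag = sigma_hat.diagonal().copy()
    diag[degenerate] = 1.0  # keep Sigma* invertible despite degenerate genes
    sigma_star = (1.0 - lam) * sigma_hat
    np.fill_diagonal(sigma_star, diag)  # lam*T + (1-lam)*Sigma on the diagonal
    return ShrinkageFit(sigma_star, lam)


def partial_correlation_from_precision(
    Omega: np.ndarray, gene_ids: list[str] | None = None
) -> AssociationMatrix:
    """rho_ij = -Omega_ij / sqrt(Omega_ii Omega_jj) for i != j, 0 on the
    diagonal; requires a symmetric positive definite precision matrix."""
    Omega = np.asarray(Omega, dtype=float)
    if Omega.ndim != 2 or Omega.shape[0] != Omega.shape[1]:
        raise ValueError("precision matrix must be square")
    if not np.allclose(Omega, Omega.T, atol=1e-10):
        raise ValueError("precision matrix must be symmetric")
    try:
        np.linalg.cholesky(Omega)
    except np.linalg.LinAlgError:
        raise ValueError("precision matrix is not positive definite") from None
    d = np.sqrt(np.diag(Omega))
    rho = -Omega / np.outer(d, d)
    np.fill_diagonal(rho, 0.0)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(Omega.shape[0])]
    return AssociationMatrix(rho, list(gene_ids), "partial_shrinkage")


def estimate_partial_correlation(X: ExpressionMatrix) -> AssociationMatrix:
    """Shrinkage partial correlations: center, fit Sigma*, invert, rescale."""
    fit = shrinkage_covariance(X)
    m = fit.sigma_star.shape[0]
    try:
        c, low = cho_factor(fit.sigma_star)
    except np.linalg.LinAlgError:
        cond = np.linalg.cond(fit.sigma_star)
        raise np.linalg.LinAlgError(
            f"shrunk covariance numerically singular (condition number {cond:.3g})"
        ) from None
    omega = cho_solve((c, low), np.eye(m))
    omega = (omega + omega.T) / 2.0
    return partial_correlation_from_precision(omega, list(X.gene_ids))


def estimate_association(
    X: ExpressionMatrix,
    measure: str = "partial_shrinkage",
    beta: float = 1.0,
    gamma: float = 0.5,
) -> AssociationMatrix:
    """Dispatch on the association measure name (see ``MEASURES``)."""
    if measure == "pearson":
        return marginal_correlation(X, "pearson")
    if measure == "spearman":
        return marginal_correlation(X, "spearman")
    if measure == "pearson_soft":
        return soft_threshold(marginal_correlation(X, "pearson"), beta)
    if measure == "pearson_hard":
        return hard_threshold(marginal_correlation(X, "pearson"), gamma)
    if measure == "partial_shrinkage":
        return estimate_partial_correlation(X)
    raise ValueError(f"unknown association measure {measure!r}")
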