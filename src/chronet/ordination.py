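"""Unconstrained ordination: PCoA, NMDS and PCA.

PCoA follows the classical Gower construction: double-center -d^2/2,
eigendecompose, scale eigenvectors by the square root of their eigenvalues.
Negative eigenvalues (possible for semi-metric dissimilarities such as
Bray-Curtis) are reported but excluded from the coordinates and from the
proportion-explained denominator; a Lingoes correction is available by
option. NMDS minimizes Kruskal stress-1 by SMACOF majorization with
monotone (pool-adjacent-violators) regression, weak-tie treatment, over
several random starts. PCA is a plain eigendecomposition of the
(optionally standardized) covariance of soil variables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from .types import DistanceMatrix, OrdinationResult, ValidationError

__all__ = ["pcoa", "nmds", "pca"]

_EIG_TOL = 1e-8


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dist: DistanceMatrix, negative_correction: str = "none") -> OrdinationResult:
    """Principal coordinate analysis of a dissimilarity matrix.

    ``negative_correction="lingoes"`` adds the constant c = |lambda_min| to
    all squared off-diagonal dissimilarities, making the matrix Euclidean
    before re-decomposing; the default reports negative eigenvalues as-is.
    """
    if dist.n < 3:
        raise ValidationError("PCoA needs at least 3 samples")
    d = dist.values
    g = _gower_center(d)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    if negative_correction == "lingoes" and eigvals[-1] < -_EIG_TOL:
        c = -eigvals[-1]
        d2 = d**2 + 2.0 * c
        np.fill_diagonal(d2, 0.0)
        g = _gower_center(np.sqrt(d2))
        eigvals, eigvecs = np.linalg.eigh(g)
        order = np.argsort(eigvals)[::-1]
        eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    elif negative_correction not in ("none", "lingoes"):
        raise ValueError(f"unknown negative_correction {negative_correction!r}")

    scale = max(abs(eigvals[0]), 1.0)
    positive = eigvals > _EIG_TOL * scale
    lam = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(lam)
    proportions = lam / lam.sum() if lam.size else lam
    frame = pd.DataFrame(
        coords, index=dist.ids, columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return OrdinationResult(
        method="PCoA",
        coordinates=frame,
        eigenvalues=eigvals,
        proportion_explained=proportions,
    )


def _weak_tie_order(d: np.ndarray, d_conf: np.ndarray) -> np.ndarray:
    """Sort by dissimilarity; within ties, by current configuration distance.

    This is the weak ("primary") tie treatment: tied input dissimilarities
    are free to receive different fitted disparities.
    """
    return np.lexsort((d_conf, d))


def _stress1(d_hat: np.ndarray, d_conf: np.ndarray) -> float:
    denom = float(np.sum(d_conf**2))
    if denom == 0:
        return 1.0
    return float(np.sqrt(np.sum((d_hat - d_conf) ** 2) / denom))


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Best configuration over ``n_starts`` random starts is returned with its
    stress; if no start converged within ``max_iter`` majorization steps the
    best found is returned with ``converged=False``.
    """
    n = dist.n
    if n <= k + 1:
        raise ValidationError(f"NMDS with k={k} needs more than {k + 1} samples")
    d = squareform(dist.values, checks=False)
    m = d.size
    rng = np.random.default_rng(seed)

    best_stress, best_x, best_conv = np.inf, None, False
    for _ in range(n_starts):
        x = rng.standard_normal((n, k))
        prev = np.inf
        converged = False
        for _ in range(max_iter):
            d_conf = pdist(x)
            order = _weak_tie_order(d, d_conf)
            fitted = isotonic_regression(d_conf[order]).x
            d_hat = np.empty(m)
            d_hat[order] = fitted
            stress = _stress1(d_hat, d_conf)
            if abs(prev - stress) < tol:
                converged = True
                break
            prev = stress
            # Guttman transform toward the fitted disparities
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_conf > 0, d_hat / d_conf, 0.0)
            b = -squareform(ratio)
            np.fill_diagonal(b, -b.sum(axis=1))
            x = b @ x / n
        d_conf = pdist(x)
        order = _weak_tie_order(d, d_conf)
        fitted = isotonic_regression(d_conf[order]).x
        d_hat = np.empty(m)
        d_hat[order] = fitted
        stress = _stress1(d_hat, d_conf)
        if stress < best_stress:
            best_stress, best_x, best_conv = stress, x.copy(), converged

    # center and orient principal axes for a reproducible representation
    best_x = best_x - best_x.mean(axis=0)
    _, _, vt = np.linalg.svd(best_x, full_matrices=False)
    best_x = best_x @ vt.T
    signs = np.sign(best_x[np.argmax(np.abs(best_x), axis=0), range(k)])
    signs[signs == 0] = 1.0
    best_x = best_x * signs
    frame = pd.DataFrame(
        best_x, index=dist.ids, columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        method="NMDS", coordinates=frame, stress=best_stress, converged=best_conv
    )


def pca(data: pd.DataFrame, scale: bool = True) -> OrdinationResult:
    """Principal component analysis of a variables table (e.g. soil chemistry).

    Columns are centered and, when ``scale``, divided by their standard
    deviation (ddof=1); a zero-variance column with scaling requested is an
    error naming the column. Scores are returned as coordinates; loadings
    (variables x components) are attached.
    """
    if data.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 numeric variables")
    if data.isna().any().any():
        raise ValidationError("PCA input contains missing values")
    x = data.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        dead = np.where(sd == 0)[0]
        if dead.size:
            raise ValidationError(
                f"zero-variance column {data.columns[dead[0]]!r} with scale=True"
            )
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    n = x.shape[0]
    eigvals = s**2 / (n - 1)
    scores = u * s
    axes = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return OrdinationResult(
        method="PCA",
        coordinates=pd.DataFrame(scores, index=data.index, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=eigvals / eigvals.sum(),
        loadings=pd.DataFrame(vt.T, index=data.columns, columns=axes),
    )
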