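"""Nonmetric multidimensional scaling under Kruskal's normalized stress-1.

The embedding alternates Kruskal's monotone regression (disparities as the
least-squares non-decreasing fit of configuration distances ordered by the
input dissimilarities, primary approach to ties) with a SMACOF/Guttman
configuration update toward the disparities.  Stress-1,

    stress1 = sqrt( sum_{i<j} (d_ij - dhat_ij)^2 / sum_{i<j} d_ij^2 ),

is the normalized criterion reported and monitored; iterations that would
increase it are not accepted.  The default start is classical (Torgerson)
scaling of the input dissimilarities; termination is by stress change
(tol_fun) OR maximum coordinate change (tol_x) OR the iteration cap, with an
optional number of random restarts (best stress kept).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.spatial.distance import pdist, squareform

from ._rng import rng_for
from .errors import InvalidArgumentError, UndefinedNormalizationError

__all__ = [
    "Embedding",
    "NMDSConfig",
    "classical_scaling_init",
    "stress1",
    "monotone_regression",
    "nmds_embed",
]


@dataclass
class Embedding:
    """d-dimensional NMDS configuration with its final stress-1."""

    coords: np.ndarray
    stress: float
    dim: int
    n_iterations: int
    converged: bool
    stress_history: list = field(default_factory=list)


@dataclass(frozen=True)
class NMDSConfig:
    dim: int = 3
    max_iter: int = 200
    tol_fun: float = 1e-4
    tol_x: float = 1e-4
    replicates: int = 1
    init: str = "classical"  # "classical" | "random"
    seed: int = 0

    def __post_init__(self):
        if self.max_iter < 1:
            raise InvalidArgumentError("max_iter must be >= 1")
        if self.tol_fun <= 0 or self.tol_x <= 0:
            raise InvalidArgumentError("tolerances must be positive")
        if self.dim < 1:
            raise InvalidArgumentError("dim must be >= 1")
        if self.replicates < 1:
            raise InvalidArgumentError("replicates must be >= 1")
        if self.init not in ("classical", "random"):
            raise InvalidArgumentError("init must be 'classical' or 'random'")


def _as_square(D) -> np.ndarray:
    M = np.asarray(getattr(D, "values", D), dtype=float)
    n = M.shape[0]
    if M.shape != (n, n) or not np.allclose(M, M.T) or np.any(np.diag(M) != 0):
        raise InvalidArgumentError("expected a symmetric matrix with zero diagonal")
    return M


def classical_scaling_init(D, dim: int) -> np.ndarray:
    """Classical (Torgerson) scaling start: double-center -1/2 D^2 and take the
    top-``dim`` spectral coordinates; negative eigenvalues contribute zero."""
    M = _as_square(D)
    n = M.shape[0]
    if dim > n - 1:
        raise InvalidArgumentError(f"dim must be <= n-1 = {n - 1}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (M ** 2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dim]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


def stress1(coords: np.ndarray, disparities) -> float:
    """Kruskal's normalized stress-1 of a configuration against disparities."""
    Dhat = _as_square(disparities)
    d = pdist(np.asarray(coords, dtype=float))
    dhat = squareform(Dhat, checks=False)
    denom = np.sum(d ** 2)
    if denom == 0:
        raise UndefinedNormalizationError("all-zero configuration: stress-1 undefined")
    return float(np.sqrt(np.sum((d - dhat) ** 2) / denom))


def monotone_regression(dissims: np.ndarray, distances: np.ndarray) -> np.ndarray:
    """Least-squares non-decreasing fit of ``distances`` in the rank order of
    ``dissims`` (pool-adjacent-violators).

    Ties in the dissimilarities are handled by Kruskal's primary approach:
    tied values are mutually unconstrained, implemented by ordering tied
    entries by ascending distance so PAV never pools them unnecessarily.
    """
    dissims = np.asarray(dissims, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if dissims.shape != distances.shape:
        raise InvalidArgumentError("dissimilarities and distances must align")
    order = np.lexsort((distances, dissims))
    fit = isotonic_regression(distances[order]).x
    out = np.empty_like(distances)
    out[order] = fit
    return out


def _guttman_update(X: np.ndarray, dhat: np.ndarray) -> np.ndarray:
    n = X.shape[0]
    d = pdist(X)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, dhat / d, 0.0)
    B = -squareform(ratio, checks=False)
    np.fill_diagonal(B, -B.sum(axis=1))
    return B @ X / n


def nmds_embed(D, cfg: NMDSConfig) -> Embedding:
    """Embed a dissimilarity matrix by iterating monotone regression and
    Guttman updates; best of ``cfg.replicates`` starts is returned."""
    M = _as_square(D)
    n = M.shape[0]
    if cfg.dim > n - 1:
        raise InvalidArgumentError(f"dim must be <= n-1 = {n - 1}")
    delta = squareform(M, checks=False)
    if np.all(delta == 0):
        return Embedding(
            coords=np.zeros((n, cfg.dim)), stress=0.0, dim=cfg.dim,
            n_iterations=0, converged=True,
        )
    scale = delta.max()

    best: Embedding | None = None
    for rep in range(cfg.replicates):
        if rep == 0 and cfg.init == "classical":
            X = classical_scaling_init(M, cfg.dim)
            # guard against a degenerate (all-negative-eigenvalue) start
            if not np.any(X):
                X = rng_for(cfg.seed, "nmds-init", rep).normal(0, scale, (n, cfg.dim))
        else:
            X = rng_for(cfg.seed, "nmds-init", rep).normal(0, scale, (n, cfg.dim))

        d = pdist(X)
        dhat = monotone_regression(delta, d)
        denom = np.sum(d ** 2)
        prev_stress = np.sqrt(np.sum((d - dhat) ** 2) / denom) if denom > 0 else np.inf
        history = [float(prev_stress)]
        converged = False
        it = 0
        for it in range(1, cfg.max_iter + 1):
            X_new = _guttman_update(X, dhat)
            d_new = pdist(X_new)
            dhat_new = monotone_regression(delta, d_new)
            denom = np.sum(d_new ** 2)
            if denom == 0:
                break
            s_new = float(np.sqrt(np.sum((d_new - dhat_new) ** 2) / denom))
            if s_new > prev_stress + 1e-12:
                # reject the step; keep the last accepted configuration
                converged = True
                break
            dx = float(np.max(np.abs(X_new - X)))
            X, dhat = X_new, dhat_new
            history.append(s_new)
            if prev_stress - s_new < cfg.tol_fun or dx < cfg.tol_x:
                prev_stress = s_new
                converged = True
                break
            prev_stress = s_new
        emb = Embedding(
            coords=X, stress=float(prev_stress), dim=cfg.dim,
            n_iterations=it, converged=converged, stress_history=history,
        )
        if best is None or emb.stress < best.stress:
            best = emb
    return best
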