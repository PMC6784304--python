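"""Dynamic Time Warping dissimilarities between multivariate trajectories.

The local cost between two time points is the (unsquared) Euclidean norm of
the channel-wise angle difference, so accumulated costs keep the units of the
data (radians). The warping path is monotone with unit diagonal, horizontal
and vertical steps, anchored at both endpoints. No band or slope constraint
is applied by default; an optional Sakoe-Chiba band is exposed for speed.

Although the accumulated cost is often loosely called a "similarity", it is a
dissimilarity and is treated strictly as such throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .errors import InvalidArgumentError

__all__ = ["DistanceMatrix", "dtw_distance", "distance_matrix"]


@njit(cache=True)
def _dtw_pair(a, b, band):  # pragma: no cover - exercised through wrappers
    na, nb = a.shape[0], b.shape[0]
    nc = a.shape[1]
    INF = np.inf
    prev = np.full(nb + 1, INF)
    curr = np.full(nb + 1, INF)
    prev[0] = 0.0
    for i in range(1, na + 1):
        curr[0] = INF
        lo, hi = 1, nb
        if band >= 0:
            # keep |i-j| <= band after scaling for unequal lengths
            c = i * nb / na
            lo = max(1, int(np.floor(c - band)))
            hi = min(nb, int(np.ceil(c + band)))
        for j in range(1, nb + 1):
            if j < lo or j > hi:
                curr[j] = INF
                continue
            acc = 0.0
            for k in range(nc):
                d = a[i - 1, k] - b[j - 1, k]
                acc += d * d
            cost = np.sqrt(acc)
            best = prev[j]          # vertical
            if prev[j - 1] < best:  # diagonal
                best = prev[j - 1]
            if curr[j - 1] < best:  # horizontal
                best = curr[j - 1]
            curr[j] = cost + best
        prev, curr = curr, prev
    return prev[nb]


@njit(cache=True)
def _dtw_all(data, lengths, band, normalize):  # pragma: no cover
    n = lengths.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _dtw_pair(data[i, : lengths[i]], data[j, : lengths[j]], band)
            if normalize:
                d = d / (lengths[i] + lengths[j])
            out[i, j] = d
            out[j, i] = d
    return out


def _as_values(x) -> np.ndarray:
    v = getattr(x, "values", x)
    v = np.asarray(v, dtype=float)
    if v.ndim != 2:
        raise InvalidArgumentError("trajectory must be a 2-D (T x channels) array")
    return v


@dataclass
class DistanceMatrix:
    """Symmetric DTW dissimilarity matrix with per-trial labels."""

    values: np.ndarray
    labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or len(self.labels) != n:
            raise InvalidArgumentError("distance matrix must be square with matching labels")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InvalidArgumentError("distances must be finite and non-negative")
        if not np.allclose(self.values, self.values.T):
            raise InvalidArgumentError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise InvalidArgumentError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def dtw_distance(a, b, band: int | None = None, path_normalize: bool = False) -> float:
    """DTW dissimilarity between two trajectories with equal channel counts.

    ``band``: optional Sakoe-Chiba half-width (samples); ``None`` = unconstrained.
    ``path_normalize``: divide the accumulated cost by T_a + T_b.
    """
    va, vb = _as_values(a), _as_values(b)
    if va.shape[1] != vb.shape[1]:
        raise InvalidArgumentError(
            f"channel count mismatch: {va.shape[1]} vs {vb.shape[1]}"
        )
    if va.shape[0] < 1 or vb.shape[0] < 1:
        raise InvalidArgumentError("trajectories must have at least one sample")
    d = float(_dtw_pair(np.ascontiguousarray(va), np.ascontiguousarray(vb),
                        -1 if band is None else int(band)))
    if path_normalize:
        d /= va.shape[0] + vb.shape[0]
    return d


def distance_matrix(
    trajs: Sequence,
    band: int | None = None,
    path_normalize: bool = False,
    standardize: bool = False,
) -> DistanceMatrix:
    """Pairwise DTW dissimilarities for a batch of trajectories.

    Only the upper triangle is computed; symmetry and the zero diagonal hold
    by construction.  ``standardize`` z-scores each channel over the pooled
    samples of all trajectories before the distance computation.
    """
    if len(trajs) < 2:
        raise InvalidArgumentError("need at least two trajectories")
    arrays = [_as_values(t) for t in trajs]
    nch = arrays[0].shape[1]
    for v in arrays:
        if v.shape[1] != nch:
            raise InvalidArgumentError("all trajectories must share the channel count")
    if standardize:
        pooled = np.vstack(arrays)
        mu = pooled.mean(axis=0)
        sd = pooled.std(axis=0)
        sd[sd == 0] = 1.0
        arrays = [(v - mu) / sd for v in arrays]
    labels = [
        getattr(t, "label", f"s{i:04d}") for i, t in enumerate(trajs)
    ]
    lengths = np.array([v.shape[0] for v in arrays], dtype=np.int64)
    packed = np.zeros((len(arrays), lengths.max(), nch))
    for i, v in enumerate(arrays):
        packed[i, : v.shape[0]] = v
    values = _dtw_all(packed, lengths, -1 if band is None else int(band),
                      bool(path_normalize))
    return DistanceMatrix(values=values, labels=labels)
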