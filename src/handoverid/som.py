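"""Eight-axis self-organizing map coding of embedded trajectories.

The map has eight lattice axes with two units along each, 2^8 = 256 units in
total. With only two units per axis the lattice is the {0,1}^8 hypercube and
inter-unit distance on the lattice is the Hamming distance; the neighbourhood
function is a Gaussian in that distance. After training, every trajectory is
coded by the 8-tuple lattice position (row, column, plane, cube, tesseract,
penteract, hexeract, hepteract) of its best-matching unit (BMU), and those
eight binary coordinates serve as the dependent variables of the MANOVA
downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._rng import rng_for
from .errors import InvalidArgumentError
from .lvq import CVPartition

__all__ = [
    "AXIS_NAMES",
    "SOMLattice",
    "SOMConfig",
    "som_init",
    "som_train",
    "bmu_coordinates",
    "cross_validated_codes",
]

AXIS_NAMES = (
    "row", "column", "plane", "cube", "tesseract", "penteract", "hexeract", "hepteract",
)

N_AXES = 8
UNITS_PER_AXIS = 2
N_UNITS = UNITS_PER_AXIS ** N_AXES  # 256

#: lattice coordinates of the 256 units, in lexicographic order
UNIT_COORDS = np.array(list(itertools.product((0, 1), repeat=N_AXES)), dtype=int)

# pairwise Hamming distances on the lattice, used by the neighbourhood function
_HAMMING = (UNIT_COORDS[:, None, :] != UNIT_COORDS[None, :, :]).sum(axis=2)


@dataclass
class SOMLattice:
    weights: np.ndarray  # 256 x d
    unit_coords: np.ndarray = None
    trained: bool = False

    def __post_init__(self):
        if self.unit_coords is None:
            self.unit_coords = UNIT_COORDS.copy()
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != N_UNITS:
            raise InvalidArgumentError(f"lattice must have exactly {N_UNITS} units")

    @property
    def input_dim(self) -> int:
        return self.weights.shape[1]


@dataclass(frozen=True)
class SOMConfig:
    epochs: int = 10
    lr0: float = 0.5
    radius0: float = 2.0
    seed: int = 0


def som_init(input_dim: int, seed: int = 0, data: np.ndarray | None = None) -> SOMLattice:
    """256-unit lattice with weights seeded around the data centroid (or the
    unit hypercube when no data is supplied)."""
    if input_dim < 1:
        raise InvalidArgumentError("input_dim must be >= 1")
    rng = rng_for(seed, "som-init")
    if data is not None:
        data = np.asarray(data, dtype=float)
        centre = data.mean(axis=0)
        scale = 0.1 * (data.std() or 1.0)
    else:
        centre = np.full(input_dim, 0.5)
        scale = 0.1
    weights = centre + rng.normal(0.0, scale, (N_UNITS, input_dim))
    return SOMLattice(weights=weights)


def som_train(
    lattice: SOMLattice,
    X: np.ndarray,
    epochs: int = 10,
    lr0: float = 0.5,
    radius0: float = 2.0,
    seed: int = 0,
) -> SOMLattice:
    """Classic online SOM training.

    Per presented sample: find the BMU (Euclidean), pull it and its lattice
    neighbours (Gaussian in Hamming distance) toward the sample. Learning rate
    and radius decay linearly over all presentations; the presentation order
    is a seeded permutation per epoch.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 1:
        raise InvalidArgumentError("need at least one sample")
    if X.shape[1] != lattice.input_dim:
        raise InvalidArgumentError("sample dimension does not match the lattice")
    W = lattice.weights.copy()
    rng = rng_for(seed, "som-train")
    n = X.shape[0]
    total = max(1, epochs * n)
    step = 0
    r_min = 0.25
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / total
            lr = lr0 * (1.0 - frac)
            radius = radius0 + (r_min - radius0) * frac
            step += 1
            if lr <= 0:
                break
            diff = W - X[i]
            bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            h = np.exp(-(_HAMMING[bmu] ** 2) / (2.0 * radius ** 2))
            W += (lr * h)[:, None] * (X[i] - W)
    return SOMLattice(weights=W, unit_coords=lattice.unit_coords.copy(), trained=True)


def bmu_coordinates(lattice: SOMLattice, X: np.ndarray) -> np.ndarray:
    """8-tuple lattice position of each sample's best-matching unit.

    Units are stored in lexicographic coordinate order, so argmin's
    first-minimum rule breaks distance ties toward the lexicographically
    smallest tuple.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    d2 = ((X[:, None, :] - lattice.weights[None, :, :]) ** 2).sum(axis=2)
    return lattice.unit_coords[np.argmin(d2, axis=1)]


def cross_validated_codes(
    X: np.ndarray,
    cv: CVPartition,
    train_cfg: SOMConfig = SOMConfig(),
) -> np.ndarray:
    """Per fold: train a map on the complement and code the held-out fold;
    codes are returned in original trial order (n x 8 binary matrix)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    codes = np.full((X.shape[0], N_AXES), -1, dtype=int)
    for k, fold in enumerate(cv.folds):
        train_idx = cv.complement(k) if cv.n_folds > 1 else fold
        lattice = som_init(X.shape[1], seed=train_cfg.seed + k, data=X[train_idx])
        lattice = som_train(
            lattice, X[train_idx], epochs=train_cfg.epochs,
            lr0=train_cfg.lr0, radius0=train_cfg.radius0, seed=train_cfg.seed + k,
        )
        codes[fold] = bmu_coordinates(lattice, X[fold])
    if np.any(codes < 0):
        raise InvalidArgumentError("CV folds do not cover every trial")
    return codes
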