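"""Mutual-information and MANOVA statistics.

Mutual information is estimated on histograms ("descriptors"): a first pass
fixes each variable's descriptor (range and cell count, Sturges-style for
continuous inputs, one cell per category otherwise), a second pass evaluates
the plug-in estimate in bits, minus a first-order Miller-Madow bias term
(Rx-1)(Ry-1)/(2 N ln 2) with Rx, Ry the occupied marginal cell counts.

The MANOVA fits a multivariate linear model to the 8 binary BMU coordinates,
forms hypothesis (H) and error (E) cross-product matrices per term (Type II:
each term against the model containing all other terms), and maps the
eigenvalues of E^-1 H to the four classical statistics - Pillai's trace,
Wilks' lambda, the Hotelling-Lawley trace and Roy's largest root - with
their standard approximate-F transforms. Backward model reduction drops, one
at a time, the candidate term with the largest Wilks p >= alpha until every
retained term is significant in every fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgumentError, RankDeficiencyError

__all__ = [
    "Descriptor",
    "choose_descriptor",
    "discretize",
    "entropy",
    "mutual_information",
    "mi_matrix",
    "ManovaResult",
    "manova",
    "model_reduction",
]

STATISTIC_NAMES = ("Pillai", "Wilks", "Hotelling", "Roy")


# --------------------------------------------------------------------------
# mutual information
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Descriptor:
    """Histogram specification for one variable."""

    lower: float
    upper: float
    n_cells: int

    def __post_init__(self):
        if self.n_cells < 1:
            raise InvalidArgumentError("n_cells must be >= 1")
        if self.upper <= self.lower:
            raise InvalidArgumentError("upper must exceed lower")


def _encode(x) -> tuple[np.ndarray, bool]:
    """Return (numeric codes, is_categorical)."""
    arr = np.asarray(x)
    if arr.dtype.kind in "OUSb":
        cats = sorted(set(arr.astype(str)))
        lut = {c: i for i, c in enumerate(cats)}
        return np.array([lut[str(v)] for v in arr], dtype=float), True
    return arr.astype(float), False


def choose_descriptor(x, categorical: bool | None = None) -> Descriptor:
    """Descriptor from the sample: one cell per category for categorical
    inputs, else a Sturges-style cell count ceil(1 + log2 n) over the sample
    range. A constant sample yields a single cell (zero entropy)."""
    codes, is_cat = _encode(x)
    if codes.size < 2:
        raise InvalidArgumentError("need at least two samples")
    if categorical is not None:
        is_cat = categorical
    lo, hi = float(codes.min()), float(codes.max())
    if is_cat:
        k = int(hi - lo) + 1
        return Descriptor(lower=lo - 0.5, upper=hi + 0.5, n_cells=k)
    if lo == hi:
        return Descriptor(lower=lo, upper=lo + 1.0, n_cells=1)
    # integer-coded labels with few distinct values behave like categories
    distinct = np.unique(codes)
    sturges = int(np.ceil(1 + np.log2(codes.size)))
    if distinct.size <= sturges and np.allclose(distinct, np.round(distinct)):
        return Descriptor(lower=lo - 0.5, upper=hi + 0.5, n_cells=int(hi - lo) + 1)
    return Descriptor(lower=lo, upper=hi, n_cells=sturges)


def discretize(x, desc: Descriptor) -> np.ndarray:
    """Cell index of each sample under the descriptor (clipped to range)."""
    codes, _ = _encode(x)
    width = (desc.upper - desc.lower) / desc.n_cells
    idx = np.floor((codes - desc.lower) / width).astype(int)
    return np.clip(idx, 0, desc.n_cells - 1)


def entropy(x, desc: Descriptor | None = None) -> float:
    """Plug-in histogram entropy in bits."""
    if desc is None:
        desc = choose_descriptor(x)
    counts = np.bincount(discretize(x, desc), minlength=desc.n_cells)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def mutual_information(
    x,
    y,
    desc_x: Descriptor | None = None,
    desc_y: Descriptor | None = None,
    corrected: bool = True,
) -> float:
    """Histogram mutual information I(x; y) in bits.

    ``corrected=True`` subtracts the first-order Miller-Madow bias term
    (Rx-1)(Ry-1)/(2 N ln 2); the uncorrected plug-in estimate is non-negative
    and satisfies I(x, x) = H(x)."""
    xa, _ = _encode(x)
    ya, _ = _encode(y)
    if xa.shape != ya.shape:
        raise InvalidArgumentError("samples must have equal length")
    if desc_x is None:
        desc_x = choose_descriptor(x)
    if desc_y is None:
        desc_y = choose_descriptor(y)
    ix = discretize(x, desc_x)
    iy = discretize(y, desc_y)
    n = ix.size
    joint = np.zeros((desc_x.n_cells, desc_y.n_cells))
    np.add.at(joint, (ix, iy), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    mask = pxy > 0
    mi = float(np.sum(pxy[mask] * np.log2(pxy[mask] / np.outer(px, py)[mask])))
    if corrected:
        rx = int(np.count_nonzero(px))
        ry = int(np.count_nonzero(py))
        mi -= (rx - 1) * (ry - 1) / (2.0 * n * np.log(2.0))
    return mi


def mi_matrix(frame: pd.DataFrame, corrected: bool = True) -> pd.DataFrame:
    """Symmetric pairwise MI over all columns, two-pass protocol: descriptors
    are fixed per column first, then every pairwise estimate reuses them."""
    cols = list(frame.columns)
    descs = {c: choose_descriptor(frame[c].to_numpy()) for c in cols}
    out = np.zeros((len(cols), len(cols)))
    for i, ci in enumerate(cols):
        for j in range(i, len(cols)):
            cj = cols[j]
            v = mutual_information(
                frame[ci].to_numpy(), frame[cj].to_numpy(),
                desc_x=descs[ci], desc_y=descs[cj], corrected=corrected,
            )
            out[i, j] = out[j, i] = v
    return pd.DataFrame(out, index=cols, columns=cols)


# --------------------------------------------------------------------------
# MANOVA
# --------------------------------------------------------------------------

def _term_columns(data: pd.DataFrame, term: str) -> np.ndarray:
    col = data[term]
    if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
        levels = sorted(set(col.astype(str)))
        # reference coding, first level dropped
        return np.column_stack([
            (col.astype(str) == lv).to_numpy(float) for lv in levels[1:]
        ]) if len(levels) > 1 else np.zeros((len(col), 0))
    v = col.to_numpy(float)
    return v[:, None]


def design_matrix(data: pd.DataFrame, terms: Sequence[str],
                  include_intercept: bool = True) -> np.ndarray:
    """The model matrix the MANOVA uses (intercept + coded term blocks)."""
    parts = [np.ones((len(data), 1))] if include_intercept else []
    parts += [_term_columns(data, t) for t in terms]
    return np.hstack(parts) if parts else np.zeros((len(data), 0))


def _residual_sscp(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual cross-product matrix and the design rank (least squares via
    pinv, so rank-deficient designs are handled)."""
    if X.shape[1] == 0:
        return Y.T @ Y, 0
    B, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    R = Y - X @ B
    return R.T @ R, int(rank)


@dataclass
class StatRow:
    statistic: str
    value: float
    F: float
    df1: float
    df2: float
    p: float


@dataclass
class ManovaResult:
    """Per-term four-statistic MANOVA table."""

    terms: dict = field(default_factory=dict)  # term -> {stat name -> StatRow}
    error_dof: int = 0
    n_obs: int = 0

    def p(self, term: str, statistic: str = "Wilks") -> float:
        return self.terms[term][statistic].p

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for term, stats in self.terms.items():
            for name, r in stats.items():
                rows.append({
                    "term": term, "statistic": name, "value": r.value,
                    "F": r.F, "df1": r.df1, "df2": r.df2, "p": r.p,
                })
        return pd.DataFrame(rows)


def _four_statistics(lam: np.ndarray, p: int, q: int, v: int) -> dict[str, StatRow]:
    """Map the eigenvalues of E^-1 H to the four classical statistics and
    their standard approximate-F transforms (p responses, q hypothesis dof,
    v error dof)."""
    lam = np.clip(np.real(lam), 0.0, None)
    s = min(p, q)
    m = (abs(p - q) - 1) / 2.0
    nn = (v - p - 1) / 2.0
    out = {}

    V = float(np.sum(lam / (1.0 + lam)))
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * V / (s - V) if s > V and df1 > 0 else np.inf
    out["Pillai"] = StatRow("Pillai", V, F, df1, df2, _fp(F, df1, df2))

    L = float(np.prod(1.0 / (1.0 + lam)))
    if p ** 2 + q ** 2 - 5 > 0:
        t = np.sqrt((p ** 2 * q ** 2 - 4) / (p ** 2 + q ** 2 - 5))
    else:
        t = 1.0
    w = v - (p - q + 1) / 2.0
    df1 = p * q
    df2 = w * t - (p * q - 2) / 2.0
    Lt = L ** (1.0 / t) if L > 0 else 0.0
    F = ((1.0 - Lt) / Lt) * (df2 / df1) if Lt > 0 and df1 > 0 else np.inf
    out["Wilks"] = StatRow("Wilks", L, F, df1, df2, _fp(F, df1, df2))

    # McKeon's approximation (the SAS convention) when the error dof allow it
    U = float(np.sum(lam))
    if nn > 1:
        b = (p + 2 * nn) * (q + 2 * nn) / (2 * (2 * nn + 1) * (nn - 1))
        df1 = p * q
        df2 = 4 + (p * q + 2) / (b - 1)
        c = (df2 - 2) / (2 * nn)
        F = (df2 / df1) * U / c
    else:
        df1 = s * (2 * m + s + 1)
        df2 = s * (s * nn + 1)
        F = (df2 / df1) * U / s if df1 > 0 else np.inf
    out["Hotelling"] = StatRow("Hotelling", U, F, df1, df2, _fp(F, df1, df2))

    r = max(p, q)
    lmax = float(lam.max(initial=0.0))
    df1 = r
    df2 = v - r + q
    F = lmax * df2 / df1 if df1 > 0 else np.inf
    out["Roy"] = StatRow("Roy", lmax, F, df1, df2, _fp(F, df1, df2))
    return out


def _fp(F: float, df1: float, df2: float) -> float:
    if not np.isfinite(F) or df1 <= 0 or df2 <= 0:
        return float("nan")
    return float(sps.f.sf(F, df1, df2))


def manova(
    Y: np.ndarray,
    data: pd.DataFrame,
    terms: Sequence[str],
    include_intercept: bool = True,
) -> ManovaResult:
    """Type II MANOVA of the responses ``Y`` on the named ``terms`` of ``data``.

    Categorical terms get reference coding; numeric terms enter as single
    regressors. Each term's H matrix is the residual-SSCP difference between
    the model without the term and the full model; E is the full-model
    residual SSCP. Raises :class:`RankDeficiencyError` when E is singular,
    naming the offending response columns."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = Y.shape
    if len(data) != n:
        raise InvalidArgumentError("data frame must align with the responses")
    blocks = {t: _term_columns(data, t) for t in terms}
    parts = [np.ones((n, 1))] if include_intercept else []
    parts += [blocks[t] for t in terms]
    X_full = np.hstack(parts) if parts else np.zeros((n, 0))
    E, full_rank = _residual_sscp(X_full, Y)
    v = n - full_rank
    if v <= 0:
        raise InvalidArgumentError("no error degrees of freedom left")
    if np.linalg.matrix_rank(E) < p:
        bad = [str(j) for j in range(p) if E[j, j] <= 1e-12]
        raise RankDeficiencyError(
            "singular error matrix; degenerate response columns: "
            + (", ".join(bad) if bad else "(linear dependence among responses)")
        )

    result = ManovaResult(error_dof=v, n_obs=n)
    tested = (["(intercept)"] if include_intercept else []) + list(terms)
    for term in tested:
        if term == "(intercept)":
            parts_red = [blocks[t] for t in terms]
        else:
            parts_red = [np.ones((n, 1))] if include_intercept else []
            parts_red += [blocks[t] for t in terms if t != term]
        X_red = np.hstack(parts_red) if parts_red else np.zeros((n, 0))
        E_red, red_rank = _residual_sscp(X_red, Y)
        q = full_rank - red_rank
        if q <= 0:
            # the term adds nothing beyond the rest of the model
            result.terms[term] = {
                name: StatRow(name, 0.0, 0.0, 0.0, float(v), 1.0)
                for name in STATISTIC_NAMES
            }
            continue
        H = E_red - E
        lam = np.linalg.eigvals(np.linalg.solve(E, H))
        result.terms[term] = _four_statistics(lam, p, q, v)
    return result


def model_reduction(
    Y,
    data,
    candidates: Sequence[str],
    alpha: float = 0.05,
    statistic: str = "Wilks",
    fixed_terms: Sequence[str] = (),
):
    """Backward elimination over candidate MANOVA terms.

    ``Y``/``data`` may be a single response matrix + frame, or parallel lists
    of them (one per fold; e.g. codes from differently trained maps).  Each
    round evaluates every retained term's worst (maximum over folds) p-value
    for the chosen statistic; if any is >= alpha, the term with the largest
    worst-case p is dropped (ties: earliest in candidate order).  Stops when
    all retained terms are significant in every fold or nothing remains.

    ``fixed_terms`` stay in the model but are never candidates for
    elimination (e.g. participant identity, to ask whether a property adds
    anything beyond individuality; a property constant within participants is
    then completely redundant and falls out immediately).

    Returns ``(retained, per_fold_results)``; ``per_fold_results`` is empty
    when no term survives."""
    if not candidates:
        raise InvalidArgumentError("need at least one candidate term")
    if isinstance(Y, (list, tuple)):
        folds = list(zip(Y, data if isinstance(data, (list, tuple)) else [data] * len(Y)))
    else:
        folds = [(Y, data)]
    fixed_terms = list(fixed_terms)
    retained = list(candidates)
    while retained:
        results = [manova(Yk, dk, fixed_terms + retained) for Yk, dk in folds]
        worst = {
            t: max(r.p(t, statistic) if np.isfinite(r.p(t, statistic)) else 1.0
                   for r in results)
            for t in retained
        }
        if all(pv < alpha for pv in worst.values()):
            return retained, results
        drop = max(retained, key=lambda t: worst[t])  # first-listed wins ties (max keeps first)
        retained.remove(drop)
    return [], []
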