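"""Directed interaction inference via box-kernel transfer entropy.

Transfer entropy (TE) from a source series X to a target series Y measures,
in bits, how much the past of X reduces uncertainty about the present of Y
beyond what Y's own past already explains:

    TE(X -> Y) = sum p(y_t, y_{t-1}, x_{t-1}) *
                 log2 [ p(y_t | y_{t-1}, x_{t-1}) / p(y_t | y_{t-1}) ]

Probabilities are plug-in estimates from box-kernel (Heaviside, max-norm)
neighbor counts in the 1-, 2- and 3-dimensional embedded spaces, after
z-normalizing each series so the kernel radius is in standard-deviation
units. Defaults: history length 1, kernel radius 0.5 normalized units,
log base 2. The estimator is fully deterministic; points at distance exactly
the kernel radius count as inside (closed ball) so results are
bit-reproducible.

Raw estimates may be slightly negative (finite-sample noise); they are
returned as-is, and flooring at zero is the caller's choice (the tail
fitting stage floors them).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .core import CommunityTable
from .errors import (
    ExperimentalWarning,
    SeriesLengthError,
    ShortSeriesWarning,
    ZeroVarianceError,
)


def normalize_series(x: np.ndarray) -> np.ndarray:
    """Z-normalize a series to mean 0 and (sample, ddof=1) sd 1.

    Raises
    ------
    ZeroVarianceError
        If the series is constant. Callers that want the TE convention
        (constant series carry no information; TE = 0) catch this flag.
    SeriesLengthError
        If the series has fewer than 2 points or contains NaN.
    """
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size < 2:
        raise SeriesLengthError(f"need at least 2 points to normalize, got {arr.size}")
    if not np.isfinite(arr).all():
        raise SeriesLengthError("series contains NaN or infinite values")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise ZeroVarianceError("constant (zero-variance) series")
    return (arr - arr.mean()) / sd


def _is_constant(x: np.ndarray) -> bool:
    return bool(np.all(x == x.ravel()[0]))


def _neighbors(a: np.ndarray, radius: float) -> np.ndarray:
    """Closed-ball neighbor matrix for a 1-D coordinate: |a_i - a_j| <= radius."""
    return np.abs(a[:, None] - a[None, :]) <= radius


def _lag_block(a: np.ndarray, history: int, radius: float) -> np.ndarray:
    """Max-norm neighbor matrix of the length-`history` past embedding of `a`.

    Row/column i corresponds to the embedded observation at time history+i,
    whose past vector is a[i : i+history].
    """
    n = a.size - history
    block = np.ones((n, n), dtype=bool)
    for lag in range(history):
        block &= _neighbors(a[lag : lag + n], radius)
    return block


def transfer_entropy(
    source: np.ndarray,
    target: np.ndarray,
    history: int = 1,
    kernel_width: float = 0.5,
) -> float:
    """Plug-in box-kernel TE(source -> target) in bits.

    Parameters
    ----------
    source, target:
        Equal-length abundance series, t >= 3.
    history:
        Target/source history length (embedding dimension of the past).
        Only 1 is the validated default; other values warn as experimental.
    kernel_width:
        Kernel (closed-ball, max-norm) radius in normalized sd units.

    Returns
    -------
    float
        The raw plug-in estimate; may be slightly negative. By convention,
        exactly 0.0 if either series has zero variance.
    """
    x = np.asarray(source, dtype=float).ravel()
    y = np.asarray(target, dtype=float).ravel()
    if x.size != y.size:
        raise SeriesLengthError(f"length mismatch: source {x.size}, target {y.size}")
    if x.size < history + 2:
        raise SeriesLengthError(
            f"need t >= {history + 2} for history {history}, got t = {x.size}"
        )
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise SeriesLengthError("series contain NaN or infinite values")
    if history != 1:
        warnings.warn(
            f"history={history} is experimental; the validated setting is 1",
            ExperimentalWarning,
            stacklevel=2,
        )
    if _is_constant(x) or _is_constant(y):
        return 0.0
    xn = normalize_series(x)
    yn = normalize_series(y)
    b_now = _neighbors(yn[history:], kernel_width)
    b_ypast = _lag_block(yn, history, kernel_width)
    b_xpast = _lag_block(xn, history, kernel_width)
    return _te_from_blocks(b_now, b_ypast, b_xpast)


def _te_from_blocks(
    b_now: np.ndarray, b_ypast: np.ndarray, b_xpast: np.ndarray
) -> float:
    """Average log2 likelihood ratio from precomputed neighbor blocks.

    Counts include the query point itself, so every count is >= 1 and the
    logarithm is always defined.
    """
    yp_xp = b_ypast & b_xpast
    c_full = (b_now & yp_xp).sum(axis=1)
    c_yp_xp = yp_xp.sum(axis=1)
    c_y_yp = (b_now & b_ypast).sum(axis=1)
    c_yp = b_ypast.sum(axis=1)
    ratios = (c_full.astype(float) * c_yp) / (c_yp_xp.astype(float) * c_y_yp)
    return float(np.mean(np.log2(ratios)))


@dataclass
class TEMatrix:
    """Directed OTU x OTU transfer-entropy matrix in bits.

    Entry (i, j) is TE(X_i -> X_j); the diagonal is undefined (NaN). The
    matrix is generally asymmetric. Pairs involving a zero-variance OTU are
    exactly 0 by convention.
    """

    otu_ids: list[str]
    values: np.ndarray

    def offdiagonal(self) -> np.ndarray:
        """All directed off-diagonal TE values (raw, possibly negative)."""
        n = len(self.otu_ids)
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]

    def pooled_values(
        self, floor_negative: bool = True, drop_zero: bool = True
    ) -> np.ndarray:
        """Off-diagonal values prepared for exceedance-tail fitting.

        Negative estimates are floored at 0 (EPDFs need non-negative
        support) and zeros dropped, per the fitting convention.
        """
        v = self.offdiagonal()
        if floor_negative:
            v = np.maximum(v, 0.0)
        if drop_zero:
            v = v[v > 0]
        return v

    def to_edgelist_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source_id\ttarget_id\tte_bits\n")
            for i, src in enumerate(self.otu_ids):
                for j, tgt in enumerate(self.otu_ids):
                    if i == j:
                        continue
                    fh.write(f"{src}\t{tgt}\t{self.values[i, j]:.10g}\n")

    def to_matrix_tsv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.otu_ids, columns=self.otu_ids).rename_axis(
            "otu_id"
        ).to_csv(path, sep="\t", float_format="%.10g")

    def to_graphml(self, path: str | Path, threshold: float = 0.0) -> None:
        """Export the directed interaction graph (edges with TE > threshold)."""
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.otu_ids)
        n = len(self.otu_ids)
        for i in range(n):
            for j in range(n):
                if i != j and self.values[i, j] > threshold:
                    g.add_edge(
                        self.otu_ids[i], self.otu_ids[j],
                        te_bits=float(self.values[i, j]),
                    )
        nx.write_graphml(g, path)


class TransferEntropy(BaseEstimator):
    """Pairwise transfer-entropy estimator over a community's OTU series.

    scikit-learn style: ``fit`` computes every ordered OTU pair and exposes
    the result as fitted attributes.

    Parameters
    ----------
    history:
        Past embedding length (default 1, the validated setting).
    kernel_width:
        Box-kernel radius in normalized sd units (default 0.5).

    Attributes
    ----------
    te_matrix_ : TEMatrix
        Directed matrix of TE values in bits (NaN diagonal).
    otu_ids_ : list of str
    n_zero_variance_ : int
        Number of constant OTU series (their TE is 0 in both directions).
    """

    def __init__(self, history: int = 1, kernel_width: float = 0.5):
        self.history = history
        self.kernel_width = kernel_width

    def fit(self, X: CommunityTable | np.ndarray, y=None) -> "TransferEntropy":
        """Compute TE for every ordered pair of rows of X.

        Parameters
        ----------
        X:
            A :class:`CommunityTable` or an (n_otu, t) array of series.
        """
        if isinstance(X, CommunityTable):
            ids = X.otu_ids
            data = X.values().astype(float)
        else:
            data = np.asarray(X, dtype=float)
            if data.ndim != 2:
                raise SeriesLengthError("expected an (n_otu, t) matrix")
            ids = [f"OTU_{i}" for i in range(data.shape[0])]
        n, t = data.shape
        if t < 3:
            raise SeriesLengthError(f"need t >= 3 for pairwise TE, got t = {t}")
        if t < 10:
            warnings.warn(
                f"t = {t} < 10: transfer-entropy estimates will be very noisy",
                ShortSeriesWarning,
                stacklevel=2,
            )
        h, r = self.history, self.kernel_width
        constant = np.array([_is_constant(row) for row in data])
        norm = [None if constant[i] else normalize_series(data[i]) for i in range(n)]
        # Past-embedding neighbor blocks are reused across every pair that
        # shares the series, so cache them per OTU (cheap: (t-h)^2 booleans).
        b_past = [None if constant[i] else _lag_block(norm[i], h, r) for i in range(n)]
        values = np.zeros((n, n), dtype=float)
        np.fill_diagonal(values, np.nan)
        for j in range(n):
            if constant[j]:
                continue
            b_now = _neighbors(norm[j][h:], r)
            b_ypast = b_past[j]
            for i in range(n):
                if i == j or constant[i]:
                    continue
                values[i, j] = _te_from_blocks(b_now, b_ypast, b_past[i])
        self.te_matrix_ = TEMatrix(otu_ids=list(ids), values=values)
        self.otu_ids_ = list(ids)
        self.n_zero_variance_ = int(constant.sum())
        return self


def pairwise_te(
    community: CommunityTable, history: int = 1, kernel_width: float = 0.5
) -> TEMatrix:
    """Directed TE between every ordered OTU pair of a community (in bits)."""
    est = TransferEntropy(history=history, kernel_width=kernel_width).fit(community)
    return est.te_matrix_


def permutation_surrogates(
    source: np.ndarray,
    target: np.ndarray,
    n_surrogates: int = 100,
    rng: np.random.Generator | int | None = None,
    history: int = 1,
    kernel_width: float = 0.5,
) -> np.ndarray:
    """TE estimates after randomly permuting the source series.

    Permuting the source destroys any lagged dependence while preserving its
    marginal distribution; the resulting distribution of TE values is the
    null against which an observed estimate can be compared (e.g. to its
    95th percentile).
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(source, dtype=float).ravel()
    out = np.empty(n_surrogates)
    for k in range(n_surrogates):
        out[k] = transfer_entropy(
            rng.permutation(x), target, history=history, kernel_width=kernel_width
        )
    return out
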