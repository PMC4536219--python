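"""Ordination: reciprocal averaging (correspondence analysis) and PCoA.

Reciprocal averaging arranges sites and taxa so that similar assemblages
and similarly-distributed taxa sit next to each other — the "latent
gradient" all downstream metacommunity statistics are measured along.
It is computed non-iteratively as the SVD of the chi-square-standardised
incidence matrix, which makes scores deterministic up to sign; a fixed
sign convention (first site scores non-negatively on every axis) removes
the remaining ambiguity.

Classical-scaling PCoA keeps the full eigendecomposition, including
negative eigenvalues, because beta-dispersion distances need the
"imaginary" axes produced by non-Euclidean dissimilarities such as
Bray–Curtis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class DegenerateMatrixError(ValueError):
    """Raised when a matrix has too low a rank for the requested axes."""


def _as_array(m) -> np.ndarray:
    return m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) else np.asarray(m, float)


class ReciprocalAveraging(BaseEstimator, TransformerMixin):
    """Reciprocal averaging (correspondence analysis) of an incidence matrix.

    Parameters
    ----------
    n_axes : int, default 2
        Number of non-trivial ordination axes to extract.

    Attributes
    ----------
    site_scores_ : ndarray of shape (n_sites, n_axes)
        Row principal coordinates.
    taxon_scores_ : ndarray of shape (n_taxa, n_axes)
        Column principal coordinates.
    eigenvalues_ : ndarray of shape (n_axes,)
        Squared singular values of the standardised matrix, descending.
    site_order_, taxon_order_ : ndarray of shape (n_axes, n)
        Permutations sorting sites/taxa by each axis score (stable ties by
        input position).
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, X, y=None):
        A = _as_array(X)
        if A.size == 0:
            raise DegenerateMatrixError("empty matrix")
        row_tot = A.sum(axis=1)
        col_tot = A.sum(axis=0)
        if np.any(row_tot == 0) or np.any(col_tot == 0):
            raise DegenerateMatrixError(
                "all-zero row or column: drop empty sites/taxa before ordination"
            )
        grand = A.sum()
        P = A / grand
        r = row_tot / grand
        c = col_tot / grand
        S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
        U, sv, Vt = np.linalg.svd(S, full_matrices=False)
        nontrivial = sv > 1e-10
        rank = int(nontrivial.sum())
        if rank < self.n_axes:
            raise DegenerateMatrixError(
                f"matrix supports only {rank} non-trivial axes, {self.n_axes} requested"
            )
        k = self.n_axes
        U, sv, Vt = U[:, :k], sv[:k], Vt[:k]
        site = (U / np.sqrt(r)[:, None]) * sv
        taxon = (Vt.T / np.sqrt(c)[:, None]) * sv
        # sign convention: first site scores >= 0 on each axis; ties broken
        # by the first taxon score
        for a in range(k):
            s0 = site[0, a]
            flip = s0 < 0 or (s0 == 0 and taxon[0, a] < 0)
            if flip:
                site[:, a] *= -1
                taxon[:, a] *= -1
        self.site_scores_ = site
        self.taxon_scores_ = taxon
        self.eigenvalues_ = sv**2
        self.site_order_ = np.vstack(
            [np.argsort(site[:, a], kind="stable") for a in range(k)]
        )
        self.taxon_order_ = np.vstack(
            [np.argsort(taxon[:, a], kind="stable") for a in range(k)]
        )
        if isinstance(X, pd.DataFrame):
            self.site_ids_ = X.index.to_numpy()
            self.taxon_ids_ = X.columns.to_numpy()
        return self

    def transform(self, X=None):
        """Return the fitted site scores (RA is not an out-of-sample map)."""
        check_is_fitted(self, "site_scores_")
        return self.site_scores_

    def scores_frame(self) -> pd.DataFrame:
        """Site scores and per-axis ranks as a tidy DataFrame."""
        check_is_fitted(self, "site_scores_")
        idx = getattr(self, "site_ids_", np.arange(self.site_scores_.shape[0]))
        out = pd.DataFrame(
            self.site_scores_,
            index=pd.Index(idx, name="site_id"),
            columns=[f"axis{a + 1}" for a in range(self.n_axes)],
        )
        for a in range(self.n_axes):
            rank = np.empty(len(out), dtype=int)
            rank[self.site_order_[a]] = np.arange(len(out))
            out[f"rank{a + 1}"] = rank
        return out


def reciprocal_averaging(m, n_axes: int = 2) -> ReciprocalAveraging:
    """Convenience wrapper: fit a :class:`ReciprocalAveraging` on ``m``."""
    return ReciprocalAveraging(n_axes=n_axes).fit(m)


def order_matrix(m, ra: ReciprocalAveraging, axis: int = 1):
    """Permute rows and columns of ``m`` by the chosen RA axis scores.

    ``axis`` is 1-based (1 = primary, 2 = secondary). The cell multiset is
    preserved — only the arrangement changes. Because an ordination axis
    is defined only up to reflection, the direction is canonicalised (the
    lexicographically smaller of the two reversals is returned), which
    makes ordering idempotent and independent of input row order.
    """
    if axis not in range(1, ra.n_axes + 1):
        raise ValueError(f"axis must be in 1..{ra.n_axes}, got {axis}")
    rows = ra.site_order_[axis - 1]
    cols = ra.taxon_order_[axis - 1]
    arr = m.to_numpy() if isinstance(m, pd.DataFrame) else np.asarray(m)
    fwd = arr[np.ix_(rows, cols)]
    rev = fwd[::-1, ::-1]
    flat_f, flat_r = fwd.ravel(), rev.ravel()
    cmp = np.nonzero(flat_f != flat_r)[0]
    if cmp.size and flat_r[cmp[0]] < flat_f[cmp[0]]:
        rows, cols = rows[::-1], cols[::-1]
    if isinstance(m, pd.DataFrame):
        return m.iloc[rows, cols]
    return np.asarray(m)[np.ix_(rows, cols)]


def geographic_distances(site_table: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distance matrix between sites from planar x/y coordinates.

    Coordinates must already be projected (metres); longitude/latitude
    input needs a projection step upstream.
    """
    if not {"x", "y"} <= set(site_table.columns):
        raise ValueError("site table lacks 'x'/'y' coordinate columns")
    xy = site_table[["x", "y"]]
    if xy.isna().any().any():
        bad = site_table.index[xy.isna().any(axis=1)].tolist()
        raise ValueError(f"missing coordinates for sites {bad}")
    d = squareform(pdist(xy.to_numpy(dtype=float)))
    return pd.DataFrame(d, index=site_table.index, columns=site_table.index)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centred matrix -J (d²/2) J used by classical scaling."""
    a = -0.5 * d**2
    row_mean = a.mean(axis=1, keepdims=True)
    return a - row_mean - row_mean.T + a.mean()


def full_pcoa(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of the Gower-centred matrix, descending.

    Returns ``(eigenvalues, eigenvectors)`` with *all* eigenvalues kept
    (negative ones arise from non-Euclidean dissimilarities).
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    w, v = eigh(gower_center(d))
    order = np.argsort(w)[::-1]
    return w[order], v[:, order]


class PCoA(BaseEstimator, TransformerMixin):
    """Principal coordinate analysis (classical multidimensional scaling).

    Used here to turn a geographic distance matrix into spatial predictor
    vectors (PCo1, PCo2). Retained axes must have positive eigenvalues.

    Attributes
    ----------
    samples_ : ndarray of shape (n_sites, n_axes)
        Coordinates (eigenvector × sqrt eigenvalue), centred.
    eigenvalues_ : ndarray
        All eigenvalues, descending.
    """

    def __init__(self, n_axes: int = 2):
        self.n_axes = n_axes

    def fit(self, X, y=None):
        ids = X.index.to_numpy() if isinstance(X, pd.DataFrame) else None
        w, v = full_pcoa(_as_array(X))
        if w[self.n_axes - 1] <= 1e-10:
            raise DegenerateMatrixError(
                f"axis {self.n_axes} has non-positive eigenvalue {w[self.n_axes - 1]:.3g}"
            )
        self.eigenvalues_ = w
        self.samples_ = v[:, : self.n_axes] * np.sqrt(w[: self.n_axes])
        self.site_ids_ = ids
        return self

    def transform(self, X=None):
        check_is_fitted(self, "samples_")
        return self.samples_

    def vectors_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "samples_")
        idx = self.site_ids_ if self.site_ids_ is not None else np.arange(len(self.samples_))
        return pd.DataFrame(
            self.samples_,
            index=pd.Index(idx, name="site_id"),
            columns=[f"PCo{a + 1}" for a in range(self.n_axes)],
        )


def pcoa(d, n_axes: int = 2) -> PCoA:
    """Convenience wrapper: fit a :class:`PCoA` on distance matrix ``d``."""
    return PCoA(n_axes=n_axes).fit(d)
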