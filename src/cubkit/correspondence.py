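"""Classical correspondence analysis of the gene x 59-codon RSCU matrix.

The nonnegative RSCU table is scaled to grand total 1, standardized residuals
(P - r c^T) / sqrt(r_i c_j) are decomposed by SVD, and principal coordinates
are returned for rows (genes) and columns (codons) together with per-axis
inertia fractions (sigma_k^2 / sum sigma^2).  Sign indeterminacy is resolved
by making the largest-magnitude column loading of each axis positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CoaResult:
    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    inertia_fraction: np.ndarray
    singular_values: np.ndarray
    axes_kept: int
    row_mass: pd.Series = None
    col_mass: pd.Series = None


def coa_rscu(matrix: pd.DataFrame, n_axes: int = 4) -> CoaResult:
    """Correspondence analysis of a genes x codons RSCU (or count) table.

    Missing entries are imputed as 0.  Rows or columns with zero margin are
    dropped from the decomposition and reported with NaN coordinates.  A
    constant (rank-one) matrix has no non-trivial axis and returns a
    zero-axis result with a warning.
    """
    X = matrix.fillna(0.0).to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("correspondence analysis requires at least 3 rows")
    if np.any(X < 0):
        raise ValueError("correspondence analysis requires a nonnegative table")
    total = X.sum()
    if total <= 0:
        raise ValueError("all-zero table")

    row_keep = X.sum(axis=1) > 0
    col_keep = X.sum(axis=0) > 0
    Xk = X[np.ix_(row_keep, col_keep)]
    P = Xk / Xk.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sig, Vt = np.linalg.svd(S, full_matrices=False)

    max_axes = min(Xk.shape) - 1
    tol = max(Xk.shape) * np.finfo(float).eps * (sig[0] if sig.size else 0.0)
    nontrivial = sig[:max_axes]
    keep = nontrivial > max(tol, 1e-12)
    nontrivial = nontrivial[keep]
    if nontrivial.size == 0:
        warnings.warn("constant table: no non-trivial correspondence axis", stacklevel=2)
        inertia = np.array([])
        k = 0
    else:
        inertia = nontrivial**2 / (nontrivial**2).sum()
        k = min(n_axes, nontrivial.size)

    U = U[:, : len(nontrivial)][:, :k]
    V = Vt[: len(nontrivial), :].T[:, :k]
    sigk = nontrivial[:k]

    # sign convention: largest-|.| column loading positive per axis
    for a in range(k):
        j = np.argmax(np.abs(V[:, a]))
        if V[j, a] < 0:
            V[:, a] = -V[:, a]
            U[:, a] = -U[:, a]

    F = (U / np.sqrt(r)[:, None]) * sigk  # row principal coordinates
    G = (V / np.sqrt(c)[:, None]) * sigk  # column principal coordinates

    axes = [f"axis{i + 1}" for i in range(k)]
    row_coords = pd.DataFrame(np.nan, index=matrix.index, columns=axes)
    col_coords = pd.DataFrame(np.nan, index=matrix.columns, columns=axes)
    row_coords.loc[matrix.index[row_keep], :] = F
    col_coords.loc[matrix.columns[col_keep], :] = G
    row_mass = pd.Series(np.nan, index=matrix.index)
    col_mass = pd.Series(np.nan, index=matrix.columns)
    row_mass.loc[matrix.index[row_keep]] = r
    col_mass.loc[matrix.columns[col_keep]] = c

    return CoaResult(
        row_coords=row_coords,
        col_coords=col_coords,
        inertia_fraction=inertia,
        singular_values=nontrivial,
        axes_kept=k,
        row_mass=row_mass,
        col_mass=col_mass,
    )
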