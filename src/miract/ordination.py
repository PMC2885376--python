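"""Non-symmetric correspondence analysis via a weighted SVD engine.

Every ordination in this package is a weighted SVD of a *duality-diagram
triple*: a transformed table ``Z`` together with positive row weights (masses)
and column weights (metric).  Non-symmetric correspondence analysis (NSCA)
produces such a triple from a nonnegative genes x samples (or genes x miRNAs)
table: with correspondence matrix ``P = X / grand_total``, row masses
``rho_i = sum_j P_ij`` and column masses ``gamma_j = sum_i P_ij``, the
transformed values are

    Z_ij = c * (P_ij / rho_i - gamma_j)

i.e. the centred row profiles scaled by the number of columns ``c``, analysed
with row weights ``rho`` and uniform column weights ``1/c``.  Under this
convention the total inertia equals ``c`` times the numerator of the
Goodman-Kruskal tau of predicting columns from rows, matching the NSCA of the
ade4 lineage so that eigenvalue magnitudes are directly comparable.

The decomposition of a triple (Z, D_r, D_c) is the SVD of
``A = D_r^{1/2} Z D_c^{1/2}``: eigenvalues are squared singular values, column
axes are ``D_c``-orthonormal, and row coordinates have ``D_r``-weighted
variance equal to the eigenvalue on each axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import ExpressionMatrix, TargetCountTable

__all__ = [
    "WeightedTable",
    "Ordination",
    "nsc_transform",
    "weighted_decomposition",
    "nsc",
    "total_inertia",
    "export_ordination",
]

#: relative eigenvalue threshold below which axes are treated as null
DEFAULT_TOL = 1e-9


def as_table(table) -> tuple[np.ndarray, list[str], list[str]]:
    """Coerce an ExpressionMatrix, TargetCountTable, DataFrame or array triple
    to ``(values, row_ids, col_ids)``."""
    if isinstance(table, ExpressionMatrix):
        return table.values.astype(float), list(table.gene_ids), list(table.sample_ids)
    if isinstance(table, TargetCountTable):
        return table.counts.astype(float), list(table.gene_ids), list(table.mirna_ids)
    if isinstance(table, pd.DataFrame):
        return (
            table.values.astype(float),
            [str(i) for i in table.index],
            [str(c) for c in table.columns],
        )
    if isinstance(table, tuple) and len(table) == 3:
        values, rows, cols = table
        return np.asarray(values, dtype=float), list(rows), list(cols)
    raise TypeError(f"cannot interpret {type(table).__name__} as a table")


@dataclass
class WeightedTable:
    """A duality-diagram triple: transformed table plus row/column weights.

    For an NSC-derived table every column is row-weight centred
    (``sum_i rho_i Z_ij = 0``) and row weights sum to one.
    """

    Z: np.ndarray
    row_ids: list[str]
    col_ids: list[str]
    row_weights: np.ndarray
    col_weights: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.row_weights = np.asarray(self.row_weights, dtype=float)
        self.col_weights = np.asarray(self.col_weights, dtype=float)
        r, c = self.Z.shape
        if len(self.row_ids) != r or len(self.col_ids) != c:
            raise ValidationError("identifier lists do not match Z shape")
        if len(self.row_weights) != r or len(self.col_weights) != c:
            raise ValidationError("weight vectors do not match Z shape")
        if (self.row_weights <= 0).any() or (self.col_weights <= 0).any():
            raise ValidationError("weights must be strictly positive")
        if abs(self.row_weights.sum() - 1.0) > 1e-12 * max(1.0, r):
            raise ValidationError(
                f"row weights must sum to 1, got {self.row_weights.sum()!r}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.Z.shape


@dataclass
class Ordination:
    """Eigenvalues, axes and coordinates of a weighted decomposition.

    ``col_axes`` (c x K) are ``D_c``-orthonormal; ``row_coords`` (r x K) are
    principal coordinates with ``D_r``-weighted variance ``lambda_k`` per axis;
    ``col_coords`` are the axes scaled by ``sqrt(lambda_k)``.
    """

    eigenvalues: np.ndarray
    col_axes: np.ndarray
    row_coords: np.ndarray
    col_coords: np.ndarray
    rank: int
    source: WeightedTable

    @property
    def row_ids(self) -> list[str]:
        return self.source.row_ids

    @property
    def col_ids(self) -> list[str]:
        return self.source.col_ids


def nsc_transform(table) -> WeightedTable:
    """Centred, scaled row profiles of a nonnegative table (the NSC triple).

    Raises on zero row or column sums: a gene with no expression or a miRNA
    with no targets has no profile.
    """
    X, row_ids, col_ids = as_table(table)
    if (X < 0).any():
        raise ValidationError("NSC requires a nonnegative table")
    total = X.sum()
    if total <= 0:
        raise ValidationError("NSC requires a positive grand total")
    P = X / total
    rho = P.sum(axis=1)
    gamma = P.sum(axis=0)
    if (rho <= 0).any():
        i = int(np.argmax(rho <= 0))
        raise ValidationError(f"row {row_ids[i]!r} has zero sum")
    if (gamma <= 0).any():
        j = int(np.argmax(gamma <= 0))
        raise ValidationError(f"column {col_ids[j]!r} has zero sum")
    c = X.shape[1]
    Z = c * (P / rho[:, None] - gamma[None, :])
    return WeightedTable(Z, row_ids, col_ids, rho, np.full(c, 1.0 / c))


def total_inertia(wt: WeightedTable) -> float:
    """Weighted total variance: ``sum_i rho_i sum_j gamma_j Z_ij**2``."""
    return float(
        np.einsum("i,ij,j->", wt.row_weights, wt.Z**2, wt.col_weights)
    )


def _orient_axes(axes: np.ndarray, *coupled: np.ndarray) -> None:
    """Flip each axis (in place, together with coupled matrices) so the
    largest-|loading| entry is positive.  Stabilises signs across platforms."""
    for k in range(axes.shape[1]):
        col = axes[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            axes[:, k] = -col
            for other in coupled:
                other[:, k] = -other[:, k]


def weighted_decomposition(
    wt: WeightedTable, n_axes: int | None = None, tol: float = DEFAULT_TOL
) -> Ordination:
    """Generalized SVD of the triple (Z, D_r, D_c).

    Computes the thin SVD of ``A = D_r^{1/2} Z D_c^{1/2}`` (evaluated through
    the smaller dimension); eigenvalues are the squared singular values, axes
    with ``lambda_k < tol * lambda_1`` are dropped, and at most *n_axes* axes
    are retained.  An all-zero table yields a valid rank-0 result.
    """
    r, c = wt.shape
    if n_axes is None:
        n_axes = min(r, c)
    if not 1 <= n_axes <= min(r, c):
        raise ValidationError(f"n_axes must be in [1, {min(r, c)}], got {n_axes}")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    sr = np.sqrt(wt.row_weights)
    sc = np.sqrt(wt.col_weights)
    A = sr[:, None] * wt.Z * sc[None, :]
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    lam = S**2
    if lam.size == 0 or lam[0] <= 0:
        keep = 0
    else:
        keep = int(np.sum(lam >= tol * lam[0]))
    keep = min(keep, n_axes)
    lam = lam[:keep]
    axes = Vt[:keep].T / sc[:, None]          # D_c-orthonormal axes
    row_coords = (wt.Z * wt.col_weights[None, :]) @ axes
    _orient_axes(axes, row_coords)
    col_coords = axes * np.sqrt(lam)[None, :]
    return Ordination(lam, axes, row_coords, col_coords, keep, wt)


def nsc(table, n_axes: int | None = None, tol: float = DEFAULT_TOL) -> Ordination:
    """Non-symmetric correspondence analysis: transform then decompose."""
    return weighted_decomposition(nsc_transform(table), n_axes=n_axes, tol=tol)


def export_ordination(ord_: Ordination, out_dir: str | Path) -> None:
    """Write eigenvalues.tsv, row_coords.tsv and col_coords.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axes = [f"Axis{k + 1}" for k in range(ord_.rank)]
    pd.DataFrame(
        {"axis": axes, "eigenvalue": ord_.eigenvalues}
    ).to_csv(out / "eigenvalues.tsv", sep="\t", index=False)
    pd.DataFrame(ord_.row_coords, index=ord_.row_ids, columns=axes).rename_axis(
        "id"
    ).to_csv(out / "row_coords.tsv", sep="\t")
    pd.DataFrame(ord_.col_coords, index=ord_.col_ids, columns=axes).rename_axis(
        "id"
    ).to_csv(out / "col_coords.tsv", sep="\t")
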