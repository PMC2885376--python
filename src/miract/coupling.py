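"""Couple two tables sharing genes as rows: co-inertia analysis, optionally
supervised through between-group condensation of the sample side.

Co-inertia analysis (CIA) takes two duality-diagram triples with identical
rows (genes) and row weights and finds pairs of axes — one in each column
space — whose projected row coordinates are maximally covariant.  It is the
SVD of the weighted cross-product ``W = Z_X^T D_r Z_Y`` under the two column
metrics.  The global association between the tables is summarised by the RV
coefficient in [0, 1] (1 for self-coupling).

Supervision follows the between-group analysis (BGA) idea: the sample-side
table is condensed to group centroids (weighted means of its columns) and
centred by the grand centroid, so that k groups leave at most k-1 axes, before
coupling to the miRNA table.  With two groups this yields a single axis that
best discriminates them, and a single ranked vector of miRNA coordinates.

Because miRNAs down-regulate their targets, the miRNAs *active* in the target
group sit at the opposite end of the coupled axis from that group: the genes
they suppress are the ones up in the *other* group.  Orientation is fixed so
the target group's coordinate is positive; active-miRNA candidates are then
the most negative miRNA coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .ordination import as_table, nsc_transform, total_inertia, WeightedTable
from .tables import (
    AlignedPair,
    ExpressionMatrix,
    GroupAssignment,
    TargetCountTable,
    align_tables,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CoinertiaResult",
    "SupervisedResult",
    "impose_row_weights",
    "between_group_condense",
    "coinertia",
    "rv_coefficient",
    "unsupervised_cia",
    "supervised_cia",
    "export_coinertia",
]


@dataclass
class CoinertiaResult:
    """Paired axes of maximal covariance between two coupled tables.

    ``singular_covariances[k]`` is the covariance achieved by axis pair k
    (its square is the squared covariance the pair maximises).  ``axes_X`` /
    ``axes_Y`` are D_c-orthonormal loadings for the columns of each table
    (samples or groups for X, miRNAs for Y); ``display_*`` are the same axes
    scaled by sqrt(s_k) for plotting; ``gene_coords_*`` project the shared
    genes into each table's space.
    """

    singular_covariances: np.ndarray
    axes_X: np.ndarray
    axes_Y: np.ndarray
    display_X: np.ndarray
    display_Y: np.ndarray
    gene_coords_X: np.ndarray
    gene_coords_Y: np.ndarray
    rv: float
    n_axes: int
    row_ids: list[str]
    col_ids_X: list[str]
    col_ids_Y: list[str]


@dataclass
class SupervisedResult:
    """One-axis supervised coupling: group and miRNA coordinates on axis 1.

    Oriented so the target group's coordinate is strictly positive; miRNAs
    opposite that group (most negative coordinates) are the activity
    candidates.
    """

    coinertia: CoinertiaResult
    target_group: str
    group_coords: pd.Series
    mirna_coords: pd.Series
    program: str


def impose_row_weights(raw_table, weights: np.ndarray) -> WeightedTable:
    """NSC transform of a table under externally imposed row weights.

    Row profiles are computed from the table's own masses; the column
    reference profile is then recomputed as the *imposed*-weight average of
    the row profiles, so columns stay centred under the shared metric —
    the requirement for coupling two tables over the same genes.
    """
    X, row_ids, col_ids = as_table(raw_table)
    d = np.asarray(weights, dtype=float)
    if len(d) != X.shape[0]:
        raise ValidationError(
            f"weight vector length {len(d)} does not match {X.shape[0]} rows"
        )
    if (d <= 0).any():
        raise ValidationError("imposed row weights must be strictly positive")
    if abs(d.sum() - 1.0) > 1e-10:
        raise ValidationError("imposed row weights must sum to 1")
    if (X < 0).any():
        raise ValidationError("NSC requires a nonnegative table")
    row_sums = X.sum(axis=1)
    if (row_sums <= 0).any():
        i = int(np.argmax(row_sums <= 0))
        raise ValidationError(f"row {row_ids[i]!r} has zero sum")
    q = X / row_sums[:, None]            # row profiles from the table's own masses
    gamma = d @ q                        # reference profile under imposed weights
    c = X.shape[1]
    Z = c * (q - gamma[None, :])
    return WeightedTable(Z, row_ids, col_ids, d, np.full(c, 1.0 / c))


def between_group_condense(wt: WeightedTable, groups: GroupAssignment) -> WeightedTable:
    """Condense sample columns to group centroids (the BGA step).

    Each group column is the column-weighted mean of its samples' columns; the
    condensed table is then centred by the weight-averaged grand centroid, so
    k groups leave at most k-1 non-null axes.  Group weights are the summed
    sample column weights.
    """
    groups.check_covers(wt.col_ids)
    labels = list(groups.labels)
    for lab in labels:
        if not any(groups.assignment[s] == lab for s in wt.col_ids):
            raise ValidationError(f"group {lab!r} contains no column of the table")
    B = np.empty((wt.Z.shape[0], len(labels)))
    w = np.empty(len(labels))
    col_pos = {s: j for j, s in enumerate(wt.col_ids)}
    for g, lab in enumerate(labels):
        members = [col_pos[s] for s in wt.col_ids if groups.assignment[s] == lab]
        if not members:
            raise ValidationError(f"group {lab!r} is empty")
        gw = wt.col_weights[members]
        w[g] = gw.sum()
        B[:, g] = (wt.Z[:, members] * gw[None, :]).sum(axis=1) / w[g]
    centroid = (B * w[None, :]).sum(axis=1) / w.sum()
    B = B - centroid[:, None]
    return WeightedTable(B, list(wt.row_ids), labels, wt.row_weights, w)


def _check_shared_rows(tabX: WeightedTable, tabY: WeightedTable) -> None:
    if tabX.row_ids != tabY.row_ids:
        for a, b in zip(tabX.row_ids, tabY.row_ids):
            if a != b:
                raise ValidationError(f"row id mismatch: {a!r} vs {b!r}")
        raise ValidationError(
            f"row counts differ: {len(tabX.row_ids)} vs {len(tabY.row_ids)}"
        )
    diff = np.abs(tabX.row_weights - tabY.row_weights)
    if diff.max() > 1e-10:
        i = int(np.argmax(diff))
        raise ValidationError(
            f"row weight mismatch at {tabX.row_ids[i]!r}: "
            f"{tabX.row_weights[i]!r} vs {tabY.row_weights[i]!r}"
        )


def _cross_spectrum_norms(tabX: WeightedTable, tabY: WeightedTable):
    """Scaled cross-product, its SVD and the two per-table spectrum norms."""
    scx = np.sqrt(tabX.col_weights)
    scy = np.sqrt(tabY.col_weights)
    W = tabX.Z.T @ (tabX.row_weights[:, None] * tabY.Z)
    M = scx[:, None] * W * scy[None, :]
    U, S, Vt = np.linalg.svd(M, full_matrices=False)

    def spectrum_sq(t: WeightedTable, sc: np.ndarray) -> float:
        K = sc[:, None] * (t.Z.T @ (t.row_weights[:, None] * t.Z)) * sc[None, :]
        return float((K**2).sum())

    return U, S, Vt, spectrum_sq(tabX, scx), spectrum_sq(tabY, scy)


def coinertia(
    tabX: WeightedTable, tabY: WeightedTable, n_axes: int | None = None,
    tol: float = 1e-9,
) -> CoinertiaResult:
    """Co-inertia analysis of two triples sharing rows and row weights."""
    _check_shared_rows(tabX, tabY)
    cx, cy = tabX.Z.shape[1], tabY.Z.shape[1]
    if n_axes is None:
        n_axes = min(cx, cy)
    if not 1 <= n_axes <= min(cx, cy):
        raise ValidationError(f"n_axes must be in [1, {min(cx, cy)}], got {n_axes}")
    U, S, Vt, normX_sq, normY_sq = _cross_spectrum_norms(tabX, tabY)
    if normX_sq <= 0 or normY_sq <= 0:
        raise ValidationError("cannot couple a table with zero total inertia")
    rv = float((S**2).sum() / np.sqrt(normX_sq * normY_sq))

    if S.size == 0 or S[0] <= 0:
        keep = 0
    else:
        keep = min(int(np.sum(S >= tol * S[0])), n_axes)
    S = S[:keep]
    axes_X = U[:, :keep] / np.sqrt(tabX.col_weights)[:, None]
    axes_Y = Vt[:keep].T / np.sqrt(tabY.col_weights)[:, None]
    # stabilise signs: flip pairs together so covariances are preserved
    for k in range(keep):
        col = axes_X[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            axes_X[:, k] = -axes_X[:, k]
            axes_Y[:, k] = -axes_Y[:, k]
    root_s = np.sqrt(S)[None, :]
    gene_coords_X = (tabX.Z * tabX.col_weights[None, :]) @ axes_X
    gene_coords_Y = (tabY.Z * tabY.col_weights[None, :]) @ axes_Y
    return CoinertiaResult(
        singular_covariances=S,
        axes_X=axes_X,
        axes_Y=axes_Y,
        display_X=axes_X * root_s,
        display_Y=axes_Y * root_s,
        gene_coords_X=gene_coords_X,
        gene_coords_Y=gene_coords_Y,
        rv=rv,
        n_axes=keep,
        row_ids=list(tabX.row_ids),
        col_ids_X=list(tabX.col_ids),
        col_ids_Y=list(tabY.col_ids),
    )


def rv_coefficient(tabX: WeightedTable, tabY: WeightedTable) -> float:
    """Global association between two coupled tables, in [0, 1]."""
    _check_shared_rows(tabX, tabY)
    _, S, _, normX_sq, normY_sq = _cross_spectrum_norms(tabX, tabY)
    if normX_sq <= 0 or normY_sq <= 0:
        raise ValidationError("RV undefined for a table with zero total inertia")
    return float((S**2).sum() / np.sqrt(normX_sq * normY_sq))


def _prepare_pair(
    expr: ExpressionMatrix,
    targets: TargetCountTable,
    row_weight_mode: str,
) -> tuple[AlignedPair, WeightedTable, WeightedTable]:
    """Align, NSC-transform the expression side and impose shared row weights
    on the target side."""
    pair = align_tables(expr, targets)
    if row_weight_mode == "expression":
        wt_expr = nsc_transform(pair.expression)
        d = wt_expr.row_weights
    elif row_weight_mode == "uniform":
        g = pair.n_genes
        d = np.full(g, 1.0 / g)
        wt_expr = impose_row_weights(pair.expression, d)
    else:
        raise ValidationError(
            f"row_weight_mode must be 'expression' or 'uniform', got {row_weight_mode!r}"
        )
    wt_targets = impose_row_weights(pair.targets, d)
    return pair, wt_expr, wt_targets


def unsupervised_cia(
    expr: ExpressionMatrix,
    targets: TargetCountTable,
    n_axes: int | None = None,
    row_weight_mode: str = "expression",
) -> CoinertiaResult:
    """Exploratory coupling of expression and target tables.

    ``display_X`` holds the sample points and ``display_Y`` the miRNA points
    of the usual two-panel ordination plot; miRNAs opposite a sample cluster
    (through the origin) are candidates for activity in those samples.
    """
    _, wt_expr, wt_targets = _prepare_pair(expr, targets, row_weight_mode)
    res = coinertia(wt_expr, wt_targets, n_axes=n_axes)
    logger.info(
        "unsupervised CIA %s: %d genes, rv=%.4f, first covariance %.4g",
        targets.source_label, len(res.row_ids), res.rv,
        res.singular_covariances[0] if res.n_axes else 0.0,
    )
    return res


def supervised_cia(
    expr: ExpressionMatrix,
    targets: TargetCountTable,
    groups: GroupAssignment,
    target_group: str,
    row_weight_mode: str = "expression",
) -> SupervisedResult:
    """Between-group supervised coupling yielding a ranked miRNA axis.

    The expression triple is condensed to group centroids before coupling;
    with two groups exactly one non-null axis remains.  Axis 1 is oriented so
    *target_group* projects positively; miRNAs active in that group are
    expected at the negative end.
    """
    if target_group not in groups.labels:
        raise ValidationError(
            f"target group {target_group!r} not among groups {groups.labels}"
        )
    _, wt_expr, wt_targets = _prepare_pair(expr, targets, row_weight_mode)
    groups.check_covers(wt_expr.col_ids)
    condensed = between_group_condense(wt_expr, groups)
    if len(condensed.col_ids) < 2:
        raise ValidationError("supervised analysis needs at least 2 groups")
    n_axes = len(condensed.col_ids) - 1
    res = None
    if total_inertia(condensed) > 1e-300:
        res = coinertia(condensed, wt_targets, n_axes=n_axes)
    if res is None or res.n_axes == 0:
        logger.warning(
            "group centroids are identical: supervised axis is degenerate (s1=0)"
        )
        degenerate = CoinertiaResult(
            singular_covariances=np.zeros(1),
            axes_X=np.zeros((len(condensed.col_ids), 1)),
            axes_Y=np.zeros((len(wt_targets.col_ids), 1)),
            display_X=np.zeros((len(condensed.col_ids), 1)),
            display_Y=np.zeros((len(wt_targets.col_ids), 1)),
            gene_coords_X=np.zeros((len(condensed.row_ids), 1)),
            gene_coords_Y=np.zeros((len(wt_targets.row_ids), 1)),
            rv=0.0,
            n_axes=0,
            row_ids=list(condensed.row_ids),
            col_ids_X=list(condensed.col_ids),
            col_ids_Y=list(wt_targets.col_ids),
        )
        return SupervisedResult(
            coinertia=degenerate,
            target_group=target_group,
            group_coords=pd.Series(
                np.zeros(len(condensed.col_ids)), index=condensed.col_ids
            ),
            mirna_coords=pd.Series(
                np.zeros(len(wt_targets.col_ids)), index=wt_targets.col_ids
            ),
            program=targets.source_label,
        )
    gpos = condensed.col_ids.index(target_group)
    if res.axes_X[gpos, 0] < 0:
        for mat in (res.axes_X, res.display_X, res.gene_coords_X,
                    res.axes_Y, res.display_Y, res.gene_coords_Y):
            mat[:, 0] = -mat[:, 0]
    if res.axes_X[gpos, 0] == 0:
        logger.warning(
            "target group %r projects exactly at the origin on axis 1", target_group
        )
    group_coords = pd.Series(res.axes_X[:, 0], index=res.col_ids_X)
    mirna_coords = pd.Series(res.axes_Y[:, 0], index=res.col_ids_Y)
    logger.info(
        "supervised CIA %s vs %r: s1=%.4g, rv=%.4f",
        targets.source_label, target_group,
        res.singular_covariances[0], res.rv,
    )
    return SupervisedResult(
        coinertia=res,
        target_group=target_group,
        group_coords=group_coords,
        mirna_coords=mirna_coords,
        program=targets.source_label,
    )


def export_coinertia(res: CoinertiaResult, out_dir: str | Path,
                     x_name: str = "samples") -> None:
    """Write the coordinate and summary TSVs for one coupling."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    axes = [f"Axis{k + 1}" for k in range(res.n_axes)]
    s = res.singular_covariances
    total = float((s**2).sum()) or 1.0
    pd.DataFrame(
        {"axis": axes, "s": s, "s_squared": s**2, "fraction": s**2 / total}
    ).to_csv(out / "covariances.tsv", sep="\t", index=False)
    pd.DataFrame(res.display_X, index=res.col_ids_X, columns=axes).rename_axis(
        "id").to_csv(out / f"{x_name}_coords.tsv", sep="\t")
    pd.DataFrame(res.display_Y, index=res.col_ids_Y, columns=axes).rename_axis(
        "id").to_csv(out / "mirna_coords.tsv", sep="\t")
    pd.DataFrame(res.gene_coords_X, index=res.row_ids, columns=axes).rename_axis(
        "id").to_csv(out / "gene_coords_X.tsv", sep="\t")
    pd.DataFrame(res.gene_coords_Y, index=res.row_ids, columns=axes).rename_axis(
        "id").to_csv(out / "gene_coords_Y.tsv", sep="\t")
    pd.DataFrame(
        {
            "key": ["rv", "total_squared_covariance", "n_axes"],
            "value": [res.rv, total if res.n_axes else 0.0, res.n_axes],
        }
    ).to_csv(out / "summary.tsv", sep="\t", index=False)
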