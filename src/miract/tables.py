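"""Input tables: expression matrices, target-prediction records and their alignment.

The analysis couples two tables over a shared set of genes: a genes x samples
expression matrix (nonnegative, typically log2 intensities) and a genes x miRNAs
table of predicted target-site counts built from the long-format output of a
target-prediction program (TargetScan, PicTar, miRanda, a curated database such
as miRecords, or a synthetic stand-in).  This module reads and validates both,
collapses probe-level matrices to gene level, and restricts the pair to the
genes present in both tables.

All file formats are plain UTF-8 TSV:

* expression matrix — header ``gene_id<TAB>sample...``, one gene per row;
* target records    — 2-3 columns ``mirna_id<TAB>gene_id[<TAB>site_count]``,
  ``#`` comment lines skipped, a missing count meaning one site;
* probe map         — 2 columns ``probe_id<TAB>gene_id``, multi-mapping probes
  occupying several lines;
* group file        — 2 columns ``sample_id<TAB>group``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "TargetRecord",
    "TargetCountTable",
    "GroupAssignment",
    "AlignedPair",
    "read_expression_matrix",
    "write_expression_matrix",
    "collapse_probes",
    "read_probe_map",
    "read_target_records",
    "write_target_records",
    "build_target_table",
    "read_group_assignment",
    "write_group_assignment",
    "align_tables",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Nonnegative genes x samples expression table.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]`` on the input scale (typically log2 intensity after the
    caller's own normalisation; no normalisation is done here).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()

    def validate(self) -> None:
        g, n = self.values.shape
        if g < 2 or n < 2:
            raise ValidationError(
                f"expression matrix must be at least 2x2, got {g}x{n}"
            )
        if len(self.gene_ids) != g or len(self.sample_ids) != n:
            raise ValidationError("identifier lists do not match matrix shape")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value {self.values[i, j]} at gene "
                f"{self.gene_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )
        row_sums = self.values.sum(axis=1)
        if (row_sums <= 0).any():
            i = int(np.argmax(row_sums <= 0))
            raise ValidationError(
                f"gene {self.gene_ids[i]!r} has zero total expression"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )


@dataclass(frozen=True)
class TargetRecord:
    """One predicted miRNA-gene interaction with its number of predicted sites."""

    mirna_id: str
    gene_id: str
    site_count: int = 1

    def __post_init__(self) -> None:
        if self.site_count < 1:
            raise ValidationError(
                f"site_count must be >= 1, got {self.site_count} for "
                f"({self.mirna_id}, {self.gene_id})"
            )


@dataclass
class TargetCountTable:
    """Genes x miRNAs table of predicted target-site counts for one program."""

    counts: np.ndarray
    gene_ids: list[str]
    mirna_ids: list[str]
    source_label: str

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.mirna_ids = [str(m) for m in self.mirna_ids]
        self.validate()

    def validate(self) -> None:
        g, m = self.counts.shape
        if len(self.gene_ids) != g or len(self.mirna_ids) != m:
            raise ValidationError("identifier lists do not match count shape")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.mirna_ids, "miRNA")
        if (self.counts < 0).any():
            raise ValidationError("target counts must be nonnegative")
        if (self.counts.sum(axis=1) < 1).any():
            i = int(np.argmax(self.counts.sum(axis=1) < 1))
            raise ValidationError(
                f"gene {self.gene_ids[i]!r} has no predicted sites"
            )
        if (self.counts.sum(axis=0) < 1).any():
            j = int(np.argmax(self.counts.sum(axis=0) < 1))
            raise ValidationError(
                f"miRNA {self.mirna_ids[j]!r} has no predicted targets"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.gene_ids, columns=self.mirna_ids
        )


@dataclass
class GroupAssignment:
    """Mapping from sample id to group label, with a stable label order."""

    assignment: dict[str, str]
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            seen: list[str] = []
            for lab in self.assignment.values():
                if lab not in seen:
                    seen.append(lab)
            self.labels = seen
        missing = set(self.assignment.values()) - set(self.labels)
        if missing:
            raise ValidationError(f"labels {sorted(missing)} missing from label order")

    def group_of(self, sample_id: str) -> str:
        try:
            return self.assignment[sample_id]
        except KeyError:
            raise ValidationError(f"sample {sample_id!r} has no group assignment")

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.assignment.items() if g == label]

    def check_covers(self, sample_ids: Iterable[str]) -> None:
        for s in sample_ids:
            self.group_of(s)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class AlignedPair:
    """An expression matrix and a target table restricted to a shared gene set.

    Gene order is identical in both members and follows the expression matrix.
    """

    expression: ExpressionMatrix
    targets: TargetCountTable

    def __post_init__(self) -> None:
        if self.expression.gene_ids != self.targets.gene_ids:
            raise ValidationError("aligned pair members disagree on gene order")

    @property
    def n_genes(self) -> int:
        return len(self.expression.gene_ids)


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression_matrix(path: str | Path, allow_shift: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (header of sample ids, first column gene ids).

    Negative entries are rejected unless *allow_shift* is set, in which case the
    global minimum is subtracted from every entry (two-colour log intensities
    can dip below zero) and a warning is logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene identifier {dup!r} in {path}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample identifier {dup!r} in {path}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        i, j = np.argwhere(bad.values)[0]
        raise ValidationError(
            f"non-numeric cell {df.iat[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} in {path}"
        )
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().values)[0]
        raise ValidationError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r} in {path}"
        )
    values = numeric.values.astype(float)
    if (values < 0).any():
        if not allow_shift:
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative expression value {values[i, j]} at gene "
                f"{df.index[i]!r}, sample {df.columns[j]!r}; "
                "pass allow_shift to shift the matrix to a zero minimum"
            )
        shift = values.min()
        values = values - shift
        logger.warning(
            "expression matrix contained negatives; shifted all entries by %g",
            -shift,
        )
    return ExpressionMatrix(values, list(df.index), list(df.columns))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_probe_map(path: str | Path) -> list[tuple[str, str]]:
    """Read a 2-column probe_id -> gene_id map; multi-mapping probes repeat."""
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"probe map line {lineno} has {len(parts)} columns, expected 2"
                )
            pairs.append((parts[0], parts[1]))
    return pairs


def collapse_probes(
    probe_matrix: ExpressionMatrix, probe_map: Sequence[tuple[str, str]]
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to gene level.

    Probes mapping to more than one distinct gene are discarded; the rows of the
    remaining probes for a gene are averaged (unweighted arithmetic mean per
    sample).  Probes absent from the map are dropped (their count is logged).
    Genes appear in order of first appearance among surviving probes.
    """
    gene_sets: dict[str, set[str]] = {}
    for probe, gene in probe_map:
        gene_sets.setdefault(probe, set()).add(gene)
    multi = {p for p, gs in gene_sets.items() if len(gs) > 1}
    if multi:
        logger.info("dropped %d probes mapping to multiple genes", len(multi))

    unmapped = 0
    gene_rows: dict[str, list[int]] = {}
    gene_order: list[str] = []
    for i, probe in enumerate(probe_matrix.gene_ids):
        if probe not in gene_sets:
            unmapped += 1
            continue
        if probe in multi:
            continue
        (gene,) = gene_sets[probe]
        if gene not in gene_rows:
            gene_rows[gene] = []
            gene_order.append(gene)
        gene_rows[gene].append(i)
    if unmapped:
        logger.info("dropped %d probes absent from the probe map", unmapped)
    if not gene_order:
        raise ValidationError("no probe survived the probe map filter")
    values = np.vstack(
        [probe_matrix.values[gene_rows[g]].mean(axis=0) for g in gene_order]
    )
    return ExpressionMatrix(values, gene_order, list(probe_matrix.sample_ids))


def read_target_records(path: str | Path) -> list[TargetRecord]:
    """Read long-format target predictions (mirna_id, gene_id[, site_count])."""
    records: list[TargetRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValidationError(
                    f"line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            if len(parts) == 2:
                count = 1
            else:
                try:
                    count = int(parts[2])
                except ValueError:
                    raise ValidationError(
                        f"line {lineno}: site_count {parts[2]!r} is not an integer"
                    ) from None
            if count < 1:
                raise ValidationError(f"line {lineno}: site_count {count} < 1")
            records.append(TargetRecord(parts[0], parts[1], count))
    return records


def write_target_records(table: TargetCountTable, path: str | Path) -> None:
    """Write a count table back to the long 3-column record format."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# mirna_id\tgene_id\tsite_count\n")
        for i, gene in enumerate(table.gene_ids):
            for j, mirna in enumerate(table.mirna_ids):
                c = table.counts[i, j]
                if c > 0:
                    fh.write(f"{mirna}\t{gene}\t{c}\n")


def build_target_table(
    records: Sequence[TargetRecord],
    source_label: str,
    binarize: bool = False,
    alias_map: Mapping[str, str] | None = None,
) -> TargetCountTable:
    """Build the genes x miRNAs frequency table of predicted site counts.

    Counts are summed over duplicate (gene, miRNA) pairs; with *binarize* every
    nonzero cell is reduced to 1 (presence/absence instead of site counts).
    *alias_map* optionally renames miRNA ids before aggregation, e.g. to merge
    family motifs across programs; no merging happens by default.
    """
    if not records:
        raise ValidationError("cannot build a target table from zero records")
    gene_index: dict[str, int] = {}
    mirna_index: dict[str, int] = {}
    triples: list[tuple[int, int, int]] = []
    for rec in records:
        mid = alias_map.get(rec.mirna_id, rec.mirna_id) if alias_map else rec.mirna_id
        gi = gene_index.setdefault(rec.gene_id, len(gene_index))
        mj = mirna_index.setdefault(mid, len(mirna_index))
        triples.append((gi, mj, rec.site_count))
    counts = np.zeros((len(gene_index), len(mirna_index)), dtype=int)
    for gi, mj, c in triples:
        counts[gi, mj] += c
    if binarize:
        counts = (counts > 0).astype(int)
    return TargetCountTable(
        counts, list(gene_index), list(mirna_index), source_label
    )


def read_group_assignment(path: str | Path) -> GroupAssignment:
    """Read a 2-column sample_id -> group TSV."""
    assignment: dict[str, str] = {}
    labels: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"group file line {lineno} has {len(parts)} columns, expected 2"
                )
            sample, group = parts
            if sample in assignment:
                raise ValidationError(
                    f"group file line {lineno}: duplicate sample {sample!r}"
                )
            assignment[sample] = group
            if group not in labels:
                labels.append(group)
    if not assignment:
        raise ValidationError(f"group file {path} is empty")
    return GroupAssignment(assignment, labels)


def write_group_assignment(groups: GroupAssignment, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, group in groups.assignment.items():
            fh.write(f"{sample}\t{group}\n")


def align_tables(expr: ExpressionMatrix, targets: TargetCountTable) -> AlignedPair:
    """Restrict both tables to the genes present in both, in expression order.

    miRNA columns whose count sum drops to zero on the shared gene set are
    removed (with a logged warning): a program's predictions for a miRNA may
    lie entirely outside the measured gene set.
    """
    target_set = set(targets.gene_ids)
    shared = [g for g in expr.gene_ids if g in target_set]
    if len(shared) < 3:
        raise ValidationError(
            f"only {len(shared)} genes shared between expression matrix and "
            f"target table {targets.source_label!r}; need at least 3"
        )
    logger.info(
        "aligned %s: %d shared genes (expression %d, targets %d)",
        targets.source_label, len(shared), len(expr.gene_ids), len(targets.gene_ids),
    )
    expr_rows = {g: i for i, g in enumerate(expr.gene_ids)}
    tgt_rows = {g: i for i, g in enumerate(targets.gene_ids)}
    expr_sub = ExpressionMatrix(
        expr.values[[expr_rows[g] for g in shared]], shared, list(expr.sample_ids)
    )
    counts = targets.counts[[tgt_rows[g] for g in shared]]
    col_sums = counts.sum(axis=0)
    keep = col_sums >= 1
    if not keep.all():
        dropped = [m for m, k in zip(targets.mirna_ids, keep) if not k]
        logger.warning(
            "dropped %d miRNA columns with no targets in the shared gene set: %s",
            len(dropped), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    tgt_sub = TargetCountTable(
        counts[:, keep],
        shared,
        [m for m, k in zip(targets.mirna_ids, keep) if k],
        targets.source_label,
    )
    return AlignedPair(expr_sub, tgt_sub)
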