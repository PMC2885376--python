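"""Paired expression / target-count simulation with a planted activity signal.

The generator emulates the mechanism the whole pipeline is built to detect:
miRNA-directed mRNA degradation.  Target-site counts are drawn per
(gene, miRNA) cell; a chosen subset of miRNAs is declared *active* in group A,
and every gene's expression in group-A samples is lowered by ``delta`` per
predicted site it carries for an active miRNA (a linear dose-response, the
simplest mechanism consistent with degradation).  Expression lives on an
RMA-like log2 scale.  Disagreement between prediction programs is emulated by
random toggling of target-table cells (`perturb_target_table`).

All randomness flows from a single seed through named `numpy` child streams
(spawned in a fixed, documented order), so identical configurations are
bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .tables import ExpressionMatrix, GroupAssignment, TargetCountTable

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_dataset",
           "perturb_target_table"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the two-group planted-signal simulation.

    delta is the per-site log2 down-regulation applied to group-A samples for
    sites of active miRNAs; sigma is the per-measurement residual noise SD;
    p_target and lambda_sites control the sparsity and magnitude of the
    site-count table (a cell is nonzero with probability p_target, and then
    carries ``1 + Poisson(lambda_sites - 1)`` sites).
    """

    g: int = 500
    n_per_group: int = 6
    m: int = 30
    n_active: int = 3
    lambda_sites: float = 1.5
    p_target: float = 0.2
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    delta: float = 0.5
    sigma: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.g, self.n_per_group, self.m, self.n_active) < 1:
            raise ValidationError("g, n_per_group, m and n_active must be >= 1")
        if self.n_active > self.m:
            raise ValidationError(
                f"n_active ({self.n_active}) cannot exceed m ({self.m})"
            )
        if self.delta < 0:
            raise ValidationError("delta must be >= 0")
        if self.sigma <= 0:
            raise ValidationError("sigma must be > 0")
        if not 0 < self.p_target <= 1:
            raise ValidationError("p_target must be in (0, 1]")
        if self.lambda_sites < 1:
            raise ValidationError("lambda_sites must be >= 1")


@dataclass
class SyntheticDataset:
    """A simulated expression/targets/groups triple with its ground truth."""

    expression: ExpressionMatrix
    targets: TargetCountTable
    groups: GroupAssignment
    active_mirnas: list[str]
    config: SimulationConfig = field(repr=False, default=SimulationConfig())


def _draw_counts(rng: np.random.Generator, g: int, m: int,
                 p_target: float, lambda_sites: float) -> np.ndarray:
    hit = rng.random((g, m)) < p_target
    sites = 1 + rng.poisson(max(lambda_sites - 1.0, 0.0), size=(g, m))
    return np.where(hit, sites, 0)


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Simulate a two-group dataset with planted active miRNAs.

    Child random streams are spawned from ``cfg.seed`` in a fixed order:
    (0) target counts and zero-row/column repair, (1) gene baselines,
    (2) residual noise and zero-expression repair.  The first ``n_active``
    miRNAs are the active set.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_counts, rng_base, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(3)
    )
    gene_ids = [f"G{i + 1:04d}" for i in range(cfg.g)]
    mirna_ids = [f"miR-{j + 1:03d}" for j in range(cfg.m)]
    sample_ids = [f"A{s + 1}" for s in range(cfg.n_per_group)] + [
        f"B{s + 1}" for s in range(cfg.n_per_group)
    ]
    group_of = {s: s[0] for s in sample_ids}

    counts = _draw_counts(rng_counts, cfg.g, cfg.m, cfg.p_target, cfg.lambda_sites)
    # repair empty genes/miRNAs: redraw until the frequency-table invariants hold
    for _ in range(1000):
        zero_rows = counts.sum(axis=1) == 0
        zero_cols = counts.sum(axis=0) == 0
        if not zero_rows.any() and not zero_cols.any():
            break
        if zero_rows.any():
            counts[zero_rows] = _draw_counts(
                rng_counts, int(zero_rows.sum()), cfg.m,
                cfg.p_target, cfg.lambda_sites,
            )
        zero_cols = counts.sum(axis=0) == 0
        if zero_cols.any():
            counts[:, zero_cols] = _draw_counts(
                rng_counts, cfg.g, int(zero_cols.sum()),
                cfg.p_target, cfg.lambda_sites,
            )
    else:  # pragma: no cover - would need pathological parameters
        raise ValidationError("could not draw a valid target table")

    active = mirna_ids[: cfg.n_active]
    baseline = rng_base.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.g)
    noise = rng_noise.normal(0.0, cfg.sigma, size=(cfg.g, 2 * cfg.n_per_group))
    values = baseline[:, None] + noise
    load = counts[:, : cfg.n_active].sum(axis=1)    # active sites per gene
    values[:, : cfg.n_per_group] -= cfg.delta * load[:, None]
    values = np.clip(values, 0.0, None)
    # repair all-zero gene rows (only possible with extreme parameters)
    for _ in range(1000):
        dead = values.sum(axis=1) <= 0
        if not dead.any():
            break
        redraw = baseline[dead, None] + rng_noise.normal(
            0.0, cfg.sigma, size=(int(dead.sum()), 2 * cfg.n_per_group)
        )
        redraw[:, : cfg.n_per_group] -= cfg.delta * load[dead, None]
        values[dead] = np.clip(redraw, 0.0, None)
    else:  # pragma: no cover
        raise ValidationError("could not draw a valid expression matrix")

    expr = ExpressionMatrix(values, gene_ids, sample_ids)
    targets = TargetCountTable(counts, gene_ids, mirna_ids, "simulated")
    groups = GroupAssignment(group_of, ["A", "B"])
    return SyntheticDataset(expr, targets, groups, active, cfg)


def perturb_target_table(
    targets: TargetCountTable, flip_rate: float, seed: int
) -> TargetCountTable:
    """Emulate another prediction program by randomly toggling cells.

    Each cell is independently toggled with probability *flip_rate*
    (nonzero -> 0, zero -> 1).  Any gene row or miRNA column reduced to a zero
    sum is repaired by reverting its first toggled cell, so the frequency-table
    invariants survive.  The source label gains a ``~flip`` suffix.
    """
    if not 0 <= flip_rate < 1:
        raise ValidationError(f"flip_rate must be in [0, 1), got {flip_rate}")
    rng = np.random.default_rng(seed)
    counts = targets.counts.copy()
    toggled = rng.random(counts.shape) < flip_rate
    new = np.where(toggled, np.where(counts > 0, 0, 1), counts)

    def revert_first(indices_iter) -> None:
        for idx in indices_iter:
            new[idx] = counts[idx]
            toggled[idx] = False

    for _ in range(counts.shape[0] + counts.shape[1]):
        zero_rows = np.flatnonzero(new.sum(axis=1) == 0)
        zero_cols = np.flatnonzero(new.sum(axis=0) == 0)
        if zero_rows.size == 0 and zero_cols.size == 0:
            break
        for i in zero_rows:
            j = int(np.flatnonzero(toggled[i])[0])
            revert_first([(i, j)])
        zero_cols = np.flatnonzero(new.sum(axis=0) == 0)
        for j in zero_cols:
            i = int(np.flatnonzero(toggled[:, j])[0])
            revert_first([(i, j)])
    label = f"{targets.source_label}~flip{flip_rate:g}#{seed}"
    return TargetCountTable(new, list(targets.gene_ids), list(targets.mirna_ids), label)
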