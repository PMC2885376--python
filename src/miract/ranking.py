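"""Per-program miRNA ranking and cross-program consensus aggregation.

A supervised coupling yields one coordinate per miRNA on the discriminating
axis, oriented so the target group projects positively.  Because miRNAs
suppress their targets, the miRNAs most associated with (active in) the
target group are those at the *opposite* end of the axis — the most negative
coordinates — and rank 1 is assigned there.

Each prediction program produces its own ranked list.  Programs disagree, so
single-program ranks are noisy; the consensus rule keeps only miRNAs ranked
in the top K (default 20) by at least ``min_programs`` (default 2) programs
and scores them by the arithmetic mean of those top-K ranks (ranks beyond K,
like absences, are left blank and excluded from the mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .coupling import SupervisedResult

__all__ = ["RankedList", "ConsensusTable", "rank_mirnas", "consensus",
           "ranked_list_from_ranks", "read_ranked_list"]


@dataclass
class RankedList:
    """One program's miRNAs ordered by association with the target group.

    ``entries`` holds (mirna_id, axis-1 coordinate, rank) with rank 1 the
    most negative coordinate; ties in coordinate break by id, ascending.
    """

    program: str
    entries: list[tuple[str, float, int]]
    target_group: str

    def __post_init__(self) -> None:
        ranks = [r for _, _, r in self.entries]
        if ranks != list(range(1, len(ranks) + 1)):
            raise ValidationError("ranks must be consecutive from 1")
        coords = [c for _, c, _ in self.entries]
        if any(b < a for a, b in zip(coords, coords[1:])):
            raise ValidationError("coordinates must be non-decreasing with rank")

    def rank_of(self) -> dict[str, int]:
        return {m: r for m, _, r in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["mirna_id", "coordinate", "rank"]
        )

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# program: {self.program}\n")
            fh.write(f"# target_group: {self.target_group}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def read_ranked_list(path: str | Path) -> RankedList:
    """Read a ranked list written by :meth:`RankedList.write`."""
    program = target_group = None
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "program":
                program = val.strip()
            elif key.strip() == "target_group":
                target_group = val.strip()
    if program is None or target_group is None:
        raise ValidationError(
            f"{path} lacks the '# program:' / '# target_group:' header lines"
        )
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = [
        (str(r.mirna_id), float(r.coordinate), int(r.rank))
        for r in df.itertuples()
    ]
    return RankedList(program, entries, target_group)


def ranked_list_from_ranks(
    program: str, ranks: Mapping[str, int], target_group: str, m: int | None = None
) -> RankedList:
    """Build a RankedList from explicit rank positions (e.g. a published
    table), padding unused positions with placeholder ids.

    Useful to replay the consensus arithmetic of a printed per-program
    ranking when only some positions are known.
    """
    if m is None:
        m = max(ranks.values())
    by_rank = {r: mid for mid, r in ranks.items()}
    if len(by_rank) != len(ranks):
        raise ValidationError("duplicate rank positions")
    if max(by_rank) > m:
        raise ValidationError("rank position beyond list length")
    entries = [
        (by_rank.get(r, f"_unranked_{program}_{r}"), float(r), r)
        for r in range(1, m + 1)
    ]
    return RankedList(program, entries, target_group)


def rank_mirnas(result: SupervisedResult) -> RankedList:
    """Rank miRNAs by their axis-1 coordinate, most negative first.

    The orientation rule (target group positive) makes the most negative
    miRNA coordinates the strongest activity candidates in the target group.
    """
    if result.coinertia.n_axes < 1:
        raise ValidationError(
            "supervised axis is degenerate (identical group centroids); "
            "no ranking is possible"
        )
    coords = result.mirna_coords
    order = sorted(coords.index, key=lambda m: (coords[m], m))
    entries = [(m, float(coords[m]), r) for r, m in enumerate(order, start=1)]
    return RankedList(result.program, entries, result.target_group)


@dataclass
class ConsensusTable:
    """Cross-program merged ranks for miRNAs supported by several programs.

    ``table`` has one row per retained miRNA, one column per program (NaN
    where the miRNA is absent or ranked beyond K), plus ``average_rank`` (mean
    of the shown ranks) and ``n_programs``; sorted by average rank ascending.
    """

    table: pd.DataFrame
    K: int
    min_programs: int
    target_group: str
    programs: list[str] = field(default_factory=list)

    def format_average(self, mirna_id: str) -> str:
        """Average rank as displayed: two decimals, round-half-to-even,
        trailing zeros trimmed."""
        v = self.table.loc[mirna_id, "average_rank"]
        s = f"{v:.2f}".rstrip("0").rstrip(".")
        return s

    def write(self, path: str | Path) -> None:
        df = self.table.copy()
        for p in self.programs:
            df[p] = df[p].map(lambda r: "" if pd.isna(r) else str(int(r)))
        df["average_rank"] = df["average_rank"].map(lambda v: f"{v:.2f}")
        df.rename_axis("mirna_id").to_csv(path, sep="\t")


def consensus(
    lists: Sequence[RankedList], K: int = 20, min_programs: int = 2
) -> ConsensusTable:
    """Aggregate per-program rankings with the top-K consensus rule.

    A miRNA is retained when at least *min_programs* programs rank it within
    the top *K*; its score is the mean of exactly those ranks.  Sorting is by
    average rank ascending, ties by more supporting programs first, then id.
    """
    if len(lists) < 2:
        raise ValidationError("consensus needs at least 2 ranked lists")
    if K < 1:
        raise ValidationError("K must be >= 1")
    if min_programs < 2:
        raise ValidationError("min_programs must be >= 2")
    target = lists[0].target_group
    for rl in lists:
        if rl.target_group != target:
            raise ValidationError(
                f"ranked lists disagree on target group: {rl.target_group!r} vs {target!r}"
            )
    programs = [rl.program for rl in lists]
    if len(set(programs)) != len(programs):
        raise ValidationError("duplicate program labels among ranked lists")
    top_ranks: dict[str, dict[str, int]] = {}
    for rl in lists:
        for mirna, _, rank in rl.entries:
            if rank <= K:
                top_ranks.setdefault(mirna, {})[rl.program] = rank
    rows = []
    for mirna, prog_ranks in top_ranks.items():
        if len(prog_ranks) < min_programs:
            continue
        rows.append(
            {
                "mirna_id": mirna,
                **{p: prog_ranks.get(p, np.nan) for p in programs},
                "average_rank": float(np.mean(list(prog_ranks.values()))),
                "n_programs": len(prog_ranks),
            }
        )
    df = pd.DataFrame(
        rows, columns=["mirna_id", *programs, "average_rank", "n_programs"]
    )
    df = df.sort_values(
        by=["average_rank", "n_programs", "mirna_id"],
        ascending=[True, False, True],
        kind="mergesort",
    ).set_index("mirna_id")
    return ConsensusTable(df, K, min_programs, target, programs)
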