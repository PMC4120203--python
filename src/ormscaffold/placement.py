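"""Phase 2: greedy non-overlapping placement of scored contigs.

Three greedy placement algorithms turn the r x m score table into an ordered
scaffold.  All three first sort each contig's m mappings by ascending score
(list ``L_C``); they differ in the order contigs are processed and in how
many mappings each contig may try:

* **GPA1** — process contigs by the start fragment of their single best
  mapping, ascending; one attempt each, overlap means discard.
* **GPA2** — process contigs by ``b_C`` (their largest matched-sites count
  over all mappings) descending; try up to ``d`` entries of ``L_C``.
* **GPA3** — process contigs by best score ascending; try up to ``d``
  entries of ``L_C``.

Overlap is defined on closed fragment-index intervals: a shared boundary
fragment counts as overlap, since one map fragment can belong to at most one
contig.  All sorts are stable and ties fall back to ascending contig input
index, so placement is fully deterministic.  Placement costs O(m*r) — the
per-contig sort of m integer scores dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ormscaffold.scoring import ScoreTable


@dataclass(frozen=True)
class PlacementConfig:
    """Placement method and retry depth ``d`` (used by GPA2/GPA3)."""

    method: str = "gpa3"
    depth: int = 5

    def __post_init__(self) -> None:
        if self.method not in ("gpa1", "gpa2", "gpa3"):
            raise ValueError(f"unknown placement method {self.method!r}")
        if self.depth < 1:
            raise ValueError("depth d must be >= 1")


@dataclass(frozen=True)
class Placement:
    """One placed contig: its interval on the map and the mapping used.

    ``rank_used`` is the 1-based position in the contig's score-sorted
    mapping list ``L_C`` that was accepted (always 1 for GPA1).
    """

    contig_id: str
    start_fragment: int
    end_fragment: int
    score: float
    rank_used: int = 1
    orientation: str = "+"

    def __post_init__(self) -> None:
        if self.start_fragment > self.end_fragment:
            raise ValueError("placement start must not exceed end")


def overlaps(a: Placement, b: Placement) -> bool:
    """True iff the closed intervals [start, end] of ``a`` and ``b`` intersect."""
    return a.start_fragment <= b.end_fragment and b.start_fragment <= a.end_fragment


@dataclass
class Scaffold:
    """An ordered, pairwise non-overlapping set of contig placements."""

    placements: list[Placement]
    discarded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.placements = sorted(self.placements, key=lambda p: p.start_fragment)
        for a, b in zip(self.placements, self.placements[1:]):
            if overlaps(a, b):
                raise ValueError(
                    f"overlapping placements: {a.contig_id} and {b.contig_id}"
                )

    def __len__(self) -> int:
        return len(self.placements)

    @property
    def placed_ids(self) -> list[str]:
        return [p.contig_id for p in self.placements]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "contig_id": p.contig_id,
                    "start_fragment": p.start_fragment,
                    "end_fragment": p.end_fragment,
                    "score": p.score,
                    "rank_used": p.rank_used,
                    "orientation": p.orientation,
                }
                for p in self.placements
            ],
            columns=[
                "contig_id",
                "start_fragment",
                "end_fragment",
                "score",
                "rank_used",
                "orientation",
            ],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)
        discarded_path = Path(path).with_suffix(".discarded.txt")
        discarded_path.write_text("".join(f"{cid}\n" for cid in self.discarded))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Scaffold":
        df = pd.read_csv(path, sep="\t")
        placements = [
            Placement(
                contig_id=str(row.contig_id),
                start_fragment=int(row.start_fragment),
                end_fragment=int(row.end_fragment),
                score=float(row.score),
                rank_used=int(row.rank_used),
                orientation=str(getattr(row, "orientation", "+")),
            )
            for row in df.itertuples(index=False)
        ]
        discarded_path = Path(path).with_suffix(".discarded.txt")
        discarded = (
            discarded_path.read_text().split() if discarded_path.exists() else []
        )
        return cls(placements, discarded)

    def sequence(self, contig_seqs: dict[str, str]) -> str:
        """Gap-free concatenation of placed contig sequences in map order."""
        return "".join(contig_seqs[p.contig_id] for p in self.placements)


def _mapping_order(table: ScoreTable, i: int) -> np.ndarray:
    """L_C for contig i: 0-based start indices sorted by ascending score.

    The stable sort keeps equal-score mappings in ascending start order.
    """
    return np.argsort(table.scores[i], kind="stable")


def _record_at(table: ScoreTable, i: int, j: int, rank: int) -> Placement:
    rec = table.record(i, j + 1)
    return Placement(
        contig_id=rec.contig_id,
        start_fragment=rec.start_fragment,
        end_fragment=rec.end_fragment,
        score=rec.score,
        rank_used=rank,
        orientation=rec.orientation,
    )


def _try_place(placed: list[Placement], cand: Placement) -> bool:
    return not any(overlaps(cand, p) for p in placed)


def gpa1(table: ScoreTable) -> Scaffold:
    """Greedy placement by best-mapping start fragment, one attempt per contig."""
    _check_table(table)
    best = [int(np.argmin(table.scores[i])) for i in range(table.r)]  # first min
    order = sorted(range(table.r), key=lambda i: best[i])  # stable: ties by index
    placed: list[Placement] = []
    discarded: list[str] = []
    for i in order:
        cand = _record_at(table, i, best[i], rank=1)
        if _try_place(placed, cand):
            placed.append(cand)
        else:
            discarded.append(table.contig_ids[i])
    return Scaffold(placed, discarded)


def _gpa_with_retries(table: ScoreTable, order: list[int], depth: int) -> Scaffold:
    placed: list[Placement] = []
    discarded: list[str] = []
    for i in order:
        lc = _mapping_order(table, i)
        success = False
        for rank, j in enumerate(lc[:depth], start=1):
            cand = _record_at(table, i, int(j), rank=rank)
            if _try_place(placed, cand):
                placed.append(cand)
                success = True
                break
        if not success:
            discarded.append(table.contig_ids[i])
    return Scaffold(placed, discarded)


def gpa2(table: ScoreTable, cfg: PlacementConfig | None = None) -> Scaffold:
    """Greedy placement by largest matched-sites count, with depth-d retries."""
    _check_table(table)
    cfg = cfg or PlacementConfig(method="gpa2")
    b = table.matched.max(axis=1)
    order = sorted(range(table.r), key=lambda i: -int(b[i]))  # stable
    return _gpa_with_retries(table, order, cfg.depth)


def gpa3(table: ScoreTable, cfg: PlacementConfig | None = None) -> Scaffold:
    """Greedy placement by best (minimum) score, with depth-d retries."""
    _check_table(table)
    cfg = cfg or PlacementConfig(method="gpa3")
    best = table.scores.min(axis=1)
    order = sorted(range(table.r), key=lambda i: best[i])  # stable
    return _gpa_with_retries(table, order, cfg.depth)


def place(table: ScoreTable, cfg: PlacementConfig | None = None) -> Scaffold:
    """Dispatch to the configured placement method."""
    cfg = cfg or PlacementConfig()
    if cfg.method == "gpa1":
        return gpa1(table)
    if cfg.method == "gpa2":
        return gpa2(table, cfg)
    return gpa3(table, cfg)


def _check_table(table: ScoreTable) -> None:
    if table.r == 0 or table.m == 0:
        raise ValueError("empty score table")
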