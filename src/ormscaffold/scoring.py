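"""Phase 1: greedy size-tolerant scoring of contigs against the ORM.

For a contig with fragment sizes ``c_1..c_n`` and a map ``o_1..o_m``, one
score is computed per possible start fragment ``o_i``.  Starting from
``(c_1, o_i)`` the scorer greedily grows a contig prefix group or a map
prefix group — whichever side currently has the smaller sum — until the two
group sums agree within the group's size tolerance, records a matched site,
and recurses on the two suffixes.  The tolerance of a group is the sum of
the per-fragment tolerances sigma_j of the map fragments it spans: sizing
errors accumulate across fragments, so a merged group must be allowed the
summed uncertainty of its parts (for a single-fragment group this is just
sigma_j; with a constant sigma and no merging, plain "agreement up to
sigma").  Every non-matching
advance is a missed restriction site (MRS).  The mapping's score is

    sum over matched groups of |contig_group_sum - map_group_sum| + P * MRS

with a large user-set penalty ``P`` (default 999).  Lower is better; a
contig whose fragments equal a contiguous map slice exactly scores 0 at the
true start.  Two base rules close the walk at the map's right edge: when the
contig runs past ``o_m`` its remaining fragments are folded into the final
group matched at ``o_m`` (one miss per folded fragment), and when the contig
is exhausted mid-group the open group is closed as a match against the
current map fragment.

The per-start walk touches each contig fragment once and advances the map
pointer a bounded number of extra steps, so scoring all contigs at all
starts costs O(m*n*r) for r contigs of at most n fragments.  The inner walk
is JIT-compiled with numba when available; the same source function runs as
plain Python otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ormscaffold.digest import ContigDigest, ORMap

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit as _njit

    def _jit(func):
        return _njit(cache=True)(func)

except ImportError:  # pragma: no cover
    def _jit(func):
        return func


@dataclass(frozen=True)
class ScoringConfig:
    """Parameters of the greedy scorer.

    Attributes
    ----------
    penalty:
        P, the cost of one missed restriction site.  Must be positive and,
        for reliable placement, large relative to typical sizing errors.
        Default 999.
    default_std:
        Global size tolerance sigma in bp, used for every map fragment unless
        the :class:`~ormscaffold.digest.ORMap` carries per-fragment stds.
    """

    penalty: float = 999.0
    default_std: float = 0.0

    def __post_init__(self) -> None:
        if self.penalty <= 0:
            raise ValueError("penalty P must be positive")
        if self.default_std < 0:
            raise ValueError("default_std must be non-negative")


@dataclass(frozen=True)
class ScoreRecord:
    """One contig-vs-map mapping: where it starts, ends, and how well it fits.

    ``start_fragment``/``end_fragment`` are 1-based ORM indices.  ``score``
    stays an exact integer whenever fragment sizes and P are integers.
    """

    contig_id: str
    start_fragment: int
    end_fragment: int
    score: float
    matched_sites: int
    missed_sites: int
    orientation: str = "+"


def _walk_one(c, o, stds, start0):
    """Greedy case-machine walk for one contig and one 0-based start.

    Returns ``(diff_sum, missed, matched, end0)`` where ``diff_sum`` is the
    summed absolute group-sum difference (penalty not yet applied) and
    ``end0`` the 0-based index of the last matched map fragment.
    """
    n = c.shape[0]
    m = o.shape[0]
    p = 0
    t = start0
    cs = c[0]
    og = o[t]
    sd = stds[t]
    diff_sum = np.int64(0)
    missed = 0
    matched = 0
    end0 = start0
    last_gc = np.int64(0)
    last_go = np.int64(0)
    last_diff = np.int64(0)
    while True:
        if og - sd <= cs <= og + sd:
            d = cs - og
            if d < 0:
                d = -d
            diff_sum += d
            matched += 1
            end0 = t
            last_gc = cs
            last_go = og
            last_diff = d
            p += 1
            t += 1
            if p >= n:
                break
            if t >= m:
                # contig runs past o_m: fold the rest into the group just
                # matched there, one miss per folded fragment
                extra = np.int64(0)
                while p < n:
                    extra += c[p]
                    missed += 1
                    p += 1
                d2 = last_gc + extra - last_go
                if d2 < 0:
                    d2 = -d2
                diff_sum += d2 - last_diff
                end0 = m - 1
                break
            cs = c[p]
            og = o[t]
            sd = stds[t]
        elif cs < og - sd:
            # contig group too small: absorb the next contig fragment
            if p + 1 >= n:
                # nothing left: close the open group against o_t
                d = cs - og
                if d < 0:
                    d = -d
                diff_sum += d
                matched += 1
                end0 = t
                break
            p += 1
            missed += 1
            cs += c[p]
        else:
            # contig group too big: absorb the next map fragment
            if t + 1 >= m:
                # map exhausted: fold remaining contig fragments, match at o_m
                while p + 1 < n:
                    p += 1
                    missed += 1
                    cs += c[p]
                d = cs - og
                if d < 0:
                    d = -d
                diff_sum += d
                matched += 1
                end0 = m - 1
                break
            t += 1
            missed += 1
            og += o[t]
            sd += stds[t]
    return diff_sum, missed, matched, end0


def _walk_all(c, o, stds):
    m = o.shape[0]
    diffs = np.zeros(m, dtype=np.int64)
    missed = np.zeros(m, dtype=np.int64)
    matched = np.zeros(m, dtype=np.int64)
    ends = np.zeros(m, dtype=np.int64)
    for i in range(m):
        diffs[i], missed[i], matched[i], ends[i] = _walk_one(c, o, stds, i)
    return diffs, missed, matched, ends


_walk_one = _jit(_walk_one)
_walk_all = _jit(_walk_all)


class ScoreTable:
    """Complete r x m grid of mapping scores (one row per contig).

    Column ``j`` (0-based) of every array refers to start fragment ``j + 1``.
    """

    def __init__(
        self,
        contig_ids: list[str],
        scores: np.ndarray,
        ends: np.ndarray,
        matched: np.ndarray,
        missed: np.ndarray,
        config: ScoringConfig,
        orientations: np.ndarray | None = None,
    ) -> None:
        self.contig_ids = list(contig_ids)
        self.scores = scores
        self.ends = ends
        self.matched = matched
        self.missed = missed
        self.config = config
        # 0 = forward, 1 = reverse-complement fragment order
        self.orientations = orientations
        r, m = scores.shape
        if len(self.contig_ids) != r:
            raise ValueError("one row of scores per contig required")
        for arr in (ends, matched, missed):
            if arr.shape != (r, m):
                raise ValueError("all score-table arrays must be r x m")

    @property
    def r(self) -> int:
        return self.scores.shape[0]

    @property
    def m(self) -> int:
        return self.scores.shape[1]

    def record(self, contig_index: int, start_fragment: int) -> ScoreRecord:
        """The :class:`ScoreRecord` for one contig at one 1-based start."""
        j = start_fragment - 1
        if not 0 <= j < self.m:
            raise IndexError(f"start_fragment {start_fragment} out of range 1..{self.m}")
        orient = "+"
        if self.orientations is not None and self.orientations[contig_index, j]:
            orient = "-"
        return ScoreRecord(
            contig_id=self.contig_ids[contig_index],
            start_fragment=start_fragment,
            end_fragment=int(self.ends[contig_index, j]),
            score=_maybe_int(self.scores[contig_index, j]),
            matched_sites=int(self.matched[contig_index, j]),
            missed_sites=int(self.missed[contig_index, j]),
            orientation=orient,
        )

    def to_dataframe(self) -> pd.DataFrame:
        r, m = self.scores.shape
        return pd.DataFrame(
            {
                "contig_id": np.repeat(self.contig_ids, m),
                "start": np.tile(np.arange(1, m + 1), r),
                "end": self.ends.ravel(),
                "score": self.scores.ravel(),
                "matched_sites": self.matched.ravel(),
                "missed_sites": self.missed.ravel(),
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, config: ScoringConfig | None = None
    ) -> "ScoreTable":
        """Rebuild a table from :meth:`to_dataframe` output (contig order =
        order of first appearance; every contig needs all m starts)."""
        contig_ids = list(dict.fromkeys(df["contig_id"]))
        m = int(df["start"].max())
        r = len(contig_ids)
        if len(df) != r * m:
            raise ValueError("incomplete score table: need r x m rows")
        idx = {cid: i for i, cid in enumerate(contig_ids)}
        scores = np.empty((r, m), dtype=np.float64)
        ends = np.empty((r, m), dtype=np.int64)
        matched = np.empty((r, m), dtype=np.int64)
        missed = np.empty((r, m), dtype=np.int64)
        rows = df["contig_id"].map(idx).to_numpy()
        cols = df["start"].to_numpy() - 1
        scores[rows, cols] = df["score"].to_numpy()
        ends[rows, cols] = df["end"].to_numpy()
        matched[rows, cols] = df["matched_sites"].to_numpy()
        missed[rows, cols] = df["missed_sites"].to_numpy()
        return cls(contig_ids, scores, ends, matched, missed, config or ScoringConfig())

    @classmethod
    def from_tsv(
        cls, path: str | Path, config: ScoringConfig | None = None
    ) -> "ScoreTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"), config)


def _maybe_int(x: float) -> float:
    return int(x) if float(x).is_integer() else float(x)


def _resolve_stds(orm: ORMap, cfg: ScoringConfig) -> np.ndarray:
    if orm.stds is not None:
        return np.ascontiguousarray(orm.stds, dtype=np.float64)
    return np.full(orm.m, float(cfg.default_std), dtype=np.float64)


def score_contig_at(
    contig: ContigDigest, orm: ORMap, start: int, cfg: ScoringConfig | None = None
) -> ScoreRecord:
    """Score one contig mapped with its first fragment at map fragment ``start``.

    ``start`` is 1-based.  See the module docstring for the recurrence.
    """
    cfg = cfg or ScoringConfig()
    if not 1 <= start <= orm.m:
        raise IndexError(f"start {start} out of range 1..{orm.m}")
    stds = _resolve_stds(orm, cfg)
    c = np.ascontiguousarray(contig.sizes, dtype=np.int64)
    o = np.ascontiguousarray(orm.sizes, dtype=np.int64)
    diff, missed, matched, end0 = _walk_one(c, o, stds, start - 1)
    return ScoreRecord(
        contig_id=contig.contig_id,
        start_fragment=start,
        end_fragment=int(end0) + 1,
        score=_maybe_int(float(diff) + cfg.penalty * int(missed)),
        matched_sites=int(matched),
        missed_sites=int(missed),
    )


def score_all(
    contigs: list[ContigDigest],
    orm: ORMap,
    cfg: ScoringConfig | None = None,
    try_reverse: bool = False,
) -> ScoreTable:
    """Score every contig at every map start fragment (the r x m table).

    With ``try_reverse=True`` each contig is additionally scored with its
    fragment order reversed (a reverse-complemented contig has the same
    fragment sizes in reverse order) and, start by start, the better-scoring
    orientation is kept.  The greedy algorithms themselves are forward-only;
    this is an optional convenience, off by default.
    """
    cfg = cfg or ScoringConfig()
    if not contigs:
        raise ValueError("empty contig list")
    o = np.ascontiguousarray(orm.sizes, dtype=np.int64)
    stds = _resolve_stds(orm, cfg)
    r, m = len(contigs), orm.m
    scores = np.empty((r, m), dtype=np.float64)
    ends = np.empty((r, m), dtype=np.int64)
    matched = np.empty((r, m), dtype=np.int64)
    missed = np.empty((r, m), dtype=np.int64)
    orients = np.zeros((r, m), dtype=np.int8) if try_reverse else None
    for i, contig in enumerate(contigs):
        c = np.ascontiguousarray(contig.sizes, dtype=np.int64)
        diffs_i, missed_i, matched_i, ends_i = _walk_all(c, o, stds)
        scores_i = diffs_i + cfg.penalty * missed_i
        if try_reverse:
            diffs_r, missed_r, matched_r, ends_r = _walk_all(c[::-1].copy(), o, stds)
            scores_r = diffs_r + cfg.penalty * missed_r
            use_rev = scores_r < scores_i  # ties keep forward
            scores_i = np.where(use_rev, scores_r, scores_i)
            missed_i = np.where(use_rev, missed_r, missed_i)
            matched_i = np.where(use_rev, matched_r, matched_i)
            ends_i = np.where(use_rev, ends_r, ends_i)
            orients[i] = use_rev.astype(np.int8)
        scores[i] = scores_i
        ends[i] = ends_i + 1
        matched[i] = matched_i
        missed[i] = missed_i
    return ScoreTable(
        [ct.contig_id for ct in contigs],
        scores,
        ends,
        matched,
        missed,
        cfg,
        orientations=orients,
    )
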