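"""Shared test utilities: a naive oracle for the greedy scorer and
hand-built score tables for placement tests."""

from __future__ import annotations

import numpy as np

from ormscaffold.scoring import ScoreTable, ScoringConfig


def naive_greedy_score(contig, orm, stds, start, penalty):
    """Exhaustive re-simulation of the greedy grouping recurrence.

    Independent of the production scorer: keeps explicit group index ranges
    and recomputes every group sum and tolerance from scratch with ``sum()``
    over slices.  Returns ``(score, matched, missed, end)`` with ``end``
    1-based.
    """
    c = [int(x) for x in contig]
    o = [int(x) for x in orm]
    sig = [float(x) for x in stds]
    n, m = len(c), len(o)
    ci, oi = 0, start - 1  # start offsets of the open group
    u, q = 1, 1  # current group lengths
    missed = 0
    groups: list[tuple[int, int, int, int]] = []
    while True:
        gc = sum(c[ci : ci + u])
        go = sum(o[oi : oi + q])
        tol = sum(sig[oi : oi + q])
        if abs(gc - go) <= tol:
            groups.append((ci, u, oi, q))
            ci, oi = ci + u, oi + q
            u = q = 1
            if ci >= n:
                break
            if oi >= m:
                # map exhausted right after a match at o_m: remaining contig
                # fragments fold into that final group, one miss each
                rem = n - ci
                missed += rem
                lci, lu, loi, lq = groups.pop()
                groups.append((lci, lu + rem, loi, lq))
                break
        elif gc < go - tol:
            if ci + u >= n:
                # contig exhausted mid-group: close against current map group
                groups.append((ci, u, oi, q))
                break
            u += 1
            missed += 1
        else:
            if oi + q >= m:
                # map exhausted mid-group: fold the rest, match at o_m
                rem = n - (ci + u)
                missed += rem
                groups.append((ci, u + rem, oi, q))
                break
            q += 1
            missed += 1
    diff = sum(
        abs(sum(c[a : a + ul]) - sum(o[b : b + ql])) for a, ul, b, ql in groups
    )
    end = groups[-1][2] + groups[-1][3]
    return diff + penalty * missed, len(groups), missed, end


def make_table(mappings, m, default_score=10_000_000.0, penalty=999.0):
    """Build a ScoreTable by hand.

    ``mappings``: one list per contig of ``(start, end, score, matched)``
    tuples (1-based starts/ends); every other start gets ``default_score``
    with matched 0.  Contig ids are C1..Cr in input order.
    """
    r = len(mappings)
    scores = np.full((r, m), default_score, dtype=np.float64)
    ends = np.tile(np.arange(1, m + 1), (r, 1)).astype(np.int64)
    matched = np.zeros((r, m), dtype=np.int64)
    missed = np.full((r, m), 99, dtype=np.int64)
    for i, maps in enumerate(mappings):
        for start, end, score, nmatch in maps:
            j = start - 1
            scores[i, j] = score
            ends[i, j] = end
            matched[i, j] = nmatch
            missed[i, j] = 0
    ids = [f"C{i + 1}" for i in range(r)]
    return ScoreTable(ids, scores, ends, matched, missed, ScoringConfig(penalty))
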