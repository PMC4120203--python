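"""Synthetic scaffolding experiments: genome -> ORM -> contigs -> errors -> truth.

The generator emulates the evaluation protocol for map-based scaffolders on
genomes where the ground truth is known: draw a uniform-random genome, digest
it in silico with a 4-bp enzyme to obtain the reference ORM, cut the genome at
randomly chosen restriction sites into ``r`` non-overlapping contigs covering
it, permute the contigs, and optionally corrupt each contig's digest by
discarding internal restriction sites with probability ``p`` (merging
neighbouring fragments) and by resizing every fragment by a uniform
multiplicative error of up to ``resize_pct`` percent.  Because breakpoints
snap to restriction sites (and avoid sites that straddle a boundary), every
error-free contig digest equals an exact contiguous slice of the ORM, the
regime in which perfect recovery is attainable.

Evaluation compares a recovered scaffold with the recorded truth: a contig is
*correctly placed* iff its assigned start fragment equals its true start
fragment, a discarded contig is a *conflict*, a placed-but-mislocated contig
a *wrong placement*, and accuracy is the percentage of contigs placed
correctly.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ormscaffold.digest import ContigDigest, Enzyme, ORMap, digest_sequence
from ormscaffold.placement import PlacementConfig, Scaffold, place
from ormscaffold.scoring import ScoreTable, ScoringConfig, score_all

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default recognition site: GATC, the classic 4-bp cutter (Sau3AI/MboI site),
#: cutting a uniform-random sequence about every 256 bp.
DEFAULT_ENZYME = Enzyme("GATC")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic experiment.

    Attributes
    ----------
    genome_length:
        Genome size in bp.
    n_contigs:
        Number r of non-overlapping contigs the genome is cut into.
    enzyme:
        Restriction enzyme used both for the ORM and the contig digests.
    missed_probability:
        Probability p of discarding each internal restriction site of a
        contig digest (merging the adjacent fragments).
    resize_pct:
        Maximum percent fragment resize; each fragment is scaled by
        ``1 + u`` with ``u ~ Uniform(-pct/100, +pct/100)``.
    seed:
        Master seed; per-stage generators are spawned from it.
    boundary_mode:
        ``"snap_to_site"`` (default) cuts the genome at restriction sites so
        error-free contigs digest to exact ORM slices; ``"arbitrary"`` cuts
        at uniform positions, producing truncated boundary fragments.
    min_fragments:
        Minimum ORM fragments per contig in snap mode.  Default 3: contigs
        below the map's size resolution (one or two fragments) are ambiguous
        by construction — a single fragment size typically recurs elsewhere
        in a multi-thousand-fragment map — and no placement method can order
        them from size information alone.
    """

    genome_length: int
    n_contigs: int
    enzyme: Enzyme = DEFAULT_ENZYME
    missed_probability: float = 0.0
    resize_pct: float = 0.0
    seed: int = 0
    boundary_mode: str = "snap_to_site"
    min_fragments: int = 3

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        if self.genome_length < 10 * self.n_contigs:
            raise ValueError("genome_length must be much larger than n_contigs")
        if not 0.0 <= self.missed_probability <= 1.0:
            raise ValueError("missed_probability must be in [0, 1]")
        if self.resize_pct < 0:
            raise ValueError("resize_pct must be non-negative")
        if self.boundary_mode not in ("snap_to_site", "arbitrary"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if self.min_fragments < 1:
            raise ValueError("min_fragments must be >= 1")


@dataclass(frozen=True)
class TruthRecord:
    """True placement of one contig: ORM interval, genomic interval, rank."""

    contig_id: str
    start_fragment: int
    end_fragment: int
    genome_start: int  # 0-based, half-open
    genome_end: int
    rank: int


@dataclass
class SimTruth:
    """True placements of all contigs, keyed by contig id."""

    records: dict[str, TruthRecord]

    @property
    def r(self) -> int:
        return len(self.records)

    def __getitem__(self, contig_id: str) -> TruthRecord:
        return self.records[contig_id]

    def to_dataframe(self) -> pd.DataFrame:
        recs = sorted(self.records.values(), key=lambda t: t.rank)
        return pd.DataFrame(
            [
                {
                    "contig_id": t.contig_id,
                    "start_fragment": t.start_fragment,
                    "end_fragment": t.end_fragment,
                    "genome_start": t.genome_start,
                    "genome_end": t.genome_end,
                    "rank": t.rank,
                }
                for t in recs
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t")
        records = {
            str(row.contig_id): TruthRecord(
                contig_id=str(row.contig_id),
                start_fragment=int(row.start_fragment),
                end_fragment=int(row.end_fragment),
                genome_start=int(row.genome_start),
                genome_end=int(row.genome_end),
                rank=int(row.rank),
            )
            for row in df.itertuples(index=False)
        }
        return cls(records)


@dataclass(frozen=True)
class EvalReport:
    """Scaffold-vs-truth metrics for one run.

    ``conflicts + wrong_placements + correctly placed == n_contigs`` and
    ``accuracy = 100 * (n - conflicts - wrong) / n`` (percent).
    """

    n_contigs: int
    placed: int
    conflicts: int
    wrong_placements: int
    accuracy: float


def _rng(seed: int | np.random.SeedSequence | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_genome(length: int, seed: int | np.random.Generator = 0) -> str:
    """A uniform-random ACGT string of the given length (iid bases)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = _rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _snap_breakpoints(
    orm_sizes: np.ndarray,
    site_len: int,
    r: int,
    min_fragments: int,
    rng: np.random.Generator,
    max_tries: int = 10_000,
) -> np.ndarray:
    """Choose r-1 internal ORM boundary indices (1-based) for contig cuts.

    Admissible boundaries have a preceding fragment of at least the
    recognition-site length (so no site occurrence straddles the cut) and the
    chosen set keeps every contig at least ``min_fragments`` fragments wide.
    """
    m = orm_sizes.size
    if r == 1:
        return np.empty(0, dtype=np.int64)
    admissible = orm_sizes[:-1] >= site_len  # boundary i+1 admissible
    g = min_fragments
    # sample gap-constrained sorted subsets directly: b_j = y_j + (j-1)(g-1)
    # with y a uniform (r-1)-subset of [g, m - g - (r-2)(g-1)] makes all
    # contigs >= g fragments wide; retry only when a pick lands on one of the
    # few (~1%) site-straddling boundaries.
    hi = m - g - (r - 2) * (g - 1)
    if admissible.sum() < r - 1 or hi - g + 1 < r - 1:
        raise ValueError(
            f"cannot cut a {m}-fragment map into {r} contigs of >= "
            f"{g} fragments each; use a longer genome or fewer contigs"
        )
    offsets = np.arange(r - 1, dtype=np.int64) * (g - 1)
    for _ in range(max_tries):
        y = np.sort(rng.choice(np.arange(g, hi + 1), size=r - 1, replace=False))
        picks = y + offsets
        if admissible[picks - 1].all():
            return picks
    raise ValueError(
        "could not find breakpoints avoiding site-straddling boundaries; "
        "use a longer genome or fewer contigs"
    )


def fragment_genome(
    genome: str,
    r: int,
    cfg: SimConfig,
    rng: int | np.random.Generator = 0,
) -> tuple[list[ContigDigest], SimTruth]:
    """Cut the genome into r non-overlapping contigs and permute them.

    Returns the permuted contig digests and the truth table.  In
    ``snap_to_site`` mode cuts land on restriction-site cut points, so every
    contig digest equals a contiguous slice of the genome's ORM.
    """
    rng = _rng(rng)
    orm_sizes = np.asarray(digest_sequence(genome, cfg.enzyme), dtype=np.int64)
    m = orm_sizes.size
    prefix = np.concatenate(([0], np.cumsum(orm_sizes)))
    if cfg.boundary_mode == "snap_to_site":
        picks = _snap_breakpoints(orm_sizes, len(cfg.enzyme), r, cfg.min_fragments, rng)
        bp_cuts = prefix[picks]  # bp offsets of contig boundaries
        frag_bounds = np.concatenate(([0], picks, [m]))  # fragment-index bounds
    else:
        if len(genome) < r:
            raise ValueError("genome too short for requested contig count")
        bp_cuts = np.sort(
            rng.choice(np.arange(1, len(genome)), size=r - 1, replace=False)
        )
        # true interval: the ORM fragments the contig's bases fall into
        edges = np.concatenate(([0], bp_cuts, [len(genome)]))
        starts_f = np.searchsorted(prefix, edges[:-1], side="right")
        ends_f = np.searchsorted(prefix, edges[1:], side="left")
        frag_bounds = None
    edges = np.concatenate(([0], bp_cuts, [len(genome)]))
    width = len(str(r))
    contigs: list[ContigDigest] = []
    records: dict[str, TruthRecord] = {}
    for j in range(r):
        a, b = int(edges[j]), int(edges[j + 1])
        cid = f"contig_{j + 1:0{width}d}"
        contigs.append(ContigDigest.from_sequence(cid, genome[a:b], cfg.enzyme))
        if frag_bounds is not None:
            sf, ef = int(frag_bounds[j]) + 1, int(frag_bounds[j + 1])
        else:
            sf, ef = int(starts_f[j]), int(ends_f[j])
        records[cid] = TruthRecord(cid, sf, ef, a, b, rank=j + 1)
    perm = rng.permutation(r)
    contigs = [contigs[k] for k in perm]
    return contigs, SimTruth(records)


def inject_missed_sites(
    digest: ContigDigest, p: float, rng: int | np.random.Generator = 0
) -> ContigDigest:
    """Drop each internal fragment boundary with probability p, merging
    the adjacent fragments.  Total bp is conserved."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    sizes = digest.sizes
    if sizes.size == 1 or p == 0.0:
        return ContigDigest(digest.contig_id, sizes.copy())
    rng = _rng(rng)
    keep = rng.random(sizes.size - 1) >= p
    starts = np.concatenate(([0], np.flatnonzero(keep) + 1))
    merged = np.add.reduceat(sizes, starts)
    return ContigDigest(digest.contig_id, merged)


def resize_fragments(
    digest: ContigDigest, pct: float, rng: int | np.random.Generator = 0
) -> ContigDigest:
    """Scale each fragment independently by 1 + Uniform(-pct/100, +pct/100),
    rounding to the nearest bp with a floor of 1 bp."""
    if pct < 0:
        raise ValueError("pct must be non-negative")
    if pct == 0.0:
        return ContigDigest(digest.contig_id, digest.sizes.copy())
    rng = _rng(rng)
    u = rng.uniform(-pct / 100.0, pct / 100.0, size=digest.sizes.size)
    sizes = np.rint(digest.sizes * (1.0 + u)).astype(np.int64)
    return ContigDigest(digest.contig_id, np.maximum(sizes, 1))


def evaluate(scaffold: Scaffold, truth: SimTruth) -> EvalReport:
    """Score a scaffold against the truth (see module docstring for terms)."""
    r = truth.r
    wrong = 0
    correct = 0
    seen: set[str] = set()
    for p in scaffold.placements:
        if p.contig_id not in truth.records:
            raise ValueError(f"scaffold references unknown contig {p.contig_id!r}")
        seen.add(p.contig_id)
        if p.start_fragment == truth[p.contig_id].start_fragment:
            correct += 1
        else:
            wrong += 1
    for cid in scaffold.discarded:
        if cid not in truth.records:
            raise ValueError(f"scaffold references unknown contig {cid!r}")
        seen.add(cid)
    if len(seen) != r:
        missing = sorted(set(truth.records) - seen)
        raise ValueError(f"scaffold does not account for contigs: {missing[:5]} ...")
    conflicts = r - len(scaffold.placements)
    return EvalReport(
        n_contigs=r,
        placed=len(scaffold.placements),
        conflicts=conflicts,
        wrong_placements=wrong,
        accuracy=100.0 * (r - conflicts - wrong) / r,
    )


@dataclass
class ExperimentResult:
    """All artifacts of one simulated scaffolding run."""

    report: EvalReport
    scaffold: Scaffold
    table: ScoreTable
    orm: ORMap
    contigs: list[ContigDigest]
    truth: SimTruth
    genome: str
    scoring_cfg: ScoringConfig
    placement_cfg: PlacementConfig


def _resolve_scoring(
    sim_cfg: SimConfig, orm: ORMap, cfg: ScoringConfig | None
) -> ScoringConfig:
    """Default scorer settings matched to the injected noise.

    Resize noise is multiplicative and bounded, so the natural per-fragment
    tolerance is proportional to fragment size: sigma_j = resize_pct/100 *
    o_j, attached to the ORM as per-fragment stds (the scorer accumulates
    them over merged groups).  Error-free runs keep sigma = 0.
    """
    if cfg is not None:
        return cfg
    if sim_cfg.resize_pct > 0:
        orm.stds = sim_cfg.resize_pct / 100.0 * orm.sizes.astype(np.float64)
    return ScoringConfig(penalty=999.0, default_std=0.0)


def generate_instance(
    sim_cfg: SimConfig,
) -> tuple[str, ORMap, list[ContigDigest], SimTruth]:
    """Genome, ORM, (permuted, error-injected) contig digests, and truth."""
    ss = np.random.SeedSequence(sim_cfg.seed)
    s_genome, s_frag, s_miss, s_resize = ss.spawn(4)
    genome = random_genome(sim_cfg.genome_length, np.random.default_rng(s_genome))
    orm = ORMap.from_sequence(genome, sim_cfg.enzyme)
    contigs, truth = fragment_genome(
        genome, sim_cfg.n_contigs, sim_cfg, np.random.default_rng(s_frag)
    )
    rng_miss = np.random.default_rng(s_miss)
    rng_resize = np.random.default_rng(s_resize)
    if sim_cfg.missed_probability > 0:
        contigs = [
            inject_missed_sites(c, sim_cfg.missed_probability, rng_miss) for c in contigs
        ]
    if sim_cfg.resize_pct > 0:
        contigs = [resize_fragments(c, sim_cfg.resize_pct, rng_resize) for c in contigs]
    return genome, orm, contigs, truth


def run_experiment(
    sim_cfg: SimConfig,
    scoring_cfg: ScoringConfig | None = None,
    placement_cfg: PlacementConfig | None = None,
) -> ExperimentResult:
    """End-to-end simulated run: generate, score, place, evaluate.

    When ``scoring_cfg`` is omitted, P defaults to 999 and sigma to
    ``resize_pct/100 * mean ORM fragment size`` (0 for error-free runs).
    Fully reproducible from ``sim_cfg.seed``.
    """
    placement_cfg = placement_cfg or PlacementConfig()
    genome, orm, contigs, truth = generate_instance(sim_cfg)
    scoring_cfg = _resolve_scoring(sim_cfg, orm, scoring_cfg)
    table = score_all(contigs, orm, scoring_cfg)
    scaffold = place(table, placement_cfg)
    report = evaluate(scaffold, truth)
    return ExperimentResult(
        report, scaffold, table, orm, contigs, truth, genome, scoring_cfg, placement_cfg
    )


def run_methods(
    sim_cfg: SimConfig,
    scoring_cfg: ScoringConfig | None = None,
    depth: int = 5,
    methods: Sequence[str] = ("gpa1", "gpa2", "gpa3"),
) -> dict[str, EvalReport]:
    """Run several placement methods on one shared score table."""
    genome, orm, contigs, truth = generate_instance(sim_cfg)
    scoring_cfg = _resolve_scoring(sim_cfg, orm, scoring_cfg)
    table = score_all(contigs, orm, scoring_cfg)
    out: dict[str, EvalReport] = {}
    for method in methods:
        scaffold = place(table, PlacementConfig(method=method, depth=depth))
        out[method] = evaluate(scaffold, truth)
    return out


def run_grid(
    genome_length: int,
    contig_counts: Iterable[int],
    error_levels: Iterable[tuple[float, float]],
    seed: int = 0,
    depth: int = 5,
    methods: Sequence[str] = ("gpa1", "gpa2", "gpa3"),
    enzyme: Enzyme = DEFAULT_ENZYME,
) -> pd.DataFrame:
    """Experiment grid over contig counts and (missed p, resize %) levels.

    Returns one row per (contig count, method, error level) with the columns
    Contigs, Method, Missed probability, % Resize, Conflicts,
    Wrong placement, % Accuracy, Time (s).
    """
    rows = []
    for r in contig_counts:
        for p, pct in error_levels:
            sim_cfg = SimConfig(
                genome_length=genome_length,
                n_contigs=r,
                enzyme=enzyme,
                missed_probability=p,
                resize_pct=pct,
                seed=seed,
            )
            t0 = time.perf_counter()
            reports = run_methods(sim_cfg, depth=depth, methods=methods)
            elapsed = time.perf_counter() - t0
            for method in methods:
                rep = reports[method]
                rows.append(
                    {
                        "Contigs": r,
                        "Method": method.upper(),
                        "Missed probability": p,
                        "% Resize": pct,
                        "Conflicts": rep.conflicts,
                        "Wrong placement": rep.wrong_placements,
                        "% Accuracy": round(rep.accuracy, 2),
                        "Time (s)": round(elapsed / len(methods), 3),
                    }
                )
    return pd.DataFrame(rows)
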