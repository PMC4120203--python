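"""Simulation harness: generators, error channels, evaluation, pipeline."""

import numpy as np
import pytest

from ormscaffold.digest import ContigDigest, Enzyme
from ormscaffold.placement import Placement, PlacementConfig, Scaffold
from ormscaffold.simulate import (
    EvalReport,
    SimConfig,
    SimTruth,
    TruthRecord,
    evaluate,
    fragment_genome,
    generate_instance,
    inject_missed_sites,
    random_genome,
    resize_fragments,
    run_experiment,
    run_grid,
    run_methods,
)


class TestRandomGenome:
    def test_alphabet_length_and_reproducibility(self):
        g = random_genome(100, seed=7)
        assert len(g) == 100 and set(g) <= set("ACGT")
        assert g == random_genome(100, seed=7)
        assert g != random_genome(100, seed=8)

    def test_base_frequencies_uniform(self):
        n = 100_000
        g = random_genome(n, seed=3)
        # iid uniform bases: each frequency within 3 binomial sd of 1/4
        sd = np.sqrt(0.25 * 0.75 / n)
        for base in "ACGT":
            assert abs(g.count(base) / n - 0.25) < 3 * sd


class TestFragmentGenome:
    def _cfg(self, r, **kw):
        return SimConfig(genome_length=60_000, n_contigs=r, **kw)

    def test_single_contig_is_whole_genome(self):
        cfg = self._cfg(1)
        genome = random_genome(cfg.genome_length, seed=0)
        contigs, truth = fragment_genome(genome, 1, cfg, rng=1)
        assert len(contigs) == 1
        from ormscaffold.digest import digest_sequence

        orm_sizes = digest_sequence(genome, cfg.enzyme)
        t = truth[contigs[0].contig_id]
        assert (t.start_fragment, t.end_fragment) == (1, len(orm_sizes))
        assert contigs[0].sizes.tolist() == orm_sizes

    def test_contigs_reconstruct_orm_exactly(self):
        cfg = self._cfg(5)
        genome = random_genome(cfg.genome_length, seed=1)
        contigs, truth = fragment_genome(genome, 5, cfg, rng=2)
        from ormscaffold.digest import digest_sequence

        orm_sizes = digest_sequence(genome, cfg.enzyme)
        # reassemble in true rank order: concatenated digests == the ORM,
        # and each contig's digest equals its true ORM slice
        ordered = sorted(contigs, key=lambda c: truth[c.contig_id].rank)
        rebuilt = [s for c in ordered for s in c.sizes.tolist()]
        assert rebuilt == orm_sizes
        for c in contigs:
            t = truth[c.contig_id]
            assert c.sizes.tolist() == orm_sizes[t.start_fragment - 1 : t.end_fragment]
            assert c.n >= cfg.min_fragments

    def test_truth_intervals_disjoint_ranks_permutation(self):
        cfg = self._cfg(8)
        genome = random_genome(cfg.genome_length, seed=2)
        _, truth = fragment_genome(genome, 8, cfg, rng=3)
        recs = sorted(truth.records.values(), key=lambda t: t.rank)
        assert [t.rank for t in recs] == list(range(1, 9))
        for a, b in zip(recs, recs[1:]):
            assert a.end_fragment < b.start_fragment

    def test_permutation_reproducible(self):
        cfg = self._cfg(6)
        genome = random_genome(cfg.genome_length, seed=4)
        a, _ = fragment_genome(genome, 6, cfg, rng=5)
        b, _ = fragment_genome(genome, 6, cfg, rng=5)
        assert [c.contig_id for c in a] == [c.contig_id for c in b]

    def test_too_many_contigs_rejected(self):
        cfg = SimConfig(genome_length=2_000, n_contigs=150)
        genome = random_genome(2_000, seed=0)
        with pytest.raises(ValueError, match="longer genome|fewer contigs"):
            fragment_genome(genome, 150, cfg, rng=0)

    def test_arbitrary_mode_covers_genome(self):
        cfg = self._cfg(5, boundary_mode="arbitrary")
        genome = random_genome(cfg.genome_length, seed=6)
        contigs, truth = fragment_genome(genome, 5, cfg, rng=7)
        assert sum(c.total_bp for c in contigs) == len(genome)
        assert truth.r == 5


class TestErrorChannels:
    def test_missed_sites_identity_and_total_merge(self):
        d = ContigDigest("c", [10, 20, 30, 40])
        assert inject_missed_sites(d, 0.0, 1).sizes.tolist() == [10, 20, 30, 40]
        merged = inject_missed_sites(d, 1.0, 1)
        assert merged.sizes.tolist() == [100]

    def test_missed_sites_conserve_total_bp(self, rng):
        d = ContigDigest("c", rng.integers(1, 500, size=30))
        for p in (0.1, 0.5, 0.9):
            out = inject_missed_sites(d, p, rng)
            assert out.total_bp == d.total_bp

    def test_missed_boundary_count_binomial(self):
        n_frag, reps, p = 51, 4_000, 0.3
        d = ContigDigest("c", np.full(n_frag, 100))
        rng = np.random.default_rng(11)
        kept = [inject_missed_sites(d, p, rng).n - 1 for _ in range(reps)]
        expected = (n_frag - 1) * (1 - p)
        sd = np.sqrt((n_frag - 1) * p * (1 - p) / reps)
        assert abs(np.mean(kept) - expected) < 3 * sd

    def test_resize_identity_and_bounds(self, rng):
        d = ContigDigest("c", rng.integers(5, 500, size=40))
        assert resize_fragments(d, 0.0, rng).sizes.tolist() == d.sizes.tolist()
        pct = 10.0
        out = resize_fragments(d, pct, rng)
        # every fragment within +/- pct (plus 0.5 rounding), floored at 1 bp
        bound = d.sizes * pct / 100.0 + 0.5
        assert (np.abs(out.sizes - d.sizes) <= bound).all()
        assert (out.sizes >= 1).all()

    def test_resize_mean_relative_change_near_zero(self):
        # symmetric uniform noise: mean relative change -> 0
        d = ContigDigest("c", np.full(100, 400))
        rng = np.random.default_rng(13)
        reps = 100
        rel = np.concatenate(
            [(resize_fragments(d, 10.0, rng).sizes - 400) / 400 for _ in range(reps)]
        )
        sd = (0.1 / np.sqrt(3)) / np.sqrt(rel.size)  # uniform(-0.1,0.1) sd
        assert abs(rel.mean()) < 3 * sd

    @pytest.mark.parametrize("bad_call", [
        lambda d: inject_missed_sites(d, 1.5, 0),
        lambda d: resize_fragments(d, -1.0, 0),
    ])
    def test_invalid_error_params_rejected(self, bad_call):
        with pytest.raises(ValueError):
            bad_call(ContigDigest("c", [10, 20]))


def _truth_of(n):
    return SimTruth(
        {
            f"C{i}": TruthRecord(f"C{i}", 3 * i + 1, 3 * i + 3, 0, 0, rank=i + 1)
            for i in range(n)
        }
    )


def _scaffold_with(n, correct, wrong):
    placements = [
        Placement(f"C{i}", 3 * i + 1, 3 * i + 3, 0.0) for i in range(correct)
    ]
    # wrongly placed contigs: shifted start, still non-overlapping (far right)
    placements += [
        Placement(f"C{correct + k}", 1000 + 3 * k, 1001 + 3 * k, 0.0)
        for k in range(wrong)
    ]
    discarded = [f"C{i}" for i in range(correct + wrong, n)]
    return Scaffold(placements, discarded)


class TestEvaluate:
    @pytest.mark.parametrize(
        "n, conflicts, wrong, accuracy",
        [
            (50, 12, 2, 72.00),
            (100, 45, 6, 49.00),
            (10, 0, 0, 100.00),
        ],
    )
    def test_accuracy_arithmetic(self, n, conflicts, wrong, accuracy):
        scaffold = _scaffold_with(n, n - conflicts - wrong, wrong)
        rep = evaluate(scaffold, _truth_of(n))
        assert rep.conflicts == conflicts
        assert rep.wrong_placements == wrong
        assert rep.accuracy == pytest.approx(accuracy)
        assert rep.n_contigs == rep.conflicts + rep.wrong_placements + (
            rep.placed - rep.wrong_placements
        )

    def test_unknown_contig_rejected(self):
        scaffold = Scaffold([Placement("ghost", 1, 2, 0.0)])
        with pytest.raises(ValueError):
            evaluate(scaffold, _truth_of(1))

    def test_unaccounted_contig_rejected(self):
        scaffold = Scaffold([Placement("C0", 1, 3, 0.0)])
        with pytest.raises(ValueError):
            evaluate(scaffold, _truth_of(2))


class TestPipeline:
    def test_zero_error_recovery_small(self):
        cfg = SimConfig(genome_length=150_000, n_contigs=15, seed=42)
        reports = run_methods(cfg)
        for method, rep in reports.items():
            assert rep.accuracy == 100.0, method
            assert rep.conflicts == 0 and rep.wrong_placements == 0

    def test_same_seed_identical_results(self):
        cfg = SimConfig(
            genome_length=120_000, n_contigs=10, missed_probability=0.2,
            resize_pct=10.0, seed=5,
        )
        a = run_experiment(cfg)
        b = run_experiment(cfg)
        assert a.report == b.report
        assert a.scaffold.to_dataframe().equals(b.scaffold.to_dataframe())
        assert np.array_equal(a.table.scores, b.table.scores)

    def test_error_channels_flow_through(self):
        cfg = SimConfig(
            genome_length=120_000, n_contigs=10, missed_probability=0.3,
            resize_pct=10.0, seed=6,
        )
        genome, orm, contigs, truth = generate_instance(cfg)
        # missed-site merging means fewer total contig fragments than the map
        assert sum(c.n for c in contigs) < orm.m
        # resize perturbs total bp a little but conserves the scale
        total = sum(c.total_bp for c in contigs)
        assert 0.8 * len(genome) < total < 1.2 * len(genome)

    def test_grid_report_layout(self):
        df = run_grid(
            80_000, contig_counts=[5], error_levels=[(0.0, 0.0), (0.3, 20.0)],
            seed=1, methods=("gpa1", "gpa3"),
        )
        assert list(df.columns) == [
            "Contigs", "Method", "Missed probability", "% Resize",
            "Conflicts", "Wrong placement", "% Accuracy", "Time (s)",
        ]
        assert len(df) == 4
        zero = df[(df["Missed probability"] == 0.0)]
        assert (zero["% Accuracy"] == 100.0).all()
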