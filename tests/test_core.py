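"""Competitive assignment: verdicts, counting, ambiguity resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from compase.alignment_io import GeneInterval, HomologPair, ReadStats, TagConfig
from compase.core import (
    GeneCountRecord,
    ReadVerdict,
    compare_read,
    count_gene,
    resolve_ambiguous,
    competitive_count,
)
from compase.errors import CompaseError

from conftest import make_bam, write_bed


def rs(read_id="r", score=100, nm=0):
    return ReadStats(read_id=read_id, alignment_score=score, mismatches=nm)


PAIR = HomologPair(
    name="g",
    interval_p1=GeneInterval("g", "c1", 0, 100),
    interval_p2=GeneInterval("g", "c2", 0, 100),
)


class TestCompareRead:
    @pytest.mark.parametrize(
        "s1, s2, expected",
        [
            ((100, 0), (95, 1), ReadVerdict.P1),
            ((95, 1), (100, 0), ReadVerdict.P2),
            ((90, 2), (90, 1), ReadVerdict.P2),
            ((90, 1), (90, 2), ReadVerdict.P1),
            ((90, 1), (90, 1), ReadVerdict.AMBIGUOUS),
            ((90, 5), None, ReadVerdict.P1),
            (None, (10, 9), ReadVerdict.P2),
        ],
    )
    def test_verdict_rule(self, s1, s2, expected):
        stats1 = rs(score=s1[0], nm=s1[1]) if s1 else None
        stats2 = rs(score=s2[0], nm=s2[1]) if s2 else None
        assert compare_read(stats1, stats2) is expected

    def test_both_absent_is_logic_error(self):
        with pytest.raises(CompaseError):
            compare_read(None, None)

    @given(
        score1=st.integers(-10, 110),
        score2=st.integers(-10, 110),
        nm1=st.integers(0, 9),
        nm2=st.integers(0, 9),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, score1, score2, nm1, nm2):
        """Swapping the two sides must swap (or preserve) the verdict."""
        v_fwd = compare_read(rs(score=score1, nm=nm1), rs(score=score2, nm=nm2))
        v_rev = compare_read(rs(score=score2, nm=nm2), rs(score=score1, nm=nm1))
        swap = {
            ReadVerdict.P1: ReadVerdict.P2,
            ReadVerdict.P2: ReadVerdict.P1,
            ReadVerdict.AMBIGUOUS: ReadVerdict.AMBIGUOUS,
        }
        assert v_rev is swap[v_fwd]


class TestCountGene:
    def test_one_sided_read(self):
        rec = count_gene(PAIR, {"r1": rs("r1")}, {})
        assert (rec.count_p1, rec.count_p2, rec.count_ambiguous) == (1, 0, 0)

    def test_identical_maps_all_ambiguous(self):
        stats = {f"r{i}": rs(f"r{i}", 90, 1) for i in range(10)}
        rec = count_gene(PAIR, stats, dict(stats))
        assert rec.count_ambiguous == 10
        assert rec.count_p1 == rec.count_p2 == 0

    def test_empty_maps(self):
        rec = count_gene(PAIR, {}, {})
        assert (rec.count_p1, rec.count_p2, rec.count_ambiguous) == (0, 0, 0)

    def test_counts_cover_union_once(self):
        s1 = {"a": rs("a", 100), "b": rs("b", 50)}
        s2 = {"b": rs("b", 60), "c": rs("c", 70)}
        rec = count_gene(PAIR, s1, s2)
        total = rec.count_p1 + rec.count_p2 + rec.count_ambiguous
        assert total == 3  # a, b, c each counted exactly once


class TestResolveAmbiguous:
    @staticmethod
    def record(c1, c2, amb):
        return GeneCountRecord("g", c1, c2, amb, c1, c2)

    def test_deterministic_exact_split(self):
        rec = resolve_ambiguous(self.record(6, 4, 10))
        assert (rec.resolved_p1, rec.resolved_p2) == (12, 8)

    def test_no_unambiguous_falls_back_to_half(self):
        rec = resolve_ambiguous(self.record(0, 0, 8))
        assert (rec.resolved_p1, rec.resolved_p2) == (4, 4)

    def test_round_half_to_even(self):
        # p = 0.5, amb = 5 -> 2.5 rounds to 2 (half-to-even)
        rec = resolve_ambiguous(self.record(1, 1, 5))
        assert (rec.resolved_p1, rec.resolved_p2) == (3, 4)

    def test_binomial_mean_matches_expectation(self, rng):
        """Monte-Carlo: 6 + Binomial(10, 0.6) has mean 12."""
        reps = 10_000
        values = [
            resolve_ambiguous(self.record(6, 4, 10), mode="binomial", rng=rng).resolved_p1
            for _ in range(reps)
        ]
        mean = np.mean(values)
        se = np.std(values, ddof=1) / np.sqrt(reps)
        assert abs(mean - 12.0) <= 3 * se

    @given(c1=st.integers(0, 50), c2=st.integers(0, 50), amb=st.integers(0, 100),
           binom=st.booleans(), seed=st.integers(0, 2**16))
    @settings(max_examples=200, deadline=None)
    def test_conservation(self, c1, c2, amb, binom, seed):
        rec = resolve_ambiguous(
            self.record(c1, c2, amb),
            mode="binomial" if binom else "deterministic",
            rng=np.random.default_rng(seed),
        )
        assert rec.resolved_p1 + rec.resolved_p2 == c1 + c2 + amb
        assert rec.resolved_p1 >= c1 and rec.resolved_p2 >= c2

    def test_already_resolved_rejected(self):
        rec = GeneCountRecord("g", 1, 1, 2, 3, 1)
        with pytest.raises(CompaseError):
            resolve_ambiguous(rec)


def _two_bam_setup(tmp_path, recs1, recs2, genes=("g1",), length=100):
    refs = {f"c{i}": length for i in range(1, len(genes) + 1)}
    bam1 = make_bam(tmp_path / "p1.bam", refs, recs1)
    bam2 = make_bam(tmp_path / "p2.bam", refs, recs2)
    rows = [(f"c{i+1}", 0, length, g) for i, g in enumerate(genes)]
    bed1 = write_bed(tmp_path / "p1.bed", rows)
    bed2 = write_bed(tmp_path / "p2.bed", rows)
    return str(bam1), str(bam2), str(bed1), str(bed2)


class TestCompetitiveCount:
    def test_three_better_one_tie(self, tmp_path):
        recs1 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 100, "nm": 0}
            for i in range(4)
        ]
        recs2 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 90, "nm": 2}
            for i in range(3)
        ] + [{"name": "r3", "ref": "c1", "pos": 3, "score": 100, "nm": 0}]
        (rec,), summary = competitive_count(
            *_two_bam_setup(tmp_path, recs1, recs2), TagConfig()
        )
        assert (rec.count_p1, rec.count_p2, rec.count_ambiguous) == (3, 0, 1)
        assert (rec.resolved_p1, rec.resolved_p2) == (4, 0)  # p = 1.0

    def test_identical_bams_split_half(self, tmp_path):
        recs = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 80, "nm": 1}
            for i in range(10)
        ]
        (rec,), _ = competitive_count(
            *_two_bam_setup(tmp_path, recs, list(recs)), TagConfig()
        )
        assert rec.count_p1 == rec.count_p2 == 0
        assert rec.count_ambiguous == 10
        assert (rec.resolved_p1, rec.resolved_p2) == (5, 5)

    def test_swap_symmetry(self, tmp_path):
        recs1 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 100 - (i % 3) * 5,
             "nm": i % 3} for i in range(12)
        ]
        recs2 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 95, "nm": 1}
            for i in range(12)
        ]
        args = _two_bam_setup(tmp_path, recs1, recs2)
        (fwd,), _ = competitive_count(*args, TagConfig())
        (rev,), _ = competitive_count(args[1], args[0], args[3], args[2], TagConfig())
        assert (fwd.count_p1, fwd.count_p2) == (rev.count_p2, rev.count_p1)
        assert (fwd.resolved_p1, fwd.resolved_p2) == (rev.resolved_p2, rev.resolved_p1)

    def test_multi_gene_overlap_discarded(self, tmp_path):
        # one read overlapping two parent-1 gene intervals is dropped everywhere
        refs = {"c1": 200}
        recs = [
            {"name": "r_multi", "ref": "c1", "pos": 95, "score": 100},
            {"name": "r_a", "ref": "c1", "pos": 5, "score": 100},
        ]
        bam1 = make_bam(tmp_path / "p1.bam", refs, recs)
        bam2 = make_bam(tmp_path / "p2.bam", refs, recs)
        rows = [("c1", 0, 105, "gA"), ("c1", 100, 200, "gB")]
        bed1 = write_bed(tmp_path / "p1.bed", rows)
        bed2 = write_bed(tmp_path / "p2.bed", rows)
        records, summary = competitive_count(
            str(bam1), str(bam2), str(bed1), str(bed2), TagConfig()
        )
        by_gene = {r.gene: r for r in records}
        totals = {
            g: r.count_p1 + r.count_p2 + r.count_ambiguous
            for g, r in by_gene.items()
        }
        assert totals == {"gA": 1, "gB": 0}
        assert summary.discarded_multi_gene == 1

    def test_deterministic_mode_is_reproducible(self, tmp_path):
        recs1 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 90 + i % 2, "nm": 0}
            for i in range(8)
        ]
        recs2 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 90, "nm": 0}
            for i in range(8)
        ]
        args = _two_bam_setup(tmp_path, recs1, recs2)
        first, _ = competitive_count(*args, TagConfig())
        second, _ = competitive_count(*args, TagConfig())
        assert first == second

    def test_binom_mode_seeded_reproducible(self, tmp_path):
        recs1 = [
            {"name": f"r{i}", "ref": "c1", "pos": i, "score": 90, "nm": 0}
            for i in range(20)
        ]
        recs2 = [
            {"name": f"r{i}", "ref": "c1", "pos": i,
             "score": 95 if i < 4 else 90, "nm": 0} for i in range(20)
        ]
        args = _two_bam_setup(tmp_path, recs1, recs2)
        cfg = TagConfig(binom_mode=True, seed=7)
        first, _ = competitive_count(*args, cfg)
        second, _ = competitive_count(*args, cfg)
        assert first == second

    def test_oracle_equivalence_small_fixture(self, tmp_path, rng):
        """Brute-force per-read verdicts reproduce competitive_count on <= 20 reads."""
        reads = {}
        recs1, recs2 = [], []
        for i in range(20):
            present1, present2 = rng.random() < 0.8, rng.random() < 0.8
            if not (present1 or present2):
                present1 = True
            s1 = (int(rng.integers(80, 101)), int(rng.integers(0, 4)))
            s2 = (int(rng.integers(80, 101)), int(rng.integers(0, 4)))
            reads[f"r{i:02d}"] = (s1 if present1 else None, s2 if present2 else None)
            if present1:
                recs1.append({"name": f"r{i:02d}", "ref": "c1", "pos": i,
                              "score": s1[0], "nm": s1[1]})
            if present2:
                recs2.append({"name": f"r{i:02d}", "ref": "c1", "pos": i,
                              "score": s2[0], "nm": s2[1]})
        # independent hand rule: one-sided wins; else score, then mismatches
        exp = {"P1": 0, "P2": 0, "AMB": 0}
        for s1, s2 in reads.values():
            if s2 is None or (
                s1 is not None
                and (s1[0] > s2[0] or (s1[0] == s2[0] and s1[1] < s2[1]))
            ):
                exp["P1"] += 1
            elif s1 is None or s1[0] < s2[0] or s1[1] > s2[1]:
                exp["P2"] += 1
            else:
                exp["AMB"] += 1
        (rec,), _ = competitive_count(
            *_two_bam_setup(tmp_path, recs1, recs2), TagConfig()
        )
        assert (rec.count_p1, rec.count_p2, rec.count_ambiguous) == (
            exp["P1"], exp["P2"], exp["AMB"],
        )
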