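"""Interval-list restriction merge and the general gap-cost scorer."""

import itertools
import math

import pytest

from spscore import (
    AffineGapCost,
    Alignment,
    ConstantGapCost,
    GapInterval,
    LogAffineGapCost,
    LogGapCost,
    MergeCounters,
    alignment_gap_intervals,
    edge_case_fixtures,
    gap_cost_from_spec,
    general_sp_score,
    identity_matrix,
    naive_sp_score,
    restrict_gap_intervals,
    restricted_gap_intervals_reference,
    sp_substitution_score,
    site_symbol_counts,
)
from spscore.errors import ConfigError


def ivs(*pairs):
    return [GapInterval(s, e) for s, e in pairs]


class TestRestrictGapIntervals:
    @pytest.mark.parametrize(
        "lg_i,lg_j,exp_i,exp_j",
        [
            # from "AC-GT" vs "A--GT": i's gap vanishes, j's shrinks
            ([(3, 3)], [(2, 3)], [], [(2, 2)]),
            # no shared gap columns: untouched
            ([], [(1, 4)], [], [(1, 4)]),
            # identical intervals vanish on both sides
            ([(1, 4)], [(1, 4)], [], []),
            # nested interval disappears, container shrinks by the overlap
            ([(2, 6)], [(4, 5)], [(2, 4)], []),
            # partial overlap, each side keeps its private columns
            ([(2, 4)], [(4, 6)], [(2, 3)], [(4, 5)]),
            # disjoint: only coordinate shifts, here none
            ([(1, 2)], [(5, 6)], [(1, 2)], [(5, 6)]),
            # container fully consumed by two sub-intervals plus equal end
            ([(1, 10)], [(1, 3), (5, 10)], [(1, 1)], []),
        ],
    )
    def test_branch_examples(self, lg_i, lg_j, exp_i, exp_j):
        got_i, got_j = restrict_gap_intervals(ivs(*lg_i), ivs(*lg_j))
        assert [(v.start, v.end) for v in got_i] == exp_i
        assert [(v.start, v.end) for v in got_j] == exp_j

    def test_matches_explicit_restriction_on_corpus(self, corpus):
        for _, aln in corpus[:400]:
            per_seq = alignment_gap_intervals(aln)
            for i, j in itertools.combinations(range(aln.n), 2):
                got = restrict_gap_intervals(per_seq[i], per_seq[j])
                ref = restricted_gap_intervals_reference(aln, i, j)
                assert got == ref, (aln.seqs[i], aln.seqs[j])

    def test_terminal_flags_inherited(self):
        lg_i = [GapInterval(1, 3, terminal=True)]
        lg_j = [GapInterval(1, 2, terminal=True)]
        got_i, got_j = restrict_gap_intervals(lg_i, lg_j)
        assert got_i == [GapInterval(1, 1, terminal=True)] and got_j == []

    def test_merge_steps_and_shift_accounting(self, corpus):
        for _, aln in corpus[:200]:
            per_seq = alignment_gap_intervals(aln)
            for i, j in itertools.combinations(range(aln.n), 2):
                c = MergeCounters()
                restrict_gap_intervals(per_seq[i], per_seq[j], c)
                assert c.steps <= len(per_seq[i]) + len(per_seq[j])
                doubly = sum(
                    1 for a, b in zip(aln.seqs[i], aln.seqs[j]) if a == "-" == b
                )
                assert c.shift == doubly

    def test_branch_coverage_over_fixtures(self):
        """The edge-case fixtures exercise every relation the merge handles."""
        hit: dict[str, int] = {}
        for aln in edge_case_fixtures().values():
            per_seq = alignment_gap_intervals(aln)
            for i, j in itertools.combinations(range(aln.n), 2):
                c = MergeCounters()
                restrict_gap_intervals(per_seq[i], per_seq[j], c)
                for k, v in c.branches.items():
                    hit[k] = hit.get(k, 0) + v
        assert {
            "equal",
            "nested_j_in_i",
            "nested_i_in_j",
            "overlap_i_first",
            "overlap_j_first",
            "disjoint_i_first",
            "disjoint_j_first",
        } <= set(hit)


class TestSubstitutionTerm:
    def test_column_closed_forms(self, identity_1_0):
        aln = Alignment(("a", "b", "c"), ("AAA", "AC-", "A-T"), alphabet="ACGT")
        counts = site_symbol_counts(aln)
        # col1: C(3,2)=3 matches; col2: A-C mismatch 0; col3: A-T mismatch 0
        assert sp_substitution_score(counts, identity_1_0) == 3

    def test_equals_naive_double_loop_when_gap_free(self, identity_1_0):
        aln = Alignment(("a", "b", "c", "d"), ("ACGT", "ACGA", "TCGA", "ACCA"), "ACGT")
        bd_naive = naive_sp_score(aln, identity_1_0, AffineGapCost(-3, -1))
        counts = site_symbol_counts(aln)
        assert sp_substitution_score(counts, identity_1_0) == bd_naive.sp_s


class TestGeneralScore:
    def test_worked_fixture(self, worked_3seq, identity_1_0):
        bd = general_sp_score(worked_3seq, identity_1_0, AffineGapCost(-3, -1))
        assert (bd.sp_s, bd.sp_g, bd.sp_total) == (10, -13, -3)

    @pytest.mark.parametrize(
        "model",
        [
            AffineGapCost(-3, -1),
            AffineGapCost(-3, -1, gap_open_terminal=-1, gap_extend_terminal=0),
            ConstantGapCost(-2),
            LogGapCost(-2, -1),
            LogAffineGapCost(-1, -0.5, -2),
        ],
        ids=["affine", "affine-terminal-split", "constant", "log", "logaffine"],
    )
    def test_equals_naive_on_fixtures(self, model, identity_1_0):
        for name, aln in edge_case_fixtures().items():
            ref = naive_sp_score(aln, identity_1_0, model)
            got = general_sp_score(aln, identity_1_0, model)
            assert math.isclose(got.sp_total, ref.sp_total, rel_tol=1e-9, abs_tol=1e-9), name
            assert math.isclose(got.sp_s, ref.sp_s, rel_tol=1e-9, abs_tol=1e-9), name

    def test_gap_model_spec_parsing(self):
        assert gap_cost_from_spec("affine:-3,-1") == AffineGapCost(-3, -1)
        assert gap_cost_from_spec("constant:-2") == ConstantGapCost(-2)
        assert gap_cost_from_spec("logaffine:-1,-0.5,-2") == LogAffineGapCost(-1, -0.5, -2)
        with pytest.raises(ConfigError):
            gap_cost_from_spec("affine:-3")
        with pytest.raises(ConfigError):
            gap_cost_from_spec("nosuch:1")

    def test_worst_case_merge_steps_scale_with_L(self):
        """On alternating-gap rows the per-pair merge degenerates to ~L work,
        the regime where the interval method loses its advantage."""
        from spscore import GeneratorConfig, generate_alignment

        cfg = GeneratorConfig(n=4, L=60, structure="alternating-worst-case", seed=7)
        aln = generate_alignment(cfg)
        bd = general_sp_score(aln, identity_matrix(1, 0), AffineGapCost(-3, -1), collect_stats=True)
        for pair in bd.stats["pairs"]:
            assert pair["steps"] >= aln.L // 3
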