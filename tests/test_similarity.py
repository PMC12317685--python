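"""Total similarity scores, training objectives, and per-peptide scoring."""

import numpy as np
import pytest

import pepmat as pm
from pepmat.similarity import TSSComponents, _normalize


class TestTSS:
    def test_single_pair_normalization(self, identity1, gaps21):
        a = pm.PeptideSet([pm.PeptideRecord("AAA", "a")])
        b = pm.PeptideSet([pm.PeptideRecord("AAA", "b")])
        assert pm.tss(a, b, identity1, gaps21) == pytest.approx(1.0)

    def test_self_set_excludes_self_pairs(self, identity1, gaps21):
        # only the two ordered cross pairs AA vs AAAA remain;
        # nw("AA","AAAA") = 2 matches - (open + extend) = -1, meanlen 3
        peptides = pm.PeptideSet(
            [pm.PeptideRecord("AA", "p1"), pm.PeptideRecord("AAAA", "p2")]
        )
        assert pm.tss(peptides, peptides, identity1, gaps21) == pytest.approx(-1 / 3)

    def test_order_permutation_invariance(self, identity1, gaps21, toy_sets):
        functional, control = toy_sets
        shuffled = pm.PeptideSet(list(reversed(functional.records)))
        assert pm.tss(functional, control, identity1, gaps21) == pytest.approx(
            pm.tss(shuffled, control, identity1, gaps21)
        )

    def test_symmetric_matrix_makes_tss_symmetric(self, identity1, gaps21, toy_sets):
        functional, control = toy_sets
        assert pm.tss(functional, control, identity1, gaps21) == pytest.approx(
            pm.tss(control, functional, identity1, gaps21)
        )

    def test_empty_and_singleton_errors(self, identity1, gaps21):
        single = pm.PeptideSet([pm.PeptideRecord("AAA", "p")])
        with pytest.raises(ValueError, match="empty"):
            pm.tss(pm.PeptideSet([]), single, identity1, gaps21)
        with pytest.raises(ValueError, match="at least 2"):
            pm.tss(single, single, identity1, gaps21)

    def test_uniform_matrix_shift_changes_tss(self, gaps21, toy_sets):
        # a constant added to every entry must NOT cancel out of the TSS:
        # guards against accidental re-normalization of matrices
        functional, control = toy_sets
        base = pm.identity_matrix(match=2, mismatch=0)
        shifted = base.with_scores(base.scores + 1)
        assert pm.tss(functional, control, base, gaps21) != pytest.approx(
            pm.tss(functional, control, shifted, gaps21)
        )


class TestObjectives:
    def test_difference_and_quotient_arithmetic(self):
        components = TSSComponents(ff=4, fn=2, nn=3, nf=1)
        assert components.combine("diff2") == 2
        assert components.combine("diff4") == 4
        assert components.combine("quotient") == 6

    def test_quotient_zero_denominator_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            TSSComponents(ff=4, fn=0, nn=3, nf=1).combine("quotient")

    def test_diff4_invariant_under_label_swap(self, identity1, gaps21, toy_sets):
        # the four terms map onto each other when the sets trade roles, so
        # the objective is label-symmetric (diff2, by contrast, is not)
        functional, control = toy_sets
        forward = pm.tssf(functional, control, identity1, gaps21, variant="diff4")
        backward = pm.tssf(control, functional, identity1, gaps21, variant="diff4")
        assert forward == pytest.approx(backward)

    def test_margin3_order_statistics(self, identity1, gaps21, toy_sets, monkeypatch):
        # stub the per-peptide scores: functional {1..5}, control {0,.5,.6,.7,.8};
        # after pooled min-max normalization the margin is (3 - 0.6)/5 = 0.48
        functional, control = toy_sets
        f5 = pm.PeptideSet(functional.records + [pm.PeptideRecord("QQQQQQQQ", "F5")])
        n5 = pm.PeptideSet(control.records + [pm.PeptideRecord("MMMMMMMM", "N5")])
        stub_scores = iter([1, 2, 3, 4, 5, 0, 0.5, 0.6, 0.7, 0.8])
        monkeypatch.setattr(
            pm.similarity, "loo_score", lambda *args, **kwargs: next(stub_scores)
        )
        assert pm.tssf(f5, n5, identity1, gaps21, variant="margin3") == pytest.approx(0.48)

    def test_margin3_needs_three_records(self, identity1, gaps21):
        two = pm.PeptideSet([pm.PeptideRecord("AAA", "a"), pm.PeptideRecord("CCC", "b")])
        with pytest.raises(ValueError, match="3"):
            pm.tssf(two, two, identity1, gaps21, variant="margin3")

    def test_unknown_variant_rejected(self, identity1, gaps21, toy_sets):
        functional, control = toy_sets
        with pytest.raises(ValueError, match="variant"):
            pm.tssf(functional, control, identity1, gaps21, variant="bogus")


class TestLooScore:
    def test_same_protein_records_excluded_from_both_sets(self, identity1, gaps21):
        functional = pm.PeptideSet(
            [
                pm.PeptideRecord("QQQQ", "P1"),
                pm.PeptideRecord("QQQP", "P1"),
                pm.PeptideRecord("QQPP", "P1"),
                pm.PeptideRecord("PPPP", "P2"),
            ]
        )
        control = pm.PeptideSet(
            [pm.PeptideRecord("AAAA", "P1"), pm.PeptideRecord("CCCC", "P3")]
        )
        # scoring any P1 peptide must compare only against P2 functionals
        # and P3 controls; with an identity matrix this is computable directly
        query = functional[0]
        expected = pm.tss(
            pm.PeptideSet([query]),
            pm.PeptideSet([functional[3]]),
            identity1,
            gaps21,
            same_set=False,
        ) - pm.tss(
            pm.PeptideSet([query]),
            pm.PeptideSet([control[1]]),
            identity1,
            gaps21,
            same_set=False,
        )
        assert pm.loo_score(query, functional, control, identity1, gaps21) == pytest.approx(
            expected
        )

    def test_query_similar_to_functional_scores_positive(self, gaps21):
        matrix = pm.identity_matrix(match=5, mismatch=-2)
        functional = pm.PeptideSet(
            [pm.PeptideRecord("QPQPQPQP", "F1"), pm.PeptideRecord("QPQPQPQP", "F2")]
        )
        control = pm.PeptideSet(
            [pm.PeptideRecord("AILVAILV", "N1"), pm.PeptideRecord("GMWCGMWC", "N2")]
        )
        assert pm.loo_score(functional[0], functional, control, matrix, gaps21) > 0

    def test_exclusion_emptying_a_set_raises(self, identity1, gaps21):
        functional = pm.PeptideSet(
            [pm.PeptideRecord("QQQQ", "P1"), pm.PeptideRecord("QQQP", "P1")]
        )
        control = pm.PeptideSet(
            [pm.PeptideRecord("AAAA", "P2"), pm.PeptideRecord("CCCC", "P3")]
        )
        with pytest.raises(ValueError, match="P1"):
            pm.loo_score(functional[0], functional, control, identity1, gaps21)


class TestContentScore:
    def test_identical_composition_scores_zero(self):
        functional = pm.PeptideSet(
            [pm.PeptideRecord("QPAG", "F1"), pm.PeptideRecord("GAPQ", "F2")]
        )
        control = pm.PeptideSet(
            [pm.PeptideRecord("APQG", "N1"), pm.PeptideRecord("QGPA", "N2")]
        )
        query = pm.PeptideRecord("QQPG", "X1")
        assert pm.content_score(query, functional, control) == pytest.approx(0.0)

    def test_sign_follows_enrichment(self):
        functional = pm.PeptideSet(
            [pm.PeptideRecord("QQQQQ", "F1"), pm.PeptideRecord("QQQQ", "F2")]
        )
        control = pm.PeptideSet(
            [pm.PeptideRecord("PPPPP", "N1"), pm.PeptideRecord("PPPP", "N2")]
        )
        assert pm.content_score(pm.PeptideRecord("QQ", "X1"), functional, control) > 0
        assert pm.content_score(pm.PeptideRecord("PP", "X2"), functional, control) < 0

    def test_same_protein_exclusion_applied(self):
        functional = pm.PeptideSet(
            [pm.PeptideRecord("QQQQ", "P1"), pm.PeptideRecord("PPPP", "P2")]
        )
        control = pm.PeptideSet(
            [pm.PeptideRecord("AAAA", "N1"), pm.PeptideRecord("CCCC", "N2")]
        )
        query = functional[0]
        # with P1 excluded the functional pool is all P, so a Q query scores
        # as Q-depleted relative to inclusion
        with_exclusion = pm.content_score(query, functional, control)
        without = pm.content_score(query, functional, control, exclude_same_protein=False)
        assert with_exclusion < without


class TestScoreTable:
    def test_min_max_normalization(self):
        records = [pm.PeptideRecord("AA", f"p{i}") for i in range(3)]
        table = pm.ScoreTable(records=records, raw=np.array([1.0, 3.0, 2.0]),
                              labels=["functional"] * 3)
        assert list(table.normalized) == [0.0, 1.0, 0.5]

    def test_constant_scores_map_to_half(self):
        assert list(_normalize(np.array([2.0, 2.0]))) == [0.5, 0.5]

    def test_tsv_round_trip_columns(self, tmp_path):
        records = [pm.PeptideRecord("AA", "p0"), pm.PeptideRecord("CC", "p1")]
        table = pm.ScoreTable(records=records, raw=np.array([0.5, 1.5]),
                              labels=["functional", "control"])
        path = tmp_path / "scores.tsv"
        table.to_tsv(path)
        lines = path.read_text().splitlines()
        assert lines[0].split("\t") == ["protein_id", "sequence", "raw", "normalized", "label"]
        assert len(lines) == 3
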