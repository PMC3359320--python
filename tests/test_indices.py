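"""Coverage/quality percentages, half-up rounding, and the ranking rule."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from equiframe.indices import (
    IndexError_,
    core_concept_coverage,
    core_concept_quality,
    overall_ranking,
    round_half_up,
    summarize_policy,
    vulnerable_group_coverage,
)
from equiframe.lexicon import UNIVERSAL
from equiframe.scoring import ScoreMatrix

from conftest import matrix_from_counts


class TestRounding:
    @pytest.mark.parametrize(
        "value, ndigits, expected",
        [
            (100 * 1 / 12, 1, 8.3),     # 8.333 rounds down, not up
            (100 * 14 / 21, 1, 66.7),
            (100 * 12 / 21, 1, 57.1),
            (100 * 8 / 21, 0, 38.0),
            (100 * 11 / 12, 0, 92.0),   # 91.67 rounds to 92
            (8.35, 1, 8.4),             # half goes up, not to even
            (0.5, 0, 1.0),
        ],
    )
    def test_half_up(self, value, ndigits, expected):
        assert round_half_up(value, ndigits) == expected


class TestCoverageArithmetic:
    @pytest.mark.parametrize(
        "n, precision, expected",
        [(14, 1, 66.7), (21, 0, 100.0), (0, 1, 0.0), (8, 0, 38.0)],
    )
    def test_core_concept_coverage(self, framework, n, precision, expected):
        matrix = matrix_from_counts(framework, 0, n, 0)
        assert core_concept_coverage(matrix, precision=precision) == expected

    @pytest.mark.parametrize(
        "n, precision, expected",
        [(1, 1, 8.3), (11, 0, 92.0), (0, 1, 0.0)],
    )
    def test_vulnerable_group_coverage(self, framework, n, precision, expected):
        matrix = matrix_from_counts(framework, n, max(n, 1) if n else 0, 0)
        assert vulnerable_group_coverage(matrix, precision=precision) == expected

    @pytest.mark.parametrize(
        "n_q, precision, expected", [(12, 1, 57.1), (0, 1, 0.0)]
    )
    def test_core_concept_quality(self, framework, n_q, precision, expected):
        matrix = matrix_from_counts(framework, 0, max(n_q, 3), n_q)
        assert core_concept_quality(matrix, precision=precision) == expected

    def test_all_concepts_at_two_score_zero_quality(self, framework):
        cells = {(cid, UNIVERSAL): 2 for cid in framework.concept_ids}
        matrix = ScoreMatrix(doc_id="d", framework=framework, cells=cells)
        assert core_concept_quality(matrix) == 0.0
        assert core_concept_coverage(matrix) == 100.0

    def test_universal_counts_for_concepts_not_groups(self, framework):
        cells = {("access", UNIVERSAL): 3}
        matrix = ScoreMatrix(doc_id="d", framework=framework, cells=cells)
        assert core_concept_coverage(matrix) > 0
        assert vulnerable_group_coverage(matrix) == 0.0

    def test_country_specific_extras_do_not_change_base_12(self, framework):
        from equiframe.lexicon import load_framework

        cfg = framework.to_dict()
        cfg["vulnerable_groups"].append(
            {"id": "extra", "name": "Extra", "key_phrases": ["nomadic herders"],
             "country_specific": True}
        )
        lex = load_framework(cfg, strict=True)
        cells = {("access", "extra"): 3, ("privacy", "disabled"): 1}
        matrix = ScoreMatrix(doc_id="d", framework=lex, cells=cells)
        assert vulnerable_group_coverage(matrix) == pytest.approx(100 / 12)
        assert matrix.mentioned_extra_groups == {"extra"}

    def test_bad_denominator(self, framework):
        matrix = matrix_from_counts(framework, 0, 1, 0)
        with pytest.raises(IndexError_):
            core_concept_coverage(matrix, 0)


class TestOverallRanking:
    @pytest.mark.parametrize(
        "triple, expected",
        [
            ((8.3, 66.7, 57.1), "Moderate"),
            ((83, 90, 62), "High"),
            ((25, 24, 24), "Low"),
            ((50, 50, 50), "High"),       # thresholds are inclusive
            ((50, 50, 49.9), "Moderate"),
            ((0, 0, 0), "Low"),
            ((49.9, 50, 0), "Low"),
        ],
    )
    def test_rule(self, triple, expected):
        assert overall_ranking(*triple) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError_):
            overall_ranking(101, 0, 0)
        with pytest.raises(IndexError_):
            overall_ranking(0, -1, 0)

    @given(
        vg=st.floats(0, 100), cc=st.floats(0, 100), q=st.floats(0, 100),
        bump=st.floats(0, 50),
    )
    def test_monotone_in_each_index(self, vg, cc, q, bump):
        order = {"Low": 0, "Moderate": 1, "High": 2}
        base = order[overall_ranking(vg, cc, q)]
        assert order[overall_ranking(min(vg + bump, 100), cc, q)] >= base
        assert order[overall_ranking(vg, min(cc + bump, 100), q)] >= base
        assert order[overall_ranking(vg, cc, min(q + bump, 100))] >= base


class TestSummarizePolicy:
    def test_table_row_shape(self, framework):
        matrix = matrix_from_counts(framework, 1, 14, 12)
        s = summarize_policy(matrix)
        assert s.rounded() == (8.3, 66.7, 57.1)
        assert s.ranking == "Moderate"
        assert s.counts == (14, 1, 12)
        assert s.denominators == (21, 12)

    def test_empty_matrix(self, framework):
        s = summarize_policy(matrix_from_counts(framework, 0, 0, 0))
        assert (s.vg_coverage_pct, s.cc_coverage_pct, s.cc_quality_pct) == (0, 0, 0)
        assert s.ranking == "Low"

    def test_ranking_uses_full_precision_not_display(self, framework):
        # 10/21 = 47.6% displays below 50 at any precision; 11/21 = 52.4%
        s = summarize_policy(matrix_from_counts(framework, 12, 21, 11), precision=0)
        assert s.rounded() == (100.0, 100.0, 52.0)
        assert s.ranking == "High"

    def test_random_matrices_match_recount_oracle(self, framework):
        rng = random.Random(99)
        base = set(framework.base_group_ids)
        for _ in range(200):
            cells = {}
            for _ in range(rng.randint(0, 30)):
                cells[(rng.choice(framework.concept_ids),
                       rng.choice(framework.column_ids))] = rng.randint(1, 4)
            matrix = ScoreMatrix(doc_id="d", framework=framework, cells=cells)
            s = summarize_policy(matrix)
            # brute-force recount from the raw cells
            concepts = {c for c, _ in cells}
            groups = {g for _, g in cells if g in base}
            best = {}
            for (c, _), q in cells.items():
                best[c] = max(best.get(c, 0), q)
            n_q = sum(1 for q in best.values() if q >= 3)
            assert s.counts == (len(concepts), len(groups), n_q)
            assert s.vg_coverage_pct == pytest.approx(100 * len(groups) / 12)
            assert s.cc_coverage_pct == pytest.approx(100 * len(concepts) / 21)
            assert s.cc_quality_pct == pytest.approx(100 * n_q / 21)
            assert s.cc_quality_pct <= s.cc_coverage_pct

    def test_exclude_na_shrinks_denominator(self, framework):
        cells = {("access", UNIVERSAL): 3}
        matrix = ScoreMatrix(doc_id="d", framework=framework, cells=cells,
                             na_concepts=frozenset({"liberty"}))
        default = summarize_policy(matrix)
        excl = summarize_policy(matrix, exclude_na=True)
        assert default.denominators[0] == 21
        assert excl.denominators[0] == 20
        assert excl.cc_coverage_pct == pytest.approx(100 / 20)
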