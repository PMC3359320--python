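"""Dual-rater agreement, Cohen's kappa, and consensus building."""

import random

import pytest

from equiframe.lexicon import UNIVERSAL
from equiframe.reliability import (
    NA_COLUMN,
    ReliabilityError,
    build_consensus,
    compare_raters,
    read_resolutions,
    write_discrepancies,
)
from equiframe.scoring import Annotation, build_matrix
from equiframe.synthetic import generate_document, plan_from_counts


def annot(concept, column, quality, rater="a", doc="d", evidence=""):
    return Annotation(rater_id=rater, doc_id=doc, concept_id=concept,
                      column_id=column, quality=quality, evidence=evidence)


def rater_set(outcomes, rater):
    return [annot(c, g, q, rater=rater) for (c, g), q in outcomes.items()]


FOUR_CELLS = [("access", "disabled"), ("privacy", "youth"),
              ("autonomy", "aged"), ("prevention", "disabled")]


class TestCompareRaters:
    def test_identical_sets(self, framework):
        a = rater_set(dict(zip(FOUR_CELLS, [1, 2, 3, 4])), "a")
        b = rater_set(dict(zip(FOUR_CELLS, [1, 2, 3, 4])), "b")
        cmp_ = compare_raters(a, b, framework)
        assert cmp_.cell_agreement == 1.0
        assert cmp_.kappa == 1.0
        assert cmp_.discrepancies == ()

    def test_disjoint_sets_zero_agreement(self, framework):
        a = [annot("access", "disabled", 2, rater="a")]
        b = [annot("privacy", "youth", 3, rater="b")]
        cmp_ = compare_raters(a, b, framework)
        assert cmp_.n_compared == 2
        assert cmp_.cell_agreement == 0.0
        assert len(cmp_.discrepancies) == 2

    def test_kappa_closed_form_2x2(self, framework):
        # outcomes over 4 shared cells: A = 1,1,1,2 ; B = 1,1,2,2
        # po = 3/4; pe = .75*.5 + .25*.5 = .5; kappa = (0.75-0.5)/(1-0.5) = 0.5
        a = rater_set(dict(zip(FOUR_CELLS, [1, 1, 1, 2])), "a")
        b = rater_set(dict(zip(FOUR_CELLS, [1, 1, 2, 2])), "b")
        cmp_ = compare_raters(a, b, framework)
        assert cmp_.cell_agreement == pytest.approx(0.75)
        assert cmp_.kappa == pytest.approx(0.5)

    def test_symmetric(self, framework):
        a = rater_set(dict(zip(FOUR_CELLS, [1, 2, 3, 4])), "a")
        b = rater_set({("access", "disabled"): 2, ("quality", UNIVERSAL): 1}, "b")
        ab = compare_raters(a, b, framework)
        ba = compare_raters(b, a, framework)
        assert ab.cell_agreement == ba.cell_agreement
        assert ab.kappa == pytest.approx(ba.kappa)

    def test_perturbed_copy_agreement(self, framework):
        plan = plan_from_counts(framework, n_groups=4, n_concepts=8, n_quality34=3)
        _, truth, _ = generate_document(plan, framework)
        a = build_matrix(truth, framework)
        n = len(a.cells)
        assert n == 8
        k = 2
        rng = random.Random(1)
        flipped = dict(a.cells)
        for cell in rng.sample(sorted(flipped), k):
            flipped[cell] = flipped[cell] % 4 + 1  # guaranteed different
        set_a = rater_set(a.cells, "a")
        set_b = rater_set(flipped, "b")
        cmp_ = compare_raters(set_a, set_b, framework)
        assert cmp_.n_compared == n
        assert cmp_.cell_agreement == pytest.approx((n - k) / n)

    def test_na_vs_scored_surfaces_as_discrepancies(self, framework):
        a = [annot("liberty", "", None, rater="a")]
        b = [annot("liberty", UNIVERSAL, 2, rater="b")]
        cmp_ = compare_raters(a, b, framework)
        cells = {(d.concept_id, d.column_id) for d in cmp_.discrepancies}
        assert cells == {("liberty", NA_COLUMN), ("liberty", UNIVERSAL)}

    def test_full_grid_counts_shared_absences(self, framework):
        a = [annot("access", "disabled", 2, rater="a")]
        b = [annot("access", "disabled", 2, rater="b")]
        cmp_ = compare_raters(a, b, framework, full_grid=True)
        assert cmp_.n_compared == 21 * 14  # 12 groups + Universal + NA pseudo-col
        assert cmp_.cell_agreement == 1.0

    def test_mismatched_documents_rejected(self, framework):
        with pytest.raises(ReliabilityError, match="different documents"):
            compare_raters([annot("access", UNIVERSAL, 1, doc="d1")],
                           [annot("access", UNIVERSAL, 1, doc="d2")], framework)


class TestConsensus:
    def test_no_discrepancies_union_passes_through(self, framework):
        a = rater_set(dict(zip(FOUR_CELLS, [1, 2, 3, 4])), "a")
        b = rater_set(dict(zip(FOUR_CELLS, [1, 2, 3, 4])), "b")
        merged = build_consensus(a, b, {}, framework=framework)
        assert {(m.concept_id, m.column_id): m.quality for m in merged} == dict(
            zip(FOUR_CELLS, [1, 2, 3, 4])
        )
        assert all(m.rater_id == "consensus" for m in merged)

    def test_resolution_takes_stated_choice(self, framework):
        a = [annot("access", "disabled", 3, rater="a", evidence="A said")]
        b = [annot("access", "disabled", 1, rater="b", evidence="B said")]
        merged = build_consensus(a, b, {("access", "disabled"): "a"},
                                 framework=framework)
        assert len(merged) == 1
        assert merged[0].quality == 3
        assert merged[0].evidence == "A said"

    def test_unresolved_discrepancy_lists_items(self, framework):
        a = [annot("access", "disabled", 3, rater="a")]
        b = [annot("access", "disabled", 1, rater="b")]
        with pytest.raises(ReliabilityError, match=r"access.*disabled"):
            build_consensus(a, b, {}, framework=framework)

    def test_scripted_resolutions_match_expectation(self, framework):
        a = rater_set(dict(zip(FOUR_CELLS, [1, 2, 3, 4])), "a")
        b = rater_set(dict(zip(FOUR_CELLS, [2, 2, 1, 4])), "b")
        resolutions = {FOUR_CELLS[0]: "b", FOUR_CELLS[2]: 2}
        merged = build_consensus(a, b, resolutions, framework=framework)
        got = {(m.concept_id, m.column_id): m.quality for m in merged}
        assert got == dict(zip(FOUR_CELLS, [2, 2, 2, 4]))

    def test_absent_resolution_drops_cell(self, framework):
        a = [annot("access", "disabled", 3, rater="a")]
        b = []
        merged = build_consensus(a, b, {("access", "disabled"): "absent"},
                                 framework=framework)
        assert merged == []

    def test_discrepancy_report_roundtrip(self, framework, tmp_path):
        a = [annot("access", "disabled", 3, rater="a")]
        b = [annot("access", "disabled", 1, rater="b")]
        cmp_ = compare_raters(a, b, framework)
        path = tmp_path / "disc.csv"
        write_discrepancies(cmp_, path)
        # simulate the adjudication meeting filling the resolution column
        text = path.read_text().splitlines()
        text[1] = text[1].rstrip(",") + ",a"
        path.write_text("\n".join(text))
        resolutions = read_resolutions(path)
        assert resolutions == {("access", "disabled"): "a"}
        merged = build_consensus(a, b, resolutions, framework=framework)
        assert merged[0].quality == 3
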