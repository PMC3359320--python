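"""Dual-rater comparison, chance-corrected agreement, and consensus.

Every policy document is assessed by two independent raters; differences are
resolved by discussion into a consensus set.  This module quantifies the
agreement before that discussion and enforces that every discrepancy gets an
explicit resolution — there is no silent auto-merge.

Cells are compared on the outcome categories {absent, 1, 2, 3, 4, NA} over
the union of cells either rater touched (an option widens this to the full
concept x column grid; the union default avoids inflating agreement through
shared absences).  A concept-level N/A is carried as a pseudo-cell
(concept, "__NA__") so that "rater A says not applicable, rater B scored the
row" surfaces as discrepancies rather than disappearing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .lexicon import FrameworkLexicon
from .scoring import Annotation, ScoringError, build_matrix

#: Pseudo-column carrying a concept-level not-applicable judgment.
NA_COLUMN = "__NA__"

ABSENT = "absent"

Cell = tuple[str, str]


class ReliabilityError(ValueError):
    """Raised for mismatched documents or unresolved discrepancies."""


@dataclass(frozen=True)
class Discrepancy:
    concept_id: str
    column_id: str
    outcome_a: str  # "1".."4", "NA", or "absent"
    outcome_b: str


@dataclass(frozen=True)
class RaterComparison:
    doc_id: str
    rater_a: str
    rater_b: str
    cell_agreement: float
    kappa: float
    discrepancies: tuple[Discrepancy, ...]
    n_compared: int

    def to_frame(self) -> pd.DataFrame:
        """Discrepancy report, doubling as the resolutions template."""
        return pd.DataFrame(
            [
                {
                    "concept_id": d.concept_id,
                    "column_id": d.column_id,
                    "rater_a": d.outcome_a,
                    "rater_b": d.outcome_b,
                    "resolution": "",
                }
                for d in self.discrepancies
            ],
            columns=["concept_id", "column_id", "rater_a", "rater_b", "resolution"],
        )


def _outcomes(
    annotations: list[Annotation], framework: FrameworkLexicon
) -> dict[Cell, str]:
    """One rater's outcome per touched cell, after max aggregation."""
    matrix = build_matrix(annotations, framework)
    out: dict[Cell, str] = {cell: str(q) for cell, q in matrix.cells.items()}
    for cid in matrix.na_concepts:
        out[(cid, NA_COLUMN)] = "NA"
    return out


def _rater_of(annotations: list[Annotation]) -> str:
    ids = {a.rater_id for a in annotations}
    if len(ids) > 1:
        raise ReliabilityError(f"annotation set mixes raters: {sorted(ids)}")
    return ids.pop() if ids else ""


def compare_raters(
    annots_a: list[Annotation],
    annots_b: list[Annotation],
    framework: FrameworkLexicon,
    *,
    full_grid: bool = False,
) -> RaterComparison:
    """Compare two raters' annotation sets for one document.

    Agreement is matching cells / compared cells; kappa is Cohen's kappa
    over the same outcome sequences.  Symmetric in its two arguments.
    With ``full_grid`` the universe is every concept x column cell (shared
    absences then count as agreement).
    """
    docs = {a.doc_id for a in annots_a + annots_b}
    if len(docs) > 1:
        raise ReliabilityError(f"raters annotated different documents: {sorted(docs)}")
    doc_id = docs.pop() if docs else ""

    oa = _outcomes(annots_a, framework)
    ob = _outcomes(annots_b, framework)
    if full_grid:
        universe = [
            (cid, col)
            for cid in framework.concept_ids
            for col in framework.column_ids + (NA_COLUMN,)
        ]
    else:
        universe = sorted(set(oa) | set(ob))

    la = [oa.get(cell, ABSENT) for cell in universe]
    lb = [ob.get(cell, ABSENT) for cell in universe]
    n = len(universe)
    matches = sum(a == b for a, b in zip(la, lb))
    agreement = matches / n if n else 1.0

    if n == 0 or agreement == 1.0:
        kappa = 1.0
    else:
        kappa = float(cohen_kappa_score(la, lb))
        if math.isnan(kappa):
            kappa = 0.0
    discrepancies = tuple(
        Discrepancy(cid, col, a, b)
        for (cid, col), a, b in zip(universe, la, lb)
        if a != b
    )
    return RaterComparison(
        doc_id=doc_id,
        rater_a=_rater_of(annots_a),
        rater_b=_rater_of(annots_b),
        cell_agreement=agreement,
        kappa=kappa,
        discrepancies=discrepancies,
        n_compared=n,
    )


def _evidence_for(annotations: list[Annotation], cell: Cell) -> str:
    for a in annotations:
        if not a.is_na and (a.concept_id, a.column_id) == cell and a.evidence:
            return a.evidence
    return ""


def build_consensus(
    annots_a: list[Annotation],
    annots_b: list[Annotation],
    resolutions: dict[Cell, object] | None = None,
    *,
    framework: FrameworkLexicon,
    rater_id: str = "consensus",
) -> list[Annotation]:
    """Merge two raters' sets into one consensus set.

    Agreed cells pass through; each discrepant cell must have an entry in
    ``resolutions``: ``"a"`` or ``"b"`` (take that rater's outcome), an
    explicit quality 1-4, ``"NA"``, or ``"absent"`` (drop the cell).  Any
    unresolved discrepancy raises :class:`ReliabilityError` listing what
    remains.
    """
    resolutions = dict(resolutions or {})
    comparison = compare_raters(annots_a, annots_b, framework)
    unresolved = [
        d for d in comparison.discrepancies
        if (d.concept_id, d.column_id) not in resolutions
    ]
    if unresolved:
        raise ReliabilityError(
            "unresolved discrepancies: "
            + "; ".join(f"({d.concept_id}, {d.column_id}): "
                        f"A={d.outcome_a} B={d.outcome_b}" for d in unresolved)
        )

    oa = _outcomes(annots_a, framework)
    ob = _outcomes(annots_b, framework)
    doc_id = (annots_a + annots_b)[0].doc_id if (annots_a or annots_b) else ""

    out: list[Annotation] = []
    for cell in sorted(set(oa) | set(ob)):
        a_out, b_out = oa.get(cell, ABSENT), ob.get(cell, ABSENT)
        if a_out == b_out:
            outcome = a_out
            evidence = _evidence_for(annots_a, cell) or _evidence_for(annots_b, cell)
        else:
            choice = resolutions[cell]
            if choice == "a":
                outcome = a_out
            elif choice == "b":
                outcome = b_out
            elif isinstance(choice, int):
                outcome = str(choice)
            else:
                outcome = str(choice)
            source = annots_a if outcome == a_out else annots_b
            evidence = _evidence_for(source, cell)
        if outcome == ABSENT:
            continue
        concept_id, column_id = cell
        out.append(
            Annotation(
                rater_id=rater_id,
                doc_id=doc_id,
                concept_id=concept_id,
                column_id=column_id,
                quality=None if outcome == "NA" else int(outcome),
                evidence=evidence,
            )
        )
    # A consensus must itself be a valid single-rater set (N/A vs score clash
    # across cells of one concept is still possible via bad resolutions).
    try:
        build_matrix(out, framework)
    except ScoringError as err:
        raise ReliabilityError(f"resolutions produce an invalid set: {err}") from err
    return out


def write_discrepancies(comparison: RaterComparison, path: str | Path) -> None:
    comparison.to_frame().to_csv(path, index=False)


def read_resolutions(path: str | Path) -> dict[Cell, object]:
    """Read a filled-in discrepancy report back as a resolutions mapping."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out: dict[Cell, object] = {}
    for row in df.itertuples(index=False):
        res = str(row.resolution).strip()
        if not res:
            continue
        value: object
        if res in ("a", "b", "NA", ABSENT):
            value = res
        else:
            value = int(res)
        out[(row.concept_id, row.column_id)] = value
    return out
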