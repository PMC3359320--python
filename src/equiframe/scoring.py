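"""Rater annotations and the concept x (group + Universal) score matrix.

Each annotation rates the quality of commitment to one core concept, in one
column (a vulnerable group or the Universal column), on the 1-4 scale:

    1  concept only mentioned
    2  concept mentioned and explained
    3  specific policy actions identified to address the concept
    4  intention to monitor the concept expressed

A concept irrelevant to the document context is marked not applicable —
concept-level, i.e. the whole row.  When several references to a concept
land in one cell, the top quality score is kept (the max rule).  Mixing N/A
and scored annotations for one concept is a rater inconsistency and is an
error here, not silently resolved: that situation belongs to the
reliability workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .lexicon import UNIVERSAL, FrameworkLexicon

QUALITY_LEVELS = (1, 2, 3, 4)

#: Sentinel for a concept marked not applicable (stored as "NA" in CSV).
NOT_APPLICABLE = None


class ScoringError(ValueError):
    """Raised for annotations that violate the framework or the N/A rule."""


@dataclass(frozen=True)
class Annotation:
    """One rater's judgment for one (concept, column) cell."""

    rater_id: str
    doc_id: str
    concept_id: str
    column_id: str  # group_id or UNIVERSAL
    quality: int | None  # 1-4, or None for not-applicable
    evidence: str = ""
    sentence_index: int | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and self.quality not in QUALITY_LEVELS:
            raise ScoringError(
                f"quality must be in {QUALITY_LEVELS} or N/A, got {self.quality!r}"
            )

    @property
    def is_na(self) -> bool:
        return self.quality is None


@dataclass(frozen=True)
class ScoreMatrix:
    """Best quality score per (concept, column) cell for one document.

    ``cells`` maps (concept_id, column_id) to the max quality among the
    contributing annotations; ``na_concepts`` holds concepts the rater(s)
    judged not applicable to the document context.
    """

    doc_id: str
    framework: FrameworkLexicon
    cells: dict[tuple[str, str], int] = field(default_factory=dict)
    na_concepts: frozenset[str] = frozenset()
    evidence: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "na_concepts", frozenset(self.na_concepts))
        valid_cols = set(self.framework.column_ids)
        valid_concepts = set(self.framework.concept_ids)
        for (cid, col), q in self.cells.items():
            if cid not in valid_concepts:
                raise ScoringError(f"unknown concept_id {cid!r}")
            if col not in valid_cols:
                raise ScoringError(f"unknown column_id {col!r}")
            if q not in QUALITY_LEVELS:
                raise ScoringError(f"cell ({cid}, {col}) has invalid quality {q!r}")
        overlap = self.na_concepts & {cid for cid, _ in self.cells}
        if overlap:
            raise ScoringError(
                f"concepts both scored and marked N/A: {sorted(overlap)}"
            )

    def concept_best_score(self, concept_id: str) -> int | None:
        """Max score across all columns for a concept; None if unmentioned."""
        if concept_id not in self.framework.concept_ids:
            raise ScoringError(f"unknown concept_id {concept_id!r}")
        scores = [q for (cid, _), q in self.cells.items() if cid == concept_id]
        return max(scores) if scores else None

    @property
    def mentioned_concepts(self) -> set[str]:
        """Concepts with at least one scored cell (Universal column included)."""
        return {cid for cid, _ in self.cells}

    @property
    def mentioned_base_groups(self) -> set[str]:
        """Base (non-country-specific) groups with at least one scored cell."""
        base = set(self.framework.base_group_ids)
        return {col for _, col in self.cells if col in base}

    @property
    def mentioned_extra_groups(self) -> set[str]:
        """Country-specific extra groups with at least one scored cell."""
        extra = set(self.framework.group_ids) - set(self.framework.base_group_ids)
        return {col for _, col in self.cells if col in extra}

    def to_dataframe(self) -> pd.DataFrame:
        """Concepts as rows, groups + Universal as columns; NaN = unmentioned."""
        df = pd.DataFrame(
            index=list(self.framework.concept_ids),
            columns=list(self.framework.column_ids),
            dtype="float64",
        )
        for (cid, col), q in self.cells.items():
            df.loc[cid, col] = q
        return df

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        out = df.map(lambda v: "" if pd.isna(v) else str(int(v)))
        for cid in self.na_concepts:
            out.loc[cid, :] = "NA"
        out.to_csv(path, index_label="concept_id")


def build_matrix(
    annotations: list[Annotation], framework: FrameworkLexicon
) -> ScoreMatrix:
    """Aggregate annotations for one document into a :class:`ScoreMatrix`.

    Each cell takes the maximum quality among its annotations (order- and
    duplication-independent).  Concepts with only N/A annotations land in
    ``na_concepts``; a concept with both N/A and scored annotations raises
    :class:`ScoringError` listing the offenders.
    """
    doc_ids = {a.doc_id for a in annotations}
    if len(doc_ids) > 1:
        raise ScoringError(f"annotations span multiple documents: {sorted(doc_ids)}")
    doc_id = doc_ids.pop() if doc_ids else ""

    valid_concepts = set(framework.concept_ids)
    valid_cols = set(framework.column_ids)
    for a in annotations:
        if a.concept_id not in valid_concepts:
            raise ScoringError(f"unknown concept_id {a.concept_id!r} in annotation")
        if not a.is_na and a.column_id not in valid_cols:
            raise ScoringError(f"unknown column_id {a.column_id!r} in annotation")

    na = {a.concept_id for a in annotations if a.is_na}
    scored = {a.concept_id for a in annotations if not a.is_na}
    mixed = na & scored
    if mixed:
        offenders = [a for a in annotations if a.concept_id in mixed]
        raise ScoringError(
            f"concepts with both N/A and scored annotations: {sorted(mixed)}; "
            f"annotations: {offenders}"
        )

    cells: dict[tuple[str, str], int] = {}
    evidence: dict[tuple[str, str], list[str]] = {}
    for a in annotations:
        if a.is_na:
            continue
        key = (a.concept_id, a.column_id)
        cells[key] = max(cells.get(key, 0), a.quality)
        if a.evidence:
            evidence.setdefault(key, []).append(a.evidence)
    return ScoreMatrix(
        doc_id=doc_id,
        framework=framework,
        cells=cells,
        na_concepts=frozenset(na),
        evidence={k: tuple(v) for k, v in evidence.items()},
    )


# -- annotation CSV I/O --------------------------------------------------

_ANNOT_COLUMNS = ["rater_id", "doc_id", "concept_id", "column_id", "quality",
                  "evidence", "sentence_index"]


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rater_id": a.rater_id,
                "doc_id": a.doc_id,
                "concept_id": a.concept_id,
                "column_id": a.column_id,
                "quality": "NA" if a.is_na else a.quality,
                "evidence": a.evidence,
                "sentence_index": a.sentence_index,
            }
            for a in annotations
        ],
        columns=_ANNOT_COLUMNS,
    )


def write_annotations(annotations: list[Annotation], path: str | Path) -> None:
    annotations_to_frame(annotations).to_csv(path, index=False)


def read_annotations(path: str | Path) -> list[Annotation]:
    df = pd.read_csv(path, dtype=str).fillna("")
    missing = set(_ANNOT_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ScoringError(f"annotation file missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        q_raw = str(row.quality).strip()
        quality = None if q_raw.upper() in ("NA", "N/A", "") else int(float(q_raw))
        sent = getattr(row, "sentence_index", "")
        out.append(
            Annotation(
                rater_id=row.rater_id,
                doc_id=row.doc_id,
                concept_id=row.concept_id,
                column_id=row.column_id,
                quality=quality,
                evidence=getattr(row, "evidence", ""),
                sentence_index=int(float(sent)) if str(sent).strip() else None,
            )
        )
    return out
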