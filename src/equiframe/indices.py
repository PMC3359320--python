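"""Summary indices: coverage, quality, and the High/Moderate/Low ranking.

Three percentages summarize a document's score matrix:

* core concept coverage   — concepts mentioned at least once / 21
* vulnerable group coverage — base groups mentioned at least once / 12
  (the Universal column and country-specific extras are excluded)
* core concept quality    — concepts whose best score is 3 or 4 / 21

The overall summary ranking counts how many of the three reach the 50%
criterion: High on all three, Moderate on exactly two, Low otherwise.
Thresholding always uses full-precision values; rounding (half-up, at a
configurable display precision) only affects what is printed.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .scoring import ScoreMatrix

RANKINGS = ("High", "Moderate", "Low")

#: Best-score threshold for the quality index: action (3) or monitoring (4).
QUALITY_THRESHOLD = 3

#: Criterion each index is tested against for the overall ranking, percent.
RANKING_THRESHOLD = 50.0


class IndexError_(ValueError):
    """Raised for invalid denominators or out-of-range percentages."""


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 8.35 -> 8.4, 91.67 -> 92 at 0 digits)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: int, denominator: int, precision: int | None) -> float:
    if denominator <= 0:
        raise IndexError_(f"denominator must be positive, got {denominator}")
    value = 100.0 * numerator / denominator
    return value if precision is None else round_half_up(value, precision)


def core_concept_coverage(
    matrix: ScoreMatrix,
    denominator: int | None = None,
    *,
    precision: int | None = None,
) -> float:
    """Percent of concepts mentioned at least once (Universal column counts).

    ``denominator`` defaults to the framework's concept count (21).
    ``precision=None`` returns the full-precision value; an integer applies
    half-up rounding to that many decimals.
    """
    denom = len(matrix.framework.concepts) if denominator is None else denominator
    return _pct(len(matrix.mentioned_concepts), denom, precision)


def vulnerable_group_coverage(
    matrix: ScoreMatrix,
    denominator: int | None = None,
    *,
    precision: int | None = None,
) -> float:
    """Percent of base vulnerable groups mentioned at least once.

    Universal-column mentions and country-specific extra groups do not count
    toward the numerator, and extras never enter the denominator (default:
    the 12 base groups).
    """
    denom = len(matrix.framework.base_groups) if denominator is None else denominator
    return _pct(len(matrix.mentioned_base_groups), denom, precision)


def core_concept_quality(
    matrix: ScoreMatrix,
    denominator: int | None = None,
    *,
    precision: int | None = None,
) -> float:
    """Percent of concepts whose best score is 3 or 4 (action or monitoring)."""
    denom = len(matrix.framework.concepts) if denominator is None else denominator
    n = sum(
        1
        for cid in matrix.framework.concept_ids
        if (matrix.concept_best_score(cid) or 0) >= QUALITY_THRESHOLD
    )
    return _pct(n, denom, precision)


def overall_ranking(
    vg_pct: float,
    cc_pct: float,
    quality_pct: float,
    *,
    threshold: float = RANKING_THRESHOLD,
) -> str:
    """High if all three indices meet the criterion, Moderate if two, else Low.

    The criterion is inclusive (a score of exactly 50 counts as achieved).
    """
    for name, v in (("vg_pct", vg_pct), ("cc_pct", cc_pct), ("quality_pct", quality_pct)):
        if not 0.0 <= v <= 100.0:
            raise IndexError_(f"{name} out of range [0, 100]: {v}")
    n_met = sum(v >= threshold for v in (vg_pct, cc_pct, quality_pct))
    return "High" if n_met == 3 else "Moderate" if n_met == 2 else "Low"


@dataclass(frozen=True)
class PolicySummary:
    """The three indices plus overall ranking for one policy document.

    Percentages are stored at full precision; ``rounded()`` applies the
    display precision.  ``counts`` is (concepts mentioned, base groups
    mentioned, concepts at quality 3-4) and ``denominators`` the
    (concept, group) denominators used.
    """

    doc_id: str
    vg_coverage_pct: float
    cc_coverage_pct: float
    cc_quality_pct: float
    ranking: str
    counts: tuple[int, int, int]
    denominators: tuple[int, int]
    country: str = ""
    title: str = ""
    precision: int = 1
    na_excluded: bool = False

    def __post_init__(self) -> None:
        for v in (self.vg_coverage_pct, self.cc_coverage_pct, self.cc_quality_pct):
            if not 0.0 <= v <= 100.0:
                raise IndexError_(f"percentage out of range: {v}")
        if self.ranking not in RANKINGS:
            raise IndexError_(f"ranking must be one of {RANKINGS}")

    def rounded(self, precision: int | None = None) -> tuple[float, float, float]:
        """(VG%, CC%, quality%) at the display precision."""
        p = self.precision if precision is None else precision
        return (
            round_half_up(self.vg_coverage_pct, p),
            round_half_up(self.cc_coverage_pct, p),
            round_half_up(self.cc_quality_pct, p),
        )

    def to_row(self) -> dict:
        vg, cc, q = self.rounded()
        return {
            "doc_id": self.doc_id,
            "country": self.country,
            "policy": self.title or self.doc_id,
            "vg_pct": vg,
            "cc_pct": cc,
            "quality_pct": q,
            "ranking": self.ranking,
        }


def summarize_policy(
    matrix: ScoreMatrix,
    *,
    cc_denominator: int | None = None,
    vg_denominator: int | None = None,
    exclude_na: bool = False,
    precision: int = 1,
    threshold: float = RANKING_THRESHOLD,
    country: str = "",
    title: str = "",
) -> PolicySummary:
    """Compute all three indices and the ranking for one score matrix.

    The ranking is decided on full-precision values; ``precision`` only sets
    how ``rounded()`` displays them.  ``exclude_na=True`` removes
    not-applicable concepts from the concept denominators (the default keeps
    the full roster denominator, 21, as the published tables do).
    """
    n_concepts = len(matrix.framework.concepts)
    cc_denom = cc_denominator if cc_denominator is not None else (
        n_concepts - len(matrix.na_concepts) if exclude_na else n_concepts
    )
    vg = vulnerable_group_coverage(matrix, vg_denominator)
    cc = core_concept_coverage(matrix, cc_denom)
    q = core_concept_quality(matrix, cc_denom)
    n_q = sum(
        1
        for cid in matrix.framework.concept_ids
        if (matrix.concept_best_score(cid) or 0) >= QUALITY_THRESHOLD
    )
    vg_denom = vg_denominator if vg_denominator is not None else len(
        matrix.framework.base_groups
    )
    return PolicySummary(
        doc_id=matrix.doc_id,
        vg_coverage_pct=vg,
        cc_coverage_pct=cc,
        cc_quality_pct=q,
        ranking=overall_ranking(vg, cc, q, threshold=threshold),
        counts=(len(matrix.mentioned_concepts), len(matrix.mentioned_base_groups), n_q),
        denominators=(cc_denom, vg_denom),
        country=country,
        title=title,
        precision=precision,
        na_excluded=exclude_na,
    )
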