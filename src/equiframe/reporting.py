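"""Benchmark tables, terminology extracts, and the published reference rows.

A benchmark table collects one country's policy summaries, ordered by
overall ranking (High, Moderate, Low) and, within a ranking, by core
concept quality descending; tallies count the policies per ranking.  The
index rows published for the original four-country study (51 policies) ship
with the package as a reference dataset for demonstrations and checks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .indices import RANKINGS, PolicySummary, overall_ranking
from .lexicon import FrameworkLexicon
from .scoring import Annotation

_RANK_ORDER = {r: i for i, r in enumerate(RANKINGS)}


class ReportingError(ValueError):
    """Raised for empty or inconsistent benchmark input."""


@dataclass(frozen=True)
class BenchmarkTable:
    """One country's ranked policy summaries with High/Moderate/Low tallies."""

    country: str
    rows: tuple[PolicySummary, ...]
    tallies: dict[str, int]

    def __post_init__(self) -> None:
        if sum(self.tallies.values()) != len(self.rows):
            raise ReportingError("tallies must sum to the row count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_row() for s in self.rows])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def benchmark_country(
    summaries: list[PolicySummary],
    *,
    country: str | None = None,
    sort: bool = True,
) -> BenchmarkTable:
    """Collect one country's summaries into a ranked benchmark table.

    All summaries must carry the same country label (or ``country`` must be
    given).  ``sort=False`` keeps input order instead of the default
    ranking-then-quality ordering.
    """
    if not summaries:
        raise ReportingError("benchmark requires at least one policy summary")
    countries = {s.country for s in summaries if s.country}
    if country is None:
        if len(countries) > 1:
            raise ReportingError(f"summaries span multiple countries: {sorted(countries)}")
        country = countries.pop() if countries else ""
    elif countries and countries != {country}:
        raise ReportingError(
            f"summaries for {sorted(countries)} do not match country {country!r}"
        )
    rows = list(summaries)
    if sort:
        rows.sort(key=lambda s: (_RANK_ORDER[s.ranking], -s.cc_quality_pct))
    tallies = Counter(s.ranking for s in rows)
    return BenchmarkTable(
        country=country,
        rows=tuple(rows),
        tallies={r: tallies.get(r, 0) for r in RANKINGS},
    )


def extract_terminologies(
    annotations: list[Annotation], framework: FrameworkLexicon
) -> dict[str, dict[str, list[tuple[str, int]]]]:
    """Group verbatim evidence excerpts by concept and by column.

    Returns ``{"concepts": {...}, "columns": {...}}`` where each inner value
    is a list of (excerpt, count), de-duplicated, preserving first-seen
    (document) order.  Supports the qualitative cross-checking of the actual
    terminology a policy uses.
    """
    by_concept: dict[str, dict[str, int]] = {}
    by_column: dict[str, dict[str, int]] = {}
    for a in annotations:
        if not a.evidence:
            continue
        by_concept.setdefault(a.concept_id, {})
        by_concept[a.concept_id][a.evidence] = by_concept[a.concept_id].get(a.evidence, 0) + 1
        if not a.is_na:
            by_column.setdefault(a.column_id, {})
            by_column[a.column_id][a.evidence] = by_column[a.column_id].get(a.evidence, 0) + 1
    return {
        "concepts": {k: list(v.items()) for k, v in by_concept.items()},
        "columns": {k: list(v.items()) for k, v in by_column.items()},
    }


def load_published_indices() -> pd.DataFrame:
    """The 51 published policy index rows (country, policy, VG%, CC%,
    quality%, ranking) from the original four-country benchmarking study."""
    ref = resources.files("equiframe.data") / "published_indices.csv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def published_summaries(df: pd.DataFrame | None = None) -> list[PolicySummary]:
    """Wrap published (or equally shaped) index rows as summary objects.

    The ranking is recomputed from the printed percentages via the ranking
    rule; counts/denominators are not recoverable from percentages alone and
    are set to zero.
    """
    if df is None:
        df = load_published_indices()
    out = []
    for i, row in df.iterrows():
        vg, cc, q = float(row.vg_pct), float(row.cc_pct), float(row.quality_pct)
        out.append(
            PolicySummary(
                doc_id=f"published-{i:02d}",
                vg_coverage_pct=vg,
                cc_coverage_pct=cc,
                cc_quality_pct=q,
                ranking=overall_ranking(vg, cc, q),
                counts=(0, 0, 0),
                denominators=(21, 12),
                country=str(row.country),
                title=str(row.policy),
            )
        )
    return out
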