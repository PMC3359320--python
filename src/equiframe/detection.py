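"""Key-language mention detection and concept/group pairing.

Detection proposes candidates for human raters to confirm; it never assigns
quality above "mentioned".  Matching is exact-phrase, case-insensitive, on
word boundaries, with no stemming (an optional text normalizer hook can be
supplied).  Pairing joins concept mentions to group or universal mentions
sharing a sentence (configurable to a +/-N sentence window); a concept with
no anchor defaults to the Universal column when ``universal_default`` is on,
mirroring the rule that population-wide concept statements score as
Universal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable

import pandas as pd

from .corpus import PolicyDocument
from .lexicon import UNIVERSAL, FrameworkLexicon, iter_phrases

_CATEGORY_ORDER = {"concept": 0, "group": 1, "universal": 2}


@dataclass(frozen=True)
class MentionCandidate:
    """One proposed mention of a concept, group or universal reference."""

    doc_id: str
    sentence_index: int
    category: str  # "concept" | "group" | "universal"
    target_id: str  # concept_id, group_id, or UNIVERSAL
    matched_phrase: str
    excerpt: str
    char_start: int = -1  # offset of the match within the sentence


@dataclass(frozen=True)
class PairedCandidate:
    """A concept mention anchored to a group or Universal column."""

    doc_id: str
    concept_id: str
    column_id: str  # group_id or UNIVERSAL
    sentence_index: int
    evidence: str


@dataclass(frozen=True)
class PairingResult:
    """Pairs plus any concept mentions left without a group/universal anchor."""

    pairs: tuple[PairedCandidate, ...]
    unpaired: tuple[MentionCandidate, ...]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@lru_cache(maxsize=4096)
def _phrase_pattern(phrase: str) -> re.Pattern:
    # Word boundaries on the phrase edges; internal whitespace matches any run.
    parts = [re.escape(w) for w in phrase.split()]
    return re.compile(r"(?<!\w)" + r"\s+".join(parts) + r"(?!\w)", re.IGNORECASE)


def find_phrase(phrase: str, text: str) -> list[int]:
    """Start offsets of case-insensitive word-boundary matches of ``phrase``."""
    return [m.start() for m in _phrase_pattern(phrase).finditer(text)]


def detect_mentions(
    document: PolicyDocument,
    lexicon: FrameworkLexicon,
    *,
    normalizer: Callable[[str], str] | None = None,
) -> list[MentionCandidate]:
    """Scan every sentence for lexicon key phrases.

    Emits one candidate per phrase occurrence, ordered by sentence, then
    category (concept, group, universal), then target, then position.
    Deterministic for a fixed document and lexicon; an empty document yields
    an empty list.
    """
    phrases = list(iter_phrases(lexicon))
    out: list[MentionCandidate] = []
    for sent in document.sentences:
        haystack = normalizer(sent.text) if normalizer else sent.text
        hits = []
        for category, target_id, phrase in phrases:
            for pos in find_phrase(phrase, haystack):
                hits.append((_CATEGORY_ORDER[category], target_id, pos, category, phrase))
        hits.sort()
        for _, target_id, pos, category, phrase in hits:
            out.append(
                MentionCandidate(
                    doc_id=document.doc_id,
                    sentence_index=sent.index,
                    category=category,
                    target_id=target_id,
                    matched_phrase=phrase,
                    excerpt=sent.text,
                    char_start=pos,
                )
            )
    return out


def pair_mentions(
    candidates: list[MentionCandidate],
    *,
    window: int = 0,
    universal_default: bool = True,
) -> PairingResult:
    """Anchor each concept mention to the groups/universal phrases near it.

    A concept mention in a sentence within ``window`` sentences of a group
    mention yields one (concept, group) pair per distinct group; if only a
    universal phrase is in range it yields (concept, Universal).  A concept
    with neither anchor becomes (concept, Universal) when
    ``universal_default`` is true, else it is reported unpaired.
    """
    doc_ids = {c.doc_id for c in candidates}
    if len(doc_ids) > 1:
        raise ValueError(f"candidates span multiple documents: {sorted(doc_ids)}")

    groups_at: dict[int, set[str]] = {}
    universal_at: set[int] = set()
    for c in candidates:
        if c.category == "group":
            groups_at.setdefault(c.sentence_index, set()).add(c.target_id)
        elif c.category == "universal":
            universal_at.add(c.sentence_index)

    pairs: list[PairedCandidate] = []
    seen: set[tuple[str, str, int]] = set()
    unpaired: list[MentionCandidate] = []
    for c in candidates:
        if c.category != "concept":
            continue
        in_range = range(c.sentence_index - window, c.sentence_index + window + 1)
        nearby_groups = sorted(
            g for i in in_range for g in groups_at.get(i, ())
        )
        nearby_universal = any(i in universal_at for i in in_range)
        columns: list[str]
        if nearby_groups:
            columns = nearby_groups
        elif nearby_universal or universal_default:
            columns = [UNIVERSAL]
        else:
            unpaired.append(c)
            continue
        for col in columns:
            key = (c.target_id, col, c.sentence_index)
            if key in seen:
                continue
            seen.add(key)
            pairs.append(
                PairedCandidate(
                    doc_id=c.doc_id,
                    concept_id=c.target_id,
                    column_id=col,
                    sentence_index=c.sentence_index,
                    evidence=c.excerpt,
                )
            )
    return PairingResult(tuple(pairs), tuple(unpaired))


def count_universal_references(
    document: PolicyDocument, lexicon: FrameworkLexicon
) -> int:
    """Total occurrences (not sentences) of universal phrases in the document."""
    return sum(
        len(find_phrase(phrase, sent.text))
        for sent in document.sentences
        for phrase in lexicon.universal_phrases
    )


def candidates_to_frame(candidates: list[MentionCandidate]) -> pd.DataFrame:
    """Tabulate candidates as a rater worksheet."""
    return pd.DataFrame(
        [
            {
                "doc_id": c.doc_id,
                "sentence_index": c.sentence_index,
                "category": c.category,
                "target_id": c.target_id,
                "matched_phrase": c.matched_phrase,
                "excerpt": c.excerpt,
            }
            for c in candidates
        ],
        columns=["doc_id", "sentence_index", "category", "target_id",
                 "matched_phrase", "excerpt"],
    )


def write_candidates(candidates: list[MentionCandidate], path: str | Path) -> None:
    candidates_to_frame(candidates).to_csv(path, index=False)
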