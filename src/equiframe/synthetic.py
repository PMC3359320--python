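"""Synthetic policy corpus with planted, analytically known ground truth.

Real policy texts cannot be redistributed, so end-to-end behaviour is
exercised on generated documents: each plan states exactly which
(concept, group-or-Universal) cells are planted, at which quality level and
how many times, how many stand-alone universal-population sentences appear,
and how many distractor sentences pad the text.  Sentence templates encode
the quality level linguistically (mention only / explained / action /
monitoring clause), but the ground-truth annotations carry the planted
quality — automated text-to-quality inference is deliberately not pretended.

Distractor sentences and template filler are drawn from a vocabulary
verified at generation time to be free of lexicon key phrases, so planted
recall and precision on synthetic text are exact by construction.  The
expected summary indices are computed analytically from the plan, making
every generated document its own oracle.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .corpus import Corpus, PolicyDocument
from .detection import PairingResult, find_phrase
from .indices import (
    PolicySummary,
    QUALITY_THRESHOLD,
    overall_ranking,
    round_half_up,
)
from .lexicon import UNIVERSAL, FrameworkLexicon, iter_phrases
from .scoring import Annotation


class GenerationError(ValueError):
    """Raised when a plan is inconsistent with the framework."""


@dataclass(frozen=True)
class PlantedCell:
    """One planted (concept, column) cell at a chosen quality level."""

    concept_id: str
    column_id: str  # group_id or UNIVERSAL
    quality: int
    n_mentions: int = 1

    def __post_init__(self) -> None:
        if self.quality not in (1, 2, 3, 4):
            raise GenerationError(f"quality must be 1-4, got {self.quality!r}")
        if self.n_mentions < 1:
            raise GenerationError("n_mentions must be >= 1")


#: Prose templates per quality level. Filler vocabulary must stay free of
#: lexicon key phrases; generation verifies this and raises otherwise.
DEFAULT_TEMPLATES: dict[int, str] = {
    1: "This document notes {concept} regarding {target}.",
    2: ("This document notes {concept} regarding {target}, explaining its "
        "meaning and scope in the present context."),
    3: ("The ministry shall undertake specific actions on {concept} "
        "regarding {target} at district level."),
    4: ("The ministry shall undertake specific actions on {concept} "
        "regarding {target}, and progress shall be tracked and reported "
        "annually."),
}

UNIVERSAL_TEMPLATE = "This provision applies to {target} throughout the country."

_DISTRACTOR_SUBJECTS = (
    "The committee", "The secretariat", "The working group", "The task force",
    "The planning unit", "The directorate",
)
_DISTRACTOR_VERBS = ("convened", "reviewed", "tabled", "circulated", "endorsed",
                     "archived")
_DISTRACTOR_OBJECTS = (
    "the quarterly budget report", "the procurement schedule",
    "the staffing roster", "the logistics memorandum", "the audit findings",
    "the annual workplan",
)


@dataclass(frozen=True)
class GenerationPlan:
    """Stated content of one synthetic policy document."""

    seed: int
    planted_cells: tuple[PlantedCell, ...] = ()
    n_universal_phrases: int = 0
    n_distractor_sentences: int = 0
    doc_id: str = "synthetic-001"
    country: str = "Synthetica"
    title: str = ""
    doc_type: str = "policy"
    templates: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_cells", tuple(self.planted_cells))
        cells = [(c.concept_id, c.column_id) for c in self.planted_cells]
        if len(cells) != len(set(cells)):
            raise GenerationError("planted cells must be unique per (concept, column)")

    # -- analytic ground truth ------------------------------------------

    def expected_counts(self, framework: FrameworkLexicon) -> tuple[int, int, int]:
        """(concepts mentioned, base groups mentioned, concepts at quality 3-4)."""
        base = set(framework.base_group_ids)
        concepts = {c.concept_id for c in self.planted_cells}
        groups = {c.column_id for c in self.planted_cells if c.column_id in base}
        best: dict[str, int] = {}
        for c in self.planted_cells:
            best[c.concept_id] = max(best.get(c.concept_id, 0), c.quality)
        n_quality = sum(1 for q in best.values() if q >= QUALITY_THRESHOLD)
        return len(concepts), len(groups), n_quality

    def expected_summary(
        self, framework: FrameworkLexicon, *, precision: int = 1
    ) -> PolicySummary:
        """The summary the scoring pipeline must recover, from the plan alone."""
        n_cc, n_vg, n_q = self.expected_counts(framework)
        cc_denom = len(framework.concepts)
        vg_denom = len(framework.base_groups)
        vg = 100.0 * n_vg / vg_denom
        cc = 100.0 * n_cc / cc_denom
        q = 100.0 * n_q / cc_denom
        return PolicySummary(
            doc_id=self.doc_id,
            vg_coverage_pct=vg,
            cc_coverage_pct=cc,
            cc_quality_pct=q,
            ranking=overall_ranking(vg, cc, q),
            counts=(n_cc, n_vg, n_q),
            denominators=(cc_denom, vg_denom),
            country=self.country,
            title=self.title or self.doc_id,
            precision=precision,
        )

    def expected_universal_count(self) -> int:
        """Total universal-phrase occurrences the document will contain."""
        planted = sum(
            c.n_mentions for c in self.planted_cells if c.column_id == UNIVERSAL
        )
        return planted + self.n_universal_phrases


def _verify_sentence(
    sentence: str,
    framework: FrameworkLexicon,
    expected: set[tuple[str, str]],
) -> None:
    """Assert the sentence matches exactly the intended lexicon phrases."""
    found = {
        (category, target_id)
        for category, target_id, phrase in iter_phrases(framework)
        if find_phrase(phrase, sentence)
    }
    if found != expected:
        raise GenerationError(
            f"template produced unintended matches in {sentence!r}: "
            f"found {sorted(found)}, expected {sorted(expected)} "
            "(check that filler vocabulary avoids lexicon key phrases)"
        )


def generate_document(
    plan: GenerationPlan, framework: FrameworkLexicon
) -> tuple[PolicyDocument, list[Annotation], PolicySummary]:
    """Render a plan into a document, its ground-truth annotations and summary.

    Deterministic for a fixed plan (seed included): sentence order, phrase
    choices and distractors all come from the plan's seeded RNG.  Every
    planted cell appears in ``n_mentions`` sentences containing exactly one
    concept phrase and one group/universal phrase; distractors contain none.
    """
    rng = random.Random(plan.seed)
    concept_ids = set(framework.concept_ids)
    column_ids = set(framework.column_ids)
    for cell in plan.planted_cells:
        if cell.concept_id not in concept_ids:
            raise GenerationError(f"unknown concept_id {cell.concept_id!r} in plan")
        if cell.column_id not in column_ids:
            raise GenerationError(f"unknown column_id {cell.column_id!r} in plan")

    # (sentence text, planted cell or None)
    pieces: list[tuple[str, PlantedCell | None]] = []
    for cell in plan.planted_cells:
        concept_phrase = framework.concept(cell.concept_id).key_phrases[0]
        for _ in range(cell.n_mentions):
            if cell.column_id == UNIVERSAL:
                target = rng.choice(framework.universal_phrases)
                expected = {("concept", cell.concept_id), ("universal", UNIVERSAL)}
            else:
                target = framework.group(cell.column_id).key_phrases[0]
                expected = {("concept", cell.concept_id), ("group", cell.column_id)}
            sentence = plan.templates[cell.quality].format(
                concept=concept_phrase, target=target
            )
            _verify_sentence(sentence, framework, expected)
            pieces.append((sentence, cell))
    for _ in range(plan.n_universal_phrases):
        target = rng.choice(framework.universal_phrases)
        sentence = UNIVERSAL_TEMPLATE.format(target=target)
        _verify_sentence(sentence, framework, {("universal", UNIVERSAL)})
        pieces.append((sentence, None))
    for _ in range(plan.n_distractor_sentences):
        sentence = (
            f"{rng.choice(_DISTRACTOR_SUBJECTS)} {rng.choice(_DISTRACTOR_VERBS)} "
            f"{rng.choice(_DISTRACTOR_OBJECTS)}."
        )
        _verify_sentence(sentence, framework, set())
        pieces.append((sentence, None))

    rng.shuffle(pieces)
    text = " ".join(s for s, _ in pieces)
    document = PolicyDocument(
        doc_id=plan.doc_id,
        text=text,
        country=plan.country,
        title=plan.title or plan.doc_id,
        doc_type=plan.doc_type,
    )
    if len(document.sentences) != len(pieces):
        raise GenerationError(
            f"segmentation produced {len(document.sentences)} units for "
            f"{len(pieces)} generated sentences"
        )

    annotations = [
        Annotation(
            rater_id="truth",
            doc_id=plan.doc_id,
            concept_id=cell.concept_id,
            column_id=cell.column_id,
            quality=cell.quality,
            evidence=sent.text,
            sentence_index=sent.index,
        )
        for sent, (_, cell) in zip(document.sentences, pieces)
        if cell is not None
    ]
    return document, annotations, plan.expected_summary(framework)


def confirm_pairs(
    pairing: PairingResult, plan: GenerationPlan, *, rater_id: str = "auto"
) -> list[Annotation]:
    """Turn detected pairs into annotations at the plan's planted quality.

    Stands in for the human rater on synthetic text: each detected
    (concept, column) pair is confirmed at the quality the plan planted for
    that cell.  A pair with no planted cell is a false positive and raises.
    """
    quality_of = {(c.concept_id, c.column_id): c.quality for c in plan.planted_cells}
    out = []
    for pair in pairing.pairs:
        key = (pair.concept_id, pair.column_id)
        if key not in quality_of:
            raise GenerationError(f"detected pair {key} was never planted")
        out.append(
            Annotation(
                rater_id=rater_id,
                doc_id=pair.doc_id,
                concept_id=pair.concept_id,
                column_id=pair.column_id,
                quality=quality_of[key],
                evidence=pair.evidence,
                sentence_index=pair.sentence_index,
            )
        )
    return out


def random_plan(
    seed: int,
    framework: FrameworkLexicon,
    *,
    max_cells: int = 12,
    max_mentions: int = 2,
    max_universal: int = 5,
    max_distractors: int = 10,
    doc_id: str = "synthetic-001",
    country: str = "Synthetica",
) -> GenerationPlan:
    """Sample a plan uniformly over cells, qualities and padding counts."""
    rng = random.Random(seed)
    columns = list(framework.base_group_ids) + [UNIVERSAL]
    all_cells = [(c, col) for c in framework.concept_ids for col in columns]
    n_cells = rng.randint(0, min(max_cells, len(all_cells)))
    chosen = rng.sample(all_cells, n_cells)
    cells = tuple(
        PlantedCell(
            concept_id=c,
            column_id=col,
            quality=rng.randint(1, 4),
            n_mentions=rng.randint(1, max_mentions),
        )
        for c, col in chosen
    )
    return GenerationPlan(
        seed=rng.randrange(2**31),
        planted_cells=cells,
        n_universal_phrases=rng.randint(0, max_universal),
        n_distractor_sentences=rng.randint(0, max_distractors),
        doc_id=doc_id,
        country=country,
    )


def plan_from_counts(
    framework: FrameworkLexicon,
    *,
    n_groups: int,
    n_concepts: int,
    n_quality34: int,
    seed: int = 0,
    doc_id: str = "synthetic-001",
    country: str = "Synthetica",
    title: str = "",
) -> GenerationPlan:
    """Construct a plan whose expected counts are exactly the ones given.

    Mirrors a published table row stated as counts: ``n_concepts`` concepts
    mentioned, the first ``n_groups`` of them anchored to distinct base
    groups (the rest Universal), and the first ``n_quality34`` at quality
    3 or 4.
    """
    if not (0 <= n_quality34 <= n_concepts <= len(framework.concepts)):
        raise GenerationError(
            f"need 0 <= n_quality34 <= n_concepts <= {len(framework.concepts)}"
        )
    if n_groups > len(framework.base_groups):
        raise GenerationError("more groups requested than the framework defines")
    if n_groups > 0 and n_concepts == 0:
        raise GenerationError("group mentions require at least one concept")

    concepts = framework.concept_ids[:n_concepts]
    groups = framework.base_group_ids[:n_groups]
    cells = []
    for i, cid in enumerate(concepts):
        quality = 3 + (i % 2) if i < n_quality34 else 1 + (i % 2)
        column = groups[i] if i < n_groups else UNIVERSAL
        cells.append(PlantedCell(cid, column, quality))
    # More groups than concepts: hang the extras off the first concept.
    for j in range(n_concepts, n_groups):
        cells.append(PlantedCell(concepts[0], groups[j], cells[0].quality))
    return GenerationPlan(
        seed=seed,
        planted_cells=tuple(cells),
        n_universal_phrases=2,
        n_distractor_sentences=4,
        doc_id=doc_id,
        country=country,
        title=title,
    )


def generate_country_corpus(
    n_documents: int,
    seed: int,
    framework: FrameworkLexicon,
    *,
    country: str = "Synthetica",
    plan_factory=None,
) -> tuple[Corpus, dict[str, tuple[GenerationPlan, list[Annotation], PolicySummary]]]:
    """Generate a reproducible corpus of ``n_documents`` with ground truth.

    ``plan_factory(seed, index)`` may supply custom plans (e.g. mimicking a
    published country table); the default samples :func:`random_plan`.
    Returns the corpus plus a per-document mapping to (plan, ground-truth
    annotations, expected summary).
    """
    if n_documents < 1:
        raise GenerationError("n_documents must be >= 1")
    rng = random.Random(seed)
    corpus = Corpus(framework_ref=framework.name)
    truth = {}
    for i in range(n_documents):
        doc_seed = rng.randrange(2**31)
        doc_id = f"{country.lower()}-{i + 1:03d}"
        if plan_factory is None:
            plan = random_plan(doc_seed, framework, doc_id=doc_id, country=country)
        else:
            plan = plan_factory(doc_seed, i)
        document, annotations, expected = generate_document(plan, framework)
        corpus.add(document)
        truth[document.doc_id] = (plan, annotations, expected)
    return corpus, truth
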