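"""Framework definition: core concepts, vulnerable groups, and their key language.

The EquiFrame rubric rates a health policy's stated commitment to 21 core
concepts of human rights, and its coverage of 12 vulnerable groups, with a
distinguished "Universal" column for statements addressing the total
population ("all people", "everyone").  The framework itself is data: it is
loaded from a YAML config so that rosters, definitions and key phrases can be
edited per study without touching code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

#: Column identifier for the distinguished total-population column.
UNIVERSAL = "universal"

#: Expected cardinalities of the default framework.
N_CONCEPTS_DEFAULT = 21
N_BASE_GROUPS_DEFAULT = 12


class LexiconError(ValueError):
    """Raised for invalid or inconsistent framework configuration."""


@dataclass(frozen=True)
class CoreConcept:
    """One human-rights concept a policy is rated against (e.g. Access)."""

    concept_id: str
    name: str
    definition: str = ""
    key_questions: tuple[str, ...] = ()
    key_phrases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "key_phrases", tuple(p.lower() for p in self.key_phrases)
        )
        object.__setattr__(self, "key_questions", tuple(self.key_questions))


@dataclass(frozen=True)
class VulnerableGroup:
    """One social group at elevated risk whose policy coverage is assessed.

    ``country_specific`` groups are additive extras: they never enter the
    base-12 coverage denominator.
    """

    group_id: str
    name: str
    definition: str = ""
    key_phrases: tuple[str, ...] = ()
    country_specific: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "key_phrases", tuple(p.lower() for p in self.key_phrases)
        )


@dataclass(frozen=True)
class PhraseConflict:
    """A phrase assigned to more than one lexicon category.

    ``kind`` is ``"group-universal"``, ``"group-group"`` or
    ``"concept-concept"``.  Only the first two violate the framework
    invariants; concept-concept sharing is permitted but flagged, because
    group-coverage denominators must be unambiguous while concept ambiguity
    is resolved by the human rater.
    """

    kind: str
    phrase: str
    targets: tuple[str, ...]

    @property
    def forbidden(self) -> bool:
        return self.kind in ("group-universal", "group-group")


@dataclass(frozen=True)
class FrameworkLexicon:
    """The full framework: ordered concepts, groups and universal phrases."""

    concepts: tuple[CoreConcept, ...]
    groups: tuple[VulnerableGroup, ...]
    universal_phrases: tuple[str, ...]
    name: str = "equiframe"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "universal_phrases", tuple(p.lower() for p in self.universal_phrases)
        )
        seen: set[str] = set()
        for c in self.concepts:
            if c.concept_id in seen:
                raise LexiconError(f"duplicate concept_id: {c.concept_id!r}")
            seen.add(c.concept_id)
        seen = set()
        for g in self.groups:
            if g.group_id in seen:
                raise LexiconError(f"duplicate group_id: {g.group_id!r}")
            seen.add(g.group_id)
        forbidden = [c for c in validate_phrase_disjointness(self) if c.forbidden]
        if forbidden:
            raise LexiconError(
                "group/universal key phrases must be disjoint: "
                + "; ".join(f"{c.phrase!r} -> {c.targets}" for c in forbidden)
            )

    # -- lookups ---------------------------------------------------------

    @property
    def concept_ids(self) -> tuple[str, ...]:
        return tuple(c.concept_id for c in self.concepts)

    @property
    def group_ids(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.groups)

    @property
    def base_groups(self) -> tuple[VulnerableGroup, ...]:
        return tuple(g for g in self.groups if not g.country_specific)

    @property
    def base_group_ids(self) -> tuple[str, ...]:
        return tuple(g.group_id for g in self.base_groups)

    @property
    def column_ids(self) -> tuple[str, ...]:
        """All score-matrix columns: every group plus the Universal column."""
        return self.group_ids + (UNIVERSAL,)

    def concept(self, concept_id: str) -> CoreConcept:
        for c in self.concepts:
            if c.concept_id == concept_id:
                return c
        raise KeyError(concept_id)

    def group(self, group_id: str) -> VulnerableGroup:
        for g in self.groups:
            if g.group_id == group_id:
                return g
        raise KeyError(group_id)

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "concepts": [
                {
                    "id": c.concept_id,
                    "name": c.name,
                    "definition": c.definition,
                    "key_questions": list(c.key_questions),
                    "key_phrases": list(c.key_phrases),
                }
                for c in self.concepts
            ],
            "vulnerable_groups": [
                {
                    "id": g.group_id,
                    "name": g.name,
                    "definition": g.definition,
                    "key_phrases": list(g.key_phrases),
                    "country_specific": g.country_specific,
                }
                for g in self.groups
            ],
            "universal_phrases": list(self.universal_phrases),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )


def _framework_from_dict(cfg: dict, *, strict: bool = False) -> FrameworkLexicon:
    for key in ("concepts", "vulnerable_groups", "universal_phrases"):
        if key not in cfg:
            raise LexiconError(f"framework config missing top-level key {key!r}")
    concepts = tuple(
        CoreConcept(
            concept_id=str(e["id"]),
            name=str(e["name"]),
            definition=str(e.get("definition", "")),
            key_questions=tuple(e.get("key_questions", ())),
            key_phrases=tuple(e.get("key_phrases", ())),
        )
        for e in cfg["concepts"]
    )
    groups = tuple(
        VulnerableGroup(
            group_id=str(e["id"]),
            name=str(e["name"]),
            definition=str(e.get("definition", "")),
            key_phrases=tuple(e.get("key_phrases", ())),
            country_specific=bool(e.get("country_specific", False)),
        )
        for e in cfg["vulnerable_groups"]
    )
    lex = FrameworkLexicon(
        concepts=concepts,
        groups=groups,
        universal_phrases=tuple(cfg["universal_phrases"]),
        name=str(cfg.get("name", "equiframe")),
    )
    n_base = len(lex.base_groups)
    if len(lex.concepts) != N_CONCEPTS_DEFAULT or n_base != N_BASE_GROUPS_DEFAULT:
        msg = (
            f"framework has {len(lex.concepts)} concepts and {n_base} base groups; "
            f"the default framework defines {N_CONCEPTS_DEFAULT} and "
            f"{N_BASE_GROUPS_DEFAULT}"
        )
        if strict:
            raise LexiconError(msg)
        warnings.warn(msg, stacklevel=3)
    return lex


def load_framework(source: str | Path | dict, *, strict: bool = False) -> FrameworkLexicon:
    """Load and validate a framework from a YAML file (or parsed mapping).

    Ordering of concepts and groups is preserved from the config.  Duplicate
    ids and group/universal phrase overlap raise :class:`LexiconError`.
    Non-default cardinalities warn, or raise when ``strict`` is true.
    """
    if isinstance(source, dict):
        cfg = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        if not isinstance(cfg, dict):
            raise LexiconError(f"framework config {source} did not parse to a mapping")
    return _framework_from_dict(cfg, strict=strict)


def default_framework(*, strict: bool = True) -> FrameworkLexicon:
    """Load the framework config shipped with the package (21 concepts, 12 groups)."""
    ref = resources.files("equiframe.data") / "default_framework.yaml"
    with resources.as_file(ref) as path:
        return load_framework(path, strict=strict)


def validate_phrase_disjointness(lexicon: FrameworkLexicon) -> list[PhraseConflict]:
    """Report every phrase assigned to more than one category.

    Group/universal and group/group overlaps are forbidden (``forbidden`` is
    true on the conflict); a phrase shared by two concepts is allowed but
    flagged as concept ambiguity.  The default framework yields an empty list.
    """
    conflicts: list[PhraseConflict] = []

    owner_of: dict[str, str] = {}
    for g in lexicon.groups:
        for p in g.key_phrases:
            if p in owner_of and owner_of[p] != g.group_id:
                conflicts.append(
                    PhraseConflict("group-group", p, (owner_of[p], g.group_id))
                )
            owner_of.setdefault(p, g.group_id)
    universal = set(lexicon.universal_phrases)
    for p, gid in owner_of.items():
        if p in universal:
            conflicts.append(PhraseConflict("group-universal", p, (gid, UNIVERSAL)))

    concept_owner: dict[str, list[str]] = {}
    for c in lexicon.concepts:
        for p in set(c.key_phrases):
            concept_owner.setdefault(p, []).append(c.concept_id)
    for p, owners in concept_owner.items():
        if len(owners) > 1:
            conflicts.append(PhraseConflict("concept-concept", p, tuple(owners)))
    return conflicts


def iter_phrases(lexicon: FrameworkLexicon) -> Iterable[tuple[str, str, str]]:
    """Yield (category, target_id, phrase) for every matchable phrase."""
    for c in lexicon.concepts:
        for p in c.key_phrases:
            yield "concept", c.concept_id, p
    for g in lexicon.groups:
        for p in g.key_phrases:
            yield "group", g.group_id, p
    for p in lexicon.universal_phrases:
        yield "universal", UNIVERSAL, p
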