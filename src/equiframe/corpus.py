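"""Policy documents, sentence segmentation and corpus management.

The unit of analysis for mention pairing is the sentence.  Segmentation is a
small deterministic rule set (documented in the methods note) rather than a
statistical model: boundaries at sentence-final ``. ! ?`` runs followed by
whitespace — unless the preceding token is a known abbreviation — and at line
breaks.  Sentence spans are 0-based half-open character coordinates into the
original text; spans plus inter-span whitespace reconstruct the text exactly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

DOC_TYPES = ("policy", "guideline", "strategic plan", "programme", "other")

#: Tokens after which a period does not end a sentence.
ABBREVIATIONS = frozenset(
    {"e.g", "i.e", "etc", "cf", "vs", "viz", "dr", "mr", "mrs", "ms",
     "st", "no", "fig", "ref", "al", "approx", "dept", "govt"}
)

_TERMINATOR = re.compile(r"[.!?]+(?=\s|$)")
_TRAILING_TOKEN = re.compile(r"([A-Za-z][A-Za-z.]*)$")


class CorpusError(ValueError):
    """Raised for invalid corpus or document metadata."""


@dataclass(frozen=True)
class Sentence:
    """One sentence unit: ``text == document.text[start:end]``."""

    index: int
    start: int
    end: int
    text: str


def segment_sentences(text: str) -> list[Sentence]:
    """Split ``text`` into ordered, non-overlapping sentence spans.

    Deterministic and lossless: the spans are in document order, lie within
    the text, and the material between consecutive spans is whitespace only.
    An empty string yields an empty list.
    """
    cuts: set[int] = set()
    for m in _TERMINATOR.finditer(text):
        tok = _TRAILING_TOKEN.search(text[: m.start()])
        if tok and tok.group(1).lower().rstrip(".") in ABBREVIATIONS:
            continue
        cuts.add(m.end())
    for m in re.finditer(r"\n", text):
        cuts.add(m.start())

    sentences: list[Sentence] = []
    prev = 0
    for cut in sorted(cuts | {len(text)}):
        raw = text[prev:cut]
        stripped = raw.strip()
        if stripped:
            start = prev + len(raw) - len(raw.lstrip())
            end = start + len(stripped)
            sentences.append(Sentence(len(sentences), start, end, stripped))
        prev = cut
    return sentences


@dataclass(frozen=True)
class PolicyDocument:
    """One policy text with metadata and its segmented sentence units."""

    doc_id: str
    text: str
    country: str = ""
    title: str = ""
    doc_type: str = "other"
    sentences: tuple[Sentence, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.doc_type not in DOC_TYPES:
            raise CorpusError(
                f"doc_type {self.doc_type!r} not one of {DOC_TYPES}"
            )
        if self.sentences is None:
            object.__setattr__(self, "sentences", tuple(segment_sentences(self.text)))
        else:
            object.__setattr__(self, "sentences", tuple(self.sentences))
        for s in self.sentences:
            if not (0 <= s.start <= s.end <= len(self.text)):
                raise CorpusError(f"sentence span {s.index} out of bounds")
            if self.text[s.start : s.end] != s.text:
                raise CorpusError(f"sentence span {s.index} does not match text")

    def __len__(self) -> int:
        return len(self.sentences)


def read_document(
    path: str | Path,
    *,
    doc_id: str | None = None,
    country: str = "",
    title: str = "",
    doc_type: str = "other",
    encoding: str = "utf-8",
    fallback_encoding: str | None = None,
) -> PolicyDocument:
    """Read a plain-text policy file into a segmented :class:`PolicyDocument`.

    UTF-8 by default with an optional fallback encoding; an undecodable file
    raises :class:`IOError` naming the encodings attempted.  An empty file
    yields a document with zero sentences.
    """
    path = Path(path)
    data = path.read_bytes()
    tried = []
    for enc in filter(None, (encoding, fallback_encoding)):
        tried.append(enc)
        try:
            text = data.decode(enc)
            break
        except UnicodeDecodeError:
            continue
    else:
        raise IOError(f"could not decode {path} with encoding(s): {', '.join(tried)}")
    return PolicyDocument(
        doc_id=doc_id or path.stem,
        text=text,
        country=country,
        title=title or path.stem,
        doc_type=doc_type,
    )


@dataclass
class Corpus:
    """A collection of policy documents analyzed under one framework."""

    documents: list[PolicyDocument] = field(default_factory=list)
    framework_ref: str = "equiframe-default"

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise CorpusError(f"duplicate doc_ids in corpus: {sorted(dupes)}")

    def add(self, document: PolicyDocument) -> None:
        if any(d.doc_id == document.doc_id for d in self.documents):
            raise CorpusError(f"duplicate doc_id: {document.doc_id!r}")
        self.documents.append(document)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    def get(self, doc_id: str) -> PolicyDocument:
        for d in self.documents:
            if d.doc_id == doc_id:
                return d
        raise KeyError(doc_id)


def read_manifest(manifest_path: str | Path, **read_kwargs) -> Corpus:
    """Load a corpus from a CSV manifest (doc_id, country, title, doc_type, path).

    Relative document paths are resolved against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str).fillna("")
    required = {"doc_id", "country", "title", "doc_type", "path"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusError(f"manifest missing columns: {sorted(missing)}")
    corpus = Corpus()
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        corpus.add(
            read_document(
                p,
                doc_id=row.doc_id,
                country=row.country,
                title=row.title,
                doc_type=row.doc_type or "other",
                **read_kwargs,
            )
        )
    return corpus


def write_manifest(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write each document as a .txt file plus a manifest.csv; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for doc in corpus:
        fname = f"{doc.doc_id}.txt"
        (out_dir / fname).write_text(doc.text, encoding="utf-8")
        rows.append(
            {"doc_id": doc.doc_id, "country": doc.country, "title": doc.title,
             "doc_type": doc.doc_type, "path": fname}
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
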