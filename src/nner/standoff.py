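"""Brat-style standoff annotation I/O and the core document model.

Clinical entity annotations are stored *standoff*: the raw note lives in a
``.txt`` file and entities live in a parallel ``.ann`` file that references
the text by character offset.  All offsets in this package are 0-based,
half-open, and always on the ORIGINAL, unmodified text — downstream
preprocessing keeps an offset map back into this frame so that predictions
can be scored against gold ``.ann`` files directly.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)

#: The closed set of medication/ADE entity categories.
CATEGORIES = (
    "ADE",
    "Dosage",
    "Duration",
    "Drug",
    "Form",
    "Frequency",
    "Reason",
    "Route",
    "Strength",
)

#: Categories in descending training-corpus frequency.  This single table is
#: shared by every component that has to break a tie between categories:
#: flattening nested gold for the flat CRF, assigning polysemous duplicates
#: to nest levels, and breaking voting ties in ensembles.
CATEGORY_PRIORITY = (
    "Drug",
    "Strength",
    "Form",
    "Frequency",
    "Route",
    "Dosage",
    "Reason",
    "ADE",
    "Duration",
)

_PRIORITY_RANK = {c: i for i, c in enumerate(CATEGORY_PRIORITY)}


def priority_rank(category: str) -> int:
    """Smaller rank = higher priority (more frequent category)."""
    return _PRIORITY_RANK[category]


class StandoffParseError(ValueError):
    """Raised for malformed .ann lines or invalid categories."""


@dataclass(frozen=True)
class Entity:
    """One annotated entity.

    ``fragments`` is an ordered tuple of half-open ``(start, end)`` character
    intervals on the original text; almost all entities are contiguous
    (a single fragment) but the data model supports brat's discontinuous
    spans.  ``nest_level`` is 1 for flat/innermost entities and grows
    outwards; it may be ``None`` when unassigned.
    """

    entity_id: str
    category: str
    fragments: tuple[tuple[int, int], ...]
    nest_level: int | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise StandoffParseError(f"unknown category {self.category!r}")
        if not self.fragments:
            raise StandoffParseError("entity requires at least one fragment")
        prev_end = -1
        for s, e in self.fragments:
            if not (0 <= s < e):
                raise StandoffParseError(f"bad fragment ({s}, {e})")
            if s < prev_end:
                raise StandoffParseError("fragments overlap or are unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.fragments[0][0]

    @property
    def end(self) -> int:
        return self.fragments[-1][1]

    def char_set(self) -> frozenset[int]:
        """The union of fragments as a set of character positions."""
        return frozenset(i for s, e in self.fragments for i in range(s, e))

    def span_key(self) -> tuple[tuple[int, int], ...]:
        return self.fragments

    def surface(self, text: str) -> str:
        return " ".join(text[s:e] for s, e in self.fragments)

    def with_level(self, level: int) -> "Entity":
        return replace(self, nest_level=level)


@dataclass(frozen=True)
class Token:
    surface: str
    start: int
    end: int
    sentence_index: int = 0


@dataclass
class Document:
    """A clinical note with its annotations, sentences, and tokens."""

    doc_id: str
    text: str
    entities: list[Entity] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)
    tokens: list[Token] = field(default_factory=list)

    def validate(self) -> None:
        seen_ids: set[str] = set()
        n = len(self.text)
        for ent in self.entities:
            if ent.entity_id in seen_ids:
                raise StandoffParseError(
                    f"{self.doc_id}: duplicate entity id {ent.entity_id}"
                )
            seen_ids.add(ent.entity_id)
            if ent.end > n:
                raise StandoffParseError(
                    f"{self.doc_id}/{ent.entity_id}: offset {ent.end} beyond "
                    f"text length {n}"
                )

    def entity_keys(self) -> set[tuple[str, tuple[tuple[int, int], ...]]]:
        """(category, fragments) keys — the identity used for scoring."""
        return {(e.category, e.fragments) for e in self.entities}

    def sentence_tokens(self) -> list[list[Token]]:
        out: list[list[Token]] = [[] for _ in self.sentences]
        for tok in self.tokens:
            out[tok.sentence_index].append(tok)
        return out


_TLINE = re.compile(
    r"^(?P<id>T\d+)\t(?P<cat>\S+) (?P<offsets>\d+ \d+(?:;\d+ \d+)*)(?:\t(?P<surf>.*))?$"
)


def read_standoff(txt_path: str, ann_path: str) -> Document:
    """Read a ``.txt``/``.ann`` pair into a :class:`Document`.

    Only entity ("T") lines are parsed; relation/attribute/note lines are
    skipped (entity identification only).  A mismatch between the ``.ann``
    reference surface and the text slice is logged as a warning — clinical
    exports are noisy and the offsets win.
    """
    with open(txt_path, encoding="utf-8") as fh:
        text = fh.read()
    doc_id = os.path.splitext(os.path.basename(txt_path))[0]
    entities: list[Entity] = []
    with open(ann_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or not line.startswith("T"):
                continue
            m = _TLINE.match(line)
            if m is None:
                raise StandoffParseError(
                    f"{ann_path}:{lineno}: malformed entity line: {line!r}"
                )
            cat = m.group("cat")
            if cat not in CATEGORIES:
                raise StandoffParseError(
                    f"{ann_path}:{lineno}: category {cat!r} not in the "
                    f"nine-type set"
                )
            frags = tuple(
                (int(a), int(b))
                for a, b in (p.split(" ") for p in m.group("offsets").split(";"))
            )
            ent = Entity(m.group("id"), cat, frags)
            ref = m.group("surf")
            if ref is not None:
                got = " ".join(text[s:e] for s, e in frags)
                if got != ref:
                    logger.warning(
                        "%s:%d: surface %r does not match text slice %r; "
                        "keeping offsets",
                        ann_path,
                        lineno,
                        ref,
                        got,
                    )
            entities.append(ent)
    doc = Document(doc_id, text, entities)
    doc.validate()
    return doc


def write_standoff(doc: Document, out_dir: str) -> tuple[str, str]:
    """Write ``doc`` as a ``.txt``/``.ann`` pair; round-trips exactly."""
    os.makedirs(out_dir, exist_ok=True)
    txt_path = os.path.join(out_dir, doc.doc_id + ".txt")
    ann_path = os.path.join(out_dir, doc.doc_id + ".ann")
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write(doc.text)
    with open(ann_path, "w", encoding="utf-8") as fh:
        for ent in doc.entities:
            offsets = ";".join(f"{s} {e}" for s, e in ent.fragments)
            surface = ent.surface(doc.text).replace("\n", " ")
            fh.write(f"{ent.entity_id}\t{ent.category} {offsets}\t{surface}\n")
    return txt_path, ann_path


def read_corpus_dir(path: str) -> list[Document]:
    docs = []
    for name in sorted(os.listdir(path)):
        if name.endswith(".txt"):
            stem = name[:-4]
            ann = os.path.join(path, stem + ".ann")
            if os.path.exists(ann):
                docs.append(read_standoff(os.path.join(path, name), ann))
    return docs


def write_corpus_dir(docs: list[Document], path: str) -> None:
    for doc in docs:
        write_standoff(doc, path)


# ---------------------------------------------------------------------------
# CoNLL-style BIO tables
# ---------------------------------------------------------------------------


def _contiguous(ent: Entity) -> bool:
    return len(ent.fragments) == 1


def entities_to_bio(
    tokens: list[Token], entities: list[Entity]
) -> list[str]:
    """Assign a BIO tag to each token from non-overlapping entities.

    A token belongs to an entity when their character spans overlap; the
    first covered token of each entity gets ``B-``, subsequent ones ``I-``.
    """
    tags = ["O"] * len(tokens)
    occupied = [False] * len(tokens)
    for ent in sorted(entities, key=lambda e: e.start):
        first = True
        for i, tok in enumerate(tokens):
            if tok.start < ent.end and ent.start < tok.end:
                if occupied[i]:
                    raise ValueError(
                        f"overlapping entities at token {tok.surface!r} "
                        f"({tok.start}, {tok.end})"
                    )
                occupied[i] = True
                tags[i] = ("B-" if first else "I-") + ent.category
                first = False
    return tags


def bio_to_entities(
    tokens: list[Token], tags: list[str], id_prefix: str = "T", id_start: int = 1
) -> list[Entity]:
    """Decode BIO tags over tokens into contiguous entities."""
    ents: list[Entity] = []
    cur_cat: str | None = None
    cur_start = cur_end = 0
    nid = id_start

    def flush() -> None:
        nonlocal cur_cat, nid
        if cur_cat is not None:
            ents.append(Entity(f"{id_prefix}{nid}", cur_cat, ((cur_start, cur_end),)))
            nid += 1
            cur_cat = None

    for tok, tag in zip(tokens, tags):
        if tag == "O":
            flush()
        elif tag.startswith("B-"):
            flush()
            cur_cat = tag[2:]
            cur_start, cur_end = tok.start, tok.end
        else:  # I-
            cat = tag[2:]
            if cur_cat == cat:
                cur_end = tok.end
            else:  # ill-formed I- treated as B- (BIO repair)
                flush()
                cur_cat = cat
                cur_start, cur_end = tok.start, tok.end
    flush()
    return ents


def to_conll(doc: Document, level: int | None = 1) -> str:
    """Render a document as a CoNLL-style TSV.

    One ``token<TAB>start<TAB>end<TAB>tag`` row per token, blank line
    between sentences.  ``level`` selects the nest level to encode (levels
    computed with :func:`nner.layered.decompose_gold` when entities carry no
    level); ``None`` uses all entities and requires them to be flat.
    """
    if level is None:
        selected = list(doc.entities)
    elif any(e.nest_level is not None for e in doc.entities):
        selected = [e for e in doc.entities if e.nest_level == level]
    else:
        from .layered import decompose_gold

        levels = decompose_gold(doc.entities)
        selected = levels[level - 1] if level <= len(levels) else []
    selected = [e for e in selected if _contiguous(e)]
    lines: list[str] = []
    for sent in doc.sentence_tokens():
        tags = entities_to_bio(sent, [
            e for e in selected
            if any(t.start < e.end and e.start < t.end for t in sent)
        ])
        for tok, tag in zip(sent, tags):
            lines.append(f"{tok.surface}\t{tok.start}\t{tok.end}\t{tag}")
        lines.append("")
    return "\n".join(lines)


def from_conll(table: str, text: str | None = None, doc_id: str = "doc") -> Document:
    """Invert :func:`to_conll`.

    When ``text`` is not given it is reconstructed by placing token surfaces
    at their recorded offsets (gaps filled with spaces).
    """
    sentences: list[list[Token]] = [[]]
    for line in table.splitlines():
        if not line.strip():
            if sentences[-1]:
                sentences.append([])
            continue
        surface, start, end, tag = line.split("\t")
        sentences[-1].append(
            (Token(surface, int(start), int(end), len(sentences) - 1), tag)
        )
    sentences = [s for s in sentences if s]
    if text is None:
        length = max((t.end for sent in sentences for t, _ in sent), default=0)
        chars = [" "] * length
        for sent in sentences:
            for tok, _ in sent:
                chars[tok.start : tok.end] = tok.surface
        text = "".join(chars)
    doc = Document(doc_id, text)
    nid = 1
    for i, sent in enumerate(sentences):
        toks = [t for t, _ in sent]
        tags = [tag for _, tag in sent]
        doc.tokens.extend(toks)
        doc.sentences.append((toks[0].start, toks[-1].end))
        ents = bio_to_entities(toks, tags, id_start=nid)
        nid += len(ents)
        doc.entities.extend(ents)
    doc.validate()
    return doc
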