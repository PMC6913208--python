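"""Cleaning and segmenting clinical text.

Discharge summaries are noisy: de-identification surrogates like
``[**Known lastname 3234**]``, tables, and random newlines break standard
sentence splitters and tokenizers.  This module substitutes every
surrogate with the static token ``DEIDTERM``, re-splits sentences at
newline markers a generic splitter would ignore, re-splits tokens at a
small set of special characters, and keeps a piecewise offset map so that
every processed span can be projected back onto the original text where
the gold annotations live.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .standoff import Document, Token

DEID_TOKEN = "DEIDTERM"
_DEID_RE = re.compile(r"\[\*\*.*?\*\*\]", re.DOTALL)

#: Characters that force token re-splitting.  Both the ASCII tilde and the
#: typographic U+223C variant are accepted.
SPECIAL_CHARS = frozenset("@*?~%()") | {"∼"}

#: Markers that force an extra sentence break immediately after them.
SPLIT_MARKERS = ("\n\n", ":\n", "]\n")

_ABBREVIATIONS = {
    "dr", "mr", "mrs", "ms", "st", "vs", "e.g", "i.e", "etc", "q", "approx",
    "no", "pt", "dx", "hx", "tab", "cap",
}


@dataclass
class OffsetMap:
    """Piecewise-monotone map from processed to original character indices.

    Stored as segments ``(proc_start, proc_end, orig_start, orig_end)``;
    a *copy* segment has equal lengths and maps by shifting, a
    *replacement* segment (lengths differ) maps any processed index inside
    it to the whole original interval.
    """

    segments: list[tuple[int, int, int, int]]

    @classmethod
    def identity(cls, length: int) -> "OffsetMap":
        return cls([(0, length, 0, length)])

    def to_original(self, index: int) -> int:
        for ps, pe, os_, oe in self.segments:
            if ps <= index < pe:
                if pe - ps == oe - os_:
                    return os_ + (index - ps)
                return os_
        if self.segments and index == self.segments[-1][1]:
            return self.segments[-1][3]
        raise IndexError(f"processed index {index} outside map")

    def to_original_span(self, start: int, end: int) -> tuple[int, int]:
        """Map a processed half-open span to original coordinates.

        A span touching a replacement segment expands to cover the whole
        replaced original interval.
        """
        if start >= end:
            o = self.to_original(start)
            return (o, o)
        o_start: int | None = None
        o_end: int | None = None
        for ps, pe, os_, oe in self.segments:
            lo, hi = max(start, ps), min(end, pe)
            if lo >= hi:
                continue
            if pe - ps == oe - os_:
                s, e = os_ + (lo - ps), os_ + (hi - ps)
            else:
                s, e = os_, oe
            o_start = s if o_start is None else min(o_start, s)
            o_end = e if o_end is None else max(o_end, e)
        if o_start is None:
            raise IndexError(f"processed span ({start}, {end}) outside map")
        return (o_start, o_end)


def replace_deid(text: str) -> tuple[str, OffsetMap]:
    """Replace every ``[** ... **]`` surrogate with ``DEIDTERM``."""
    out: list[str] = []
    segments: list[tuple[int, int, int, int]] = []
    ppos = 0
    opos = 0
    for m in _DEID_RE.finditer(text):
        if m.start() > opos:
            chunk = text[opos : m.start()]
            segments.append((ppos, ppos + len(chunk), opos, m.start()))
            out.append(chunk)
            ppos += len(chunk)
        segments.append((ppos, ppos + len(DEID_TOKEN), m.start(), m.end()))
        out.append(DEID_TOKEN)
        ppos += len(DEID_TOKEN)
        opos = m.end()
    if opos < len(text) or not segments:
        chunk = text[opos:]
        segments.append((ppos, ppos + len(chunk), opos, len(text)))
        out.append(chunk)
    return "".join(out), OffsetMap(segments)


def _base_sentence_breaks(text: str) -> list[int]:
    """Candidate break positions after sentence-final punctuation."""
    breaks = []
    for m in re.finditer(r"[.?!]+(?=\s)", text):
        before = text[: m.start()]
        last = re.search(r"(\S+)$", before)
        word = (last.group(1).lower() if last else "").rstrip(".")
        if word in _ABBREVIATIONS:
            continue
        breaks.append(m.end())
    return breaks


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split processed text into sentence spans.

    A baseline splitter breaks after sentence-final punctuation (with an
    abbreviation guard); any candidate sentence containing one of the
    markers ``"\\n\\n"``, ``":\\n"``, ``"]\\n"`` is split again immediately
    after each marker.  Returned spans are trimmed of surrounding
    whitespace and tile the text in order.
    """
    cuts = [0] + _base_sentence_breaks(text) + [len(text)]
    spans: list[tuple[int, int]] = []
    for a, b in zip(cuts, cuts[1:]):
        if a >= b:
            continue
        # extra splits after each marker occurrence
        sub_cuts = [a]
        for marker in SPLIT_MARKERS:
            pos = text.find(marker, a, b)
            while pos != -1:
                sub_cuts.append(pos + len(marker))
                pos = text.find(marker, pos + 1, b)
        sub_cuts = sorted(set(sub_cuts)) + [b]
        for s, e in zip(sub_cuts, sub_cuts[1:]):
            while s < e and text[s].isspace():
                s += 1
            while e > s and text[e - 1].isspace():
                e -= 1
            if s < e:
                spans.append((s, e))
    return spans


_BASE_TOKEN_RE = re.compile(r"\d+\.\d+|[A-Za-z0-9'\-]+|\S")


def split_special(surface: str, start: int) -> list[tuple[str, int, int]]:
    """Split a token so each special character stands alone."""
    parts: list[tuple[str, int, int]] = []
    buf_start = 0
    for i, ch in enumerate(surface):
        if ch in SPECIAL_CHARS:
            if i > buf_start:
                parts.append((surface[buf_start:i], start + buf_start, start + i))
            parts.append((ch, start + i, start + i + 1))
            buf_start = i + 1
    if buf_start < len(surface):
        parts.append((surface[buf_start:], start + buf_start, start + len(surface)))
    return parts


def tokenize(text: str, span: tuple[int, int] | None = None,
             sentence_index: int = 0) -> list[Token]:
    """Tokenize one sentence of processed text.

    Offsets are on the processed text; callers map them back through the
    :class:`OffsetMap`.
    """
    s, e = span if span is not None else (0, len(text))
    tokens: list[Token] = []
    for m in _BASE_TOKEN_RE.finditer(text, s, e):
        for surf, ts, te in split_special(m.group(), m.start()):
            if surf:
                tokens.append(Token(surf, ts, te, sentence_index))
    return tokens


def word_shape(token: str) -> str:
    """Orthographic shape: uppercase→A, lowercase→a, digit→#, rest verbatim."""
    out = []
    for ch in token:
        if ch.isupper():
            out.append("A")
        elif ch.islower():
            out.append("a")
        elif ch.isdigit():
            out.append("#")
        else:
            out.append(ch)
    return "".join(out)


def preprocess_document(doc: Document, deid: bool = True) -> Document:
    """Fill ``doc.sentences`` and ``doc.tokens`` in original coordinates.

    Token surfaces come from the processed text (so a surrogate shows as
    ``DEIDTERM``) while offsets are mapped back to the original text.
    """
    if deid:
        processed, omap = replace_deid(doc.text)
    else:
        processed, omap = doc.text, OffsetMap.identity(len(doc.text))
    doc.sentences = []
    doc.tokens = []
    for si, (s, e) in enumerate(split_sentences(processed)):
        os_, oe = omap.to_original_span(s, e)
        doc.sentences.append((os_, oe))
        for tok in tokenize(processed, (s, e), si):
            ts, te = omap.to_original_span(tok.start, tok.end)
            doc.tokens.append(Token(tok.surface, ts, te, si))
    return doc
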