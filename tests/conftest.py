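from __future__ import annotations

import numpy as np
import pytest

from nner.standoff import CATEGORIES, Document, Entity


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_random_document(rng: np.random.Generator, doc_id: str,
                         allow_nesting: bool = True) -> Document:
    """A random valid document with token-aligned entities.

    Includes occasional polysemous duplicates and discontinuous fragments
    so the standoff round-trip is exercised on the full data model.
    """
    n_words = int(rng.integers(4, 15))
    words = [
        "".join(chr(97 + rng.integers(0, 26)) for _ in range(rng.integers(2, 8)))
        for _ in range(n_words)
    ]
    spans = []
    pos = 0
    for w in words:
        spans.append((pos, pos + len(w)))
        pos += len(w) + 1
    text = " ".join(words)
    entities: list[Entity] = []
    nid = 1
    used: set[int] = set()
    for _ in range(int(rng.integers(0, 4))):
        i = int(rng.integers(0, n_words))
        j = min(n_words, i + int(rng.integers(1, 3)))
        if any(k in used for k in range(i, j)):
            continue
        used.update(range(i, j))
        cat = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
        frag = ((spans[i][0], spans[j - 1][1]),)
        entities.append(Entity(f"T{nid}", cat, frag))
        nid += 1
        if rng.random() < 0.2:  # polysemous duplicate
            other = CATEGORIES[int(rng.integers(len(CATEGORIES)))]
            if other != cat:
                entities.append(Entity(f"T{nid}", other, frag))
                nid += 1
    if n_words >= 6 and rng.random() < 0.3:
        # a discontinuous entity over two word fragments
        free = [k for k in range(n_words) if k not in used]
        if len(free) >= 2:
            a, b = sorted(rng.choice(free, size=2, replace=False).tolist())
            if a != b:
                entities.append(
                    Entity(f"T{nid}", "Duration", (spans[a], spans[b]))
                )
    doc = Document(doc_id, text, entities)
    doc.validate()
    return doc
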