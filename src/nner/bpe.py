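"""Byte pair encoding for subword-level sequence labeling.

Rare and unknown words are frequent in clinical notes and hard to label at
the word level.  BPE induces a subword vocabulary by iteratively merging
the most frequent pair of adjacent symbols over the training words; words
are then segmented by replaying the learned merges, labels are projected
from words onto subwords for training (``B-X`` on the first piece, ``I-X``
on the rest), and predicted subword labels are merged back by keeping each
word's first subword label.

Word-initial subwords carry the prefix marker ``-`` standing for the
preceding whitespace, e.g. ``vincristine`` → ``-v in c r ist ine`` under a
small model.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

MARKER = "-"


@dataclass
class BPEModel:
    merges: list[tuple[str, str]]
    vocab: dict[str, int]
    vocab_size_target: int
    marker: str = MARKER
    _cache: dict[str, tuple[str, ...]] = field(default_factory=dict, repr=False)

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#vocab_size_target\t{self.vocab_size_target}\n")
            fh.write("#vocab\n")
            for sub, idx in sorted(self.vocab.items(), key=lambda kv: kv[1]):
                fh.write(f"{sub}\t{idx}\n")
            fh.write("#merges\n")
            for a, b in self.merges:
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def load(cls, path: str) -> "BPEModel":
        vocab: dict[str, int] = {}
        merges: list[tuple[str, str]] = []
        target = 0
        section = ""
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#vocab_size_target"):
                    target = int(line.split("\t")[1])
                elif line in ("#vocab", "#merges"):
                    section = line
                elif section == "#vocab" and line:
                    sub, idx = line.split("\t")
                    vocab[sub] = int(idx)
                elif section == "#merges" and line:
                    a, b = line.split("\t")
                    merges.append((a, b))
        return cls(merges, vocab, target)


def word_to_symbols(word: str, marker: str = MARKER) -> tuple[str, ...]:
    if not word:
        raise ValueError("cannot segment an empty word")
    return (marker + word[0],) + tuple(word[1:])


def _merge_symbols(symbols: tuple[str, ...], pair: tuple[str, str]) -> tuple[str, ...]:
    """Merge all non-overlapping occurrences of ``pair``, left to right."""
    out: list[str] = []
    i = 0
    n = len(symbols)
    while i < n:
        if i + 1 < n and symbols[i] == pair[0] and symbols[i + 1] == pair[1]:
            out.append(symbols[i] + symbols[i + 1])
            i += 2
        else:
            out.append(symbols[i])
            i += 1
    return tuple(out)


def count_pairs(
    segmentations: Mapping[tuple[str, ...], int]
) -> Counter[tuple[str, str]]:
    """Frequency-weighted counts of adjacent symbol pairs.

    Overlapping occurrences within one word count once per non-overlapping
    left-to-right occurrence, matching what a merge would actually replace
    (``a a a`` contains one mergeable ``(a, a)``).
    """
    counts: Counter[tuple[str, str]] = Counter()
    for symbols, freq in segmentations.items():
        i = 0
        while i + 1 < len(symbols):
            counts[(symbols[i], symbols[i + 1])] += freq
            if symbols[i] == symbols[i + 1]:
                i += 2  # overlapping pair of a repeated symbol merges once
            else:
                i += 1
    return counts


def train_bpe(
    words: Mapping[str, int] | Iterable[str],
    vocab_size: int,
    weighted: bool = True,
    marker: str = MARKER,
) -> BPEModel:
    """Learn a BPE model from the training words.

    ``words`` is a multiset (mapping word → frequency, or an iterable with
    repeats).  Merging proceeds greedily by pair frequency — ties broken
    lexicographically on the ``(left, right)`` symbol pair — and stops when
    the vocabulary (initial characters + one new symbol per merge) reaches
    ``vocab_size`` or no pair occurs at least twice.  ``weighted=False``
    counts each distinct word once.
    """
    if not isinstance(words, Mapping):
        words = Counter(words)
    if not words:
        raise ValueError("empty training word set")
    freqs = {w: (c if weighted else 1) for w, c in words.items()}
    segs: dict[tuple[str, ...], int] = {}
    for w, c in freqs.items():
        sym = word_to_symbols(w, marker)
        segs[sym] = segs.get(sym, 0) + c

    inventory: list[str] = sorted({s for sym in segs for s in sym})
    if vocab_size < len(inventory):
        raise ValueError(
            f"vocab_size {vocab_size} below character inventory "
            f"({len(inventory)} symbols)"
        )
    merges: list[tuple[str, str]] = []
    vocab_symbols = list(inventory)
    while len(vocab_symbols) < vocab_size:
        counts = count_pairs(segs)
        if not counts:
            break
        best_count = max(counts.values())
        if best_count < 2:
            break
        best = min(p for p, c in counts.items() if c == best_count)
        merges.append(best)
        vocab_symbols.append(best[0] + best[1])
        segs = _apply_merge_to_segs(segs, best)
    vocab = {s: i for i, s in enumerate(vocab_symbols)}
    return BPEModel(merges, vocab, vocab_size, marker)


def _apply_merge_to_segs(
    segs: dict[tuple[str, ...], int], pair: tuple[str, str]
) -> dict[tuple[str, ...], int]:
    out: dict[tuple[str, ...], int] = {}
    for symbols, freq in segs.items():
        merged = _merge_symbols(symbols, pair)
        out[merged] = out.get(merged, 0) + freq
    return out


def apply_bpe(word: str, model: BPEModel) -> list[str]:
    """Segment ``word`` by replaying the model's merges in training order.

    Words seen in training reproduce their training-time segmentation
    exactly; unknown characters simply remain single-character subwords.
    """
    cached = model._cache.get(word)
    if cached is not None:
        return list(cached)
    symbols = word_to_symbols(word, model.marker)
    for pair in model.merges:
        if len(symbols) == 1:
            break
        symbols = _merge_symbols(symbols, pair)
    model._cache[word] = symbols
    return list(symbols)


def segment_sentence(
    words: list[str], model: BPEModel
) -> tuple[list[str], list[int]]:
    """Segment a word sequence; returns (subwords, per-word piece counts)."""
    subwords: list[str] = []
    alignment: list[int] = []
    for w in words:
        pieces = apply_bpe(w, model)
        subwords.extend(pieces)
        alignment.append(len(pieces))
    return subwords, alignment


def project_labels_to_subwords(
    word_labels: list[str], alignment: list[int]
) -> list[str]:
    """Project word-level BIO labels onto subwords.

    The first subword of a ``B-X`` word keeps ``B-X``; every other subword
    of an entity word gets ``I-X``; subwords of ``O`` words get ``O``.
    """
    if len(word_labels) != len(alignment):
        raise ValueError(
            f"{len(word_labels)} labels vs {len(alignment)} aligned words"
        )
    out: list[str] = []
    for label, n in zip(word_labels, alignment):
        if n < 1:
            raise ValueError("alignment contains an empty word")
        if label == "O":
            out.extend(["O"] * n)
        else:
            cat = label[2:]
            out.append(label)
            out.extend([f"I-{cat}"] * (n - 1))
    return out


def merge_subword_labels(
    subword_labels: list[str], alignment: list[int], repair: bool = True
) -> list[str]:
    """Merge subword labels back to word labels: keep each word's FIRST
    subword label.

    With ``repair`` (default) a BIO-repair pass then rewrites any ``I-X``
    not preceded by ``B-X``/``I-X`` into ``B-X`` so downstream decoding
    always sees well-formed BIO.
    """
    if sum(alignment) != len(subword_labels):
        raise ValueError(
            f"{len(subword_labels)} subword labels vs alignment covering "
            f"{sum(alignment)}"
        )
    out: list[str] = []
    pos = 0
    for n in alignment:
        out.append(subword_labels[pos])
        pos += n
    return bio_repair(out) if repair else out


def bio_repair(labels: list[str]) -> list[str]:
    """Rewrite ill-formed ``I-X`` (no ``B-X``/``I-X`` head) into ``B-X``."""
    out: list[str] = []
    prev = "O"
    for lab in labels:
        if lab.startswith("I-") and prev not in (f"B-{lab[2:]}", f"I-{lab[2:]}"):
            lab = "B-" + lab[2:]
        out.append(lab)
        prev = lab
    return out
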