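"""Deterministic generator of clinical-style annotated corpora.

The real medication/ADE corpus is access-restricted, so every stage of
the pipeline is exercised on generated documents that reproduce its
*structural* challenges: medication sentences with attribute entities,
Drug mentions nested inside Reason/ADE phrases, polysemous spans carrying
both Reason and ADE, de-identification surrogates ``[** ... **]``, noisy
newlines and section headers, morphologically regular pseudo-drug names
(shared suffix families, so BPE has something to learn), and held-out
drug names that appear only in the test split (unknown-word probes).

Generation is a pure function of :class:`SynthConfig` — the same config
yields a byte-identical corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .standoff import CATEGORIES, Document, Entity

# -- lexicons ---------------------------------------------------------------

_DRUG_PREFIXES = [
    "velo", "dora", "xani", "mira", "lofe", "bexa", "cari", "tuna",
    "zopi", "fane", "geld", "hyra", "juve", "kelo", "nimo", "pexa",
]
_HELDOUT_PREFIXES = ["quar", "rilo", "sava", "tebo"]
_DRUG_SUFFIXES = [
    "micin", "pril", "olol", "statin", "azole", "cycline", "parin",
    "mab", "zide", "oxetine",
]
_STRENGTH_UNITS = ["mg", "mcg", "g", "mL", "units"]
_DOSAGES = ["one", "two", "three", "1", "2", "3"]
_FORMS = ["tablet", "capsule", "puff", "solution", "cream", "patch"]
_ROUTES = [
    "by mouth", "orally", "IV", "intravenously", "subcutaneously",
    "topically", "via inhalation",
]
_FREQUENCIES = [
    "daily", "twice daily", "three times daily", "q8h", "q12h", "q6h",
    "at bedtime", "every morning", "as needed", "once weekly",
]
_DURATION_NUMS = ["5", "7", "10", "14", "two", "three"]
_DURATION_UNITS = ["days", "weeks"]
_REASONS = [
    "back pain", "hypertension", "anxiety", "high cholesterol",
    "atrial fibrillation", "seizures", "constipation", "insomnia",
    "chest pain", "migraine", "gout", "depression",
]
_ADES = [
    "rash", "nausea", "dizziness", "acute renal failure",
    "thrombocytopenia", "angioedema", "drowsiness", "pruritus",
    "hyperkalemia", "dry cough",
]
#: Conditions used only as polysemous spans: they read both as the reason
#: for a prescription and as a drug-induced event, so they carry both
#: categories — a learnable lexical cue for the polysemy machinery.
_DUAL_CONDITIONS = [
    "worsening rash", "persistent nausea", "recurrent dizziness",
    "ongoing pruritus", "refractory hyperkalemia",
]
_OPENERS = [
    "Patient was started on", "The patient continued", "She was given",
    "He received", "We restarted", "Continue",
]
_NEST_CONNECTORS = ["from", "due to", "secondary to"]
_HEADERS = ["Medications:\n", "Allergies:\n", "Hospital Course:\n", "Plan:\n"]

_TABLE1_MIX = {
    "ADE": 785, "Dosage": 3401, "Drug": 13109, "Duration": 499,
    "Form": 5340, "Frequency": 5075, "Reason": 3105, "Route": 4479,
    "Strength": 5378,
}


@dataclass
class SynthConfig:
    n_documents: int = 50
    sentences_per_doc: int = 10
    seed: int = 0
    category_mix: dict[str, int] = field(
        default_factory=lambda: dict(_TABLE1_MIX)
    )
    nesting_rate: float = 0.3
    polysemy_rate: float = 0.1
    rare_word_rate: float = 0.3
    deid_rate: float = 0.1
    noise_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("nesting_rate", "polysemy_rate", "rare_word_rate",
                     "deid_rate", "noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        unknown = set(self.category_mix) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in mix: {sorted(unknown)}")
        if self.nesting_rate > 0 and self.category_mix.get("Drug", 0) <= 0:
            raise ValueError("nesting requires non-zero Drug mass")


@dataclass
class SynthCorpus:
    train: list[Document]
    dev: list[Document]
    test: list[Document]

    @property
    def all_documents(self) -> list[Document]:
        return self.train + self.dev + self.test


class _SentenceBuilder:
    def __init__(self, offset: int):
        self.offset = offset
        self.parts: list[str] = []
        self.cursor = offset
        self.entities: list[tuple[int, int, str]] = []

    def add(self, text: str) -> tuple[int, int]:
        start = self.cursor
        self.parts.append(text)
        self.cursor += len(text)
        return start, self.cursor

    def add_entity(self, text: str, category: str) -> tuple[int, int]:
        span = self.add(text)
        self.entities.append((*span, category))
        return span

    def text(self) -> str:
        return "".join(self.parts)


def _rand_word(rng: np.random.Generator, syllables: int = 3) -> str:
    cons = "bcdfghklmnprstvz"
    vow = "aeiou"
    return "".join(
        cons[rng.integers(len(cons))] + vow[rng.integers(len(vow))]
        for _ in range(syllables)
    )


def _drug_names() -> tuple[list[str], list[str]]:
    train = [p + s for p in _DRUG_PREFIXES for s in _DRUG_SUFFIXES]
    heldout = [p + s for p in _HELDOUT_PREFIXES for s in _DRUG_SUFFIXES]
    return train, heldout


def _pick(rng: np.random.Generator, items: list[str]) -> str:
    return items[int(rng.integers(len(items)))]


def generate_corpus(config: SynthConfig) -> SynthCorpus:
    """Generate an annotated corpus with a train/dev/test split (60/20/20).

    Held-out drug names occur only in test documents, emulating unknown
    words; fresh random filler words (mostly frequency 1) emulate the
    rare-word load of real notes.
    """
    rng = np.random.default_rng(config.seed)
    train_drugs, heldout_drugs = _drug_names()
    mix = config.category_mix
    drug_mass = max(mix.get("Drug", 0), 1)

    def slot_p(cat: str) -> float:
        return min(1.0, mix.get(cat, 0) / drug_mass)

    def build_sentence(offset: int, split: str) -> _SentenceBuilder:
        b = _SentenceBuilder(offset)
        if rng.random() < config.deid_rate:
            if rng.random() < 0.5:
                y, m, d = rng.integers(10, 99), rng.integers(1, 13), rng.integers(1, 29)
                b.add(f"On [**21{y}-{m}-{d}**] ")
            else:
                b.add(f"Seen by [**Known lastname {rng.integers(100, 9999)}**] ")
        b.add(_pick(rng, _OPENERS) + " ")
        if split == "test" and rng.random() < 0.2:
            drug = _pick(rng, heldout_drugs)
        else:
            drug = _pick(rng, train_drugs)
        b.add_entity(drug, "Drug")
        if rng.random() < slot_p("Strength"):
            b.add(" ")
            if rng.random() < 0.1:  # digits-symbol-digits pattern
                s = f"{rng.integers(10, 500)}({rng.integers(1, 9)}"
            else:
                num = (f"{rng.integers(1, 50)}.5" if rng.random() < 0.2
                       else str(rng.integers(1, 1000)))
                s = f"{num} {_pick(rng, _STRENGTH_UNITS)}"
            b.add_entity(s, "Strength")
        if rng.random() < slot_p("Dosage"):
            b.add(" ")
            b.add_entity(_pick(rng, _DOSAGES), "Dosage")
            b.add(" ")
            b.add_entity(_pick(rng, _FORMS), "Form")
        elif rng.random() < slot_p("Form"):
            b.add(" ")
            b.add_entity(_pick(rng, _FORMS), "Form")
        if rng.random() < slot_p("Route"):
            b.add(" ")
            b.add_entity(_pick(rng, _ROUTES), "Route")
        if rng.random() < slot_p("Frequency"):
            b.add(" ")
            b.add_entity(_pick(rng, _FREQUENCIES), "Frequency")
        if rng.random() < slot_p("Duration"):
            b.add(" ")
            dur = (f"for {_pick(rng, _DURATION_NUMS)} "
                   f"{_pick(rng, _DURATION_UNITS)}")
            b.add_entity(dur, "Duration")
        if rng.random() < slot_p("Reason"):
            b.add(" for ")
            polysemous = rng.random() < config.polysemy_rate
            head = (_pick(rng, _DUAL_CONDITIONS) if polysemous
                    else _pick(rng, _REASONS))
            if rng.random() < config.nesting_rate:
                start = b.cursor
                b.add(head + " " + _pick(rng, _NEST_CONNECTORS) + " ")
                inner = _pick(rng, train_drugs)
                b.add_entity(inner, "Drug")
                b.entities.append((start, b.cursor, "Reason"))
                if polysemous:
                    b.entities.append((start, b.cursor, "ADE"))
            else:
                span = b.add_entity(head, "Reason")
                if polysemous:
                    b.entities.append((*span, "ADE"))
        if rng.random() < slot_p("ADE"):
            b.add(" but developed ")
            head = _pick(rng, _ADES)
            if rng.random() < config.nesting_rate:
                start = b.cursor
                b.add(head + " " + _pick(rng, _NEST_CONNECTORS) + " ")
                b.add_entity(_pick(rng, train_drugs), "Drug")
                b.entities.append((start, b.cursor, "ADE"))
            else:
                b.add_entity(head, "ADE")
        if rng.random() < config.rare_word_rate:
            b.add(f" ( see {_rand_word(rng)} notes )")
        b.add(".")
        return b

    def build_document(doc_id: str, split: str) -> Document:
        pieces: list[str] = []
        entities: list[tuple[int, int, str]] = []
        cursor = 0
        if rng.random() < config.noise_rate * 2:
            header = _pick(rng, _HEADERS)
            pieces.append(header)
            cursor += len(header)
        for si in range(config.sentences_per_doc):
            b = build_sentence(cursor, split)
            sent_text = b.text()
            if rng.random() < config.noise_rate:
                # replace one inter-word space with a newline; entity
                # offsets are unaffected (same length)
                spaces = [
                    i for i, ch in enumerate(sent_text)
                    if ch == " " and not any(
                        s <= b.offset + i < e for s, e, _ in b.entities
                    )
                ]
                if spaces:
                    i = spaces[int(rng.integers(len(spaces)))]
                    sent_text = sent_text[:i] + "\n" + sent_text[i + 1:]
            pieces.append(sent_text)
            entities.extend(b.entities)
            cursor += len(sent_text)
            if si + 1 < config.sentences_per_doc:
                sep = "\n\n" if rng.random() < config.noise_rate else " "
                pieces.append(sep)
                cursor += len(sep)
        text = "".join(pieces)
        ents = [
            Entity(f"T{i + 1}", cat, ((s, e),))
            for i, (s, e, cat) in enumerate(sorted(entities))
        ]
        doc = Document(doc_id, text, ents)
        doc.validate()
        for ent in doc.entities:  # offsets must slice to the surface
            assert doc.text[ent.start:ent.end].strip() == doc.text[ent.start:ent.end]
        return doc

    n = config.n_documents
    n_train = max(1, int(round(n * 0.6)))
    n_dev = max(1, int(round(n * 0.2))) if n > 2 else 0
    splits = (["train"] * n_train + ["dev"] * n_dev
              + ["test"] * (n - n_train - n_dev))
    corpus = SynthCorpus([], [], [])
    for i, split in enumerate(splits):
        doc = build_document(f"synth-{split}-{i:04d}", split)
        getattr(corpus, split).append(doc)
    return corpus


# ---------------------------------------------------------------------------
# Controlled degradation — closed-loop fixtures for the scorer
# ---------------------------------------------------------------------------


@dataclass
class DegradeProfile:
    """Exact numbers of each edit applied to a gold corpus."""

    n_widen: int = 0       # -> "Includes" matches
    n_narrow: int = 0      # -> "Is included"
    n_shift: int = 0       # -> "Partial overlap"
    n_swap: int = 0        # category swap -> CE false positives
    n_hallucinate: int = 0  # spurious spans -> SE false positives
    n_delete: int = 0      # -> false negatives
    seed: int = 0

    @property
    def n_span_edits(self) -> int:
        return self.n_widen + self.n_narrow + self.n_shift

    @property
    def n_entity_edits(self) -> int:
        return self.n_span_edits + self.n_swap + self.n_delete


def expected_report(n_gold: int, profile: DegradeProfile) -> dict:
    """The scorer outcome the profile's edits must produce."""
    p = profile
    lenient_tp = n_gold - p.n_swap - p.n_delete
    return {
        "lenient": {
            "tp": lenient_tp,
            "fp": p.n_swap + p.n_hallucinate,
            "fn": p.n_swap + p.n_delete,
        },
        "strict": {
            "tp": n_gold - p.n_entity_edits,
            "fp": p.n_entity_edits - p.n_delete + p.n_hallucinate,
            "fn": p.n_entity_edits,
        },
        "match_types": {
            "Strict": lenient_tp - p.n_span_edits,
            "Includes": p.n_widen,
            "Is included": p.n_narrow,
            "Partial overlap": p.n_shift,
        },
        "errors": {"CE": p.n_swap, "SE": p.n_hallucinate},
    }


def _eligible(doc: Document) -> list[Entity]:
    """Entities safe to edit without disturbing any other gold entity:
    contiguous, length >= 4, >= 3 chars from every other entity, and with
    >= 2 chars of document margin."""
    out = []
    for e in doc.entities:
        if len(e.fragments) != 1:
            continue
        s, ee = e.fragments[0]
        if ee - s < 4 or s < 2 or ee + 2 > len(doc.text):
            continue
        ok = True
        for o in doc.entities:
            if o is e:
                continue
            if o.start < ee + 3 and s - 3 < o.end:
                ok = False
                break
        if ok:
            out.append(e)
    return out


def degrade_predictions(
    gold_docs: list[Document], profile: DegradeProfile
) -> tuple[list[Document], dict]:
    """Apply the profile's edits to copies of the gold annotations.

    Returns the synthetic prediction documents and the exact score
    bookkeeping (:func:`expected_report`).  Each edit targets a distinct,
    isolated entity, so the intended match/error type is guaranteed.
    """
    rng = np.random.default_rng(profile.seed)
    pool: list[tuple[int, Entity]] = []
    for di, doc in enumerate(gold_docs):
        pool.extend((di, e) for e in _eligible(doc))
    if len(pool) < profile.n_entity_edits:
        raise ValueError(
            f"profile needs {profile.n_entity_edits} editable entities, "
            f"only {len(pool)} are eligible"
        )
    order = rng.permutation(len(pool))
    picks = [pool[i] for i in order[: profile.n_entity_edits]]
    plan: dict[tuple[int, str], str] = {}
    kinds = (
        ["widen"] * profile.n_widen + ["narrow"] * profile.n_narrow
        + ["shift"] * profile.n_shift + ["swap"] * profile.n_swap
        + ["delete"] * profile.n_delete
    )
    for (di, ent), kind in zip(picks, kinds):
        plan[(di, ent.entity_id)] = kind

    pred_docs: list[Document] = []
    n_halluc_left = profile.n_hallucinate
    for di, doc in enumerate(gold_docs):
        pred = Document(doc.doc_id, doc.text)
        nid = 1
        for ent in doc.entities:
            kind = plan.get((di, ent.entity_id))
            s, e = ent.start, ent.end
            if kind == "delete":
                continue
            if kind == "widen":
                span, cat = (s - 2, e + 2), ent.category
            elif kind == "narrow":
                span, cat = (s + 1, e - 1), ent.category
            elif kind == "shift":
                span, cat = (s + 1, e + 1), ent.category
            elif kind == "swap":
                others = [c for c in CATEGORIES if c != ent.category]
                span, cat = (s, e), others[int(rng.integers(len(others)))]
            else:
                span, cat = (s, e), ent.category
            pred.entities.append(Entity(f"T{nid}", cat, (span,)))
            nid += 1
        # hallucinations: spans over text regions clear of every entity
        if n_halluc_left > 0:
            occupied = sorted(
                [(x.start - 1, x.end + 1) for x in doc.entities]
                + [(x.start, x.end) for x in pred.entities]
            )
            pos = 0
            import re as _re

            for m in _re.finditer(r"[A-Za-z]{3,}", doc.text):
                if n_halluc_left == 0:
                    break
                a, b = m.start(), m.end()
                if any(a < oe and os_ < b for os_, oe in occupied):
                    continue
                pred.entities.append(Entity(f"T{nid}", "Drug", ((a, b),)))
                occupied.append((a, b))
                nid += 1
                n_halluc_left -= 1
            _ = pos
        pred_docs.append(pred)
    if n_halluc_left > 0:
        raise ValueError("not enough free text regions for hallucinations")
    n_gold = sum(len(d.entities) for d in gold_docs)
    return pred_docs, expected_report(n_gold, profile)


def flat_copy(config: SynthConfig) -> SynthConfig:
    """The same study conditions without nesting or polysemy."""
    return replace(config, nesting_rate=0.0, polysemy_rate=0.0)
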