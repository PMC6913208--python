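"""Scoring and error analysis for entity predictions.

Two regimes are computed side by side:

* **strict** — a prediction is correct iff its category and its exact
  character fragments both match a gold entity;
* **lenient** — correct iff the category matches and the spans overlap at
  all (the primary shared-task regime for this task).

Matching is one-to-one: exact (category, fragments) pairs are matched
first, then remaining candidates greedily in descending overlap order, so
the strict true-positive set is always a subset of the lenient one.
Lenient true positives are further broken down into four matching types
(Strict / Includes / Is included / Partial overlap) and false positives
into category errors (CE: right region, wrong category) versus span
errors (SE: no gold overlap at all).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .standoff import CATEGORIES, Document, Entity

MATCH_TYPES = ("Strict", "Includes", "Is included", "Partial overlap")


def _union_intervals(ent: Entity) -> list[tuple[int, int]]:
    return list(ent.fragments)


def overlap_length(a: Entity, b: Entity) -> int:
    """Length of the intersection of the two fragment unions."""
    total = 0
    for s1, e1 in a.fragments:
        for s2, e2 in b.fragments:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def _covers(outer: Entity, inner: Entity) -> bool:
    """Every character of ``inner`` lies inside ``outer``'s fragments."""
    for s, e in inner.fragments:
        pos = s
        for os_, oe in outer.fragments:
            if os_ <= pos and e <= oe:
                pos = e
                break
            if os_ <= pos < oe:
                pos = oe
        if pos < e:
            return False
    return True


def classify_match(gold: Entity, pred: Entity) -> str:
    """Matching type of a lenient true-positive pair."""
    if overlap_length(gold, pred) == 0:
        raise ValueError("classify_match requires an overlapping pair")
    if gold.fragments == pred.fragments:
        return "Strict"
    if _covers(pred, gold):
        return "Includes"  # prediction wider than gold
    if _covers(gold, pred):
        return "Is included"  # prediction narrower than gold
    return "Partial overlap"


@dataclass
class MatchResult:
    pairs: list[tuple[Entity, Entity]]  # (gold, pred) true positives
    false_positives: list[Entity]
    false_negatives: list[Entity]

    @property
    def tp(self) -> int:
        return len(self.pairs)


def match_entities(
    gold: list[Entity], pred: list[Entity], regime: str = "lenient"
) -> MatchResult:
    """One-to-one matching between gold and predicted entities.

    Both lists must describe the same document (offsets in the same
    frame).  Duplicate (category, fragments) predictions are kept — the
    duplicates count as false positives.
    """
    if regime not in ("strict", "lenient"):
        raise ValueError(f"unknown regime {regime!r}")
    gold_open = list(range(len(gold)))
    pred_open = list(range(len(pred)))
    pairs: list[tuple[Entity, Entity]] = []

    # pass 1: exact matches (this IS the strict matching)
    by_key: dict[tuple, list[int]] = {}
    for gi in gold_open:
        by_key.setdefault((gold[gi].category, gold[gi].fragments), []).append(gi)
    used_g: set[int] = set()
    used_p: set[int] = set()
    for pi in pred_open:
        key = (pred[pi].category, pred[pi].fragments)
        cands = [gi for gi in by_key.get(key, []) if gi not in used_g]
        if cands:
            gi = cands[0]
            used_g.add(gi)
            used_p.add(pi)
            pairs.append((gold[gi], pred[pi]))

    if regime == "lenient":
        # pass 2: greedy descending-overlap on the remainder
        cands = []
        for gi in gold_open:
            if gi in used_g:
                continue
            for pi in pred_open:
                if pi in used_p:
                    continue
                if gold[gi].category != pred[pi].category:
                    continue
                ov = overlap_length(gold[gi], pred[pi])
                if ov > 0:
                    cands.append((-ov, gold[gi].start, pred[pi].start, gi, pi))
        for _, _, _, gi, pi in sorted(cands):
            if gi in used_g or pi in used_p:
                continue
            used_g.add(gi)
            used_p.add(pi)
            pairs.append((gold[gi], pred[pi]))

    fps = [pred[pi] for pi in pred_open if pi not in used_p]
    fns = [gold[gi] for gi in gold_open if gi not in used_g]
    return MatchResult(pairs, fps, fns)


def classify_errors(
    gold: list[Entity], false_positives: list[Entity]
) -> Counter:
    """CE/SE taxonomy of lenient false positives.

    A false positive whose span overlaps some gold entity of a *different*
    category is a category error (CE); one with no such overlap is a span
    error (SE).
    """
    counts: Counter = Counter()
    for fp in false_positives:
        is_ce = any(
            g.category != fp.category and overlap_length(g, fp) > 0
            for g in gold
        )
        counts["CE" if is_ce else "SE"] += 1
    return counts


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


@dataclass
class EvalReport:
    """Per-category and micro scores plus the fine-grained breakdowns."""

    strict: dict[str, dict[str, float]] = field(default_factory=dict)
    lenient: dict[str, dict[str, float]] = field(default_factory=dict)
    match_types: Counter = field(default_factory=Counter)
    errors: Counter = field(default_factory=Counter)  # CE / SE
    per_category_errors: dict[str, Counter] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "strict": self.strict,
            "lenient": self.lenient,
            "match_types": dict(self.match_types),
            "errors": dict(self.errors),
            "per_category_errors": {
                k: dict(v) for k, v in self.per_category_errors.items()
            },
        }

    def to_tsv(self) -> str:
        lines = ["regime\tcategory\tTP\tFP\tFN\tprecision\trecall\tf1"]
        for regime, table in (("strict", self.strict), ("lenient", self.lenient)):
            for cat in list(CATEGORIES) + ["micro"]:
                row = table.get(cat)
                if row is None:
                    continue
                lines.append(
                    f"{regime}\t{cat}\t{row['tp']}\t{row['fp']}\t{row['fn']}\t"
                    f"{row['precision']:.4f}\t{row['recall']:.4f}\t{row['f1']:.4f}"
                )
        return "\n".join(lines)


def score_documents(
    gold_docs: list[Document], pred_docs: list[Document]
) -> EvalReport:
    """Aggregate matching over paired documents into an :class:`EvalReport`.

    Documents are paired by ``doc_id``; a prediction document without a
    gold counterpart is an error.  Micro scores pool TP/FP/FN over
    categories.
    """
    gold_by_id = {d.doc_id: d for d in gold_docs}
    for d in pred_docs:
        if d.doc_id not in gold_by_id:
            raise ValueError(f"prediction for unknown document {d.doc_id!r}")
    pred_by_id = {d.doc_id: d for d in pred_docs}

    counts = {
        regime: {cat: Counter() for cat in CATEGORIES} for regime in ("strict", "lenient")
    }
    match_types: Counter = Counter()
    error_counts: Counter = Counter()
    per_cat_err: dict[str, Counter] = {cat: Counter() for cat in CATEGORIES}

    for doc_id, gdoc in gold_by_id.items():
        pdoc = pred_by_id.get(doc_id)
        pred_entities = pdoc.entities if pdoc is not None else []
        for regime in ("strict", "lenient"):
            res = match_entities(gdoc.entities, pred_entities, regime)
            for g, p in res.pairs:
                counts[regime][g.category]["tp"] += 1
                if regime == "lenient":
                    match_types[classify_match(g, p)] += 1
            for fp in res.false_positives:
                counts[regime][fp.category]["fp"] += 1
            for fn in res.false_negatives:
                counts[regime][fn.category]["fn"] += 1
            if regime == "lenient":
                errs = classify_errors(gdoc.entities, res.false_positives)
                error_counts.update(errs)
                for fp in res.false_positives:
                    is_ce = any(
                        g.category != fp.category and overlap_length(g, fp) > 0
                        for g in gdoc.entities
                    )
                    per_cat_err[fp.category]["CE" if is_ce else "SE"] += 1

    report = EvalReport(
        match_types=match_types,
        errors=error_counts,
        per_category_errors=per_cat_err,
    )
    for regime, table in (("strict", report.strict), ("lenient", report.lenient)):
        micro = Counter()
        for cat in CATEGORIES:
            c = counts[regime][cat]
            micro.update(c)
            p, r, f = _prf(c["tp"], c["fp"], c["fn"])
            table[cat] = {
                "tp": c["tp"], "fp": c["fp"], "fn": c["fn"],
                "precision": p, "recall": r, "f1": f,
            }
        p, r, f = _prf(micro["tp"], micro["fp"], micro["fn"])
        table["micro"] = {
            "tp": micro["tp"], "fp": micro["fp"], "fn": micro["fn"],
            "precision": p, "recall": r, "f1": f,
        }
    return report


def score_dirs(gold_dir: str, pred_dir: str) -> EvalReport:
    from .standoff import read_corpus_dir

    return score_documents(read_corpus_dir(gold_dir), read_corpus_dir(pred_dir))


# ---------------------------------------------------------------------------
# Corpus statistics
# ---------------------------------------------------------------------------


def corpus_stats(
    docs: list[Document], reference_vocabulary: set[str] | None = None
) -> dict:
    """Descriptive statistics of an annotated corpus.

    Includes entity counts per category and per nest level, polysemous and
    textually nested entity counts, the rare-word ratio among unique words
    (rare = frequency 1), the unknown-word ratio against a reference
    vocabulary (typically the training-split vocabulary), and the
    fractions of entities containing unknown (EUNK) or rare (ERARE)
    words.
    """
    from .layered import decompose_gold

    word_counts: Counter = Counter()
    for doc in docs:
        if doc.tokens:
            words = [t.surface.lower() for t in doc.tokens]
        else:
            words = doc.text.lower().split()
        word_counts.update(words)
    unique = set(word_counts)
    rare = {w for w, c in word_counts.items() if c == 1}

    stats: dict = {
        "documents": len(docs),
        "entities": sum(len(d.entities) for d in docs),
        "per_category": {cat: 0 for cat in CATEGORIES},
        "per_nest_level": Counter(),
        "polysemous_entities": 0,
        "textually_nested_entities": 0,
        "unique_words": len(unique),
        "rare_word_ratio": (len(rare) / len(unique)) if unique else 0.0,
    }

    eunk = erare = 0
    for doc in docs:
        for ent in doc.entities:
            stats["per_category"][ent.category] += 1
        for level, ents in enumerate(decompose_gold(doc.entities), start=1):
            stats["per_nest_level"][level] += len(ents)
        span_cats: dict[tuple, set[str]] = {}
        for ent in doc.entities:
            span_cats.setdefault(ent.fragments, set()).add(ent.category)
        for ent in doc.entities:
            if len(span_cats[ent.fragments]) >= 2:
                stats["polysemous_entities"] += 1
            if any(
                o is not ent and _covers(o, ent) and o.fragments != ent.fragments
                for o in doc.entities
            ):
                stats["textually_nested_entities"] += 1
            ent_words = [
                w.lower() for s, e in ent.fragments for w in doc.text[s:e].split()
            ]
            if any(w in rare for w in ent_words):
                erare += 1
            if reference_vocabulary is not None and any(
                w not in reference_vocabulary for w in ent_words
            ):
                eunk += 1

    n_ent = stats["entities"]
    stats["per_nest_level"] = dict(stats["per_nest_level"])
    stats["erare_fraction"] = erare / n_ent if n_ent else 0.0
    if reference_vocabulary is not None:
        stats["unknown_word_ratio"] = (
            len(unique - reference_vocabulary) / len(unique) if unique else 0.0
        )
        stats["eunk_fraction"] = eunk / n_ent if n_ent else 0.0
    return stats
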