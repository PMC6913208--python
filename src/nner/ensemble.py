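"""Majority-voting ensembles of entity predictions.

Two flavours are used in practice: an *intra*-ensemble votes over one
model architecture run with different settings (here: the five BPE
vocabulary sizes), an *inter*-ensemble votes over different models or
over intra-ensembles.  Votes are cast per exact span (the tuple of
character fragments); for each span the category with the most votes is
kept when it reaches ``min_votes``, ties broken by the shared category
priority.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .standoff import Document, Entity, priority_rank, read_corpus_dir

SpanKey = tuple[tuple[int, int], ...]


@dataclass
class PredictionSet:
    """One member's predictions: per document, a set of (category, span)."""

    member_id: str
    docs: dict[str, set[tuple[str, SpanKey]]] = field(default_factory=dict)

    @classmethod
    def from_documents(cls, member_id: str, docs: list[Document]
                       ) -> "PredictionSet":
        return cls(member_id, {d.doc_id: d.entity_keys() for d in docs})

    @classmethod
    def from_dir(cls, member_id: str, path: str) -> "PredictionSet":
        return cls.from_documents(member_id, read_corpus_dir(path))

    def to_documents(self, texts: dict[str, str] | None = None
                     ) -> list[Document]:
        out = []
        for doc_id in sorted(self.docs):
            text = (texts or {}).get(doc_id, "")
            doc = Document(doc_id, text)
            nid = 1
            for cat, frags in sorted(
                self.docs[doc_id], key=lambda cf: (cf[1], priority_rank(cf[0]))
            ):
                doc.entities.append(Entity(f"T{nid}", cat, frags))
                nid += 1
            out.append(doc)
        return out


def majority_vote(
    members: list[PredictionSet],
    min_votes: int | None = None,
    member_id: str = "ensemble",
) -> PredictionSet:
    """Vote the members' predictions span by span.

    For every exact span key the categories with the most votes win,
    provided they reach ``min_votes``; spans where no category reaches
    the threshold are dropped.  ``min_votes`` defaults to a strict
    majority, ``floor(k/2) + 1``; pass 1 for plurality voting.

    Categories tied at the span's maximum are ALL kept: a span every
    member annotates with both Reason and ADE is genuinely polysemous,
    and dropping one category would undo exactly the behaviour the
    layered models add.  This also makes voting idempotent over
    duplicated members and invariant to member order.
    """
    if not members:
        raise ValueError("majority_vote requires at least one member")
    k = len(members)
    if min_votes is None:
        min_votes = k // 2 + 1
    if min_votes < 1:
        raise ValueError("min_votes must be >= 1")

    doc_ids = sorted({doc_id for m in members for doc_id in m.docs})
    result: dict[str, set[tuple[str, SpanKey]]] = {}
    for doc_id in doc_ids:
        tally: dict[SpanKey, Counter] = {}
        for m in members:
            for cat, span in m.docs.get(doc_id, set()):
                tally.setdefault(span, Counter())[cat] += 1
        chosen: set[tuple[str, SpanKey]] = set()
        for span, votes in tally.items():
            best = max(votes.values())
            if best < min_votes:
                continue
            for cat, v in votes.items():
                if v == best:
                    chosen.add((cat, span))
        result[doc_id] = chosen
    return PredictionSet(member_id, result)


def build_intra(
    members: list[PredictionSet],
    min_votes: int | None = None,
    member_id: str = "intra",
) -> PredictionSet:
    """Intra-ensemble: one architecture, several settings (e.g. the five
    subword vocabulary sizes)."""
    return majority_vote(members, min_votes, member_id)


def build_inter(
    members: list[PredictionSet],
    min_votes: int | None = None,
    member_id: str = "inter",
) -> PredictionSet:
    """Inter-ensemble over different models and/or intra-ensembles."""
    return majority_vote(members, min_votes, member_id)


def ensemble_from_spec(spec: dict) -> PredictionSet:
    """Resolve a declarative ensemble spec.

    ``spec`` mirrors the YAML accepted by the CLI::

        member_id: submission
        min_votes: 2
        members:
          - dir: preds/inter_crf
          - member_id: intra_wcsub
            min_votes: 3
            members: [...]

    Leaves name prediction directories; internal nodes vote over their
    children, so nested intra/inter combinations are expressible.
    """
    if "dir" in spec:
        return PredictionSet.from_dir(
            spec.get("member_id", spec["dir"]), spec["dir"]
        )
    members = [ensemble_from_spec(m) for m in spec["members"]]
    return majority_vote(
        members, spec.get("min_votes"), spec.get("member_id", "ensemble")
    )
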