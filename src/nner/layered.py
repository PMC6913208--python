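"""Layered BiLSTM-CRF for nested and polysemous entity recognition.

The model stacks *flat NER layers*.  Each layer is a BiLSTM over the
current unit sequence followed by a linear-chain CRF decode.  After a
layer detects entities, each detected entity's unit run is collapsed into
a single unit carrying the arithmetic mean of the run's context
representations, non-entity units pass through unchanged, and the next
layer runs on the shorter sequence.  Stacking repeats until a layer finds
nothing (or a configured cap), so inner entities are found first and feed
the detection of the entities that contain them — including *polysemous*
entities, where a later layer assigns a second category to a span an
earlier layer already found.

Labeling units are words for the ``baseline`` variant and BPE subwords
for the ``csub``/``wsub``/``wcsub`` variants; subword-level predictions
are merged back to word labels by keeping each word's first subword
label.  Training decomposes nested gold into per-level flat label
sequences and teacher-forces the merges with the gold inner entities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import crf
from .bpe import BPEModel, apply_bpe, train_bpe
from .nnet import Adam, BiLSTM, Embedding, Linear, Param, dropout_mask
from .preprocess import preprocess_document
from .standoff import (
    CATEGORIES,
    Document,
    Entity,
    Token,
    priority_rank,
)

UNK = "<unk>"

VARIANTS = ("baseline", "csub", "wsub", "wcsub")


@dataclass
class VariantConfig:
    """Hyperparameters of one layered model.

    ``variant`` selects the input composition: ``baseline`` = word+char
    embeddings over word units; ``csub`` = char+subword over subword
    units; ``wsub`` = word+subword; ``wcsub`` = word+char+subword.
    Defaults follow common practice for this family of taggers; the
    smaller sizes used in the test suite are passed explicitly.
    """

    variant: str = "wcsub"
    word_dim: int = 100
    char_dim: int = 25
    char_hidden: int = 25
    subword_dim: int = 50
    hidden_dim: int = 100
    subword_vocab_size: int = 1000
    max_layers: int = 4
    dropout: float = 0.5
    lr: float = 1e-3
    epochs: int = 30
    patience: int = 5
    seed: int = 0
    shared_weights: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")

    @property
    def uses_words(self) -> bool:
        return self.variant in ("baseline", "wsub", "wcsub")

    @property
    def uses_chars(self) -> bool:
        return self.variant in ("baseline", "csub", "wcsub")

    @property
    def uses_subwords(self) -> bool:
        return self.variant != "baseline"


# ---------------------------------------------------------------------------
# Gold decomposition into nest levels
# ---------------------------------------------------------------------------


def _covers_key(a: tuple, b: tuple) -> bool:
    """Fragment-union containment: does span key ``a`` cover key ``b``?"""
    for s, e in b:
        pos = s
        for os_, oe in a:
            if os_ <= pos and e <= oe:
                pos = e
                break
            if os_ <= pos < oe:
                pos = oe
        if pos < e:
            return False
    return True


def _overlap_keys(a: tuple, b: tuple) -> int:
    return sum(
        max(0, min(e1, e2) - max(s1, s2)) for s1, e1 in a for s2, e2 in b
    )


def decompose_gold(entities: list[Entity]) -> list[list[Entity]]:
    """Split a nested entity set into flat per-level sets, inside-out.

    Level 1 holds entities that contain no other entity; an entity's
    level is one more than the deepest entity it strictly contains.
    Polysemous duplicates (identical span, different category) go to
    successive levels in descending category-priority order.  Entities
    that partially overlap (neither containing the other) cannot be
    layered and raise ``ValueError``.
    """
    uniq: dict[tuple, Entity] = {}
    for e in entities:
        uniq.setdefault((e.category, e.fragments), e)
    ents = list(uniq.values())

    keys = sorted({e.fragments for e in ents},
                  key=lambda k: (sum(e - s for s, e in k), k))
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            if a != b and _overlap_keys(a, b) > 0:
                if not (_covers_key(a, b) or _covers_key(b, a)):
                    raise ValueError(
                        f"entities partially overlap and cannot be layered: "
                        f"{a} vs {b}"
                    )

    top_level: dict[tuple, int] = {}  # highest level used by a span key
    leveled: list[Entity] = []
    for key in keys:  # ascending size: inner spans first
        contained = [
            top_level[k] for k in top_level
            if k != key and _covers_key(key, k)
        ]
        base = 1 + max(contained, default=0)
        group = sorted(
            (e for e in ents if e.fragments == key),
            key=lambda e: priority_rank(e.category),
        )
        for off, e in enumerate(group):
            leveled.append(e.with_level(base + off))
        top_level[key] = base + len(group) - 1

    depth = max((e.nest_level for e in leveled), default=0)
    levels: list[list[Entity]] = [[] for _ in range(depth)]
    for e in leveled:
        levels[e.nest_level - 1].append(e)
    for lv in levels:
        lv.sort(key=lambda e: e.start)
    return levels


def flatten_gold(entities: list[Entity]) -> list[Entity]:
    """Outermost, single-category view of a nested entity set.

    Polysemous spans keep the highest-priority category; entities strictly
    contained in another surviving entity are dropped.  This is the gold
    a flat single-layer tagger can be trained on.
    """
    uniq: dict[tuple, Entity] = {}
    for e in sorted(entities, key=lambda e: priority_rank(e.category)):
        uniq.setdefault(e.fragments, e)
    survivors = list(uniq.values())
    out = [
        e for e in survivors
        if not any(
            o.fragments != e.fragments and _covers_key(o.fragments, e.fragments)
            for o in survivors
        )
    ]
    out.sort(key=lambda e: e.start)
    return out


# ---------------------------------------------------------------------------
# Region merging (module-level, pure — unit tested directly)
# ---------------------------------------------------------------------------


def merge_regions(
    reps: np.ndarray, runs: list[tuple[int, int]]
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Collapse each unit run into one mean vector.

    ``runs`` are half-open, non-overlapping index ranges over ``reps``
    (the decoded entities of one layer).  Returns the next layer's input
    and, per output row, the input range it covers (singletons for
    pass-through units) — the provenance later layers need to map their
    entities back to original offsets.
    """
    runs = sorted(runs)
    for (a1, b1), (a2, b2) in zip(runs, runs[1:]):
        if b1 > a2:
            raise ValueError(f"overlapping entity runs ({a1},{b1}) and ({a2},{b2})")
    for a, b in runs:
        if not (0 <= a < b <= reps.shape[0]):
            raise ValueError(f"run ({a},{b}) outside sequence")
    out: list[np.ndarray] = []
    spans: list[tuple[int, int]] = []
    pos = 0
    run_iter = iter(runs)
    nxt = next(run_iter, None)
    while pos < reps.shape[0]:
        if nxt is not None and pos == nxt[0]:
            a, b = nxt
            out.append(reps[a:b].mean(axis=0))
            spans.append((a, b))
            pos = b
            nxt = next(run_iter, None)
        else:
            out.append(reps[pos])
            spans.append((pos, pos + 1))
            pos += 1
    return np.stack(out), spans


# ---------------------------------------------------------------------------
# Prepared sentences
# ---------------------------------------------------------------------------


@dataclass
class _Sentence:
    doc_id: str
    tokens: list[Token]
    words: list[str]
    word_ids: list[int]
    char_ids: list[list[int]]          # per word
    sub_ids: list[int]                 # per subword ('' when unused)
    sub_char_ids: list[list[int]]      # per subword
    alignment: list[int]               # subwords per word
    parent: list[int]                  # per unit: parent word index
    levels: list[list[tuple[int, int, str]]] = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return len(self.parent)


def _token_span(entity: Entity, tokens: list[Token]) -> tuple[int, int] | None:
    idx = [
        i for i, t in enumerate(tokens)
        if t.start < entity.end and entity.start < t.end
    ]
    if not idx:
        return None
    return idx[0], idx[-1] + 1


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------


class LayeredNER:
    def __init__(
        self,
        config: VariantConfig,
        word_vocab: dict[str, int],
        char_vocab: dict[str, int],
        bpe_model: BPEModel | None,
        categories: tuple[str, ...] = CATEGORIES,
    ):
        if config.uses_subwords and bpe_model is None:
            raise ValueError(f"variant {config.variant} requires a BPE model")
        self.config = config
        self.categories = tuple(categories)
        self.labels = crf.bio_labels(self.categories)
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        self.word_vocab = word_vocab
        self.char_vocab = char_vocab
        self.bpe_model = bpe_model
        self.sub_vocab: dict[str, int] = {}
        if bpe_model is not None:
            self.sub_vocab = {UNK: 0}
            for s in sorted(bpe_model.vocab, key=bpe_model.vocab.get):
                self.sub_vocab[s] = len(self.sub_vocab)

        rng = np.random.default_rng(config.seed)
        self.params: list[Param] = []
        c = config
        in_dim = 0
        if c.uses_words:
            self.emb_word = Embedding("emb_word", len(word_vocab), c.word_dim, rng)
            self.params += self.emb_word.params
            in_dim += c.word_dim
        if c.uses_chars:
            self.emb_char = Embedding("emb_char", len(char_vocab), c.char_dim, rng)
            self.char_bilstm = BiLSTM("char", c.char_dim, c.char_hidden, rng)
            self.params += self.emb_char.params + self.char_bilstm.params
            in_dim += 2 * c.char_hidden
        if c.uses_subwords:
            self.emb_sub = Embedding("emb_sub", len(self.sub_vocab), c.subword_dim, rng)
            self.params += self.emb_sub.params
            in_dim += c.subword_dim
        self.input_dim = in_dim

        L = len(self.labels)
        self.layers: list[dict] = []
        n_distinct = 1 if c.shared_weights else c.max_layers
        for k in range(n_distinct):
            d_in = in_dim if k == 0 else 2 * c.hidden_dim
            layer = {
                "bilstm": BiLSTM(f"layer{k}", d_in, c.hidden_dim, rng),
                "proj": Linear(f"layer{k}.proj", 2 * c.hidden_dim, L, rng),
                "trans": Param(f"layer{k}.trans", np.zeros((L, L))),
                "start": Param(f"layer{k}.start", np.zeros(L)),
                "stop": Param(f"layer{k}.stop", np.zeros(L)),
            }
            self.params += layer["bilstm"].params + layer["proj"].params
            self.params += [layer["trans"], layer["start"], layer["stop"]]
            self.layers.append(layer)
        if c.shared_weights and c.max_layers > 1:
            # deeper shared layers need matching input dims
            if in_dim != 2 * c.hidden_dim:
                raise ValueError(
                    "shared_weights requires input_dim == 2*hidden_dim"
                )

    def _layer(self, k: int) -> dict:
        return self.layers[0 if self.config.shared_weights else k]

    # -- vocabulary construction ------------------------------------------

    @staticmethod
    def build_vocabs(
        docs: list[Document],
    ) -> tuple[dict[str, int], dict[str, int]]:
        words = {UNK: 0}
        chars = {UNK: 0}
        for doc in docs:
            for tok in doc.tokens:
                w = tok.surface.lower()
                if w not in words:
                    words[w] = len(words)
                for ch in tok.surface:
                    if ch not in chars:
                        chars[ch] = len(chars)
        return words, chars

    # -- sentence preparation ---------------------------------------------

    def _word_id(self, surface: str) -> int:
        return self.word_vocab.get(surface.lower(), 0)

    def _char_seq(self, text: str) -> list[int]:
        if not text:
            return [0]
        return [self.char_vocab.get(ch, 0) for ch in text]

    def prepare_sentence(
        self, doc_id: str, tokens: list[Token], entities: list[Entity] | None
    ) -> _Sentence:
        words = [t.surface for t in tokens]
        c = self.config
        sub_ids: list[int] = []
        sub_char_ids: list[list[int]] = []
        alignment: list[int] = []
        parent: list[int] = []
        if c.uses_subwords:
            for wi, w in enumerate(words):
                pieces = apply_bpe(w, self.bpe_model)
                alignment.append(len(pieces))
                for p in pieces:
                    sub_ids.append(self.sub_vocab.get(p, 0))
                    bare = p[len(self.bpe_model.marker):] if p.startswith(
                        self.bpe_model.marker) and len(p) > len(
                        self.bpe_model.marker) else p
                    sub_char_ids.append(self._char_seq(bare))
                    parent.append(wi)
        else:
            alignment = [1] * len(words)
            parent = list(range(len(words)))
        sent = _Sentence(
            doc_id=doc_id,
            tokens=tokens,
            words=words,
            word_ids=[self._word_id(w) for w in words],
            char_ids=[self._char_seq(w) for w in words],
            sub_ids=sub_ids,
            sub_char_ids=sub_char_ids,
            alignment=alignment,
            parent=parent,
        )
        if entities is not None:
            sent.levels = []
            for level_ents in decompose_gold(entities):
                spans = []
                for e in level_ents:
                    ts = _token_span(e, tokens)
                    if ts is not None:
                        spans.append((ts[0], ts[1], e.category))
                sent.levels.append(spans)
            while sent.levels and not sent.levels[-1]:
                sent.levels.pop()
        return sent

    def prepare_corpus(self, docs: list[Document], with_gold: bool = True
                       ) -> list[_Sentence]:
        sents = []
        for doc in docs:
            if not doc.tokens:
                preprocess_document(doc)
            by_sent = doc.sentence_tokens()
            for si, toks in enumerate(by_sent):
                if not toks:
                    continue
                if with_gold:
                    s0, e0 = toks[0].start, toks[-1].end
                    ents = [
                        e for e in doc.entities
                        if e.start >= s0 and e.end <= e0
                    ]
                else:
                    ents = None
                sents.append(self.prepare_sentence(doc.doc_id, toks, ents))
        return sents

    # -- input composition -------------------------------------------------

    def char_embed(self, text: str) -> np.ndarray:
        """Character BiLSTM embedding of a word (or subword) string."""
        X = self.emb_char.forward(self._char_seq(text))
        vec, _ = self.char_bilstm.forward_last(X)
        return vec

    def _compose(self, sent: _Sentence) -> tuple[np.ndarray, dict]:
        c = self.config
        cache: dict = {"char": {}}
        char_vecs: dict[int, np.ndarray] = {}

        def char_vec(key: int, ids: list[int]) -> np.ndarray:
            if key not in char_vecs:
                X = self.emb_char.forward(ids)
                vec, cc = self.char_bilstm.forward_last(X)
                char_vecs[key] = vec
                cache["char"][key] = {
                    "ids": ids, "cache": cc, "dvec": np.zeros_like(vec)
                }
            return char_vecs[key]

        rows = []
        if c.variant == "baseline":
            for wi in range(len(sent.words)):
                rows.append(np.concatenate([
                    self.emb_word.forward([sent.word_ids[wi]])[0],
                    char_vec(wi, sent.char_ids[wi]),
                ]))
        elif c.variant == "csub":
            for ui in range(sent.n_units):
                rows.append(np.concatenate([
                    char_vec(-(ui + 1), sent.sub_char_ids[ui]),
                    self.emb_sub.forward([sent.sub_ids[ui]])[0],
                ]))
        elif c.variant == "wsub":
            for ui in range(sent.n_units):
                wi = sent.parent[ui]
                rows.append(np.concatenate([
                    self.emb_word.forward([sent.word_ids[wi]])[0],
                    self.emb_sub.forward([sent.sub_ids[ui]])[0],
                ]))
        else:  # wcsub
            for ui in range(sent.n_units):
                wi = sent.parent[ui]
                rows.append(np.concatenate([
                    self.emb_word.forward([sent.word_ids[wi]])[0],
                    char_vec(wi, sent.char_ids[wi]),
                    self.emb_sub.forward([sent.sub_ids[ui]])[0],
                ]))
        X = np.stack(rows)
        return X, cache

    def compose_input(self, sent: _Sentence) -> np.ndarray:
        """Composed per-unit input vectors for one prepared sentence."""
        X, _ = self._compose(sent)
        return X

    def _compose_backward(self, sent: _Sentence, dX: np.ndarray,
                          cache: dict) -> None:
        c = self.config
        col = 0
        if c.uses_words:
            d_word = dX[:, col:col + c.word_dim]
            if c.variant == "baseline":
                ids = sent.word_ids
            else:
                ids = [sent.word_ids[sent.parent[ui]] for ui in range(sent.n_units)]
            self.emb_word.backward(ids, d_word)
            col += c.word_dim
        if c.uses_chars:
            d_char = dX[:, col:col + 2 * c.char_hidden]
            if c.variant == "csub":
                for ui in range(sent.n_units):
                    cache["char"][-(ui + 1)]["dvec"] += d_char[ui]
            elif c.variant == "baseline":
                for wi in range(len(sent.words)):
                    cache["char"][wi]["dvec"] += d_char[wi]
            else:  # wcsub
                for ui in range(sent.n_units):
                    cache["char"][sent.parent[ui]]["dvec"] += d_char[ui]
            for entry in cache["char"].values():
                dXc = self.char_bilstm.backward_last(entry["dvec"], entry["cache"])
                self.emb_char.backward(entry["ids"], dXc)
            col += 2 * c.char_hidden
        if c.uses_subwords:
            d_sub = dX[:, col:col + c.subword_dim]
            self.emb_sub.backward(sent.sub_ids, d_sub)

    # -- label plumbing -----------------------------------------------------

    def _position_labels(
        self,
        prov: list[tuple[int, int]],
        spans: list[tuple[int, int, str]],
    ) -> list[int]:
        """BIO label indices over layer positions from word-range spans."""
        labels = ["O"] * len(prov)
        for ws, we, cat in spans:
            inside = [
                p for p, (a, b) in enumerate(prov)
                if a < we and ws < b
            ]
            for j, p in enumerate(inside):
                pa, pb = prov[p]
                if pa < ws or pb > we:
                    raise ValueError(
                        "gold entity boundary falls inside a merged region"
                    )
                labels[p] = ("B-" if j == 0 else "I-") + cat
        return [self.label_index[lab] for lab in labels]

    # -- training -----------------------------------------------------------

    def sentence_loss(self, sent: _Sentence, train: bool = True,
                      rng: np.random.Generator | None = None) -> float:
        """Forward+backward for one sentence; gradients accumulate."""
        c = self.config
        X0, ccache = self._compose(sent)
        if train and c.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(0)
            mask = dropout_mask(rng, X0.shape, c.dropout)
            X_in = X0 * mask
        else:
            mask = None
            X_in = X0

        depth = len(sent.levels)
        n_layers = min(depth + 1, c.max_layers)
        # per-layer word-range provenance; start: one unit per subword/word
        prov = [(w, w + 1) for w in sent.parent]

        layer_caches = []
        X = X_in
        total = 0.0
        for k in range(n_layers):
            layer = self._layer(k)
            C, bc = layer["bilstm"].forward_seq(X)
            em, lin_cache = layer["proj"].forward(C)
            spans = sent.levels[k] if k < depth else []
            gold = self._position_labels(prov, spans)
            scores = crf.ChainScores(
                em, layer["trans"].value, layer["start"].value,
                layer["stop"].value,
            )
            nll, g = crf.nll_and_gradient(scores, gold)
            total += nll
            entry = {
                "bc": bc, "lin_cache": lin_cache, "crf_grads": g, "C": C,
                "merge_spans": None, "k": k,
            }
            if k + 1 < n_layers:
                runs = []
                for ws, we, _cat in sorted(spans):
                    inside = [
                        p for p, (a, b) in enumerate(prov)
                        if a >= ws and b <= we
                    ]
                    if inside:
                        runs.append((inside[0], inside[-1] + 1))
                X, spans_map = merge_regions(C, runs)
                entry["merge_spans"] = spans_map
                prov = [
                    (prov[a][0], prov[b - 1][1]) for a, b in spans_map
                ]
            layer_caches.append(entry)

        # backward, top layer first
        dX_from_above: np.ndarray | None = None
        for entry in reversed(layer_caches):
            layer = self._layer(entry["k"])
            dC = layer["proj"].backward(
                entry["crf_grads"]["emission"], entry["lin_cache"]
            )
            layer["trans"].grad += entry["crf_grads"]["transition"]
            layer["start"].grad += entry["crf_grads"]["start"]
            layer["stop"].grad += entry["crf_grads"]["stop"]
            if dX_from_above is not None:
                for out_pos, (a, b) in enumerate(entry["merge_spans"]):
                    dC[a:b] += dX_from_above[out_pos] / (b - a)
            dX_from_above = layer["bilstm"].backward_seq(dC, entry["bc"])

        dX0 = dX_from_above
        if mask is not None:
            dX0 = dX0 * mask
        self._compose_backward(sent, dX0, ccache)
        return total

    def fit(
        self,
        train_sents: list[_Sentence],
        dev_docs: list[Document] | None = None,
        verbose: bool = False,
    ) -> "LayeredNER":
        c = self.config
        rng = np.random.default_rng(c.seed + 1)
        opt = Adam(self.params, lr=c.lr)
        best_f = -1.0
        best_state: list[np.ndarray] | None = None
        stale = 0
        order = np.arange(len(train_sents))
        self.loss_history: list[float] = []
        for epoch in range(c.epochs):
            rng.shuffle(order)
            total = 0.0
            for idx in order:
                opt.zero_grad()
                total += self.sentence_loss(train_sents[idx], train=True, rng=rng)
                opt.step()
            self.loss_history.append(total / max(len(train_sents), 1))
            if dev_docs is not None:
                from .evaluate import score_documents

                preds = [self.predict_document(d) for d in dev_docs]
                f = score_documents(dev_docs, preds).lenient["micro"]["f1"]
                if verbose:
                    print(f"epoch {epoch + 1}: loss {self.loss_history[-1]:.4f} "
                          f"dev lenient F {f:.4f}")
                if f >= best_f:
                    # on ties keep the LATER snapshot: rare patterns (e.g.
                    # polysemous spans) are learned after the bulk metric
                    # saturates and barely move dev F
                    best_state = [p.value.copy() for p in self.params]
                if f > best_f:
                    best_f = f
                    stale = 0
                else:
                    stale += 1
                    if stale >= c.patience:
                        break
            elif verbose:
                print(f"epoch {epoch + 1}: loss {self.loss_history[-1]:.4f}")
        if best_state is not None:
            for p, v in zip(self.params, best_state):
                p.value = v
        return self

    # -- decoding -----------------------------------------------------------

    def flat_layer(self, X: np.ndarray, k: int = 0
                   ) -> tuple[np.ndarray, list[str]]:
        """One flat NER layer: context reps and decoded BIO labels."""
        layer = self._layer(k)
        C, _ = layer["bilstm"].forward_seq(X)
        em, _ = layer["proj"].forward(C)
        scores = crf.ChainScores(
            em, layer["trans"].value, layer["start"].value, layer["stop"].value
        )
        path, _ = crf.viterbi(scores)
        return C, [self.labels[y] for y in path]

    def layered_decode(
        self, sent: _Sentence
    ) -> list[list[tuple[int, int, str]]]:
        """Decode all nest levels of one sentence.

        Returns per layer a list of ``(word_start, word_end, category)``
        spans; the layer index (1-based) is the entity's nest level.
        """
        from .bpe import bio_repair

        X, _ = self._compose(sent)
        prov = [(w, w + 1) for w in sent.parent]
        gkey = list(sent.parent)
        fresh = -1
        out: list[list[tuple[int, int, str]]] = []
        k = 0
        while k < self.config.max_layers:
            C, unit_labels = self.flat_layer(X, k)
            # group positions by parent key; label = first position's label
            groups: list[tuple[int, int]] = []
            for p in range(len(gkey)):
                if groups and gkey[p] == gkey[groups[-1][0]]:
                    groups[-1] = (groups[-1][0], p + 1)
                else:
                    groups.append((p, p + 1))
            glabels = bio_repair([unit_labels[a] for a, b in groups])
            spans: list[tuple[int, int, str]] = []  # in group space
            i = 0
            while i < len(glabels):
                if glabels[i].startswith("B-"):
                    cat = glabels[i][2:]
                    j = i + 1
                    while j < len(glabels) and glabels[j] == f"I-{cat}":
                        j += 1
                    spans.append((i, j, cat))
                    i = j
                else:
                    i += 1
            if not spans:
                out.append([])
                break
            word_spans = [
                (prov[groups[gi][0]][0], prov[groups[gj - 1][1] - 1][1], cat)
                for gi, gj, cat in spans
            ]
            out.append(word_spans)
            if k + 1 >= self.config.max_layers:
                break
            runs = [
                (groups[gi][0], groups[gj - 1][1]) for gi, gj, _ in spans
            ]
            X, spans_map = merge_regions(C, runs)
            new_prov = []
            new_gkey = []
            run_starts = {a for a, _ in runs}
            for a, b in spans_map:
                new_prov.append((prov[a][0], prov[b - 1][1]))
                if a in run_starts and (b - a) == (
                    next(rb for ra, rb in runs if ra == a) - a
                ):
                    new_gkey.append(fresh)
                    fresh -= 1
                else:
                    new_gkey.append(gkey[a])
            prov, gkey = new_prov, new_gkey
            k += 1
        return out

    def predict_document(self, doc: Document) -> Document:
        """Predict entities for one (preprocessed) document."""
        if not doc.tokens:
            preprocess_document(doc)
        pred = Document(doc.doc_id, doc.text)
        nid = 1
        for toks in doc.sentence_tokens():
            if not toks:
                continue
            sent = self.prepare_sentence(doc.doc_id, toks, None)
            for level, spans in enumerate(self.layered_decode(sent), start=1):
                for ws, we, cat in spans:
                    start = toks[ws].start
                    end = toks[we - 1].end
                    pred.entities.append(
                        Entity(f"T{nid}", cat, ((start, end),), nest_level=level)
                    )
                    nid += 1
        return pred

    # -- persistence --------------------------------------------------------

    def save(self, prefix: str) -> None:
        np.savez(prefix + ".npz", **{p.name: p.value for p in self.params})
        meta = {
            "config": asdict(self.config),
            "categories": list(self.categories),
            "word_vocab": self.word_vocab,
            "char_vocab": self.char_vocab,
            "bpe": None if self.bpe_model is None else {
                "merges": self.bpe_model.merges,
                "vocab": self.bpe_model.vocab,
                "vocab_size_target": self.bpe_model.vocab_size_target,
                "marker": self.bpe_model.marker,
            },
        }
        with open(prefix + ".json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh)

    @classmethod
    def load(cls, prefix: str) -> "LayeredNER":
        with open(prefix + ".json", encoding="utf-8") as fh:
            meta = json.load(fh)
        bpe_model = None
        if meta["bpe"] is not None:
            bpe_model = BPEModel(
                [tuple(m) for m in meta["bpe"]["merges"]],
                meta["bpe"]["vocab"],
                meta["bpe"]["vocab_size_target"],
                meta["bpe"]["marker"],
            )
        model = cls(
            VariantConfig(**meta["config"]),
            meta["word_vocab"],
            meta["char_vocab"],
            bpe_model,
            tuple(meta["categories"]),
        )
        data = np.load(prefix + ".npz")
        for p in model.params:
            p.value = data[p.name]
        return model


# ---------------------------------------------------------------------------
# Convenience trainer
# ---------------------------------------------------------------------------


def train(
    train_docs: list[Document],
    config: VariantConfig,
    dev_docs: list[Document] | None = None,
    bpe_model: BPEModel | None = None,
    verbose: bool = False,
) -> LayeredNER:
    """Train a layered model from annotated documents.

    Documents are preprocessed in place if needed.  For subword variants a
    BPE model is trained on the training-split words when not supplied —
    never on development or test text.
    """
    if not train_docs:
        raise ValueError("empty training corpus")
    for doc in train_docs:
        if not doc.tokens:
            preprocess_document(doc)
    if dev_docs:
        for doc in dev_docs:
            if not doc.tokens:
                preprocess_document(doc)
    if config.uses_subwords and bpe_model is None:
        from collections import Counter

        words = Counter(t.surface for d in train_docs for t in d.tokens)
        bpe_model = train_bpe(words, config.subword_vocab_size)
    word_vocab, char_vocab = LayeredNER.build_vocabs(train_docs)
    model = LayeredNER(config, word_vocab, char_vocab, bpe_model)
    sents = model.prepare_corpus(train_docs, with_gold=True)
    model.fit(sents, dev_docs=dev_docs, verbose=verbose)
    return model
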