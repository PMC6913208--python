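"""Feature-based linear-chain CRF tagger for flat entities.

A classic sparse-feature tagger: lowercased surfaces and word shapes
(orthography), gazetteer lookups with longest match (dictionary
knowledge), and word-embedding cluster ids (distributional knowledge),
each templated over a context window, trained with L2-regularized
maximum likelihood on the shared CRF core.  Part-of-speech features are a
pluggable provider hook — when no provider is configured those features
are simply absent.

The tagger is deliberately flat: it predicts one non-overlapping,
single-category layer, so nested gold is first flattened to outermost
entities and polysemous spans are resolved by the shared category
priority.
"""

from __future__ import annotations

from collections.abc import Callable, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from . import crf
from .layered import flatten_gold
from .preprocess import preprocess_document, word_shape
from .standoff import CATEGORIES, Document, Token, bio_to_entities, entities_to_bio


@dataclass
class FeatureConfig:
    use_word_shape: bool = True
    gazetteer_paths: dict[str, str] = field(default_factory=dict)
    cluster_assignments: dict[str, dict[str, int]] = field(default_factory=dict)
    context_window: tuple[int, ...] = (-2, -1, 0, 1, 2)
    pos_provider: Callable[[list[str]], list[str]] | None = None
    l2: float = 1.0
    max_iter: int = 100
    tol: float = 1e-5


class GazetteerIndex:
    """Longest-match dictionary over token sequences, case-insensitive."""

    def __init__(self, terms: Sequence[str]):
        self.term_set: set[tuple[str, ...]] = set()
        self.max_len = 1
        for term in terms:
            toks = tuple(term.lower().split())
            if toks:
                self.term_set.add(toks)
                self.max_len = max(self.max_len, len(toks))

    @classmethod
    def from_file(cls, path: str) -> "GazetteerIndex":
        with open(path, encoding="utf-8") as fh:
            return cls([line.strip() for line in fh if line.strip()])

    def match_bio(self, tokens: list[str]) -> list[str]:
        """Per-token B/I/O flags from greedy longest-match scanning."""
        low = [t.lower() for t in tokens]
        flags = ["O"] * len(tokens)
        i = 0
        while i < len(tokens):
            matched = 0
            for n in range(min(self.max_len, len(tokens) - i), 0, -1):
                if tuple(low[i : i + n]) in self.term_set:
                    matched = n
                    break
            if matched:
                flags[i] = "B"
                for j in range(i + 1, i + matched):
                    flags[j] = "I"
                i += matched
            else:
                i += 1
        return flags


def cluster_embeddings(
    embedding_path: str, k: int, seed: int = 0
) -> dict[str, int]:
    """K-means cluster assignment of every word in a text embedding file.

    The file holds one ``word v1 ... vd`` line per word (an optional
    ``count dim`` header line is skipped).
    """
    from sklearn.cluster import KMeans

    words: list[str] = []
    vecs: list[np.ndarray] = []
    with open(embedding_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh):
            parts = line.rstrip().split()
            if lineno == 0 and len(parts) == 2:
                continue  # word2vec-style header
            if len(parts) < 2:
                continue
            words.append(parts[0])
            vecs.append(np.array([float(x) for x in parts[1:]]))
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(words):
        raise ValueError(f"k={k} exceeds vocabulary size {len(words)}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    assign = km.fit_predict(np.stack(vecs))
    return {w: int(c) for w, c in zip(words, assign)}


def extract_features(
    tokens: list[Token], config: FeatureConfig,
    gazetteers: dict[str, GazetteerIndex] | None = None,
) -> list[list[str]]:
    """Per-token feature strings, templated over the context window.

    A pure function of (tokens, config): identical inputs produce
    identical feature matrices.
    """
    if gazetteers is None:
        gazetteers = {
            name: GazetteerIndex.from_file(path)
            for name, path in config.gazetteer_paths.items()
        }
    surfaces = [t.surface for t in tokens]
    base: list[dict[str, str]] = []
    gaz_flags = {
        name: gaz.match_bio(surfaces) for name, gaz in gazetteers.items()
    }
    pos_tags = (
        config.pos_provider(surfaces) if config.pos_provider is not None else None
    )
    for i, surf in enumerate(surfaces):
        feats = {"w": surf.lower()}
        if config.use_word_shape:
            feats["shape"] = word_shape(surf)
        for name, flags in gaz_flags.items():
            feats[f"dict:{name}"] = flags[i]
        for name, assign in config.cluster_assignments.items():
            feats[f"cl:{name}"] = str(assign.get(surf.lower(), "UNK"))
        if pos_tags is not None:
            feats["pos"] = pos_tags[i]
        base.append(feats)
    out: list[list[str]] = []
    for i in range(len(tokens)):
        row = ["bias"]
        for off in config.context_window:
            j = i + off
            if 0 <= j < len(tokens):
                for key, val in base[j].items():
                    row.append(f"{key}[{off}]={val}")
            else:
                row.append(f"pad[{off}]")
        out.append(row)
    return out


class FeatureCRF:
    """Trainable feature CRF over the nine flat categories."""

    def __init__(self, config: FeatureConfig | None = None,
                 categories: tuple[str, ...] = CATEGORIES):
        self.config = config or FeatureConfig()
        self.categories = tuple(categories)
        self.labels = crf.bio_labels(self.categories)
        self.label_index = {lab: i for i, lab in enumerate(self.labels)}
        self.feature_index: dict[str, int] = {}
        self.W: np.ndarray | None = None
        self.trans: np.ndarray | None = None
        self.start: np.ndarray | None = None
        self.stop: np.ndarray | None = None
        self._gazetteers = {
            name: GazetteerIndex.from_file(path)
            for name, path in self.config.gazetteer_paths.items()
        }
        self._trans_ok, self._start_ok = crf.bio_transition_mask(self.labels)

    # -- data preparation ---------------------------------------------------

    def _sentence_data(self, doc: Document):
        flat = flatten_gold(doc.entities)
        for toks in doc.sentence_tokens():
            if not toks:
                continue
            s0, e0 = toks[0].start, toks[-1].end
            ents = [e for e in flat if e.start >= s0 and e.end <= e0]
            tags = entities_to_bio(toks, ents)
            feats = extract_features(toks, self.config, self._gazetteers)
            yield toks, feats, [self.label_index[t] for t in tags]

    def _emissions(self, feat_ids: list[list[int]]) -> np.ndarray:
        em = np.zeros((len(feat_ids), len(self.labels)))
        for t, ids in enumerate(feat_ids):
            em[t] = self.W[ids].sum(axis=0)
        return em

    # -- training -----------------------------------------------------------

    def train(self, docs: list[Document], verbose: bool = False) -> "FeatureCRF":
        if not docs:
            raise ValueError("empty training corpus")
        for doc in docs:
            if not doc.tokens:
                preprocess_document(doc)
        data = []
        for doc in docs:
            for toks, feats, gold in self._sentence_data(doc):
                data.append((feats, gold))
        for feats, _ in data:
            for row in feats:
                for f in row:
                    if f not in self.feature_index:
                        self.feature_index[f] = len(self.feature_index)
        F, L = len(self.feature_index), len(self.labels)
        indexed = [
            ([[self.feature_index[f] for f in row] for row in feats], gold)
            for feats, gold in data
        ]
        n_w = F * L
        n_t = L * L

        def unpack(x):
            W = x[:n_w].reshape(F, L)
            trans = x[n_w : n_w + n_t].reshape(L, L)
            start = x[n_w + n_t : n_w + n_t + L]
            stop = x[n_w + n_t + L :]
            return W, trans, start, stop

        def objective(x):
            W, trans, start, stop = unpack(x)
            trans_m = np.where(self._trans_ok, trans, crf.NEG_INF)
            start_m = np.where(self._start_ok, start, crf.NEG_INF)
            self.W = W
            total = 0.0
            dW = np.zeros_like(W)
            dtr = np.zeros_like(trans)
            dst = np.zeros_like(start)
            dsp = np.zeros_like(stop)
            for feat_ids, gold in indexed:
                em = self._emissions(feat_ids)
                scores = crf.ChainScores(em, trans_m, start_m, stop)
                nll, g = crf.nll_and_gradient(scores, gold)
                total += nll
                for t, ids in enumerate(feat_ids):
                    dW[ids] += g["emission"][t]
                dtr += np.where(self._trans_ok, g["transition"], 0.0)
                dst += np.where(self._start_ok, g["start"], 0.0)
                dsp += g["stop"]
            l2 = self.config.l2
            total += 0.5 * l2 * (
                np.sum(W * W) + np.sum(trans[self._trans_ok] ** 2)
                + np.sum(start[self._start_ok] ** 2) + np.sum(stop * stop)
            )
            dW += l2 * W
            dtr += l2 * np.where(self._trans_ok, trans, 0.0)
            dst += l2 * np.where(self._start_ok, start, 0.0)
            dsp += l2 * stop
            grad = np.concatenate([dW.ravel(), dtr.ravel(), dst, dsp])
            return total, grad

        x0 = np.zeros(n_w + n_t + 2 * L)
        res = minimize(
            objective, x0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.config.max_iter, "ftol": self.config.tol,
                     "gtol": 1e-6},
        )
        if verbose:
            print(f"L-BFGS finished: {res.message} (nll {res.fun:.2f})")
        self.W, self.trans, self.start, self.stop = unpack(res.x)
        return self

    # -- tagging ------------------------------------------------------------

    def tag_tokens(self, tokens: list[Token]) -> list[str]:
        feats = extract_features(tokens, self.config, self._gazetteers)
        feat_ids = [
            [self.feature_index[f] for f in row if f in self.feature_index]
            for row in feats
        ]
        em = self._emissions(feat_ids)
        scores = crf.ChainScores(
            em,
            np.where(self._trans_ok, self.trans, crf.NEG_INF),
            np.where(self._start_ok, self.start, crf.NEG_INF),
            self.stop,
        )
        path, _ = crf.viterbi(scores)
        return [self.labels[y] for y in path]

    def tag(self, doc: Document) -> Document:
        """Predict a flat, single-category entity layer for a document."""
        if self.W is None:
            raise RuntimeError("model is not trained")
        if not doc.tokens:
            preprocess_document(doc)
        pred = Document(doc.doc_id, doc.text)
        nid = 1
        for toks in doc.sentence_tokens():
            if not toks:
                continue
            tags = self.tag_tokens(toks)
            ents = bio_to_entities(toks, tags, id_start=nid)
            nid += len(ents)
            pred.entities.extend(ents)
        return pred
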