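# nner — nested medication & ADE entity recognition

`nner` extracts medications and their attributes from clinical
narratives: nine entity categories (**ADE, Dosage, Duration, Drug, Form,
Frequency, Reason, Route, Strength**) annotated as character spans in
brat-style standoff.  Unlike ordinary flat taggers it handles **nested**
entities (a Drug inside a Reason/ADE phrase) and **polysemous** entities
(one span carrying two categories, e.g. both Reason and ADE), and it can
label text at the **subword** level to cope with the rare and unknown
words that dominate clinical vocabulary.

It is written for NLP researchers and clinical-informatics engineers who
need a complete, dependency-light, CPU-only reference pipeline: data
model and I/O, preprocessing, two trainable taggers, ensembling,
scoring, and a synthetic corpus generator that stands in for
access-restricted clinical data.

## The models

**Layered BiLSTM-CRF.**  A *flat NER layer* is a BiLSTM encoder plus a
linear-chain CRF decoder producing one non-overlapping BIO layer.  After
a layer detects entities, each entity's unit run is replaced by the mean
of its context representations and another flat layer runs on the
shortened sequence — inner entities first, then the entities containing
them — until a layer finds nothing.  A second category on an identical
span simply arrives one layer later, which is how polysemy is decoded.
Input vectors compose per variant: `baseline` = word ⊕ char-BiLSTM
embeddings on word units; `csub`/`wsub`/`wcsub` add byte-pair-encoding
subword units (labels predicted per subword, merged back by keeping each
word's first subword label).  For a label sequence `y` over units `x`,
each layer models

    p(y | x) = exp( Σ_t e(t, y_t) + Σ_t T[y_{t-1}, y_t] ) / Z(x)

with BiLSTM emissions `e`, learned transitions `T`, and partition `Z`
computed by the forward algorithm; training minimizes the exact NLL per
nest level with gold inner entities teacher-forced.

**Feature CRF.**  A flat baseline over the same CRF core: word shape
(`Fioricet → Aaaaaaaa`), gazetteer longest-match flags, and
word-embedding k-means cluster features in a ±2 context window, trained
with L2-regularized L-BFGS.

**Ensembles.**  Majority voting per exact span, with intra-ensembles
(one model across the five subword vocabulary sizes 300–16000) and
inter-ensembles (across models), nestable via a YAML spec.

**Evaluation.**  Strict (exact span) and lenient (any overlap, same
category) precision/recall/F per category and micro, the four
matching types (Strict / Includes / Is included / Partial overlap), the
CE/SE false-positive taxonomy, and corpus statistics (nesting, polysemy,
rare/unknown words).

## Worked example

```python
from collections import Counter
from nner import SynthConfig, generate_corpus, train_bpe, apply_bpe
from nner.preprocess import preprocess_document

corpus = generate_corpus(SynthConfig(n_documents=50, seed=1))
doc = corpus.train[0]
print(doc.text[:120])
for e in doc.entities[:4]:
    print(e.entity_id, e.category, e.fragments[0], repr(doc.text[e.start:e.end]))
```

```
Patient was started on xanistatin for gout. He received nimoazole 204 g for seizures. She was given veloparin puff. He r
T1 Drug (23, 33) 'xanistatin'
T2 Reason (38, 42) 'gout'
T3 Drug (56, 65) 'nimoazole'
T4 Strength (66, 71) '204 g'
```

Entities reference the raw text by half-open character offsets — `T1`
says characters 23–33 are a Drug.  Training a BPE model on this corpus
shows subwords capturing the drug-name morphology, including for a name
never seen in training:

```python
for d in corpus.train:
    preprocess_document(d)
words = Counter(t.surface for d in corpus.train for t in d.tokens)
bpe = train_bpe(words, 300)
print(" ".join(apply_bpe("velomicin", bpe)))   # -velo m icin
print(" ".join(apply_bpe("quarmicin", bpe)))   # -q u ar m icin  (unseen word)
```

The scorer closes the loop against controlled degradations of gold:

```python
from nner import DegradeProfile, degrade_predictions, score_documents
docs = generate_corpus(SynthConfig(n_documents=20, seed=1)).all_documents
preds, expected = degrade_predictions(
    docs, DegradeProfile(n_widen=3, n_swap=2, n_delete=2, seed=0))
rep = score_documents(docs, preds)
m = rep.lenient["micro"]
print(f"lenient micro P={m['precision']:.4f} R={m['recall']:.4f} F={m['f1']:.4f}")
print(dict(rep.match_types), dict(rep.errors))
```

```
lenient micro P=0.9971 R=0.9943 F=0.9957
{'Strict': 689, 'Includes': 3} {'CE': 2}
```

Of 696 gold entities, 2 deletions and 2 category swaps cost recall and
precision exactly as requested; the 3 widened spans still count
leniently but show up as `Includes` matches, and the swaps as category
errors (CE).

Training the layered model end to end (a few minutes on one CPU):

```python
from nner import VariantConfig, train
cfg = VariantConfig(variant="wcsub", subword_vocab_size=1000,
                    word_dim=32, char_dim=16, char_hidden=16,
                    subword_dim=32, hidden_dim=48, dropout=0.3,
                    lr=5e-3, epochs=25, patience=25, seed=0)
model = train(corpus.train, cfg, dev_docs=corpus.dev)
preds = [model.predict_document(d) for d in corpus.test]
print(score_documents(corpus.test, preds).lenient["micro"])
```

The same pipeline is scriptable from the shell: `nner synth`,
`nner bpe train`, `nner train` / `nner predict`, `nner crf-train` /
`nner crf-tag`, `nner ensemble`, `nner evaluate`, `nner stats`
(see `nner --help`).

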