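# Methods

## The task

Clinical discharge summaries mention medications together with their
attributes and consequences.  The package recognizes nine entity
categories — ADE, Dosage, Duration, Drug, Form, Frequency, Reason, Route,
Strength — as character spans on the raw note (brat-style standoff).  Two
phenomena make this harder than ordinary flat NER:

* **nesting** — a Drug mention can sit inside a Reason or ADE phrase
  ("worsening rash *from velomicin*");
* **polysemy** — one span can legitimately carry two categories (the same
  condition is both the reason for one prescription and an adverse event
  of another).  Polysemy is treated as a special case of nesting: two
  entities with identical spans at successive nest levels.

## Layered BiLSTM-CRF

The neural tagger stacks *flat NER layers*.  One layer is a BiLSTM over
the unit sequence followed by a linear-chain CRF decode producing one
non-overlapping BIO layer.  After a layer detects entities, each entity's
unit run is collapsed into a single unit carrying the arithmetic mean of
the run's BiLSTM context representations; non-entity units pass their
context representation through.  The next layer runs on this shorter
sequence, so inner entities inform the detection of the entities
containing them.  Stacking continues until a layer detects nothing, or
`max_layers` (default 4: one more than the deepest gold nesting the
generator produces) is reached.  The layer index is the predicted
entity's nest level.

For training, nested gold is decomposed inside-out: level 1 holds
entities containing no other entity; an entity's level is one more than
the deepest entity it strictly contains; polysemous duplicates occupy
successive levels ordered by a fixed category-priority table (descending
corpus frequency: Drug > Strength > Form > Frequency > Route > Dosage >
Reason > ADE > Duration).  The same table resolves every categorical tie
in the package (CRF gold flattening, polysemous level order).  Each layer
is trained with the CRF negative log-likelihood against its level's BIO
sequence; merges during training use the *gold* inner entities (teacher
forcing), predictions at inference.  One extra all-O layer beyond the
gold depth teaches the model to stop.  Each nest level has its own
BiLSTM/projection/transition weights (a shared-weights flag exists,
default off).

Input composition per variant (units are words for `baseline`, BPE
subwords otherwise):

| variant  | unit    | input vector                                      |
|----------|---------|---------------------------------------------------|
| baseline | word    | word embedding ⊕ char-BiLSTM(word)                |
| csub     | subword | char-BiLSTM(subword) ⊕ subword embedding          |
| wsub     | subword | word embedding(parent) ⊕ subword embedding        |
| wcsub    | subword | word ⊕ char-BiLSTM(parent word) ⊕ subword         |

Character embeddings are the concatenated final hidden states of a
BiLSTM over randomly initialized character vectors.  Pretrained word
vectors can be supplied as a plain-text file; by default embeddings are
randomly initialized (fixed seed), since the original in-domain vectors
come from access-restricted text.  Unknown words map to a learned UNK
vector (lookup is lowercased).

All neural machinery is implemented in NumPy with hand-written backward
passes (`nner.nnet`), trained with Adam (gradient-norm clip 5.0),
per-sentence updates, inverted dropout on the composed input vectors.
Gradient correctness is established by finite-difference tests on the
complete stacked model.  Early stopping monitors development lenient
micro-F; on *ties* the later parameter snapshot is kept, because rare
patterns (a handful of polysemous spans) are learned long after the bulk
metric saturates and barely move the development score.

### Subword labeling

BPE is trained on the tokenized training split only: starting from
characters (the word-initial symbol carries the prefix marker `-`, which
stands for the preceding whitespace), the most frequent adjacent symbol
pair is merged until the vocabulary reaches the target size or no pair
occurs twice.  Pair counts are frequency-weighted (a flag selects the
unweighted variant) and count non-overlapping left-to-right occurrences —
the number of merge sites an application of the merge would actually
touch; ties break lexicographically on the (left, right) symbol strings
for cross-platform determinism.

Subword variants predict labels per subword.  Word labels are projected
onto subwords as B-X on the entity-initial subword and I-X elsewhere —
the unique scheme making the reverse merge lossless — and predictions are
merged back by keeping each word's **first** subword label, followed by a
BIO-repair pass (an I-X with no head becomes B-X) so decoding always sees
well-formed BIO.  At nesting levels above one, a "word" generalizes to a
provenance group: a merged entity unit forms its own group, remaining
subwords group under their parent word.

### CRF core

`nner.crf` implements the linear-chain primitives shared by both taggers:
log-partition via the forward recursion in log space, Viterbi (ties to
the lowest label index), forward-backward marginals, and the exact NLL
gradient (marginals minus gold indicators).  Disallowed BIO transitions
can be masked to −∞ (−1e30 in practice, keeping arithmetic NaN-free); the
mask is ON for the feature CRF and OFF for the neural head, whose
occasional ill-formed output the BIO-repair pass fixes.

## Feature CRF

A deliberately flat baseline: lowercased surfaces and word shapes
(uppercase→A, lowercase→a, digit→#, other characters kept), gazetteer
longest-match B/I/O flags per dictionary, and word-embedding k-means
cluster ids (scikit-learn KMeans; the conventional sweep is windows
{2, 5} × k ∈ {128, 256, 512}), each templated over a −2..+2 context
window with a bias and padding indicators.  Part-of-speech features are a
pluggable provider hook; absent a provider they are simply omitted, and
every feature group is a config switch.  Training maximizes the
L2-regularized likelihood (default strength 1.0) with L-BFGS on the
shared CRF core.  Nested gold is flattened to outermost entities and
polysemous spans keep their highest-priority category, since a flat
tagger can predict only one non-overlapping single-category layer.

## Ensembles

Members are sets of (category, fragment-tuple) predictions per document.
Votes are tallied per exact span; every category tied at the span's
maximum vote count survives if it reaches `min_votes` (default strict
majority, floor(k/2)+1; plurality `min_votes=1` is selectable — which of
the two the original systems used is not documented, so both are
exposed).  Keeping all tied categories rather than forcing a single
winner is a deliberate choice: a span that every member labels both
Reason and ADE is genuinely polysemous, and a forced tie-break would
strip exactly the behaviour the layered models add; it also makes voting
idempotent and order-invariant.  Intra-ensembles combine one
architecture across settings (the five subword vocabulary sizes 300,
1000, 4000, 8000, 16000); inter-ensembles combine different models or
intra-ensembles, declaratively nestable via a YAML spec.

## Evaluation

Strict matching requires identical category and fragments; lenient
matching requires identical category and any span overlap (fragment
unions for discontinuous entities).  Matching is one-to-one and
deterministic: exact pairs first, then remaining candidates greedily in
descending overlap (ties by offsets).  Matching exact pairs first makes
strict-TP ⊆ lenient-TP structural.  Lenient true positives are
classified as Strict / Includes (prediction strictly wider) / Is included
(strictly narrower) / Partial overlap; these counts always sum to the
lenient TP.  Lenient false positives split into category errors (CE —
the span overlaps gold of a different category) and span errors (SE — no
gold overlap).  Zero denominators yield precision = recall = F = 0.
Corpus statistics report entities per category and nest level,
polysemous and textually nested counts, the rare-word ratio among unique
words (frequency 1), the unknown-word ratio against a reference
vocabulary, and the fractions of entities containing rare (ERARE) or
unknown (EUNK) words.

## Preprocessing

De-identification surrogates `[** ... **]` (shortest match) become the
literal token `DEIDTERM`; a piecewise offset map projects every processed
span back to the original text, expanding over replacement blocks, so all
downstream offsets live in the gold frame.  A baseline splitter breaks
after sentence-final punctuation (with an abbreviation guard), then any
candidate containing `\n\n`, `:\n`, or `]\n` is split again after each
marker — these fire on the section headers and table fragments generic
splitters ignore.  Tokens are alphanumeric runs (decimals kept intact)
with every other symbol standing alone; any token containing one of
`@ * ? ~ % ) (` (both tilde codepoints) is split so each such character
is its own token.  Sentence splitting runs before tokenization, and the
`]\n` rule applies after de-identification (which removes most
brackets).

## Synthetic corpus

The generator emulates the *structure* of real medication narratives
while remaining a pure function of its config (fixed seed ⇒
byte-identical corpus): grammar-based medication sentences whose slots
(Strength, Dosage+Form, Route, Frequency, Duration, Reason, ADE clause)
appear with probabilities proportional to the real corpus's per-category
frequencies relative to Drug; pseudo-drug names built from prefix ×
suffix families (velomicin, dorapril, …) so subword models have morphology
to learn; digit-symbol-digit Strength patterns ("150(2"); nested
Reason/ADE phrases embedding a Drug at `nesting_rate`; a dedicated
dual-condition lexicon ("worsening rash", …) used only for polysemous
Reason≡ADE spans at `polysemy_rate`, giving the polysemy machinery a
learnable lexical cue; fresh random filler words (frequency 1) for
rare-word load; de-identification surrogates; newline noise, `\n\n`
blocks, and `Medications:`-style headers.  A 60/20/20 train/dev/test
split is emitted; four drug-name prefixes are reserved for the test split
as unknown-word probes.  Default rates: nesting 0.3 and polysemy 0.1
(deliberately far above the real corpus's per-mille nesting so the
layered machinery is actually exercised), rare-word 0.3, de-id 0.1,
noise 0.05.

What the generator does **not** emulate: real clinical vocabulary and
spelling variation, cross-sentence context, discontinuous gold spans,
annotation inconsistency, and genuinely ambiguous category boundaries.
Passing the end-to-end benchmark therefore demonstrates that the
pipeline's machinery (offsets, nesting, polysemy, subwords, ensembling,
scoring) is correct and learnable, not that comparable scores would be
reached on restricted clinical data.

`degrade_predictions` applies controlled edits to gold — widening,
narrowing, shifting (each ±≤2 characters on entities isolated by ≥3
characters), category swaps, hallucinated spans over entity-free words,
deletions — with exact bookkeeping of the match-type and error counts the
scorer must report, giving a closed-loop oracle for the evaluation
module.

## Problem sizes and numerical choices

The benchmark used by the test suite and the acceptance script is a
500-sentence corpus (50 documents × 10 sentences, ≈1650 entities);
layered models there use word/char-embedding/char-hidden/subword/hidden
dimensions 32/16/16/32/48, dropout 0.3, Adam lr 5e-3, 25 epochs (the
five intra-ensemble members: 10 epochs, per-member seeds).  The
`VariantConfig` defaults keep conventional larger sizes
(100/25/25/50/100, dropout 0.5, lr 1e-3).  CRF oracle equivalence is
checked to 1e-8 against exhaustive enumeration (sequences ≤ 6, labels
≤ 5); finite-difference gradient checks pass at relative error < 1e-4.
L-BFGS for the feature CRF runs at most 100–120 iterations, ftol 1e-5.

## Known limitations

* Both taggers emit only contiguous entities; discontinuous spans are
  read and scored (fragment unions) but never predicted.
* The feature CRF cannot express nesting or polysemy by construction.
* Sentence-level context only: entities whose category depends on
  neighbouring sentences are out of reach by design.
* The official shared-task scorer's matching policy is not public; the
  matcher here is documented and deterministic but not guaranteed
  identical, and an approximate-randomization significance test is out
  of scope.
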