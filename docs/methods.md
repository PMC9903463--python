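# Methods

This note documents the models and procedures `coloner` implements, the
choices made where the design was genuinely open, and what the synthetic
corpus does and does not establish about real clinical data.

## Annotation schema and IOB2 encoding

The schema has 17 entity labels split across the report's two parts: nine
for the semi-structured procedure note (SEDATION, SEDATIONLEVEL,
MEDICATION, DOSAGE, ANTISPASMODICS, DRE, PREPARATION, DEVICE, EXTENT) and
eight for the free-text findings (LESION, LOCATION, SHAPE, COLOR, SIZE,
NUMBER, BIOPSY, NEGATION). Token supervision uses IOB2: `B-X` opens an
entity, `I-X` continues it, `O` is outside; a reserved `PAD` symbol (id 0,
36 tags total) fills batch padding and is excluded from loss, metrics and
decoding. Tags are spelled with full label names (`B-LOCATION`);
abbreviated display spellings (`B-LOC`) are accepted on input through a
normalization table. Only contiguous spans are modeled: "on the ascending
colon and descending colon" is two LOCATION entities, while "ascending and
descending colon" is one. Nested/overlapping entities and relations
(linking a SIZE to its LESION) are out of scope.

**Negation scope.** Whether a NEGATION span covers only the cue ("no") or
the whole negated phrase is not externally fixed; this package's
convention — in the generator and therefore in all fixtures — is the full
scope ("no evidence of tumor recurrence"). This is a documented artifact
decision, not a claim about any particular annotation effort.

## Text processing

Cleaning operates under one invariant, asserted as a property test:
normalization never changes the number or position of words or sentences.
Tokens are exactly the whitespace-delimited words; edge punctuation is
stripped per token (a trailing period survives when the token contains
another period, protecting `T.I.`), and a token that would be emptied is
kept verbatim. Sentence boundaries are newlines plus
terminator-whitespace-capital transitions, with an abbreviation list
(`Desc.`, `T.I.`, ...) and decimal numbers (`0.5 cm`) protected — the
boundary rules are this package's choice, made to keep the quoted
abbreviation vocabulary intact. Vocabulary lookup is case-folded (reports
mix `A-colon`/`a-colon`); surfaces and offsets keep the original case. An
UNK index is reserved for out-of-vocabulary words in held-out folds;
padding goes to the per-batch maximum with a configurable hard cap
(default 128 tokens, truncation always warns).

## Word representations

*One-hot*: each word is a unit basis vector of vocabulary dimension (the
no-pretraining baseline); the matrix is frozen — it *is* the
representation — and the recurrent layer's input weights do the learning.

*CBOW*: word2vec continuous bag-of-words with negative sampling (5
negatives, unigram^0.75 noise distribution), dimension 128, window 5,
minimum count 3, 5 epochs, initial learning rate 0.05 decaying linearly.
The context window is a fixed symmetric window rather than word2vec's
per-position random shrink, so context tables can be precomputed and the
trainer vectorised; this is recorded in the matrix metadata. Training is
single-threaded pure numpy and bit-deterministic given the seed (the
strong determinism contract). Words present in annotated data but absent
from the pretrained vocabulary are initialized from seeded N(0, 0.05²)
vectors; the PAD row is pinned to zero. Pretrained matrices remain
trainable during tagger training by default (freezing is a config flag).
Matrices serialize in the word2vec text format.

## The tagger

Embedding → recurrent encoder → dense projection → CRF (or token softmax).
The encoder is an LSTM (forget-gate bias 1, Glorot initialization) run in
one or both directions; the right-to-left pass runs over length-reversed
valid prefixes so tail padding can never contaminate valid positions. The
linear-chain CRF holds a transition matrix plus start/stop scores over the
35 non-PAD tags; the loss is the exact sequence negative log-likelihood
with the partition function from the forward recursion in log space, and
its gradient from forward–backward marginals. Decoding is Viterbi with
hard IOB2 feasibility masks applied at decode time only (transitions are
learned unconstrained during training; the mask guarantees valid output
regardless), ties broken toward the lowest tag index. The no-CRF variants
(LSTM, Bi-LSTM) train with masked token-level softmax losses —
categorical cross-entropy, KL divergence (gradient-identical to
cross-entropy for one-hot targets), or elementwise Poisson deviance — and
decode by per-token argmax, repairing orphan `I` tags at span extraction.

All gradients are manual and checked against central finite differences
to ~1e-9; CRF quantities are checked against exhaustive path enumeration
for T ≤ 5, K ≤ 5.

Defaults: embedding 128, hidden 256 per direction, 10 epochs, RMSProp.
Batch size 32, learning rate 1e-3, gradient clipping at global norm 5,
and no dropout are this package's own defaults (configurable and recorded
in the saved bundle). Batches are length-sorted to cut padding waste;
batch order is reshuffled per epoch from the run seed. With BLAS pinned
to one thread (the test suite and acceptance script do this), runs are
bit-reproducible per seed on one machine.

## Evaluation

Entity-level scoring with partial matching: a predicted span is a true
positive when it has the same label as a still-unmatched gold span and
overlaps it by ≥ 1 character; assignment is greedy left-to-right,
one-to-one. Exact mode (identical boundaries) is available for
sensitivity analysis; partial-match TP ≥ exact-match TP always
(relaxation monotonicity, property-tested). Label-mismatched overlaps are
never credited. Precision/recall/F1 are computed per label and
micro-averaged strictly from summed counts — never by averaging per-label
metrics — with F1 = 0 when P + R = 0, and a `no_entities` flag for the
all-zero degenerate case.

Cross-validation partitions documents, not sentences, into k seeded
near-equal folds, so sentences of one report never straddle train and
test. The vocabulary (and any one-hot matrix) is rebuilt from training
folds only. A CBOW matrix pretrained on the separate unlabeled corpus may
be shared across folds: that corpus is disjoint from the annotation
labels, so no label information leaks. Aggregates pool counts over folds.
The experiment grid reuses fold assignments across arms, so one-hot vs
pretrained comparisons see identical splits.

## The synthetic corpus

The generator emulates what is documented about real colonoscopy corpora:
the two-part report structure; a label distribution proportioned to an
empirical 1,000-report annotated set (EXTENT ~1.0/document, COLOR
~0.2/document); anatomical-site synonym/acronym variant sets (descending
colon as `D-colon`, `D colon`, `Desc. colon`, `DC`, `mid-d-colon`,
`proximal-d-colon`; terminal ileum as `T-ileum`, `TI`, `T.I.`; hepatic
flexure as `H-flexure`, `H-Fx`, `HF`; ascending colon as `a-colon`, `ac`,
`a-c`); both discontinuity phrasings; full-scope negation sentences; and
character-level typos (transposition, doubling, character shift — the
class containing `bleeding → bleeingd`) at a default rate of 1% of
eligible tokens. Lexicon entries are provenance-flagged: surfaces quoted
from the domain literature versus invented fillers added for lexicon
size. Sentence templates derive slot-inclusion probabilities from the
configured label weights, so realized per-document label rates land
within ±20% relative of their targets (verified by `frequency_check` at
n ≥ 500). Every slot yields a gold span with exact offsets, snapped to
the pipeline tokenizer's token boundaries, which makes span → IOB2 → span
an exact identity — the basis of the round-trip tests. Typos only touch
purely-alphabetic tokens lying outside spans or wholly inside one, so the
alignment survives noise injection.

What the synthetic corpus does *not* have: real lexical diversity (a few
hundred word types versus tens of thousands), clinically plausible lesion
co-occurrence, inter-annotator disagreement, or institution-specific
formatting drift. Consequently, passing the end-to-end tests shows the
pipeline is correct and that its qualitative orderings (CRF > no-CRF;
more data helps; pretraining helps free-text labels under scarce
annotation; semi-structured text is easier than free text) emerge under
controlled conditions — it does not certify any particular F1 on real
reports.

## Problem sizes

Default generator scale is a 1,000-document annotated corpus (the
"D1 analog") and a 10,000-document unlabeled corpus — desk-scale
stand-ins for an institutional archive. The heavier checks run at the
following reduced sizes, chosen as this package's own test scale:

- End-to-end fivefold CV at the full defaults (embed 128 / hidden 256 /
  10 epochs / RMSProp): 250 annotated documents.
- Ablation trends (architecture ordering; dataset sizes 200 → 500 →
  1,000; one-hot vs pretrained at 200 documents): one held-out fold
  (identical split across arms), reduced tagger (hidden 96, 5 epochs),
  averaged over seeds 0/1/2. Individual-seed trend violations are logged
  as warnings; only seed averages are asserted.
- CBOW properties: ~3,000 unlabeled documents (≈40k sentences).
- Acceptance script: 250 annotated / 2,500 unlabeled documents.

## Numerical choices and degenerate inputs

Log-space forward/backward recursions are stable for scores in at least
[−50, 50]; hard constraint masks use a large finite negative constant
(−1e30) instead of −inf to keep arithmetic NaN-free, and an infeasible
constrained decode raises an explicit error. Zero-length sentences are
rejected at the CRF boundary; empty documents produce zero spans; an
empty training set and a post-filter-empty CBOW corpus raise typed
errors. Viterbi tie-breaking (lowest tag index, so all-zero scores decode
to all-O) is fixed so cross-implementation comparisons are reproducible.

## Known limitations

The tagger is desk-scale numpy: training throughput is roughly 100
sentences/second at the default dimensions on one CPU, which is ample for
the synthetic corpus but not for archive-scale pretraining. Transformer
emission scorers (e.g. domain-pretrained BERT variants) are out of scope;
the emission interface is pluggable so one could be added behind the same
CRF. The sentence splitter's abbreviation list is small and English-only,
and the generator makes no attempt at non-English report formatting.
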