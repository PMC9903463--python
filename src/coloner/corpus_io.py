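"""Reading/writing annotated corpora and span <-> IOB2 conversion.

Annotated reports travel as JSON Lines, one document per line, in the
dialect produced by web annotation tools (doccano-style exports).  Two
field spellings are accepted and mapped onto one internal convention:

======================  =============================================
internal field          accepted input spellings
======================  =============================================
``doc_id``              ``doc_id``, ``id`` (stringified)
``text``                ``text``
``spans``               ``spans`` / ``labels``: list of
                        ``[start, end, label]`` triples; or
                        ``entities``: list of objects with
                        ``start_offset`` / ``end_offset`` / ``label``
======================  =============================================

Character offsets are 0-based half-open throughout.  Token-level files use
a CoNLL-style two-column format (token TAB tag), blank line between
sentences, with a ``# doc_id = ... sentence = ...`` comment line per
sentence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ParseError, SchemaError, ValidationError
from .schema import LabelSet, PAD_TAG, TagVocabulary, is_valid_iob2


@dataclass(frozen=True)
class Span:
    """A labeled character range; ``text`` is the surface string, kept for validation."""

    start: int
    end: int
    label: str
    text: str = ""

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class AnnotatedDocument:
    """A report text plus its labeled spans (gold or predicted)."""

    doc_id: str
    text: str
    spans: list[Span] = field(default_factory=list)
    origin: str = "gold"  # gold | predicted

    def __post_init__(self):
        self.spans = sorted(self.spans, key=lambda s: (s.start, s.end))
        self.validate()

    def validate(self, label_set: LabelSet | None = None) -> None:
        label_set = label_set or LabelSet.default()
        n = len(self.text)
        prev: Span | None = None
        for sp in self.spans:
            if not (0 <= sp.start < sp.end <= n):
                raise ValidationError(
                    f"doc {self.doc_id}: span ({sp.start},{sp.end}) outside text of length {n}"
                )
            if sp.label not in label_set:
                raise SchemaError(f"doc {self.doc_id}: unknown label {sp.label!r}")
            if sp.text and self.text[sp.start : sp.end] != sp.text:
                raise ValidationError(
                    f"doc {self.doc_id}: span text {sp.text!r} does not match "
                    f"document slice {self.text[sp.start:sp.end]!r}"
                )
            if prev is not None and sp.overlaps(prev):
                raise ValidationError(
                    f"doc {self.doc_id}: overlapping spans at {prev.start} and {sp.start}"
                )
            prev = sp

    def with_spans(self, spans: Sequence[Span], origin: str = "predicted") -> "AnnotatedDocument":
        return AnnotatedDocument(self.doc_id, self.text, list(spans), origin=origin)


@dataclass
class TaggedSentence:
    """Tokens of one sentence with aligned IOB2 tags and character offsets.

    ``char_offsets`` are per-token ``(start, end)`` into the parent document;
    they are ``None`` for sentences read back from CoNLL files, which do not
    carry offsets.
    """

    tokens: list[str]
    tags: list[str]
    char_offsets: list[tuple[int, int]] | None = None
    doc_id: str = ""
    sentence_index: int = 0

    def __post_init__(self):
        if len(self.tokens) != len(self.tags):
            raise ValidationError(
                f"doc {self.doc_id} sent {self.sentence_index}: "
                f"{len(self.tokens)} tokens vs {len(self.tags)} tags"
            )
        if self.char_offsets is not None and len(self.char_offsets) != len(self.tokens):
            raise ValidationError("char_offsets misaligned with tokens")

    def __len__(self) -> int:
        return len(self.tokens)


# ---------------------------------------------------------------------------
# JSON Lines annotation dialect
# ---------------------------------------------------------------------------

def _parse_spans(obj: dict, lineno: int) -> list[tuple[int, int, str]]:
    if "spans" in obj or "labels" in obj:
        raw = obj.get("spans", obj.get("labels"))
        try:
            return [(int(s), int(e), str(lab)) for s, e, lab in raw]
        except (TypeError, ValueError) as exc:
            raise ParseError(f"malformed span triple: {exc}", lineno)
    if "entities" in obj:
        out = []
        for ent in obj["entities"]:
            try:
                out.append((int(ent["start_offset"]), int(ent["end_offset"]), str(ent["label"])))
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"malformed entity object: {exc}", lineno)
        return out
    return []


def read_annotations(path: str | Path, label_set: LabelSet | None = None) -> list[AnnotatedDocument]:
    """Read a JSON Lines annotation export into validated documents.

    Raises :class:`ParseError` (with line number) on malformed JSON,
    :class:`ValidationError` on bad spans, :class:`SchemaError` on unknown
    labels.
    """
    label_set = label_set or LabelSet.default()
    docs: list[AnnotatedDocument] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"malformed JSON: {exc.msg}", lineno)
            if "text" not in obj:
                raise ParseError("missing 'text' field", lineno)
            text = obj["text"]
            doc_id = str(obj.get("doc_id", obj.get("id", lineno)))
            spans = []
            for s, e, lab in _parse_spans(obj, lineno):
                if s >= e:
                    raise ValidationError(
                        f"line {lineno}: span ({s},{e}) has start >= end"
                    )
                lab = label_set.normalize(lab)
                spans.append(Span(s, e, lab, text[s:e]))
            docs.append(AnnotatedDocument(doc_id, text, spans))
    return docs


def write_annotations(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    """Write documents as JSON Lines in the canonical field spelling."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            obj = {
                "doc_id": doc.doc_id,
                "text": doc.text,
                "spans": [[sp.start, sp.end, sp.label] for sp in doc.spans],
                "origin": doc.origin,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# span <-> IOB2 conversion
# ---------------------------------------------------------------------------

def spans_to_iob2(
    doc: AnnotatedDocument,
    sentences: Sequence[TaggedSentence],
    vocab: TagVocabulary | None = None,
) -> list[TaggedSentence]:
    """Project a document's spans onto tokenized sentences as IOB2 tags.

    The first token overlapping a span receives ``B-label``, subsequent
    overlapping tokens ``I-label``, everything else ``O``.  A token that a
    span only partially covers is included whole (tokenization must not
    fragment clinical terms).  A span crossing a sentence boundary is a data
    defect and raises :class:`ValidationError`.
    """
    vocab = vocab or TagVocabulary()
    doc.validate(vocab.label_set)
    out: list[TaggedSentence] = []
    consumed: dict[int, int] = {}  # span index -> sentence index where it was opened
    for sent in sentences:
        if sent.char_offsets is None:
            raise ValidationError("sentences must carry character offsets")
        tags = ["O"] * len(sent)
        for si, sp in enumerate(doc.spans):
            opened = False
            for ti, (ts, te) in enumerate(sent.char_offsets):
                if ts < sp.end and sp.start < te:  # token overlaps span
                    if si in consumed and consumed[si] != id(sent):
                        raise ValidationError(
                            f"doc {doc.doc_id}: span ({sp.start},{sp.end},{sp.label}) "
                            f"crosses a sentence boundary"
                        )
                    tags[ti] = ("I-" if opened else "B-") + sp.label
                    opened = True
                    consumed[si] = id(sent)
        out.append(
            TaggedSentence(
                tokens=list(sent.tokens),
                tags=tags,
                char_offsets=list(sent.char_offsets),
                doc_id=doc.doc_id,
                sentence_index=sent.sentence_index,
            )
        )
    return out


def iob2_to_spans(
    sent: TaggedSentence,
    text: str | None = None,
    vocab: TagVocabulary | None = None,
    strict: bool = True,
) -> list[Span]:
    """Recover entity spans from an IOB2-tagged sentence.

    One span per maximal ``B-X (I-X)*`` run; the character range stretches
    from the first token's start to the last token's end.  With
    ``strict=False`` an orphan ``I-X`` (no preceding ``B-X``/``I-X`` of the
    same label) is repaired by promoting it to ``B-X``; with ``strict=True``
    it raises :class:`ValidationError`.
    """
    vocab = vocab or TagVocabulary()
    if sent.char_offsets is None:
        raise ValidationError("sentence has no character offsets")
    if strict and not is_valid_iob2(sent.tags, vocab):
        raise ValidationError(
            f"doc {sent.doc_id} sent {sent.sentence_index}: invalid IOB2 sequence"
        )
    spans: list[Span] = []
    open_label: str | None = None
    open_start = open_end = 0

    def close():
        nonlocal open_label
        if open_label is not None:
            surface = text[open_start:open_end] if text is not None else ""
            spans.append(Span(open_start, open_end, open_label, surface))
            open_label = None

    for tag, (ts, te) in zip(sent.tags, sent.char_offsets):
        tag = vocab.normalize(tag)
        prefix, label = vocab.split(tag)
        if prefix == "B" or (prefix == "I" and label != open_label):
            # orphan I reaches here only in lenient mode: promote to B
            close()
            open_label, open_start, open_end = label, ts, te
        elif prefix == "I":
            open_end = te
        else:  # O or PAD
            close()
    close()
    return spans


# ---------------------------------------------------------------------------
# CoNLL-style token/tag files
# ---------------------------------------------------------------------------

def write_conll(sentences: Iterable[TaggedSentence], path: str | Path) -> None:
    """Write sentences in two-column CoNLL format (UTF-8, blank-line separated)."""
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sentences:
            if PAD_TAG in sent.tags:
                raise ValidationError("PAD is internal only and cannot be serialized")
            fh.write(f"# doc_id = {sent.doc_id} sentence = {sent.sentence_index}\n")
            for tok, tag in zip(sent.tokens, sent.tags):
                fh.write(f"{tok}\t{tag}\n")
            fh.write("\n")


def read_conll(path: str | Path, vocab: TagVocabulary | None = None) -> Iterator[TaggedSentence]:
    """Stream sentences back from a CoNLL file written by :func:`write_conll`."""
    vocab = vocab or TagVocabulary()
    tokens: list[str] = []
    tags: list[str] = []
    doc_id, sent_idx = "", 0

    def flush():
        nonlocal tokens, tags
        if tokens:
            yield TaggedSentence(tokens=tokens, tags=tags, char_offsets=None,
                                 doc_id=doc_id, sentence_index=sent_idx)
        tokens, tags = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# doc_id = "):
                body = line[len("# doc_id = "):]
                doc_part, _, idx_part = body.rpartition(" sentence = ")
                doc_id = doc_part
                sent_idx = int(idx_part) if idx_part else 0
                continue
            if not line.strip():
                yield from flush()
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ParseError("tag column missing", lineno)
            tokens.append(cols[0])
            tags.append(vocab.normalize(cols[1]))
    yield from flush()
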