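"""Synthetic colonoscopy-report generator with gold annotations.

Real colonoscopy corpora are institutional and private, so this module
fabricates reports that emulate their documented anatomy: a
semi-structured "Procedure Note" (sedation, medication and dosage,
antispasmodics, digital rectal examination, bowel preparation, instrument,
extent of examination) and a free-text "Colonoscopic finding" section
(lesions with location, size, number, shape and color attributes, biopsy
statements, and negated findings), followed by an unannotated conclusion.

Design points:

* Label frequencies default to the relative distribution observed in a
  1,000-report annotated set (e.g. EXTENT in essentially every report,
  COLOR in under a fifth); ``corpus_statistics`` verifies the realized
  shares against the configured weights.
* Anatomical-site slots draw from synonym/acronym variant sets
  ("descending colon" / "D-colon" / "DC" / "Desc. colon" ...), so the same
  concept surfaces many ways -- the phenomenon pretrained embeddings are
  meant to absorb.  Entries are provenance-flagged: ``paper`` for surface
  forms quoted from the domain literature, ``invented`` for fillers added
  to reach usable lexicon sizes.
* Both discontinuity phrasings occur: "X colon and Y colon" yields two
  LOCATION spans, "X and Y colon" yields one.
* NEGATION spans cover the full negated phrase ("no evidence of tumor
  recurrence"), this package's convention for negation scope.
* Typos are injected at a configurable per-token rate (transposition,
  doubling, character shift -- the class that turns "bleeding" into
  "bleeingd"), only on purely alphabetic tokens so span/token alignment
  survives.

Every filled slot yields a gold span with exact character offsets, snapped
to the pipeline tokenizer's token boundaries so span -> IOB2 -> span is
the identity.  Generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import AnnotatedDocument, Span
from .errors import ConfigError
from .preprocess import sentences_of, split_sentences, tokenize

#: Per-document expected span counts (relative label distribution of a
#: 1,000-document annotated set).
DEFAULT_LABEL_WEIGHTS: dict[str, float] = {
    "SEDATION": 0.860, "SEDATIONLEVEL": 0.679, "MEDICATION": 0.871,
    "DOSAGE": 0.872, "ANTISPASMODICS": 0.799, "DRE": 0.995,
    "PREPARATION": 0.996, "DEVICE": 0.999, "EXTENT": 1.000,
    "LESION": 1.043, "LOCATION": 1.118, "SHAPE": 0.719, "COLOR": 0.197,
    "SIZE": 0.726, "NUMBER": 0.219, "BIOPSY": 0.995, "NEGATION": 0.651,
}

# -- lexicons (surface, provenance) -----------------------------------------

LOCATION_VARIANTS: dict[str, list[tuple[str, str]]] = {
    "descending colon": [
        ("descending colon", "paper"), ("distal descending colon", "paper"),
        ("D-colon", "paper"), ("D colon", "paper"), ("Desc. colon", "paper"),
        ("DC", "paper"), ("mid-d-colon", "paper"), ("proximal-d-colon", "paper"),
    ],
    "terminal ileum": [
        ("terminal ileum", "paper"), ("T-ileum", "paper"), ("T ileum", "paper"),
        ("TI", "paper"), ("T.I.", "paper"),
    ],
    "hepatic flexure": [
        ("hepatic flexure", "paper"), ("H-flexure", "paper"),
        ("H flexure", "paper"), ("H-Fx", "paper"), ("HF", "paper"),
    ],
    "ascending colon": [
        ("ascending colon", "paper"), ("a-colon", "paper"), ("a colon", "paper"),
        ("ac", "paper"), ("a-c", "paper"),
    ],
    "sigmoid colon": [
        ("sigmoid colon", "invented"), ("S-colon", "invented"), ("SC", "invented"),
    ],
    "transverse colon": [
        ("transverse colon", "invented"), ("T-colon", "invented"), ("TC", "invented"),
    ],
    "rectum": [("rectum", "paper"), ("distal rectum", "invented")],
    "cecum": [("cecum", "paper"), ("cecal base", "invented")],
}

#: (singular, plural, provenance); lesion inventory follows the endoscopic
#: findings the schema covers (polyp, erosion, ulcer, stenosis, ...).
LESIONS: list[tuple[str, str, str]] = [
    ("polyp", "polyps", "paper"),
    ("erosion", "erosions", "paper"),
    ("ulcer", "ulcers", "paper"),
    ("outpouching lesion", "outpouching lesions", "paper"),
    ("stenosis", "stenoses", "paper"),
    ("edema", "edemas", "paper"),
    ("erythema", "erythemas", "paper"),
    ("hyperemia", "hyperemias", "paper"),
    ("hemorrhage", "hemorrhages", "paper"),
    ("mass", "masses", "invented"),
    ("nodule", "nodules", "invented"),
    ("diverticulum", "diverticula", "paper"),
]

SHAPES = [("Is", "paper"), ("shallow", "paper"), ("Ip", "invented"),
          ("IIa", "invented"), ("flat", "invented"), ("elevated", "invented"),
          ("sessile", "invented"), ("pedunculated", "invented")]
COLORS = [("reddish", "invented"), ("whitish", "invented"), ("pale", "invented"),
          ("hyperemic", "invented"), ("yellowish", "invented")]
NUMBERS = [("several", "paper"), ("two", "invented"), ("three", "invented"),
           ("multiple", "invented"), ("a few", "invented")]
MEDICATIONS = [("midazolam", "paper"), ("pethidine", "paper"),
               ("propofol", "invented"), ("fentanyl", "invented")]
DOSAGES = [("3 mg", "paper"), ("50 mg", "paper"), ("5 mg", "invented"),
           ("2 mg", "invented"), ("25 mg", "invented")]
SEDATION_LEVELS = [("moderate", "paper"), ("deep", "invented"),
                   ("minimal", "invented")]
DEVICES = [("CF 260AI", "paper"), ("CF-H260AL", "invented"),
           ("PCF-Q260", "invented"), ("CF-HQ290", "invented")]
PREPARATIONS = [("fair", "paper"), ("good", "invented"), ("poor", "invented"),
                ("excellent", "invented")]
DRES = [("normal", "paper"), ("no palpable mass", "invented")]
EXTENTS = [("terminal ileum", "paper"), ("cecum", "invented"), ("T.I.", "paper")]
NEGATIONS = [
    ("no evidence of tumor recurrence", "paper"),
    ("no mucosal lesion", "paper"),
    ("no other mucosal abnormality", "paper"),
    ("no definite mass lesion", "paper"),
]
CONCLUSIONS = ["Colon polyp, removed", "Rectal polyp, removed",
               "Nonspecific finding", "A-colon diverticulum",
               "Chronic gastritis pattern", "Surveillance advised"]


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults emulate the study conditions."""

    n_documents: int = 1000
    n_unlabeled: int = 10000
    seed: int = 0
    label_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_WEIGHTS))
    negation_rate: float | None = None  # defaults to the NEGATION weight
    typo_rate: float = 0.01
    p_two_lesions: float = 0.08
    p_disc_two_spans: float = 0.05      # "X colon and Y colon" -> 2 spans
    p_disc_one_span: float = 0.05       # "X and Y colon" -> 1 span
    max_lesion_sentences: int = 3

    def __post_init__(self):
        if self.n_documents < 0 or self.n_unlabeled < 0:
            raise ConfigError("document counts must be >= 0")
        for name, w in self.label_weights.items():
            if w < 0:
                raise ConfigError(f"negative weight for {name}")
        for name in ("typo_rate", "p_two_lesions", "p_disc_two_spans",
                     "p_disc_one_span"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.negation_rate is None:
            self.negation_rate = min(1.0, self.label_weights.get("NEGATION", 0.0))


class _Builder:
    """Accumulates text and records exact offsets for labeled slots."""

    def __init__(self):
        self.parts: list[str] = []
        self.pos = 0
        self.spans: list[Span] = []

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.pos += len(text)

    def slot(self, text: str, label: str) -> None:
        self.spans.append(Span(self.pos, self.pos + len(text), label, text))
        self.add(text)

    def end_sentence(self) -> None:
        if self.parts and not self.parts[-1].rstrip().endswith("."):
            self.add(".")
        self.add("\n")

    def text(self) -> str:
        return "".join(self.parts)


def _pick(rng: np.random.Generator, table):
    return table[int(rng.integers(len(table)))][0]


class ReportGenerator:
    """Renders one report at a time from the templates and lexicons."""

    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        w = config.label_weights
        self.lesion_lambda = w.get("LESION", 1.0) / (1.0 + config.p_two_lesions)
        lam = max(self.lesion_lambda, 1e-9)
        self.p_size = min(1.0, w.get("SIZE", 0) / lam)
        self.p_shape = min(1.0, w.get("SHAPE", 0) / lam)
        self.p_color = min(1.0, w.get("COLOR", 0) / lam)
        self.p_number = min(1.0, w.get("NUMBER", 0) / lam)
        loc_from_lesions = lam * (1.0 + config.p_disc_two_spans)
        neg = max(config.negation_rate, 1e-9)
        self.p_neg_location = float(np.clip(
            (w.get("LOCATION", 0) - loc_from_lesions) / neg, 0.0, 1.0))

    # -- sections -----------------------------------------------------------

    def _location_phrase(self, b: _Builder, rng) -> None:
        concepts = list(LOCATION_VARIANTS)
        u = rng.random()
        if u < self.cfg.p_disc_two_spans:
            c1, c2 = rng.choice(len(concepts), size=2, replace=False)
            b.slot(_pick(rng, LOCATION_VARIANTS[concepts[c1]]), "LOCATION")
            b.add(" and ")
            b.slot(_pick(rng, LOCATION_VARIANTS[concepts[c2]]), "LOCATION")
        elif u < self.cfg.p_disc_two_spans + self.cfg.p_disc_one_span:
            # contiguous "ascending and descending colon": one entity
            b.slot("ascending and descending colon", "LOCATION")
        else:
            concept = concepts[int(rng.integers(len(concepts)))]
            b.slot(_pick(rng, LOCATION_VARIANTS[concept]), "LOCATION")

    def _lesion_np(self, b: _Builder, rng, plural: bool) -> None:
        if rng.random() < self.p_number:
            b.slot(_pick(rng, NUMBERS), "NUMBER")
            b.add(" ")
            plural = True
        if rng.random() < self.p_size:
            b.add("about ")
            d = 0.1 * int(rng.integers(2, 21))
            b.slot(f"{d:.1f} cm", "SIZE")
            b.add(" sized ")
        if rng.random() < self.p_color:
            b.slot(_pick(rng, COLORS), "COLOR")
            b.add(" ")
        if rng.random() < self.p_shape:
            b.slot(_pick(rng, SHAPES), "SHAPE")
            b.add(" ")
        sing, plur, _ = LESIONS[int(rng.integers(len(LESIONS)))]
        b.slot(plur if plural else sing, "LESION")

    def _lesion_sentence(self, b: _Builder, rng) -> None:
        two = rng.random() < self.cfg.p_two_lesions
        if rng.random() < 0.6:
            b.add("On the ")
            self._location_phrase(b, rng)
            b.add(", ")
            self._lesion_np(b, rng, plural=False)
            if two:
                b.add(" and ")
                self._lesion_np(b, rng, plural=False)
                b.add(" were noticed")
            else:
                b.add(" was noticed")
        else:
            b.add("There were " if two else "There was ")
            self._lesion_np(b, rng, plural=False)
            if two:
                b.add(" and ")
                self._lesion_np(b, rng, plural=False)
            b.add(" on the ")
            self._location_phrase(b, rng)
        b.end_sentence()
        if rng.random() < min(1.0, self.cfg.label_weights.get("BIOPSY", 0)):
            b.add("It was removed by ")
            b.slot("cold biopsy" if rng.random() < 0.7 else "biopsy +", "BIOPSY")
            b.end_sentence()

    def render(self, rng: np.random.Generator, doc_id: str) -> AnnotatedDocument:
        w = self.cfg.label_weights
        b = _Builder()
        b.add("Clinical information\n")
        b.add("Indication: Checkup\n")
        b.add("Procedure Note\n")
        if rng.random() < w.get("SEDATION", 0):
            b.add("Sedation: ")
            b.slot("Yes", "SEDATION")
            n_pairs = 1 + (rng.random() < max(0.0, w.get("MEDICATION", 0)
                                              / max(w.get("SEDATION", 1), 1e-9) - 1.0))
            for _ in range(int(n_pairs)):
                b.add(": " if b.parts[-1] == "Yes" else " ")
                b.slot(_pick(rng, MEDICATIONS), "MEDICATION")
                b.add(" ")
                b.slot(_pick(rng, DOSAGES), "DOSAGE")
            b.add("\n")
        if rng.random() < w.get("SEDATIONLEVEL", 0):
            b.add("Level of sedation: ")
            b.slot(_pick(rng, SEDATION_LEVELS), "SEDATIONLEVEL")
            b.add(" (paradoxical response: no)\n")
        if rng.random() < w.get("ANTISPASMODICS", 0):
            b.add("Antispasmodics (cimetropium 5 mg): ")
            b.slot("Yes", "ANTISPASMODICS")
            b.add("\n")
        if rng.random() < w.get("DRE", 0):
            b.add("Digital rectal examination was ")
            b.slot(_pick(rng, DRES), "DRE")
            b.add("\n")
        if rng.random() < w.get("PREPARATION", 0):
            b.add("Bowel preparation was ")
            b.slot(_pick(rng, PREPARATIONS), "PREPARATION")
            b.add("\n")
        b.add("The ")
        if rng.random() < w.get("DEVICE", 0):
            b.slot(_pick(rng, DEVICES), "DEVICE")
            b.add(" ")
        else:
            b.add("scope ")
        b.add("was inserted up to the ")
        b.slot(_pick(rng, EXTENTS), "EXTENT")
        b.add("\n")

        b.add("Colonoscopic finding\n")
        n_lesion = min(int(rng.poisson(self.lesion_lambda)),
                       self.cfg.max_lesion_sentences)
        for _ in range(n_lesion):
            self._lesion_sentence(b, rng)
        if rng.random() < self.cfg.negation_rate:
            b.add("There was ")
            b.slot(_pick(rng, NEGATIONS), "NEGATION")
            if rng.random() < self.p_neg_location:
                b.add(" in the ")
                self._location_phrase(b, rng)
            b.end_sentence()
        if n_lesion == 0 and rng.random() < 0.5:
            b.add("Otherwise the examination was unremarkable")
            b.end_sentence()

        b.add("Conclusion\n")
        b.add("1. " + CONCLUSIONS[int(rng.integers(len(CONCLUSIONS)))] + "\n")
        doc = AnnotatedDocument(doc_id=doc_id, text=b.text(), spans=b.spans)
        return snap_spans_to_tokens(doc)


def snap_spans_to_tokens(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Snap span boundaries to the pipeline tokenizer's token cores.

    Guarantees the span -> IOB2 -> span round trip: each span's range
    becomes [first overlapped token core start, last overlapped token core
    end], matching how IOB2 projection assigns tokens to spans.
    """
    cores: list[tuple[int, int]] = []
    for sent, s, _e in split_sentences(doc.text):
        cores.extend((t.start, t.end) for t in tokenize(sent, offset=s))
    new_spans = []
    for sp in doc.spans:
        hit = [(ts, te) for ts, te in cores if ts < sp.end and sp.start < te]
        if not hit:
            continue
        start, end = hit[0][0], hit[-1][1]
        new_spans.append(Span(start, end, sp.label, doc.text[start:end]))
    return AnnotatedDocument(doc.doc_id, doc.text, new_spans, origin=doc.origin)


# ---------------------------------------------------------------------------
# Noise injection
# ---------------------------------------------------------------------------

def _typo_candidates(word: str) -> list[str]:
    """All single-perturbation variants: adjacent swap, doubling, char shift."""
    out = []
    for i in range(len(word) - 1):
        if word[i] != word[i + 1]:
            out.append(word[:i] + word[i + 1] + word[i] + word[i + 2:])
    for i in range(len(word)):
        out.append(word[: i + 1] + word[i] + word[i + 1:])
    for i in range(len(word)):          # remove char i, reinsert at j > i
        rest = word[:i] + word[i + 1:]
        for j in range(i + 1, len(rest) + 1):
            cand = rest[:j] + word[i] + rest[j:]
            if cand != word:
                out.append(cand)
    return out


def inject_noise(doc: AnnotatedDocument, typo_rate: float,
                 seed: int | np.random.Generator = 0) -> AnnotatedDocument:
    """Perturb alphabetic tokens at ``typo_rate`` without breaking spans.

    Only tokens lying fully outside spans or fully inside one span are
    eligible; offsets of everything downstream are re-synchronized, so the
    perturbed document still satisfies every span invariant and the token
    count is unchanged.
    """
    if not 0.0 <= typo_rate <= 1.0:
        raise ConfigError("typo_rate must be in [0, 1]")
    if typo_rate == 0.0:
        return doc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    import re
    text = doc.text
    edits: list[tuple[int, int, str]] = []
    for m in re.finditer(r"[A-Za-z]{4,}", text):
        s, e = m.span()
        inside = [sp for sp in doc.spans if sp.start <= s and e <= sp.end]
        crossing = [sp for sp in doc.spans if sp.start < e and s < sp.end]
        if crossing and not inside:
            continue  # straddles a span boundary: leave alone
        if rng.random() < typo_rate:
            cands = _typo_candidates(m.group())
            edits.append((s, e, cands[int(rng.integers(len(cands)))]))
    if not edits:
        return doc
    new_text = []
    new_spans = {id(sp): [sp.start, sp.end] for sp in doc.spans}
    shift = 0
    prev = 0
    for s, e, repl in edits:
        new_text.append(text[prev:s])
        new_text.append(repl)
        delta = len(repl) - (e - s)
        for sp in doc.spans:
            pos = new_spans[id(sp)]
            if sp.start >= e:
                pos[0] += delta
            if sp.end >= e:
                pos[1] += delta
        prev = e
        shift += delta
    new_text.append(text[prev:])
    out_text = "".join(new_text)
    spans = [Span(a, b2, sp.label, out_text[a:b2])
             for sp, (a, b2) in ((sp, new_spans[id(sp)]) for sp in doc.spans)]
    return AnnotatedDocument(doc.doc_id, out_text, spans, origin=doc.origin)


# ---------------------------------------------------------------------------
# Corpus-level API
# ---------------------------------------------------------------------------

def generate_corpus(config: GeneratorConfig) -> tuple[list[AnnotatedDocument], list[str]]:
    """Generate the annotated corpus and the unlabeled superset corpus.

    Returns ``(annotated documents, unlabeled texts)``; the unlabeled list
    contains the annotated documents' texts plus additional unannotated
    reports from the same templates, up to ``n_unlabeled`` total.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    gen = ReportGenerator(config)
    docs: list[AnnotatedDocument] = []
    for i in range(config.n_documents):
        doc = gen.render(rng, doc_id=f"synth-{i:05d}")
        if config.typo_rate > 0:
            doc = inject_noise(doc, config.typo_rate, rng)
            doc = snap_spans_to_tokens(doc)
        docs.append(doc)
    unlabeled = [d.text for d in docs]
    for i in range(max(0, config.n_unlabeled - config.n_documents)):
        unlabeled.append(gen.render(rng, doc_id=f"synth-u-{i:05d}").text)
    return docs, unlabeled


@dataclass
class CorpusStatistics:
    n_documents: int
    n_sentences: int
    n_tokens: int
    n_types: int
    label_counts: dict[str, int]

    def to_table(self) -> str:
        lines = [
            f"documents\t{self.n_documents}",
            f"sentences\t{self.n_sentences}",
            f"word tokens\t{self.n_tokens}",
            f"word types\t{self.n_types}",
        ]
        for lab, c in sorted(self.label_counts.items()):
            lines.append(f"label {lab}\t{c}")
        return "\n".join(lines)


def corpus_statistics(docs: list[AnnotatedDocument]) -> CorpusStatistics:
    """Summary counts computed with the pipeline's own splitter/tokenizer."""
    n_sent = 0
    n_tok = 0
    types: set[str] = set()
    label_counts: dict[str, int] = {}
    for doc in docs:
        for sent in sentences_of(doc.text, doc.doc_id):
            n_sent += 1
            n_tok += len(sent)
            types.update(t.lower() for t in sent.tokens)
        for sp in doc.spans:
            label_counts[sp.label] = label_counts.get(sp.label, 0) + 1
    return CorpusStatistics(len(docs), n_sent, n_tok, len(types), label_counts)


def frequency_check(stats: CorpusStatistics, config: GeneratorConfig,
                    tolerance: float = 0.2) -> dict[str, tuple[float, float, bool]]:
    """Compare realized per-document label rates against configured weights.

    Returns ``{label: (realized, configured, within tolerance)}`` where the
    tolerance is relative (default +/-20%).
    """
    out = {}
    n = max(stats.n_documents, 1)
    for lab, w in config.label_weights.items():
        realized = stats.label_counts.get(lab, 0) / n
        ok = (abs(realized - w) <= tolerance * w) if w > 0 else realized == 0
        out[lab] = (realized, w, ok)
    return out
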