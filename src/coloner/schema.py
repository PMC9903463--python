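"""Annotation schema for colonoscopy-report NER.

Colonoscopy reports carry two kinds of content: a semi-structured procedure
note (sedation, medication, bowel preparation, instrument, extent of
examination, ...) and free-text colonoscopic findings (lesions and the
attributes that describe them -- anatomical site, size, number, shape,
color -- plus biopsy statements and negated findings such as "no mucosal
lesion").  The default schema covers both with 17 labels: 9 for the
procedure note and 8 for the findings section, including a NEGATION label
for statements of absence.

Token-level supervision uses the IOB2 scheme: ``B-X`` opens an entity of
label ``X``, ``I-X`` continues it, ``O`` marks non-entity tokens, and a
reserved ``PAD`` symbol fills batch padding (never predicted, excluded from
loss and metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SchemaError

PAD_TAG = "PAD"
OUTSIDE_TAG = "O"

PROCEDURE = "PROCEDURE"
FINDINGS = "FINDINGS"

#: Default labels in schema order: 9 procedure-note labels then 8 findings labels.
DEFAULT_LABELS: tuple[tuple[str, str], ...] = (
    ("SEDATION", PROCEDURE),
    ("SEDATIONLEVEL", PROCEDURE),
    ("MEDICATION", PROCEDURE),
    ("DOSAGE", PROCEDURE),
    ("ANTISPASMODICS", PROCEDURE),
    ("DRE", PROCEDURE),
    ("PREPARATION", PROCEDURE),
    ("DEVICE", PROCEDURE),
    ("EXTENT", PROCEDURE),
    ("LESION", FINDINGS),
    ("LOCATION", FINDINGS),
    ("SHAPE", FINDINGS),
    ("COLOR", FINDINGS),
    ("SIZE", FINDINGS),
    ("NUMBER", FINDINGS),
    ("BIOPSY", FINDINGS),
    ("NEGATION", FINDINGS),
)

#: Abbreviated display spellings accepted on input (e.g. "B-LOC" for "B-LOCATION").
LABEL_ALIASES: dict[str, str] = {
    "LOC": "LOCATION",
    "MED": "MEDICATION",
    "DOS": "DOSAGE",
    "NEG": "NEGATION",
    "PREP": "PREPARATION",
    "SED": "SEDATION",
    "SEDLEVEL": "SEDATIONLEVEL",
    "ANTI": "ANTISPASMODICS",
    "NUM": "NUMBER",
}


@dataclass(frozen=True)
class LabelSet:
    """An ordered set of entity labels, each assigned to a report section."""

    labels: tuple[str, ...]
    section: dict[str, str] = field(compare=False)

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("duplicate labels in schema")
        for lab in self.labels:
            if self.section.get(lab) not in (PROCEDURE, FINDINGS):
                raise SchemaError(f"label {lab!r} has no valid section")

    @classmethod
    def default(cls) -> "LabelSet":
        return cls(
            labels=tuple(name for name, _ in DEFAULT_LABELS),
            section={name: sec for name, sec in DEFAULT_LABELS},
        )

    def __contains__(self, label: str) -> bool:
        return label in self.section

    def __len__(self) -> int:
        return len(self.labels)

    def normalize(self, label: str) -> str:
        """Map an abbreviated display spelling onto the canonical label name."""
        lab = label.upper()
        lab = LABEL_ALIASES.get(lab, lab)
        if lab not in self.section:
            raise SchemaError(f"unknown label {label!r}")
        return lab

    def by_section(self, section: str) -> list[str]:
        return [lab for lab in self.labels if self.section[lab] == section]

    # -- plain-text config block ------------------------------------------------

    def dumps(self) -> str:
        lines = []
        for sec in (PROCEDURE, FINDINGS):
            lines.append(f"[{sec}]")
            lines.extend(self.by_section(sec))
        return "\n".join(lines) + "\n"

    @classmethod
    def loads(cls, text: str) -> "LabelSet":
        labels: list[str] = []
        section: dict[str, str] = {}
        current = None
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                if current not in (PROCEDURE, FINDINGS):
                    raise SchemaError(f"unknown section {current!r}")
                continue
            if current is None:
                raise SchemaError(f"label {line!r} outside any section")
            labels.append(line)
            section[line] = current
        return cls(labels=tuple(labels), section=section)


class TagVocabulary:
    """Bijection between IOB2 tag strings and integer ids; PAD is always 0."""

    def __init__(self, label_set: LabelSet | None = None):
        self.label_set = label_set or LabelSet.default()
        tags = [PAD_TAG, OUTSIDE_TAG]
        for lab in self.label_set.labels:
            tags.append(f"B-{lab}")
            tags.append(f"I-{lab}")
        self.tags: tuple[str, ...] = tuple(tags)
        self._index = {t: i for i, t in enumerate(self.tags)}

    def __len__(self) -> int:
        return len(self.tags)

    @property
    def pad_id(self) -> int:
        return 0

    @property
    def outside_id(self) -> int:
        return self._index[OUTSIDE_TAG]

    def index(self, tag: str) -> int:
        tag = self.normalize(tag)
        return self._index[tag]

    def tag(self, idx: int) -> str:
        return self.tags[idx]

    def normalize(self, tag: str) -> str:
        """Canonical spelling of a tag, accepting abbreviated labels ("B-LOC")."""
        if tag in self._index:
            return tag
        if tag.startswith(("B-", "I-")):
            prefix, label = tag[:2], tag[2:]
            try:
                return prefix + self.label_set.normalize(label)
            except SchemaError:
                pass
        raise SchemaError(f"unknown tag {tag!r}")

    def split(self, tag: str) -> tuple[str, str | None]:
        """Split a canonical tag into (prefix, label); O/PAD have label None."""
        if tag in (OUTSIDE_TAG, PAD_TAG):
            return tag, None
        return tag[0], tag[2:]


def is_valid_iob2(tags, vocab: TagVocabulary | None = None) -> bool:
    """Check structural validity of an IOB2 tag sequence.

    A sequence is valid iff every ``I-X`` is immediately preceded by ``B-X``
    or ``I-X`` of the same label.  ``PAD`` is tolerated only as a trailing
    run (batch padding); any tag after a ``PAD`` makes the sequence invalid.
    Unknown tag strings raise :class:`SchemaError` naming the offender.
    """
    vocab = vocab or TagVocabulary()
    canon = [vocab.normalize(t) for t in tags]
    # strip the trailing PAD run; a PAD anywhere else is a violation
    while canon and canon[-1] == PAD_TAG:
        canon.pop()
    prev_label = None  # label of the entity still open at the previous token
    for tag in canon:
        if tag == PAD_TAG:
            return False
        prefix, label = vocab.split(tag)
        if prefix == "I" and label != prev_label:
            return False
        prev_label = label if prefix in ("B", "I") else None
    return True


@dataclass
class TransitionMask:
    """Boolean IOB2 feasibility over (from-tag, to-tag) plus start/stop rows.

    ``allowed[i, j]`` is True when tag ``j`` may follow tag ``i``;
    ``start[j]`` when ``j`` may open a sequence; ``stop[i]`` when the
    sequence may end at ``i``.  Used for constrained Viterbi decoding.
    """

    allowed: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    vocab: TagVocabulary

    def nopad(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Restriction to the non-PAD tag block (what the CRF decodes over)."""
        return self.allowed[1:, 1:], self.start[1:], self.stop[1:]


def transition_mask(vocab: TagVocabulary | None = None) -> TransitionMask:
    """Build the hard IOB2 transition mask for a tag vocabulary.

    Forbidden: any transition into ``I-X`` unless the source is ``B-X`` or
    ``I-X``; opening a sequence with ``I-X``; any transition into ``PAD``
    except from ``PAD`` itself (stopping is instead expressed by ``stop``).
    """
    vocab = vocab or TagVocabulary()
    n = len(vocab)
    allowed = np.ones((n, n), dtype=bool)
    start = np.ones(n, dtype=bool)
    stop = np.ones(n, dtype=bool)
    for j, to_tag in enumerate(vocab.tags):
        pj, lj = vocab.split(to_tag)
        if pj == "I":
            start[j] = False
        if to_tag == PAD_TAG:
            start[j] = False
        for i, from_tag in enumerate(vocab.tags):
            pi, li = vocab.split(from_tag)
            if pj == "I" and not (pi in ("B", "I") and li == lj):
                allowed[i, j] = False
            if to_tag == PAD_TAG and from_tag != PAD_TAG:
                allowed[i, j] = False
            if from_tag == PAD_TAG and to_tag != PAD_TAG:
                allowed[i, j] = False
    return TransitionMask(allowed=allowed, start=start, stop=stop, vocab=vocab)
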