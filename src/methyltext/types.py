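"""Core data types carried through every stage of the extraction pipeline.

The unit of collection is a PubMed-style abstract; the unit of extraction is
a tokenized, entity-annotated sentence; the unit of classification is a
relation instance holding exactly one entity pair (gene-methylation or
gene-cancer) in one sentence.
"""

from __future__ import annotations

import copy
import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence


class EntityKind(str, enum.Enum):
    GENE = "GENE"
    METHYLATION = "METHYLATION"
    CANCER = "CANCER"


class Direction(str, enum.Enum):
    """Methylation direction: abnormally increased (HYPER), decreased (HYPO),
    or not stated. Always UNSPECIFIED for non-methylation mentions."""

    HYPER = "HYPER"
    HYPO = "HYPO"
    UNSPECIFIED = "UNSPECIFIED"


class RelationKind(str, enum.Enum):
    GM = "GM"  # gene - methylation
    GC = "GC"  # gene - cancer


class Label(str, enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNLABELED = "UNLABELED"


@dataclass(frozen=True)
class Token:
    """A surface token with 0-based half-open character offsets into the
    sentence text."""

    surface: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty token span [{self.start},{self.end})")


@dataclass(frozen=True)
class EntityMention:
    """An entity mention anchored to character offsets in its sentence.

    ``normalized_id`` holds an Entrez-style identifier for genes and the
    canonical dictionary name for cancers; it is empty for methylation
    mentions.  ``direction`` distinguishes hyper- from hypomethylation and is
    UNSPECIFIED for every non-methylation mention.
    """

    kind: EntityKind
    start: int
    end: int
    surface: str
    normalized_id: str = ""
    direction: Direction = Direction.UNSPECIFIED
    rule: str = ""  # which tagging rule produced the mention (audit trail)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty mention span [{self.start},{self.end})")
        if self.kind is not EntityKind.METHYLATION and self.direction is not Direction.UNSPECIFIED:
            raise ValueError("direction is only meaningful for METHYLATION mentions")

    def overlaps(self, other: "EntityMention") -> bool:
        return self.start < other.end and other.start < self.end

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class AnnotatedSentence:
    """A tokenized sentence with entity mentions and its position within the
    source abstract.

    Invariants (checked by :meth:`validate`): token spans are ordered and
    non-overlapping; every mention surface equals the corresponding text
    slice and aligns to token boundaries; ``sentence_index`` is strictly less
    than ``sentences_in_abstract``.
    """

    text: str
    tokens: list[Token]
    mentions: list[EntityMention] = field(default_factory=list)
    sentence_index: int = 0
    sentences_in_abstract: int = 1
    document_id: str = ""

    def validate(self) -> None:
        if not (0 <= self.sentence_index < self.sentences_in_abstract):
            raise ValueError(
                f"sentence_index {self.sentence_index} out of range for "
                f"{self.sentences_in_abstract} sentences"
            )
        prev_end = -1
        boundaries = set()
        for tok in self.tokens:
            if tok.start < prev_end:
                raise ValueError(f"token spans overlap or are unordered at {tok}")
            if self.text[tok.start : tok.end] != tok.surface:
                raise ValueError(
                    f"token surface {tok.surface!r} != text slice "
                    f"{self.text[tok.start:tok.end]!r}"
                )
            prev_end = tok.end
            boundaries.add(tok.start)
            boundaries.add(tok.end)
        for m in self.mentions:
            if self.text[m.start : m.end] != m.surface:
                raise ValueError(
                    f"mention surface {m.surface!r} != text slice "
                    f"{self.text[m.start:m.end]!r}"
                )
            if m.start not in boundaries or m.end not in boundaries:
                raise ValueError(f"mention {m.surface!r} not aligned to token boundaries")

    def mentions_of(self, kind: EntityKind) -> list[EntityMention]:
        return [m for m in self.mentions if m.kind is kind]

    def token_index_range(self, mention: EntityMention) -> tuple[int, int]:
        """Half-open token-index range covered by ``mention``."""
        lo = hi = None
        for i, tok in enumerate(self.tokens):
            if tok.start >= mention.start and tok.end <= mention.end:
                if lo is None:
                    lo = i
                hi = i + 1
        if lo is None:
            raise ValueError(f"mention {mention.surface!r} covers no token")
        return lo, hi

    def copy(self) -> "AnnotatedSentence":
        """Deep, independent copy: duplicated relation instances must not
        share mutable annotation state."""
        return AnnotatedSentence(
            text=self.text,
            tokens=list(self.tokens),
            mentions=list(self.mentions),
            sentence_index=self.sentence_index,
            sentences_in_abstract=self.sentences_in_abstract,
            document_id=self.document_id,
        )


@dataclass
class RelationInstance:
    """One sentence plus exactly one candidate entity pair.

    Multi-entity sentences are expanded so that each instance carries a single
    pair; the sentence annotation context is an independent copy per instance.
    """

    sentence: AnnotatedSentence
    relation_kind: RelationKind
    first_entity: EntityMention
    second_entity: EntityMention
    label: Label = Label.UNLABELED
    probability: Optional[float] = None

    def __post_init__(self) -> None:
        expected = (
            EntityKind.METHYLATION if self.relation_kind is RelationKind.GM else EntityKind.CANCER
        )
        if self.first_entity.kind is not EntityKind.GENE:
            raise ValueError("first entity of a relation pair must be a GENE mention")
        if self.second_entity.kind is not expected:
            raise ValueError(
                f"second entity of a {self.relation_kind.value} pair must be "
                f"{expected.value}, got {self.second_entity.kind.value}"
            )
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability {self.probability} outside [0,1]")

    @property
    def gene(self) -> EntityMention:
        return self.first_entity

    @property
    def partner(self) -> EntityMention:
        return self.second_entity

    def ordered_pair(self) -> tuple[EntityMention, EntityMention]:
        """The pair in document order (leftmost mention first)."""
        if self.first_entity.start <= self.second_entity.start:
            return self.first_entity, self.second_entity
        return self.second_entity, self.first_entity


@dataclass
class Corpus:
    """A homogeneous collection of relation instances (all GM or all GC)."""

    name: str
    relation_kind: RelationKind
    instances: list[RelationInstance] = field(default_factory=list)

    def __post_init__(self) -> None:
        for inst in self.instances:
            if inst.relation_kind is not self.relation_kind:
                raise ValueError(
                    f"corpus {self.name!r} is {self.relation_kind.value} but holds a "
                    f"{inst.relation_kind.value} instance"
                )

    def __len__(self) -> int:
        return len(self.instances)

    def __iter__(self):
        return iter(self.instances)

    def label_counts(self) -> dict[Label, int]:
        counts = {Label.POSITIVE: 0, Label.NEGATIVE: 0, Label.UNLABELED: 0}
        for inst in self.instances:
            counts[inst.label] += 1
        return counts


@dataclass
class AbstractRecord:
    """A PubMed-style abstract: document id, optional title, body text, and
    the ordered annotated sentences extracted from it."""

    document_id: str
    title: str = ""
    body: str = ""
    sentences: list[AnnotatedSentence] = field(default_factory=list)

    def validate(self) -> None:
        n = len(self.sentences)
        for i, sent in enumerate(self.sentences):
            if sent.sentence_index != i:
                raise ValueError(f"sentence {i} has index {sent.sentence_index}")
            if sent.sentences_in_abstract != n:
                raise ValueError("sentences_in_abstract inconsistent with sentence count")
            sent.validate()
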