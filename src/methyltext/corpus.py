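"""Corpus construction: sentence splitting, tokenization, expansion of
multi-entity sentences into single-pair relation instances, and standoff I/O.

Abstracts arrive as JSON-lines records ``{"pmid":…, "title":…, "abstract":…}``
or one plain-text file per abstract.  Annotated relation corpora are stored in
a JSON-lines standoff format, one relation instance per line, so that
overlapping candidate mentions (which inline bracket markup cannot represent)
round-trip exactly.
"""

from __future__ import annotations

import json
import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, TextIO

from .types import (
    AbstractRecord,
    AnnotatedSentence,
    Corpus,
    Direction,
    EntityKind,
    EntityMention,
    Label,
    RelationInstance,
    RelationKind,
    Token,
)

# Punctuation split off token edges; internal hyphens are kept so that
# "hypo-methylated" and "BRCA-1" stay single tokens.
_EDGE_PUNCT = ".,;:()[]\"'%"

_TERMINATOR_RE = re.compile(r"[.!?]+(?=\s|$)")


def _default_abbreviations() -> frozenset[str]:
    text = resources.files("methyltext.data").joinpath("sentence_abbreviations.txt").read_text()
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


_ABBREVIATIONS: Optional[frozenset[str]] = None


def default_abbreviations() -> frozenset[str]:
    """Packaged list of abbreviations ('et al.', 'Fig.', …) protected from
    sentence splitting; extensible via the ``abbreviations`` argument of
    :func:`split_sentences`."""
    global _ABBREVIATIONS
    if _ABBREVIATIONS is None:
        _ABBREVIATIONS = _default_abbreviations()
    return _ABBREVIATIONS


def split_sentences(
    body: str, abbreviations: Optional[Iterable[str]] = None
) -> list[tuple[int, int]]:
    """Split ``body`` into sentence spans (0-based half-open char offsets).

    Splits after sentence-final ``.!?`` followed by whitespace, unless the
    terminator closes a known abbreviation or a single capital initial
    ("A. Smith").  Spans cover all non-whitespace text in order; an empty
    body yields an empty list.
    """
    if not body or not body.strip():
        return []
    abbrevs = default_abbreviations() if abbreviations is None else frozenset(abbreviations)
    # lowercase, dot-less keys for case-insensitive abbreviation lookup
    abbrev_keys = {a.rstrip(".").lower() for a in abbrevs}

    boundaries: list[int] = []
    for m in _TERMINATOR_RE.finditer(body):
        end = m.end()
        if end >= len(body):
            break
        # word immediately before the terminator
        wstart = m.start()
        while wstart > 0 and not body[wstart - 1].isspace():
            wstart -= 1
        word = body[wstart : m.start()]
        key = word.strip("([\"'").lower()
        if key in abbrev_keys:
            continue
        if len(word) == 1 and word.isupper():  # single initial: "A. Smith"
            continue
        boundaries.append(end)

    spans: list[tuple[int, int]] = []
    start = 0
    for b in boundaries + [len(body)]:
        chunk = body[start:b]
        lstrip = len(chunk) - len(chunk.lstrip())
        rstrip = len(chunk.rstrip())
        if rstrip > lstrip:
            spans.append((start + lstrip, start + rstrip))
        start = b
    return spans


def tokenize(text: str, offset: int = 0) -> list[Token]:
    """Whitespace tokenization followed by splitting leading/trailing
    punctuation into separate tokens.  Internal punctuation (hyphens,
    slashes) is kept, so gene variants like "BRCA-1" survive as one token.
    Offsets are relative to ``text`` shifted by ``offset``.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", text):
        chunk, start = m.group(), m.start()
        # peel leading punctuation
        while chunk and chunk[0] in _EDGE_PUNCT:
            tokens.append(Token(chunk[0], offset + start, offset + start + 1))
            chunk, start = chunk[1:], start + 1
        # peel trailing punctuation (collect, emit after the core)
        trail: list[Token] = []
        end = start + len(chunk)
        while chunk and chunk[-1] in _EDGE_PUNCT:
            trail.append(Token(chunk[-1], offset + end - 1, offset + end))
            chunk, end = chunk[:-1], end - 1
        if chunk:
            tokens.append(Token(chunk, offset + start, offset + end))
        tokens.extend(reversed(trail))
    return tokens


def sentence_from_text(
    text: str,
    sentence_index: int = 0,
    sentences_in_abstract: int = 1,
    document_id: str = "",
) -> AnnotatedSentence:
    """Tokenize ``text`` into an (unannotated) :class:`AnnotatedSentence`."""
    sent = AnnotatedSentence(
        text=text,
        tokens=tokenize(text),
        sentence_index=sentence_index,
        sentences_in_abstract=sentences_in_abstract,
        document_id=document_id,
    )
    sent.validate()
    return sent


def build_abstract(
    document_id: str, title: str, body: str, abbreviations: Optional[Iterable[str]] = None
) -> AbstractRecord:
    """Split an abstract into annotated (but untagged) sentences.

    A non-empty title is treated as sentence 0 of the abstract, so the
    relative-sentence-position feature sees it at position zero.
    """
    texts: list[str] = []
    if title.strip():
        texts.append(title.strip())
    texts.extend(body[a:b] for a, b in split_sentences(body, abbreviations))
    n = max(len(texts), 1)
    sentences = [
        sentence_from_text(t, i, len(texts) or 1, document_id) for i, t in enumerate(texts)
    ]
    return AbstractRecord(document_id=document_id, title=title, body=body, sentences=sentences)


def read_abstracts(path: str | Path) -> list[AbstractRecord]:
    """Read abstracts from a JSON-lines file with pmid/title/abstract fields."""
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON record: {exc}") from exc
            for key in ("pmid", "abstract"):
                if key not in obj:
                    raise ValueError(f"{path}:{lineno}: missing field {key!r}")
            records.append(
                build_abstract(str(obj["pmid"]), str(obj.get("title", "")), str(obj["abstract"]))
            )
    return records


def write_abstracts(records: Iterable[AbstractRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {"pmid": rec.document_id, "title": rec.title, "abstract": rec.body},
                    ensure_ascii=False,
                )
                + "\n"
            )


def enumerate_pairs(
    sentence: AnnotatedSentence, relation_kind: RelationKind
) -> list[RelationInstance]:
    """Expand a multi-entity sentence into single-pair relation instances.

    Returns the Cartesian product of GENE mentions with METHYLATION (GM) or
    CANCER (GC) mentions — the sentence is "duplicated" once per combination,
    each instance holding an independent copy of the annotation context so
    feature extraction cannot leak across pairs.  Labels start UNLABELED.
    """
    partner_kind = EntityKind.METHYLATION if relation_kind is RelationKind.GM else EntityKind.CANCER
    genes = sentence.mentions_of(EntityKind.GENE)
    partners = sentence.mentions_of(partner_kind)
    instances = []
    for g in genes:
        for p in partners:
            instances.append(
                RelationInstance(
                    sentence=sentence.copy(),
                    relation_kind=relation_kind,
                    first_entity=g,
                    second_entity=p,
                )
            )
    return instances


# ---------------------------------------------------------------------------
# Standoff JSON-lines corpus format
# ---------------------------------------------------------------------------

def _mention_to_json(m: EntityMention) -> dict:
    return {
        "kind": m.kind.value,
        "start": m.start,
        "end": m.end,
        "normalized_id": m.normalized_id,
        "direction": m.direction.value,
    }


def _mention_from_json(obj: dict, text: str, lineno: int, path: str) -> EntityMention:
    try:
        mention = EntityMention(
            kind=EntityKind(obj["kind"]),
            start=int(obj["start"]),
            end=int(obj["end"]),
            surface=text[int(obj["start"]) : int(obj["end"])],
            normalized_id=str(obj.get("normalized_id", "")),
            direction=Direction(obj.get("direction", "UNSPECIFIED")),
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}:{lineno}: bad mention record: {exc}") from exc
    return mention


def instance_to_json(inst: RelationInstance) -> dict:
    sent = inst.sentence
    mentions = list(sent.mentions)
    pair = []
    for ent in (inst.first_entity, inst.second_entity):
        if ent not in mentions:
            mentions.append(ent)
        pair.append(mentions.index(ent))
    return {
        "text": sent.text,
        "tokens": [[t.surface, t.start, t.end] for t in sent.tokens],
        "mentions": [_mention_to_json(m) for m in mentions],
        "relation_kind": inst.relation_kind.value,
        "pair": pair,
        "label": inst.label.value,
        "probability": inst.probability,
        "sentence_index": sent.sentence_index,
        "sentences_in_abstract": sent.sentences_in_abstract,
        "document_id": sent.document_id,
    }


def instance_from_json(obj: dict, lineno: int = 0, path: str = "<stream>") -> RelationInstance:
    for key in ("text", "mentions", "relation_kind", "pair", "label"):
        if key not in obj:
            raise ValueError(f"{path}:{lineno}: missing field {key!r}")
    text = obj["text"]
    if "tokens" in obj:
        tokens = [Token(s, int(a), int(b)) for s, a, b in obj["tokens"]]
    else:
        tokens = tokenize(text)
    mentions = [_mention_from_json(m, text, lineno, path) for m in obj["mentions"]]
    for raw, m in zip(obj["mentions"], mentions):
        if "surface" in raw and raw["surface"] != m.surface:
            raise ValueError(
                f"{path}:{lineno}: mention surface {raw['surface']!r} does not match "
                f"text slice {m.surface!r} (field 'mentions')"
            )
    sent = AnnotatedSentence(
        text=text,
        tokens=tokens,
        mentions=mentions,
        sentence_index=int(obj.get("sentence_index", 0)),
        sentences_in_abstract=int(obj.get("sentences_in_abstract", 1)),
        document_id=str(obj.get("document_id", "")),
    )
    try:
        sent.validate()
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: {exc}") from exc
    i, j = obj["pair"]
    prob = obj.get("probability")
    return RelationInstance(
        sentence=sent,
        relation_kind=RelationKind(obj["relation_kind"]),
        first_entity=mentions[int(i)],
        second_entity=mentions[int(j)],
        label=Label(obj["label"]),
        probability=None if prob is None else float(prob),
    )


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for inst in corpus.instances:
            fh.write(json.dumps(instance_to_json(inst), ensure_ascii=False) + "\n")


def read_corpus(path: str | Path, name: Optional[str] = None) -> Corpus:
    """Read a standoff JSON-lines corpus; malformed records raise a
    ValueError naming the line and offending field."""
    path = Path(path)
    instances = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}:{lineno}: malformed JSON: {exc}") from exc
            instances.append(instance_from_json(obj, lineno, str(path)))
    if not instances:
        return Corpus(name=name or path.stem, relation_kind=RelationKind.GM, instances=[])
    kind = instances[0].relation_kind
    return Corpus(name=name or path.stem, relation_kind=kind, instances=instances)
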