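"""Binary feature extraction for relation instances.

Feature groups, mirroring the classifier's input design:

* ``NGRAM1`` / ``NGRAM2`` — word unigrams and bigrams strictly between the
  two entities;
* ``SURROUND_LEFT`` / ``SURROUND_RIGHT`` — the two words before the first
  entity and the two words after the second (document order);
* ``CHUNK_HEAD_INTER`` / ``CHUNK_TYPE_INTER`` / ``CHUNK_HEAD_SURROUND`` —
  shallow-parse chunk heads and types between and around the entities;
* ``PARSE_PATH`` — the syntactic path between the entities (falls back to
  the chunk-type sequence when no constituency parser is configured);
* ``SENT_POS`` — the relative position of the sentence in its abstract,
  discretized into quintiles;
* ``TEMPLATE`` — one feature per induced template matching the sentence;
* ``ORDER`` — whether the gene precedes its partner entity.

Extraction is pure: identical instances and annotators yield identical
vectors.  Vectors serialize to the classic sparse text format
``label feat:1 feat:1 …``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence, Union

from .chunking import ChunkAnnotation, chunk_sentence
from .templates import Template, match_template, slotify
from .types import Label, RelationInstance

ALL_GROUPS = frozenset(
    {
        "NGRAM1",
        "NGRAM2",
        "SURROUND_LEFT",
        "SURROUND_RIGHT",
        "CHUNK_HEAD_INTER",
        "CHUNK_HEAD_SURROUND",
        "CHUNK_TYPE_INTER",
        "PARSE_PATH",
        "SENT_POS",
        "TEMPLATE",
        "ORDER",
    }
)

BOUNDARY = "<S>"
_NUM_RE = re.compile(r"^\d+([.,]\d+)?%?$")


@dataclass(frozen=True)
class FeatureVector:
    """A set of named binary features; presence means the feature fires."""

    features: frozenset[str]

    def __contains__(self, name: str) -> bool:
        return name in self.features

    def group(self, group: str) -> frozenset[str]:
        prefix = group + "="
        return frozenset(f for f in self.features if f.startswith(prefix))


@dataclass(frozen=True)
class FeatureConfig:
    """Which groups to extract and how to normalize word forms."""

    groups: frozenset[str] = ALL_GROUPS
    map_numerals: bool = True  # numerals -> NUM placeholder to limit sparsity

    def without(self, *groups: str) -> "FeatureConfig":
        return FeatureConfig(groups=self.groups - set(groups), map_numerals=self.map_numerals)


DEFAULT_CONFIG = FeatureConfig()


_WS_OR_COLON = re.compile(r"[\s:]+")


def _feat(group: str, value: str) -> str:
    return group + "=" + _WS_OR_COLON.sub("_", value)


def _norm(surface: str, config: FeatureConfig) -> str:
    low = surface.lower()
    if config.map_numerals and _NUM_RE.match(low):
        return "NUM"
    return low


def _entity_token_ranges(instance: RelationInstance) -> tuple[tuple[int, int], tuple[int, int]]:
    """Token-index ranges of the two entities in document order."""
    first, second = instance.ordered_pair()
    sent = instance.sentence
    return sent.token_index_range(first), sent.token_index_range(second)


def ngram_features(
    instance: RelationInstance, config: FeatureConfig = DEFAULT_CONFIG
) -> set[str]:
    """Unigrams and bigrams of the tokens strictly between the entities."""
    (_, first_end), (second_start, _) = _entity_token_ranges(instance)
    toks = [
        _norm(t.surface, config) for t in instance.sentence.tokens[first_end:second_start]
    ]
    feats = {_feat("NGRAM1", t) for t in toks}
    feats |= {_feat("NGRAM2", f"{a}_{b}") for a, b in zip(toks, toks[1:])}
    return feats


def surrounding_word_features(
    instance: RelationInstance, config: FeatureConfig = DEFAULT_CONFIG
) -> set[str]:
    """The two words before the first entity and the two after the second;
    positions beyond the sentence emit the boundary marker."""
    (first_start, _), (_, second_end) = _entity_token_ranges(instance)
    toks = instance.sentence.tokens
    feats = set()
    for offset in (2, 1):
        idx = first_start - offset
        word = _norm(toks[idx].surface, config) if idx >= 0 else BOUNDARY
        feats.add(_feat("SURROUND_LEFT", f"-{offset}_{word}"))
    for offset in (1, 2):
        idx = second_end - 1 + offset
        word = _norm(toks[idx].surface, config) if idx < len(toks) else BOUNDARY
        feats.add(_feat("SURROUND_RIGHT", f"+{offset}_{word}"))
    return feats


def _inter_chunk_indices(
    instance: RelationInstance, chunks: ChunkAnnotation
) -> tuple[int, int, list[int]]:
    """(chunk index of first entity, of second entity, chunks strictly between)."""
    (first_start, first_end), (second_start, second_end) = _entity_token_ranges(instance)
    c_first = chunks.chunk_of(first_end - 1)
    c_second = chunks.chunk_of(second_start)
    inter = [
        ci
        for ci, c in enumerate(chunks.chunks)
        if c.start >= first_end and c.end <= second_start
    ]
    return c_first, c_second, inter


def chunk_features(
    instance: RelationInstance,
    chunks: Optional[ChunkAnnotation] = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> set[str]:
    """Inter-entity chunk heads, the concatenated inter-entity chunk-type
    sequence, and the heads of the chunks flanking the pair."""
    if chunks is None:
        chunks = chunk_sentence(instance.sentence)
    c_first, c_second, inter = _inter_chunk_indices(instance, chunks)
    toks = instance.sentence.tokens
    feats = set()
    for ci in inter:
        feats.add(_feat("CHUNK_HEAD_INTER", _norm(toks[chunks.chunks[ci].head].surface, config)))
    type_seq = "-".join(chunks.chunks[ci].type for ci in inter)
    feats.add(_feat("CHUNK_TYPE_INTER", type_seq or "EMPTY"))
    if c_first > 0:
        head = chunks.chunks[c_first - 1].head
        feats.add(_feat("CHUNK_HEAD_SURROUND", "L_" + _norm(toks[head].surface, config)))
    if c_second + 1 < len(chunks.chunks):
        head = chunks.chunks[c_second + 1].head
        feats.add(_feat("CHUNK_HEAD_SURROUND", "R_" + _norm(toks[head].surface, config)))
    return feats


ParserAdapter = Callable[[RelationInstance], str]


def parse_path_feature(
    instance: RelationInstance,
    parser: Optional[ParserAdapter] = None,
    chunks: Optional[ChunkAnnotation] = None,
) -> set[str]:
    """Syntactic path between the entities.

    With a configured constituency-parser adapter the path is whatever the
    adapter returns (e.g. ``NP↑S↓VP``).  Without one — the packaged default —
    the path degrades to the inter-entity chunk-type sequence prefixed
    ``FALLBACK:``.
    """
    if parser is not None:
        try:
            return {_feat("PARSE_PATH", parser(instance))}
        except Exception:  # parser failure degrades to the fallback
            pass
    if chunks is None:
        chunks = chunk_sentence(instance.sentence)
    _, _, inter = _inter_chunk_indices(instance, chunks)
    seq = "-".join(chunks.chunks[ci].type for ci in inter)
    return {_feat("PARSE_PATH", "FALLBACK:" + (seq or "EMPTY"))}


def sentence_position_feature(instance: RelationInstance) -> set[str]:
    """Relative sentence position r = index/(total−1) (r = 0 for a
    single-sentence abstract), discretized into quintile buckets 1–5."""
    sent = instance.sentence
    total = sent.sentences_in_abstract
    r = 0.0 if total <= 1 else sent.sentence_index / (total - 1)
    bucket = min(int(r * 5) + 1, 5)
    return {_feat("SENT_POS", str(bucket))}


def template_features(
    instance: RelationInstance, templates: Sequence[Template]
) -> set[str]:
    """One binary feature per induced template occurring contiguously in the
    slotified sentence."""
    toks = slotify(instance.sentence)
    return {
        _feat("TEMPLATE", t.identifier) for t in templates if match_template(t, toks)
    }


def order_feature(instance: RelationInstance) -> set[str]:
    gene_first = instance.first_entity.start <= instance.second_entity.start
    return {_feat("ORDER", "gene_first" if gene_first else "gene_last")}


def featurize(
    instance: RelationInstance,
    templates: Sequence[Template] = (),
    parser: Optional[ParserAdapter] = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Assemble the full feature vector for one relation instance.

    Deterministic; disabling a group in ``config`` removes exactly that
    group's features (the ablation harness relies on this).
    """
    g = config.groups
    feats: set[str] = set()
    chunks = None
    if g & {"CHUNK_HEAD_INTER", "CHUNK_HEAD_SURROUND", "CHUNK_TYPE_INTER", "PARSE_PATH"}:
        chunks = chunk_sentence(instance.sentence)
    if g & {"NGRAM1", "NGRAM2"}:
        ngrams = ngram_features(instance, config)
        if "NGRAM1" not in g:
            ngrams = {f for f in ngrams if not f.startswith("NGRAM1=")}
        if "NGRAM2" not in g:
            ngrams = {f for f in ngrams if not f.startswith("NGRAM2=")}
        feats |= ngrams
    if g & {"SURROUND_LEFT", "SURROUND_RIGHT"}:
        surround = surrounding_word_features(instance, config)
        if "SURROUND_LEFT" not in g:
            surround = {f for f in surround if not f.startswith("SURROUND_LEFT=")}
        if "SURROUND_RIGHT" not in g:
            surround = {f for f in surround if not f.startswith("SURROUND_RIGHT=")}
        feats |= surround
    if g & {"CHUNK_HEAD_INTER", "CHUNK_HEAD_SURROUND", "CHUNK_TYPE_INTER"}:
        chunk_feats = chunk_features(instance, chunks, config)
        for grp in ("CHUNK_HEAD_INTER", "CHUNK_HEAD_SURROUND", "CHUNK_TYPE_INTER"):
            if grp not in g:
                chunk_feats = {f for f in chunk_feats if not f.startswith(grp + "=")}
        feats |= chunk_feats
    if "PARSE_PATH" in g:
        feats |= parse_path_feature(instance, parser, chunks)
    if "SENT_POS" in g:
        feats |= sentence_position_feature(instance)
    if "TEMPLATE" in g and templates:
        feats |= template_features(instance, templates)
    if "ORDER" in g:
        feats |= order_feature(instance)
    return FeatureVector(frozenset(feats))


# ---------------------------------------------------------------------------
# Sparse text serialization: "label feat:1 feat:1 ..."
# ---------------------------------------------------------------------------

def write_sparse(
    rows: Iterable[tuple[Label, FeatureVector]], path: Union[str, Path]
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for label, vec in rows:
            feats = " ".join(f"{f}:1" for f in sorted(vec.features))
            fh.write(f"{label.value} {feats}".rstrip() + "\n")


def read_sparse(path: Union[str, Path]) -> list[tuple[Label, FeatureVector]]:
    rows = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        try:
            label = Label(parts[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad label {parts[0]!r}") from exc
        feats = frozenset(p.rsplit(":", 1)[0] for p in parts[1:])
        rows.append((label, FeatureVector(feats)))
    return rows
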