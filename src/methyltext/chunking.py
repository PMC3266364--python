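"""Rule-based shallow parsing: a suffix/lexicon POS guesser and a
finite-state NP/VP/PP chunker.

The chunker exists to feed the chunk-head, chunk-type and (fallback)
parse-path features.  It is deliberately deterministic and self-contained;
a statistical parser can be plugged in through the ``parser`` adapter of
``features.featurize`` where higher-quality syntax is wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .types import AnnotatedSentence

_DETERMINERS = {"the", "a", "an", "this", "that", "these", "those", "each", "every", "both"}
_PREPOSITIONS = {
    "in", "of", "on", "at", "by", "for", "with", "from", "to", "into", "within",
    "among", "between", "during", "as", "through", "via", "across", "after", "before",
}
_CONJUNCTIONS = {"and", "or", "but", "nor", "while", "whereas", "although", "however"}
_AUX_VERBS = {
    "is", "are", "was", "were", "be", "been", "being", "has", "have", "had",
    "may", "might", "can", "could", "should", "would", "will", "shall", "must",
    "do", "does", "did", "remains", "remained", "appears", "appeared", "occurs",
}
_ADJ_SUFFIXES = ("al", "ous", "ive", "ic", "ant", "ent", "able", "ible", "ary")


def guess_pos(surface: str) -> str:
    """Coarse POS guess: DT, IN, CC, VB, RB, JJ, CD, NN, or PUNCT."""
    low = surface.lower()
    if not any(ch.isalnum() for ch in surface):
        return "PUNCT"
    if low in _DETERMINERS:
        return "DT"
    if low in _PREPOSITIONS:
        return "IN"
    if low in _CONJUNCTIONS:
        return "CC"
    if low in _AUX_VERBS:
        return "VB"
    if low.replace(".", "").replace(",", "").replace("-", "").isdigit():
        return "CD"
    if low.endswith("ly") and len(low) > 3:
        return "RB"
    if low.endswith(("ed", "ing", "ates", "ate")) and len(low) > 4:
        return "VB"
    if low.endswith(_ADJ_SUFFIXES) and len(low) > 4:
        return "JJ"
    return "NN"


@dataclass(frozen=True)
class Chunk:
    """A shallow-parse phrase: type, head token index, half-open token span."""

    type: str  # NP, VP, PP, or O
    head: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.head < self.end):
            raise ValueError(f"chunk head {self.head} outside span [{self.start},{self.end})")


@dataclass
class ChunkAnnotation:
    """Chunks partitioning a token sequence, in order."""

    chunks: list[Chunk]

    def chunk_of(self, token_index: int) -> int:
        for ci, c in enumerate(self.chunks):
            if c.start <= token_index < c.end:
                return ci
        raise IndexError(f"token {token_index} not covered by any chunk")


def chunk_sentence(sentence: AnnotatedSentence) -> ChunkAnnotation:
    """Partition the sentence tokens into NP / VP / PP / O chunks.

    Grammar: NP = DT? (JJ|NN|CD)* (NN|CD); VP = a VB/RB run containing at
    least one VB (head: last VB); PP = IN followed by an NP (head: the NP
    head).  Everything else is a single-token O chunk.
    """
    pos = [guess_pos(t.surface) for t in sentence.tokens]
    n = len(pos)
    chunks: list[Chunk] = []
    i = 0

    def _np_end(start: int) -> int:
        """End of a maximal NP starting at ``start``, or start if none."""
        j = start
        if j < n and pos[j] == "DT":
            j += 1
        k = j
        while k < n and pos[k] in ("JJ", "NN", "CD"):
            k += 1
        # must contain at least one NN/CD
        if any(pos[x] in ("NN", "CD") for x in range(j, k)):
            return k
        return start

    while i < n:
        if pos[i] == "IN":
            np_end = _np_end(i + 1)
            if np_end > i + 1:
                head = max(x for x in range(i + 1, np_end) if pos[x] in ("NN", "CD"))
                chunks.append(Chunk("PP", head, i, np_end))
                i = np_end
                continue
        if pos[i] in ("VB", "RB"):
            j = i
            while j < n and pos[j] in ("VB", "RB"):
                j += 1
            vbs = [x for x in range(i, j) if pos[x] == "VB"]
            if vbs:
                chunks.append(Chunk("VP", vbs[-1], i, j))
                i = j
                continue
        np_end = _np_end(i)
        if np_end > i:
            head = max(x for x in range(i, np_end) if pos[x] in ("NN", "CD"))
            chunks.append(Chunk("NP", head, i, np_end))
            i = np_end
            continue
        chunks.append(Chunk("O", i, i, i + 1))
        i += 1
    return ChunkAnnotation(chunks)
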