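"""Relation-template induction by token-level Smith-Waterman local alignment.

Positive sentences are first "slotified" — every entity span collapses to a
slot symbol (``<gene>``, ``<methylation>``, ``<cancer>``) — so two sentences
stating the same relation about different genes still align.  All sentence
pairs are locally aligned with +1 for a match and −1 for both mismatch and
gap; the agreement subsequences of the top-scoring pairs (those containing at
least one slot, length ≥ 2) become templates, which are then matched as
binary classification features by contiguous occurrence in a slotified
sentence.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .types import AnnotatedSentence, EntityKind

MATCH_AWARD = 1
MISMATCH_PENALTY = -1
GAP_PENALTY = -1

SLOT_SYMBOLS = {
    EntityKind.GENE: "<gene>",
    EntityKind.METHYLATION: "<methylation>",
    EntityKind.CANCER: "<cancer>",
}

GAP = None  # gap marker inside aligned_pairs


@dataclass(frozen=True)
class Template:
    """A token sequence with entity slots, e.g. ``<gene> promoter <methylation>``."""

    tokens: tuple[str, ...]
    source_score: int
    identifier: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens) < 2:
            raise ValueError("template must have length >= 2")
        if not any(t in SLOT_SYMBOLS.values() for t in self.tokens):
            raise ValueError("template must contain at least one entity slot")
        if not self.identifier:
            object.__setattr__(self, "identifier", template_id(self.tokens))


def template_id(tokens: Sequence[str]) -> str:
    return hashlib.sha1(" ".join(tokens).encode("utf-8")).hexdigest()[:12]


@dataclass(frozen=True)
class AlignmentResult:
    """A maximal-scoring local alignment of two token sequences.

    ``aligned_pairs`` lists (index-in-a | None, index-in-b | None) steps;
    None marks a gap.  The score equals +1 per match, −1 per mismatch and −1
    per gap summed over the pairs (0 for the empty alignment).
    """

    score: int
    region_a: tuple[int, int]
    region_b: tuple[int, int]
    aligned_pairs: tuple[tuple[Optional[int], Optional[int]], ...]


def slotify(sentence: AnnotatedSentence) -> list[str]:
    """Token sequence with each entity span replaced by one slot symbol and
    all other tokens lower-cased.  Re-applying to a sentence built from the
    output changes nothing (slot symbols are fixed points)."""
    mentions = sorted(sentence.mentions, key=lambda m: (m.start, m.end))
    out: list[str] = []
    mi = 0
    for tok in sentence.tokens:
        while mi < len(mentions) and mentions[mi].end <= tok.start:
            mi += 1
        if mi < len(mentions) and mentions[mi].start <= tok.start and tok.end <= mentions[mi].end:
            if tok.start == mentions[mi].start:  # first token of the span emits the slot
                out.append(SLOT_SYMBOLS[mentions[mi].kind])
            continue
        out.append(tok.surface.lower())
    return out


def local_align(a: Sequence[str], b: Sequence[str]) -> AlignmentResult:
    """Smith-Waterman local alignment over tokens (match +1, mismatch −1,
    gap −1).  Slot symbols only match identical slot symbols (plain token
    equality).  Ties are broken toward the smallest end cell and, during
    traceback, diagonal over up over left — making the result deterministic.
    """
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    for i in range(1, n + 1):
        row = H[i]
        prev = H[i - 1]
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = prev[j - 1] + (MATCH_AWARD if ai == b[j - 1] else MISMATCH_PENALTY)
            best = max(0, diag, prev[j] + GAP_PENALTY, row[j - 1] + GAP_PENALTY)
            row[j] = best
    score = int(H.max())
    if score == 0:
        return AlignmentResult(0, (0, 0), (0, 0), ())
    end_i, end_j = min(
        (i, j) for i in range(n + 1) for j in range(m + 1) if H[i, j] == score
    )
    pairs: list[tuple[Optional[int], Optional[int]]] = []
    i, j = end_i, end_j
    while i > 0 and j > 0 and H[i, j] > 0:
        diag = H[i - 1, j - 1] + (MATCH_AWARD if a[i - 1] == b[j - 1] else MISMATCH_PENALTY)
        if H[i, j] == diag:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + GAP_PENALTY:
            pairs.append((i - 1, GAP))
            i -= 1
        else:
            pairs.append((GAP, j - 1))
            j -= 1
    pairs.reverse()
    return AlignmentResult(
        score=score,
        region_a=(i, end_i),
        region_b=(j, end_j),
        aligned_pairs=tuple(pairs),
    )


def agreement_tokens(a: Sequence[str], b: Sequence[str], result: AlignmentResult) -> list[str]:
    """Tokens at aligned positions where both sides agree (matches only;
    mismatches and gaps elided)."""
    out = []
    for i, j in result.aligned_pairs:
        if i is not GAP and j is not GAP and a[i] == b[j]:
            out.append(a[i])
    return out


def induce_templates(
    positive_sentences: Sequence[AnnotatedSentence],
    top_k: int = 100,
    max_sentences: int = 5000,
    seed: int = 0,
) -> list[Template]:
    """Induce templates from the top-``top_k`` highest-scoring sentence pairs.

    All unordered pairs of slotified sentences are aligned and ranked by
    score (descending; ties by the lexicographic order of the agreement
    subsequence).  Each top pair whose agreement subsequence contains ≥1 slot
    and ≥2 tokens yields a template; duplicates merge, keeping the best
    score.  Corpora larger than ``max_sentences`` are subsampled with
    ``seed`` before the quadratic all-pairs pass.
    """
    if len(positive_sentences) < 2:
        raise ValueError("template induction needs at least 2 positive sentences")
    slotted = [tuple(slotify(s)) for s in positive_sentences]
    if len(slotted) > max_sentences:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(slotted), size=max_sentences, replace=False)
        slotted = [slotted[i] for i in sorted(idx)]
    # canonical pair order -> alignment independent of input order
    scored: list[tuple[int, tuple[str, ...]]] = []
    uniq = sorted(set(slotted))
    for x in range(len(uniq)):
        for y in range(x, len(uniq)):
            if x == y and slotted.count(uniq[x]) < 2:
                continue
            a, b = uniq[x], uniq[y]
            res = local_align(a, b)
            if res.score <= 0:
                continue
            agree = tuple(agreement_tokens(a, b, res))
            scored.append((res.score, agree))
    scored.sort(key=lambda sa: (-sa[0], sa[1]))
    best: dict[tuple[str, ...], int] = {}
    for score, agree in scored[: max(top_k, 0)]:
        if len(agree) < 2 or not any(t in SLOT_SYMBOLS.values() for t in agree):
            continue
        if agree not in best:
            best[agree] = score
    templates = [Template(tokens=t, source_score=s) for t, s in best.items()]
    templates.sort(key=lambda t: (-t.source_score, t.tokens))
    return templates


def match_template(
    template: Template, sentence: Union[AnnotatedSentence, Sequence[str]]
) -> bool:
    """True iff the template token sequence occurs contiguously in the
    slotified sentence."""
    toks = slotify(sentence) if isinstance(sentence, AnnotatedSentence) else list(sentence)
    t = list(template.tokens)
    k = len(t)
    return any(toks[i : i + k] == t for i in range(len(toks) - k + 1))


def write_templates(templates: Iterable[Template], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in templates:
            fh.write(f"{t.identifier}\t{t.source_score}\t{' '.join(t.tokens)}\n")


def read_templates(path: Union[str, Path]) -> list[Template]:
    out = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        try:
            ident, score, tokens = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields") from exc
        out.append(Template(tokens=tuple(tokens.split(" ")), source_score=int(score), identifier=ident))
    return out
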