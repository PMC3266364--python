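"""Named entity recognition for methylation terms, cancer names, and genes.

Methylation mentions come from the token-level pattern
``(hyper|hypo)?(-)?(methylat.+)``; the optional prefix records whether the
text describes hyper- or hypomethylation.  Cancer mentions combine a
dictionary of canonical names with three patterns: (1) case-sensitive
abbreviations such as "NPC", (2) an anatomical site immediately followed by a
cancer-related keyword ("breast cancer"), and (3) morphology suffixes
(``.+oma``, ``leukemia``/``leukaemia``).  Gene mentions come from dictionary
lookup after orthographic-variant expansion ("BRCA1" ↔ "BRCA-1"), standing in
for a statistical gene tagger behind the same interface.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .types import AnnotatedSentence, Direction, EntityKind, EntityMention

METHYLATION_PATTERN = re.compile(r"(hyper|hypo)?(-)?(methylat.+)", re.IGNORECASE)

# Morphology suffix pattern; we require >= 3 stem characters before "oma"
# (the bare pattern's single-character minimum admits noise like "soma").
_OMA_PATTERN = re.compile(r"(.{3,}oma|leukemia|leukaemia)", re.IGNORECASE)

#: The fixed cancer-related keyword lexicon used by the site+keyword pattern.
CANCER_KEYWORDS = frozenset(
    {"cancer", "tumor", "tumour", "neoplasm", "carcinogenesis", "tumorigenesis", "metastasis"}
)


class MatchStrategy(str, enum.Enum):
    EXACT = "EXACT"
    APPROXIMATE = "APPROXIMATE"


@dataclass(frozen=True)
class MatchResult:
    """Mention-level evaluation counts under an exact or approximate
    (same-kind span overlap) matching strategy."""

    true_positives: int
    false_positives: int
    false_negatives: int
    strategy: MatchStrategy
    undefined_precision: bool = False
    undefined_recall: bool = False

    @property
    def precision(self) -> float:
        denom = self.true_positives + self.false_positives
        return self.true_positives / denom if denom else 0.0

    @property
    def recall(self) -> float:
        denom = self.true_positives + self.false_negatives
        return self.true_positives / denom if denom else 0.0


@dataclass
class CancerLexicon:
    """Dictionary resources for the cancer tagger.

    ``canonical_names`` are matched case-insensitively (longest match);
    ``abbreviations`` are matched case-SENSITIVELY; ``site_terms`` feed the
    site+keyword pattern; ``keyword_terms`` is the fixed keyword list.
    """

    canonical_names: dict[str, str] = field(default_factory=dict)  # lower name -> canonical
    abbreviations: dict[str, str] = field(default_factory=dict)  # acronym -> expansion
    site_terms: frozenset[str] = frozenset()
    keyword_terms: frozenset[str] = CANCER_KEYWORDS

    @classmethod
    def from_files(
        cls,
        names_path: Optional[Union[str, Path]] = None,
        abbreviations_path: Optional[Union[str, Path]] = None,
        sites_path: Optional[Union[str, Path]] = None,
    ) -> "CancerLexicon":
        """Load the packaged fixture lexicon, overriding any part from
        user-supplied TSV/plain-text files."""
        data = resources.files("methyltext.data")

        def _read(p, default_name):
            if p is not None:
                return Path(p).read_text(encoding="utf-8")
            return data.joinpath(default_name).read_text(encoding="utf-8")

        canonical = {}
        for line in _read(names_path, "cancer_names.tsv").splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            surface = parts[0].strip().lower()
            canonical[surface] = (parts[1].strip() if len(parts) > 1 else surface).lower()
        abbrevs = {}
        for line in _read(abbreviations_path, "cancer_abbreviations.tsv").splitlines():
            if not line.strip():
                continue
            acro, _, expansion = line.partition("\t")
            abbrevs[acro.strip()] = expansion.strip().lower()
        sites = frozenset(
            w.strip().lower()
            for w in _read(sites_path, "tumor_sites.txt").splitlines()
            if w.strip()
        )
        return cls(canonical_names=canonical, abbreviations=abbrevs, site_terms=sites)


@dataclass
class GeneLexicon:
    """Surface-form dictionary for gene lookup after variant expansion.

    ``entries`` maps each surface variant to ``(gene_id, official_symbol)``;
    ``folded`` supports the case-insensitive second pass.  Multi-token
    surfaces are matched over token n-grams (longest first).
    """

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    folded: dict[str, tuple[str, str]] = field(default_factory=dict)
    max_tokens: int = 1

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, Sequence[str]]]) -> "GeneLexicon":
        """Build from (identifier, official symbol, aliases) records, expanding
        each surface with :func:`generate_variants`."""
        lex = cls()
        for gene_id, symbol, aliases in records:
            for surface in [symbol, *aliases]:
                surface = surface.strip()
                if not surface:
                    continue
                for variant in generate_variants(surface):
                    # official symbols take precedence over colliding aliases
                    if variant not in lex.entries or surface == symbol:
                        lex.entries[variant] = (gene_id, symbol)
                    lex.folded.setdefault(variant.casefold(), (gene_id, symbol))
                    lex.max_tokens = max(lex.max_tokens, len(variant.split()))
        return lex

    @classmethod
    def from_file(cls, path: Optional[Union[str, Path]] = None) -> "GeneLexicon":
        """Load a TSV gene dictionary (id, symbol, comma-separated aliases);
        defaults to the packaged fixture."""
        if path is None:
            text = resources.files("methyltext.data").joinpath("gene_dictionary.tsv").read_text()
        else:
            text = Path(path).read_text(encoding="utf-8")
        records = []
        for line in text.splitlines():
            if not line.strip():
                continue
            parts = line.split("\t")
            gene_id, symbol = parts[0].strip(), parts[1].strip()
            aliases = [a for a in parts[2].split(",")] if len(parts) > 2 else []
            records.append((gene_id, symbol, aliases))
        return cls.from_records(records)


def generate_variants(symbol: str) -> set[str]:
    """Orthographic variants of a gene symbol, closed under re-application.

    Rules: insert a hyphen at the trailing letter→digit boundary ("BRCA1" →
    "BRCA-1"), remove hyphens ("BRCA-1" → "BRCA1"), and case-fold (lower and
    upper).  The result always contains ``symbol`` itself.
    """
    if not symbol:
        raise ValueError("empty gene symbol")
    variants = {symbol}
    while True:
        new = set()
        for v in variants:
            m = re.match(r"^(.*[A-Za-z])(\d+)$", v)
            if m and not m.group(1).endswith("-"):
                new.add(f"{m.group(1)}-{m.group(2)}")
            if "-" in v:
                new.add(v.replace("-", ""))
            new.add(v.lower())
            new.add(v.upper())
        if new <= variants:
            return variants
        variants |= new


def tag_methylation(sentence: AnnotatedSentence) -> list[EntityMention]:
    """Add a METHYLATION mention for every token fully matching the
    methylation pattern; direction comes from the hyper/hypo prefix."""
    added = []
    for tok in sentence.tokens:
        m = METHYLATION_PATTERN.fullmatch(tok.surface)
        if not m:
            continue
        prefix = (m.group(1) or "").lower()
        direction = {"hyper": Direction.HYPER, "hypo": Direction.HYPO}.get(
            prefix, Direction.UNSPECIFIED
        )
        added.append(
            EntityMention(
                kind=EntityKind.METHYLATION,
                start=tok.start,
                end=tok.end,
                surface=tok.surface,
                direction=direction,
                rule="methylation-regex",
            )
        )
    _merge_mentions(sentence, added)
    return added


def _candidate_cancer_mentions(
    sentence: AnnotatedSentence, lexicon: CancerLexicon
) -> list[EntityMention]:
    toks = sentence.tokens
    out = []
    # (a) canonical-name dictionary, case-insensitive longest n-gram match
    max_len = max((len(name.split()) for name in lexicon.canonical_names), default=1)
    for i in range(len(toks)):
        for n in range(min(max_len, len(toks) - i), 0, -1):
            window = toks[i : i + n]
            key = " ".join(t.surface for t in window).lower()
            if key in lexicon.canonical_names:
                out.append(
                    EntityMention(
                        kind=EntityKind.CANCER,
                        start=window[0].start,
                        end=window[-1].end,
                        surface=sentence.text[window[0].start : window[-1].end],
                        normalized_id=lexicon.canonical_names[key],
                        rule="dictionary",
                    )
                )
                break
    for i, tok in enumerate(toks):
        # (1) abbreviations, case-sensitive
        if tok.surface in lexicon.abbreviations:
            out.append(
                EntityMention(
                    kind=EntityKind.CANCER,
                    start=tok.start,
                    end=tok.end,
                    surface=tok.surface,
                    normalized_id=lexicon.abbreviations[tok.surface],
                    rule="pattern-1-abbreviation",
                )
            )
        # (2) tumor site + cancer keyword, case-insensitive, two-token span
        if (
            tok.surface.lower() in lexicon.site_terms
            and i + 1 < len(toks)
            and toks[i + 1].surface.lower() in lexicon.keyword_terms
        ):
            nxt = toks[i + 1]
            out.append(
                EntityMention(
                    kind=EntityKind.CANCER,
                    start=tok.start,
                    end=nxt.end,
                    surface=sentence.text[tok.start : nxt.end],
                    normalized_id=f"{tok.surface.lower()} {nxt.surface.lower()}",
                    rule="pattern-2-site-keyword",
                )
            )
        # (3) morphology suffix, case-insensitive
        if _OMA_PATTERN.fullmatch(tok.surface):
            out.append(
                EntityMention(
                    kind=EntityKind.CANCER,
                    start=tok.start,
                    end=tok.end,
                    surface=tok.surface,
                    normalized_id=tok.surface.lower(),
                    rule="pattern-3-suffix",
                )
            )
    return out


def resolve_overlaps(candidates: Iterable[EntityMention]) -> list[EntityMention]:
    """Keep a non-overlapping subset: longest span first, ties leftmost-first
    (single kind per span)."""
    chosen: list[EntityMention] = []
    for cand in sorted(candidates, key=lambda m: (-(m.end - m.start), m.start)):
        if not any(cand.overlaps(c) for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda m: (m.start, m.end))
    return chosen


def tag_cancer(sentence: AnnotatedSentence, lexicon: CancerLexicon) -> list[EntityMention]:
    """Add CANCER mentions from the dictionary and the three patterns;
    overlapping candidates are resolved longest-span-first, leftmost-first.
    Each mention records the rule that produced it."""
    added = resolve_overlaps(_candidate_cancer_mentions(sentence, lexicon))
    _merge_mentions(sentence, added)
    return added


def tag_genes(sentence: AnnotatedSentence, lexicon: GeneLexicon) -> list[EntityMention]:
    """Add GENE mentions by longest-match dictionary lookup over token
    n-grams: case-sensitive first, then case-insensitive; each mention
    carries the lexicon's gene identifier."""
    toks = sentence.tokens
    added = []
    i = 0
    while i < len(toks):
        hit = None
        for n in range(min(lexicon.max_tokens, len(toks) - i), 0, -1):
            window = toks[i : i + n]
            key = " ".join(t.surface for t in window)
            entry = lexicon.entries.get(key) or lexicon.folded.get(key.casefold())
            if entry is not None:
                hit = (window, entry)
                break
        if hit is None:
            i += 1
            continue
        window, (gene_id, symbol) = hit
        added.append(
            EntityMention(
                kind=EntityKind.GENE,
                start=window[0].start,
                end=window[-1].end,
                surface=sentence.text[window[0].start : window[-1].end],
                normalized_id=gene_id,
                rule="gene-dictionary",
            )
        )
        i += len(window)
    _merge_mentions(sentence, added)
    return added


def _merge_mentions(sentence: AnnotatedSentence, new: list[EntityMention]) -> None:
    """Add mentions, dropping exact duplicates and any new mention whose span
    overlaps an existing mention (first tagger wins across kinds)."""
    for m in list(new):
        if any(m.overlaps(old) for old in sentence.mentions):
            new.remove(m)
            continue
        sentence.mentions.append(m)
    sentence.mentions.sort(key=lambda m: (m.start, m.end))


def tag_all(
    sentence: AnnotatedSentence,
    gene_lexicon: Optional[GeneLexicon] = None,
    cancer_lexicon: Optional[CancerLexicon] = None,
    kinds: Iterable[EntityKind] = (EntityKind.GENE, EntityKind.METHYLATION, EntityKind.CANCER),
) -> AnnotatedSentence:
    """Tag the requested entity kinds in place (gene, then methylation, then
    cancer; earlier kinds claim overlapping spans) and return the sentence."""
    kinds = set(kinds)
    if EntityKind.GENE in kinds:
        tag_genes(sentence, gene_lexicon or GeneLexicon.from_file())
    if EntityKind.METHYLATION in kinds:
        tag_methylation(sentence)
    if EntityKind.CANCER in kinds:
        tag_cancer(sentence, cancer_lexicon or CancerLexicon.from_files())
    sentence.validate()
    return sentence


_MentionItem = Union[EntityMention, tuple[object, EntityMention]]


def _with_keys(items: Iterable[_MentionItem]) -> list[tuple[object, EntityMention]]:
    out = []
    for it in items:
        if isinstance(it, EntityMention):
            out.append((0, it))
        else:
            out.append((it[0], it[1]))
    return out


def evaluate_mentions(
    gold: Iterable[_MentionItem],
    predicted: Iterable[_MentionItem],
    strategy: MatchStrategy = MatchStrategy.EXACT,
) -> MatchResult:
    """Score predicted mentions against gold under EXACT (identical kind and
    span) or APPROXIMATE (same kind, spans overlap by ≥1 character) matching.

    Matching is one-to-one and greedy left-to-right over gold mentions; under
    APPROXIMATE, a prediction with the identical span is preferred before any
    merely-overlapping one, so approximate scores never fall below exact ones.
    Items may be bare mentions (single sentence) or ``(sentence_key, mention)``
    pairs.
    """
    gold_items = sorted(_with_keys(gold), key=lambda km: (str(km[0]), km[1].start, km[1].end))
    pred_items = sorted(_with_keys(predicted), key=lambda km: (str(km[0]), km[1].start, km[1].end))
    used = [False] * len(pred_items)
    tp = 0
    for gkey, gm in gold_items:
        exact_hit = overlap_hit = None
        for j, (pkey, pm) in enumerate(pred_items):
            if used[j] or pkey != gkey or pm.kind is not gm.kind:
                continue
            if pm.start == gm.start and pm.end == gm.end:
                exact_hit = j
                break
            if strategy is MatchStrategy.APPROXIMATE and overlap_hit is None and pm.overlaps(gm):
                overlap_hit = j
        j = exact_hit if exact_hit is not None else (
            overlap_hit if strategy is MatchStrategy.APPROXIMATE else None
        )
        if j is not None:
            used[j] = True
            tp += 1
    fp = used.count(False)
    fn = len(gold_items) - tp
    return MatchResult(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        strategy=strategy,
        undefined_precision=(tp + fp == 0),
        undefined_recall=(tp + fn == 0),
    )
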