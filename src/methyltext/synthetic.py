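"""Synthetic annotated corpora with controllable relational signal.

The generator emulates the *structure* of methylation-focused abstract
sentences — gene, methylation and cancer mentions in positive and negative
relational contexts, multi-gene list sentences that expand into several
single-pair instances, numeric fillers exercising tokenization — with known
gold labels at every stage.  It makes no attempt at the lexical richness of
real abstracts; see docs/methods.md for what that does and does not allow
tests to conclude.

Frames fall into four pools:

* cue-positive frames (clearly relational wording, used with probability
  ``signal_strength`` for positive sentences);
* neutral-positive frames (hedged wording; one of them is deliberately
  shared with the non-relational pool, making a small fraction of instances
  irreducibly ambiguous);
* negated-negative frames (explicit negation, probability
  ``negation_fraction`` among negatives);
* non-relational negative frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus import enumerate_pairs, tokenize
from .ner import GeneLexicon
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

_DEFAULT_CANCERS = (
    "melanoma",
    "breast cancer",
    "lung cancer",
    "colorectal cancer",
    "gastric cancer",
    "prostate cancer",
    "NPC",
    "CRC",
    "hepatocellular carcinoma",
    "nasopharyngeal carcinoma",
    "leukemia",
    "renal cell carcinoma",
)

_METHYL_WORDS = (
    ("methylated", Direction.UNSPECIFIED),
    ("methylation", Direction.UNSPECIFIED),
    ("hypermethylated", Direction.HYPER),
    ("hypermethylation", Direction.HYPER),
    ("hypomethylated", Direction.HYPO),
    ("hypomethylation", Direction.HYPO),
)

# Placeholders: G gene, M methylation term, C cancer, NUM numeric filler.
_CUE_FRAMES = (
    "the G promoter was M:hypermethylated in NUM % of C samples .",
    "G is frequently M:methylated in C .",
    "aberrant G promoter M:hypermethylation occurs in C .",
    "promoter M:hypermethylation of G silences its expression in C .",
    "M:hypomethylation of G was frequently detected in C tissues .",
    "G was M:methylated in NUM % of C samples .",
)
# list-form cue frame used when the sentence carries several genes
_LIST_FRAME = "GLIST were M:methylated in NUMLIST % of C samples , respectively ."

_NEUTRAL_POSITIVE_FRAMES = (
    "M:methylation of G in C was discussed .",
    "the M:methylation status of G in C was evaluated in this study .",
)

_NEGATED_FRAMES = (
    "G was not M:methylated in C samples .",
    "no M:methylation of G was detected in C specimens .",
    "G showed no evidence of M:methylation in C .",
)

_NONRELATIONAL_FRAMES = (
    "M:methylation of G in C was discussed .",  # shared with the neutral-positive pool
    "G expression was measured in C samples , and M:methylation was not assessed .",
    "we examined G expression in C , while global M:methylation levels varied .",
)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic corpora.

    Defaults yield 2,000 sentences → 2,000 instances per corpus, half
    positive and half negative, with strong (0.9) but imperfect lexical
    signal — the regime the classifier-recovery properties are stated in.
    """

    seed: int = 0
    n_abstracts: int = 250
    sentences_per_abstract: int = 8
    gene_vocabulary: Sequence[tuple[str, str]] = ()  # (symbol, identifier)
    cancer_vocabulary: Sequence[str] = _DEFAULT_CANCERS
    positive_fraction: float = 0.5
    signal_strength: float = 0.9
    negation_fraction: float = 0.5
    multi_entity_rate: float = 0.0  # expected extra genes per positive sentence

    def __post_init__(self) -> None:
        for name in ("positive_fraction", "signal_strength", "negation_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if not self.gene_vocabulary:
            lex = GeneLexicon.from_file()
            symbols = sorted({(sym, gid) for gid, sym in lex.entries.values()})
            self.gene_vocabulary = tuple(symbols)
        if not self.cancer_vocabulary:
            raise ValueError("cancer vocabulary must be non-empty")


@dataclass
class _Draft:
    """A sentence under construction: token surfaces plus mention plans."""

    surfaces: list[str] = field(default_factory=list)
    mentions: list[tuple[int, str, str, Direction, int]] = field(default_factory=list)
    # (surface index, kind, normalized_id, direction, word count)

    def add(self, surface: str) -> None:
        self.surfaces.extend(surface.split(" "))

    def add_entity(self, surface: str, kind: str, normalized: str, direction: Direction) -> None:
        self.mentions.append(
            (len(self.surfaces), kind, normalized, direction, len(surface.split(" ")))
        )
        self.add(surface)


def _realize(draft: _Draft, sentence_index: int, total: int, document_id: str) -> AnnotatedSentence:
    """Turn a draft into a validated AnnotatedSentence with exact offsets."""
    starts: list[int] = []
    pos = 0
    for s in draft.surfaces:
        starts.append(pos)
        pos += len(s) + 1
    text = " ".join(draft.surfaces)
    sent = AnnotatedSentence(
        text=text,
        tokens=tokenize(text),
        sentence_index=sentence_index,
        sentences_in_abstract=total,
        document_id=document_id,
    )
    for idx, kind, normalized, direction, n_words in draft.mentions:
        # a multi-word entity spans n_words consecutive surfaces joined by
        # single spaces, so its span is contiguous in the text
        surface = " ".join(draft.surfaces[idx : idx + n_words])
        start = starts[idx]
        end = start + len(surface)
        sent.mentions.append(
            EntityMention(
                kind=EntityKind(kind),
                start=start,
                end=end,
                surface=surface,
                normalized_id=normalized,
                direction=direction,
            )
        )
    sent.mentions.sort(key=lambda m: (m.start, m.end))
    sent.validate()
    return sent


def _fill_frame(
    frame: str,
    rng: np.random.Generator,
    genes: list[tuple[str, str]],
    cancer: str,
) -> _Draft:
    draft = _Draft()
    for word in frame.split(" "):
        if word == "G":
            sym, gid = genes[0]
            draft.add_entity(sym, "GENE", gid, Direction.UNSPECIFIED)
        elif word == "GLIST":
            for i, (sym, gid) in enumerate(genes):
                if i == len(genes) - 1 and len(genes) > 1:
                    draft.add("and")
                draft.add_entity(sym, "GENE", gid, Direction.UNSPECIFIED)
                if i < len(genes) - 2:
                    draft.add(",")
                elif i == len(genes) - 2:
                    draft.add(",")
        elif word.startswith("M:"):
            base = word.split(":", 1)[1]
            # pick a methylation surface consistent with the frame's morphology
            wants_noun = base.endswith("ion")
            choices = [
                (w, d) for w, d in _METHYL_WORDS if w.endswith("ion") == wants_noun
            ]
            surface, direction = choices[rng.integers(len(choices))]
            draft.add_entity(surface, "METHYLATION", "", direction)
        elif word == "C":
            draft.add_entity(cancer, "CANCER", cancer.lower(), Direction.UNSPECIFIED)
        elif word == "NUM":
            draft.add(str(int(rng.integers(5, 96))))
        elif word == "NUMLIST":
            nums = [str(int(rng.integers(5, 96))) for _ in genes]
            for i, nstr in enumerate(nums):
                if i == len(nums) - 1 and len(nums) > 1:
                    draft.add("and")
                draft.add(nstr)
                if i < len(nums) - 1:
                    draft.add(",")
        else:
            draft.add(word)
    return draft


def _choose_genes(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> list[tuple[str, str]]:
    vocab = list(config.gene_vocabulary)
    if n > len(vocab):
        raise ValueError(
            f"gene vocabulary of {len(vocab)} exhausted: sentence needs {n} distinct genes"
        )
    idx = rng.choice(len(vocab), size=n, replace=False)
    return [vocab[i] for i in idx]


def generate_corpus(
    config: Optional[GeneratorConfig] = None,
) -> tuple[Corpus, Corpus, list[AbstractRecord]]:
    """Generate gold-annotated GM and GC corpora plus the source abstracts.

    Fully deterministic given ``config.seed``.  Every sentence contains at
    least one gene, one methylation term and one cancer mention; positive
    counts match ``positive_fraction`` up to rounding.  Multi-gene sentences
    (rate ``multi_entity_rate``) expand to one instance per gene, all
    inheriting the sentence label.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    n_sentences = config.n_abstracts * config.sentences_per_abstract
    n_pos = round(n_sentences * config.positive_fraction)
    base = [Label.POSITIVE] * n_pos + [Label.NEGATIVE] * (n_sentences - n_pos)
    labels = [base[i] for i in rng.permutation(n_sentences)]

    gm_instances: list[RelationInstance] = []
    gc_instances: list[RelationInstance] = []
    abstracts: list[AbstractRecord] = []
    si = 0
    for a in range(config.n_abstracts):
        doc_id = f"SYN{a + 1:07d}"
        sentences = []
        for s in range(config.sentences_per_abstract):
            label = labels[si]
            si += 1
            n_extra = 0
            if config.multi_entity_rate > 0 and label is Label.POSITIVE:
                n_extra = min(int(rng.poisson(config.multi_entity_rate)), 4)
            genes = _choose_genes(rng, config, 1 + n_extra)
            cancer = config.cancer_vocabulary[rng.integers(len(config.cancer_vocabulary))]
            if label is Label.POSITIVE:
                if rng.random() < config.signal_strength:
                    frame = (
                        _LIST_FRAME
                        if len(genes) > 1
                        else _CUE_FRAMES[rng.integers(len(_CUE_FRAMES))]
                    )
                else:
                    frame = _NEUTRAL_POSITIVE_FRAMES[
                        rng.integers(len(_NEUTRAL_POSITIVE_FRAMES))
                    ]
            else:
                if rng.random() < config.negation_fraction:
                    frame = _NEGATED_FRAMES[rng.integers(len(_NEGATED_FRAMES))]
                else:
                    frame = _NONRELATIONAL_FRAMES[rng.integers(len(_NONRELATIONAL_FRAMES))]
            draft = _fill_frame(frame, rng, genes, cancer)
            sent = _realize(draft, s, config.sentences_per_abstract, doc_id)
            sentences.append(sent)
            for inst in enumerate_pairs(sent, RelationKind.GM):
                inst.label = label
                gm_instances.append(inst)
            for inst in enumerate_pairs(sent, RelationKind.GC):
                inst.label = label
                gc_instances.append(inst)
        abstracts.append(
            AbstractRecord(
                document_id=doc_id,
                title="",
                body=" ".join(x.text for x in sentences),
                sentences=sentences,
            )
        )
    gm = Corpus(name=f"synthetic-gm-seed{config.seed}", relation_kind=RelationKind.GM,
                instances=gm_instances)
    gc = Corpus(name=f"synthetic-gc-seed{config.seed}", relation_kind=RelationKind.GC,
                instances=gc_instances)
    return gm, gc, abstracts


def instance_groups(corpus: Corpus) -> list[str]:
    """Group keys (document id + sentence index) so that expansion copies of
    one source sentence stay in the same cross-validation fold."""
    return [
        f"{inst.sentence.document_id}:{inst.sentence.sentence_index}"
        for inst in corpus.instances
    ]
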