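"""End-to-end extraction and evidence ranking.

The two-stage scheme: tag genes and methylation terms, classify every
gene-methylation (GM) pair; in sentences with at least one positive GM pair,
tag cancer names and classify gene-cancer (GC) pairs over the positively
methylated genes.  Every positive GC classification yields an evidence
sentence carrying the GC model probability.  Evidence is aggregated per
(gene, cancer) association: the ranking score is the sum of the evidence
probabilities, and the average maximum probability is that sum divided by
the number of evidence sentences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Protocol, Sequence

from .corpus import enumerate_pairs
from .features import DEFAULT_CONFIG, FeatureConfig, FeatureVector, featurize
from .ner import (
    CancerLexicon,
    GeneLexicon,
    MatchResult,
    MatchStrategy,
    tag_cancer,
    tag_genes,
    tag_methylation,
)
from .templates import Template
from .types import (
    AbstractRecord,
    AnnotatedSentence,
    Direction,
    EntityKind,
    EntityMention,
    Label,
    RelationInstance,
    RelationKind,
)

logger = logging.getLogger(__name__)


class RelationModel(Protocol):
    """Anything that maps a feature vector to P(POSITIVE); satisfied by
    :class:`methyltext.maxent.MaxEntModel` and by test oracles."""

    def predict_probability(self, vector: FeatureVector) -> float: ...


@dataclass(frozen=True)
class EvidenceSentence:
    """One sentence supporting a (gene, cancer) association.

    ``gc_probability`` is the GC model's positive probability — the quantity
    summed by the ranking score; the GM probability of the gene's positive
    methylation pair is retained as metadata.
    """

    document_id: str
    sentence_index: int
    text: str
    gene_id: str
    gene_surface: str
    cancer_name: str
    gc_probability: float
    gm_probability: float
    direction: Direction = Direction.UNSPECIFIED


@dataclass
class RankedAssociation:
    """A (gene, cancer) association aggregated over its evidence sentences.

    ranking_score = Σ_i P(positive | evidence sentence i)  (GC model)
    average_max_probability = ranking_score / n_sentences
    """

    gene_id: str
    cancer_name: str
    ranking_score: float
    evidence: list[EvidenceSentence]
    direction_counts: dict[Direction, int] = field(default_factory=dict)

    @property
    def n_sentences(self) -> int:
        return len(self.evidence)

    @property
    def average_max_probability(self) -> float:
        return self.ranking_score / self.n_sentences if self.evidence else 0.0


#: Cues that flip the bootstrap labeling heuristic to NEGATIVE.
NEGATION_TOKENS = frozenset(
    {"not", "no", "never", "cannot", "neither", "nor", "without", "absent", "lacked", "lacking"}
)


def rule_label(instance: RelationInstance, margin: int = 3) -> Label:
    """Weak bootstrap labeling heuristic: a pair is POSITIVE unless a
    negation cue occurs between the entities or within ``margin`` tokens
    after the later one.  Used to bootstrap corpora and for the worked
    example; the trained classifier supersedes it."""
    sent = instance.sentence
    first, second = instance.ordered_pair()
    lo = sent.token_index_range(first)[1]
    hi = sent.token_index_range(second)[1] + margin
    window = [t.surface.lower() for t in sent.tokens[lo:hi]]
    return Label.NEGATIVE if any(w in NEGATION_TOKENS for w in window) else Label.POSITIVE


def extract(
    abstracts: Iterable[AbstractRecord],
    gm_model: RelationModel,
    gc_model: RelationModel,
    gene_lexicon: Optional[GeneLexicon] = None,
    cancer_lexicon: Optional[CancerLexicon] = None,
    templates: Sequence[Template] = (),
    config: FeatureConfig = DEFAULT_CONFIG,
    threshold: float = 0.5,
) -> list[EvidenceSentence]:
    """Run the full two-stage extraction over abstracts.

    Stage gating: the cancer tagger and GC classifier only ever see sentences
    with at least one positive GM pair, and only the genes from those
    positive pairs are paired with cancer mentions.
    """
    gene_lexicon = gene_lexicon or GeneLexicon.from_file()
    cancer_lexicon = cancer_lexicon or CancerLexicon.from_files()
    evidence: list[EvidenceSentence] = []
    n_sentences = n_gm_pairs = n_gm_pos = n_gc_pairs = 0
    for abstract in abstracts:
        for sentence in abstract.sentences:
            n_sentences += 1
            tag_genes(sentence, gene_lexicon)
            tag_methylation(sentence)
            gm_instances = enumerate_pairs(sentence, RelationKind.GM)
            n_gm_pairs += len(gm_instances)
            positive_gm: dict[tuple[int, int], tuple[float, EntityMention]] = {}
            for inst in gm_instances:
                p = gm_model.predict_probability(featurize(inst, templates, config=config))
                if p >= threshold:
                    key = inst.gene.span()
                    if key not in positive_gm or p > positive_gm[key][0]:
                        positive_gm[key] = (p, inst.partner)
            if not positive_gm:
                continue
            n_gm_pos += len(positive_gm)
            tag_cancer(sentence, cancer_lexicon)
            genes = [g for g in sentence.mentions_of(EntityKind.GENE) if g.span() in positive_gm]
            cancers = sentence.mentions_of(EntityKind.CANCER)
            for gene in genes:
                gm_prob, methyl = positive_gm[gene.span()]
                for cancer in cancers:
                    n_gc_pairs += 1
                    gc_inst = RelationInstance(
                        sentence=sentence.copy(),
                        relation_kind=RelationKind.GC,
                        first_entity=gene,
                        second_entity=cancer,
                    )
                    p = gc_model.predict_probability(
                        featurize(gc_inst, templates, config=config)
                    )
                    if p >= threshold:
                        evidence.append(
                            EvidenceSentence(
                                document_id=abstract.document_id,
                                sentence_index=sentence.sentence_index,
                                text=sentence.text,
                                gene_id=gene.normalized_id or gene.surface,
                                gene_surface=gene.surface,
                                cancer_name=cancer.normalized_id or cancer.surface.lower(),
                                gc_probability=p,
                                gm_probability=gm_prob,
                                direction=methyl.direction,
                            )
                        )
    logger.info(
        "extract: %d sentences, %d GM pairs, %d positive GM genes, %d GC pairs, %d evidence",
        n_sentences, n_gm_pairs, n_gm_pos, n_gc_pairs, len(evidence),
    )
    return evidence


def rank(evidence: Iterable[EvidenceSentence]) -> list[RankedAssociation]:
    """Aggregate evidence into ranked (gene, cancer) associations.

    Associations sort by ranking score descending (ties: gene id, then
    cancer name); evidence within an association sorts by its probability,
    highest first.
    """
    grouped: dict[tuple[str, str], list[EvidenceSentence]] = {}
    for ev in evidence:
        grouped.setdefault((ev.gene_id, ev.cancer_name), []).append(ev)
    associations = []
    for (gene_id, cancer_name), evs in grouped.items():
        evs.sort(key=lambda e: (-e.gc_probability, e.document_id, e.sentence_index))
        counts: dict[Direction, int] = {}
        for ev in evs:
            counts[ev.direction] = counts.get(ev.direction, 0) + 1
        associations.append(
            RankedAssociation(
                gene_id=gene_id,
                cancer_name=cancer_name,
                ranking_score=sum(e.gc_probability for e in evs),
                evidence=evs,
                direction_counts=counts,
            )
        )
    associations.sort(key=lambda a: (-a.ranking_score, a.gene_id, a.cancer_name))
    return associations


def template_ablation(
    corpus,
    k: int = 10,
    seed: int = 0,
    top_k: int = 100,
    sample_positives: int = 60,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict:
    """Measure the contribution of template features to cross-validated
    precision/recall.

    Templates are induced from a seeded subsample of the corpus's positive
    sentences (the all-pairs alignment is quadratic), then k-fold CV is run
    with and without the TEMPLATE feature group; the report carries both
    fold reports and the mean deltas.
    """
    from .maxent import cross_validate
    from .templates import induce_templates

    rng_order = sorted(
        {
            (i.sentence.document_id, i.sentence.sentence_index, i.sentence.text): i.sentence
            for i in corpus.instances
            if i.label is Label.POSITIVE
        }.items()
    )
    positives = [s for _, s in rng_order][:sample_positives]
    templates = induce_templates(positives, top_k=top_k, seed=seed)
    labels = [i.label for i in corpus.instances]
    groups = [f"{i.sentence.document_id}:{i.sentence.sentence_index}" for i in corpus.instances]
    base_cfg = config.without("TEMPLATE")
    with_vecs = [featurize(i, templates, config=config) for i in corpus.instances]
    without_vecs = [featurize(i, config=base_cfg) for i in corpus.instances]
    with_report = cross_validate(
        with_vecs, labels, relation_kind=corpus.relation_kind, k=k, seed=seed, groups=groups
    )
    without_report = cross_validate(
        without_vecs, labels, relation_kind=corpus.relation_kind, k=k, seed=seed, groups=groups
    )
    return {
        "templates": templates,
        "with": with_report,
        "without": without_report,
        "delta_precision": with_report.mean_precision - without_report.mean_precision,
        "delta_recall": with_report.mean_recall - without_report.mean_recall,
    }


def _relation_key(inst: RelationInstance) -> tuple:
    return (
        inst.sentence.document_id,
        inst.sentence.sentence_index,
        inst.relation_kind.value,
        inst.gene.normalized_id or inst.gene.surface,
        inst.partner.normalized_id or inst.partner.surface.lower(),
    )


def evaluate_relations(
    gold: Iterable[RelationInstance], predicted: Iterable[RelationInstance]
) -> MatchResult:
    """Pair-level precision/recall: a predicted-POSITIVE pair is a true
    positive when the gold pair with the same sentence and normalized
    entities is POSITIVE.  Degenerate denominators report 0 with a flag."""
    gold_labels = { _relation_key(i): i.label for i in gold }
    tp = fp = 0
    seen = set()
    for inst in predicted:
        if inst.label is not Label.POSITIVE:
            continue
        key = _relation_key(inst)
        if key in seen:
            continue
        seen.add(key)
        if gold_labels.get(key) is Label.POSITIVE:
            tp += 1
        else:
            fp += 1
    n_gold_pos = sum(1 for lbl in gold_labels.values() if lbl is Label.POSITIVE)
    fn = n_gold_pos - tp
    return MatchResult(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        strategy=MatchStrategy.EXACT,
        undefined_precision=(tp + fp == 0),
        undefined_recall=(tp + fn == 0),
    )
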