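# methyltext

Gene methylation–cancer relation extraction from biomedical abstracts.

Aberrant DNA methylation — hyper- or hypomethylation of gene promoters —
is a candidate diagnostic and prognostic biomarker across human cancers,
and the evidence for which gene is methylated in which cancer is scattered
over thousands of abstracts. `methyltext` is a text-mining toolkit for
curators and epigenetics researchers that turns plain abstracts into a
ranked table of (gene, cancer) methylation associations with per-sentence
probabilistic evidence.

The pipeline:

1. **NER** — methylation terms via the pattern
   `(hyper|hypo)?(-)?(methylat.+)`; cancer names via a dictionary plus three
   patterns (case-sensitive acronyms, anatomical site + cancer keyword,
   `.+oma`/`leukemia` morphology); genes via dictionary lookup with
   orthographic variants (BRCA1 ↔ BRCA-1).
2. **Expansion** — a sentence with several candidate pairs is duplicated so
   each relation instance contains exactly one (gene, methylation) or
   (gene, cancer) pair.
3. **Classification** — two maximum-entropy (L2-regularized logistic)
   models: GM decides whether the gene is described as methylated; in
   sentences with a positive GM pair, GC decides whether that methylated
   gene is tied to the mentioned cancer. Features: inter-entity n-grams,
   surrounding words, chunk heads/types, a parse-path fallback, sentence
   position, and templates induced by token-level Smith–Waterman alignment
   (+1 match, −1 mismatch, −1 gap) of positive sentences.
4. **Ranking** — for each gene *G* and cancer *C* with evidence sentences
   s₁…sₙ:

       RankingScore(G, C) = Σᵢ P(positive | sᵢ)      (GC model probability)
       AvgMaxProb(G, C)   = RankingScore / n

   Associations are returned in descending score order with their evidence
   sentences, probabilities and hyper/hypo counts.

A synthetic-corpus generator produces gold-annotated abstracts with
controllable relational signal, so every stage is testable end to end
without any download. See `docs/methods.md` for the model details and what
synthetic results do and do not establish.

## Worked example

Train both models on a generated corpus that includes multi-gene list
sentences, then extract from a five-gene melanoma profiling sentence:

```python
from methyltext import (
    GeneratorConfig, generate_corpus, instance_groups, featurize,
    cross_validate, train, extract, rank, RelationKind, build_abstract,
)

gm, gc, _ = generate_corpus(GeneratorConfig(seed=1, multi_entity_rate=1.0))
vec_gm = [featurize(i) for i in gm.instances]
lab_gm = [i.label for i in gm.instances]
print("GM", cross_validate(vec_gm, lab_gm, k=10, seed=1,
                           groups=instance_groups(gm)).summary())

gm_model = train(vec_gm, lab_gm, relation_kind=RelationKind.GM)
gc_model = train([featurize(i) for i in gc.instances],
                 [i.label for i in gc.instances], relation_kind=RelationKind.GC)

sentence = ("SOCS1, SOCS2, RASSF1a, CDKN2a, and MGMT were methylated in "
            "75, 43, 64, 75, and 64% of melanoma samples, respectively")
evidence = extract([build_abstract("18632602", "", sentence)], gm_model, gc_model)
for assoc in rank(evidence):
    print(f"{assoc.gene_id:>6}  {assoc.cancer_name:<10} "
          f"score={assoc.ranking_score:.3f}  n={assoc.n_sentences}  "
          f"avg_max_p={assoc.average_max_probability:.3f}")
```

Output:

```
GM 10-fold CV: precision 99.9 ± 0.2 / recall 97.4 ± 1.1 %
  4255  melanoma   score=1.000  n=1  avg_max_p=1.000
 11186  melanoma   score=1.000  n=1  avg_max_p=1.000
  8835  melanoma   score=1.000  n=1  avg_max_p=1.000
  1029  melanoma   score=1.000  n=1  avg_max_p=1.000
  8651  melanoma   score=1.000  n=1  avg_max_p=1.000
```

The sentence expands into five single-pair GM instances; all five genes
(MGMT 4255, RASSF1 11186, SOCS2 8835, CDKN2A 1029, SOCS1 8651) are
classified as methylated and associated with melanoma, each backed by one
evidence sentence whose GC probability is the association's score.

The same workflow is available from the shell:

```bash
methyltext synth --seed 1 --out-dir work/
methyltext train work/gm.jsonl --model-out work/gm-model.json --cv
methyltext train work/gc.jsonl --model-out work/gc-model.json
methyltext induce work/gm.jsonl --out work/templates.tsv
methyltext extract work/abstracts.jsonl --gm-model work/gm-model.json \
    --gc-model work/gc-model.json --out work/evidence.jsonl
methyltext rank work/evidence.jsonl --out work/associations.tsv
```

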