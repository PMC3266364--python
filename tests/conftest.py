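"""Shared fixtures: the multi-gene worked-example sentence and
session-scoped synthetic corpora with their feature vectors."""

import pytest

from methyltext.corpus import sentence_from_text
from methyltext.features import featurize
from methyltext.ner import tag_all
from methyltext.synthetic import GeneratorConfig, generate_corpus, instance_groups

# A melanoma methylation-profiling sentence with five genes, one methylation
# term and one cancer mention: the canonical multi-pair expansion example.
S1_TEXT = (
    "SOCS1, SOCS2, RASSF1a, CDKN2a, and MGMT were methylated in "
    "75, 43, 64, 75, and 64% of melanoma samples, respectively"
)


@pytest.fixture
def s1_sentence():
    return tag_all(sentence_from_text(S1_TEXT))


@pytest.fixture(scope="session")
def default_corpora():
    """GM and GC corpora plus abstracts under the default study conditions
    (2,000 instances per corpus, 1,000 positive / 1,000 negative,
    signal strength 0.9)."""
    return generate_corpus(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def gm_training_data(default_corpora):
    gm, _, _ = default_corpora
    vectors = [featurize(i) for i in gm.instances]
    labels = [i.label for i in gm.instances]
    return vectors, labels, instance_groups(gm)


@pytest.fixture(scope="session")
def gc_training_data(default_corpora):
    _, gc, _ = default_corpora
    vectors = [featurize(i) for i in gc.instances]
    labels = [i.label for i in gc.instances]
    return vectors, labels, instance_groups(gc)
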