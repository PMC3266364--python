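"""Slot substitution, Smith-Waterman local alignment (with an exhaustive
independent oracle), template induction and matching."""

from itertools import combinations, product

import pytest
from hypothesis import given, settings, strategies as st

from methyltext.corpus import sentence_from_text
from methyltext.ner import tag_all
from methyltext.templates import (
    GAP,
    Template,
    agreement_tokens,
    induce_templates,
    local_align,
    match_template,
    read_templates,
    slotify,
    write_templates,
)


def brute_force_local_score(a, b):
    """Independent oracle: enumerate every gapped local alignment as a pair
    of equal-length increasing index tuples; +1 per matching aligned pair,
    −1 per mismatching pair, −1 per skipped internal position (gap).  The
    empty alignment scores 0."""
    best = 0
    for k in range(1, min(len(a), len(b)) + 1):
        for ii in combinations(range(len(a)), k):
            for jj in combinations(range(len(b)), k):
                s = sum(1 if a[i] == b[j] else -1 for i, j in zip(ii, jj))
                s -= sum(
                    (ii[t + 1] - ii[t] - 1) + (jj[t + 1] - jj[t] - 1) for t in range(k - 1)
                )
                best = max(best, s)
    return best


class TestSlotify:
    def test_s1_substitution(self, s1_sentence):
        assert " ".join(slotify(s1_sentence)) == (
            "<gene> , <gene> , <gene> , <gene> , and <gene> were <methylation> in "
            "75 , 43 , 64 , 75 , and 64 % of <cancer> samples , respectively"
        )

    def test_sentence_without_entities_unchanged(self):
        sent = sentence_from_text("No entities appear here")
        assert slotify(sent) == ["no", "entities", "appear", "here"]

    def test_idempotent(self, s1_sentence):
        once = slotify(s1_sentence)
        again = slotify(sentence_from_text(" ".join(once)))
        assert again == once

    def test_multiword_entity_collapses_to_one_slot(self):
        sent = tag_all(sentence_from_text("methylation in breast cancer tissue"))
        assert slotify(sent) == ["<methylation>", "in", "<cancer>", "tissue"]


class TestLocalAlign:
    def test_identical_sequences_score_length(self):
        a = "the <gene> promoter was <methylation>".split()
        res = local_align(a, a)
        assert res.score == len(a)
        assert res.region_a == (0, len(a))

    def test_disjoint_vocabularies_score_zero(self):
        res = local_align("a b c".split(), "x y z".split())
        assert res.score == 0
        assert res.aligned_pairs == ()

    def test_five_token_example(self):
        a = "x <gene> promoter <methylation> y".split()
        b = "z <gene> promoter <methylation> w".split()
        res = local_align(a, b)
        assert res.score == 3
        assert res.score == brute_force_local_score(a, b)
        assert agreement_tokens(a, b, res) == ["<gene>", "promoter", "<methylation>"]

    def test_score_decomposition_invariant(self):
        a = "a b c d e".split()
        b = "a x c d".split()
        res = local_align(a, b)
        recomputed = 0
        for i, j in res.aligned_pairs:
            if i is GAP or j is GAP:
                recomputed -= 1
            elif a[i] == b[j]:
                recomputed += 1
            else:
                recomputed -= 1
        assert recomputed == res.score

    def test_exhaustive_oracle_small(self):
        """DP score equals the enumeration oracle on all sequence pairs of
        length ≤ 3 over a 2-symbol alphabet."""
        seqs = [list(p) for n in range(4) for p in product("ab", repeat=n)]
        for a in seqs:
            for b in seqs:
                assert local_align(a, b).score == brute_force_local_score(a, b), (a, b)

    @given(
        st.lists(st.sampled_from("abc"), max_size=6),
        st.lists(st.sampled_from("abc"), max_size=6),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_symmetry(self, a, b):
        assert local_align(a, b).score == local_align(b, a).score

    @given(
        st.lists(st.sampled_from("abc"), max_size=5),
        st.lists(st.sampled_from("abc"), max_size=5),
        st.lists(st.sampled_from("abc"), min_size=1, max_size=4),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_shared_suffix_never_decreases_score(self, a, b, suffix):
        base = local_align(a, b).score
        assert local_align(a + suffix, b + suffix).score >= base


def _tagged(text):
    return tag_all(sentence_from_text(text))


class TestInduceTemplates:
    def test_shared_promoter_pattern_induced(self):
        sents = [
            _tagged("aberrant MGMT promoter hypermethylation occurs in melanoma"),
            _tagged("aberrant BRCA1 promoter hypermethylation occurs in NPC"),
        ]
        templates = induce_templates(sents, top_k=10)
        joined = {" ".join(t.tokens) for t in templates}
        assert any("<gene> promoter <methylation>" in t for t in joined)

    def test_frequently_methylated_pattern_from_three_sentences(self):
        sents = [
            _tagged("MGMT is frequently methylated in melanoma"),
            _tagged("BRCA1 is frequently methylated in NPC"),
            _tagged("SOCS1 is frequently methylated in CRC"),
        ]
        templates = induce_templates(sents, top_k=3)
        assert "<gene> is frequently <methylation> in <cancer>" in {
            " ".join(t.tokens) for t in templates
        }

    def test_top_k_zero_is_empty(self):
        sents = [_tagged("MGMT is methylated"), _tagged("BRCA1 is methylated")]
        assert induce_templates(sents, top_k=0) == []

    def test_fewer_than_two_sentences_raises(self):
        with pytest.raises(ValueError):
            induce_templates([_tagged("MGMT is methylated")])

    def test_invariant_to_input_order(self):
        sents = [
            _tagged("MGMT is frequently methylated in melanoma"),
            _tagged("aberrant BRCA1 promoter hypermethylation occurs in NPC"),
            _tagged("SOCS1 is frequently methylated in CRC"),
            _tagged("aberrant TP53 promoter hypermethylation occurs in melanoma"),
        ]
        forward = induce_templates(sents, top_k=10)
        backward = induce_templates(list(reversed(sents)), top_k=10)
        assert forward == backward

    def test_every_template_has_slot_and_min_length(self, default_corpora):
        gm, _, _ = default_corpora
        seen, positives = set(), []
        for inst in gm.instances:
            key = (inst.sentence.document_id, inst.sentence.sentence_index)
            if inst.label.value == "POSITIVE" and key not in seen:
                seen.add(key)
                positives.append(inst.sentence)
        for t in induce_templates(positives[:40], top_k=50):
            assert len(t.tokens) >= 2
            assert any(tok.startswith("<") for tok in t.tokens)


class TestMatchTemplate:
    TEMPLATE = Template(tokens=("<gene>", "promoter", "<methylation>"), source_score=3)

    def test_contiguous_occurrence(self):
        assert match_template(
            self.TEMPLATE, ["the", "<gene>", "promoter", "<methylation>", "was", "studied"]
        )

    def test_gap_breaks_match(self):
        assert not match_template(self.TEMPLATE, ["<gene>", "<methylation>"])
        assert not match_template(
            self.TEMPLATE, ["<gene>", "region", "promoter", "<methylation>"]
        )

    def test_template_matches_its_source_sentence(self):
        sent = _tagged("aberrant MGMT promoter hypermethylation occurs in melanoma")
        (first, *_ ) = induce_templates([sent, _tagged(
            "aberrant BRCA1 promoter hypermethylation occurs in NPC")], top_k=5)
        assert match_template(first, sent)


class TestTemplateStore:
    def test_round_trip(self, tmp_path):
        templates = [
            Template(tokens=("<gene>", "promoter", "<methylation>"), source_score=7),
            Template(tokens=("<gene>", "is", "frequently", "<methylation>"), source_score=5),
        ]
        path = tmp_path / "templates.tsv"
        write_templates(templates, path)
        assert read_templates(path) == templates
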