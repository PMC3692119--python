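"""The ten ranking features against independent oracles."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import evirank as ev
from evirank.features import (DEFAULT_PENALTY, dep_path_length, detect_agents,
                              event_depth, mention_anchor, term_distances,
                              token_depths)
from conftest import random_tree_tokens


def _nx_graph(tokens):
    g = nx.Graph()
    g.add_nodes_from(t.index for t in tokens)
    g.add_edges_from((t.index, t.head) for t in tokens if t.head != -1)
    return g


# ---------------------------------------------------------------------------
# Dependency-path distance
# ---------------------------------------------------------------------------

class TestDepPathLength:
    def test_identity_is_zero(self):
        toks = random_tree_tokens(np.random.default_rng(0), 5)
        assert dep_path_length(toks, 3, 3) == 0

    def test_root_to_child_is_one(self):
        (toks,) = ev.parse_dependencies("1 a 0 root\n2 b 1 dep\n")
        assert dep_path_length(toks, 0, 1) == 1

    def test_out_of_range_raises(self):
        toks = random_tree_tokens(np.random.default_rng(0), 4)
        with pytest.raises(IndexError):
            dep_path_length(toks, 0, 9)

    def test_matches_bfs_oracle_on_random_trees(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            toks = random_tree_tokens(rng, 12)
            oracle = dict(nx.shortest_path_length(_nx_graph(toks)))
            for a, b in itertools.combinations(range(12), 2):
                assert dep_path_length(toks, a, b) == oracle[a][b]

    def test_is_a_metric_on_random_trees(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            toks = random_tree_tokens(rng, n)
            d = [[dep_path_length(toks, a, b) for b in range(n)]
                 for a in range(n)]
            for a, b, c in itertools.product(range(n), repeat=3):
                assert d[a][b] == d[b][a]
                assert d[a][c] <= d[a][b] + d[b][c]
                assert (d[a][b] == 0) == (a == b)

    def test_depth_equals_distance_from_root(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            toks = random_tree_tokens(rng, 10)
            depths = token_depths(toks)
            for i in range(10):
                assert depths[i] == dep_path_length(toks, 0, i)

    def test_geometry_invariant_under_index_relabeling(self):
        rng = np.random.default_rng(4)
        toks = random_tree_tokens(rng, 10)
        perm = rng.permutation(10)
        inv = np.argsort(perm)
        relabeled = [None] * 10
        for t in toks:
            relabeled[inv[t.index]] = ev.Token(
                index=int(inv[t.index]), surface=t.surface, lemma=t.lemma,
                head=-1 if t.head == -1 else int(inv[t.head]),
                deplabel=t.deplabel)
        for a, b in itertools.combinations(range(10), 2):
            assert dep_path_length(toks, a, b) == dep_path_length(
                relabeled, int(inv[a]), int(inv[b]))


# ---------------------------------------------------------------------------
# Term distances
# ---------------------------------------------------------------------------

class TestTermDistances:
    def test_worked_example_regulation_penalty(self, fixture_docs, lexicons):
        doc = fixture_docs[0]
        cand = next(c for c in ev.assemble_candidates(doc, lexicons)
                    if c.trigger.text == "down-regulation"
                    and c.gene.token_span == (4, 5))
        ge, er, ec = term_distances(cand, lexicons)
        assert er == DEFAULT_PENALTY  # no regulation-lexicon term present
        assert ge == 2 and ec == 4

    def test_trigger_that_is_its_own_comparison_anchor(self, lexicons):
        # trigger word doubles as the regulation term -> distance 0
        (toks,) = ev.parse_dependencies("1 G1 2 nsubj\n2 regulates 0 root\n")
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a", tokens=toks,
            mentions=[
                ev.Mention(kind="GENE", token_span=(0, 1), text="G1"),
                ev.Mention(kind="EVENT_TRIGGER", token_span=(1, 2),
                           text="regulates", event_type="regulation")])
        cand = ev.Candidate(sent, sent.mentions[0], sent.mentions[1], 0, 1)
        _, er, _ = term_distances(cand, lexicons)
        assert er == 0

    def test_distance_matches_tree_construction(self, lexicons):
        # chain: root showed -> f1 -> trigger -> f2 -> f3 -> GENE (3 edges)
        text = ("1 showed 0 root\n2 effect 1 dep\n3 expression 2 dep\n"
                "4 pathway 3 dep\n5 role 4 dep\n6 G1 5 dep\n7 cancer 3 dep\n"
                "8 . 1 punct\n")
        (toks,) = ev.parse_dependencies(text)
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a", tokens=toks,
            mentions=[
                ev.Mention(kind="GENE", token_span=(5, 6), text="G1"),
                ev.Mention(kind="EVENT_TRIGGER", token_span=(2, 3),
                           text="expression", event_type="gene expression")])
        cand = ev.Candidate(sent, sent.mentions[0], sent.mentions[1], 0, 1)
        ge, er, ec = term_distances(cand, lexicons)
        assert (ge, er, ec) == (3, DEFAULT_PENALTY, 1)

    def test_multitoken_mention_uses_span_head_anchor(self):
        # "protein levels": head token of the span is "levels"
        (toks,) = ev.parse_dependencies(
            "1 reduced 0 root\n2 protein 3 nn\n3 levels 1 dobj\n")
        assert mention_anchor(toks, (1, 3)) == 2


# ---------------------------------------------------------------------------
# Score normalisation
# ---------------------------------------------------------------------------

class TestNormalizeScores:
    def test_minmax_endpoints(self):
        assert ev.normalize_scores([2.0, -1.0, 0.5]) == [1.0, 0.0, 0.5]

    def test_constant_batch_maps_to_half(self):
        assert ev.normalize_scores([3.3]) == [0.5]
        assert ev.normalize_scores([1.1, 1.1]) == [0.5, 0.5]

    def test_missing_score_maps_to_zero(self):
        assert ev.normalize_scores([None, 4.0, 2.0]) == [0.0, 1.0, 0.0]

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=50))
    def test_bounded_order_preserving_idempotent(self, batch):
        out = ev.normalize_scores(batch)
        assert all(0.0 <= x <= 1.0 for x in out)
        for (a, oa), (b, ob) in itertools.combinations(zip(batch, out), 2):
            if a < b:
                assert oa <= ob
        again = ev.normalize_scores(out)
        if max(batch) > min(batch):
            assert np.allclose(again, out, atol=1e-12)


# ---------------------------------------------------------------------------
# Keyword counting and cues
# ---------------------------------------------------------------------------

class TestKeywordFeatures:
    def test_worked_example_counts(self, fixture_docs, lexicons):
        s1 = fixture_docs[0].sentences[0]
        assert ev.keyword_count(s1, lexicons.cancer_terms) == 1
        assert ev.keyword_count(s1, lexicons.hallmark_terms) == 2

    def test_empty_sentence_counts_zero(self, lexicons):
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a",
            tokens=[ev.Token(0, "x", "x", -1, "root")])
        assert ev.keyword_count(sent, lexicons.cancer_terms) == 0

    def test_purpose_statement_has_cue(self, fixture_docs, lexicons):
        s2 = fixture_docs[1].sentences[0]
        assert ev.negative_cue_score(s2, lexicons) >= 1

    def test_positive_example_has_no_cue(self, fixture_docs, lexicons):
        s1 = fixture_docs[0].sentences[0]
        assert ev.negative_cue_score(s1, lexicons) == 0

    def test_every_occurrence_counts(self, lexicons):
        words = ["this", "was", "not", "not", "observed"]
        toks = [ev.Token(i, w, w, -1 if i == 0 else 0, "dep")
                for i, w in enumerate(words)]
        sent = ev.AnnotatedSentence(sentence_id="s", abstract_id="a",
                                    tokens=toks)
        assert ev.negative_cue_score(sent, lexicons) == 2


# ---------------------------------------------------------------------------
# Event depth and agents
# ---------------------------------------------------------------------------

class TestEventDepth:
    def test_trigger_at_root_is_zero(self):
        (toks,) = ev.parse_dependencies("1 expression 0 root\n2 G1 1 dep\n")
        trig = ev.Mention(kind="EVENT_TRIGGER", token_span=(0, 1),
                          text="expression", event_type="gene expression")
        assert event_depth(toks, trig) == 0

    def test_worked_example_depth_two(self, fixture_docs):
        s1 = fixture_docs[0].sentences[0]
        trig = next(m for m in s1.triggers if m.text == "down-regulation")
        assert event_depth(s1.tokens, trig) == 2


class TestDetectAgents:
    def test_worked_example_sox9_is_agent_of_reduced(self, fixture_docs,
                                                     lexicons):
        doc = fixture_docs[0]
        cand = next(c for c in ev.assemble_candidates(doc, lexicons)
                    if c.trigger.text == "reduced" and c.gene.text == "AR"
                    and c.gene.token_span == (13, 14))
        assert {m.text for m in detect_agents(cand)} == {"SOX9"}

    def test_single_gene_has_no_agent(self, lexicons):
        (toks,) = ev.parse_dependencies(
            "1 expression 0 root\n2 G1 1 dep\n3 cancer 1 dep\n")
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a", tokens=toks,
            mentions=[ev.Mention(kind="GENE", token_span=(1, 2), text="G1"),
                      ev.Mention(kind="EVENT_TRIGGER", token_span=(0, 1),
                                 text="expression",
                                 event_type="gene expression")])
        cand = ev.Candidate(sent, sent.mentions[0], sent.mentions[1], 0, 1)
        assert detect_agents(cand) == []

    def test_gene_below_query_gene_is_not_agent(self):
        # trigger -> G1 (query) -> G2: same branch, no agent
        (toks,) = ev.parse_dependencies(
            "1 expression 0 root\n2 G1 1 dep\n3 G2 2 dep\n")
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a", tokens=toks,
            mentions=[ev.Mention(kind="GENE", token_span=(1, 2), text="G1"),
                      ev.Mention(kind="GENE", token_span=(2, 3), text="G2"),
                      ev.Mention(kind="EVENT_TRIGGER", token_span=(0, 1),
                                 text="expression",
                                 event_type="gene expression")])
        cand = ev.Candidate(sent, sent.mentions[0], sent.mentions[2], 0, 2)
        assert detect_agents(cand) == []

    def test_gene_in_other_branch_is_agent(self):
        (toks,) = ev.parse_dependencies(
            "1 expression 0 root\n2 G1 1 dep\n3 G2 1 dep\n")
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a", tokens=toks,
            mentions=[ev.Mention(kind="GENE", token_span=(1, 2), text="G1"),
                      ev.Mention(kind="GENE", token_span=(2, 3), text="G2"),
                      ev.Mention(kind="EVENT_TRIGGER", token_span=(0, 1),
                                 text="expression",
                                 event_type="gene expression")])
        cand = ev.Candidate(sent, sent.mentions[0], sent.mentions[2], 0, 2)
        assert [m.text for m in detect_agents(cand)] == ["G2"]


# ---------------------------------------------------------------------------
# Full vector assembly
# ---------------------------------------------------------------------------

class TestExtractFeatureVector:
    def test_worked_example_vector(self, fixture_docs, lexicons):
        doc = fixture_docs[0]
        cands = ev.assemble_candidates(doc, lexicons)
        vectors = ev.extract_features(cands, lexicons)
        fv = next(v for v, c in zip(vectors, cands)
                  if c.trigger.text == "down-regulation"
                  and c.gene.token_span == (4, 5))
        assert fv.cancer_count == 1
        assert fv.hallmark_count == 2
        assert fv.event_depth == 2
        assert fv.event_regulation_dist == DEFAULT_PENALTY
        assert fv.label == "POSITIVE"

    def test_extraction_is_deterministic(self, fixture_docs, lexicons):
        doc = fixture_docs[0]
        cands = ev.assemble_candidates(doc, lexicons)
        v1 = ev.extract_features(cands, lexicons)
        v2 = ev.extract_features(cands, lexicons)
        assert [a.values() for a in v1] == [b.values() for b in v2]

    def test_minimal_chain_sentence(self, lexicons):
        (toks,) = ev.parse_dependencies(
            "1 G1 2 nsubj\n2 expression 0 root\n3 cancer 2 dep\n")
        sent = ev.AnnotatedSentence(
            sentence_id="s", abstract_id="a", tokens=toks,
            mentions=[ev.Mention(kind="GENE", token_span=(0, 1), text="G1"),
                      ev.Mention(kind="EVENT_TRIGGER", token_span=(1, 2),
                                 text="expression",
                                 event_type="gene expression",
                                 trigger_score=1.0, edge_scores={0: 0.5})])
        doc = ev.AbstractDoc("a", [sent])
        (fv,) = ev.extract_features(ev.assemble_candidates(doc, lexicons),
                                    lexicons)
        assert fv.gene_event_dist == 1
        assert fv.event_cancer_dist == 1
        assert fv.cancer_count == 1
        assert fv.hallmark_count == 0
        assert fv.event_depth == 0
        assert not fv.agent_present

    def test_feature_frame_has_named_columns(self, paper_corpus):
        frame = ev.feature_frame(paper_corpus[2][:10])
        for name in ev.FEATURE_NAMES:
            assert name in frame.columns
        assert len(frame) == 10
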