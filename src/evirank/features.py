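"""The ten linguistically motivated ranking features.

For each candidate (sentence, gene mention, event trigger) pair the
extractor computes:

==================== =======================================================
norm_event_score     trigger-classifier confidence, min-max normalised
                     within the scoring batch
norm_edge_score      trigger->gene edge-classifier confidence, normalised
                     the same way
gene_event_dist      dependency-path edges between gene and trigger
event_regulation_dist trigger to nearest regulation-lexicon term, or penalty
event_cancer_dist    trigger to nearest in-sentence cancer term, or penalty
cancer_count         occurrences of cancer lexicon terms in the sentence
hallmark_count       occurrences of the six hallmark keywords
event_depth          edges from the tree root down to the trigger
negative_score       occurrences of purpose/negation cues
agent_present        a gene other than the query gene sits in another
                     branch under the trigger (gene--gene statement signal)
==================== =======================================================

Distances are measured on the undirected dependency tree between mention
*anchor* tokens (the token of a span whose head lies outside the span).
A term missing from the sentence yields a configurable penalty constant
whose magnitude only matters as "absent" downstream.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .corpus import (GENE, REGULATION_TERM, ROOT, Candidate, Lexicons,
                     Mention, AnnotatedSentence, Token, match_terms)

DEFAULT_PENALTY = 10

FEATURE_NAMES = (
    "norm_event_score",
    "norm_edge_score",
    "gene_event_dist",
    "event_regulation_dist",
    "event_cancer_dist",
    "cancer_count",
    "hallmark_count",
    "event_depth",
    "negative_score",
    "agent_present",
)

#: Features taking the penalty constant when a term is absent.
DISTANCE_FEATURES = ("gene_event_dist", "event_regulation_dist",
                     "event_cancer_dist")


@dataclass
class FeatureVector:
    """The ten feature values for one (sentence, query) pair, plus the
    identifiers needed to trace it back."""

    sentence_id: str
    abstract_id: str
    gene_id: Optional[str]
    gene_text: str
    event_type: str
    norm_event_score: float
    norm_edge_score: float
    gene_event_dist: float
    event_regulation_dist: float
    event_cancer_dist: float
    cancer_count: int
    hallmark_count: int
    event_depth: int
    negative_score: int
    agent_present: bool
    label: Optional[str] = None

    def values(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Tree geometry
# ---------------------------------------------------------------------------

def _adjacency(tokens: Sequence[Token]) -> list[list[int]]:
    adj: list[list[int]] = [[] for _ in tokens]
    for t in tokens:
        if t.head != ROOT:
            adj[t.index].append(t.head)
            adj[t.head].append(t.index)
    return adj


def dep_path_length(tokens: Sequence[Token], a: int, b: int) -> int:
    """Edges on the unique undirected path between tokens *a* and *b*."""
    n = len(tokens)
    if not (0 <= a < n and 0 <= b < n):
        raise IndexError(f"token index out of range: {a}, {b} (n={n})")
    if a == b:
        return 0
    adj = _adjacency(tokens)
    dist = {a: 0}
    queue = deque([a])
    while queue:
        cur = queue.popleft()
        for nxt in adj[cur]:
            if nxt not in dist:
                dist[nxt] = dist[cur] + 1
                if nxt == b:
                    return dist[nxt]
                queue.append(nxt)
    raise ValueError(f"tokens {a} and {b} are disconnected")  # pragma: no cover


def token_depths(tokens: Sequence[Token]) -> list[int]:
    depths = [-1] * len(tokens)

    def depth(i: int) -> int:
        if depths[i] >= 0:
            return depths[i]
        d = 0 if tokens[i].head == ROOT else depth(tokens[i].head) + 1
        depths[i] = d
        return d

    for t in tokens:
        depth(t.index)
    return depths


def mention_anchor(tokens: Sequence[Token], span: tuple[int, int]) -> int:
    """Representative token of a span: the span token whose head lies
    outside the span (shallowest, then leftmost, if several)."""
    inside = range(span[0], span[1])
    cands = [i for i in inside
             if tokens[i].head == ROOT or not span[0] <= tokens[i].head < span[1]]
    if not cands:  # span swallows its own subtree root chain; fall back
        cands = list(inside)
    depths = token_depths(tokens)
    return min(cands, key=lambda i: (depths[i], i))


def event_depth(tokens: Sequence[Token], trigger: Mention) -> int:
    """Depth of the event trigger's anchor token below the root."""
    return token_depths(tokens)[mention_anchor(tokens, trigger.token_span)]


# ---------------------------------------------------------------------------
# Lexical features
# ---------------------------------------------------------------------------

def keyword_count(sentence: AnnotatedSentence, term_set: Iterable[str]) -> int:
    """Occurrences of lexicon terms in the sentence (every occurrence
    counts, case-insensitive, multi-word terms matched longest-first)."""
    return len(match_terms(sentence.tokens, term_set))


def negative_cue_score(sentence: AnnotatedSentence, lexicons: Lexicons) -> int:
    """Occurrences of purpose/method phrases and negation words."""
    return keyword_count(sentence, lexicons.negative_cues)


def term_distances(candidate: Candidate, lexicons: Lexicons,
                   penalty: float = DEFAULT_PENALTY
                   ) -> tuple[float, float, float]:
    """(gene-event, event-regulation, event-cancer) dependency distances.

    Each is the minimum path length between the trigger anchor and any
    occurrence of the partner term in the sentence; the penalty constant
    stands in when the partner term does not occur.
    """
    sent, tokens = candidate.sentence, candidate.sentence.tokens
    t_anchor = mention_anchor(tokens, candidate.trigger.token_span)
    g_anchor = mention_anchor(tokens, candidate.gene.token_span)
    gene_event = float(dep_path_length(tokens, g_anchor, t_anchor))

    def min_dist(spans: list[tuple[int, int]]) -> float:
        if not spans:
            return float(penalty)
        return float(min(dep_path_length(tokens, mention_anchor(tokens, sp),
                                         t_anchor) for sp in spans))

    reg_spans = [(s, e) for s, e, _ in
                 match_terms(tokens, lexicons.regulation_terms)]
    reg_spans += [m.token_span for m in sent.mentions_of(REGULATION_TERM)]
    cancer_spans = [(s, e) for s, e, _ in
                    match_terms(tokens, lexicons.cancer_terms)]
    return gene_event, min_dist(reg_spans), min_dist(cancer_spans)


# ---------------------------------------------------------------------------
# Score normalisation
# ---------------------------------------------------------------------------

def normalize_scores(batch: Sequence[Optional[float]]) -> list[float]:
    """Min-max normalise raw classifier scores within a batch.

    Raw SVM margins can be negative, so plain division by the batch
    maximum is ill-defined; (x - min)/(max - min) is used instead.  A
    constant batch maps to 0.5 everywhere; a missing score maps to 0.
    """
    present = [x for x in batch if x is not None]
    if not present:
        return [0.0] * len(batch)
    lo, hi = min(present), max(present)
    if hi == lo:
        return [0.5 if x is not None else 0.0 for x in batch]
    return [(x - lo) / (hi - lo) if x is not None else 0.0 for x in batch]


class BatchContext:
    """Normalisation pool shared by all candidates of one scoring batch
    (one search result, one training corpus, ...)."""

    def __init__(self, candidates: Sequence[Candidate]):
        trig_raw = [c.trigger.trigger_score for c in candidates]
        edge_raw = [None if c.trigger.edge_scores is None
                    else c.trigger.edge_scores.get(c.gene_index)
                    for c in candidates]
        trig_norm = normalize_scores(trig_raw)
        edge_norm = normalize_scores(edge_raw)
        self._trig = {id(c): v for c, v in zip(candidates, trig_norm)}
        self._edge = {id(c): v for c, v in zip(candidates, edge_norm)}

    def event_score(self, candidate: Candidate) -> float:
        return self._trig[id(candidate)]

    def edge_score(self, candidate: Candidate) -> float:
        return self._edge[id(candidate)]


# ---------------------------------------------------------------------------
# Agent detection
# ---------------------------------------------------------------------------

def _path_to_root(tokens: Sequence[Token], i: int) -> list[int]:
    path = [i]
    while tokens[path[-1]].head != ROOT:
        path.append(tokens[path[-1]].head)
    return path


def detect_agents(candidate: Candidate) -> list[Mention]:
    """Agent genes: genes other than the query gene sitting in a different
    branch under the event trigger.

    The trigger anchor must be a proper ancestor of the query gene's
    anchor; any other gene whose anchor also lies under the trigger but
    reaches it through a different child subtree is an agent.  Agents
    signal gene--gene rather than gene--disease assertions.
    """
    sent, tokens = candidate.sentence, candidate.sentence.tokens
    t = mention_anchor(tokens, candidate.trigger.token_span)
    g = mention_anchor(tokens, candidate.gene.token_span)
    g_path = _path_to_root(tokens, g)
    if t == g or t not in g_path:
        return []
    g_branch = g_path[g_path.index(t) - 1]

    def same_gene(m: Mention) -> bool:
        if m.token_span == candidate.gene.token_span:
            return True
        if m.gene_id is not None and m.gene_id == candidate.gene.gene_id:
            return True
        return (m.gene_id is None and candidate.gene.gene_id is None
                and m.text.lower() == candidate.gene.text.lower())

    agents = []
    for m in sent.mentions_of(GENE):
        if same_gene(m):
            continue
        a = mention_anchor(tokens, m.token_span)
        a_path = _path_to_root(tokens, a)
        if a != t and t in a_path and a_path[a_path.index(t) - 1] != g_branch:
            agents.append(m)
    return agents


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def extract_feature_vector(candidate: Candidate, batch: BatchContext,
                           lexicons: Lexicons,
                           penalty: float = DEFAULT_PENALTY) -> FeatureVector:
    """Populate all ten features for one candidate."""
    sent = candidate.sentence
    ge, er, ec = term_distances(candidate, lexicons, penalty)
    return FeatureVector(
        sentence_id=sent.sentence_id,
        abstract_id=sent.abstract_id,
        gene_id=candidate.gene.gene_id,
        gene_text=candidate.gene.text,
        event_type=candidate.trigger.event_type or "",
        norm_event_score=batch.event_score(candidate),
        norm_edge_score=batch.edge_score(candidate),
        gene_event_dist=ge,
        event_regulation_dist=er,
        event_cancer_dist=ec,
        cancer_count=keyword_count(sent, lexicons.cancer_terms),
        hallmark_count=keyword_count(sent, lexicons.hallmark_terms),
        event_depth=event_depth(sent.tokens, candidate.trigger),
        negative_score=negative_cue_score(sent, lexicons),
        agent_present=bool(detect_agents(candidate)),
        label=sent.label,
    )


def extract_features(candidates: Sequence[Candidate], lexicons: Lexicons,
                     penalty: float = DEFAULT_PENALTY) -> list[FeatureVector]:
    """Extract vectors for a batch of candidates sharing one
    normalisation pool."""
    batch = BatchContext(candidates)
    return [extract_feature_vector(c, batch, lexicons, penalty)
            for c in candidates]


def feature_frame(vectors: Sequence[FeatureVector]) -> pd.DataFrame:
    """Tabulate vectors (ids + 10 named columns + label) for TSV export
    and for the evaluation module."""
    rows = []
    for v in vectors:
        row = {"sentence_id": v.sentence_id, "abstract_id": v.abstract_id,
               "gene_id": v.gene_id, "gene_text": v.gene_text,
               "event_type": v.event_type}
        row.update(v.values())
        row["label"] = v.label
        rows.append(row)
    return pd.DataFrame(rows)
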