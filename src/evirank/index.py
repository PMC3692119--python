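"""Miniature retrieval layer over scored evidence sentences.

Two inverted indexes mirror the production workflow: an evidence
sentence index keyed by (canonical cancer name, gene id, event type) and
an abstract index mapping each abstract to its candidates and maximum
sentence score.  Trigger pre-screening removes event keywords known to
be irrelevant for their event type and cytogenetic band notation
misread as localization.  Query results can be summarised as a gene
co-occurrence graph (nodes: genes with their best evidence score;
edges: shared abstracts).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

from .corpus import (EVENT_TRIGGER, EVENT_TYPES, AbstractDoc, Candidate,
                     Lexicons, Mention, QueryTriple, collect_cancer_terms)
from .ranker import RankedEvidence

#: Cytogenetic band notation, e.g. "17q21", "Xp11.2" — chromosomal
#: locations that the event extractor sometimes tags as localization.
CYTOBAND_RE = re.compile(
    r"^(?:[1-9]|1[0-9]|2[0-2]|[xy])[pq]\d+(?:\.\d+)?$", re.IGNORECASE)


def prescreen_triggers(mentions: Sequence[Mention],
                       blacklist: Mapping[str, set[str]]) -> list[Mention]:
    """Drop event triggers blacklisted for their event type, and
    localization triggers that are chromosomal band locations."""
    out = []
    for m in mentions:
        if m.kind == EVENT_TRIGGER:
            word = m.text.lower()
            if word in blacklist.get(m.event_type or "", ()):
                continue
            if m.event_type == "localization" and CYTOBAND_RE.match(m.text):
                continue
        out.append(m)
    return out


def prescreen_corpus(docs: Iterable[AbstractDoc], lexicons: Lexicons) -> None:
    """Apply trigger pre-screening to every sentence in place.

    Edge-score keys are re-indexed to the surviving mention list.
    """
    for doc in docs:
        for sent in doc.sentences:
            kept = prescreen_triggers(sent.mentions, lexicons.trigger_blacklist)
            remap = {id(m): i for i, m in enumerate(kept)}
            old_by_index = {i: m for i, m in enumerate(sent.mentions)}
            for m in kept:
                if m.edge_scores:
                    m.edge_scores = {
                        remap[id(old_by_index[k])]: v
                        for k, v in m.edge_scores.items()
                        if id(old_by_index[k]) in remap}
            sent.mentions = kept


@dataclass
class AbstractHit:
    abstract_id: str
    max_score: float
    best: RankedEvidence
    evidences: list[RankedEvidence]


@dataclass
class EvidenceIndex:
    """In-memory inverted indexes over a scored corpus."""

    sentence_index: dict[tuple[str, str, str], list[RankedEvidence]]
    abstract_index: dict[str, list[RankedEvidence]]
    abstract_max: dict[str, float]
    synonym_table: dict[str, str]
    sentences: dict[tuple[str, str], object]  # (abstract_id, sentence_id)

    def canonical(self, name: str) -> str:
        low = name.lower()
        return self.synonym_table.get(low, low)


def default_synonyms() -> dict[str, str]:
    """The tiny packaged demo synonym table."""
    from importlib import resources
    text = (resources.files("evirank.lexicons")
            / "cancer_synonyms.tsv").read_text("utf-8")
    return _parse_synonyms(text)


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Two-column TSV: synonym -> canonical cancer name, lowercased."""
    return _parse_synonyms(Path(path).read_text("utf-8"))


def _parse_synonyms(text: str) -> dict[str, str]:
    table: dict[str, str] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        syn, canon = line.split("\t")
        table[syn.strip().lower()] = canon.strip().lower()
    return table


def build_indexes(candidates: Sequence[Candidate],
                  evidences: Sequence[RankedEvidence],
                  docs: Sequence[AbstractDoc], lexicons: Lexicons,
                  synonym_table: Optional[Mapping[str, str]] = None
                  ) -> EvidenceIndex:
    """Index scored candidates under every (cancer key, gene, event type)
    combination they satisfy.

    ``candidates`` and ``evidences`` must be aligned (the ranker's output
    order).  Each abstract contributes its matched cancer terms, mapped
    through the synonym table to canonical keys.
    """
    synonym_table = dict(synonym_table or {})
    seen_sentences: dict[str, str] = {}
    sentences: dict[tuple[str, str], object] = {}
    doc_by_id = {}
    for doc in docs:
        doc_by_id[doc.abstract_id] = doc
        for sent in doc.sentences:
            if sent.sentence_id in seen_sentences \
                    and seen_sentences[sent.sentence_id] != doc.abstract_id:
                raise ValueError(
                    f"sentence id {sent.sentence_id!r} appears in multiple "
                    f"abstracts")
            seen_sentences[sent.sentence_id] = doc.abstract_id
            sentences[(doc.abstract_id, sent.sentence_id)] = sent

    extra = set(synonym_table) | set(synonym_table.values())
    cancer_keys: dict[str, set[str]] = {}
    for doc in docs:
        terms = collect_cancer_terms(doc, lexicons, extra_terms=extra)
        cancer_keys[doc.abstract_id] = {synonym_table.get(t, t) for t in terms}

    sentence_index: dict[tuple[str, str, str], list[RankedEvidence]] = {}
    abstract_index: dict[str, list[RankedEvidence]] = {}
    abstract_max: dict[str, float] = {}
    for cand, ev in zip(candidates, evidences):
        abstract_index.setdefault(ev.abstract_id, []).append(ev)
        cur = abstract_max.get(ev.abstract_id)
        if cur is None or ev.score > cur:
            abstract_max[ev.abstract_id] = ev.score
        for key in sorted(cancer_keys.get(ev.abstract_id, ())):
            sentence_index.setdefault(
                (key, ev.gene_id or "", ev.event_type), []).append(ev)
    return EvidenceIndex(sentence_index=sentence_index,
                         abstract_index=abstract_index,
                         abstract_max=abstract_max,
                         synonym_table=synonym_table,
                         sentences=sentences)


def query(index: EvidenceIndex, q: QueryTriple) -> list[AbstractHit]:
    """Answer a (cancer, genes, event types) triple query.

    Empty gene set and empty event set act as wildcards.  Abstracts are
    returned sorted by their maximum matching sentence score (descending,
    ties by abstract id), each carrying its best sentence and the full
    matching evidence list.  An unknown cancer name yields an empty
    result.
    """
    keys = {index.canonical(q.cancer_name)}
    keys.update(index.canonical(s) for s in q.synonyms)
    events = set(q.event_types) or set(EVENT_TYPES)
    matched: dict[int, RankedEvidence] = {}
    for (ckey, gene, etype), evs in index.sentence_index.items():
        if ckey not in keys or etype not in events:
            continue
        if q.gene_ids and gene not in q.gene_ids:
            continue
        for ev in evs:
            matched[id(ev)] = ev
    by_abstract: dict[str, list[RankedEvidence]] = {}
    for ev in matched.values():
        by_abstract.setdefault(ev.abstract_id, []).append(ev)
    hits = []
    for aid, evs in by_abstract.items():
        evs.sort(key=lambda e: (-e.score, e.sentence_id, e.gene_id or ""))
        hits.append(AbstractHit(abstract_id=aid, max_score=evs[0].score,
                                best=evs[0], evidences=evs))
    hits.sort(key=lambda h: (-h.max_score, h.abstract_id))
    return hits


def group_by_gene(hits: Sequence[AbstractHit]
                  ) -> dict[str, list[RankedEvidence]]:
    out: dict[str, list[RankedEvidence]] = {}
    for h in hits:
        for ev in h.evidences:
            out.setdefault(ev.gene_id or ev.gene_text, []).append(ev)
    return out


def group_by_event(hits: Sequence[AbstractHit]
                   ) -> dict[str, list[RankedEvidence]]:
    out: dict[str, list[RankedEvidence]] = {}
    for h in hits:
        for ev in h.evidences:
            out.setdefault(ev.event_type, []).append(ev)
    return out


def cooccurrence_graph(hits: Sequence[AbstractHit], top_n: int) -> nx.Graph:
    """Gene co-occurrence graph over a query result.

    Nodes are the ``top_n`` genes by maximum evidence score (node
    attribute ``score``); an edge connects two genes sharing at least one
    abstract, annotated with the shared-abstract count and list.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    best: dict[str, float] = {}
    abstracts: dict[str, set[str]] = {}
    for h in hits:
        for ev in h.evidences:
            gid = ev.gene_id or ev.gene_text
            best[gid] = max(best.get(gid, float("-inf")), ev.score)
            abstracts.setdefault(gid, set()).add(ev.abstract_id)
    top = sorted(best, key=lambda g: (-best[g], g))[:top_n]
    graph = nx.Graph()
    for g in top:
        graph.add_node(g, score=best[g])
    for i, g1 in enumerate(top):
        for g2 in top[i + 1:]:
            shared = abstracts[g1] & abstracts[g2]
            if shared:
                graph.add_edge(g1, g2, count=len(shared),
                               abstracts=sorted(shared))
    return graph


def write_graph_edgelist(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene1\tgene2\tshared_abstracts\tabstract_ids\n")
        for g1, g2, data in sorted(graph.edges(data=True)):
            fh.write(f"{g1}\t{g2}\t{data['count']}\t"
                     f"{','.join(data['abstracts'])}\n")


def write_graph_graphml(graph: nx.Graph, path: str | Path) -> None:
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        data["abstracts"] = ",".join(data["abstracts"])
    nx.write_graphml(g, str(path))


# ---------------------------------------------------------------------------
# Persistence: plain sorted key-value files
# ---------------------------------------------------------------------------

def save_index(index: EvidenceIndex, directory: str | Path) -> None:
    """Persist the index as sorted plain-text key-value files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ev_key = lambda e: (e.abstract_id, e.sentence_id, e.gene_id or "",
                        e.event_type)
    evidences = sorted({ev_key(e): e for evs in index.abstract_index.values()
                        for e in evs}.values(), key=ev_key)
    ev_ids = {ev_key(e): i for i, e in enumerate(evidences)}
    with open(directory / "evidences.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tabstract_id\tsentence_id\tgene_id\tgene_text\t"
                 "event_type\tlog_lr\tscore\n")
        for i, e in enumerate(evidences):
            fh.write(f"{i}\t{e.abstract_id}\t{e.sentence_id}\t"
                     f"{e.gene_id or ''}\t{e.gene_text}\t{e.event_type}\t"
                     f"{e.log_lr!r}\t{e.score!r}\n")
    with open(directory / "sentence_index.tsv", "w", encoding="utf-8") as fh:
        fh.write("cancer_key\tgene_id\tevent_type\tevidence_ids\n")
        for key in sorted(index.sentence_index):
            ids = ",".join(str(ev_ids[ev_key(e)])
                           for e in index.sentence_index[key])
            fh.write(f"{key[0]}\t{key[1]}\t{key[2]}\t{ids}\n")
    with open(directory / "synonyms.tsv", "w", encoding="utf-8") as fh:
        for syn in sorted(index.synonym_table):
            fh.write(f"{syn}\t{index.synonym_table[syn]}\n")


def load_index(directory: str | Path) -> EvidenceIndex:
    directory = Path(directory)
    evidences: list[RankedEvidence] = []
    lines = (directory / "evidences.tsv").read_text("utf-8").splitlines()[1:]
    for line in lines:
        (_, aid, sid, gid, gtext, etype, llr, score) = line.split("\t")
        evidences.append(RankedEvidence(
            sentence_id=sid, abstract_id=aid, gene_id=gid or None,
            gene_text=gtext, event_type=etype, log_lr=float(llr),
            score=float(score)))
    sentence_index: dict[tuple[str, str, str], list[RankedEvidence]] = {}
    lines = (directory / "sentence_index.tsv").read_text(
        "utf-8").splitlines()[1:]
    for line in lines:
        ckey, gid, etype, ids = line.split("\t")
        sentence_index[(ckey, gid, etype)] = [
            evidences[int(i)] for i in ids.split(",")]
    abstract_index: dict[str, list[RankedEvidence]] = {}
    abstract_max: dict[str, float] = {}
    for e in evidences:
        abstract_index.setdefault(e.abstract_id, []).append(e)
        cur = abstract_max.get(e.abstract_id)
        if cur is None or e.score > cur:
            abstract_max[e.abstract_id] = e.score
    synonyms: dict[str, str] = {}
    syn_path = directory / "synonyms.tsv"
    if syn_path.exists():
        synonyms = load_synonyms(syn_path)
    return EvidenceIndex(sentence_index=sentence_index,
                         abstract_index=abstract_index,
                         abstract_max=abstract_max, synonym_table=synonyms,
                         sentences={})
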