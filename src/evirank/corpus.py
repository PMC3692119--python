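"""Domain types and readers for annotated candidate evidence sentences.

The unit of analysis is a sentence pre-annotated with gene mentions,
biological-event triggers (with classifier confidence scores), cancer
mentions and a dependency parse.  A *candidate evidence sentence* is a
sentence containing at least one gene and one event trigger, in an
abstract that mentions a cancer term somewhere.  Candidates are scored
per (gene mention, event trigger) pair downstream.

Readers cover BioNLP-shared-task-style standoff annotation (``.a1``
entity lines, ``.a2`` event lines), CoNLL-X/CoNLL-U dependency columns,
the package's own JSON-lines document format (one abstract per line) and
a two-column gold-label TSV.  No NER, parsing or event extraction happens
here: annotations are inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from importlib import resources

ROOT = -1
"""Head sentinel for the unique root token of a dependency tree."""

GENE = "GENE"
EVENT_TRIGGER = "EVENT_TRIGGER"
CANCER = "CANCER"
REGULATION_TERM = "REGULATION_TERM"
MENTION_KINDS = (GENE, EVENT_TRIGGER, CANCER, REGULATION_TERM)

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"
LABELS = (POSITIVE, NEGATIVE)

#: The seven event types served by the ranker.  Positive and negative
#: regulation are folded into plain "regulation" because event polarity
#: does not determine the polarity of the gene-disease relation.
EVENT_TYPES = (
    "binding",
    "gene expression",
    "localization",
    "phosphorylation",
    "protein catabolism",
    "regulation",
    "transcription",
)

#: Raw event-extractor output types (nine) -> served event type (seven).
TURKU_EVENT_MAP = {
    "Binding": "binding",
    "Gene_expression": "gene expression",
    "Localization": "localization",
    "Phosphorylation": "phosphorylation",
    "Protein_catabolism": "protein catabolism",
    "Regulation": "regulation",
    "Positive_regulation": "regulation",
    "Negative_regulation": "regulation",
    "Transcription": "transcription",
}

_ENTITY_KIND_MAP = {"Protein": GENE, "Gene": GENE,
                    "Cancer": CANCER, "Disease": CANCER,
                    "Regulation_term": REGULATION_TERM}


class AnnotationError(ValueError):
    """Malformed standoff annotation input."""


class InvalidTreeError(ValueError):
    """Dependency heads do not form a single-rooted tree."""


class LexiconError(OSError):
    """A lexicon file could not be read."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Token:
    """One token of a dependency-parsed sentence.

    ``head`` is the 0-based index of the governing token, or :data:`ROOT`
    for the single root token.  ``lemma`` is lowercase.
    """

    index: int
    surface: str
    lemma: str
    head: int
    deplabel: str = "dep"


@dataclass
class Mention:
    """A contiguous annotated span: gene, event trigger, cancer or
    regulation term.

    ``token_span`` is a half-open 0-based token interval.  Event triggers
    carry the merged ``event_type``, the raw trigger-classifier score and
    per-theme edge scores keyed by the gene mention's position in the
    sentence's mention list.
    """

    kind: str
    token_span: tuple[int, int]
    text: str
    gene_id: Optional[str] = None
    event_type: Optional[str] = None
    trigger_score: Optional[float] = None
    edge_scores: Optional[dict[int, float]] = None

    def __post_init__(self) -> None:
        if self.kind not in MENTION_KINDS:
            raise AnnotationError(f"unknown mention kind {self.kind!r}")
        if (self.event_type is not None) != (self.kind == EVENT_TRIGGER):
            raise AnnotationError(
                "event_type must be present exactly for EVENT_TRIGGER mentions")
        if self.token_span[0] >= self.token_span[1]:
            raise AnnotationError(f"empty token span {self.token_span}")


@dataclass
class AnnotatedSentence:
    sentence_id: str
    abstract_id: str
    tokens: list[Token]
    mentions: list[Mention] = field(default_factory=list)
    label: Optional[str] = None
    text: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.tokens)
        for m in self.mentions:
            if not (0 <= m.token_span[0] < m.token_span[1] <= n):
                raise AnnotationError(
                    f"mention span {m.token_span} outside sentence of {n} tokens")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    def mentions_of(self, kind: str) -> list[Mention]:
        return [m for m in self.mentions if m.kind == kind]

    @property
    def genes(self) -> list[Mention]:
        return self.mentions_of(GENE)

    @property
    def triggers(self) -> list[Mention]:
        return self.mentions_of(EVENT_TRIGGER)

    def raw_text(self) -> str:
        return self.text if self.text is not None else " ".join(
            t.surface for t in self.tokens)


@dataclass
class AbstractDoc:
    abstract_id: str
    sentences: list[AnnotatedSentence]
    abstract_cancer_terms: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        ids = [s.sentence_id for s in self.sentences]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sentence ids in abstract {self.abstract_id}")


@dataclass
class Lexicons:
    """Hand-curated term sets driving the lexical features.

    All entries are lowercase.  ``trigger_blacklist`` maps an event type
    to trigger words known to be irrelevant for it (pre-screening).
    """

    cancer_terms: set[str]
    hallmark_terms: set[str]
    negative_cues: set[str]
    regulation_terms: set[str]
    subcellular_terms: set[str]
    trigger_blacklist: dict[str, set[str]]


@dataclass
class QueryTriple:
    """A (cancer, genes, event types) retrieval request.

    Empty ``gene_ids`` means all genes; empty ``event_types`` means all
    seven types.
    """

    cancer_name: str
    synonyms: set[str] = field(default_factory=set)
    gene_ids: set[str] = field(default_factory=set)
    event_types: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.cancer_name:
            raise ValueError("cancer_name must be nonempty")
        bad = set(self.event_types) - set(EVENT_TYPES)
        if bad:
            raise ValueError(f"unsupported event types {sorted(bad)}; "
                             f"allowed: {EVENT_TYPES}")


@dataclass(frozen=True)
class Candidate:
    """One scorable (sentence, gene mention, event trigger) triple."""

    sentence: AnnotatedSentence
    gene: Mention
    trigger: Mention
    gene_index: int
    trigger_index: int


# ---------------------------------------------------------------------------
# Dependency-tree handling
# ---------------------------------------------------------------------------

def validate_tree(tokens: Sequence[Token]) -> None:
    """Raise :class:`InvalidTreeError` unless heads form a single-rooted tree."""
    n = len(tokens)
    roots = [t.index for t in tokens if t.head == ROOT]
    if len(roots) != 1:
        raise InvalidTreeError(f"expected exactly one root, found {len(roots)}")
    for t in tokens:
        if t.head != ROOT and not 0 <= t.head < n:
            raise InvalidTreeError(f"token {t.index} head {t.head} out of range")
        if t.head == t.index:
            raise InvalidTreeError(f"token {t.index} is its own head")
    # cycle check: walk to root from every node
    for t in tokens:
        seen = set()
        cur = t.index
        while cur != ROOT:
            if cur in seen:
                raise InvalidTreeError(f"head cycle involving token {cur}")
            seen.add(cur)
            cur = tokens[cur].head


def parse_dependencies(conll_text: str) -> list[list[Token]]:
    """Parse CoNLL-style dependency columns into token lists.

    Accepts CoNLL-X/CoNLL-U rows (10+ columns: head in column 7, deprel
    in column 8) or a minimal 4-column ``id form head deprel`` format.
    Sentence blocks are separated by blank lines; 1-based heads are
    converted to 0-based with head 0 becoming the :data:`ROOT` sentinel.
    Every block is validated as a single-rooted acyclic tree.
    """
    sentences: list[list[Token]] = []
    block: list[Token] = []

    def flush() -> None:
        if block:
            validate_tree(block)
            sentences.append(list(block))
            block.clear()

    for lineno, line in enumerate(conll_text.splitlines(), 1):
        line = line.strip()
        if not line:
            flush()
            continue
        if line.startswith("#"):
            continue
        cols = line.split()
        if "-" in cols[0] or "." in cols[0]:  # CoNLL-U range / empty nodes
            continue
        try:
            if len(cols) >= 8:
                form, lemma, head, dep = cols[1], cols[2], cols[6], cols[7]
            elif len(cols) == 4:
                form, head, dep = cols[1], cols[2], cols[3]
                lemma = form.lower()
            else:
                raise ValueError(f"expected 4 or >=8 columns, got {len(cols)}")
            head_i = int(head)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from exc
        if lemma == "_":
            lemma = form.lower()
        idx = len(block)
        if head_i < 0 or head_i > 10**6:
            raise InvalidTreeError(f"line {lineno}: head index {head_i} out of range")
        block.append(Token(index=idx, surface=form, lemma=lemma.lower(),
                           head=ROOT if head_i == 0 else head_i - 1,
                           deplabel=dep))
    flush()
    return sentences


# ---------------------------------------------------------------------------
# Standoff annotation
# ---------------------------------------------------------------------------

def _token_char_offsets(sentence: AnnotatedSentence) -> list[tuple[int, int]]:
    text = sentence.raw_text()
    offsets = []
    cursor = 0
    for tok in sentence.tokens:
        pos = text.find(tok.surface, cursor)
        if pos < 0:
            raise AnnotationError(
                f"token {tok.surface!r} not found in sentence text")
        offsets.append((pos, pos + len(tok.surface)))
        cursor = pos + len(tok.surface)
    return offsets


def _char_to_token_span(sentence: AnnotatedSentence, start: int, end: int,
                        lineno: int) -> tuple[int, int]:
    text = sentence.raw_text()
    if not (0 <= start < end <= len(text)):
        raise AnnotationError(
            f"line {lineno}: offsets {start}..{end} outside sentence "
            f"of length {len(text)}")
    covered = [i for i, (s, e) in enumerate(_token_char_offsets(sentence))
               if s < end and e > start]
    if not covered:
        raise AnnotationError(
            f"line {lineno}: offsets {start}..{end} cover no token")
    return covered[0], covered[-1] + 1


def _parse_attrs(col: str) -> dict[str, str]:
    out = {}
    for item in col.split():
        if "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def parse_standoff(entity_lines: str, event_lines: str,
                   sentence: AnnotatedSentence) -> AnnotatedSentence:
    """Attach standoff entity/event annotations to a tokenised sentence.

    Entity (``T``) lines use the BioNLP-ST dialect with sentence-local,
    0-based, half-open character offsets::

        T1<TAB>Protein 34 38<TAB>SOX9[<TAB>key=value ...]

    Recognised entity types are ``Protein``/``Gene``, ``Cancer``/
    ``Disease``, ``Regulation_term`` and the nine raw event-extractor
    types (mapped through :func:`merge_event_types`).  Optional attribute
    columns carry ``gene_id=`` and ``trigger_score=``.  Event (``E``)
    lines bind a trigger to a theme gene with an optional edge score::

        E1<TAB>Negative_regulation:T2 Theme:T1[<TAB>edge_score=1.25]

    A mention covers every token its character span overlaps.
    """
    mentions: list[Mention] = []
    by_tid: dict[str, int] = {}
    for lineno, line in enumerate(entity_lines.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise AnnotationError(f"line {lineno}: expected tab-separated columns")
        tid = cols[0].strip()
        try:
            etype, start_s, end_s = cols[1].split()
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: bad span column: {exc}") from exc
        span = _char_to_token_span(sentence, start, end, lineno)
        text = cols[2] if len(cols) > 2 else sentence.raw_text()[start:end]
        attrs = _parse_attrs(cols[3]) if len(cols) > 3 else {}
        if etype in _ENTITY_KIND_MAP:
            m = Mention(kind=_ENTITY_KIND_MAP[etype], token_span=span, text=text,
                        gene_id=attrs.get("gene_id"))
        elif etype in TURKU_EVENT_MAP:
            score = attrs.get("trigger_score")
            m = Mention(kind=EVENT_TRIGGER, token_span=span, text=text,
                        event_type=merge_event_types(etype),
                        trigger_score=float(score) if score is not None else None,
                        edge_scores={})
        else:
            raise AnnotationError(
                f"line {lineno}: unknown annotation type {etype!r}; allowed "
                f"entities {sorted(_ENTITY_KIND_MAP)}, events "
                f"{sorted(TURKU_EVENT_MAP)}")
        by_tid[tid] = len(mentions)
        mentions.append(m)

    for lineno, line in enumerate(event_lines.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 2:
            raise AnnotationError(f"event line {lineno}: expected tab columns")
        parts = dict(p.split(":", 1) for p in cols[1].split() if ":" in p)
        attrs = _parse_attrs(cols[2]) if len(cols) > 2 else {}
        trig_tid = next((v for k, v in parts.items() if k in TURKU_EVENT_MAP), None)
        theme_tid = parts.get("Theme")
        if trig_tid is None or theme_tid is None:
            raise AnnotationError(
                f"event line {lineno}: need '<EventType>:Tx Theme:Ty'")
        try:
            trig_i, theme_i = by_tid[trig_tid], by_tid[theme_tid]
        except KeyError as exc:
            raise AnnotationError(
                f"event line {lineno}: unknown entity id {exc}") from exc
        trig = mentions[trig_i]
        if trig.kind != EVENT_TRIGGER:
            raise AnnotationError(
                f"event line {lineno}: {trig_tid} is not an event trigger")
        if mentions[theme_i].kind != GENE:
            raise AnnotationError(
                f"event line {lineno}: theme {theme_tid} is not a gene")
        if trig.edge_scores is None:
            trig.edge_scores = {}
        if "edge_score" in attrs:
            trig.edge_scores[theme_i] = float(attrs["edge_score"])
        else:
            trig.edge_scores.setdefault(theme_i, 0.0)
    return replace(sentence, mentions=mentions)


def merge_event_types(raw_type: str) -> str:
    """Map a raw nine-type event label onto the seven served types.

    Positive and negative regulation collapse to plain ``regulation``.
    Already-merged lowercase names pass through unchanged.
    """
    if raw_type in TURKU_EVENT_MAP:
        return TURKU_EVENT_MAP[raw_type]
    if raw_type in EVENT_TYPES:
        return raw_type
    raise ValueError(f"unknown event type {raw_type!r}; expected one of "
                     f"{sorted(TURKU_EVENT_MAP)} or {EVENT_TYPES}")


# ---------------------------------------------------------------------------
# Lexicons
# ---------------------------------------------------------------------------

_LEXICON_FILES = {
    "cancer_terms": "cancer_terms.txt",
    "hallmark_terms": "hallmark_terms.txt",
    "negative_cues": "negative_cues.txt",
    "regulation_terms": "regulation_terms.txt",
    "subcellular_terms": "subcellular_terms.txt",
}
_BLACKLIST_FILE = "trigger_blacklist.tsv"


def _read_term_file(text: str) -> set[str]:
    terms = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            terms.add(line)
    return terms


def _default_text(filename: str) -> str:
    return (resources.files("evirank.lexicons") / filename).read_text("utf-8")


def load_lexicons(config_paths: Optional[Mapping[str, str | Path]] = None
                  ) -> Lexicons:
    """Load the term lexicons, falling back to packaged defaults.

    ``config_paths`` may override any of ``cancer_terms``,
    ``hallmark_terms``, ``negative_cues``, ``regulation_terms``,
    ``subcellular_terms`` (one lowercase entry per line, ``#`` comments)
    and ``trigger_blacklist`` (TSV: event type, word).
    """
    config_paths = dict(config_paths or {})
    unknown = set(config_paths) - set(_LEXICON_FILES) - {"trigger_blacklist"}
    if unknown:
        raise ValueError(f"unknown lexicon names {sorted(unknown)}")
    fields: dict[str, set[str]] = {}
    for name, default_file in _LEXICON_FILES.items():
        if name in config_paths:
            path = Path(config_paths[name])
            try:
                text = path.read_text("utf-8")
            except OSError as exc:
                raise LexiconError(f"cannot read {name} lexicon at {path}: {exc}"
                                   ) from exc
        else:
            text = _default_text(default_file)
        fields[name] = _read_term_file(text)

    if "trigger_blacklist" in config_paths:
        path = Path(config_paths["trigger_blacklist"])
        try:
            bl_text = path.read_text("utf-8")
        except OSError as exc:
            raise LexiconError(
                f"cannot read trigger_blacklist at {path}: {exc}") from exc
    else:
        bl_text = _default_text(_BLACKLIST_FILE)
    blacklist: dict[str, set[str]] = {}
    for line in bl_text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        etype, word = line.split("\t")
        blacklist.setdefault(merge_event_types(etype.strip()), set()).add(
            word.strip().lower())
    return Lexicons(trigger_blacklist=blacklist, **fields)


def match_terms(tokens: Sequence[Token], terms: Iterable[str]
                ) -> list[tuple[int, int, str]]:
    """Find term occurrences over a token sequence.

    Multi-word terms match on consecutive lowercase surfaces, longest
    match first and non-overlapping; single-word terms match the lemma or
    the lowercase surface.  Returns ``(start, end, term)`` token spans.
    """
    singles = {t for t in terms if " " not in t}
    multis = sorted((t.split() for t in terms if " " in t),
                    key=len, reverse=True)
    low = [t.surface.lower() for t in tokens]
    lem = [t.lemma for t in tokens]
    hits: list[tuple[int, int, str]] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for words in multis:
            j = i + len(words)
            if j <= n and low[i:j] == words:
                hits.append((i, j, " ".join(words)))
                i = j
                matched = True
                break
        if matched:
            continue
        if lem[i] in singles or low[i] in singles:
            hits.append((i, i + 1, lem[i] if lem[i] in singles else low[i]))
        i += 1
    return hits


# ---------------------------------------------------------------------------
# Candidate assembly
# ---------------------------------------------------------------------------

def collect_cancer_terms(abstract: AbstractDoc, lexicons: Lexicons,
                         extra_terms: Iterable[str] = ()) -> set[str]:
    """All cancer lexicon / synonym terms matched anywhere in the abstract,
    plus texts of explicit CANCER mentions."""
    terms = set(lexicons.cancer_terms) | set(extra_terms)
    found: set[str] = set()
    for sent in abstract.sentences:
        found.update(t for _, _, t in match_terms(sent.tokens, terms))
        found.update(m.text.lower() for m in sent.mentions_of(CANCER))
    return found


def assemble_candidates(abstract: AbstractDoc, lexicons: Lexicons
                        ) -> list[Candidate]:
    """Enumerate scorable (gene, trigger) pairs of an abstract.

    A sentence yields candidates only if it has at least one gene and one
    event trigger and a cancer term occurs in the sentence or anywhere in
    the abstract.  Trigger pre-screening (blacklists, chromosomal-location
    filtering) is expected to have run beforehand.
    """
    if not abstract.abstract_cancer_terms:
        abstract.abstract_cancer_terms = collect_cancer_terms(abstract, lexicons)
    if not abstract.abstract_cancer_terms:
        return []
    out: list[Candidate] = []
    for sent in abstract.sentences:
        gene_ix = [i for i, m in enumerate(sent.mentions) if m.kind == GENE]
        trig_ix = [i for i, m in enumerate(sent.mentions)
                   if m.kind == EVENT_TRIGGER]
        for gi in gene_ix:
            for ti in trig_ix:
                out.append(Candidate(sentence=sent, gene=sent.mentions[gi],
                                     trigger=sent.mentions[ti],
                                     gene_index=gi, trigger_index=ti))
    return out


# ---------------------------------------------------------------------------
# Document format (JSON lines, one abstract per line) and gold TSV
# ---------------------------------------------------------------------------

def _mention_to_obj(m: Mention) -> dict:
    obj: dict = {"kind": m.kind, "span": list(m.token_span), "text": m.text}
    if m.gene_id is not None:
        obj["gene_id"] = m.gene_id
    if m.event_type is not None:
        obj["event_type"] = m.event_type
    if m.trigger_score is not None:
        obj["trigger_score"] = m.trigger_score
    if m.edge_scores:
        obj["edge_scores"] = {str(k): v for k, v in m.edge_scores.items()}
    return obj


def _mention_from_obj(obj: Mapping) -> Mention:
    return Mention(
        kind=obj["kind"], token_span=tuple(obj["span"]), text=obj["text"],
        gene_id=obj.get("gene_id"), event_type=obj.get("event_type"),
        trigger_score=obj.get("trigger_score"),
        edge_scores={int(k): v for k, v in obj["edge_scores"].items()}
        if "edge_scores" in obj else None)


def doc_to_obj(doc: AbstractDoc) -> dict:
    return {
        "abstract_id": doc.abstract_id,
        "cancer_terms": sorted(doc.abstract_cancer_terms),
        "sentences": [
            {
                "sentence_id": s.sentence_id,
                "text": s.text,
                "label": s.label,
                "tokens": [[t.surface, t.lemma, t.head, t.deplabel]
                           for t in s.tokens],
                "mentions": [_mention_to_obj(m) for m in s.mentions],
            }
            for s in doc.sentences
        ],
    }


def doc_from_obj(obj: Mapping) -> AbstractDoc:
    sentences = []
    for s in obj["sentences"]:
        tokens = [Token(index=i, surface=c[0], lemma=c[1], head=c[2],
                        deplabel=c[3]) for i, c in enumerate(s["tokens"])]
        validate_tree(tokens)
        sentences.append(AnnotatedSentence(
            sentence_id=s["sentence_id"], abstract_id=obj["abstract_id"],
            tokens=tokens, mentions=[_mention_from_obj(m) for m in s["mentions"]],
            label=s.get("label"), text=s.get("text")))
    return AbstractDoc(abstract_id=obj["abstract_id"], sentences=sentences,
                       abstract_cancer_terms=set(obj.get("cancer_terms", [])))


def write_docs(docs: Iterable[AbstractDoc], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc_to_obj(doc), sort_keys=True) + "\n")


def read_docs(path: str | Path) -> list[AbstractDoc]:
    docs = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(doc_from_obj(json.loads(line)))
    return docs


def write_gold(labels: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid in sorted(labels):
            fh.write(f"{sid}\t{labels[sid]}\n")


def read_gold(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, label = line.split("\t")
            if label not in LABELS:
                raise ValueError(f"line {lineno}: label must be in {LABELS}")
            out[sid] = label
    return out
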