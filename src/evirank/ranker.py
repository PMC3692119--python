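"""Likelihood-ratio ranking of candidate evidence sentences.

The classifier is a semi-naive Bayes model over the ten features.  With
equal class priors the posterior odds reduce to a likelihood ratio; its
log is a sum of per-feature log ratios

    log LR = sum_f log P(f | positive) / P(f | negative)

with two empirically chosen feature dependencies replacing the
corresponding marginals: the cancer keyword count is conditioned on the
event-cancer distance (a cancer keyword matters most when it does not
co-occur closely with the event), and agent presence is conditioned on
hallmark presence (an agent stops signalling a negative sentence when a
hallmark keyword appears).

Continuous features are discretised with equal-frequency quartile bins
fit on the pooled training data; zero values and the absent-term penalty
get dedicated bins so the penalty's magnitude never matters.  Tables are
add-alpha smoothed, so every probability is strictly positive and unseen
bins fall back to the smoothed floor.  The log ratio is mapped to a
(0, 1) relevance score by a sigmoid; localization candidates whose
sentence names no sub-cellular compartment are demoted by a
multiplicative factor, because the event extractor often tags mere
protein presence as localization while sub-cellular relocation is what
matters for gene-disease analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .corpus import (Candidate, Lexicons, AnnotatedSentence, NEGATIVE,
                     POSITIVE, match_terms)
from .features import (DEFAULT_PENALTY, DISTANCE_FEATURES, FEATURE_NAMES,
                       FeatureVector, extract_features)

MODEL_FORMAT_VERSION = 1

#: Features whose marginal is replaced by a conditional table when
#: dependencies are enabled.
DEPENDENT_FEATURES = ("cancer_count", "agent_present")

_ZERO_BIN = 0
_PENALTY_BIN = 1
_REGULAR_OFFSET = 2


class NotFittedError(RuntimeError):
    pass


@dataclass
class RankerConfig:
    smoothing_alpha: float = 1.0     # add-alpha pseudo-count per bin
    sigmoid_slope: float = 1.0       # slope of the log-LR -> score sigmoid
    localization_factor: float = 0.5 # demotion for localization w/o compartment
    penalty: float = DEFAULT_PENALTY # absent-term distance stand-in
    use_dependencies: bool = True    # two conditional tables vs plain naive
    near_distance_edges: int = 4     # event-cancer "near" threshold (edges)

    def __post_init__(self) -> None:
        if self.smoothing_alpha <= 0:
            raise ValueError("smoothing_alpha must be > 0")
        if self.sigmoid_slope <= 0:
            raise ValueError("sigmoid_slope must be > 0")
        if not 0 < self.localization_factor <= 1:
            raise ValueError("localization_factor must be in (0, 1]")


@dataclass
class FeatureBinner:
    """Discretiser for one feature.

    Bin codes: 0 = exact zero, 1 = penalty (distance features only),
    2.. = equal-frequency quartile bins of the remaining pooled values.
    """

    edges: np.ndarray            # inner cut points, possibly empty
    uses_penalty: bool
    penalty: float

    @property
    def n_bins(self) -> int:
        return _REGULAR_OFFSET + len(self.edges) + 1

    def code(self, value: float) -> int:
        if value == 0:
            return _ZERO_BIN
        if self.uses_penalty and value == self.penalty:
            return _PENALTY_BIN
        return _REGULAR_OFFSET + int(np.searchsorted(self.edges, value,
                                                     side="left"))

    @classmethod
    def fit(cls, values: np.ndarray, uses_penalty: bool,
            penalty: float) -> "FeatureBinner":
        regular = values[(values != 0)
                         & ~(uses_penalty & (values == penalty))]
        if regular.size:
            edges = np.unique(np.quantile(regular, [0.25, 0.5, 0.75]))
        else:
            edges = np.empty(0)
        return cls(edges=np.asarray(edges, dtype=float),
                   uses_penalty=uses_penalty, penalty=float(penalty))


def _boolean_binner() -> FeatureBinner:
    # codes: 0 (False, the zero bin) and 2 (True, single regular bin)
    return FeatureBinner(edges=np.empty(0), uses_penalty=False, penalty=0.0)


def _cancer_dist_group(value: float, config: RankerConfig) -> int:
    """3-way conditioning variable: 0 near, 1 far, 2 absent."""
    if value == config.penalty:
        return 2
    return 0 if value < config.near_distance_edges else 1


@dataclass
class ClassConditionalModel:
    """Fitted conditional probability tables of the ranker.

    ``tables[feature][class]`` holds the smoothed marginal P(bin | class)
    for all ten features; ``dep_cancer[class]`` holds
    P(cancer_count bin | event-cancer-distance group, class) and
    ``dep_agent[class]`` P(agent | hallmark present, class).
    """

    config: RankerConfig
    binners: dict[str, FeatureBinner]
    tables: dict[str, dict[str, np.ndarray]]
    dep_cancer: dict[str, np.ndarray]
    dep_agent: dict[str, np.ndarray]
    n_pos: int = 0
    n_neg: int = 0

    # -- persistence --------------------------------------------------------

    def to_obj(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "binners": {
                name: {"edges": b.edges.tolist(),
                       "uses_penalty": b.uses_penalty, "penalty": b.penalty}
                for name, b in self.binners.items()},
            "tables": {name: {c: t.tolist() for c, t in per.items()}
                       for name, per in self.tables.items()},
            "dep_cancer": {c: t.tolist() for c, t in self.dep_cancer.items()},
            "dep_agent": {c: t.tolist() for c, t in self.dep_agent.items()},
        }

    @classmethod
    def from_obj(cls, obj: dict) -> "ClassConditionalModel":
        if obj.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {obj.get('format_version')!r}")
        return cls(
            config=RankerConfig(**obj["config"]),
            binners={name: FeatureBinner(edges=np.asarray(b["edges"]),
                                         uses_penalty=b["uses_penalty"],
                                         penalty=b["penalty"])
                     for name, b in obj["binners"].items()},
            tables={name: {c: np.asarray(t) for c, t in per.items()}
                    for name, per in obj["tables"].items()},
            dep_cancer={c: np.asarray(t) for c, t in obj["dep_cancer"].items()},
            dep_agent={c: np.asarray(t) for c, t in obj["dep_agent"].items()},
            n_pos=obj["n_pos"], n_neg=obj["n_neg"])

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_obj(), sort_keys=True),
                              encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ClassConditionalModel":
        return cls.from_obj(json.loads(Path(path).read_text("utf-8")))


@dataclass(frozen=True)
class RankedEvidence:
    sentence_id: str
    abstract_id: str
    gene_id: Optional[str]
    gene_text: str
    event_type: str
    log_lr: float
    score: float


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _smoothed_dist(counts: np.ndarray, alpha: float) -> np.ndarray:
    counts = counts.astype(float) + alpha
    return counts / counts.sum()


def fit(vectors: Sequence[FeatureVector],
        config: Optional[RankerConfig] = None) -> ClassConditionalModel:
    """Fit the conditional tables from labeled feature vectors.

    Binners are fit on the pooled (both-class) data; tables are add-alpha
    smoothed per class.  Requires at least one example of each class.
    """
    config = config or RankerConfig()
    if not vectors:
        raise ValueError("cannot fit on an empty training set")
    labels = [v.label for v in vectors]
    if any(lb not in (POSITIVE, NEGATIVE) for lb in labels):
        raise ValueError("every training vector needs a POSITIVE/NEGATIVE label")
    n_pos = labels.count(POSITIVE)
    n_neg = labels.count(NEGATIVE)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both classes")

    cols = {name: np.array([v.values()[name] for v in vectors])
            for name in FEATURE_NAMES}
    binners: dict[str, FeatureBinner] = {}
    for name in FEATURE_NAMES:
        if name == "agent_present":
            binners[name] = _boolean_binner()
        else:
            binners[name] = FeatureBinner.fit(
                cols[name], uses_penalty=name in DISTANCE_FEATURES,
                penalty=config.penalty)

    masks = {POSITIVE: np.array([lb == POSITIVE for lb in labels]),
             NEGATIVE: np.array([lb == NEGATIVE for lb in labels])}
    tables: dict[str, dict[str, np.ndarray]] = {}
    codes = {name: np.array([binners[name].code(v) for v in cols[name]])
             for name in FEATURE_NAMES}
    for name in FEATURE_NAMES:
        nb = binners[name].n_bins
        tables[name] = {}
        for cls, mask in masks.items():
            counts = np.bincount(codes[name][mask], minlength=nb)
            tables[name][cls] = _smoothed_dist(counts, config.smoothing_alpha)

    # cancer_count | event-cancer-distance group
    cc_bins = binners["cancer_count"].n_bins
    groups = np.array([_cancer_dist_group(v, config)
                       for v in cols["event_cancer_dist"]])
    dep_cancer = {}
    for cls, mask in masks.items():
        table = np.empty((3, cc_bins))
        for g in range(3):
            sel = mask & (groups == g)
            counts = np.bincount(codes["cancer_count"][sel], minlength=cc_bins)
            table[g] = _smoothed_dist(counts, config.smoothing_alpha)
        dep_cancer[cls] = table

    # agent_present | hallmark present
    hp = (cols["hallmark_count"] > 0).astype(int)
    agent = (cols["agent_present"] > 0).astype(int)
    dep_agent = {}
    for cls, mask in masks.items():
        table = np.empty((2, 2))
        for h in (0, 1):
            sel = mask & (hp == h)
            counts = np.bincount(agent[sel], minlength=2)
            table[h] = _smoothed_dist(counts, config.smoothing_alpha)
        dep_agent[cls] = table

    return ClassConditionalModel(config=config, binners=binners, tables=tables,
                                 dep_cancer=dep_cancer, dep_agent=dep_agent,
                                 n_pos=n_pos, n_neg=n_neg)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def log_likelihood_ratio(model: ClassConditionalModel, fv: FeatureVector,
                         feature_subset: Optional[Sequence[str]] = None
                         ) -> float:
    """Sum of per-feature log P(bin|pos)/P(bin|neg) contributions.

    Equal priors contribute nothing.  With dependencies enabled the
    cancer-count and agent terms use their conditional tables; otherwise
    the model reduces to plain naive Bayes.  ``feature_subset`` restricts
    the sum to the named features (used by the ablation study); a
    dependent feature keeps its conditioning variable.
    """
    if not model.tables:
        raise NotFittedError("model has no fitted tables")
    names = FEATURE_NAMES if feature_subset is None else tuple(feature_subset)
    unknown = set(names) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    vals = fv.values()
    total = 0.0
    for name in names:
        if model.config.use_dependencies and name == "cancer_count":
            g = _cancer_dist_group(vals["event_cancer_dist"], model.config)
            code = model.binners[name].code(vals[name])
            p_pos = model.dep_cancer[POSITIVE][g, code]
            p_neg = model.dep_cancer[NEGATIVE][g, code]
        elif model.config.use_dependencies and name == "agent_present":
            h = int(vals["hallmark_count"] > 0)
            a = int(vals["agent_present"] > 0)
            p_pos = model.dep_agent[POSITIVE][h, a]
            p_neg = model.dep_agent[NEGATIVE][h, a]
        else:
            code = model.binners[name].code(vals[name])
            nb = model.binners[name].n_bins
            if code >= nb:  # out-of-range value at scoring time
                code = nb - 1
            p_pos = model.tables[name][POSITIVE][code]
            p_neg = model.tables[name][NEGATIVE][code]
        total += math.log(p_pos) - math.log(p_neg)
    return total


def sigmoid_score(log_lr: float, slope: float = 1.0) -> float:
    """Map a log likelihood ratio to (0, 1): 1/(1 + exp(-slope * log_lr))."""
    if slope <= 0:
        raise ValueError("slope must be > 0")
    return float(expit(slope * log_lr))


def sentence_has_subcellular_term(sentence: AnnotatedSentence,
                                  lexicons: Lexicons) -> bool:
    return bool(match_terms(sentence.tokens, lexicons.subcellular_terms))


def localization_adjust(evidence: RankedEvidence,
                        sentence: AnnotatedSentence, lexicons: Lexicons,
                        factor: float = 0.5) -> RankedEvidence:
    """Demote localization evidence lacking sub-cellular vocabulary.

    Applies only to localization candidates: if the sentence names no
    sub-cellular compartment the score is multiplied by ``factor``;
    everything else passes through unchanged.
    """
    if evidence.event_type != "localization":
        return evidence
    if sentence_has_subcellular_term(sentence, lexicons):
        return evidence
    return RankedEvidence(**{**asdict(evidence),
                             "score": evidence.score * factor})


def _tie_key(ev: RankedEvidence) -> tuple:
    return (-ev.score, ev.abstract_id, ev.sentence_id, ev.gene_id or "")


def score_candidates(model: ClassConditionalModel,
                     candidates: Sequence[Candidate], lexicons: Lexicons,
                     feature_subset: Optional[Sequence[str]] = None
                     ) -> list[RankedEvidence]:
    """Score candidates (shared normalisation batch), unranked."""
    vectors = extract_features(candidates, lexicons,
                               penalty=model.config.penalty)
    out = []
    for cand, fv in zip(candidates, vectors):
        llr = log_likelihood_ratio(model, fv, feature_subset)
        ev = RankedEvidence(sentence_id=fv.sentence_id,
                            abstract_id=fv.abstract_id, gene_id=fv.gene_id,
                            gene_text=fv.gene_text, event_type=fv.event_type,
                            log_lr=llr,
                            score=sigmoid_score(llr, model.config.sigmoid_slope))
        out.append(localization_adjust(ev, cand.sentence, lexicons,
                                       model.config.localization_factor))
    return out


def rank(model: ClassConditionalModel, candidates: Sequence[Candidate],
         lexicons: Lexicons
         ) -> tuple[list[RankedEvidence], dict[str, float]]:
    """Score, adjust and sort candidates.

    Returns the evidence list in stable descending score order (ties
    broken by abstract, sentence and gene ids) together with the
    per-abstract maximum score used to order abstracts in search results.
    """
    scored = score_candidates(model, candidates, lexicons)
    scored.sort(key=_tie_key)
    abstract_max: dict[str, float] = {}
    for ev in scored:
        cur = abstract_max.get(ev.abstract_id)
        if cur is None or ev.score > cur:
            abstract_max[ev.abstract_id] = ev.score
    return scored, abstract_max
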