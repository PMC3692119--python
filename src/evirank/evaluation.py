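"""Cross-validated evaluation of the evidence-sentence ranker.

The protocol: stratified k-fold cross-validation; for each candidate
cut-off the top-k ranked sentences of every fold are classified positive
and the rest negative; the cut-off maximising the fold-averaged
F-measure is reported together with the AUC of the ranking.  Cut-offs
are aligned across unequal-size folds as *fractions* of the fold size so
that "average F per cut-off" is well defined.  Baselines: a random-order
ranking (uniform scores, repeated and averaged) and an optional
bag-of-words linear SVM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .corpus import NEGATIVE, POSITIVE
from .features import FEATURE_NAMES, FeatureVector
from . import ranker as _ranker


@dataclass
class EvalReport:
    """Precision/recall/F at the selected cut-off plus AUC, all in
    percent, with the per-event breakdown and run provenance."""

    precision: float
    recall: float
    f_measure: float
    auc: float
    chosen_cutoff_fraction: float
    n_pos: int
    n_neg: int
    seed: int
    per_event: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_obj(self) -> dict:
        return asdict(self)


def _f_measure(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


# ---------------------------------------------------------------------------
# Primitive metrics
# ---------------------------------------------------------------------------

def stratified_folds(labels: Sequence[str], k: int, seed: int
                     ) -> list[np.ndarray]:
    """Deterministic stratified partition into k folds (test-index arrays)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.array([1 if lb == POSITIVE else 0 for lb in labels])
    if min(np.sum(y == 1), np.sum(y == 0)) < k:
        raise ValueError(f"need at least {k} examples of each class")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(y)), y)]


def prf_at_cutoff(ranked_labels: Sequence[bool], k: int
                  ) -> tuple[float, float, float]:
    """Precision, recall, F (percent) when the top-k ranked items are
    called positive."""
    n = len(ranked_labels)
    if not 1 <= k <= n:
        raise ValueError(f"cutoff k={k} outside 1..{n}")
    n_pos = sum(bool(x) for x in ranked_labels)
    tp = sum(bool(x) for x in ranked_labels[:k])
    p = 100.0 * tp / k
    r = 100.0 * tp / n_pos if n_pos else 0.0
    return p, r, _f_measure(p, r)


def best_cutoff_f(fold_rankings: Sequence[Sequence[bool]]
                  ) -> tuple[float, float, float, float]:
    """Sweep cut-off fractions, pick the one maximising fold-averaged F.

    For fraction c each fold of size n classifies its top round(c*n)
    items (at least 1) positive.  Returns (fraction, avg P, avg R, avg F);
    ties go to the smallest fraction.
    """
    sizes = [len(fr) for fr in fold_rankings]
    fractions = np.array(sorted({i / n for n in sizes
                                 for i in range(1, n + 1)}))
    p_mat, r_mat, f_mat = [], [], []
    for fr, n in zip(fold_rankings, sizes):
        arr = np.asarray(fr, dtype=bool)
        n_pos = int(arr.sum())
        tp = np.cumsum(arr)
        ks = np.clip(np.rint(fractions * n).astype(int), 1, n)
        p = 100.0 * tp[ks - 1] / ks
        r = (100.0 * tp[ks - 1] / n_pos) if n_pos else np.zeros_like(p)
        with np.errstate(invalid="ignore"):
            f = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
        p_mat.append(p)
        r_mat.append(r)
        f_mat.append(f)
    avg_p = np.mean(p_mat, axis=0)
    avg_r = np.mean(r_mat, axis=0)
    avg_f = np.mean(f_mat, axis=0)
    i = int(np.argmax(avg_f))  # first maximum -> smallest fraction on ties
    return float(fractions[i]), float(avg_p[i]), float(avg_r[i]), float(avg_f[i])


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-statistic (Mann-Whitney) AUC in percent; ties count 1/2."""
    y = np.array([bool(x) for x in labels])
    if y.all() or not y.any():
        raise ValueError("AUC needs both classes present")
    return 100.0 * float(roc_auc_score(y, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Random-order baseline
# ---------------------------------------------------------------------------

def random_order_baseline(n_pos: int, n_neg: int, reps: int = 100,
                          seed: int = 42) -> EvalReport:
    """Average performance of uniformly random rankings.

    Each repetition draws i.i.d. uniform scores for the fixed label
    composition, applies the same best-cut-off-F sweep and AUC as the
    real evaluation, and metrics are averaged across repetitions.
    Because random precision is flat at the positive ratio, the F-optimal
    cut-off sits near the bottom of the list, giving recall near 100%.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    labels = np.array([True] * n_pos + [False] * n_neg)
    ps, rs, fs, aucs, cuts = [], [], [], [], []
    for _ in range(reps):
        scores = rng.random(labels.size)
        order = np.argsort(-scores, kind="stable")
        ranked = labels[order]
        frac, p, r, f = best_cutoff_f([ranked])
        ps.append(p)
        rs.append(r)
        fs.append(f)
        cuts.append(frac)
        aucs.append(auc(scores, labels))
    avg_p, avg_r = float(np.mean(ps)), float(np.mean(rs))
    return EvalReport(precision=avg_p, recall=avg_r,
                      f_measure=_f_measure(avg_p, avg_r),
                      auc=float(np.mean(aucs)),
                      chosen_cutoff_fraction=float(np.mean(cuts)),
                      n_pos=n_pos, n_neg=n_neg, seed=seed)


# ---------------------------------------------------------------------------
# Cross-validated model evaluation
# ---------------------------------------------------------------------------

def _fold_ranking(model, test: Sequence[FeatureVector],
                  feature_subset: Optional[Sequence[str]]
                  ) -> tuple[list[bool], list[float]]:
    scored = []
    for i, fv in enumerate(test):
        llr = _ranker.log_likelihood_ratio(model, fv, feature_subset)
        scored.append((-llr, fv.abstract_id, fv.sentence_id, i, fv))
    scored.sort(key=lambda t: t[:4])
    ranked_labels = [t[4].label == POSITIVE for t in scored]
    scores = [_ranker.log_likelihood_ratio(model, fv, feature_subset)
              for fv in test]
    return ranked_labels, scores


def cross_validate(vectors: Sequence[FeatureVector], k: int = 5,
                   seed: int = 42,
                   config: Optional[_ranker.RankerConfig] = None,
                   feature_subset: Optional[Sequence[str]] = None,
                   per_event: bool = False) -> EvalReport:
    """Stratified k-fold CV of the likelihood-ratio ranker.

    AUC is the mean of per-fold AUCs on the held-out log ratios.  With
    ``per_event`` the same protocol is repeated on each event type's
    subset (skipped when a class has fewer than k examples there).
    """
    labels = [v.label for v in vectors]
    folds = stratified_folds(labels, k, seed)
    all_idx = np.arange(len(vectors))
    fold_rankings, fold_aucs = [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        model = _ranker.fit([vectors[i] for i in train_idx], config)
        test = [vectors[i] for i in test_idx]
        ranked, scores = _fold_ranking(model, test, feature_subset)
        fold_rankings.append(ranked)
        fold_aucs.append(auc(scores, [fv.label == POSITIVE for fv in test]))
    frac, p, r, _ = best_cutoff_f(fold_rankings)
    report = EvalReport(precision=p, recall=r, f_measure=_f_measure(p, r),
                        auc=float(np.mean(fold_aucs)),
                        chosen_cutoff_fraction=frac,
                        n_pos=labels.count(POSITIVE),
                        n_neg=labels.count(NEGATIVE), seed=seed)
    if per_event:
        for etype in sorted({v.event_type for v in vectors}):
            sub = [v for v in vectors if v.event_type == etype]
            sub_labels = [v.label for v in sub]
            if min(sub_labels.count(POSITIVE), sub_labels.count(NEGATIVE)) < k:
                continue
            rep = cross_validate(sub, k=k, seed=seed, config=config,
                                 feature_subset=feature_subset)
            report.per_event[etype] = {"precision": rep.precision,
                                       "recall": rep.recall,
                                       "f_measure": rep.f_measure,
                                       "auc": rep.auc}
    return report


def single_feature_ablation(vectors: Sequence[FeatureVector], k: int = 5,
                            seed: int = 42,
                            config: Optional[_ranker.RankerConfig] = None
                            ) -> dict[str, dict[str, float]]:
    """Per-feature accuracy table: each of the ten features evaluated
    alone (the two dependent features keep their conditioning variable),
    plus the all-features "total" row."""
    out: dict[str, dict[str, float]] = {}
    for name in FEATURE_NAMES:
        rep = cross_validate(vectors, k=k, seed=seed, config=config,
                             feature_subset=[name])
        out[name] = {"f_measure": rep.f_measure, "auc": rep.auc}
    rep = cross_validate(vectors, k=k, seed=seed, config=config)
    out["total"] = {"f_measure": rep.f_measure, "auc": rep.auc}
    return out


# ---------------------------------------------------------------------------
# Bag-of-words SVM baseline (pluggable comparison, not acceptance surface)
# ---------------------------------------------------------------------------

_STOP_WORDS = frozenset("""a an the and or but of in on at to for with by from
as is are was were be been being this that these those we our it its
""".split())


def bow_svm_baseline(sentences: Sequence[Sequence[str]],
                     labels: Sequence[str], k: int = 5, seed: int = 42
                     ) -> EvalReport:
    """Linear-SVM bag-of-words comparison model.

    Tokens are lowercased; stop-words and corpus hapaxes are dropped.
    Evaluated under the same CV + best-cut-off protocol as the ranker.
    """
    from collections import Counter
    from sklearn.svm import LinearSVC

    counts: Counter = Counter()
    for toks in sentences:
        counts.update(t.lower() for t in toks if t.lower() not in _STOP_WORDS)
    vocab = {w: i for i, w in enumerate(sorted(w for w, c in counts.items()
                                               if c > 1))}
    X = np.zeros((len(sentences), max(1, len(vocab))))
    for r, toks in enumerate(sentences):
        for t in toks:
            j = vocab.get(t.lower())
            if j is not None:
                X[r, j] += 1
    y = np.array([lb == POSITIVE for lb in labels])
    folds = stratified_folds(list(labels), k, seed)
    all_idx = np.arange(len(labels))
    fold_rankings, fold_aucs = [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx)
        clf = LinearSVC(random_state=seed)
        clf.fit(X[train_idx], y[train_idx])
        margins = clf.decision_function(X[test_idx])
        order = np.argsort(-margins, kind="stable")
        fold_rankings.append(list(y[test_idx][order]))
        fold_aucs.append(auc(margins, y[test_idx]))
    frac, p, r, _ = best_cutoff_f(fold_rankings)
    yl = list(labels)
    return EvalReport(precision=p, recall=r, f_measure=_f_measure(p, r),
                      auc=float(np.mean(fold_aucs)),
                      chosen_cutoff_fraction=frac,
                      n_pos=yl.count(POSITIVE), n_neg=yl.count(NEGATIVE),
                      seed=seed)
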