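# Methods

This note records the model, the design choices made where the design
was genuinely open, and what the synthetic evaluation does and does not
demonstrate.

## Problem and unit of analysis

The target relation is a *triple*: a gene participates, through a
specific biological event, in the development of a cancer. The unit
being scored is a candidate pair (gene mention, event trigger) inside a
sentence that has at least one of each, in an abstract containing a
cancer term. A sentence's score is the maximum over its pairs, and an
abstract's score the maximum over its sentences; retrieval orders
abstracts by that maximum. Scoring pairs rather than whole sentences
was a choice: the features (distances, edge score, agent) are defined
relative to one gene and one trigger, and the max-pair convention makes
sentence- and abstract-level displays well defined.

Annotations are inputs. The upstream stack this package expects —
gene NER, gene-id normalisation, a dependency parser, an event
extractor emitting nine event types with trigger and trigger→gene edge
confidences — is consumed through standoff/CoNLL readers or the
package's JSON-lines document format. Positive and negative regulation
are merged into one `regulation` type because event polarity does not
determine the polarity of the gene–disease relation.

Trigger pre-screening removes, per event type, trigger words that are
practically always wrong for that type (packaged default: *described,
derived, prescribed, transition* for transcription — the four
documented examples; the original full lists are no longer published,
so the blacklist is a config file), plus cytogenetic band notation
(`17q21`, `Xp11.2`, …) tagged as localization: band coordinates are
chromosomal locations, not sub-cellular events.

## The ten features

Distances are path lengths on the undirected dependency tree between
*anchor* tokens. The anchor of a multi-token mention is the span token
whose head lies outside the span (shallowest, then leftmost, on the
rare non-constituent span). When a partner term is absent from the
sentence, a penalty constant (default 10, configurable) stands in; the
classifier bins the penalty separately, so its magnitude never matters
beyond "absent".

* **norm_event_score, norm_edge_score** — raw SVM margins of the
  upstream trigger and edge classifiers, min–max normalised within the
  scoring batch. Raw margins can be negative, so dividing by the batch
  maximum (the obvious alternative) is ill-defined; min–max is used and
  documented as a deviation. A constant batch maps to 0.5, a missing
  score to 0.
* **gene_event_dist, event_regulation_dist, event_cancer_dist** — the
  minimum anchor-to-anchor distance over all occurrences of the partner
  term; which occurrence the original method paired is unspecified, and
  minimum distance is this package's choice. Regulation terms are
  relational verbs (*regulates, mediates, modulates, …*) from a small
  lexicon. The lexicon deliberately excludes bare event nominals such
  as "regulation": the worked positive example contains the word
  "regulation" twice yet is documented as having *no* regulation term,
  so the original (unpublished) lexicon cannot have contained it.
* **cancer_count, hallmark_count** — occurrences (not distinct terms;
  the two readings coincide on the documented examples) of the
  12-term cancer lexicon and the six textbook hallmark keywords
  (*apoptosis, angiogenesis, growth, invasion, metastasis,
  proliferation*). Only three of the twelve cancer terms are documented;
  the shipped set is a reconstruction and fully overridable.
* **event_depth** — edges from the parse root to the trigger anchor;
  deep triggers are rarely the sentence's main assertion.
* **negative_score** — occurrence count of purpose/method cues
  (*to determine, to assess, …*, troponyms of *study*) and negation
  words (*not, never*). The aggregation arithmetic was unspecified; an
  integer occurrence count is used.
* **agent_present** — true when the trigger anchor is an ancestor of
  the query gene's anchor and some other gene reaches the trigger
  through a *different* child subtree ("the other branch of the
  event"). Agents mark gene–gene rather than gene–disease assertions.
  The flag enters the classifier; the agent set itself is retained for
  display.

## The classifier

With equal class priors the posterior odds equal the likelihood ratio,
so the score is

    log LR(x) = Σ_f log P(x_f | pos) / P(x_f | neg),

a sum over binned per-feature conditional tables, with two dependencies
replacing the corresponding marginals:

* `P(cancer_count | group(event_cancer_dist), class)` with three
  conditioning groups — near (< 4 edges), far (≥ 4), absent (penalty).
  A cancer keyword matters most precisely when it does not co-occur
  closely with the event.
* `P(agent_present | hallmark_count > 0, class)` — an agent stops
  signalling a negative sentence when a hallmark keyword appears.

The original functional form was published only as figures; the
parameterisation here (equal-frequency quartile bins fit on the pooled
training data, with dedicated bins for exact zeros and for the penalty;
add-α smoothing, α = 1) is this package's reconstruction, chosen for
small-n robustness — the reference gold standard had only a few hundred
sentences, and smoothed quartile tables cannot produce zero
probabilities or overfit narrow bins. Quantile cut points use
`searchsorted(..., side="left")`; unseen or out-of-range codes at
scoring time fall back to the smoothed floor. Disabling the
dependencies (`use_dependencies=False`) reduces the model exactly to
naive Bayes, which the tests assert.

Scores are displayed as `sigmoid(slope · log LR)` with slope 1 by
default; the sigmoid is order-preserving, so ranking never depends on
it. Localization candidates whose sentence names no sub-cellular
compartment are demoted by multiplying the *score* (after the sigmoid —
before/after was unspecified; score-space keeps the factor
interpretable) by `localization_factor` = 0.5 by default. Ranking ties
break by (abstract id, sentence id, gene id), making the order
permutation-invariant.

## Evaluation protocol

Stratified 5-fold cross-validation (stratification is a choice for
small-n stability; fold seed default 42). All top-k cut-offs are swept;
because folds can differ in size, cut-offs are aligned across folds as
*fractions* k/n (k = round(c·n), at least 1), which makes "average F
per cut-off" well defined. The cut-off maximising the fold-averaged F
is selected; the report states the averaged precision and recall at
that cut-off and F as their harmonic mean, so the published invariant
F = 2PR/(P+R) holds exactly within a report. AUC is the Mann–Whitney
rank statistic (ties ½), averaged over held-out folds.

The random-order baseline redraws i.i.d. uniform scores for the fixed
label composition and applies the identical machinery, averaged over
repetitions (default 100). Its behaviour is a useful sanity anchor:
random precision is flat at the positive ratio, so the F-optimal
cut-off sits near the bottom of the list and recall approaches 100 %.
The best-cut-off selection inflates the baseline's precision slightly
above the positive ratio at small n (≈ +1.3 points at n = 98); the
convergence property test therefore uses n = 980, where the bias is
below 0.2.

The per-feature ablation evaluates each feature alone (the two
dependent features keep their conditioning variable) plus the
all-features row, under the same protocol. A bag-of-words linear SVM
(stop-words and hapaxes removed) is provided as a pluggable comparison
baseline.

## The synthetic corpus

Generated sentences are dependency trees assembled from six skeleton
shapes (result statement, purpose statement, gene–gene interaction,
hallmark result, negated finding, localization with/without
compartment term), with the trigger placed at a sampled depth and the
gene, cancer-term, and regulation-term branches grown to sampled path
lengths. Per-class parameters control: cancer-term presence in the
sentence (0.80 pos / 0.40 neg by default) and its distance distribution
(near for positives, far for negatives), hallmark inclusion (0.45 /
0.20), purpose/negation cues (0.08 / 0.45), agent genes (0.15 / 0.30),
regulation-verb presence (0.55 / 0.30), sub-cellular terms in
localization sentences (0.70 / 0.25), and Gaussian raw classifier
margins (trigger μ 1.2 vs 0.0). Distance distributions are categorical
over 1..8 edges, with absence governed by the presence probabilities.
The default corpus is 207 positive / 356 negative sentences with
per-class event-type mixtures matching the published gold-standard
composition; when a candidate sentence lacks a cancer term, a
context sentence containing one keeps the abstract retrievable. These
rates were fixed once, to reproduce the qualitative informativeness
ordering reported for the real features (event–cancer distance and
cancer count strongest; edge score and event depth weak), and are the
package's standing study conditions.

What this emulates: the class-conditional *feature signature* of
curated evidence sentences — the statistical structure the classifier
actually consumes. What it does not emulate: natural-language fluency,
parser noise (trees are valid by construction), NER/extractor errors
beyond score overlap, correlated features within a sentence beyond the
two modelled dependencies, and the unknown joint distribution of the
real gold corpus. Passing tests therefore demonstrate correctness of
the machinery and recoverability of known structure, not absolute
accuracy on real abstracts; the original headline accuracies depend on
an unpublished 563-sentence corpus and are out of scope here.

Problem sizes used by the test suite and acceptance script: the
563-sentence default corpus for cross-validation and ablation;
n = 2000 for generator-calibration and parameter-recovery checks
(tolerances ±0.03 and ±0.05); 100 orderings for baseline statistics
and 1000 for convergence properties; 1000 random trees for the
path-length oracle. The full suite runs in well under a minute.

## Known limitations

* The regulation-term and negative-cue lexicons are reconstructions;
  swap in project-specific lists via `load_lexicons` overrides.
* Cancer synonym handling is a flat synonym→canonical table; the
  production ancestor used a curated synonym database, which is out of
  scope.
* The index is in-memory with plain-text persistence, sized for
  corpora of thousands of sentences, not millions.
* `parse_standoff` expects sentence-local character offsets;
  document-level offsets must be shifted by the caller.
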