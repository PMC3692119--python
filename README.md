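# evirank

Rank sentences from biomedical abstracts as **evidence that a gene is
involved in the development of a disease through a biological event**
(gene expression, transcription, phosphorylation, localization,
regulation, binding, protein catabolism).

Search tools that merely co-mention a gene and a disease cannot say *how*
the gene matters. evirank operates one level deeper: its unit is a
*candidate evidence sentence* — a sentence containing at least one gene
mention and one event trigger, in an abstract that mentions a cancer term
— and its job is to order candidates so that sentences genuinely
asserting "gene → event → disease" come first, while purpose statements
("To determine the role of …"), gene–gene assertions and extractor noise
sink to the bottom.

evirank does **no** NER, parsing or event extraction itself: gene
mentions, event triggers (with classifier confidence scores) and
dependency parses are inputs, read from BioNLP-shared-task-style standoff
annotation, CoNLL dependency columns, or the package's own JSON-lines
document format.

## The model

For each candidate pair (gene mention *g*, event trigger *e*) ten
features are computed: the normalised trigger and edge classifier scores;
three dependency-tree path distances d(g,e), d(e, regulation term),
d(e, cancer term), with a penalty constant when the partner term is
absent; cancer-keyword and hallmark-keyword counts; the trigger's depth
below the parse root; a count of purpose/negation cues; and a binary
*agent* flag (another gene in a different branch under the trigger,
signalling a gene–gene statement).

With equal class priors, the ranking score is a log likelihood ratio

    log LR(x) = Σ_f log P(x_f | positive) / P(x_f | negative)

over smoothed, binned conditional tables — naive Bayes augmented with two
feature dependencies chosen for this problem: the cancer-keyword count is
conditioned on the event–cancer distance, and the agent flag on hallmark
presence. The log ratio is mapped to (0, 1) by a sigmoid, and
localization candidates whose sentence names no sub-cellular compartment
are demoted. A small inverted-index layer answers (cancer, genes, event
types) triple queries with abstracts ordered by their best sentence, and
can summarise results as a gene co-occurrence graph.

Because curated gold-standard evidence sentences are not
redistributable, the package ships a synthetic-corpus generator whose
class-conditional structure (cancer-term placement, hallmark/cue rates,
path-length distributions, agent genes, classifier-score separation) is
explicit and testable.

## Worked example

```bash
evirank simulate --n-pos 207 --n-neg 356 --seed 7 --out synth.jsonl --gold gold.tsv
evirank train    --gold gold.tsv --docs synth.jsonl --out model.json
evirank evaluate --gold gold.tsv --docs synth.jsonl --folds 5 --seed 42 --report report.json
evirank score    --model model.json --docs synth.jsonl --out ranked.tsv
evirank index    --docs synth.jsonl --model model.json --out idx
evirank query    --index idx --cancer cancer --events "gene expression,regulation" \
                 --out hits.tsv --graph cooc.tsv
```

which prints, in order:

```
wrote 563 abstracts to synth.jsonl
fitted on 698 candidates (241 pos / 457 neg) -> model.json
F=82.8 P=83.8 R=81.7 AUC=94.2 -> report.json
ranked 698 candidates -> ranked.tsv
indexed 698 candidates -> idx/
53 abstracts -> hits.tsv
```

The evaluate line is the 5-fold cross-validated performance of the full
model on the 563-sentence synthetic corpus: at the cut-off maximising
fold-averaged F, precision 83.8 % and recall 81.7 % (F = 82.8 %), with a
mean held-out AUC of 94.2 % — far above the random-ordering baseline,
which sits at AUC 50.0 with F = 51.5 for this class balance
(`random_order_baseline(241, 457, reps=100, seed=0)`). `ranked.tsv`
lists every candidate with its log likelihood ratio and sigmoid score,
best first; `hits.tsv` contains the abstracts answering the triple query,
each led by its best-scoring sentence; `cooc.tsv` is the edge list of
genes sharing abstracts in the result.

The same operations are available as library calls (`evirank.fit`,
`evirank.rank`, `evirank.cross_validate`, `evirank.query`, ...); see the
module docstrings.

## Layout

```
src/evirank/corpus.py      domain types, standoff/CoNLL/JSONL readers, lexicons
src/evirank/features.py    the ten ranking features
src/evirank/ranker.py      likelihood-ratio model, sigmoid, localization rule
src/evirank/evaluation.py  CV, cut-off sweep, AUC, baselines, ablation
src/evirank/index.py       trigger pre-screening, inverted indexes, queries, graph
src/evirank/simulate.py    synthetic corpus generator + worked-example fixtures
src/evirank/cli.py         the evirank command
docs/methods.md            modelling and design notes
```
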