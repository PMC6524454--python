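# neurofind

Detection of incidentally documented **silent brain infarction (SBI)** and
**white matter disease (WMD)** in free-text neuroimaging (CT/MRI) reports.

Two classification routes are implemented side by side:

* **Rule engine** (`neurofind.rule_engine`) — sentence segmentation, section
  detection, regex concept matching against a shipped keyword lexicon
  (findings, acute/chronic modifiers, locations, WMD exclusions), cue-and-scope
  context assignment (negated/probable status, present/historical/hypothetical
  temporality, patient/other experiencer, chronicity), and a precedence-ladder
  document summarizer producing 3-way labels (positive / indeterminate /
  negative) per condition.
* **Sentence classifiers** — a convolutional network over word embeddings
  (windowed convolution + ReLU, max-over-time pooling, fully connected layer,
  softmax; implemented in NumPy with explicit gradients,
  `neurofind.embedding_cnn`) and three traditional baselines (logistic
  regression, linear SVM, random forest over mean-pooled embeddings or
  bag-of-words; `neurofind.baselines`), with max-score document aggregation.

Supporting modules:

* `corpus_io` — JSONL report/annotation/prediction formats and the seeded
  three-way corpus split (1000 reports → 334/333/333, remainder to train).
* `pmi_features` — pointwise-mutual-information ranking of n-grams against
  labels, for prototyping and auditing the lexicon.
* `evaluation` — 2×2 confusion metrics (sensitivity/specificity/PPV/NPV/
  accuracy with explicit undefined markers), Cohen kappa + percent agreement,
  exact-binomial and continuity-corrected McNemar tests, F-measure.
* `synthetic_corpus` — a labeled synthetic report generator (two site styles
  with contrasting phrasing richness, configurable SBI/WMD prevalence, hedged/
  historical/negated mentions, location-only confounders, coreference-split
  hard cases), skip-gram or seeded-random stand-in embedding tables, and an
  oversampling utility. It makes the entire system trainable and testable
  with no external data.

Known limitation (by design): the rule engine does not resolve coreference,
so findings split across sentences ("The above findings … suggest post
ischemic change") are missed; this failure mode is pinned in the test suite
and is controllable in the generator via `coreference_rate`.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes brute-force statistical oracles, hand-computed forward-pass
checks for the CNN, property tests (hypothesis), and end-to-end acceptance
tests on the synthetic corpus. It completes in well under a minute on one CPU.

## CLI

```bash
neurofind generate --n-reports 1000 --seed 7 --out corpus/
neurofind split --in corpus/reports.jsonl --seed 7 --out splits.json
neurofind rule-classify --in corpus/reports.jsonl --out rule_preds.jsonl
neurofind evaluate --gold corpus/gold.jsonl --pred rule_preds.jsonl \
    --policy positive-vs-rest --out metrics.json
neurofind build-embeddings --in corpus/reports.jsonl --d 100 \
    --mode skipgram --seed 7 --out vecs.txt
neurofind train-cnn --train corpus/sentence_labels.jsonl \
    --dev corpus/sentence_labels.jsonl --embeddings vecs.txt \
    --concept wmd --seed 7 --out model/
neurofind predict --model model/ --embeddings vecs.txt \
    --in corpus/reports.jsonl --concept wmd --out cnn_preds.jsonl
neurofind compare --gold corpus/gold.jsonl --pred-a rule_preds.jsonl \
    --pred-b cnn_preds.jsonl --concept wmd --method exact
neurofind pmi --in corpus/reports.jsonl --labels corpus/gold.jsonl \
    --ngram-max 3 --min-count 5 --out pmi.tsv
neurofind train-baseline --kind svm --train corpus/sentence_labels.jsonl \
    --dev corpus/sentence_labels.jsonl --embeddings vecs.txt --seed 7
```

Lexicon and context-cue files are editable TSVs shipped as package data
(`src/neurofind/data/`); pass `--lexicon` to `rule-classify` to substitute
your own.

## Data formats

* Report JSONL: `{"report_id", "site": "site_a"|"site_b",
  "scan_type": "ct"|"mri", "text"}`
* Annotation JSONL: `{"report_id", "sbi": label, "wmd": label, "annotator"}`
  with labels `positive|indeterminate|negative` (case-insensitive on read).
* Prediction JSONL: `{"report_id", "sbi": label, "wmd": label}`.
* Embedding table: word2vec text format (`<n> <d>` header, one token + d
  floats per line).
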