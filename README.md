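# aderelex

Detecting drug–adverse-drug-event (ADE) relations in clinical narratives:
an end-to-end, fully offline pipeline covering corpus I/O, preprocessing,
automatic tagging, candidate-relation construction, a classifier zoo, and
intra-/inter-corpus generalizability evaluation. Because real clinical
corpora cannot be redistributed, every stage is exercised against a
deterministic synthetic clinical-note generator that emits BRAT standoff
corpora with exact gold annotations and a ground-truth manifest.

## What's inside

| Module | Purpose |
| --- | --- |
| `aderelex.corpus_io` | Read/write paired `.txt`/`.ann` BRAT standoff files; assemble corpora with per-patient longitudinal ordering |
| `aderelex.preprocess` | Whitespace/drug-name/abbreviation cleaning; rule-based sentence segmentation with protect/split/restore handling of abbreviations, decimals, and list markers |
| `aderelex.tagging` | Exact-match lexicon tagging (8 immune-checkpoint-inhibitor drugs + ADE groups, causal cues) and rule-based date tagging |
| `aderelex.candidates` | Enumerate within-sentence drug×ADE pairs, label positives from gold relations (negatives derived by subtraction), extract entity-bounded input spans, deduplicate |
| `aderelex.models` | Registry of classifiers over input spans: `svm` (character n-gram TF-IDF + RBF margin classifier), `cnn` and `bilstm` (NumPy token-level networks with manual backprop), plus a plug-point for external adapters such as transformer fine-tuners |
| `aderelex.evaluation` | Positive-class P/R/F scoring, stratified 5-fold intra-corpus CV, fixed-split and inter-corpus (70/30 internal validation) protocols, Cohen's kappa, pairwise-F annotation agreement, model-agreement cluster maps |
| `aderelex.synthetic` | Seeded synthetic corpus generator: templated notes, tunable label-signal strength, multi-entity sentences, boilerplate repetition, cross-sentence relations, whitespace noise outside entity spans; presets `ici-like` and `n2c2-like` |

The neural models are implemented directly in NumPy (embedding → encoder →
dropout → dense sigmoid, Adam, early stopping on validation F1) so the whole
package runs on one CPU with no deep-learning framework; the backward passes
are verified against finite differences in the test suite.

## CLI

```bash
aderelex synth --preset ici-like --seed 1 --out corpus/    # synthetic BRAT corpus + manifest
aderelex corpus validate corpus/                           # load report + invariant check
aderelex preprocess corpus/ cleaned/ --config cleaning.yml # text cleaning
aderelex tag corpus/ --out tagged/                         # auto-tag drugs/ADEs/cues/dates
aderelex candidates corpus/ --out dataset.tsv              # labeled candidate dataset
aderelex train --model svm --train dataset.tsv --out model.bin
aderelex eval --protocol intra_cv --train dataset.tsv --models svm,cnn,bilstm --out report/
aderelex eval --protocol inter --train A.tsv --test B.tsv --models svm --out report/
```

## Conventions

- Offsets are 0-based half-open `[start, end)` (BRAT convention).
- Cleaning precedes tagging/annotation, so gold offsets never need remapping.
- A lone newline is not a sentence boundary (clinical notes wrap lines); a
  blank line is.
- Reported F is positive-class F1; CV confusion counts are pooled (micro).
- All randomness flows from explicit seeds; training is bit-reproducible
  given the same dataset order and seed.
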