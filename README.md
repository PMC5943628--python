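# aderex — clinical relation extraction for drug-safety surveillance

Adverse drug events (ADEs) are often described only in the free-text
narrative of electronic health records, where surveillance systems cannot
see them.  Extracting them requires linking annotated entity mentions —
medications, their attributes, indications, ADEs, severities — into typed
relations, frequently across sentence boundaries.  `aderex` implements and
compares three supervised approaches to this document-level relation
identification task:

* a **rule-induction baseline** that classifies an entity pair by which
  per-type average-distance bin its token distance falls into;
* a **linear SVM** over five rich sparse feature families (document
  statistics, distance features, TF-IDF n-grams, entity character n-grams,
  semantic tags, Brown-cluster prefixes, word-vector classes, embeddings);
* **end-to-end neural extractors**: per-entity LSTM window encoders (uni-
  or bidirectional), optional global attention, a tanh MLP composition with
  softmax output, and a feature-augmented variant that embeds the
  distance/type features.

Formally the task learns `f(x): (e_l, e_r) → y ∈ Y`, where `Y` is the 7
positive relation types plus `None`; `None` examples are generated by
corrupting gold relations and may be down-sampled in training with a keep
rate.  Scoring is macro-averaged P/R/F1 over the positive types
(`p = TP/(TP+FP)`, `r = TP/(TP+FN)`, `F1 = 2pr/(p+r)`).

Annotated clinical corpora cannot be redistributed, so the package includes
a **synthetic corpus generator** that reproduces the statistical shape of
such data (9 entity types, 7 relation types with realistic frequencies,
right-skewed token-distance distribution with mean ≈ 7 and a long
intersentential tail, long-distance Indication/Adverse relations) and
standoff (.txt/.ann) I/O for real corpora in BRAT-style format.  See
`docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```bash
aderex generate --n-docs 50 --seed 3 --out corpus/
aderex train    --corpus corpus/ --model rule --seed 3 --out models/rule/
aderex evaluate --corpus corpus/ --model-dir models/rule/ --split test --out reports/
```

The evaluation prints per-class and overall rows (50-document corpus,
seed 3):

```
Relation           P       R      F1     TP     FP     FN
Adverse         3.45   20.00    5.88      2     56      8
Dosage         35.56   76.19   48.48     16     29      5
Duration        0.00    0.00    0.00      0      7      4
Frequency      20.69   28.57   24.00      6     23     15
Indication     28.57    6.06   10.00      2      5     31
Route           0.00    0.00    0.00      0      0     20
Severity        0.00    0.00    0.00      0      0     11
None           97.41   93.89   95.62    676     18     44
Overall        12.61   18.69   12.62
```

— the distance-only baseline recovers short-distance attribute relations
(Dosage is its best class) but collapses on everything else — exactly the
behaviour that motivates the feature-based systems.  `None` scores high
because most candidate pairs are unrelated; the Overall row macro-averages
the positive types only.

The library API mirrors the workflow:

```python
from aderex.experiments import prepare_bundle, train_system, evaluate_system
from aderex.synthetic import GenConfig

bundle = prepare_bundle(GenConfig(n_docs=100, seed=0), keep_rate=0.3, seed=0)
model, predict = train_system("svm", bundle, seed=0)
print(evaluate_system(predict, bundle.test).macro_f1)   # 90.3
```

A full cross-system comparison (`aderex.experiments.run_benchmark`, 100
synthetic documents, neural scores = 3-seed medians) prints:

```
rule 13.17   svm 90.30   lstm 7.19   bilstm 23.70   bilstm-att 36.79   bilstm-att-feat 89.79
```

The ordering — SVM far above the rule baseline; bidirectionality,
attention, and especially the embedded distance features each improving the
neural models — is the study's qualitative finding, reproduced on
synthetic data.  Absolute numbers depend on the generated corpus and are
not clinical-performance claims.

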