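# pssm-dt

Identify DNA-binding proteins from sequence alone by combining **PSSM
distance transformation** with a soft-margin **RBF-kernel SVM**, and explain
the classifier's decisions through discriminant-weight analysis of
amino-acid-pair descriptors.

DNA-binding proteins (transcription factors, histones, restriction
enzymes, ...) are central to replication, transcription and repair, and
telling them apart from non-binders computationally is a standing genome
annotation problem. This package is aimed at computational biologists who
have protein sequences plus PSI-BLAST evolutionary profiles (or want to
simulate them) and need a classifier whose features remain biologically
interpretable.

## The method

For a protein of length *L*, PSI-BLAST (3 iterations, E-value cutoff 0.001
against a protein database) yields a PSSM: an *L* × 20 matrix *S* whose
entry *S*<sub>*j*,*a*</sub> is the log-odds score of amino acid *a* at
position *j*. The distance transformation converts this variable-length
profile into a fixed-length vector indexed by ordered amino-acid pairs and
sequence separations (lags):

```
DT(a1, a2, lg) = ( Σ_{j=1..L−lg}  S[j, a1] · S[j+lg, a2] ) / (L − lg),   lg = 1..LG
```

Each coordinate approximately measures how often the pair (a1, a2) co-occurs
at separation *lg* along the sequence. The same-pair block (a1 = a2, 20·LG
features, "SDT") and the different-pair block (a1 ≠ a2, 380·LG features,
"DDT") concatenate into the 400·LG-dimensional DT encoding; at the default
maximum lag LG = 5 that is exactly **2000 features**. An RBF-kernel SVM
(*K*(x, x′) = exp(−γ‖x − x′‖²)) with (C, γ) tuned by stratified 5-fold
grid search classifies the vectors; evaluation supports leave-one-out
(jackknife), k-fold and independent-test protocols with SN/SP/ACC/MCC and
ROC/AUC.

To interpret a trained model, the discriminant weight vector
**W** = **A**ᵀ·**M** (signed dual weights times the training feature matrix)
is projected onto pairs: each ordered pair's weight is the quadratic sum of
its positive per-lag coordinates, and the ranking identifies which pairs —
at which separations — drive the DNA-binding call.

Four classical fixed-length PSSM summaries (AvePscore-20, AvePscore-400,
Pscore-100 and the auto-covariance transform) are included as comparison
encoders, and a seeded synthetic-profile generator with *planted* pair/lag
signal makes the whole chain testable without any database download.

## Worked example

Simulate a labeled dataset whose positives carry planted co-occurrence
signal for the pairs (R,R) at lag 4 and (P,R) at lag 2, encode it, and run
the full pipeline:

```bash
pssmdt simulate --out-dir data --seed 42 --n-pos 15 --n-neg 15
pssmdt encode   --fasta data/sequences.fasta --pssm-dir data \
                --labels data/labels.tsv --scheme dt --lg 5 --out features.tsv
pssmdt train    --table features.tsv --sidecar features.tsv.schema.jsonl \
                --C 2.0 --gamma 0.00048828125 --model-out model.json
pssmdt evaluate --table features.tsv --sidecar features.tsv.schema.jsonl \
                --protocol jackknife --C 2.0 --gamma 0.00048828125 --out report.json
pssmdt analyze  --model model.json --table features.tsv \
                --sidecar features.tsv.schema.jsonl --out-prefix fa
```

which prints

```
encoded 30 sequences x 2000 features
trained on 30 samples; model -> model.json
protocol=jackknife n=30 TP=13 FP=0 TN=15 FN=2 | SN=86.67% SP=100.00% ACC=93.33% MCC=0.8745 AUC=1.0000
top discriminative pairs: (R,R), (P,R), (R,P), (P,P)
```

Reading the numbers: of 30 held-out predictions (each sample left out once),
13 of 15 planted positives and all 15 background negatives are called
correctly — 93.33% accuracy, MCC 0.87, and a perfect ranking (AUC 1.0). The
discriminant analysis puts the two planted pairs at the top, and the per-lag
table (`fa.per_lag.tsv`) localizes their signal at the planted separations —
(R,R) peaks at lag 4 and (P,R) at lag 2:

```
aa1  aa2  lg1      lg2      lg3      lg4      lg5
R    R    38.5066  33.0548  48.784   75.8713  43.4475
P    R    15.9801  62.1675  16.7612  14.5766  18.2157
```

`pssmdt predict` applies a saved model to new FASTA + PSSM inputs and prints
the call as "DNA-binding protein" / "non DNA-binding protein". The same
functionality is available as a library of scikit-learn-style estimators
(`DistanceTransformEncoder`, `BaselineEncoder`, `RbfSvmClassifier`) that
compose with sklearn pipelines and model selection.

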