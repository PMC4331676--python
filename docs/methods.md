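# Methods

## Profile model

A PSSM profile is an L × 20 matrix of real-valued log-odds scores, row =
sequence position, column = amino acid in the PSI-BLAST header order
`A R N D C Q E G H I L K M F P S T W Y V`. Parsing keeps only the first 20
(log-odds) columns of the `-out_ascii_pssm` dialect — the weighted-percentage
columns and trailing statistics are ignored — and no normalization (sigmoid,
z-score) is applied to the scores anywhere in the pipeline. Scores are
stored as floats even though the dialect prints integers, so synthetic
profiles may be real-valued. Sequences containing ambiguity codes (`X` etc.)
are rejected at parse time rather than imputed: the pair-descriptor algebra
is only defined over the 20 canonical residues. A separate, optional
curation validator enforces the conventional 50-residue minimum; it is not
an I/O invariant. When PSI-BLAST finds no hits for a query there is no
principled fallback matrix, so the wrapper surfaces an error instead of
inventing one.

## Distance-transformation encoding

With S indexed `[position, amino acid]`,

    DT(a1, a2, lg) = ( Σ_{j=1}^{L−lg} S[j,a1]·S[j+lg,a2] ) / (L − lg)

for lg = 1..LG. One index convention deserves emphasis: the defining sum
runs over *positions* j with (a1, a2) fixed; a transposed reading (summing
over amino acids) silently yields wrong features, which is why the
vectorized implementation is pinned to naive triple-loop oracles in the
tests, coordinate for coordinate, at 1e-9.

Feature order is fixed and recorded in a schema sidecar: the same-pair
block is amino-acid-major/lag-minor, the different-pair block ordered-pair
lexicographic (in column order) then lag-minor, concatenated same-pair
first. Any fixed order is equivalent for the SVM; stability is what matters
for the discriminant analysis. L ≤ LG is a hard error (the defining
denominator would be ≤ 0), not zero-padding; curated data (≥ 50 residues)
never hits it at the default LG = 5. Encoders apply no feature scaling —
scaling is an explicit, separate classifier option.

## Comparison encoders

The four baseline schemes are known in the literature by one-line
descriptions; this package freezes one precise reading each (stated in the
module docstring): column means (AvePscore-20), per-residue-type column
means with absent residues contributing 0 (AvePscore-400), per-column
quintile-boundary percentiles {0,25,50,75,100}% with linear interpolation —
the only 5-point grid consistent with 100 features over 20 columns
(Pscore-100) — and per-column auto-covariance with divisor (L − lg),
covariance rather than Pearson correlation so constant columns give exactly
zero (ACC). Internal consistency is checked by naive oracles and algebraic
identities (frequency-weighted AvePscore-400 rows reconstruct AvePscore-20;
ACC is translation-invariant).

## Classifier

The soft-margin RBF SVM is solved by LIBSVM (scikit-learn `SVC`) with the
solver tolerance tightened to 1e-7 so that decision values agree with a
direct dual-QP solve (SLSQP plus an exact active-set polish, used only as a
test oracle) to 1e-6 on small instances. Labels are strictly {+1, −1};
decision value 0 ties to +1. Hyperparameters (C, γ) are chosen by
stratified, seeded 5-fold grid search maximizing CV accuracy with ties
broken toward smaller C then smaller γ; the default grids follow the LIBSVM
convention C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵}, γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}. Tuning happens
once on the full training set and the chosen pair is then held fixed during
jackknife — the conventional sequencing for this classifier family, but
optimistically biased since the tuning saw every sample; per-fold re-tuning
can be assembled from the public pieces. No feature scaling is applied by
default (raw squared-PSSM features are used as-is); an optional min–max
scaler fitted on training data only is available because these features
span a large dynamic range.

Models serialize to a single JSON file (support vectors, signed dual
coefficients, bias, (C, γ), optional scaling, schema, and the support
indices within the training set — the last so that discriminant analysis on
the training table remains correctly aligned after a load).

## Evaluation

SN, SP, ACC are the standard confusion-matrix ratios; MCC uses the
square-root denominator and is defined as 0 when the denominator vanishes
(this convention keeps "random predictions score ≈ 0" true on degenerate
draws). ROC curves sweep the decision threshold over pooled decision
values; AUC is the Mann–Whitney statistic with ties credited 0.5
(scikit-learn's implementation, cross-checked against brute-force pair
counting). The jackknife pools held-out decision values across all n rounds
into a single report — the only construction under which a single
benchmark-wide ROC exists for a leave-one-out protocol. The LG sweep
re-tunes (C, γ) per LG, since each LG changes the dimensionality and a
shared tuning would be ill-defined. Percentages are reported to 2 decimals.

## Discriminant-weight analysis

W = Aᵀ·M applies a linear read-out to a kernel model: exact for the linear
kernel, a first-order surrogate (not the true decision-function gradient)
for the RBF kernel. It is implemented exactly in this conventional form,
with the caveat stated here. Pair weights keep only coordinates with W > 0
— the descriptors enriched in the positive (DNA-binding) class — and sum
their squares per ordered pair, so the sum of all 400 pair weights equals
Σ W⁺². "Descriptor occurrence" on a sequence is interpreted literally:
positions (j, j+lg), 1-based, whose residues match the ordered pair; both
all-lags and chosen-lag counting are available.

## Synthetic data generator

The generator emulates labeled sets of PSI-BLAST-style profiles with known
ground truth. Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| background scores | round(N(0, 2)) clipped to [−5, 9] | integer range of real PSI-BLAST log-odds |
| lengths | uniform 60–100 | above the 50-residue curation floor, desk-scale |
| n_pos, n_neg | 30, 30 | n = 60, the size at which recovery properties are stated |
| planted pairs | (R,R) lag 4; (P,R) lag 2 | arginine-rich pairs and lags of the kind DNA-binding analyses single out |
| effect_size | 6.0 (3 background SD) | a strong, clearly plantable co-occurrence signal |
| density | 0.15 | ~10 plants per 80-residue positive |

Positives receive, at a density-controlled subset of eligible positions j,
simultaneous boosts of +effect_size to column aa1 at j and column aa2 at
j+lg, with the residues set to aa1/aa2 — coherent planting, so PSSM-based
encoders and the sequence-based occurrence locator see the same signal.
Negatives are pure background. Because the background mean is 0, a boost
changes the expectation of a product coordinate only where *both* factors
are boosted, which is what makes planted-lag localization meaningful.

What the generator does **not** emulate: realistic alignment statistics,
pseudocounts, inter-column correlations, residue-composition biases, or
homology structure between sequences. Passing recovery tests therefore
demonstrates that the pipeline detects pair/lag co-occurrence signal of the
kind the encoding targets — not that any particular accuracy carries over
to real benchmark datasets, which depend on database-era PSI-BLAST
profiles.

## Problem sizes and experiment design in the test suite

Tests use compact hyperparameter grids (4 × 4, and a 6-point γ grid for the
lag sweep) and datasets of 12–60 samples; the library defaults remain the
full grids. The lag-resolution experiment plants a single pair (R,R) at lag
3 with effect 5.0 and density 0.10: weak enough that lag-1 features alone
are insufficient (incidental lag-1 co-boosts occur at rate ≈ density², an
order below the deterministic planted-lag rate), strong enough that
encodings containing lag 3 classify well — the regime in which maximum-lag
choice demonstrably matters. The replicate recovery property (planted pairs
within the top 2K ranked pairs) is asserted over 20 seeded replicates at
the generator defaults.

## Numerical notes and limitations

- Grid-search tie-breaking is exact-float equality on fold-pooled accuracy;
  with few samples many grid points tie and the smallest (C, γ) wins,
  deterministically.
- The ASCII-PSSM writer prints integers (as PSI-BLAST does); round-tripping
  real-valued synthetic scores through it rounds them. The generator
  pre-rounds all scores so written datasets round-trip exactly.
- Jackknife is O(n) SVM fits; at n in the hundreds with 2000 features this
  is minutes, not seconds. The k-fold protocol is the cheaper alternative.
- The discriminant read-out ignores the RBF kernel's nonlinearity; rankings
  are a screening tool, not effect estimates.
- Class imbalance is not reweighted (out of scope); MCC is reported
  precisely because it is informative under imbalance.
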