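# Methods

## Problem setting and model

`malosite` predicts whether a lysine in a protein is malonylated, using
only the local sequence context. A candidate site is represented as a
fixed-length odd window (default L = 25) centered on the `K`; windows
that overhang a protein terminus are filled with the pad symbol `X`.
Padding is treated as "no observation": pad positions are excluded from
every count and denominator in every encoder, so a terminal window is
described by the residues it actually has. How boundary sites should be
handled is genuinely open in this problem; padding (rather than
discarding boundary sites) was chosen to keep one window per lysine.
Non-standard residues (B, Z, U, O, J, `*`) also map to `X` with a logged
warning, since real proteomes contain them and dropping whole proteins
for one ambiguous residue would bias the site inventory.

## Encoders

**EAAC** slides a length-5 subwindow (stride 1) across the window and
computes per-residue frequencies `g(m,n) = H(m,n)/H(n)` with `H(n)` the
subwindow's non-pad length. The per-subwindow vectors are averaged into a
20-length feature by default; this keeps the encoder's printed
dimensionality at 20 while the `collapse="concat"` mode retains the full
20 × 21 per-subwindow profile for positional analyses (the end-to-end
Fisher-score recovery test uses it precisely because averaging discards
position identity).

**EGAAC** pools residues into five physicochemical groups — aliphatic
{G,A,V,L,M,I}, aromatic {F,Y,W}, positively charged {K,R,H}, negatively
charged {D,E}, neutral {S,T,C,P,N,Q} — and computes group frequencies in
length-5 subwindows at stride 3, right-padding the final placement: 9
placements × 5 groups = 45 features on a 25-mer. The stride/padding
combination is the one consistent with that 45-length output; stride 1
would give 105. G is assigned to the aliphatic group only, because the
five groups must partition the alphabet for the frequencies of one
placement to sum to 1.

**DDE** standardizes observed overlapping dipeptide frequencies
`DC(m,n) = H_mn/(H−1)` against the codon-usage expectation
`TM(m,n) = (C_m/61)(C_n/61)` with variance `TV = TM(1−TM)/(H−1)`:
`DDE = (DC − TM)/√TV`. `C_m` are sense-codon multiplicities of the
standard genetic code (A=4, L=6, M=W=1, …, totalling 61). The numerator
is the *deviation* `DC − TM`; a dipeptide observed exactly at its
expectation scores 0.

**pKa** is a single scalar: the mean per-residue pKa over non-pad
positions. The shipped table (versioned, swappable via `PkaTable`) uses
side-chain pKa for the seven ionizable residues (D 3.65, E 4.25, H 6.0,
C 8.18, Y 10.07, K 10.53, R 12.48) and, for residues with no ionizable
side chain, the mean of the free amino acid's α-amino and α-carboxyl pKa,
so every residue contributes on a common 0–14 scale. Mean (not sum)
aggregation is the default so the feature is window-length invariant.

**TF-IDF** treats the 20 amino acids as terms and windows as documents.
`DF(t)` counts training windows containing t at least once;
`IDF = ln(|D|/DF)` with an add-one fallback for corpus-absent terms; the
transform is `TF × IDF` with `TF` the within-window frequency. The log
base (natural) is a convention; it only rescales features and is removed
by z-scoring.

**TF-CRF** weights each term by its class relevance:
`crfValue(t,c) = positiveRF/negativeRF`, where `positiveRF` is the
fraction of class-c training windows containing t and `negativeRF` the
same fraction outside c, both Laplace-smoothed (`(count+s)/(total+2s)`,
s = 1 by default) so the ratio is finite and positive even for one-sided
terms. The window weight is `log(max(tf, ε) · crfValue)` with
`ε = 1/(2L)` guarding absent terms, L2-normalized over the 20 terms. The
defining property — a term concentrated inside a class outweighs the same
term spread across classes, at a fixed number of containing windows — is
asserted as a four-state ordering test (w² < w¹ < w³ < w⁴). At inference
the true class is unknown, so the transform uses a fixed reference class
(positive) for every window, making the encoder class-blind at test time;
this is the only self-consistent reading that yields a 20-length vector.

**PSSM** estimates per-position occurrence probabilities from the
*positive* training windows only, with pseudo-count smoothing
`M_ij = (count_ij + pc·b_j)/(n_i + pc)` (pc = 1) against a uniform
background `b_j = 0.05`, and scores `P_ij = log2(M_ij/b_j)`. Probability
rows sum to 1 by construction. The window feature is the standard
400-length profile composition: for each residue type r and matrix
column j, the sum of `P_ij` over positions where the window carries r.
The matrix is estimated in-package from the fixed-length training
alignment rather than from database search profiles, keeping the tool
self-contained; externally computed matrices can be supplied as TSV.

## Normalization, selection, evaluation

Features are z-scored with the population (divide-by-n) standard
deviation; constant columns map to exactly 0 rather than NaN. Fisher
scores are computed on the normalized training matrix (normalization
precedes selection in the stage order); the ratio's degenerate cases are
resolved as +inf (separating feature with zero within-class variance,
ranked first) and 0 (constant feature). Ties in the ranking break
lexicographically by feature name so runs are reproducible. Selection
keeps the top 80% by default (`ceil(0.8·n)` features).

Cross-validation is stratified tenfold with a seeded shuffle. Within each
fold, corpus encoders, the scaler and the ranking are fitted on the nine
training folds and applied to the held-out fold — the paired null test
(shuffled labels → AUROC ≈ 0.5) is the leak detector for this contract.
Error bars are the sample standard deviation of each metric across folds.
MCC with a zero denominator is defined as 0. The hard-label threshold on
the positive-class probability is 0.5.

Significance against random prediction uses a one-sided label-permutation
test, `p = (r+1)/(n_perm+1)`, computed on the pooled out-of-fold scores;
reports label the procedure explicitly. The permutation test was chosen
because it is assumption-free and exact at small n_perm; the minimum
attainable p is 1/(n_perm+1).

Classifier hyperparameters are fixed defaults per family: XGBoost 80
estimators at learning rate 0.1; random forest 100 trees with the Gini
criterion; RBF-SVM with soft-margin cost C = 2 (the data-scaled default
kernel width); a 4-hidden-layer MLP (widths 128-64-32-16, learning rate
0.08). The SVM cost reading of "penalty 2" and the geometric MLP widths
are design choices where only the layer count and learning rate are
pinned down.

## Synthetic data: what it emulates, and what it does not

The generator samples each window position independently from a
background composition (uniform 0.05 by default, a Swiss-Prot-like table
is shipped), fixes the center to `K`, and perturbs chosen
(offset, residue) pairs in the positive class by additive log-odds
shifts, renormalizing per position. This reproduces the one structure the
pipeline is built to detect — class-dependent positional residue
enrichment/depletion around the site — and nothing else: there is no
positional coupling, no homology between windows, no protein-level
composition structure, and no claim that the shift magnitudes match real
malonylation data. Passing the null/signal acceptance checks therefore
demonstrates that the pipeline is leak-free and can recover positional
enrichment when present; it does not certify real-data accuracy, which
depends on external benchmark sets.

Two named conditions are used throughout the tests:

- **null**: uniform background, no enrichment — classes exchangeable,
  expected cross-validated AUROC 0.5.
- **strong**: eight flanking (offset, residue) pairs at +3.5 log-odds
  (5% → ~64% occupancy in positives) and two depleted at −2.5. The
  Bayes-optimal AUROC of this condition is ≈ 0.997 — the positive-class
  motif-hit count ~ Binomial(8, 0.64) barely overlaps the negative
  ~ Binomial(8, 0.05) — so it is strongly separable by construction,
  with headroom for encoder and classifier loss. (A weaker candidate,
  six pairs at +2.5, has Bayes AUROC ≈ 0.93 and is *not* a strongly
  separable condition; the magnitude was set from this analysis.)

Problem sizes in the shipped study runs: 250 windows per class for the
null condition, 1000 per class for the strong condition, 120 per class ×
50 replicates for the Fisher-score recovery rate. These sizes put the
Monte-Carlo error of each check well below its decision margin.

## Numerical and degenerate-input conventions

- All-pad subwindows contribute zero rows (logged), never NaN; all-pad
  windows are rejected where a denominator would vanish (pKa, DDE).
- Encoder outputs are validated to be finite; feature names are unique
  and namespaced (`EAAC:A`, `DDE:AC`, `PSSM:r:j`).
- Determinism: every stochastic step (generator, fold shuffle, classifier
  seeds, permutation draws) flows from one integer seed; rerunning a
  pipeline config with the same seed reproduces the CV report
  byte-for-byte.
- Site positions are 1-based in all files, 0-based in memory; FASTA
  output is LF-terminated and wrapped at 60 columns.

## Known limitations

- Real benchmark datasets are not bundled; reported numbers are synthetic
  unless the user supplies window FASTA or protein+site inputs.
- The TF-CRF inference rule (fixed reference class) is one defensible
  reading of a method defined only for labeled corpora.
- The PSSM is an ungapped, alignment-free estimate from positive windows;
  it carries no evolutionary information from homology searches.
- The composition-style encoders (EAAC averaged, TF-IDF, TF-CRF, pKa)
  discard position identity; positional signal enters through EGAAC's
  placements and the PSSM. Encoder combinations should be chosen with
  that in mind.
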