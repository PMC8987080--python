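# malosite

Prediction of lysine malonylation sites in proteins from sequence alone.

Malonylation is a post-translational modification that attaches a
negatively charged malonyl group to lysine side chains, altering protein
charge and function. Experimental mapping of modified sites is slow and
expensive, so sequence-based classifiers are used to prioritize candidate
lysines. `malosite` is a complete, reproducible implementation of a hybrid
feature-extraction pipeline for this task, aimed at computational
biologists who want to train, evaluate and dissect window-based PTM-site
predictors.

## The method

Each candidate site is a 25-residue peptide window centered on a lysine
(`K`), padded with `X` at protein termini. Windows are converted to
numbers by seven encoders:

| Encoder | Idea | Length |
|---|---|---|
| EAAC | residue frequencies `g(m,n) = H(m,n)/H(n)` over sliding length-5 subwindows, averaged | 20 |
| EGAAC | the same over five physicochemical groups (aliphatic GAVLMI, aromatic FYW, positive KRH, negative DE, neutral STCPNQ), stride 3 | 45 |
| DDE | dipeptide deviation from expected mean: `(DC − TM)/√TV`, `TM` from sense-codon multiplicities | 400 |
| pKa | mean per-residue pKa (single scalar) | 1 |
| TF-IDF | amino acids as terms, windows as documents: `TF(t,d) · log(|D|/DF(t))` | 20 |
| TF-CRF | term frequency × category relevancy factor `crfValue = positiveRF/negativeRF`, L2-normalized | 20 |
| PSSM | position-specific log₂-odds `P_ij = log2(M_ij/b_j)` against a uniform background `b_j = 0.05`, grouped into a 400-length residue composition | 400 |

TF-IDF, TF-CRF and the PSSM are fitted on training folds only. Encoded
features are z-scored (`z = (x − μ)/σ`), ranked by Fisher score

```
F(i) = Σ_k n_k (x̄_i^k − x̄_i)² / Σ_k [1/(n_k−1)] Σ_j (x_{j,i}^k − x̄_i^k)²
```

and the top 80% retained. Classification uses XGBoost (80 estimators,
learning rate 0.1), random forest (100 trees, Gini), RBF-SVM (C = 2) or a
4-layer MLP, evaluated by stratified tenfold cross-validation with
Sn/Sp/ACC/MCC/AUROC/AUPR, across-fold error bars and label-permutation
p-values.

Because public malonylation benchmarks are not bundled, the package ships
a first-class synthetic generator that mimics the positional residue
enrichment (offsets −12..+12 around the central K) real datasets show, so
every stage is testable end to end.

## Worked example

```python
from malosite.synthetic_data import generate, strong_profile
from malosite.model_eval import tenfold_cv, ClassifierSpec

data = generate(n_pos=300, n_neg=300, profile=strong_profile(), seed=1)
report = tenfold_cv(
    data,
    encoders=["EAAC", "PKA", "PSSM", "TFCRF"],
    selection_fraction=0.8,
    spec=ClassifierSpec("gradient_boosted_trees"),
    seed=1,
)
print(f"AUROC {report.mean['AUROC']:.3f} ± {report.sd['AUROC']:.3f}")
print(f"ACC   {report.mean['ACC']:.3f}   MCC {report.mean['MCC']:.3f}")
```

prints

```
AUROC 0.994 ± 0.007
ACC   0.962   MCC 0.925
```

i.e. on a strongly enriched synthetic motif the cross-validated pipeline
recovers the signal almost perfectly; with the null (zero-enrichment)
profile the same call returns AUROC ≈ 0.5, confirming the fold-wise
fit/transform separation leaks nothing.

The same pipeline is scriptable from the shell:

```bash
malosite simulate --n-pos 500 --n-neg 500 --seed 1 --pos-out pos.fa --neg-out neg.fa
malosite train-cv config.yaml
malosite predict --model run/model --windows new_windows.fa --out scores.tsv
```

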