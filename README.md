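# psepro

Sequence-based identification of DNA-binding proteins from evolutionary
profiles: profile-based pseudo amino acid composition features, an RBF-kernel
support vector machine with jackknife evaluation and discriminant-weight
analysis, and a probability-averaging ensemble for large negative pools.

## Who this is for

Annotating whether a protein binds DNA from sequence alone is a routine need
in function prediction: structures are unavailable for most sequences, and
experimental assays do not scale. `psepro` is a library plus a command-line
tool for building such predictors. It takes protein sequences (FASTA) and
per-sequence evolutionary information — PSI-BLAST ASCII PSSM files, or a
multiple alignment from which a profile is computed — and turns each protein
into a fixed-length descriptor that a kernel classifier can consume.

## The representation and model

**Profile consensus P′.** The evolutionary profile of a protein of length *L*
is an *L* × 20 row-stochastic matrix *M* of per-position amino-acid
probabilities. When built from an alignment, observed column frequencies
*f<sub>ij</sub>* are regularized with BLOSUM62 pseudo-counts:

```
g_ij = Σ_k (f_kj / p_k) · q_ik
m_ij = (α_j · f_ij + β · g_ij) / (α_j + β)
```

where *q<sub>ik</sub>* are BLOSUM62 target pair frequencies, *p<sub>k</sub>*
the background frequencies, *α<sub>j</sub>* the number of distinct residues
observed in column *j* minus one, and *β* = 10. The consensus sequence P′
takes the most probable residue at each position and carries the
evolutionary signal into a plain sequence.

**Pseudo amino acid composition.** P′ is encoded as a (20 + λ)-vector: the 20
residue frequencies *f<sub>u</sub>* followed by λ sequence-order correlation
factors

```
θ_k = (1 / (L − k)) Σ_i Θ(R_i, R_{i+k}),
Θ(a, b) = (1/7) Σ_j (H_j(a) − H_j(b))²,
```

with *H<sub>j</sub>* seven z-scored physicochemical properties
(hydrophobicity, hydrophilicity, side-chain mass, pK1, pK2, pI, accessible
surface area; user-overridable). The vector is normalized so that

```
x_u = f_u / D  (u ≤ 20),   x_u = ω·θ_{u−20} / D  (u > 20),
D = Σ f_v + ω Σ θ_k,
```

giving a nonnegative feature vector summing to 1. Defaults λ = 3, ω = 0.7 →
23 features.

**Classifier.** An SVM with RBF kernel exp(−γ‖x−y‖²), defaults C = 8192 and
γ = 8.0, with Platt-calibrated probabilities. Evaluation uses the jackknife
(leave-one-out) with sensitivity, specificity, accuracy, Matthews correlation
and ROC/AUC. Per-feature discriminant weights W_j = Σ_i A_i·M_ij (dual
coefficients through the training matrix) indicate which features favor the
DNA-binding class. For imbalanced data, a negative pool is partitioned into
k disjoint subsets, one SVM trained per subset plus the shared positives, and
predictions averaged over the members' probabilities.

## Worked example (library)

```python
import numpy as np
from psepro import (SyntheticSpec, generate_dataset, jackknife, train,
                    discriminant_weights, feature_names)

X, y, manifest = generate_dataset(SyntheticSpec(seed=0))   # 30 + 30 proteins
report = jackknife(X, y)
print(f"jackknife: Acc {report.acc:.2f}%  MCC {report.mcc:.3f}  "
      f"Sn {report.sn:.2f}%  Sp {report.sp:.2f}%  AUC {report.auc:.3f}")
W = discriminant_weights(train(X, y))
top = np.argsort(W)[::-1][:3]
names = feature_names(3)
print("top discriminant features:",
      ", ".join(f"{names[i]} ({W[i]:+.2f})" for i in top))
```

prints

```
jackknife: Acc 95.00%  MCC 0.901  Sn 93.33%  Sp 96.67%  AUC 0.992
top discriminant features: K (+7.46), R (+5.93), theta_1 (+3.00)
```

The synthetic positive class is enriched in arginine and lysine — the
residues over-represented in real DNA-binding regions — and the model both
separates the classes (AUC 0.992 over 60 leave-one-out rounds) and assigns
its largest positive discriminant weights to exactly those composition
features, i.e. it recovers the planted biology, not an artifact.

## Worked example (command line)

```sh
psepro simulate --out-dir data --n-pos 10 --n-neg 10 --seed 7
psepro extract  --fasta data/sequences.fasta --profiles data/profiles --out features.csv
psepro jackknife --features features.csv --labels data/labels.tsv --out report.json
```

```
wrote 20 sequences to data
wrote 20 feature vectors (23 columns) to features.csv
jackknife on 20 samples: Acc 95.00% MCC 0.905 AUC 1.0000
```

`extract` accepts a directory of PSI-BLAST `<id>.pssm` files or aligned
`<id>.afa` FASTA files; `train`, `predict`, `weights`, `paramscan`,
`ensemble-train` and `ensemble-predict` complete the toolkit. Exit codes:
0 success, 2 input error, 3 configuration error.

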