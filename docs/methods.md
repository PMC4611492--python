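# Methods

## Problem setting

Given only a protein's sequence and its evolutionary profile, decide whether
it is a DNA-binding protein. The package implements the representation, the
classifier, the evaluation protocol, and an ensemble scheme for exploiting
negative pools larger than the positive set, together with a synthetic data
generator that makes every stage testable without running PSI-BLAST or
downloading any database.

## Evolutionary profiles and the consensus sequence

A frequency profile is an L × 20 row-stochastic matrix over the canonical
residue order A, C, D, …, Y (alphabetical; every parser reorders into it at
the boundary). Three sources are supported:

* **PSI-BLAST ASCII PSSM files.** Only the second (percentage) block is
  used: percentages are divided by 100 and renormalized per row. PSI-BLAST
  emits all-zero percentage rows at positions with no alignment evidence;
  these are replaced by a one-hot row on the query residue, the
  no-information fallback. Whether upstream percentage rows should be
  renormalized at all is a convention choice; renormalizing makes every
  downstream invariant (row-stochasticity) hold regardless of how the file
  was produced.
* **Multiple alignments.** Observed column frequencies count standard
  residues only; gaps and ambiguity codes are excluded, and a column with no
  standard residue is an error rather than a silently uniform row.
* **Synthetic profiles** (below).

Observed frequencies are regularized by substitution-matrix pseudo-counts:
for column j,

    g_ij = Σ_k (f_kj / p_k) q_ik
    m_ij = (α_j f_ij + β g_ij) / (α_j + β)

with β = 10 and α_j = (number of distinct standard residues in column j) − 1,
the count of independent observations. α_j = 0 for a perfectly conserved
column, so a single observation defers entirely to the prior, which is the
intended limit of this estimator family. Because the column marginals of q
equal the background p, Σ_i g_ij = 1 and rows stay stochastic — asserted to
1e-9 throughout.

**Substitution model.** q must be the BLOSUM62 *target pair frequency*
matrix: the integer log-odds scores cannot enter the formula directly, since
only pair frequencies make g a probability vector. None of the installed
libraries ships the frequency table, so the model derives it from the
published integer scores by the standard inversion: a valid score matrix
satisfies s_ij = ln(q_ij/(p_i p_j))/λ for a unique (q, p, λ); given λ the
marginal-consistency condition is the linear system exp(λS)·p = 1, and λ is
fixed by Σp = 1 (a bracketed scalar root-find). For BLOSUM62 this yields
λ ≈ 0.324 and backgrounds close to the usual amino-acid frequencies; q is
symmetric and its marginals equal p to machine precision, so the
row-stochasticity guarantee is exact by construction. Because the integer
scores are rounded, the reconstructed q differs slightly from the historical
frequency table computed from the original alignment blocks; all package
invariants are insensitive to this difference.

The consensus P′ takes the arg-max residue per row. Ties are broken by
canonical order (first wins) — profiles rarely tie in practice, but the rule
makes the pipeline deterministic. Ambiguity codes can never appear in P′
because all profile math is defined over the 20 standard residues.

## PseAAC features

P′ of length L becomes a (20 + λ)-vector: relative residue frequencies f_u
followed by λ sequence-order correlation factors

    θ_k = (1/(L−k)) Σ_{i=1..L−k} Θ(R_i, R_{i+k}),
    Θ(a,b) = (1/n_props) Σ_j (H_j(a) − H_j(b))²,

jointly normalized by D = Σf_v + ω Σθ_k so the vector is nonnegative and
sums to 1. Defaults λ = 3, ω = 0.7 (the optimum reported for this
representation on the DNA-binding benchmark); the feature vector then has 23
entries. λ must be strictly smaller than L; shorter sequences are rejected
rather than zero-padded, because θ_k is undefined at L − k ≤ 0 (curated
benchmarks exclude proteins under 50 residues, so this bites only on
fragments).

**Properties.** H_j are z-scored over the 20 residues using the population
standard deviation (divide by n = 20), the convention of this feature
family; a flag-level switch would be a one-line change and a test pins the
convention. The packaged panel — hydrophobicity, hydrophilicity, side-chain
mass, pK1, pK2, pI, mean accessible surface area — is the canonical
seven-property set of the PseAAC literature. The exact raw values differ
across publications; since z-scoring absorbs affine differences and the
table is loadable from TSV, users who need a specific published panel can
drop it in. A constant property row is rejected (zero variance), with the
threshold scaled by the row's magnitude to catch floating-point-constant
rows.

## Classifier and evaluation

The classifier is an RBF-kernel SVM, K(x,y) = exp(−γ‖x−y‖²), C = 8192 = 2¹³
and γ = 8.0 = 2³ by default; `grid_search` scans the conventional
powers-of-two grids C ∈ 2^{−5..15}, γ ∈ 2^{−15..3} with stratified k-fold
accuracy and breaks ties toward smaller C then smaller γ. Probabilities are
Platt-style sigmoid calibrations of the decision values (libsvm's internal
cross-validated fit, seeded for determinism); the calibrator is isolated
behind `predict_proba` so an alternative calibration is a local change.

Jackknife evaluation holds each sample out once and accumulates confusion
counts over the N rounds; ROC/AUC is computed from the N held-out decision
values, where AUC is the tie-aware Mann–Whitney statistic. Sn, Sp, Acc are
reported in percent and MCC on [−1, 1]; a zero MCC denominator is defined as
0 with a warning. `counts_from_rates` inverts printed two-decimal Sn/Sp
percentages to the unique integer confusion counts, accepting either
rounding or truncation since published tables use both.

One caveat worth knowing: leave-one-out on *structureless* data is
pessimistically biased, not centered at AUC 0.5 — removing a sample tilts
the training balance against its own class, so null-data jackknife AUCs
scatter below one half. The null-control test therefore uses a fixed seed,
and the one-sided reading ("no apparent signal") is the robust one.

**Discriminant weights.** W_j = Σ_i A_i M_ij, with A the signed dual
coefficients (zero for non-support samples) and M the training feature
matrix. For a linear kernel this is exactly the primal weight vector (a test
pins the identity at 1e-6); for the RBF kernel it is the same linear
projection applied to the dual solution, and its signs indicate which class
each feature favors. Σ_i A_i = 0 at the SVM optimum, so constant feature
columns get weight exactly 0.

**Persistence.** Models are stored as versioned JSON archives holding
hyperparameters, the training set and the fitted dual coefficients; loading
refits the deterministic SVM on the stored data and verifies the dual
coefficients against the archive. This keeps artifacts text-only and
independent of libsvm's internal serialization.

## Negative-pool ensemble

Non-DNA-binding proteins vastly outnumber binders, but training one SVM on
all of them biases the margin. The ensemble partitions the negative pool
into k (default 4) disjoint subsets by seeded shuffle + round-robin slicing
(sizes differ by at most one; a 2059-sample pool splits 515/515/515/514),
trains one member per subset with the shared positives, and averages the
members' calibrated probabilities; the label is positive when the mean
reaches 0.5 (exact ties are positive and logged — the threshold is the
calibrated-probability default, and the tie rule only matters on degenerate
inputs).

## Synthetic data generator

The generator emulates the statistical shape of the real inputs:

* **Sequences.** Negatives are i.i.d. draws from the substitution-model
  background frequencies; positives multiply the background by per-residue
  enrichment factors, default {R: 2.5, K: 2.5}, echoing the residues
  enriched in DNA-binding regions so that sign-level discriminant checks are
  meaningful. An optional order-effect parameter makes successive residues
  physicochemically similar (transition weights ∝ exp(−order_effect·Θ)),
  planting signal in the θ features; it defaults to 0. Lengths are uniform
  on 50–150 (benchmarks exclude sub-50-residue fragments; the upper end
  keeps tests fast). Default sizes are 30 positives + 30 negatives.
* **Profiles.** Row j is drawn from Dirichlet(1 + c·onehot(R_j)) with
  concentration c = 50 by default — sharp enough that the consensus mostly
  recovers the sequence, noisy enough to exercise the profile math. As
  c → ∞ the profile tends to one-hot.
* **PSSM files.** Profiles can be written in PSI-BLAST's ASCII layout
  (including its different column order) with largest-remainder integer
  percentages, so parser round-trips are exact to better than 1% per cell.

Everything is a pure function of the spec and seed. What this does *not*
emulate: substitution processes along a phylogeny, domain architecture,
alignment depth heterogeneity, or composition–length correlations of real
proteomes. Passing the pipeline-recovery tests therefore shows the machinery
is correct and sensitive to planted compositional signal — not that any
particular accuracy will be achieved on real PSI-BLAST profiles, which also
depend on the search database and iteration count (treated as the caller's
input, deliberately outside this package).

## Problem sizes and numerical choices

Tests and the acceptance script run on desk-scale fixtures chosen once: the
default two-class fixture (n = 60) for jackknife recovery, a 30 + 120
training pool with a 40 + 40 held-out set for the ensemble, and a 2059-id
partition check mirroring the published pool size. Row-stochasticity and
feature-simplex invariants are asserted at 1e-9; oracle equivalences at
1e-10–1e-12; the linear-kernel discriminant identity at 1e-6 (libsvm
tolerance). Feature extraction rejects non-finite inputs; the SVM wrapper
validates two-class, finite inputs via scikit-learn's checks.

## Known limitations

* The seven-property raw values are a canonical stand-in, not a specific
  publication's supplementary table (z-scoring removes affine but not
  rank-order differences between scales).
* The reconstructed BLOSUM62 pair frequencies invert integer-rounded scores
  (see above).
* Discriminant weights from an RBF model are a linear summary of a
  non-linear decision function; signs are interpretable, magnitudes only
  comparatively.
* The jackknife refits N models; for N beyond a few thousand samples a
  k-fold protocol would be the practical choice.
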