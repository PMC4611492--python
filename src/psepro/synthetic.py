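"""Synthetic fixtures: sequences, alignments, profiles and labeled datasets.

Real inputs to this package are PSI-BLAST profiles of curated protein sets,
which cannot be regenerated on demand. The generators here emulate their
statistical shape so that every pipeline stage is testable offline:

* two sequence classes differing in residue composition — by default the
  positive class is enriched in arginine and lysine, the residues
  over-represented in DNA-binding regions — and, optionally, in short-range
  physicochemical order correlation;
* per-sequence frequency profiles obtained by smearing the one-hot encoding
  of each residue with Dirichlet noise, so rows stay stochastic and a single
  concentration parameter tunes how sharply the profile identifies the
  underlying sequence;
* PSI-BLAST-format ASCII PSSM files for parser round-trips.

Everything is a pure function of the spec and its seed. What the generators
do not emulate: realistic substitution processes along a phylogeny, domain
structure, and length/composition correlations of real proteomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS
from .profiles import (
    FrequencyProfile,
    ProfileSource,
    Sequence,
    blosum62_model,
    consensus_sequence,
    write_fasta,
)
from .pseaac import DEFAULT_LAMBDA, DEFAULT_OMEGA, _pairwise_theta_matrix, featurize_batch
from .properties import default_property_table


@dataclass
class SyntheticSpec:
    """Parameters of a two-class synthetic dataset.

    ``enrichment`` multiplies the background frequency of chosen residues in
    the positive class (renormalized); ``order_effect`` > 0 makes successive
    residues physicochemically similar by down-weighting dissimilar
    transitions; ``profile_noise`` is the Dirichlet concentration added on the
    true residue when smearing one-hot rows into profiles (larger = sharper).
    """

    n_pos: int = 30
    n_neg: int = 30
    length_range: tuple[int, int] = (50, 150)
    enrichment: dict[str, float] = field(
        default_factory=lambda: {"R": 2.5, "K": 2.5}
    )
    order_effect: float = 0.0
    profile_noise: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be nonnegative")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("length_range must satisfy 2 <= min <= max")
        for r, b in self.enrichment.items():
            if r not in AA_INDEX:
                raise ValueError(f"unknown residue {r!r} in enrichment")
            if b <= 0:
                raise ValueError("enrichment biases must be positive")
        if self.profile_noise <= 0:
            raise ValueError("profile_noise concentration must be positive")
        if self.order_effect < 0:
            raise ValueError("order_effect must be nonnegative")


def _class_distributions(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    background = blosum62_model().background
    bias = np.ones(20)
    for r, b in spec.enrichment.items():
        bias[AA_INDEX[r]] = b
    pos = background * bias
    return pos / pos.sum(), background


def _sample_sequence(
    dist: np.ndarray, length: int, order_effect: float, theta_mat: np.ndarray,
    rng: np.random.Generator,
) -> str:
    if order_effect == 0.0:
        idx = rng.choice(20, size=length, p=dist)
    else:
        trans = dist[None, :] * np.exp(-order_effect * theta_mat)
        trans /= trans.sum(axis=1, keepdims=True)
        if np.any(~np.isfinite(trans)):
            raise ValueError("degenerate transition distribution")
        idx = np.empty(length, dtype=int)
        idx[0] = rng.choice(20, p=dist)
        for i in range(1, length):
            idx[i] = rng.choice(20, p=trans[idx[i - 1]])
    return "".join(AMINO_ACIDS[i] for i in idx)


def generate_sequences(
    spec: SyntheticSpec,
) -> tuple[list[Sequence], np.ndarray]:
    """Labeled sequences: positives first (+1), then negatives (-1)."""
    rng = np.random.default_rng(spec.seed)
    pos_dist, neg_dist = _class_distributions(spec)
    theta_mat = _pairwise_theta_matrix(default_property_table())
    lo, hi = spec.length_range
    seqs: list[Sequence] = []
    labels: list[int] = []
    for label, n, dist in ((1, spec.n_pos, pos_dist), (-1, spec.n_neg, neg_dist)):
        tag = "pos" if label == 1 else "neg"
        for i in range(n):
            length = int(rng.integers(lo, hi + 1))
            residues = _sample_sequence(
                dist, length, spec.order_effect if label == 1 else 0.0,
                theta_mat, rng,
            )
            seqs.append(Sequence(id=f"{tag}_{i:04d}", residues=residues))
            labels.append(label)
    return seqs, np.array(labels)


def generate_msa(
    seq: Sequence, n_rows: int, mutation_rate: float, seed: int
) -> list[Sequence]:
    """Aligned homolog set: the sequence plus point-mutated copies."""
    rng = np.random.default_rng(seed)
    rows = [seq]
    for r in range(1, n_rows):
        residues = list(seq.residues)
        for i, ch in enumerate(residues):
            if ch in AA_INDEX and rng.random() < mutation_rate:
                residues[i] = AMINO_ACIDS[rng.integers(20)]
        rows.append(Sequence(id=f"{seq.id}_hom{r}", residues="".join(residues)))
    return rows


def generate_profiles(
    seqs: list[Sequence], spec: SyntheticSpec
) -> list[FrequencyProfile]:
    """Dirichlet-smeared one-hot profiles, one per sequence.

    Row j is drawn from Dirichlet(1 + concentration * onehot(R_j)); as the
    concentration grows the profile tends to one-hot and the consensus
    recovers the source sequence.
    """
    rng = np.random.default_rng(spec.seed + 1)
    profiles = []
    for seq in seqs:
        alpha = np.ones((len(seq.residues), 20))
        for j, ch in enumerate(seq.residues):
            if ch not in AA_INDEX:
                raise ValueError(
                    f"{seq.id!r}: cannot build profile over ambiguous "
                    f"residue {ch!r}"
                )
            alpha[j, AA_INDEX[ch]] += spec.profile_noise
        matrix = np.vstack([rng.dirichlet(a) for a in alpha])
        profiles.append(
            FrequencyProfile(
                seq_id=seq.id, matrix=matrix, source=ProfileSource.SYNTHETIC
            )
        )
    return profiles


#: Column order PSI-BLAST prints; used when emitting PSSM fixtures.
_PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


def write_pssm(
    profile: FrequencyProfile, query: Sequence, path: str | Path
) -> None:
    """Write a profile as a PSI-BLAST-format ASCII PSSM file.

    Percentages are written as integers like PSI-BLAST's; largest-remainder
    rounding keeps each row summing to exactly 100, so a round-trip through
    the parser reproduces the profile to better than 1% per cell.
    """
    background = blosum62_model().background
    perm = [AA_INDEX[a] for a in _PSIBLAST_ORDER]
    with open(path, "w") as fh:
        fh.write(
            "\nLast position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        letters = "  ".join(_PSIBLAST_ORDER)
        fh.write(f"            {letters}   {letters}\n")
        for j, row in enumerate(profile.matrix):
            with np.errstate(divide="ignore"):
                lods = np.rint(
                    2.0 * np.log2(np.maximum(row, 1e-9) / background)
                ).astype(int)
            scaled = 100.0 * row
            perc = np.floor(scaled).astype(int)
            shortfall = 100 - perc.sum()
            if shortfall > 0:
                top_up = np.argsort(-(scaled - perc), kind="stable")[:shortfall]
                perc[top_up] += 1
            fh.write(
                f"{j + 1:5d} {query.residues[j]} "
                + " ".join(f"{lods[i]:3d}" for i in perm)
                + "  "
                + " ".join(f"{perc[i]:3d}" for i in perm)
                + "  0.00 0.00\n"
            )
        fh.write("\n")


def generate_dataset(
    spec: SyntheticSpec,
    lam: int = DEFAULT_LAMBDA,
    omega: float = DEFAULT_OMEGA,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """End-to-end fixture: sequences -> profiles -> consensus -> features.

    Returns the feature matrix, +/-1 labels, and a manifest recording every
    parameter needed to regenerate the matrix bit-for-bit.
    """
    seqs, labels = generate_sequences(spec)
    profiles = generate_profiles(seqs, spec)
    consensus = [consensus_sequence(p) for p in profiles]
    X, ids = featurize_batch(consensus, lam=lam, omega=omega)
    manifest = {
        "spec": {**asdict(spec), "length_range": list(spec.length_range)},
        "lam": lam,
        "omega": omega,
        "n_features": X.shape[1],
        "ids": ids,
    }
    return X, labels, manifest


def write_dataset(
    out_dir: str | Path,
    spec: SyntheticSpec,
) -> dict:
    """Materialize a synthetic dataset on disk: FASTA, PSSM files, labels.

    Returns the manifest, which is also written as JSON.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seqs, labels = generate_sequences(spec)
    profiles = generate_profiles(seqs, spec)
    write_fasta(seqs, out_dir / "sequences.fasta")
    pssm_dir = out_dir / "profiles"
    pssm_dir.mkdir(exist_ok=True)
    for seq, prof in zip(seqs, profiles):
        write_pssm(prof, seq, pssm_dir / f"{seq.id}.pssm")
    with open(out_dir / "labels.tsv", "w") as fh:
        for seq, label in zip(seqs, labels):
            fh.write(f"{seq.id}\t{label}\n")
    manifest = {
        "spec": {**asdict(spec), "length_range": list(spec.length_range)},
        "n_sequences": len(seqs),
        "files": ["sequences.fasta", "profiles/", "labels.tsv"],
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
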