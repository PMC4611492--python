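"""Sequences, evolutionary frequency profiles, and the profile consensus.

A frequency profile is an ``L x 20`` row-stochastic matrix giving, for each
position of a protein, a probability distribution over the 20 standard amino
acids. Profiles come from three places:

* parsed from PSI-BLAST ASCII PSSM output (:func:`parse_psiblast_pssm`),
* observed column frequencies of a user-supplied multiple alignment
  (:func:`observed_profile`), optionally regularized with BLOSUM62
  pseudo-counts (:func:`apply_pseudocounts`), or
* synthetic (see :mod:`psepro.synthetic`).

The per-position argmax of the profile yields the profile consensus sequence
P' (:func:`consensus_sequence`), the carrier of evolutionary information that
downstream feature extraction operates on.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy.optimize import brentq

from .alphabet import AA_INDEX, ALPHABET, AMBIGUITY, AMINO_ACIDS, GAP_CHARS

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9

#: Column order used by PSI-BLAST ASCII PSSM files.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class Sequence:
    """A protein sequence over the 20 standard letters plus ``X``."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class ProfileSource(str, enum.Enum):
    OBSERVED = "observed"
    PSEUDO_COUNTED = "pseudo_counted"
    PARSED_PSSM = "parsed_pssm"
    SYNTHETIC = "synthetic"


@dataclass
class FrequencyProfile:
    """``L x 20`` row-stochastic matrix of per-position residue probabilities.

    Columns follow the canonical alphabetical order of
    :data:`psepro.alphabet.AMINO_ACIDS`.
    """

    seq_id: str
    matrix: np.ndarray
    source: ProfileSource

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(
                f"profile {self.seq_id!r}: expected shape (L, 20), "
                f"got {self.matrix.shape}"
            )
        if self.matrix.shape[0] < 1:
            raise ValueError(f"profile {self.seq_id!r}: L must be >= 1")
        if np.any(self.matrix < -1e-12) or np.any(self.matrix > 1 + 1e-12):
            raise ValueError(f"profile {self.seq_id!r}: entries outside [0, 1]")
        rowsum = self.matrix.sum(axis=1)
        if np.max(np.abs(rowsum - 1.0)) > ROW_SUM_TOL:
            worst = int(np.argmax(np.abs(rowsum - 1.0)))
            raise ValueError(
                f"profile {self.seq_id!r}: row {worst} sums to "
                f"{rowsum[worst]:.12f}, not 1"
            )

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ProfileSequence:
    """Consensus string P' of the most frequent residue at each position."""

    seq_id: str
    residues: str
    top_freqs: np.ndarray = field(compare=False)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SubstitutionModel:
    """Pair-frequency substitution model used for profile pseudo-counts.

    ``joint_freqs[i, k]`` is the joint probability q_ik of seeing residues i
    and k aligned; ``background[k]`` is the marginal background frequency p_k;
    ``beta`` weights the pseudo-count against the observed column counts.
    """

    joint_freqs: np.ndarray
    background: np.ndarray
    beta: float = 10.0

    def __post_init__(self) -> None:
        q = np.asarray(self.joint_freqs, dtype=float)
        p = np.asarray(self.background, dtype=float)
        if q.shape != (20, 20):
            raise ValueError("joint_freqs must be 20x20")
        if not np.allclose(q, q.T, atol=1e-12):
            raise ValueError("joint_freqs must be symmetric")
        if p.shape != (20,) or np.any(p <= 0):
            raise ValueError("background must be 20 positive frequencies")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("background frequencies must sum to 1")
        if np.max(np.abs(q.sum(axis=1) - p)) > 1e-3:
            raise ValueError("joint_freqs marginals must equal background")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        self.joint_freqs = q
        self.background = p


@lru_cache(maxsize=None)
def _blosum62_pair_frequencies() -> tuple[np.ndarray, np.ndarray, float]:
    """Derive (q, p, lambda) self-consistently from BLOSUM62 integer scores.

    A valid log-odds matrix S satisfies s_ij = ln(q_ij / (p_i p_j)) / lambda
    for a unique triple of target frequencies q, background p and scale
    lambda. Given lambda the marginal-consistency condition is linear,
    ``exp(lambda * S) @ p = 1``; lambda is then fixed by requiring the
    resulting p to sum to 1. This reconstructs target pair frequencies from
    the published integer scores without shipping a frequency table.
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    idx = [mat.alphabet.index(a) for a in AMINO_ACIDS]
    scores = np.array(mat)[np.ix_(idx, idx)]

    def background_for(lam: float) -> np.ndarray:
        return np.linalg.solve(np.exp(lam * scores), np.ones(20))

    lam = brentq(lambda s: background_for(s).sum() - 1.0, 0.1, 1.0, xtol=1e-14)
    p = background_for(lam)
    q = np.outer(p, p) * np.exp(lam * scores)
    q = (q + q.T) / 2.0  # remove last-bit asymmetry
    return q, p, lam


def blosum62_model(beta: float = 10.0) -> SubstitutionModel:
    """BLOSUM62 substitution model with pseudo-count weight ``beta``."""
    q, p, _ = _blosum62_pair_frequencies()
    return SubstitutionModel(joint_freqs=q.copy(), background=p.copy(), beta=beta)


# ---------------------------------------------------------------------------
# FASTA


def parse_fasta(path: str | Path) -> list[Sequence]:
    """Read a FASTA file into :class:`Sequence` records, order preserved.

    Residues are uppercased; any character outside the 21-letter alphabet is
    mapped to ``X`` with a logged warning.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    out: list[Sequence] = []
    for rec in records:
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        mapped = []
        replaced = set()
        for ch in residues:
            if ch in ALPHABET:
                mapped.append(ch)
            else:
                mapped.append(AMBIGUITY)
                replaced.add(ch)
        if replaced:
            logger.warning(
                "record %r: mapped non-standard characters %s to %s",
                rec.id, sorted(replaced), AMBIGUITY,
            )
        out.append(Sequence(id=rec.id, residues="".join(mapped)))
    return out


def write_fasta(seqs: list[Sequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM

_HEADER_RE = re.compile(r"^\s*(?:[A-Z]\s+){39}[A-Z]\s*$")


def parse_psiblast_pssm(path: str | Path) -> FrequencyProfile:
    """Parse a PSI-BLAST ASCII PSSM into a frequency profile.

    Only the second block (percentage of weighted observed frequencies) is
    used; it is divided by 100 and renormalized per row. An all-zero
    percentage row — emitted by PSI-BLAST for positions without alignment
    evidence — is replaced by a one-hot row on the query residue.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    for i, line in enumerate(lines):
        if _HEADER_RE.match(line):
            header_idx = i
            break
    if header_idx is None:
        raise ParseError(f"{path}: no PSSM column header line found")
    header_letters = lines[header_idx].split()
    file_order = header_letters[:20]
    if sorted(file_order) != sorted(AMINO_ACIDS):
        raise ParseError(
            f"{path}: line {header_idx + 1}: header does not name the 20 "
            "standard amino acids"
        )
    col_map = [file_order.index(a) for a in AMINO_ACIDS]

    rows: list[np.ndarray] = []
    query: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1:], start=header_idx + 2):
        stripped = line.strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if not tokens[0].isdigit():
            break  # trailing K/Lambda statistics block
        if len(tokens) < 42:
            raise ParseError(
                f"{path}: line {lineno}: expected position, residue and 40 "
                f"numeric columns, got {len(tokens)} fields"
            )
        pos, residue = int(tokens[0]), tokens[1]
        if pos != len(rows) + 1:
            raise ParseError(
                f"{path}: line {lineno}: position {pos} out of order"
            )
        try:
            perc = np.array([float(t) for t in tokens[22:42]])
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric cell ({exc})")
        rows.append(perc[col_map])
        query.append(residue.upper())

    if not rows:
        raise ParseError(f"{path}: no PSSM data rows found")

    matrix = np.vstack(rows) / 100.0
    for j, row in enumerate(matrix):
        total = row.sum()
        if total <= 0:
            res = query[j]
            if res not in AA_INDEX:
                raise ParseError(
                    f"{path}: all-zero row at position {j + 1} with "
                    f"non-standard query residue {res!r}"
                )
            onehot = np.zeros(20)
            onehot[AA_INDEX[res]] = 1.0
            matrix[j] = onehot
        else:
            matrix[j] = row / total

    return FrequencyProfile(
        seq_id=path.stem, matrix=matrix, source=ProfileSource.PARSED_PSSM
    )


# ---------------------------------------------------------------------------
# MSA-derived profiles


def observed_profile(msa: list[Sequence], seq_id: str | None = None) -> FrequencyProfile:
    """Observed column frequencies f_ij of a multiple alignment.

    Gaps and ambiguity symbols are excluded from the counts; frequencies are
    relative to the number of standard residues in the column.
    """
    if not msa:
        raise ValueError("MSA must contain at least one sequence")
    L = len(msa[0].residues)
    for s in msa:
        if len(s.residues) != L:
            raise ValueError(
                f"aligned sequences must have equal length: {s.id!r} has "
                f"{len(s.residues)}, expected {L}"
            )
    counts = np.zeros((L, 20))
    for s in msa:
        for j, ch in enumerate(s.residues):
            if ch in AA_INDEX:
                counts[j, AA_INDEX[ch]] += 1
    totals = counts.sum(axis=1)
    if np.any(totals == 0):
        bad = int(np.argmin(totals))
        raise ValueError(
            f"column {bad + 1} contains no standard residues (all gaps or "
            "ambiguity symbols)"
        )
    matrix = counts / totals[:, None]
    return FrequencyProfile(
        seq_id=seq_id if seq_id is not None else msa[0].id,
        matrix=matrix,
        source=ProfileSource.OBSERVED,
    )


def apply_pseudocounts(
    f: FrequencyProfile, model: SubstitutionModel
) -> FrequencyProfile:
    """Blend observed column frequencies with substitution-model pseudo-counts.

    For each column j with observed frequencies f_.j the pseudo-count target
    is ``g_ij = sum_k (f_kj / p_k) q_ik`` and the blended target frequency is

        m_ij = (alpha_j * f_ij + beta * g_ij) / (alpha_j + beta)

    where ``alpha_j`` is the number of distinct standard residues observed in
    the column minus one (the count of independent observations) and ``beta``
    weights the prior. Rows remain stochastic because the marginals of q
    equal the background p.
    """
    if f.source is not ProfileSource.OBSERVED:
        raise ValueError(
            f"pseudo-counts apply to observed profiles, got source "
            f"{f.source.value!r}"
        )
    p = model.background
    q = model.joint_freqs
    beta = model.beta
    F = f.matrix  # (L, 20)
    alpha = (F > 0).sum(axis=1).astype(float) - 1.0  # (L,)
    G = (F / p) @ q.T  # g_ij = sum_k q_ik f_kj / p_k
    M = (alpha[:, None] * F + beta * G) / (alpha[:, None] + beta)
    return FrequencyProfile(
        seq_id=f.seq_id, matrix=M, source=ProfileSource.PSEUDO_COUNTED
    )


# ---------------------------------------------------------------------------
# Consensus


def consensus_sequence(m: FrequencyProfile) -> ProfileSequence:
    """Profile consensus P': the most frequent residue at each position.

    Ties are broken by canonical alphabetical order (first wins), so the
    result is deterministic.
    """
    winners = np.argmax(m.matrix, axis=1)  # argmax takes the first maximum
    residues = "".join(AMINO_ACIDS[i] for i in winners)
    top = m.matrix[np.arange(len(m)), winners].copy()
    return ProfileSequence(seq_id=m.seq_id, residues=residues, top_freqs=top)


# ---------------------------------------------------------------------------
# Profile TSV round-trip


def write_profile_tsv(profile: FrequencyProfile, path: str | Path) -> None:
    """Write a profile as TSV with a header naming the canonical column order."""
    with open(path, "w") as fh:
        fh.write(f"# seq_id={profile.seq_id}\tsource={profile.source.value}\n")
        fh.write("pos\t" + "\t".join(AMINO_ACIDS) + "\n")
        for j, row in enumerate(profile.matrix, start=1):
            fh.write(str(j) + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def read_profile_tsv(path: str | Path) -> FrequencyProfile:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3 or not lines[0].startswith("#"):
        raise ParseError(f"{path}: not a profile TSV")
    meta = dict(kv.split("=", 1) for kv in lines[0][1:].strip().split("\t"))
    header = lines[1].split("\t")
    if header != ["pos"] + list(AMINO_ACIDS):
        raise ParseError(f"{path}: column header does not match canonical order")
    matrix = np.array(
        [[float(v) for v in ln.split("\t")[1:]] for ln in lines[2:] if ln.strip()]
    )
    return FrequencyProfile(
        seq_id=meta.get("seq_id", path.stem),
        matrix=matrix,
        source=ProfileSource(meta.get("source", "observed")),
    )
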