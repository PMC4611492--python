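"""Sequence/profile parsing, pseudo-counts and the profile consensus."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_pssm_text, random_sequence
from psepro import (
    FrequencyProfile,
    ProfileSource,
    Sequence,
    apply_pseudocounts,
    blosum62_model,
    consensus_sequence,
    observed_profile,
    parse_fasta,
    parse_psiblast_pssm,
    read_profile_tsv,
    write_profile_tsv,
)
from psepro.alphabet import AA_INDEX, AMINO_ACIDS
from psepro.profiles import ParseError


# ---------------------------------------------------------------------------
# FASTA


class TestParseFasta:
    def test_minimal_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">s\nACDE\n")
        seqs = parse_fasta(path)
        assert seqs == [Sequence(id="s", residues="ACDE")]

    def test_case_folding(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">s\nacde\n")
        assert parse_fasta(path)[0].residues == "ACDE"

    def test_nonstandard_characters_fold_to_ambiguity(self, tmp_path, caplog):
        path = tmp_path / "a.fasta"
        path.write_text(">s\nAC1E\n")
        with caplog.at_level("WARNING"):
            seqs = parse_fasta(path)
        assert seqs[0].residues == "ACXE"
        assert any("mapped" in rec.message for rec in caplog.records)

    def test_order_preserved_and_multiple_records(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">b\nAA\n>a\nCC\n")
        assert [s.id for s in parse_fasta(path)] == ["b", "a"]

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ParseError):
            parse_fasta(path)

    def test_empty_record_named_in_error(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">ghost\n>s\nACDE\n")
        with pytest.raises(ParseError, match="ghost"):
            parse_fasta(path)


# ---------------------------------------------------------------------------
# PSI-BLAST PSSM


class TestParsePssm:
    def test_percentages_scaled_to_probabilities(self, tmp_path):
        rows = np.zeros((3, 20))
        rows[0, AA_INDEX["A"]] = 100
        rows[1, AA_INDEX["C"]] = 100
        rows[2, AA_INDEX["A"]] = 50
        rows[2, AA_INDEX["C"]] = 50
        path = tmp_path / "q.pssm"
        path.write_text(make_pssm_text(rows, "ACA"))
        prof = parse_psiblast_pssm(path)
        assert prof.source is ProfileSource.PARSED_PSSM
        expected = rows / 100.0
        np.testing.assert_allclose(prof.matrix, expected, atol=1e-12)

    def test_all_zero_row_becomes_one_hot_on_query(self, tmp_path):
        rows = np.zeros((2, 20))
        rows[0, AA_INDEX["A"]] = 100
        path = tmp_path / "q.pssm"
        path.write_text(make_pssm_text(rows, "AD"))
        prof = parse_psiblast_pssm(path)
        onehot = np.zeros(20)
        onehot[AA_INDEX["D"]] = 1.0
        np.testing.assert_allclose(prof.matrix[1], onehot)

    def test_row_not_summing_to_100_renormalized(self, tmp_path):
        rows = np.zeros((1, 20))
        rows[0, AA_INDEX["A"]] = 66
        rows[0, AA_INDEX["R"]] = 33
        path = tmp_path / "q.pssm"
        path.write_text(make_pssm_text(rows, "A"))
        prof = parse_psiblast_pssm(path)
        assert prof.matrix[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert prof.matrix[0, AA_INDEX["A"]] == pytest.approx(66 / 99)

    def test_consensus_of_dominant_pssm_recovers_string(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = random_sequence(rng, 25)
        rows = np.full((25, 20), 1.0)
        for j, ch in enumerate(seq):
            rows[j, AA_INDEX[ch]] = 60.0
        path = tmp_path / "q.pssm"
        path.write_text(make_pssm_text(rows, seq))
        assert consensus_sequence(parse_psiblast_pssm(path)).residues == seq

    def test_non_numeric_cell_reports_line(self, tmp_path):
        rows = np.zeros((1, 20))
        rows[0, AA_INDEX["A"]] = 100
        text = make_pssm_text(rows, "A").replace("100", "1x0")
        path = tmp_path / "bad.pssm"
        path.write_text(text)
        with pytest.raises(ParseError, match="line 4"):
            parse_psiblast_pssm(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.pssm"
        path.write_text("not a pssm at all\n")
        with pytest.raises(ParseError, match="header"):
            parse_psiblast_pssm(path)

    def test_truncated_row_rejected(self, tmp_path):
        rows = np.zeros((1, 20))
        rows[0, AA_INDEX["A"]] = 100
        lines = make_pssm_text(rows, "A").splitlines()
        lines[3] = " ".join(lines[3].split()[:10])
        path = tmp_path / "bad.pssm"
        path.write_text("\n".join(lines))
        with pytest.raises(ParseError, match="line 4"):
            parse_psiblast_pssm(path)


# ---------------------------------------------------------------------------
# Observed profiles


class TestObservedProfile:
    def test_single_sequence_is_one_hot(self):
        prof = observed_profile([Sequence("s", "AR")])
        assert prof.source is ProfileSource.OBSERVED
        expected = np.zeros((2, 20))
        expected[0, AA_INDEX["A"]] = 1.0
        expected[1, AA_INDEX["R"]] = 1.0
        np.testing.assert_array_equal(prof.matrix, expected)

    def test_gaps_excluded_from_counts(self):
        msa = [Sequence("a", "AX"), Sequence("b", "AA"),
               Sequence("c", "RA"), Sequence("d", "XA")]
        # column 1 holds residues {A, A, R, X}: f_A = 2/3, f_R = 1/3
        prof = observed_profile(msa)
        assert prof.matrix[0, AA_INDEX["A"]] == pytest.approx(2 / 3)
        assert prof.matrix[0, AA_INDEX["R"]] == pytest.approx(1 / 3)

    def test_duplicated_rows_leave_profile_unchanged(self):
        one = observed_profile([Sequence("s", "ACDR")])
        two = observed_profile([Sequence("s", "ACDR"), Sequence("t", "ACDR")])
        np.testing.assert_array_equal(one.matrix, two.matrix)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            observed_profile([Sequence("a", "AC"), Sequence("b", "ACD")])

    def test_column_without_standard_residues_rejected(self):
        with pytest.raises(ValueError, match="column 2"):
            observed_profile([Sequence("a", "AX"), Sequence("b", "CX")])


# ---------------------------------------------------------------------------
# Pseudo-counts


def _observed_from_counts(counts: np.ndarray) -> FrequencyProfile:
    matrix = counts / counts.sum(axis=1, keepdims=True)
    return FrequencyProfile("t", matrix, ProfileSource.OBSERVED)


class TestApplyPseudocounts:
    def test_conserved_column_equals_pure_pseudocount(self, subst_model):
        # alpha = 0 for a single-residue column, so m reduces to g exactly
        prof = observed_profile([Sequence("s", "W")])
        out = apply_pseudocounts(prof, subst_model)
        q, p = subst_model.joint_freqs, subst_model.background
        g = q[:, AA_INDEX["W"]] / p[AA_INDEX["W"]]
        np.testing.assert_allclose(out.matrix[0], g, atol=1e-12)
        assert out.source is ProfileSource.PSEUDO_COUNTED

    def test_vanishing_beta_recovers_observed(self):
        model = blosum62_model(beta=1e-9)
        counts = np.zeros((1, 20))
        counts[0, AA_INDEX["A"]] = 3
        counts[0, AA_INDEX["R"]] = 1
        prof = _observed_from_counts(counts)
        out = apply_pseudocounts(prof, model)
        np.testing.assert_allclose(out.matrix, prof.matrix, atol=1e-8)

    def test_two_residue_column_matches_naive_formula(self, subst_model):
        # brute-force evaluation of the blending formula, scalar by scalar
        counts = np.zeros((1, 20))
        counts[0, AA_INDEX["D"]] = 2
        counts[0, AA_INDEX["E"]] = 2
        prof = _observed_from_counts(counts)
        out = apply_pseudocounts(prof, subst_model)
        q, p, beta = (subst_model.joint_freqs, subst_model.background,
                      subst_model.beta)
        alpha = 2 - 1
        expected = np.empty(20)
        for i in range(20):
            g = sum(prof.matrix[0, k] / p[k] * q[i, k] for k in range(20))
            expected[i] = (alpha * prof.matrix[0, i] + beta * g) / (alpha + beta)
        np.testing.assert_allclose(out.matrix[0], expected, atol=1e-12)

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_rows_remain_stochastic(self, subst_model, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 5, size=(8, 20)).astype(float)
        counts[counts.sum(axis=1) == 0, 0] = 1.0
        out = apply_pseudocounts(_observed_from_counts(counts), subst_model)
        np.testing.assert_allclose(out.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(out.matrix >= 0)

    def test_invariant_to_msa_row_order(self, subst_model):
        msa = [Sequence("a", "ACD"), Sequence("b", "ACE"), Sequence("c", "RCD")]
        fwd = apply_pseudocounts(observed_profile(msa), subst_model)
        rev = apply_pseudocounts(observed_profile(msa[::-1]), subst_model)
        np.testing.assert_allclose(fwd.matrix, rev.matrix, atol=1e-15)

    def test_requires_observed_source(self, subst_model):
        prof = FrequencyProfile(
            "s", np.full((1, 20), 0.05), ProfileSource.PARSED_PSSM
        )
        with pytest.raises(ValueError, match="observed"):
            apply_pseudocounts(prof, subst_model)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            blosum62_model(beta=0.0)


class TestSubstitutionModel:
    def test_blosum62_invariants(self, subst_model):
        q, p = subst_model.joint_freqs, subst_model.background
        np.testing.assert_allclose(q, q.T, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p > 0)
        np.testing.assert_allclose(q.sum(axis=1), p, atol=1e-3)
        assert q.sum() == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# Consensus


def _one_hot_profile(residues: str) -> FrequencyProfile:
    matrix = np.zeros((len(residues), 20))
    for j, ch in enumerate(residues):
        matrix[j, AA_INDEX[ch]] = 1.0
    return FrequencyProfile("s", matrix, ProfileSource.OBSERVED)


class TestConsensus:
    @given(st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_one_hot_identity(self, residues):
        assert consensus_sequence(_one_hot_profile(residues)).residues == residues

    def test_two_way_tie_broken_canonically(self):
        matrix = np.zeros((1, 20))
        matrix[0, AA_INDEX["A"]] = 0.5
        matrix[0, AA_INDEX["R"]] = 0.5
        prof = FrequencyProfile("s", matrix, ProfileSource.OBSERVED)
        out = consensus_sequence(prof)
        assert out.residues == "A"
        assert out.top_freqs[0] == pytest.approx(0.5)

    def test_five_way_tie_takes_first_canonical(self):
        matrix = np.zeros((1, 20))
        for ch in "GHKLM":
            matrix[0, AA_INDEX[ch]] = 0.2
        prof = FrequencyProfile("s", matrix, ProfileSource.OBSERVED)
        assert consensus_sequence(prof).residues == "G"

    def test_top_freqs_record_winning_probability(self):
        counts = np.zeros((1, 20))
        counts[0, AA_INDEX["A"]] = 3
        counts[0, AA_INDEX["R"]] = 1
        out = consensus_sequence(_observed_from_counts(counts))
        assert out.top_freqs[0] == pytest.approx(0.75)


# ---------------------------------------------------------------------------
# Profile TSV round-trip


def test_profile_tsv_round_trip(tmp_path, subst_model):
    msa = [Sequence("a", "ACDR"), Sequence("b", "ACER")]
    prof = apply_pseudocounts(observed_profile(msa), subst_model)
    path = tmp_path / "p.tsv"
    write_profile_tsv(prof, path)
    back = read_profile_tsv(path)
    assert back.seq_id == prof.seq_id
    assert back.source is prof.source
    np.testing.assert_allclose(back.matrix, prof.matrix, atol=1e-9)
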