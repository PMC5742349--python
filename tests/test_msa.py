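"""Alignment, conservation normalisation, logo matrices, reference maps."""

import math
import random

import numpy as np
import pytest

from _oracles import gotoh_global
from sweetsuite import msa, synthetic
from sweetsuite.records import ProteinRecord


def rec(acc, seq):
    return ProteinRecord(accession=acc, sequence=seq)


class TestAlign:
    def test_identical_sequences_align_gap_free(self):
        records = [rec(f"A{i}", "MKTAYIAKQRQISFVKSHFSRQ") for i in range(4)]
        aln = msa.align(records)
        assert aln.n_columns == 22
        assert len(set(aln.rows)) == 1
        assert "-" not in aln.rows[0]

    def test_zero_noise_family_gap_free(self, zero_noise_family):
        records, _ = zero_noise_family
        aln = msa.align(records)
        assert all("-" not in row for row in aln.rows)

    def test_ungapping_reproduces_inputs(self, two_family_records):
        records, _ = two_family_records
        aln = msa.align(records[:8] + records[10:14])
        for r in records[:8] + records[10:14]:
            assert aln.ungapped(r.accession) == r.sequence

    def test_two_sequence_score_matches_global_dp_oracle(self):
        rng = random.Random(1)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(60):
            a = "".join(rng.choice(aa) for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice(aa) for _ in range(rng.randint(1, 12)))
            mine = msa.global_alignment_score(a, b)
            assert mine == pytest.approx(gotoh_global(a, b), abs=1e-9)

    def test_single_record_warns_and_returns_trivial(self):
        with pytest.warns(UserWarning):
            aln = msa.align([rec("A", "MKL")])
        assert aln.rows == ["MKL"]

    def test_deterministic(self, two_family_records):
        records, _ = two_family_records
        a1 = msa.align(records[:6])
        a2 = msa.align(records[:6])
        assert a1.rows == a2.rows and a1.accessions == a2.accessions


class TestConservation:
    def test_invariant_column_scores_100(self):
        # column 3 invariant W; other columns maximally variable
        rows = ["AKWDE", "CRWFG", "DEWHI", "FGWKL"]
        aln = msa.MSA(accessions=list("abcd"), rows=rows)
        prof = msa.conservation(aln)
        assert prof.frame.loc[2, "relative_score"] == 100.0
        assert prof.frame["relative_score"].max() == 100.0

    def test_all_gap_column_scores_zero(self):
        aln = msa.MSA(accessions=list("ab"), rows=["A-C", "A-C"])
        prof = msa.conservation(aln)
        assert prof.frame.loc[1, "raw_score"] == 0.0
        assert prof.frame.loc[1, "gap_fraction"] == 1.0

    def test_max_relative_is_100_whenever_any_positive(self, two_family_records):
        records, _ = two_family_records
        aln = msa.align(records[:8])
        prof = msa.conservation(aln)
        assert prof.frame["relative_score"].max() == 100.0

    def test_gap_majority_columns_excluded_from_anchor(self):
        # column 1: W in 1 of 4 rows (75% gaps); column 2: invariant A
        rows = ["WA", "-A", "-A", "-A"]
        aln = msa.MSA(accessions=list("abcd"), rows=rows)
        prof = msa.conservation(aln)
        assert prof.frame.loc[1, "relative_score"] == 100.0

    def test_row_order_irrelevant(self):
        rows = ["AKWDE", "CRWFG", "DEWHI", "FGWKL"]
        aln1 = msa.MSA(accessions=list("abcd"), rows=rows)
        aln2 = msa.MSA(accessions=list("dcba"), rows=rows[::-1])
        p1 = msa.conservation(aln1).frame
        p2 = msa.conservation(aln2).frame
        assert np.allclose(p1["raw_score"], p2["raw_score"])

    def test_frequencies_sum_to_one_over_residues(self):
        rows = ["AK-", "AR-", "A-W"]
        aln = msa.MSA(accessions=list("abc"), rows=rows)
        prof = msa.conservation(aln)
        sums = prof.frequencies.sum(axis=1)
        assert sums[0] == pytest.approx(1.0)
        assert sums[1] == pytest.approx(1.0)
        assert sums[2] == pytest.approx(1.0)

    def test_planted_invariants_recovered_at_high_noise(self):
        # single family; planted invariant (tryptophan) columns should be the
        # top-scoring columns, with MSA columns mapped back to ancestral
        # coordinates through a reference row
        recalls = []
        for seed in range(5):
            scenario, templates = synthetic.demo_scenario(
                seed=100 + seed, n_families=1, seqs_per_family=25,
                substitution_rate=0.3, n_invariant=10, n_covarying=0,
            )
            records, truth = synthetic.generate(scenario, templates)
            aln = msa.align(records)
            prof = msa.conservation(aln)
            refmap = msa.map_reference(aln, records[0].accession)
            fam = truth.families.iloc[0]
            inv = {int(c) for c in fam["invariant_columns"].split(",")}
            rel = prof.frame.sort_values("relative_score", ascending=False)
            top_ancestral = set()
            for col in rel["column"]:
                if col in refmap.column_to_residue:
                    top_ancestral.add(refmap.column_to_residue[col])
                if len(top_ancestral) == len(inv):
                    break
            recalls.append(len(top_ancestral & inv) / len(inv))
        assert all(r >= 0.9 for r in recalls), recalls


class TestLogo:
    def test_uniform_column_has_zero_bits(self):
        rows = [a + "W" for a in "ACDEFGHIKLMNPQRSTVWY"]
        aln = msa.MSA(accessions=[f"s{i}" for i in range(20)], rows=rows)
        logo = msa.logo_matrix(aln)
        assert logo.loc[0, "information_bits"] == pytest.approx(0.0, abs=1e-12)

    def test_single_residue_column_has_log2_20_bits(self):
        rows = ["W", "W", "W"]
        aln = msa.MSA(accessions=list("abc"), rows=rows)
        logo = msa.logo_matrix(aln)
        assert logo.loc[0, "information_bits"] == pytest.approx(math.log2(20))
        assert logo.loc[0, "height_W"] == pytest.approx(math.log2(20))

    def test_fifty_fifty_column(self):
        rows = ["A", "A", "C", "C"]
        aln = msa.MSA(accessions=list("abcd"), rows=rows)
        logo = msa.logo_matrix(aln)
        expected = math.log2(20) - 1.0
        assert logo.loc[0, "information_bits"] == pytest.approx(expected)
        assert logo.loc[0, "height_A"] == pytest.approx(0.5 * expected)

    def test_bits_within_bounds(self, two_family_records):
        records, _ = two_family_records
        aln = msa.align(records[:6])
        logo = msa.logo_matrix(aln)
        assert (logo["information_bits"] >= -1e-12).all()
        assert (logo["information_bits"] <= math.log2(20) + 1e-12).all()


class TestReferenceMap:
    def test_gap_free_reference_is_identity(self):
        aln = msa.MSA(accessions=["r", "o"], rows=["AKW", "AR-"])
        m = msa.map_reference(aln, "r")
        assert m.column_to_residue == {1: 1, 2: 2, 3: 3}

    def test_gapped_reference_mapping(self):
        aln = msa.MSA(accessions=["r", "o"], rows=["A-C", "AKC"])
        m = msa.map_reference(aln, "r")
        assert m.column_to_residue == {1: 1, 3: 2}
        assert 2 not in m.column_to_residue

    def test_round_trip(self, two_family_records):
        records, _ = two_family_records
        aln = msa.align(records[:4] + records[10:12])
        m = msa.map_reference(aln, records[0].accession)
        for col, res in m.column_to_residue.items():
            assert m.residue_to_column[res] == col
        # strictly increasing
        cols = sorted(m.column_to_residue)
        residues = [m.column_to_residue[c] for c in cols]
        assert residues == sorted(residues)

    def test_missing_reference_rejected(self):
        aln = msa.MSA(accessions=["a"], rows=["AK"])
        with pytest.raises(ValueError):
            msa.map_reference(aln, "nope")
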