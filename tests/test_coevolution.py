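"""Mutual information, shuffle-null significance, edge classes, cMI/pMI."""

import itertools
import math
import random

import numpy as np
import pytest

from _oracles import mi_contingency
from sweetsuite import coevolution, msa, synthetic
from sweetsuite.coevolution import MIPair, StructureCoords
from sweetsuite.msa import MSA, ReferenceMap


def make_msa(columns: list[str]) -> MSA:
    """Build an MSA from per-column strings (rows = zip of columns)."""
    n_rows = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(n_rows)]
    return MSA(accessions=[f"s{i}" for i in range(n_rows)], rows=rows)


class TestMutualInformation:
    def test_constant_column_has_zero_mi(self):
        aln = make_msa(["AAAAAA", "ACDEFG"])
        pairs = coevolution.mutual_information(aln, pseudocount=0.0)
        assert pairs[0].mi_raw == pytest.approx(0.0, abs=1e-12)

    def test_perfect_binary_covariation_is_ln2(self):
        aln = make_msa(["EEKKEEKK", "KKEEKKEE"])
        pairs = coevolution.mutual_information(aln, pseudocount=0.0)
        assert pairs[0].mi_raw == pytest.approx(math.log(2))

    def test_matches_contingency_oracle_on_random_msas(self):
        rng = random.Random(3)
        aa = "ACDEFG-"
        for _ in range(50):
            cols = [
                "".join(rng.choice(aa) for _ in range(6)) for _ in range(4)
            ]
            aln = make_msa(cols)
            pairs = coevolution.mutual_information(
                aln, pseudocount=0.0, min_effective_rows=1
            )
            for p in pairs:
                col_a = "".join(r[p.col_a - 1] for r in aln.rows)
                col_b = "".join(r[p.col_b - 1] for r in aln.rows)
                assert p.mi_raw == pytest.approx(
                    mi_contingency(col_a, col_b), abs=1e-9
                )

    def test_symmetric_and_non_negative(self):
        rng = random.Random(5)
        cols = ["".join(rng.choice("ACDEFGHIK") for _ in range(12)) for _ in range(5)]
        aln = make_msa(cols)
        pairs = coevolution.mutual_information(aln)
        for p in pairs:
            assert p.mi_raw >= -1e-12
        # symmetry: swapping column roles is the same pair (a < b enforced)
        mi_map = {(p.col_a, p.col_b): p.mi_raw for p in pairs}
        assert set(mi_map) == set(itertools.combinations(range(1, 6), 2))

    def test_row_duplication_leaves_unweighted_mi_unchanged(self):
        aln = make_msa(["AACCGG".replace("G", "D"), "CKCKCK"])
        doubled = MSA(
            accessions=aln.accessions + [a + "x" for a in aln.accessions],
            rows=aln.rows + aln.rows,
        )
        p1 = coevolution.mutual_information(aln, pseudocount=0.0)[0].mi_raw
        p2 = coevolution.mutual_information(doubled, pseudocount=0.0)[0].mi_raw
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_low_coverage_pair_skipped(self):
        aln = make_msa(["A---AA", "CCCCCC"])
        pairs = coevolution.mutual_information(aln, min_effective_rows=5)
        assert pairs == []


class TestZScores:
    def test_same_seed_gives_identical_z(self):
        rng = random.Random(7)
        cols = ["".join(rng.choice("ACDE") for _ in range(20)) for _ in range(4)]
        aln = make_msa(cols)
        p1 = coevolution.mutual_information(aln)
        p2 = coevolution.mutual_information(aln)
        coevolution.mi_zscores(p1, aln, n_shuffles=30, seed=11)
        coevolution.mi_zscores(p2, aln, n_shuffles=30, seed=11)
        assert [p.mi_z for p in p1] == [p.mi_z for p in p2]

    def test_too_few_shuffles_rejected(self):
        aln = make_msa(["ACAC", "CACA"])
        pairs = coevolution.mutual_information(aln, min_effective_rows=1)
        with pytest.raises(ValueError):
            coevolution.mi_zscores(pairs, aln, n_shuffles=5)

    def test_independent_columns_rarely_significant(self):
        # 3 seeds x ~200 pairs of independent uniform columns
        exceed = total = 0
        for seed in range(3):
            rng = random.Random(seed)
            cols = [
                "".join(rng.choice("ACDEFGHIKL") for _ in range(30))
                for _ in range(21)
            ]
            aln = make_msa(cols)
            pairs = coevolution.mutual_information(aln)
            coevolution.mi_zscores(pairs, aln, n_shuffles=50, seed=seed)
            total += len(pairs)
            exceed += sum(1 for p in pairs if abs(p.mi_z) >= 6.5)
        assert total >= 600
        assert exceed / total < 0.01

    def test_planted_covarying_pairs_significant_across_seeds(self):
        for seed in range(5):
            scenario, templates = synthetic.demo_scenario(
                seed=200 + seed, n_families=1, seqs_per_family=50,
                substitution_rate=0.3, n_invariant=0, n_covarying=2,
            )
            records, _ = synthetic.generate(scenario, templates)
            aln = MSA(
                accessions=[r.accession for r in records],
                rows=[r.sequence for r in records],
            )
            planted = [
                (p.pos_a, p.pos_b) for p in scenario.covarying_pairs
            ]
            pairs = coevolution.mutual_information(aln, pairs=planted)
            coevolution.mi_zscores(pairs, aln, n_shuffles=100, seed=seed)
            for p in pairs:
                assert p.mi_z > 6.5, (seed, p)


class TestEdgeClasses:
    def make_pairs(self, n):
        return [
            MIPair(col_a=1, col_b=i + 2, mi_raw=float(n - i), mi_z=10.0)
            for i in range(n)
        ]

    def test_hundred_edges_split_5_25_70(self):
        ranked = coevolution.classify_edges(self.make_pairs(100))
        counts = {c: sum(1 for p in ranked if p.edge_class == c)
                  for c in ("red", "black", "gray")}
        assert counts == {"red": 5, "black": 25, "gray": 70}

    def test_single_edge_is_red(self):
        ranked = coevolution.classify_edges(self.make_pairs(1))
        assert ranked[0].edge_class == "red"

    def test_twenty_edges_split_1_5_14(self):
        ranked = coevolution.classify_edges(self.make_pairs(20))
        counts = {c: sum(1 for p in ranked if p.edge_class == c)
                  for c in ("red", "black", "gray")}
        assert counts == {"red": 1, "black": 5, "gray": 14}

    def test_classes_partition_and_red_is_ceiling(self):
        for n in (1, 2, 7, 19, 33, 100, 101):
            ranked = coevolution.classify_edges(self.make_pairs(n))
            n_red = sum(1 for p in ranked if p.edge_class == "red")
            assert n_red == math.ceil(0.05 * n)
            assert all(p.edge_class in ("red", "black", "gray") for p in ranked)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            coevolution.classify_edges([])


class TestCumulativeAndProximity:
    def test_no_significant_pairs_gives_zero_cmi(self):
        assert coevolution.cumulative_mi([], 5).tolist() == [0.0] * 5

    def test_single_pair_contributes_to_both_columns(self):
        cmi = coevolution.cumulative_mi(
            [MIPair(col_a=2, col_b=4, mi_raw=0.7)], 5
        )
        assert cmi.tolist() == [0.0, 0.7, 0.0, 0.7, 0.0]

    def test_star_pattern_sums(self):
        pairs = [
            MIPair(col_a=1, col_b=2, mi_raw=1.0),
            MIPair(col_a=1, col_b=3, mi_raw=2.0),
            MIPair(col_a=1, col_b=4, mi_raw=3.0),
        ]
        cmi = coevolution.cumulative_mi(pairs, 4)
        assert cmi[0] == pytest.approx(6.0)

    def _refmap(self, n):
        return ReferenceMap(
            reference="r",
            column_to_residue={i: i for i in range(1, n + 1)},
            residue_to_column={i: i for i in range(1, n + 1)},
        )

    def test_isolated_residue_has_zero_pmi(self):
        coords = StructureCoords(
            residues=(1, 2), coords=np.array([[0.0, 0, 0], [100.0, 0, 0]])
        )
        out = coevolution.proximity_mi(
            np.array([4.0, 1.0]), coords, self._refmap(2), radius_angstrom=5.0
        )
        assert out["pMI"].tolist() == [0.0, 0.0]

    def test_two_close_residues_swap_cmi(self):
        coords = StructureCoords(
            residues=(1, 2), coords=np.array([[0.0, 0, 0], [3.0, 0, 0]])
        )
        out = coevolution.proximity_mi(
            np.array([4.0, 0.0]), coords, self._refmap(2), radius_angstrom=5.0
        )
        assert out["pMI"].tolist() == [0.0, 4.0]

    def test_line_of_residues_matches_hand_computation(self):
        # residues at x = 0, 3, 6, 9, 12 with radius 5: neighbours are +-3
        coords = StructureCoords(
            residues=(1, 2, 3, 4, 5),
            coords=np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0],
                             [9.0, 0, 0], [12.0, 0, 0]]),
        )
        cmi = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = coevolution.proximity_mi(cmi, coords, self._refmap(5), 5.0)
        assert out["pMI"].tolist() == [2.0, 2.0, 3.0, 4.0, 4.0]
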