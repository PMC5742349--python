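"""Architecture classes, unit decomposition, fusion evidence."""

import numpy as np
import pytest

from sweetsuite import architecture, screen, synthetic
from sweetsuite.records import ProteinRecord
from sweetsuite.screen import TMHTopology


def topo_of(count, helix_len=20, loop=12):
    helices = []
    pos = loop + 1
    for _ in range(count):
        helices.append((pos, pos + helix_len - 1))
        pos += helix_len + loop
    return TMHTopology(helices=tuple(helices))


class TestClassify:
    @pytest.mark.parametrize(
        "count, expected",
        [
            (3, "semiSWEET"), (4, "semiSWEET"),
            (6, "SWEET"), (7, "SWEET"),
            (14, "extraSWEET"), (15, "extraSWEET"),
            (18, "superSWEET"), (23, "superSWEET"), (25, "superSWEET"),
            (0, "atypical"), (5, "atypical"), (10, "atypical"), (17, "atypical"),
        ],
    )
    def test_default_bins(self, count, expected):
        assert architecture.classify(count) == expected

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            architecture.classify(7, bins={"a": (3, 7), "b": (7, 8)})

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            architecture.classify(-1)


class TestDecompose:
    @pytest.mark.parametrize(
        "count, expected_types",
        [
            (3, ["triplet"]),
            (4, ["triplet", "linker"]),
            (7, ["triplet", "linker", "triplet"]),
            (15, ["triplet", "linker"] * 3 + ["triplet"]),
        ],
    )
    def test_canonical_plans(self, count, expected_types):
        n = 12 + count * 32 + 12
        units = architecture.decompose_units(topo_of(count), "A" * n)
        assert [u.unit_type for u in units] == expected_types

    def test_seven_tmh_indices(self):
        units = architecture.decompose_units(topo_of(7), "A" * 250)
        assert units[0].tmh_indices == (1, 2, 3)
        assert units[1].tmh_indices == (4,)
        assert units[2].tmh_indices == (5, 6, 7)

    @pytest.mark.parametrize("count", [3, 4, 5, 7, 8, 15, 18, 23, 25])
    def test_partition_properties(self, count):
        n = 12 + count * 32 + 12
        units = architecture.decompose_units(topo_of(count), "A" * n)
        # helix indices partition 1..count in order
        flat = [i for u in units for i in u.tmh_indices]
        assert flat == list(range(1, count + 1))
        # residue spans tile 1..n without overlap
        pos = 1
        for u in units:
            assert u.seq_span[0] == pos
            pos = u.seq_span[1] + 1
        assert pos == n + 1

    def test_greedy_25_has_unresolved_tail(self):
        units = architecture.decompose_units(topo_of(25), "A" * 850)
        types = [u.unit_type for u in units]
        assert types.count("triplet") == 6
        assert types.count("linker") == 5
        assert types[-1] == "unresolved"
        assert units[-1].tmh_indices == (24, 25)

    def test_zero_helices_rejected(self):
        with pytest.raises(ValueError):
            architecture.decompose_units(TMHTopology(helices=()), "AAAA")


class TestTruthRecovery:
    def test_zero_noise_class_and_boundaries_match_truth(self, templates):
        scenario = synthetic.EvolutionScenario(
            n_families=2, seqs_per_family=1, architecture_per_family=(7, 3),
            substitution_rate=0.0, seed=0,
        )
        records, truth = synthetic.generate(scenario, templates)
        for rec, row in zip(records, truth.sequences.itertuples(index=False)):
            topo = screen.predict_tmh(rec.sequence)
            call = architecture.call_architecture(rec.accession, topo, rec.sequence)
            assert call.arch_class == row.arch_class
            assert call.tmh_count == row.tmh_count
            truth_spans = [
                tuple(int(x) for x in span.split(":")[0].split("-"))
                for span in row.unit_boundaries.split(";")
            ]
            called = [u.seq_span for u in call.units]
            assert len(called) == len(truth_spans)
            # shared loop-midpoint convention: cuts agree to within the
            # hydropathy detector's (symmetric) edge margin
            for (ts, te), (cs, ce) in zip(truth_spans, called):
                assert abs(ts - cs) <= 2 and abs(te - ce) <= 2

    def test_low_noise_class_recovery_and_boundary_error(self, templates):
        scenario = synthetic.EvolutionScenario(
            n_families=1, seqs_per_family=20, architecture_per_family=(7,),
            substitution_rate=0.05, seed=13,
        )
        records, truth = synthetic.generate(scenario, templates)
        truth_spans = []
        for span in truth.sequences.iloc[0]["unit_boundaries"].split(";"):
            rng, _, label = span.partition(":")
            s, e = (int(x) for x in rng.split("-"))
            truth_spans.append((s, e, label.split(":")[0]))
        unit_truth = [sp for sp in truth_spans if sp[2] == "unit"]
        for rec in records:
            topo = screen.predict_tmh(rec.sequence)
            call = architecture.call_architecture(rec.accession, topo, rec.sequence)
            assert call.arch_class == "SWEET"
            called_units = [u for u in call.units if u.unit_type == "triplet"]
            assert len(called_units) == len(unit_truth)
            for (ts, te, _), u in zip(unit_truth, called_units):
                # interior boundaries within a few residues of the planted cut
                if ts > 1:
                    assert abs(u.seq_span[0] - ts) <= 3
                if te < len(rec.sequence):
                    assert abs(u.seq_span[1] - te) <= 3


class TestFusion:
    def test_duplicated_unit_detected_against_reference(self, templates):
        scenario = synthetic.EvolutionScenario(
            n_families=1, seqs_per_family=1, architecture_per_family=(7,),
            substitution_rate=0.05, seed=2,
        )
        records, _ = synthetic.generate(scenario, templates)
        rec = records[0]
        ref = ProteinRecord(accession="REF_U1", sequence=templates[0].sequence)
        topo = screen.predict_tmh(rec.sequence)
        call = architecture.call_architecture(rec.accession, topo, rec.sequence)
        evidence = architecture.detect_fusion(call, rec.sequence, [ref])
        assert len(evidence) == 2  # both triplet units scored
        for ev in evidence:
            assert ev.best_reference_accession == "REF_U1"
            assert ev.percent_identity >= 90.0
            assert ev.flagged

    def test_degenerate_zero_score_alignment_is_zero_identity(self):
        call = architecture.ArchitectureCall(
            accession="K", tmh_count=3, arch_class="semiSWEET",
            units=(architecture.UnitSpan("triplet", (1, 2, 3), (1, 40)),),
        )
        ref = ProteinRecord(accession="R", sequence="LLLLLLLLLL")
        evidence = architecture.detect_fusion(call, "K" * 40, [ref])
        assert evidence[0].percent_identity == 0.0
        assert not evidence[0].flagged

    def test_unrelated_units_not_flagged(self, templates):
        rng_seq = synthetic.make_templates(n_units=2, seed=99)
        call = architecture.ArchitectureCall(
            accession="X", tmh_count=3, arch_class="semiSWEET",
            units=(architecture.UnitSpan(
                "triplet", (1, 2, 3), (1, len(rng_seq[0].sequence))),),
        )
        ref = ProteinRecord(accession="R", sequence=rng_seq[1].sequence)
        evidence = architecture.detect_fusion(
            call, rng_seq[0].sequence, [ref], fusion_identity_threshold=70.0
        )
        assert evidence[0].percent_identity < 70.0
        assert not evidence[0].flagged

    def test_empty_reference_set_rejected(self):
        call = architecture.ArchitectureCall(
            accession="X", tmh_count=3, arch_class="semiSWEET", units=())
        with pytest.raises(ValueError):
            architecture.detect_fusion(call, "MKL", [])
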