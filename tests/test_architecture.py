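"""Architecture strings, repeat classes, purity, frequency report."""

import pytest

from screp.architecture import (COMBINATORIAL, NON_REPEAT, PURE,
                                build_architecture, domain_frequency_report,
                                parse_domain_string, repeat_purity)
from screp.seqio import DomainAnnotation, SequenceRecord


def ann(acc, type_id, start, stop, analysis="Pfam"):
    return DomainAnnotation(acc, analysis, type_id, f"{type_id} domain",
                            start, stop)


def record(length=200, acc="A"):
    return SequenceRecord(acc, ("CWKHEDRYGS" * 40)[:length])


class TestBuildArchitecture:
    def test_two_same_type_units_are_pure(self):
        arch = build_architecture(record(), [ann("A", "Kunitz", 5, 58),
                                             ann("A", "Kunitz", 70, 120)])
        assert arch.domain_string == "[AA]"
        assert arch.repeat_class == PURE

    def test_letters_assigned_by_first_appearance(self):
        arch = build_architecture(record(), [ann("A", "Lectin", 1, 40),
                                             ann("A", "Kunitz", 50, 100),
                                             ann("A", "Kunitz", 110, 160)])
        assert arch.domain_string == "[ABB]"
        assert arch.repeat_class == COMBINATORIAL

    def test_single_unit_is_non_repeat(self):
        arch = build_architecture(record(), [ann("A", "Kunitz", 5, 58)])
        assert arch.domain_string == "[A]"
        assert arch.repeat_class == NON_REPEAT
        assert arch.purity_pct is None

    def test_no_annotations_empty_architecture(self):
        arch = build_architecture(record(), [])
        assert arch.domain_string == "[]"
        assert arch.units == ()
        assert arch.repeat_class == NON_REPEAT

    def test_two_singleton_types_are_non_repeat(self):
        arch = build_architecture(record(), [ann("A", "Lectin", 1, 40),
                                             ann("A", "Kunitz", 50, 100)])
        assert arch.repeat_class == NON_REPEAT

    def test_linker_length_irrelevant_for_pure_class(self):
        for gap in (1, 50, 120):
            arch = build_architecture(
                record(length=200),
                [ann("A", "K", 1, 40), ann("A", "K", 40 + gap, 79 + gap)])
            assert arch.repeat_class == PURE

    def test_same_type_majority_overlap_merged(self):
        arch = build_architecture(record(), [ann("A", "K", 10, 60),
                                             ann("A", "K", 30, 80)])
        assert len(arch.units) == 1
        unit = arch.units[0]
        assert (unit.start, unit.stop) == (9, 80)  # merged union, internal coords

    def test_cross_type_majority_overlap_first_listed_wins(self):
        arch = build_architecture(record(), [ann("A", "K", 10, 60),
                                             ann("A", "L", 15, 55)])
        assert [u.type_id for u in arch.units] == ["K"]

    def test_small_overlap_keeps_both(self):
        arch = build_architecture(record(), [ann("A", "K", 10, 60),
                                             ann("A", "L", 55, 120)])
        assert [u.type_id for u in arch.units] == ["K", "L"]

    def test_interpro_id_preferred_as_type_identity(self):
        a1 = DomainAnnotation("A", "Pfam", "PF00014", "Kunitz", 5, 58,
                              interpro_id="IPR002223")
        a2 = DomainAnnotation("A", "SMART", "SM0131", "Kunitz", 70, 120,
                              interpro_id="IPR002223")
        arch = build_architecture(record(), [a1, a2])
        assert arch.repeat_class == PURE  # same InterPro id -> same type


class TestRepeatPurity:
    def test_identical_pair_is_100(self, scheme):
        arch = build_architecture(record(), [ann("A", "K", 1, 40),
                                             ann("A", "K", 51, 90)],
                                  scheme)
        rec = record()
        assert rec.sequence[0:40] == rec.sequence[50:90]
        assert arch.purity_pct == 100.0

    def test_three_identical_units_mean_of_three_pairs(self, scheme):
        arch = build_architecture(
            record(length=160),
            [ann("A", "K", 1, 40), ann("A", "K", 51, 90),
             ann("A", "K", 101, 140)], scheme)
        assert arch.purity_pct == 100.0

    def test_half_substituted_unit_purity_matches_hand_count(self, scheme):
        # units at 1..10 and 11..20; the optimal global alignment of the
        # two units is gapless, so purity equals the column-wise identity
        rec = SequenceRecord("A", "CWKHECWKHE" + "CAKHEGWKAE" + "A" * 10)
        arch = build_architecture(rec, [ann("A", "K", 1, 10),
                                        ann("A", "K", 11, 20)], scheme)
        u1, u2 = (u.sequence for u in arch.units)
        hand = 100.0 * sum(a == b for a, b in zip(u1, u2)) / 10
        assert arch.purity_pct == pytest.approx(hand)

    def test_purity_undefined_without_repeat(self, scheme):
        arch = build_architecture(record(), [ann("A", "K", 5, 58)])
        with pytest.raises(ValueError, match="purity undefined"):
            repeat_purity(arch, scheme)

    def test_purity_uses_most_copied_type(self, scheme):
        # B repeated twice (identical), A singleton: purity over B units
        rec = record(length=200)
        arch = build_architecture(rec, [ann("A", "Lec", 1, 30),
                                        ann("A", "K", 41, 80),
                                        ann("A", "K", 91, 130)], scheme)
        assert arch.repeat_class == COMBINATORIAL
        assert arch.purity_pct == 100.0


class TestDomainFrequencyReport:
    def test_two_proteins_two_copies_each(self):
        archs = [
            build_architecture(record(acc=a),
                               [ann(a, "Kunitz", 1, 40), ann(a, "Kunitz", 51, 90)])
            for a in ("A", "B")
        ]
        table = domain_frequency_report(archs)
        row = table.iloc[0]
        assert (row.domain_type, row.n_proteins,
                row.mean_copies_per_protein) == ("Kunitz", 2, 2.0)

    def test_combinatorial_counts_per_type(self):
        arch = build_architecture(record(), [ann("A", "A", 1, 30),
                                             ann("A", "B", 41, 70),
                                             ann("A", "B", 81, 110)])
        table = domain_frequency_report([arch]).set_index("domain_type")
        assert table.loc["A", "mean_copies_per_protein"] == 1.0
        assert table.loc["B", "mean_copies_per_protein"] == 2.0

    def test_mean_copies_at_least_one(self):
        archs = [build_architecture(record(acc=f"r{i}"),
                                    [ann(f"r{i}", f"T{i % 3}", 1, 30)])
                 for i in range(9)]
        table = domain_frequency_report(archs)
        assert (table.mean_copies_per_protein >= 1.0).all()


def test_domain_string_roundtrip():
    rec = record()
    arch = build_architecture(rec, [ann("A", "X", 1, 30), ann("A", "Y", 41, 70),
                                    ann("A", "Y", 81, 110)])
    assert parse_domain_string(arch.domain_string) == arch.letters == "ABB"
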