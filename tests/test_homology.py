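"""Homology screen: threshold gating, overlap and taxonomy reports."""

import math
import random

import pytest

from screp.homology import (HomologyConfig, overlap_report, screen,
                            taxonomy_overlap, write_hits_tsv)
from screp.seqio import SequenceRecord

from conftest import random_protein

TOXIN = "EDCIPKWKGCVNRHGDCCEGLECWKRRRSFEVCVPKTPKT"  # 40-aa knottin-like


def reference_set(rng, n=20):
    # one planted toxin plus 19 unrelated 208-mers: ~4000 residues total
    refs = [SequenceRecord("TOX0001", TOXIN)]
    for i in range(1, n):
        refs.append(SequenceRecord(f"TOX{i + 1:04d}",
                                   random_protein(rng, 208)))
    return refs


class TestScreen:
    def test_planted_copy_passes_with_derived_bit_score(self, rng, scheme):
        refs = reference_set(rng)
        flank = random_protein(rng, 20)
        query = SequenceRecord("Q1", flank + TOXIN + random_protein(rng, 20))
        hits = screen([query], refs, HomologyConfig())
        hit = next(h for h in hits if h.toxin_id == "TOX0001")
        assert hit.passes
        aln = hit.alignment
        # local score at least the gapless self-score of the planted copy
        assert aln.raw_score >= scheme.self_score(TOXIN)
        # statistics recomputed by hand from the raw score
        search_space = sum(len(r.sequence) for r in refs)
        expected_bits = (0.267 * aln.raw_score - math.log(0.041)) / math.log(2)
        assert aln.bit_score == pytest.approx(expected_bits, rel=1e-9)
        assert aln.evalue == pytest.approx(
            len(query.sequence) * search_space * 2 ** (-expected_bits), rel=1e-9)
        assert expected_bits > 35 and aln.evalue < 1e-6

    def test_shuffled_queries_never_pass(self, rng):
        refs = reference_set(rng)
        residues = list(TOXIN + random_protein(rng, 40))
        for _ in range(10):
            rng.shuffle(residues)
            query = SequenceRecord("SHUF", "".join(residues))
            hits = screen([query], refs, HomologyConfig())
            assert hits == []

    def test_self_hit_identity_100(self, rng):
        refs = reference_set(rng)
        hits = screen([SequenceRecord("Q", TOXIN)], refs, HomologyConfig())
        top = hits[0]
        assert top.toxin_id == "TOX0001"
        assert top.alignment.identity_pct == 100.0
        assert top.alignment.gap_openings == 0

    def test_bit_cutoff_gating_exact(self, rng):
        refs = reference_set(rng)
        query = SequenceRecord("Q", TOXIN)
        none = screen([query], refs, HomologyConfig(bit_cutoff=math.inf))
        assert none == []
        loose = screen([query], refs,
                       HomologyConfig(bit_cutoff=0.0, evalue_cutoff=1e-6))
        strict = screen([query], refs, HomologyConfig())
        assert {(h.screp_id, h.toxin_id) for h in strict} <= \
            {(h.screp_id, h.toxin_id) for h in loose}

    def test_score_symmetric_evalue_not(self, rng, scheme):
        a = SequenceRecord("A", TOXIN)
        b = SequenceRecord("B", TOXIN + random_protein(rng, 160))
        (fwd,) = screen([a], [b], HomologyConfig(bit_cutoff=0.0, evalue_cutoff=1e3),
                        keep_all=True)
        (rev,) = screen([b], [a], HomologyConfig(bit_cutoff=0.0, evalue_cutoff=1e3),
                        keep_all=True)
        assert fwd.alignment.raw_score == rev.alignment.raw_score
        # m*n differs: 40*200 vs 200*40 are equal, so construct unequal spaces
        (fwd2,) = screen([a], [b, b.__class__("B2", "W" * 100)],
                         HomologyConfig(bit_cutoff=0.0, evalue_cutoff=1e3),
                         keep_all=True)[:1]
        assert fwd2.alignment.evalue != fwd.alignment.evalue

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            screen([SequenceRecord("Q", TOXIN)], [], HomologyConfig())

    def test_output_sorted_and_deterministic(self, rng, tmp_path):
        refs = reference_set(rng)
        queries = [SequenceRecord("Q2", TOXIN), SequenceRecord("Q1", TOXIN)]
        hits = screen(queries, refs, HomologyConfig(), keep_all=True)
        keys = [(h.screp_id, h.alignment.evalue) for h in hits]
        grouped = [keys[i:i + len(refs)] for i in range(0, len(keys), len(refs))]
        for group in grouped:
            assert group == sorted(group)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_hits_tsv(hits, p1)
        write_hits_tsv(screen(queries, refs, HomologyConfig(), keep_all=True), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_best_hit_only_mode(self, rng):
        refs = reference_set(rng)
        query = SequenceRecord("Q", TOXIN)
        hits = screen([query], refs,
                      HomologyConfig(best_hit_only=True, bit_cutoff=0,
                                     evalue_cutoff=1e6), keep_all=True)
        assert len(hits) == 1 and hits[0].toxin_id == "TOX0001"


class TestOverlapReport:
    def test_disjoint_sets_empty(self):
        assert overlap_report([SequenceRecord("A", "CWKH")],
                              [SequenceRecord("B", "MNPQ")]) == []

    def test_shared_accession(self):
        pairs = overlap_report([SequenceRecord("A", "CWKH")],
                               [SequenceRecord("A", "CWKH")])
        assert pairs == [("A", "A")]

    def test_identical_sequence_distinct_accessions(self):
        pairs = overlap_report([SequenceRecord("A", "CWKH")],
                               [SequenceRecord("B", "CWKH")])
        assert pairs == [("A", "B")]


class TestTaxonomyOverlap:
    def hits(self, rng):
        refs = reference_set(rng)
        queries = [SequenceRecord(f"Q{i}", TOXIN) for i in range(3)]
        return screen(queries, refs, HomologyConfig())

    def test_single_shared_class(self, rng):
        hits = self.hits(rng)
        tax = {f"Q{i}": ("Arachnida",) for i in range(3)}
        table = taxonomy_overlap(hits, tax, {"TOX0001": ("Arachnida",)}, rank=0)
        assert len(table) == 1
        row = table.iloc[0]
        assert (row.taxon, row.n_screps, row.shared_with_reference) == \
            ("Arachnida", 3, True)

    def test_empty_hits_empty_table(self):
        assert len(taxonomy_overlap([], {}, {}, rank=0)) == 0

    def test_counts_sum_to_distinct_screps_and_missing_tax_bucketed(self, rng):
        hits = self.hits(rng)
        tax = {"Q0": ("Arachnida",), "Q1": ("Mammalia",)}  # Q2 unannotated
        table = taxonomy_overlap(hits, tax, {}, rank=0)
        assert table.n_screps.sum() == 3
        assert "unannotated" in set(table.taxon)
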