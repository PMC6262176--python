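"""Homology screening of candidates against a reference toxin set.

Every candidate mature sequence is locally aligned against every
reference sequence (all-vs-all, exact Smith-Waterman).  E-values use the
query length as ``m`` and the total residue count of the reference set
as the search space ``n``.  A hit passes when its E-value is at or below
``evalue_cutoff`` (default 1e-6, selecting moderate-to-high similarity)
AND its bit score strictly exceeds ``bit_cutoff`` (default 35 bits).
Both thresholds are applied jointly by default; each is independently
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import LocalAlignment, ScoringScheme, evalue, local_align
from .seqio import SequenceRecord

log = logging.getLogger(__name__)

__all__ = ["HomologyConfig", "HomologyHit", "screen", "overlap_report",
           "taxonomy_overlap", "write_hits_tsv"]


@dataclass
class HomologyConfig:
    evalue_cutoff: float = 1e-6
    bit_cutoff: float = 35.0  # strict >
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    best_hit_only: bool = False

    def __post_init__(self) -> None:
        if self.evalue_cutoff <= 0:
            raise ValueError("evalue_cutoff must be positive")
        if self.bit_cutoff < 0:
            raise ValueError("bit_cutoff must be non-negative")


@dataclass(frozen=True)
class HomologyHit:
    screp_id: str
    toxin_id: str
    alignment: LocalAlignment
    passes: bool


def screen(screps: Sequence[SequenceRecord],
           reference: Sequence[SequenceRecord],
           config: Optional[HomologyConfig] = None,
           keep_all: bool = False) -> list[HomologyHit]:
    """All-vs-all local alignment of candidates against the reference set.

    Returns hits sorted by (candidate id, ascending E-value, reference
    id).  By default only passing hits are returned; ``keep_all`` keeps
    every alignment with its pass flag.  ``best_hit_only`` restricts the
    output to each candidate's lowest-E-value hit.
    """
    config = config or HomologyConfig()
    if not reference:
        raise ValueError("empty reference set")
    if not screps:
        raise ValueError("empty candidate set")
    search_space = sum(len(r.sequence) for r in reference)
    hits: list[HomologyHit] = []
    for query in screps:
        per_query: list[HomologyHit] = []
        for subject in reference:
            aln = local_align(query.sequence, subject.sequence, config.scheme,
                              query_id=query.accession,
                              subject_id=subject.accession)
            bits, ev = evalue(aln.raw_score, len(query.sequence),
                              search_space, config.scheme)
            aln = LocalAlignment(
                aln.raw_score, bits, ev, aln.identity_pct, aln.n_identical,
                aln.length, aln.q_start, aln.q_end, aln.s_start, aln.s_end,
                aln.gap_openings, aln.query_id, aln.subject_id)
            passes = ev <= config.evalue_cutoff and bits > config.bit_cutoff
            if passes or keep_all:
                per_query.append(
                    HomologyHit(query.accession, subject.accession, aln, passes))
        per_query.sort(key=lambda h: (h.alignment.evalue, h.toxin_id))
        if config.best_hit_only and per_query:
            per_query = per_query[:1]
        hits.extend(per_query)
    return hits


def overlap_report(screps: Sequence[SequenceRecord],
                   reference: Sequence[SequenceRecord]) -> list[tuple[str, str]]:
    """Candidates already present in the reference set.

    Reports (candidate accession, reference accession) pairs for shared
    accessions and for byte-identical sequences filed under distinct
    accessions.
    """
    by_acc = {r.accession: r for r in reference}
    by_seq: dict[str, list[str]] = {}
    for r in reference:
        by_seq.setdefault(r.sequence, []).append(r.accession)
    pairs: list[tuple[str, str]] = []
    for rec in screps:
        if rec.accession in by_acc:
            pairs.append((rec.accession, rec.accession))
            continue
        for acc in by_seq.get(rec.sequence, ()):
            pairs.append((rec.accession, acc))
    return pairs


def taxonomy_overlap(hits: Sequence[HomologyHit],
                     screp_tax: Mapping[str, Sequence[str]],
                     ref_tax: Mapping[str, Sequence[str]],
                     rank: int = 0) -> pd.DataFrame:
    """Taxon counts of candidates with hits, flagged when the taxon also
    occurs in the reference set.

    ``rank`` indexes into the ordered lineage (0 = coarsest supplied
    level).  Candidates without taxonomy at that rank are tallied under
    ``unannotated``.  Counts sum to the number of distinct candidates
    with hits.
    """
    def taxon_at(lineage: Optional[Sequence[str]]) -> str:
        if lineage is None or rank >= len(lineage):
            return "unannotated"
        return lineage[rank]

    ref_taxa = {taxon_at(lin) for lin in ref_tax.values()}
    counts: dict[str, int] = {}
    for acc in sorted({h.screp_id for h in hits}):
        taxon = taxon_at(screp_tax.get(acc))
        counts[taxon] = counts.get(taxon, 0) + 1
    rows = [(taxon, n, taxon in ref_taxa)
            for taxon, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    return pd.DataFrame(rows, columns=["taxon", "n_screps",
                                       "shared_with_reference"])


def write_hits_tsv(hits: Iterable[HomologyHit], path) -> None:
    cols = ["screp_id", "toxin_id", "raw_score", "bit_score", "evalue",
            "identity_pct", "gap_openings", "q_start", "q_end",
            "s_start", "s_end", "passes"]
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for h in hits:
            a = h.alignment
            fh.write("\t".join(map(str, [
                h.screp_id, h.toxin_id, a.raw_score,
                f"{a.bit_score:.2f}", f"{a.evalue:.3g}",
                f"{a.identity_pct:.1f}", a.gap_openings,
                a.q_start, a.q_end, a.s_start, a.s_end, h.passes,
            ])) + "\n")
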