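"""The tandem-repeat detection scan (SCREPs Processing Algorithm).

A candidate mature sequence is first prefiltered on simple features:
length between ``min_len`` and ``max_len`` (inclusive; the lower bound
avoids short non-domain repetitive elements, the upper avoids large
multi-pass membrane proteins) and at least ``min_cys`` cysteines (two
disulfide-rich domains need at least one disulfide each, hence 4).

Each surviving sequence is then bisected at every multiple of ``step_n``
residues: the N-terminal prefix and C-terminal suffix at each division
site are locally aligned against each other.  A self-alignment raw score
strictly above ``strong_threshold`` at any division site calls the
sequence a strong tandem-repeat hit; a positive best score at or below
the threshold is a weak hit.  Both segments must be at least ``step_n``
residues, so degenerate stubs are never aligned.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .align import LocalAlignment, ScoringScheme, local_align
from .seqio import SequenceRecord, mature_sequence

log = logging.getLogger(__name__)

__all__ = ["SPAConfig", "SPAResult", "prefilter", "split_points", "scan",
           "run_spa", "write_spa_tsv"]

PASS = "pass"
TOO_SHORT = "too_short"
TOO_LONG = "too_long"
TOO_FEW_CYS = "too_few_cys"

STRONG = "strong"
WEAK = "weak"
NONE = "none"


@dataclass
class SPAConfig:
    """Scan parameters.

    step_n is the division-site increment in residues: a compromise
    between boundary resolution and the number of alignments per
    sequence.  strong_threshold applies to the raw BLOSUM62 local
    alignment score, strictly greater-than.
    """

    min_len: int = 20
    max_len: int = 500
    min_cys: int = 4
    step_n: int = 10
    strong_threshold: int = 30
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("require 0 < min_len <= max_len")
        if self.min_cys < 0 or self.step_n < 1 or self.strong_threshold < 0:
            raise ValueError("invalid SPA parameters")


@dataclass(frozen=True)
class SPAResult:
    """Per-sequence scan outcome.

    split_scores holds one (division site, raw score) pair per scanned
    site; division sites are 0-based indices into the mature sequence
    (the suffix starts at the site).  best_split is the site with the
    highest raw score, ties broken toward the smallest site.
    """

    accession: str
    mature_length: int
    cys_count: int
    filter_status: str
    split_scores: tuple[tuple[int, int], ...] = ()
    best_split: Optional[tuple[int, LocalAlignment]] = None
    call: str = NONE

    @property
    def best_score(self) -> int:
        return self.best_split[1].raw_score if self.best_split else 0


def prefilter(mature: str, config: SPAConfig) -> str:
    """Classify a mature sequence against the simple-feature filters.

    Length bounds are inclusive; selenocysteine (U) is not counted as
    cysteine.
    """
    if len(mature) < config.min_len:
        return TOO_SHORT
    if len(mature) > config.max_len:
        return TOO_LONG
    if mature.count("C") < config.min_cys:
        return TOO_FEW_CYS
    return PASS


def split_points(length: int, config: SPAConfig) -> list[int]:
    """Division sites: multiples of step_n leaving both segments >= step_n."""
    n = config.step_n
    return list(range(n, length - n + 1, n))


def scan(record: SequenceRecord, config: Optional[SPAConfig] = None) -> SPAResult:
    """Run the bisection scan on one record (sequence assumed mature).

    Prefilter failures are encoded in ``filter_status`` (call ``none``,
    no splits scored), never raised.
    """
    config = config or SPAConfig()
    seq = record.sequence
    cys = seq.count("C")
    status = prefilter(seq, config)
    if status != PASS:
        return SPAResult(record.accession, len(seq), cys, status)

    scores: list[tuple[int, int]] = []
    best: Optional[tuple[int, LocalAlignment]] = None
    for k in split_points(len(seq), config):
        aln = local_align(seq[:k], seq[k:], config.scheme,
                          query_id=f"{record.accession}:prefix@{k}",
                          subject_id=f"{record.accession}:suffix@{k}")
        scores.append((k, aln.raw_score))
        if best is None or aln.raw_score > best[1].raw_score:
            best = (k, aln)

    if best is None or best[1].raw_score == 0:
        call = NONE
    elif best[1].raw_score > config.strong_threshold:
        call = STRONG
    else:
        call = WEAK
    return SPAResult(record.accession, len(seq), cys, PASS,
                     tuple(scores), best, call)


def run_spa(records: Iterable[SequenceRecord],
            signal_map: Optional[Mapping[str, int]] = None,
            config: Optional[SPAConfig] = None) -> list[SPAResult]:
    """Trim signals and scan every record, in input order.

    ``signal_map`` (accession -> last signal residue, 1-based) overrides
    per-record annotations; records without either are treated as already
    mature, with a warning.  Per-record errors (e.g. a signal annotation
    leaving an empty mature sequence) skip the record with a warning.
    """
    config = config or SPAConfig()
    signal_map = signal_map or {}
    results: list[SPAResult] = []
    counts: Counter[str] = Counter()
    n_unannotated = 0
    for rec in records:
        try:
            if rec.accession in signal_map:
                rec = rec.with_signal_end(signal_map[rec.accession])
            elif rec.signal_end is None:
                n_unannotated += 1
            mature = mature_sequence(rec)
            result = scan(replace(rec, sequence=mature, signal_end=None), config)
        except ValueError as exc:
            log.warning("skipping %s: %s", rec.accession, exc)
            counts["skipped"] += 1
            continue
        counts[result.call if result.filter_status == PASS else result.filter_status] += 1
        results.append(result)
    if n_unannotated:
        log.warning("%d record(s) had no signal annotation; treated as "
                    "already mature", n_unannotated)
    log.info("scan complete: %s", dict(counts))
    return results


def write_spa_tsv(results: Iterable[SPAResult], path) -> None:
    """Write scan results as a tab-separated table with a '#' header."""
    cols = ["accession", "mature_length", "cys_count", "filter_status",
            "call", "best_split", "best_score", "n_splits_scored"]
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        for r in results:
            best_split = r.best_split[0] if r.best_split else ""
            fh.write("\t".join(map(str, [
                r.accession, r.mature_length, r.cys_count, r.filter_status,
                r.call, best_split, r.best_score, len(r.split_scores),
            ])) + "\n")
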