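"""Refinement of raw scan output.

Three independent operations clean the candidate set:

* cysteine-density profiling — percent cysteine on the mature sequence,
  binned for inspection (false positives such as heme-coordinating
  cytochrome c domains concentrate in the 2-3% density range);
* annotation-driven exclusion — candidates whose domain annotations match
  a configurable list of non-disulfide cysteine classes (by default
  cytochrome c and thioredoxin, whose cysteines coordinate heme or form a
  catalytic dithiol rather than structural disulfides) are removed;
* redundancy clustering — greedy incremental clustering at a high
  identity threshold (cd-hit semantics: identity = identical aligned
  columns over the length of the shorter sequence, threshold applied as
  >=), collapsing near-duplicates to one representative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .align import ScoringScheme, global_align
from .seqio import DomainAnnotation, SequenceRecord

log = logging.getLogger(__name__)

__all__ = ["RefineConfig", "Cluster", "cysteine_density", "density_histogram",
           "exclude_non_screps", "cluster_redundant"]


@dataclass
class RefineConfig:
    density_bin_width: float = 1.0
    exclusion_terms: tuple[str, ...] = ("cytochrome c", "thioredoxin")
    exclusion_ids: tuple[str, ...] = ()
    cluster_identity: float = 0.99

    def __post_init__(self) -> None:
        if self.density_bin_width <= 0:
            raise ValueError("density_bin_width must be positive")
        if not (0 < self.cluster_identity <= 1):
            raise ValueError("cluster_identity must be in (0, 1]")


@dataclass(frozen=True)
class Cluster:
    """One redundancy cluster: the longest member represents the rest."""

    representative: str
    members: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.members)


def cysteine_density(mature: str) -> float:
    """Percent of residues that are cysteine (selenocysteine excluded)."""
    if not mature:
        raise ValueError("empty sequence")
    return 100.0 * mature.count("C") / len(mature)


def density_histogram(records: Iterable[SequenceRecord],
                      config: Optional[RefineConfig] = None) -> pd.DataFrame:
    """Histogram of cysteine densities with half-open bins [k*w, (k+1)*w).

    Returns a table with columns ``bin_lower_pct`` and ``count``; counts
    sum to the number of input records.
    """
    config = config or RefineConfig()
    w = config.density_bin_width
    counts: dict[float, int] = {}
    for rec in records:
        lower = int(cysteine_density(rec.sequence) // w) * w
        counts[lower] = counts.get(lower, 0) + 1
    table = pd.DataFrame(
        sorted(counts.items()), columns=["bin_lower_pct", "count"]
    )
    return table


def _matches(ann: DomainAnnotation, config: RefineConfig) -> Optional[str]:
    for ident in config.exclusion_ids:
        if ident in (ann.signature_id, ann.interpro_id):
            return f"excluded id {ident} ({ann.signature_id})"
    for term in config.exclusion_terms:
        t = term.lower()
        if t in ann.signature_desc.lower() or t in ann.interpro_desc.lower():
            return f"matched term {term!r} ({ann.signature_id}: {ann.signature_desc})"
    return None


def exclude_non_screps(
    records: Sequence[SequenceRecord],
    annotations: Mapping[str, Sequence[DomainAnnotation]],
    config: Optional[RefineConfig] = None,
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Remove records whose annotations match an exclusion term or id.

    Matching is a case-insensitive substring test against the signature
    and InterPro descriptions, or an exact id match.  Records without
    annotations are kept (default-keep: absence of evidence is not
    treated as evidence of a non-candidate class).
    """
    config = config or RefineConfig()
    kept: list[SequenceRecord] = []
    removed: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        reason = None
        for ann in annotations.get(rec.accession, ()):
            reason = _matches(ann, config)
            if reason:
                break
        if reason:
            log.info("excluding %s: %s", rec.accession, reason)
            removed.append((rec, reason))
        else:
            kept.append(rec)
    return kept, removed


def _identity(a: SequenceRecord, b: SequenceRecord,
              scheme: ScoringScheme) -> float:
    """Fraction of identical aligned columns over the shorter length."""
    if a.sequence == b.sequence:
        return 1.0
    aln = global_align(a.sequence, b.sequence, scheme)
    return aln.n_identical / min(len(a.sequence), len(b.sequence))


def cluster_redundant(records: Sequence[SequenceRecord],
                      config: Optional[RefineConfig] = None,
                      scheme: Optional[ScoringScheme] = None) -> list[Cluster]:
    """Greedy incremental redundancy clustering.

    Sequences are visited longest first (ties: accession ascending); each
    joins the first existing cluster whose representative it matches at
    identity >= ``cluster_identity``, else founds a new cluster.  Because
    founders are the longest members, the representative of each cluster
    is its longest sequence.  Deterministic for fixed input.
    """
    config = config or RefineConfig()
    scheme = scheme or ScoringScheme()
    order = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    reps: list[SequenceRecord] = []
    members: list[list[str]] = []
    for rec in order:
        for i, rep in enumerate(reps):
            if _identity(rec, rep, scheme) >= config.cluster_identity:
                members[i].append(rec.accession)
                break
        else:
            reps.append(rec)
            members.append([rec.accession])
    return [Cluster(rep.accession, tuple(mem))
            for rep, mem in zip(reps, members)]
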