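"""Domain-architecture strings, repeat classes and repeat purity.

A protein's architecture is written as a bracketed letter string such as
``[AA]`` or ``[ABB]``: each distinct domain type gets a letter in order
of first appearance along the sequence.  A protein whose units all share
one type (and has at least two of them) is a *pure* domain repeat; a
protein with a repeated type plus at least one unit of another type is a
*combinatorial* domain repeat; anything else (zero or one unit, or
several singleton types) is a non-repeat.

*Repeat purity* is the mean pairwise global-alignment identity among the
units of the most-copied domain type — 100% for perfect copies,
degrading as the copies diverge.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import pandas as pd

from .align import ScoringScheme, global_align
from .seqio import DomainAnnotation, SequenceRecord, to_internal

__all__ = ["DomainUnit", "Architecture", "build_architecture",
           "repeat_purity", "domain_frequency_report", "parse_domain_string"]

PURE = "pure"
COMBINATORIAL = "combinatorial"
NON_REPEAT = "non_repeat"


@dataclass(frozen=True)
class DomainUnit:
    """One placed domain: type, letter, interval (0-based half-open), sequence."""

    type_id: str
    letter: str
    start: int
    stop: int
    sequence: str


@dataclass(frozen=True)
class Architecture:
    accession: str
    domain_string: str
    units: tuple[DomainUnit, ...]
    repeat_class: str
    purity_pct: Optional[float] = None

    @property
    def letters(self) -> str:
        return "".join(u.letter for u in self.units)


def _letters() -> Iterable[str]:
    for ch in string.ascii_uppercase:
        yield ch
    for a in string.ascii_uppercase:
        for b in string.ascii_uppercase:
            yield a + b


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _resolve(annotations: Sequence[DomainAnnotation]) -> list[tuple[str, int, int]]:
    """Resolve overlapping annotations into disjoint-enough units.

    Same-type annotations overlapping by more than half of the shorter
    interval are merged (union).  Across types the first-listed annotation
    wins and the later one is dropped.  Returns (type_id, start, stop)
    triples in 0-based half-open coordinates, sorted by start.
    """
    accepted: list[tuple[str, int, int]] = []
    for ann in annotations:
        start, stop = to_internal(ann.start, ann.stop)
        merged = False
        drop = False
        for i, (tid, s, e) in enumerate(accepted):
            ov = _overlap((start, stop), (s, e))
            shorter = min(stop - start, e - s)
            if ov * 2 <= shorter:
                continue
            if tid == ann.type_id:
                accepted[i] = (tid, min(s, start), max(e, stop))
                merged = True
            else:
                drop = True  # earlier-listed annotation of another type wins
            break
        if not merged and not drop:
            accepted.append((ann.type_id, start, stop))
    return sorted(accepted, key=lambda t: (t[1], t[2]))


def build_architecture(record: SequenceRecord,
                       annotations: Sequence[DomainAnnotation],
                       scheme: Optional[ScoringScheme] = None) -> Architecture:
    """Assemble the architecture of one record from its domain annotations.

    Domain type identity is the InterPro accession when present, else the
    signature accession.  If ``scheme`` is given and the record has a
    repeated type, ``purity_pct`` is filled in.
    """
    units: list[DomainUnit] = []
    letter_of: dict[str, str] = {}
    letters = _letters()
    for type_id, start, stop in _resolve(annotations):
        if type_id not in letter_of:
            letter_of[type_id] = next(letters)
        units.append(DomainUnit(type_id, letter_of[type_id], start, stop,
                                record.sequence[start:stop]))

    per_type: dict[str, int] = {}
    for u in units:
        per_type[u.type_id] = per_type.get(u.type_id, 0) + 1
    has_repeat = any(n >= 2 for n in per_type.values())
    if has_repeat and len(per_type) == 1:
        repeat_class = PURE
    elif has_repeat:
        repeat_class = COMBINATORIAL
    else:
        repeat_class = NON_REPEAT

    arch = Architecture(
        accession=record.accession,
        domain_string="[" + "".join(u.letter for u in units) + "]",
        units=tuple(units),
        repeat_class=repeat_class,
    )
    if scheme is not None and has_repeat:
        arch = Architecture(arch.accession, arch.domain_string, arch.units,
                            arch.repeat_class, repeat_purity(arch, scheme))
    return arch


def _repeated_type(arch: Architecture) -> Optional[str]:
    """The most-copied domain type; ties go to the type appearing first."""
    counts: dict[str, int] = {}
    first: dict[str, int] = {}
    for u in arch.units:
        counts[u.type_id] = counts.get(u.type_id, 0) + 1
        first.setdefault(u.type_id, u.start)
    best = None
    for tid, n in counts.items():
        if n < 2:
            continue
        if best is None or (n, -first[tid]) > (counts[best], -first[best]):
            best = tid
    return best


def repeat_purity(arch: Architecture,
                  scheme: Optional[ScoringScheme] = None) -> float:
    """Mean pairwise global-alignment identity among the repeated units.

    Computed over the most-copied domain type; identity counts identical
    columns over the full alignment length, gap columns included.  Raises
    when no type has two or more units.
    """
    scheme = scheme or ScoringScheme()
    tid = _repeated_type(arch)
    if tid is None:
        raise ValueError(f"{arch.accession}: purity undefined (no repeated type)")
    seqs = [u.sequence for u in arch.units if u.type_id == tid]
    idents = [global_align(a, b, scheme).identity_pct
              for a, b in combinations(seqs, 2)]
    return sum(idents) / len(idents)


def domain_frequency_report(architectures: Iterable[Architecture]) -> pd.DataFrame:
    """Per-domain-type frequency table.

    Columns: domain_type, n_proteins (proteins containing at least one
    unit of the type) and mean_copies_per_protein (mean copy number among
    those proteins), sorted by n_proteins descending then type id.
    """
    copies: dict[str, list[int]] = {}
    for arch in architectures:
        per_type: dict[str, int] = {}
        for u in arch.units:
            per_type[u.type_id] = per_type.get(u.type_id, 0) + 1
        for tid, n in per_type.items():
            copies.setdefault(tid, []).append(n)
    rows = [
        (tid, len(ns), sum(ns) / len(ns))
        for tid, ns in copies.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["domain_type", "n_proteins",
                                       "mean_copies_per_protein"])


def parse_domain_string(domain_string: str) -> str:
    """Recover the letter sequence from a bracketed architecture string."""
    if not (domain_string.startswith("[") and domain_string.endswith("]")):
        raise ValueError(f"malformed domain string: {domain_string!r}")
    return domain_string[1:-1]
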