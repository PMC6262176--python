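"""FASTA and annotation I/O, and signal-region trimming.

Sequence identifiers follow the UniProt convention: a header of the form
``>sp|ACC|NAME description`` (Swiss-Prot) or ``>tr|ACC|NAME description``
(TrEMBL) is parsed so that ``accession`` is the middle field; any other
header uses its first whitespace-delimited token.

Coordinate convention: every *external* coordinate (signal-region end,
domain start/stop) is 1-based inclusive, as in UniProt and InterProScan
output.  All *internal* interval arithmetic is 0-based half-open; the
converters live in this module only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "SequenceRecord",
    "DomainAnnotation",
    "read_fasta",
    "write_fasta",
    "read_signal_annotations",
    "mature_sequence",
    "is_fragment",
    "read_interproscan_tsv",
    "to_internal",
    "to_external",
]

# 20 canonical residues plus the ambiguity/rare codes tolerated on input.
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYXBZUO")


def to_internal(start: int, stop: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start - 1, stop


def to_external(start: int, stop: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, stop


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry.

    ``signal_end`` is the 1-based index of the LAST residue of the signal
    region, when known; the mature protein starts at ``signal_end + 1``.
    ``taxonomy`` is an ordered lineage (coarse to fine), when known.
    """

    accession: str
    sequence: str
    description: str = ""
    taxonomy: Optional[tuple[str, ...]] = None
    signal_end: Optional[int] = None
    reviewed: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.signal_end is not None:
            if self.signal_end < 1:
                raise ValueError(f"{self.accession}: signal_end must be >= 1")
            if self.signal_end >= len(self.sequence):
                raise ValueError(
                    f"{self.accession}: signal_end {self.signal_end} leaves an "
                    f"empty mature sequence (length {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def with_signal_end(self, signal_end: Optional[int]) -> "SequenceRecord":
        return replace(self, signal_end=signal_end)


@dataclass(frozen=True)
class DomainAnnotation:
    """One InterProScan match: a signature hit on a sequence region.

    ``start``/``stop`` are 1-based inclusive, as emitted by InterProScan.
    """

    accession: str
    analysis: str
    signature_id: str
    signature_desc: str
    start: int
    stop: int
    interpro_id: str = ""
    interpro_desc: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.stop):
            raise ValueError(
                f"{self.accession}: invalid interval {self.start}..{self.stop}"
            )

    @property
    def type_id(self) -> str:
        """Domain type identity: the InterPro accession when present,
        otherwise the member-database signature accession."""
        return self.interpro_id or self.signature_id


def _parse_header(header: str) -> tuple[str, str, Optional[bool]]:
    """Return (accession, description, reviewed) from a FASTA header line
    (without the leading '>')."""
    token, _, desc = header.partition(" ")
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1], desc.strip(), parts[0] == "sp"
    return token, desc.strip(), None


def _find_line(path: Path, bad_char: str) -> int:
    """Line number (1-based) of the first body line containing bad_char."""
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if not line.startswith(">") and bad_char in line.upper():
                return i
    return 0


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein FASTA file into an ordered list of records.

    Sequences are uppercased and internal whitespace removed.  ``*``
    (stop/translation artefact) is stripped with a warning; any other
    non-amino-acid character is an error.  Duplicate accessions are an
    error: accessions must be unique within a dataset.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        accession, desc, reviewed = _parse_header(rec.description)
        seq = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        if "*" in seq:
            log.warning("%s: stripping '*' characters from sequence", accession)
            seq = seq.replace("*", "")
        bad = set(seq) - VALID_RESIDUES
        if bad:
            ch = sorted(bad)[0]
            raise ValueError(
                f"{path}: non-amino-acid character {ch!r} in {accession} "
                f"(line {_find_line(path, ch)})"
            )
        if accession in seen:
            raise ValueError(f"{path}: duplicate accession {accession!r}")
        seen.add(accession)
        records.append(
            SequenceRecord(accession=accession, sequence=seq,
                           description=desc, reviewed=reviewed)
        )
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    """Write records as plain-header FASTA (``>accession description``)."""
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            header = rec.accession
            if rec.description:
                header += " " + rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


def is_fragment(record: SequenceRecord) -> bool:
    """Keyword-based fragment flag: the description mentions "Fragment".

    Database entries derived from partial sequencing are often marked
    this way; there is no sequence-intrinsic fragment test here.
    """
    return "fragment" in record.description.lower()


def read_signal_annotations(path) -> dict[str, int]:
    """Read a two-column TSV mapping accession -> signal-region end.

    The second column is the 1-based index of the last residue of the
    signal region.  A header line is detected by a non-numeric second
    column and skipped.  Lines starting with ``#`` are skipped.
    """
    path = Path(path)
    mapping: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            acc, raw = fields[0], fields[1]
            try:
                value = int(raw)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ValueError(
                    f"{path}:{lineno}: signal_end {raw!r} is not an integer"
                ) from None
            if value <= 0:
                raise ValueError(f"{path}:{lineno}: signal_end must be positive")
            mapping[acc] = value
    return mapping


def mature_sequence(record: SequenceRecord) -> str:
    """The sequence after removal of the signal region.

    Returns residues ``signal_end + 1 .. length`` (1-based inclusive) when
    a signal end is annotated, otherwise the full sequence unchanged.
    """
    if record.signal_end is None:
        return record.sequence
    if record.signal_end >= len(record.sequence):
        raise ValueError(f"{record.accession}: empty mature sequence")
    return record.sequence[record.signal_end:]


def read_interproscan_tsv(path) -> list[DomainAnnotation]:
    """Parse InterProScan tab-separated output.

    The standard dialect has >= 11 columns: protein accession, MD5, length,
    analysis, signature accession, signature description, start, stop,
    score, status, date, then optional InterPro accession and description.
    Rows without the InterPro columns get empty optional fields.
    """
    path = Path(path)
    annotations: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 11:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 11 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                start, stop = int(cols[6]), int(cols[7])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > stop:
                raise ValueError(f"{path}:{lineno}: start {start} > stop {stop}")
            annotations.append(
                DomainAnnotation(
                    accession=cols[0], analysis=cols[3],
                    signature_id=cols[4], signature_desc=cols[5],
                    start=start, stop=stop,
                    interpro_id=cols[11] if len(cols) > 11 and cols[11] != "-" else "",
                    interpro_desc=cols[12] if len(cols) > 12 and cols[12] != "-" else "",
                )
            )
    return annotations


def annotations_by_accession(
    annotations: Iterable[DomainAnnotation],
) -> dict[str, list[DomainAnnotation]]:
    """Group annotations by accession, sorted by (accession, start)."""
    grouped: dict[str, list[DomainAnnotation]] = {}
    for ann in annotations:
        grouped.setdefault(ann.accession, []).append(ann)
    return grouped
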