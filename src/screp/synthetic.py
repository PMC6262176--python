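"""Deterministic synthetic fixtures: repeat proteins and decoys.

The generator emulates the sequence layout of secreted multi-domain
disulfide-rich proteins: an optional hydrophobic signal prefix, then
``n_domains`` copies of one random disulfide-rich unit joined by short
low-complexity glycine/serine linkers.  Cysteines are pinned at fixed
within-domain offsets (six by default, a knottin-like scaffold); every
other position of each copy is substituted independently with
probability ``divergence``, so the expected pairwise divergence between
copies equals the configured value.

Decoys provide the matching negatives: ``shuffled`` permutes a generated
repeat protein (destroying the tandem structure while preserving length
and composition), ``cxxch_heme`` emulates heme-coordinating cytochrome
c-like sequences (~3% cysteine arranged as CxxCH motifs, no repeat), and
``low_cys`` carries only 2-3 cysteines and must fail the scan prefilter.

All construction is integer/choice-based on ``random.Random`` with
explicit seeds, so output is byte-identical across platforms and runs.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

from .seqio import SequenceRecord, write_fasta

log = logging.getLogger(__name__)

__all__ = ["SynthConfig", "SynthRecord", "make_screp", "make_decoy",
           "make_benchmark", "DIVERGENCE_GRID"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
NON_CYS = AMINO_ACIDS.replace("C", "")
HYDROPHOBIC = "AAILLLVVFFMWST"  # signal-peptide-biased residue pool

# Six-cysteine scaffold offsets within the default 35-residue unit.
DEFAULT_CYS_POSITIONS = (2, 7, 13, 20, 26, 32)

# Pairwise-divergence grid used by the shipped benchmark.
DIVERGENCE_GRID = (0.0, 0.1, 0.2, 0.3, 0.4)

SHUFFLED = "shuffled"
CXXCH_HEME = "cxxch_heme"
LOW_CYS = "low_cys"


@dataclass
class SynthConfig:
    seed: int = 0
    n_domains: int = 2
    domain_len: int = 35
    cys_positions: tuple[int, ...] = DEFAULT_CYS_POSITIONS
    divergence: float = 0.0
    linker_len: int = 5
    signal_len: int = 0
    decoy_kind: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.domain_len < 1:
            raise ValueError("need n_domains >= 1 and domain_len >= 1")
        if not all(0 <= p < self.domain_len for p in self.cys_positions):
            raise ValueError("cys_positions must lie within the domain")
        if not (0.0 <= self.divergence <= 1.0):
            raise ValueError("divergence must be in [0, 1]")
        if self.linker_len < 0 or self.signal_len < 0:
            raise ValueError("lengths must be non-negative")


@dataclass(frozen=True)
class SynthRecord:
    """A generated record plus its ground truth."""

    record: SequenceRecord
    true_splits: tuple[int, ...]   # 0-based mature index of each next unit
    true_architecture: str
    true_divergence: float

    @property
    def accession(self) -> str:
        return self.record.accession


def _unit(rng: random.Random, config: SynthConfig) -> list[str]:
    unit = [rng.choice(AMINO_ACIDS) for _ in range(config.domain_len)]
    for p in config.cys_positions:
        unit[p] = "C"
    return unit


def _diverge(unit: list[str], rng: random.Random, config: SynthConfig) -> list[str]:
    pinned = set(config.cys_positions)
    copy = list(unit)
    for i in range(len(copy)):
        if i in pinned:
            continue
        if rng.random() < config.divergence:
            copy[i] = rng.choice(NON_CYS.replace(copy[i], "") if copy[i] != "C"
                                 else NON_CYS)
    return copy


def make_screp(config: SynthConfig, accession: str = "SYN0001") -> SynthRecord:
    """Generate one multi-domain repeat protein with ground truth.

    Layout: [signal][unit][linker][unit]...[linker][unit].  The first
    domain is the master unit; later copies are divergence-substituted
    versions of it.  Layouts longer than 500 residues are allowed but
    logged (useful for exercising the upper length filter).
    """
    rng = random.Random(config.seed)
    master = _unit(rng, config)
    domains = [master] + [_diverge(master, rng, config)
                          for _ in range(config.n_domains - 1)]
    linkers = ["".join(rng.choice("GS") for _ in range(config.linker_len))
               for _ in range(config.n_domains - 1)]
    mature_parts: list[str] = []
    splits: list[int] = []
    pos = 0
    for i, dom in enumerate(domains):
        if i > 0:
            mature_parts.append(linkers[i - 1])
            pos += config.linker_len
            splits.append(pos)
        mature_parts.append("".join(dom))
        pos += config.domain_len
    mature = "".join(mature_parts)

    signal = ""
    signal_end = None
    if config.signal_len:
        signal = "M" + "".join(rng.choice(HYDROPHOBIC)
                               for _ in range(config.signal_len - 1))
        signal_end = config.signal_len
    sequence = signal + mature
    if len(sequence) > 500:
        log.warning("%s: generated layout exceeds 500 residues (%d)",
                    accession, len(sequence))
    record = SequenceRecord(accession=accession, sequence=sequence,
                            description="synthetic repeat protein",
                            signal_end=signal_end)
    return SynthRecord(record, tuple(splits), "[" + "A" * config.n_domains + "]",
                       config.divergence)


def make_decoy(config: SynthConfig, accession: str = "DEC0001") -> SynthRecord:
    """Generate one negative fixture of the configured ``decoy_kind``."""
    if config.decoy_kind is None:
        raise ValueError("decoy_kind must be set for make_decoy")
    rng = random.Random(config.seed ^ 0x5EED)
    if config.decoy_kind == SHUFFLED:
        base = make_screp(replace(config, decoy_kind=None, signal_len=0),
                          accession)
        residues = list(base.record.sequence)
        rng.shuffle(residues)
        record = replace(base.record, sequence="".join(residues),
                         description="shuffled decoy")
        return SynthRecord(record, (), "", config.divergence)
    if config.decoy_kind == CXXCH_HEME:
        length = 140
        seq = [rng.choice(NON_CYS) for _ in range(length)]
        for start in (20, 80):  # two CxxCH motifs -> 4 Cys, ~2.9% density
            seq[start] = "C"
            seq[start + 3] = "C"
            seq[start + 4] = "H"
        record = SequenceRecord(accession, "".join(seq),
                                description="cytochrome-c-like decoy")
        return SynthRecord(record, (), "", 0.0)
    if config.decoy_kind == LOW_CYS:
        length = 100
        seq = [rng.choice(NON_CYS) for _ in range(length)]
        for p in rng.sample(range(length), rng.choice((2, 3))):
            seq[p] = "C"
        record = SequenceRecord(accession, "".join(seq),
                                description="cysteine-poor decoy")
        return SynthRecord(record, (), "", 0.0)
    raise ValueError(f"unknown decoy_kind {config.decoy_kind!r}")


def _subseed(seed: int, salt: int, i: int) -> int:
    return (seed * 1_000_003 + salt * 7919 + i) % (2 ** 31)


def benchmark_records(seed: int, n_pos: int, n_neg: int,
                      signal_len: int = 18) -> list[SynthRecord]:
    """The mixed positive/negative fixture set behind ``make_benchmark``.

    Positives are two-domain repeat proteins with a signal prefix, their
    pairwise divergence cycling through ``DIVERGENCE_GRID``; negatives
    cycle through the three decoy kinds.
    """
    out: list[SynthRecord] = []
    for i in range(n_pos):
        cfg = SynthConfig(seed=_subseed(seed, 1, i),
                          divergence=DIVERGENCE_GRID[i % len(DIVERGENCE_GRID)],
                          signal_len=signal_len)
        out.append(make_screp(cfg, accession=f"SPOS{i + 1:04d}"))
    kinds = (SHUFFLED, CXXCH_HEME, LOW_CYS)
    for i in range(n_neg):
        cfg = SynthConfig(seed=_subseed(seed, 2, i),
                          decoy_kind=kinds[i % len(kinds)])
        out.append(make_decoy(cfg, accession=f"SNEG{i + 1:04d}"))
    return out


def make_benchmark(seed: int, n_pos: int, n_neg: int, out_dir) -> dict[str, Path]:
    """Write the benchmark fixture set to disk.

    Emits ``fixtures.fa`` (full sequences), ``signals.tsv`` (signal-region
    ends), ``truth.tsv`` (ground truth per record) and ``interpro.tsv``
    (a miniature InterProScan-style annotation table: one synthetic
    domain signature per generated unit, plus a cytochrome c signature on
    the heme-motif decoys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    synths = benchmark_records(seed, n_pos, n_neg)
    paths = {
        "fasta": out_dir / "fixtures.fa",
        "signals": out_dir / "signals.tsv",
        "truth": out_dir / "truth.tsv",
        "interpro": out_dir / "interpro.tsv",
    }
    write_fasta([s.record for s in synths], paths["fasta"])
    with open(paths["signals"], "w", newline="\n") as fh:
        fh.write("#accession\tsignal_end\n")
        for s in synths:
            if s.record.signal_end is not None:
                fh.write(f"{s.accession}\t{s.record.signal_end}\n")
    with open(paths["truth"], "w", newline="\n") as fh:
        fh.write("#accession\tkind\tdivergence\ttrue_splits\ttrue_architecture\n")
        for s in synths:
            kind = "positive" if s.true_architecture else s.record.description.split()[0]
            fh.write("\t".join([
                s.accession, kind, f"{s.true_divergence:g}",
                ";".join(map(str, s.true_splits)), s.true_architecture,
            ]) + "\n")
    with open(paths["interpro"], "w", newline="\n") as fh:
        for s in synths:
            fh.writelines(_interpro_rows(s))
    return paths


def _interpro_rows(s: SynthRecord) -> list[str]:
    """InterProScan-style rows (11+ columns) describing a fixture."""
    rec = s.record
    rows = []

    def row(sig_id: str, sig_desc: str, start: int, stop: int,
            ipr_id: str, ipr_desc: str) -> str:
        return "\t".join([
            rec.accession, "-", str(len(rec.sequence)), "SynthScan",
            sig_id, sig_desc, str(start), str(stop), "1e-10", "T",
            "2020-01-01", ipr_id, ipr_desc,
        ]) + "\n"

    if s.true_architecture:  # positive: one row per domain unit
        offset = rec.signal_end or 0
        mature_len = len(rec.sequence) - offset
        starts = [0, *s.true_splits]
        unit_len = mature_len - starts[-1]  # equal-length units by layout
        for start in starts:
            rows.append(row("SYNKNOT", "Knottin-like disulfide domain",
                            offset + start + 1, offset + start + unit_len,
                            "IPRSYN01", "Synthetic knottin-like domain"))
    elif rec.description.startswith("cytochrome"):
        rows.append(row("SYNCYTC", "Cytochrome c-like heme-binding domain",
                        10, len(rec.sequence) - 10,
                        "IPRSYN02", "Cytochrome c domain (synthetic)"))
    return rows
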