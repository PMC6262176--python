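"""End-to-end orchestration: scan -> refine -> architecture -> homology.

Stage order follows the discovery workflow: self-alignment scanning of
mature sequences, refinement of the strong hits only (annotation-driven
exclusion, then redundancy clustering), domain-architecture
characterization of the survivors, and an optional homology screen
against a reference toxin FASTA.  Every stage writes a tab-separated
table and contributes a sequence-count line to the run summary, so the
count flow through the pipeline is inspectable at a glance.

Logging goes to standard error; results only ever go to files.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Any, Mapping, Optional

from . import architecture as arch_mod
from . import homology as hom_mod
from . import refine as refine_mod
from . import spa as spa_mod
from .seqio import (annotations_by_accession, mature_sequence, read_fasta,
                    read_interproscan_tsv, read_signal_annotations,
                    write_fasta)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "report"]

_SECTIONS = {"io", "spa", "refine", "homology", "verbosity"}
_IO_KEYS = {"fasta", "signals", "interpro", "reference", "out_dir"}


class PipelineConfig:
    """Validated pipeline configuration.

    Built from a nested mapping (typically parsed YAML) with sections
    ``io``, ``spa``, ``refine`` and ``homology``; unknown keys are
    rejected, and all defaults are materialized so the resolved
    configuration can be echoed into the run log.
    """

    def __init__(self, raw: Mapping[str, Any]):
        unknown = set(raw) - _SECTIONS
        if unknown:
            raise ValueError(f"unknown config section(s): {sorted(unknown)}")
        io = dict(raw.get("io") or {})
        unknown = set(io) - _IO_KEYS
        if unknown:
            raise ValueError(f"unknown io key(s): {sorted(unknown)}")
        if "fasta" not in io:
            raise ValueError("io.fasta is required")
        self.fasta = Path(io["fasta"])
        self.signals = Path(io["signals"]) if io.get("signals") else None
        self.interpro = Path(io["interpro"]) if io.get("interpro") else None
        self.reference = Path(io["reference"]) if io.get("reference") else None
        self.out_dir = Path(io.get("out_dir", "screp_out"))
        self.spa = _build(spa_mod.SPAConfig, raw.get("spa"))
        self.refine = _build(refine_mod.RefineConfig, raw.get("refine"))
        self.homology = _build(hom_mod.HomologyConfig, raw.get("homology"))
        self.verbosity = str(raw.get("verbosity", "info"))

    def resolved(self) -> dict[str, Any]:
        return {
            "io": {"fasta": str(self.fasta),
                   "signals": str(self.signals) if self.signals else None,
                   "interpro": str(self.interpro) if self.interpro else None,
                   "reference": str(self.reference) if self.reference else None,
                   "out_dir": str(self.out_dir)},
            "spa": {k: v for k, v in vars(self.spa).items() if k != "scheme"},
            "refine": dict(vars(self.refine)),
            "homology": {k: v for k, v in vars(self.homology).items()
                         if k != "scheme"},
            "verbosity": self.verbosity,
        }


def _build(cls, section: Optional[Mapping[str, Any]]):
    section = dict(section or {})
    for key in section:
        if key not in cls.__dataclass_fields__:
            raise ValueError(f"unknown {cls.__name__} key: {key}")
        if isinstance(section[key], list):
            section[key] = tuple(section[key])
    return cls(**section)


class _Stage:
    """Renames this stage's outputs to ``*.partial`` if the stage fails."""

    def __init__(self, name: str):
        self.name = name
        self.files: list[Path] = []

    def path(self, out_dir: Path, name: str) -> Path:
        p = out_dir / name
        self.files.append(p)
        return p

    def fail(self) -> None:
        for p in self.files:
            if p.exists():
                p.rename(p.with_suffix(p.suffix + ".partial"))


def run_pipeline(config: PipelineConfig) -> dict[str, int]:
    """Run all stages; returns the per-stage sequence counts.

    Raises FileNotFoundError for missing inputs and RuntimeError (with
    partial outputs kept under a ``.partial`` suffix) on stage failure.
    """
    for path in (config.fasta, config.signals, config.interpro,
                 config.reference):
        if path is not None and not path.exists():
            raise FileNotFoundError(str(path))
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    records = read_fasta(config.fasta)
    signal_map = (read_signal_annotations(config.signals)
                  if config.signals else {})
    annotations = (annotations_by_accession(
        read_interproscan_tsv(config.interpro)) if config.interpro else {})
    counts["input"] = len(records)
    log.info("input: %d sequences", len(records))

    # --- scan ---------------------------------------------------------
    stage = _Stage("spa")
    try:
        results = spa_mod.run_spa(records, signal_map, config.spa)
        spa_mod.write_spa_tsv(results, stage.path(out, "spa.tsv"))
        strong = {r.accession for r in results if r.call == spa_mod.STRONG}
        by_acc = {r.accession: r for r in records}
        strong_mature = [
            replace(by_acc[acc],
                    sequence=mature_sequence(by_acc[acc].with_signal_end(
                        signal_map.get(acc, by_acc[acc].signal_end))),
                    signal_end=None)
            for acc in (r.accession for r in results if r.call == spa_mod.STRONG)
        ]
        write_fasta(strong_mature, stage.path(out, "spa_strong.fa"))
    except Exception:
        stage.fail()
        raise RuntimeError("scan stage failed")
    counts["spa_strong"] = len(strong_mature)
    log.info("scan: %d strong hit(s)", len(strong_mature))

    # --- refine (strong hits only) ------------------------------------
    stage = _Stage("refine")
    try:
        kept, removed = refine_mod.exclude_non_screps(
            strong_mature, annotations, config.refine)
        with open(stage.path(out, "removed.tsv"), "w", newline="\n") as fh:
            fh.write("#accession\treason\n")
            for rec, reason in removed:
                fh.write(f"{rec.accession}\t{reason}\n")
        hist = refine_mod.density_histogram(kept, config.refine)
        hist.to_csv(stage.path(out, "density_histogram.tsv"), sep="\t",
                    index=False, header=["#bin_lower_pct", "count"],
                    lineterminator="\n")
        clusters = refine_mod.cluster_redundant(kept, config.refine,
                                                config.spa.scheme)
        with open(stage.path(out, "clusters.tsv"), "w", newline="\n") as fh:
            fh.write("#representative\tmember\n")
            for cl in clusters:
                for member in cl.members:
                    fh.write(f"{cl.representative}\t{member}\n")
        kept_by_acc = {r.accession: r for r in kept}
        refined = [kept_by_acc[cl.representative] for cl in clusters]
        write_fasta(refined, stage.path(out, "refined.fa"))
    except Exception:
        stage.fail()
        raise RuntimeError("refine stage failed")
    counts["after_exclusion"] = len(kept)
    counts["non_redundant"] = len(refined)
    log.info("refine: %d after exclusion, %d non-redundant clusters",
             len(kept), len(refined))

    # --- architecture -------------------------------------------------
    stage = _Stage("architecture")
    try:
        by_acc = {r.accession: r for r in records}
        archs = [
            arch_mod.build_architecture(by_acc[rec.accession],
                                        annotations.get(rec.accession, ()),
                                        config.spa.scheme)
            for rec in refined
        ]
        with open(stage.path(out, "architecture.tsv"), "w", newline="\n") as fh:
            fh.write("#accession\tdomain_string\trepeat_class\tn_units\tpurity_pct\n")
            for a in archs:
                purity = f"{a.purity_pct:.1f}" if a.purity_pct is not None else ""
                fh.write(f"{a.accession}\t{a.domain_string}\t{a.repeat_class}"
                         f"\t{len(a.units)}\t{purity}\n")
        freq = arch_mod.domain_frequency_report(archs)
        freq.to_csv(stage.path(out, "domain_frequency.tsv"), sep="\t",
                    index=False,
                    header=["#domain_type", "n_proteins",
                            "mean_copies_per_protein"],
                    lineterminator="\n")
    except Exception:
        stage.fail()
        raise RuntimeError("architecture stage failed")
    counts["architectures"] = len(archs)

    # --- homology screen (optional) -----------------------------------
    if config.reference is not None:
        stage = _Stage("homology")
        try:
            reference = read_fasta(config.reference)
            hits = hom_mod.screen(refined, reference, config.homology)
            hom_mod.write_hits_tsv(hits, stage.path(out, "hits.tsv"))
            overlap = hom_mod.overlap_report(refined, reference)
            with open(stage.path(out, "overlap.tsv"), "w", newline="\n") as fh:
                fh.write("#screp_id\treference_id\n")
                for a, b in overlap:
                    fh.write(f"{a}\t{b}\n")
        except Exception:
            stage.fail()
            raise RuntimeError("homology stage failed")
        counts["homology_hits"] = len(hits)
        counts["reference_overlap"] = len(overlap)
        log.info("homology: %d passing hit(s)", len(hits))

    with open(out / "counts.tsv", "w", newline="\n") as fh:
        fh.write("#stage\tcount\n")
        for k, v in counts.items():
            fh.write(f"{k}\t{v}\n")
    return counts


def report(out_dir) -> str:
    """Plain-text run report summarizing the stage outputs in out_dir.

    Missing stage files are listed as absent, not fatal.
    """
    out_dir = Path(out_dir)
    lines = [f"run report: {out_dir}"]
    for name in ("counts.tsv", "spa.tsv", "removed.tsv", "clusters.tsv",
                 "density_histogram.tsv", "architecture.tsv",
                 "domain_frequency.tsv", "hits.tsv", "overlap.tsv"):
        path = out_dir / name
        if not path.exists():
            lines.append(f"  {name}: absent")
            continue
        with open(path) as fh:
            n = sum(1 for line in fh if line.strip() and not line.startswith("#"))
        if name == "hits.tsv" and n == 0:
            lines.append(f"  {name}: zero hits")
        else:
            lines.append(f"  {name}: {n} row(s)")
    return "\n".join(lines)
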