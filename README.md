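# screp

Mining **secreted cysteine-rich repeat proteins (SCREPs)** from protein
sequence data.

Peptide toxins built from *two or more* disulfide-rich domains in tandem
(double-knot toxins, double-Kunitz protease inhibitors, and relatives)
show unusual pharmacology: each domain can engage its receptor
independently, and the tethered pair binds with very high avidity. Such
tandem-repeat architectures are hard to find by annotation alone because
most entries in sequence databases carry no structural information.
`screp` implements a sequence-only discovery workflow for this protein
class, aimed at venom/toxin researchers and anyone mining proteomes for
multivalent disulfide-rich ligands:

1. **Tandem-repeat scan.** Each mature sequence (signal region removed)
   is prefiltered on simple features — length 20–500 residues inclusive,
   at least 4 cysteines — then bisected at every multiple of *n* = 10
   residues. The N-terminal prefix and C-terminal suffix at each
   division site are aligned with exact Smith–Waterman local alignment
   (BLOSUM62, affine gaps 11/1). A raw score > 30 at any site calls a
   **strong** tandem-repeat hit; the peak position estimates the
   inter-domain boundary.
2. **Refinement.** Cysteine-density profiling (density = %C of the
   mature sequence), annotation-driven exclusion of cysteine-rich
   *non*-disulfide classes (cytochrome c, thioredoxin — their cysteines
   coordinate heme or form catalytic dithiols), and greedy incremental
   clustering at ≥ 99% identity (cd-hit semantics: identical columns /
   shorter sequence length) to remove redundancy.
3. **Architecture.** Domain annotations (InterProScan TSV) become
   bracketed architecture strings — `[AA]` pure repeat, `[ABB]`
   combinatorial repeat — and **repeat purity**, the mean pairwise
   global-alignment identity among the repeated units.
4. **Homology screen.** All-vs-all local alignment of candidates against
   a reference toxin FASTA with Karlin–Altschul statistics:
   `bits = (λ·S − ln K)/ln 2`, `E = m·n·2^(−bits)` with λ = 0.267,
   K = 0.041 (gapped BLOSUM62-11/1). Hits pass at E ≤ 10⁻⁶ **and**
   bit score > 35.

A deterministic synthetic generator (`screp.synthetic`) produces
repeat-protein positives with controlled inter-domain divergence and
three decoy classes, so the whole workflow is testable without any
database download.

## Worked example

```bash
python examples/01_scan_tandem_repeats.py
```

```
sequence (75 aa):
  EACIIFECDWQCACHITYAVCVQIRWCAGQMKCHMGGSSSEACIIFTCDWQCACHITYLVCVQIRWCAGQMKCHH
true inter-domain boundary: 40

division site -> self-alignment raw score (BLOSUM62):
   10    57
   20   111
   30   173
   40   200 <- best
   50   143
   60    89

call: strong (raw score 200 > 30 marks a strong tandem-repeat hit)
```

The fixture is two 35-residue knottin-like domains (six pinned
cysteines each, 10% divergence between copies) joined by a `GS` linker.
The self-alignment score profile peaks exactly at the true boundary
(position 40): there the prefix contains one complete domain copy and
the suffix the other, so the cross-copy alignment is complete; earlier
or later cuts can only align partial copies and score lower.

The other examples cover refinement (`02`), architecture strings and
purity (`03`), the homology screen with hand-checkable statistics
(`04`), and the full pipeline with its count flow (`05`). The `screp`
command exposes the same stages for shell use (`screp --help`;
subcommands `synth`, `spa`, `refine`, `arch`, `screen`, `report`,
`pipeline`).

## Working with real data

The toolkit consumes standard inputs: UniProt-style FASTA
(`sp|ACC|NAME` / `tr|ACC|NAME` headers), two-column TSV signal-cleavage
annotations (accession, last residue of the signal region — e.g. from a
SignalP run), InterProScan TSV domain output, and any reference toxin
FASTA. A Tox-Prot-style reference can be exported from UniProt with the
animal-toxin annotation query; an ion-channel-impairing subset can be
built by keyword search ("toxin" or "venom", reviewed Metazoa, with
experimentally supported ion-channel-impairing annotation). Sequences
without signal annotations are treated as already mature, with a logged
warning.
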