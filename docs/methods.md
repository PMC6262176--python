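# Methods

## The detection model

The scan targets proteins made of two or more homologous disulfide-rich
domains in tandem. Its core assumption is that a tandem repeat leaves a
detectable self-similarity signal in the primary sequence: if a mature
sequence is cut between two repeat copies, the prefix and suffix share a
full domain copy, and their optimal local alignment scores far above the
chance level. The scan therefore bisects each sequence at every multiple
of the step *n* and locally aligns the two segments; the peak of the
score profile estimates the inter-domain boundary. Divided sequences are
the full prefix and full suffix at each site (not sliding windows), and
both segments must be at least *n* residues, so 1–9-residue stubs are
never aligned. A strong hit at *any* division site suffices; scores are
not length-normalized.

Prefiltering encodes the biology of the target class: mature length
20–500 (inclusive at both bounds — shorter sequences risk matching
non-domain repetitive elements, longer ones are dominated by large
multi-pass proteins), and ≥ 4 cysteines (two disulfide-rich domains need
at least one disulfide each). Selenocysteine (U) is never counted as
cysteine and is scored as X in alignments (BLOSUM62 has no U column).
Filters apply to the mature sequence, after signal removal.

Signal regions are consumed as annotations (two-column TSV, 1-based last
signal residue), never predicted; unannotated sequences are treated as
already mature with a logged warning. All external coordinates are
1-based inclusive (UniProt/InterProScan convention); internal interval
arithmetic is 0-based half-open, with the converters confined to the I/O
module.

## Alignment and statistics

Pairwise alignment is exact Smith–Waterman (local) / Needleman–Wunsch
(global) under BLOSUM62 with affine gap costs: a gap of length *g* costs
`gap_open + g·gap_extend` = 11 + *g*. The engine is Biopython's
`PairwiseAligner`; scores are therefore optimal and deterministic, and
never lower than a heuristic (seeded) search would report — the raw- and
bit-score thresholds are applied to exact scores, a documented
divergence from heuristic-search behaviour. Co-optimal tracebacks are
resolved by the aligner's deterministic first-traceback order, so
repeated runs are byte-identical; the test suite verifies exactness
against two independent oracles (exhaustive enumeration for short
strings, a plain-Python Gotoh DP for longer ones). A local score of 0 is
reported as an empty alignment.

Bit scores and E-values use the Karlin–Altschul formulas
`bits = (λS − ln K)/ln 2` and `E = m·n·2^(−bits)` with the published
gapped BLOSUM62-11/1 constants λ = 0.267, K = 0.041; `m` is the query
length and `n` the total residue count of the search space (the
reference set, for the homology screen). No composition-based score
adjustment and no edge-effect length correction are applied — a
simplicity/reproducibility trade-off that makes E-values slightly
conservative for short queries.

### Threshold interpretation

The strong/weak call threshold (> 30, strictly; a best score of exactly
30, or any positive score up to 30, is weak; 0 is no call) is applied to
the **raw** BLOSUM62 score, since the scan's scoring is defined directly
in matrix units. Under the Karlin–Altschul constants above, raw 30
corresponds to about 16.2 bits — a permissive threshold whose false
positives are expected to be removed downstream; that is precisely the
refinement stage's job (see "What the generator shows" below). The
homology screen's bit threshold (> 35) and E-value cutoff (≤ 10⁻⁶) are
applied jointly — the stricter reading — with each independently
configurable.

## Refinement

Cysteine density is 100·#C/length of the mature sequence, binned into
half-open `[k·w, (k+1)·w)` bins (default width 1 percentage point).
Density is descriptive, not a filter: exclusion is annotation-driven.
A candidate is removed iff any of its domain annotations matches an
exclusion term (case-insensitive substring on the signature or InterPro
description; defaults: "cytochrome c", "thioredoxin", the two classes
whose cysteines serve heme coordination or catalysis rather than
structural disulfides) or an exclusion id (exact match). Unannotated
candidates are kept: absence of annotation is not treated as evidence of
a non-candidate class.

Redundancy clustering re-implements the greedy incremental scheme of
cd-hit at desk scale: sequences visited longest-first (ties: accession
ascending), each compared only against existing cluster representatives,
joining the first representative matched at identity ≥ 0.99, where
identity = identical aligned columns of the global alignment / length of
the shorter sequence. There is no k-mer prefilter, so the worst case is
O(n²) representative comparisons — appropriate for thousands, not
millions, of sequences. Compared with cd-hit's word filter, which can
only reject candidate pairs, this exact comparison can only *merge*
clusters cd-hit might split, never the reverse. The ≥ threshold matches
cd-hit's `-c 0.99` semantics: one substitution in 100 residues (0.99)
merges; one in 50 (0.98) does not.

## Architecture and purity

Domain type identity is the InterPro accession when present, else the
member-database signature accession, so the same domain found by two
member databases counts as one type. Overlapping annotations are
resolved before unit assembly: same-type annotations overlapping by more
than half of the shorter interval are merged (union); across types the
first-listed annotation wins. Letters are assigned by order of first
appearance; a record with ≥ 2 units all of one type is a pure repeat,
a repeated type plus any other unit is combinatorial, anything else is a
non-repeat. Repeat purity is the mean pairwise global-alignment identity
(identical columns / full alignment length, gap columns included) over
the units of the most-copied type (ties: the type whose first unit
starts earliest); per-pair identity is symmetric and unit order is
irrelevant. Purity is undefined (an error) when no type has two units.

## The synthetic generator

Fixtures emulate the target layout: optional hydrophobic signal prefix
(`M` + residues drawn from a hydrophobic-biased pool), then `n_domains`
copies of one random unit joined by low-complexity G/S linkers. Defaults:
2 domains of 35 residues with six pinned cysteines at offsets
(2, 7, 13, 20, 26, 32) — a knottin-like scaffold at a realistic ~17%
cysteine density — and a 5-residue linker, so one unit+linker spans 40
residues and the true boundary falls on the 10-residue scan grid.
Non-pinned positions are uniform over the 20 residues; copies diverge by
independent per-position substitution with the configured probability.
Construction is purely `random.Random`-driven with explicit integer
seeds: byte-identical across runs and platforms.

Decoys: `shuffled` permutes a generated repeat protein (length and
composition preserved, tandem order destroyed); `cxxch_heme` emulates
cytochrome c (two CxxCH motifs, 4 cysteines in 140 residues ≈ 2.9%
density, no repeat); `low_cys` carries 2–3 cysteines and must fail the
prefilter.

### What the generator shows — and does not

Zero-divergence two-domain fixtures are always recovered as strong hits
at the true boundary, and recovery stays high through 40% pairwise
divergence: the six pinned cysteines alone contribute 54 raw score, and
conserved columns dominate the cross-copy alignment. The shuffled-decoy
null, however, is *not* quiet at the raw-score-30 threshold: a shuffled
two-domain protein retains both its ~20% cysteine content and a
duplicated composition (every master residue occurs about twice), and
such sequences frequently produce chance self-alignments above 30
(`scripts/acceptance.py` measures this rate). This mirrors the central
practical property of the workflow: the scan is a high-recall,
low-precision front end, and the refinement stage — density inspection
plus annotation-driven exclusion — carries the burden of precision.
Passing tests on these fixtures demonstrate boundary recovery,
determinism and threshold semantics; they do not demonstrate precision
on real proteomes, where composition is less extreme but annotation is
also less complete.

## Numerical and design choices

* Tie-breaks: best division site at equal score → smallest site; cluster
  representative at equal length → lexicographically smallest accession;
  repeated-type selection at equal copy number → earliest first unit.
* Degenerate inputs: empty sequences are errors at the alignment layer;
  prefilter failures are encoded in the result status, never raised;
  a signal annotation covering the whole sequence is an error
  ("empty mature sequence"), and the batch runner skips such records
  with a warning rather than aborting.
* `*` in FASTA bodies is stripped with a warning; any other
  non-amino-acid character is an error with a line number. Duplicate
  accessions are rejected.
* The benchmark and acceptance measurements use 20 fixtures per
  divergence level, 200 shuffled decoys, a 40-sequence pipeline
  benchmark and a 20-sequence (~4,000-residue) reference set — sizes at
  which every quantity is recomputed from scratch in seconds while the
  binomial noise on the reported rates stays a few percentage points.
* Known limitations: no heuristic seeding (all-vs-all screening is
  O(n·m) alignments), no propeptide handling between domains (a
  propeptide-separated multi-domain precursor is still called a repeat),
  no fragment detection beyond an optional description-keyword flag, and
  the architecture stage depends entirely on the quality of the supplied
  domain annotations.
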