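"""Detect a tandem repeat by bisection self-alignment.

Builds a two-domain cysteine-rich protein (two 35-residue knottin-like
units joined by a 5-residue linker), then scans it: the sequence is cut
at every multiple of 10 residues and the two segments are locally
aligned against each other.  The score profile peaks sharply at the true
inter-domain boundary.
"""

from screp.spa import SPAConfig, scan
from screp.synthetic import SynthConfig, make_screp

synth = make_screp(SynthConfig(seed=42, divergence=0.1), accession="DEMO1")
print(f"sequence ({len(synth.record.sequence)} aa):")
print(" ", synth.record.sequence)
print(f"true inter-domain boundary: {synth.true_splits[0]}")

result = scan(synth.record, SPAConfig())
print("\ndivision site -> self-alignment raw score (BLOSUM62):")
for site, score in result.split_scores:
    marker = " <- best" if site == result.best_split[0] else ""
    print(f"  {site:>3}  {score:>4}{marker}")

print(f"\ncall: {result.call} (raw score {result.best_score} > 30 "
      f"marks a strong tandem-repeat hit)")
# The peak at the true boundary is the full cross-domain alignment; the
# neighbouring sites only align partial domain copies and score lower.
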