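"""Refine scan output: density profile, exclusion, redundancy clustering.

A cytochrome c-like decoy carries cysteines that coordinate heme rather
than form structural disulfides; its annotation gets it excluded.  Two
near-identical candidates collapse into one redundancy cluster at the
99% identity threshold.
"""

from screp.refine import (RefineConfig, cluster_redundant, cysteine_density,
                          exclude_non_screps)
from screp.seqio import DomainAnnotation
from screp.synthetic import CXXCH_HEME, SynthConfig, make_decoy, make_screp

screp_a = make_screp(SynthConfig(seed=1), accession="CAND1").record
screp_b = make_screp(SynthConfig(seed=1), accession="CAND2").record  # duplicate
decoy = make_decoy(SynthConfig(seed=2, decoy_kind=CXXCH_HEME), "CYTC1").record

for rec in (screp_a, decoy):
    print(f"{rec.accession}: cysteine density "
          f"{cysteine_density(rec.sequence):.1f}%")
# Disulfide-rich repeat candidates sit far above the 2-3% density band
# where heme/catalytic-cysteine false positives concentrate.

annotations = {
    "CYTC1": [DomainAnnotation("CYTC1", "SynthScan", "SYNCYTC",
                               "Cytochrome c-like heme-binding domain",
                               10, 130)],
}
kept, removed = exclude_non_screps([screp_a, screp_b, decoy], annotations,
                                   RefineConfig())
print(f"\nkept: {[r.accession for r in kept]}")
for rec, reason in removed:
    print(f"removed {rec.accession}: {reason}")

clusters = cluster_redundant(kept, RefineConfig())
print(f"\n{len(clusters)} non-redundant cluster(s):")
for cl in clusters:
    print(f"  representative {cl.representative}, members {list(cl.members)}")
# CAND1 and CAND2 are byte-identical, so they merge; the representative
# is the longest member (ties broken by accession).
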