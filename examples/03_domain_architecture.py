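"""Domain-architecture strings, repeat classes and repeat purity.

Domain annotations are turned into a bracketed letter string ([AA] =
pure two-domain repeat, [ABB] = combinatorial repeat) and the repeated
units are globally aligned pairwise to measure repeat purity.
"""

from screp.align import ScoringScheme
from screp.architecture import build_architecture, domain_frequency_report
from screp.seqio import DomainAnnotation, SequenceRecord

scheme = ScoringScheme()
seq = "CWKHEDRYGS" * 16


def ann(acc, type_id, start, stop):
    return DomainAnnotation(acc, "Pfam", type_id, f"{type_id} domain",
                            start, stop)


pure = build_architecture(
    SequenceRecord("PURE1", seq),
    [ann("PURE1", "Kunitz", 1, 40), ann("PURE1", "Kunitz", 51, 90)], scheme)
print(f"{pure.accession}: {pure.domain_string} {pure.repeat_class}, "
      f"purity {pure.purity_pct:.1f}%")
# Both Kunitz units are exact copies here, so purity is 100%.

combi = build_architecture(
    SequenceRecord("COMBI1", seq),
    [ann("COMBI1", "Lectin", 1, 40),
     ann("COMBI1", "Kunitz", 51, 90),
     ann("COMBI1", "Kunitz", 101, 140)], scheme)
print(f"{combi.accession}: {combi.domain_string} {combi.repeat_class}, "
      f"purity {combi.purity_pct:.1f}%")
# Letters are assigned by first appearance along the sequence; purity is
# computed over the most-copied type (Kunitz).

table = domain_frequency_report([pure, combi])
print("\ndomain frequency report:")
print(table.to_string(index=False))
# n_proteins counts proteins containing the type at least once;
# mean_copies_per_protein is the average copy number among those.
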