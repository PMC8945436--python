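"""Find canonical seed sites and CG-bulge sites for miR-184 in toy UTRs.

miR-184's seed (GGACGGA) contains a CG dimer, so besides the perfect match
TCCGTCC its UTR targets include bulged sites such as TCC[A]GTCC, where one
extra nucleotide sits between the target-side C and G.
"""

from mirbulge import (
    enumerate_bulge_patterns,
    find_bulge_targets,
    find_seed_targets,
    make_mirna_record,
)
from mirbulge.io import UTRRecord

mir184 = make_mirna_record("hsa-mir-184", "UGGACGGAGAACUGAUAAGGGU")
print(f"{mir184.mirna_id}: seed {mir184.seed}, CG at {list(mir184.cg_positions)}")

utrs = [
    UTRRecord("geneA", "txA", "AAATCCGTCCAAATTTGGG", "chr1", 0, 19, "+"),
    UTRRecord("geneB", "txB", "GGGTCCAGTCCTTAAACCC", "chr1", 100, 119, "+"),
    UTRRecord("geneC", "txC", "TTTTTTTTTTTTTTTTTTT", "chr1", 200, 219, "+"),
]

seed_sites = find_seed_targets(mir184.seed, utrs)
bulge_sites = find_bulge_targets(
    mir184.seed, utrs, enumerate_bulge_patterns(mir184.seed)
)

for s in seed_sites:
    print(f"seed site   : {s.gene_id} @ {s.utr_offset}  pattern {s.pattern}")
for s in bulge_sites:
    print(
        f"cg_bulge    : {s.gene_id} @ {s.utr_offset}  pattern {s.pattern} "
        f"(bulged base {s.bulge_base})"
    )
# geneA carries the perfect site, geneB only the bulged one, geneC neither —
# the bulge class enlarges the target set of CG-seed miRNAs.
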