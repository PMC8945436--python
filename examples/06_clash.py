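"""CLASH chimeric reads: classify interactions and test bulge enrichment.

Simulated chimeras (miRNA ligated to its bound target fragment) are split
against the catalog, classified (canonical seed / CG bulge / wobble /
mismatch / other), and compared with shuffle and scramble nulls.
"""

import numpy as np

from mirbulge import (
    classify_reads,
    enrichment_report,
    scramble_reads,
    shuffle_pairs,
    split_chimera,
)
from mirbulge.simulate import gen_chimeras, gen_mirnas

rng = np.random.default_rng(0)
mirnas, _ = gen_mirnas(6, 2, rng)
reads, truth = gen_chimeras(
    mirnas,
    {"canonical_seed": 0.3, "cg_bulge": 0.5, "unclassified": 0.2},
    n_reads=300,
    rng=rng,
)

catalog = {m.mirna_id: m.mature for m in mirnas}
seeds = {m.mirna_id: m.seed for m in mirnas}
real = classify_reads(
    [split_chimera(rid, seq, catalog) for rid, seq in reads], seeds
)
shuffled = classify_reads(shuffle_pairs(real, rng), seeds)
scrambled = classify_reads(scramble_reads(real, rng), seeds)

rep = enrichment_report(real, shuffled, scrambled)
for name, props in rep["proportions"].items():
    shown = {k: round(v, 3) for k, v in props.items() if v > 0}
    print(f"{name:9s} {shown}")
print("cg_bulge fold enrichment vs shuffle:",
      round(rep["fold_enrichment"]["shuffle"]["cg_bulge"], 1))
print("non-canonical : canonical ratio:",
      round(rep["noncanonical_to_canonical"], 2))
# The planted 50% CG-bulge fraction survives only in the real pairings;
# shuffling miRNA-target assignments or scrambling target sequences
# collapses it to background, showing the signal is pairing-specific.
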