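"""CpG mutation burden: hypermutable in UTRs, protected in miRNA loci.

Simulates population variants in which CpG positions in 3'UTRs mutate 10x
faster (methyl-C deamination) than CpGs in miRNA loci, then recovers the
contrast with an exact binomial rate-ratio test and MAF-binned profiles.
"""

import numpy as np

from mirbulge import compare_burden, bin_by_maf, normalize_counts
from mirbulge.simulate import (
    gen_mirnas,
    gen_utr_cohort,
    gen_variants,
    mirna_loci_regions,
)

rng = np.random.default_rng(0)
mirnas, _ = gen_mirnas(30, 30, rng)
utrs, _, _, _ = gen_utr_cohort(
    100, mirnas[:4], {"seed": 20}, {"seed": 1.0}, n_species=2, rng=rng
)
loci, locus_seqs = mirna_loci_regions(mirnas, locus_len=80, rng=rng)

variants, normalizers, truth = gen_variants(
    utrs, loci, locus_seqs, base_rate=0.006, cpg_multiplier_utr=10.0, rng=rng
)
sites = truth.items["cpg_site_counts"]
counts = truth.items["cpg_variant_counts"]

rep = compare_burden(
    counts["utr"], sites["utr"], counts["mirna"], sites["mirna"],
    alternative="greater",
)
print(f"{len(variants)} variants; CpG mutations UTR={counts['utr']} "
      f"(of {sites['utr']} CpG positions), miRNA={counts['mirna']} "
      f"(of {sites['mirna']})")
print(f"rate ratio UTR/miRNA = {rep['rate_ratio']:.1f}, binomial p = {rep['p']:.2e}")

mafs = [v.maf for v in variants]
counts_per_bin = bin_by_maf(mafs)
norm = normalize_counts(counts_per_bin, n_synonymous=4, gene_length=500)
print("MAF-binned counts (0,1e-3] ... (0.1,0.5]:", counts_per_bin.tolist())
print("normalized (x1000 / n_syn / length):", np.round(norm, 3).tolist())
# The rate ratio recovers the planted 10x CpG hypermutability of target UTRs;
# most variants are rare (first MAF bin), as in real population data.
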