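"""Cross-species conservation of planted seed, CG-bulge, and control sites.

Simulates 23-species alignments in which seed and CG-bulge sites are retained
per species with probability 0.7 but random-bulge controls only 0.3, then
recovers that contrast from the alignments alone.
"""

import numpy as np

from mirbulge import compare_site_classes, project_site, site_conservation_rate
from mirbulge.simulate import gen_mirnas, gen_utr_cohort
from mirbulge.targets import TargetSite

rng = np.random.default_rng(0)
mirnas, _ = gen_mirnas(3, 1, rng)
utrs, regions, blocks, truth = gen_utr_cohort(
    n_genes=80,
    mirnas=mirnas,
    site_plan={"seed": 80, "cg_bulge": 80, "random_bulge": 80},
    retention_probs={"seed": 0.7, "cg_bulge": 0.7, "random_bulge": 0.3},
    n_species=23,
    rng=rng,
)

by_gene = {u.gene_id: (u, b) for u, b in zip(utrs, blocks)}
rates = {"seed": [], "cg_bulge": [], "random_bulge": []}
for p in truth.items["planted_sites"]:
    utr, block = by_gene[p["gene"]]
    site = TargetSite(
        gene_id=p["gene"], utr_offset=p["offset"], site_len=len(p["pattern"]),
        site_type=p["site_type"], pattern=p["pattern"], source_seed=p["seed"],
        bulge_base="" if p["site_type"] == "seed" else p["pattern"][0],
        bulge_gap_index=-1 if p["site_type"] == "seed" else 0,
    )
    res = site_conservation_rate(site, project_site(site, utr, [block]))
    rates[p["site_type"]].append(res.rate)

report = compare_site_classes(rates["seed"], rates["cg_bulge"], rates["random_bulge"])
print("median conservation rate (of 23 species):", report["medians"])
print("cg_bulge vs random_bulge:", report["pairwise"]["cg_bulge|random_bulge"])
# CG-bulge sites are conserved in ~16 of 23 species, controls in ~8; the
# rank-sum p-value shows the bulge class behaves like real sites, not noise.
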