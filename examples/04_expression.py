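"""Expression evidence: targets anticorrelate with their miRNA and shift
after transfection.

Seed targets are planted at Spearman rho -0.6 to the miRNA across 12 samples,
bulge targets at -0.35, background at 0 — the ordering the analysis must
recover against a 1000-draw random-gene null.
"""

import numpy as np

from mirbulge import (
    compare_rho_groups,
    random_gene_null,
    spearman_profile,
    transfection_shift_test,
)
from mirbulge.simulate import gen_expression, gen_transfection

seed_genes = [f"seed{i}" for i in range(100)]
bulge_genes = [f"bulge{i}" for i in range(100)]
background = [f"bg{i}" for i in range(1000)]

mirna, genes, _ = gen_expression(
    "mir-126", seed_genes, bulge_genes, background,
    n_samples=12, rho_seed=-0.6, rho_bulge=-0.35, rng=0,
)
rhos = spearman_profile(mirna, genes)
null = random_gene_null(
    100, genes, mirna, n_draws=1000, rng=0, exclude=seed_genes + bulge_genes
)
report = compare_rho_groups(
    {
        "seed_target": rhos[seed_genes],
        "bulge_target": rhos[bulge_genes],
        "random": null.ravel(),
    }
)
print("median rho:", {k: round(v, 3) for k, v in report["medians"].items()})
print("ordering (most negative first):", report["ordering"])
print("bulge vs random p:", report["pairwise"]["bulge_target|random"]["p"])

fc, _ = gen_transfection(seed_genes, bulge_genes, -0.4, -0.4, 1000, rng=1)
shift = transfection_shift_test(
    fc, bulge_genes, [g for g in fc.index if g.startswith("bg")], "down"
)
print(f"over-expression: bulge targets shifted "
      f"{shift['median_difference']:.2f} log-units, one-sided p = {shift['p']:.2e}")
# Bulge targets sit between seed targets and background in correlation, and
# drop after miRNA over-expression — both signatures of genuine regulation.
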