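"""End-to-end: curated-table statistics plus the full synthetic study.

Runs the shipped vertebrate-conserved miRNA table through the CG
classification and group means, then generates a complete synthetic study
(conservation, mutation, expression, transfection, duplex, CLASH) and checks
every planted ordering is recovered.
"""

from mirbulge import RunConfig, load_builtin_table1, reproduce_synthetic, table1_stats

stats = table1_stats(load_builtin_table1())
print(f"{stats['n_cg']} of {stats['n_rows']} vertebrate-conserved seeds carry a CG dimer")
print(f"mean conservative targets: CG group {stats['cg_mean_display']} "
      f"(exact {stats['cg_mean_exact']}), "
      f"non-CG group {stats['noncg_mean_display']} (exact {stats['noncg_mean_exact']})")
print(f"rank-sum p (CG vs non-CG): {stats['cg_vs_noncg_p']:.2e}")

report = reproduce_synthetic(RunConfig(rng_seed=0))
print("\nsynthetic study recovery checks:")
for name, check in report["checks"].items():
    keys = [k for k in check if k == "p" or k.startswith("p_")]
    ps = ", ".join(f"{k}={check[k]:.2e}" for k in keys)
    print(f"  {name:28s} {'ok' if check['passed'] else 'FAILED'}  {ps}")
print("all planted orderings recovered:", report["all_recovered"])
# CG-seed miRNAs have ~10x fewer conserved canonical targets than the rest;
# the synthetic study shows each validation stage detects its planted effect.
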