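"""Orchestration: curated-table statistics and the end-to-end synthetic run.

``table1_stats`` reproduces the arithmetic on the shipped table of
vertebrate-conserved human miRNAs (seed, conservative-target count, total
target count): CG-dimer classification of each seed, per-row
conservative/total ratios, and the CG vs non-CG group means.  Display follows
the table's own convention — ratios truncated (not rounded) to 4 decimals,
group means truncated to integers — while exact rationals are also emitted.

``reproduce_synthetic`` generates a full synthetic study with planted effects
at the package's default problem sizes, runs every pipeline stage on it, and
reports whether each planted ordering was recovered:

* conservation: seed and CG-bulge sites more conserved than random-bulge
  controls (rank-sum);
* mutation: CpG mutation burden higher in UTRs than in miRNA loci (exact
  binomial rate-ratio test);
* expression: median Spearman rho ordering seed < bulge < random, bulge
  significantly below the resampled random-gene null;
* transfection: bulge targets shifted down after over-expression and up
  after knock-down (one-sided rank-sum);
* CLASH: CG-bulge chimera proportion enriched over shuffle and scramble
  nulls (Fisher exact).

Duplex energies are computed and reported for the three site classes; under
this package's nearest-neighbor model a single-nucleotide bulge costs the
same wherever it sits, so no CG-gap vs random-gap energy ordering is asserted
(see the methods note).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import clash as clash_mod
from . import simulate
from .conserve import compare_site_classes, project_site, site_conservation_rate
from .duplex import compare_mfe_classes, duplex_mfe
from .expression import (
    compare_rho_groups,
    random_gene_null,
    spearman_profile,
    transfection_shift_test,
)
from .io import dna_to_rna
from .mutation import compare_burden
from .targets import (
    SITE_RANDOM_BULGE,
    enumerate_bulge_patterns,
    find_bulge_targets,
    find_cg_dimers,
    find_seed_targets,
)
from .conserve import _class_patterns
from .targets import BulgePattern


def load_builtin_table1() -> pd.DataFrame:
    """The shipped vertebrate-conserved miRNA target-count table."""
    path = resources.files("mirbulge.data") / "vertebrate_mirna_targets.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def truncate_ratio(numerator: int, denominator: int, places: int = 4) -> float:
    """conservative/total truncated (not rounded) to ``places`` decimals."""
    if denominator == 0:
        return float("nan")
    scale = 10**places
    return (numerator * scale // denominator) / scale


def table1_stats(table: pd.DataFrame) -> dict:
    """CG classification, per-row ratios, and group means for a target table.

    Expects columns ``seed``, ``n_conserved``, ``n_total`` (and optionally
    ``mirna_id``).  Means are reported both as exact fractions and with the
    display truncation; a two-sided rank-sum test compares the CG and non-CG
    groups' conservative-target counts.
    """
    df = table.copy()
    df["has_cg"] = [bool(find_cg_dimers(s)) for s in df["seed"]]
    df["ratio"] = [
        truncate_ratio(int(c), int(t))
        for c, t in zip(df["n_conserved"], df["n_total"])
    ]
    cg = df[df["has_cg"]]
    noncg = df[~df["has_cg"]]
    out: dict = {
        "n_rows": len(df),
        "n_cg": len(cg),
        "n_noncg": len(noncg),
        "rows": df,
    }
    for name, grp in (("cg", cg), ("noncg", noncg)):
        if len(grp):
            mean = Fraction(int(grp["n_conserved"].sum()), len(grp))
            out[f"{name}_mean_exact"] = mean
            out[f"{name}_mean_display"] = int(mean)  # integer truncation
    if len(cg) and len(noncg):
        res = stats.mannwhitneyu(
            cg["n_conserved"], noncg["n_conserved"], alternative="two-sided"
        )
        out["cg_vs_noncg_p"] = float(res.pvalue)
    return out


def external_claims() -> dict[str, str]:
    """Published quantities that require external datasets to recompute.

    These are declared, never fabricated: each needs a download (miRBase,
    TargetScan, 1000 Genomes, GEO, or the CLASH supplementary chimeras) that
    this package does not perform.
    """
    return {
        "mean_canonical_targets_cg_vs_noncg": "~900 vs ~4500 targets per miRNA "
        "(full miRBase catalog + TargetScan run)",
        "n_cg_mirnas_of_catalog": "346 CG-seed miRNAs of 1917 (miRBase-version "
        "dependent)",
        "mirna_cpg_normalized_level": "<0.03 (1000 Genomes + real normalizers)",
        "utr_cpg_normalized_level": ">1.25 (1000 Genomes + real normalizers)",
        "transfection_p_values": "per-experiment GEO series p-values",
        "clash_bulge_chimeras": "264 bulge chimeric reads over 8 CG miRNAs "
        "(published CLASH supplementary data)",
        "clash_noncanonical_fold": "~1.7-fold non-canonical vs canonical "
        "interactions (published CLASH supplementary data)",
    }


# ---------------------------------------------------------------------------
# end-to-end synthetic reproduction
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Parameters of the synthetic study and of the analysis stages."""

    rng_seed: int = 0
    seed_len: int = 7
    # catalog
    n_cg_mirnas: int = 4
    n_noncg_mirnas: int = 4
    # UTR cohort / conservation
    n_genes: int = 150
    utr_len: int = 500
    n_species: int = 23
    sites_per_type: int = 200
    retention_seed: float = 0.7
    retention_bulge: float = 0.7
    retention_control: float = 0.3
    divergence: float = 0.1
    # variants
    base_rate: float = 0.006
    cpg_multiplier_utr: float = 10.0
    n_mutation_loci: int = 60  # miRNA loci surveyed for the burden contrast
    locus_len: int = 80  # pre-miRNA scale, gives the loci real exposure
    # expression
    n_samples: int = 12
    genes_per_group: int = 100
    n_background_genes: int = 1000
    rho_seed: float = -0.6
    rho_bulge: float = -0.35
    n_resamples: int = 1000
    # transfection
    shift: float = 0.4
    # duplex
    mfe_per_group: int = 100
    mfe_flank: int = 3
    # chimeras
    n_reads: int = 300
    chimera_mixture: dict = field(
        default_factory=lambda: {
            clash_mod.CANONICAL: 0.3,
            clash_mod.CG_BULGE: 0.5,
            clash_mod.UNCLASSIFIED: 0.2,
        }
    )
    alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _fisher_greater(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-sided Fisher exact p that proportion 1 exceeds proportion 2."""
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _count_cpg_positions(seq: str) -> int:
    """Positions participating in a CpG dyad (both the C and the G count)."""
    return sum(
        1
        for i, b in enumerate(seq)
        if (b == "C" and i + 1 < len(seq) and seq[i + 1] == "G")
        or (b == "G" and i > 0 and seq[i - 1] == "C")
    )


def reproduce_synthetic(config: RunConfig | None = None) -> dict:
    """Generate a synthetic study, run every stage, report planted recovery.

    Returns a report whose ``checks`` map names to ``{passed, p, ...}`` and
    whose ``all_recovered`` is True when every planted ordering was recovered
    at the configured significance level.
    """
    cfg = config or RunConfig()
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(6)
    rngs = [np.random.default_rng(s) for s in seeds]
    report: dict = {"config": cfg.to_dict(), "checks": {}, "details": {}}
    checks = report["checks"]

    # -- catalog ------------------------------------------------------------
    mirnas, _tiers = simulate.gen_mirnas(
        cfg.n_cg_mirnas, cfg.n_noncg_mirnas, rngs[0], seed_len=cfg.seed_len
    )
    cg_mirnas = [m for m in mirnas if m.has_cg]

    # -- conservation (planted retention ordering) --------------------------
    utrs, _regions, blocks, cohort_truth = simulate.gen_utr_cohort(
        cfg.n_genes,
        mirnas,
        {
            "seed": cfg.sites_per_type,
            "cg_bulge": cfg.sites_per_type,
            "random_bulge": cfg.sites_per_type,
        },
        {
            "seed": cfg.retention_seed,
            "cg_bulge": cfg.retention_bulge,
            "random_bulge": cfg.retention_control,
        },
        n_species=cfg.n_species,
        rng=rngs[1],
        utr_len=cfg.utr_len,
        divergence=cfg.divergence,
    )
    utr_by_gene = {u.gene_id: u for u in utrs}
    blocks_by_gene = {u.gene_id: [b] for u, b in zip(utrs, blocks)}
    rates: dict[str, list[int]] = {"seed": [], "cg_bulge": [], "random_bulge": []}
    mfe_sites: dict[str, list] = {"seed": [], "cg_bulge": [], "random_bulge": []}
    for mir in cg_mirnas:
        found = {
            "seed": find_seed_targets(mir.seed, utrs),
            "cg_bulge": find_bulge_targets(
                mir.seed, utrs, enumerate_bulge_patterns(mir.seed)
            ),
            "random_bulge": find_bulge_targets(
                mir.seed,
                utrs,
                [
                    BulgePattern(p, 0, p[0])
                    for p in sorted(_class_patterns(SITE_RANDOM_BULGE, mir.seed))
                ],
                site_type=SITE_RANDOM_BULGE,
            ),
        }
        for stype, sites in found.items():
            for site in sites:
                utr = utr_by_gene[site.gene_id]
                proj = project_site(site, utr, blocks_by_gene[site.gene_id])
                rates[stype].append(site_conservation_rate(site, proj).rate)
                mfe_sites[stype].append((mir, site))
    cons_report = compare_site_classes(
        rates["seed"], rates["cg_bulge"], rates["random_bulge"]
    )
    bulge_ctrl = cons_report["pairwise"]["cg_bulge|random_bulge"]
    seed_ctrl = cons_report["pairwise"]["seed|random_bulge"]
    checks["conservation_ordering"] = {
        "passed": bulge_ctrl["higher_median"] == "cg_bulge"
        and bulge_ctrl["p"] < cfg.alpha
        and seed_ctrl["higher_median"] == "seed"
        and seed_ctrl["p"] < cfg.alpha,
        "p_bulge_vs_control": bulge_ctrl["p"],
        "p_seed_vs_control": seed_ctrl["p"],
        "medians": cons_report["medians"],
    }
    report["details"]["conservation"] = cons_report

    # -- mutation burden (planted CpG multiplier) ----------------------------
    panel, _ = simulate.gen_mirnas(
        cfg.n_mutation_loci // 2,
        cfg.n_mutation_loci - cfg.n_mutation_loci // 2,
        rngs[2],
        seed_len=cfg.seed_len,
    )
    loci, mirna_seqs = simulate.mirna_loci_regions(
        panel, locus_len=cfg.locus_len, rng=rngs[2]
    )
    variants, _normalizers, var_truth = simulate.gen_variants(
        utrs,
        loci,
        mirna_seqs,
        base_rate=cfg.base_rate,
        cpg_multiplier_utr=cfg.cpg_multiplier_utr,
        rng=rngs[2],
    )
    utr_cpg_exposure = sum(_count_cpg_positions(u.sequence) for u in utrs)
    mirna_cpg_exposure = sum(_count_cpg_positions(s) for s in mirna_seqs.values())
    utr_positions = {
        (u.chrom, p) for u in utrs for p in range(u.start, u.end)
    }

    def _is_cpg_variant(v) -> bool:
        seqs = utr_by_gene
        if (v.chrom, v.pos0) in utr_positions:
            for u in utrs:
                if u.chrom == v.chrom and u.start <= v.pos0 < u.end:
                    i = v.pos0 - u.start
                    s = u.sequence
                    break
        else:
            for r, (name, seq) in zip(loci, mirna_seqs.items()):
                if r.chrom == v.chrom and r.start <= v.pos0 < r.end:
                    i, s = v.pos0 - r.start, seq
                    break
            else:
                return False
        return (s[i] == "C" and i + 1 < len(s) and s[i + 1] == "G") or (
            s[i] == "G" and i > 0 and s[i - 1] == "C"
        )

    utr_cpg_count = sum(
        1 for v in variants if (v.chrom, v.pos0) in utr_positions and _is_cpg_variant(v)
    )
    mirna_cpg_count = sum(
        1
        for v in variants
        if (v.chrom, v.pos0) not in utr_positions and _is_cpg_variant(v)
    )
    burden = compare_burden(
        utr_cpg_count,
        utr_cpg_exposure,
        max(mirna_cpg_count, 0),
        mirna_cpg_exposure,
        alternative="greater",
    ) if mirna_cpg_exposure else {"p": float("nan"), "rate_ratio": float("inf")}
    checks["cpg_burden_direction"] = {
        "passed": burden["p"] < cfg.alpha and burden["rate_ratio"] > 1,
        "p": burden["p"],
        "rate_ratio": burden["rate_ratio"],
        "n_variants": len(variants),
    }
    report["details"]["mutation"] = {**burden, "truth": var_truth.items}

    # -- expression correlation ----------------------------------------------
    focal = cg_mirnas[0]
    seed_genes = [f"sg{i}" for i in range(cfg.genes_per_group)]
    bulge_genes = [f"bg_t{i}" for i in range(cfg.genes_per_group)]
    background = [f"nbg{i}" for i in range(cfg.n_background_genes)]
    mirna_vec, gene_mat, _expr_truth = simulate.gen_expression(
        focal.mirna_id,
        seed_genes,
        bulge_genes,
        background,
        n_samples=cfg.n_samples,
        rho_seed=cfg.rho_seed,
        rho_bulge=cfg.rho_bulge,
        rng=rngs[3],
    )
    rhos = spearman_profile(mirna_vec, gene_mat)
    null = random_gene_null(
        cfg.genes_per_group,
        gene_mat,
        mirna_vec,
        n_draws=cfg.n_resamples,
        rng=rngs[3],
        exclude=list(seed_genes) + list(bulge_genes),
    )
    rho_report = compare_rho_groups(
        {
            "seed_target": rhos[seed_genes].to_numpy(),
            "bulge_target": rhos[bulge_genes].to_numpy(),
            "random": null.ravel(),
        }
    )
    ordering_ok = rho_report["ordering"] == ["seed_target", "bulge_target", "random"]
    p_bulge_null = rho_report["pairwise"]["bulge_target|random"]["p"]
    checks["expression_ordering"] = {
        "passed": ordering_ok and p_bulge_null < cfg.alpha,
        "p_bulge_vs_random": p_bulge_null,
        "medians": rho_report["medians"],
    }
    report["details"]["expression"] = rho_report

    # -- transfection shifts -------------------------------------------------
    over_fc, _t1 = simulate.gen_transfection(
        seed_genes, bulge_genes, -cfg.shift, -cfg.shift,
        n_background=cfg.n_background_genes, rng=rngs[4],
    )
    down = transfection_shift_test(
        over_fc, bulge_genes, [g for g in over_fc.index if g.startswith("bg") and g[2].isdigit()],
        direction="down",
    )
    kd_fc, _t2 = simulate.gen_transfection(
        seed_genes, bulge_genes, cfg.shift, cfg.shift,
        n_background=cfg.n_background_genes, rng=rngs[4],
    )
    up = transfection_shift_test(
        kd_fc, bulge_genes, [g for g in kd_fc.index if g.startswith("bg") and g[2].isdigit()],
        direction="up",
    )
    checks["transfection_directions"] = {
        "passed": down["p"] < cfg.alpha
        and down["median_difference"] < 0
        and up["p"] < cfg.alpha
        and up["median_difference"] > 0,
        "p_overexpression_down": down["p"],
        "p_knockdown_up": up["p"],
    }
    report["details"]["transfection"] = {"overexpression": down, "knockdown": up}

    # -- duplex energies (reported, no asserted CG-vs-random ordering) -------
    rng_mfe = rngs[5]
    energies: dict[str, list[float]] = {}
    for stype, entries in mfe_sites.items():
        if len(entries) > cfg.mfe_per_group:
            pick = rng_mfe.choice(len(entries), size=cfg.mfe_per_group, replace=False)
            entries = [entries[int(i)] for i in pick]
        vals = []
        for mir, site in entries:
            utr = utr_by_gene[site.gene_id]
            lo = max(0, site.utr_offset - cfg.mfe_flank)
            hi = min(len(utr.sequence), site.utr_offset + site.site_len + cfg.mfe_flank)
            vals.append(
                duplex_mfe(mir.seed, dna_to_rna(utr.sequence[lo:hi])).mfe
            )
        energies[stype] = vals
    mfe_report = compare_mfe_classes(
        energies["seed"], energies["cg_bulge"], energies["random_bulge"]
    )
    report["details"]["duplex"] = mfe_report

    # -- CLASH chimeras -------------------------------------------------------
    reads_raw, chim_truth = simulate.gen_chimeras(
        mirnas, cfg.chimera_mixture, cfg.n_reads, rng=rngs[5]
    )
    catalog = {m.mirna_id: m.mature for m in mirnas}
    seeds_map = {m.mirna_id: m.seed for m in mirnas}
    split = [
        clash_mod.split_chimera(rid, seq, catalog) for rid, seq in reads_raw
    ]
    real = clash_mod.classify_reads(split, seeds_map)
    shuffled = clash_mod.classify_reads(
        clash_mod.shuffle_pairs(real, rngs[5]), seeds_map
    )
    scrambled = clash_mod.classify_reads(
        clash_mod.scramble_reads(real, rngs[5]), seeds_map
    )
    enrich = clash_mod.enrichment_report(real, shuffled, scrambled)

    def _count(rs, cls):
        return sum(r.interaction_class == cls for r in rs)

    k_real = _count(real, clash_mod.CG_BULGE)
    p_shuf = _fisher_greater(
        k_real, len(real), _count(shuffled, clash_mod.CG_BULGE), len(shuffled)
    )
    p_scram = _fisher_greater(
        k_real, len(real), _count(scrambled, clash_mod.CG_BULGE), len(scrambled)
    )
    checks["clash_cg_bulge_enrichment"] = {
        "passed": p_shuf < cfg.alpha and p_scram < cfg.alpha,
        "p_vs_shuffle": p_shuf,
        "p_vs_scramble": p_scram,
        "real_proportion": enrich["proportions"]["real"][clash_mod.CG_BULGE],
    }
    report["details"]["clash"] = enrich
    report["details"]["clash_truth"] = chim_truth.params

    report["all_recovered"] = all(c["passed"] for c in checks.values())
    return report


def report_to_json(report: dict) -> str:
    """Serialize a reproduce report (DataFrames and fractions removed)."""

    def default(obj):
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, Fraction):
            return {"num": obj.numerator, "den": obj.denominator}
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return str(obj)

    return json.dumps(report, indent=1, default=default, sort_keys=True)
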