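import numpy as np
import pytest
from scipy import stats

from mirbulge.clash import CANONICAL, CG_BULGE, UNCLASSIFIED
from mirbulge.conserve import (
    compare_site_classes,
    project_site,
    site_conservation_rate,
)
from mirbulge.mutation import compare_burden
from mirbulge.simulate import (
    gen_chimeras,
    gen_expression,
    gen_mirnas,
    gen_transfection,
    gen_utr_cohort,
    gen_variants,
    mirna_loci_regions,
)
from mirbulge.targets import (
    enumerate_bulge_patterns,
    extract_seed,
    find_bulge_targets,
    find_cg_dimers,
    find_seed_targets,
)


class TestGenMirnas:
    def test_group_sizes_and_cg_constraints(self):
        records, tiers = gen_mirnas(8, 52, rng=1)
        assert len(records) == 60 and len(tiers) == 60
        cg = [r for r in records if find_cg_dimers(extract_seed(r.mature))]
        assert len(cg) == 8
        assert all(r.has_cg == (r in cg) for r in records)

    def test_no_cg_group_has_none(self):
        records, _ = gen_mirnas(0, 5, rng=2)
        assert all(not r.has_cg for r in records)

    def test_same_seed_reproduces_identical_catalog(self):
        a, _ = gen_mirnas(3, 3, rng=7)
        b, _ = gen_mirnas(3, 3, rng=7)
        assert [(r.mirna_id, r.mature) for r in a] == [
            (r.mirna_id, r.mature) for r in b
        ]


def cohort(rng_seed, retention, n_sites=40, n_species=8, n_genes=40):
    mirnas, _ = gen_mirnas(3, 1, rng=rng_seed)
    return (
        mirnas,
        *gen_utr_cohort(
            n_genes,
            mirnas,
            {"seed": n_sites, "cg_bulge": n_sites, "random_bulge": n_sites},
            retention,
            n_species=n_species,
            rng=rng_seed,
        ),
    )


def planted_rates(utrs, blocks, truth):
    """Score the planted sites listed in the truth, per type."""
    from mirbulge.targets import TargetSite

    by_gene = {u.gene_id: (u, b) for u, b in zip(utrs, blocks)}
    rates = {"seed": [], "cg_bulge": [], "random_bulge": []}
    for p in truth.items["planted_sites"]:
        utr, block = by_gene[p["gene"]]
        site = TargetSite(
            gene_id=p["gene"],
            utr_offset=p["offset"],
            site_len=len(p["pattern"]),
            site_type=p["site_type"],
            pattern=p["pattern"],
            source_seed=p["seed"],
            bulge_base="" if p["site_type"] == "seed" else p["pattern"][0],
            bulge_gap_index=-1 if p["site_type"] == "seed" else 0,
        )
        proj = project_site(site, utr, [block])
        rates[p["site_type"]].append(
            site_conservation_rate(site, proj, mode="exact").rate
        )
    return rates


class TestUtrCohort:
    def test_full_retention_saturates_conservation(self):
        r = {"seed": 1.0, "cg_bulge": 1.0, "random_bulge": 1.0}
        mirnas, utrs, regions, blocks, truth = cohort(3, r, n_sites=10)
        rates = planted_rates(utrs, blocks, truth)
        assert all(v == 8 for vals in rates.values() for v in vals)

    def test_zero_retention_leaves_reference_only(self):
        r = {"seed": 0.0, "cg_bulge": 0.0, "random_bulge": 0.0}
        mirnas, utrs, regions, blocks, truth = cohort(4, r, n_sites=10)
        rates = planted_rates(utrs, blocks, truth)
        assert all(v == 1 for vals in rates.values() for v in vals)

    def test_planted_retention_contrast_detected(self):
        r = {"seed": 0.7, "cg_bulge": 0.7, "random_bulge": 0.3}
        mirnas, utrs, regions, blocks, truth = cohort(
            5, r, n_sites=200, n_species=23, n_genes=150
        )
        rates = planted_rates(utrs, blocks, truth)
        report = compare_site_classes(
            rates["seed"], rates["cg_bulge"], rates["random_bulge"]
        )
        pair = report["pairwise"]["cg_bulge|random_bulge"]
        assert pair["higher_median"] == "cg_bulge" and pair["p"] < 0.01

    def test_planted_sites_discoverable_in_reference(self):
        r = {"seed": 1.0, "cg_bulge": 1.0, "random_bulge": 1.0}
        mirnas, utrs, regions, blocks, truth = cohort(6, r, n_sites=15)
        for mir in (m for m in mirnas if m.has_cg):
            seed_sites = find_seed_targets(mir.seed, utrs)
            planted = [
                p
                for p in truth.items["planted_sites"]
                if p["site_type"] == "seed" and p["mirna_id"] == mir.mirna_id
            ]
            found = {(s.gene_id, s.utr_offset) for s in seed_sites}
            assert all((p["gene"], p["offset"]) in found for p in planted)


class TestGenVariants:
    @pytest.fixture
    def small_world(self):
        mirnas, _ = gen_mirnas(3, 3, rng=8)
        utrs, _, _, _ = gen_utr_cohort(
            30, mirnas, {"seed": 5}, {"seed": 1.0}, n_species=2, rng=8
        )
        loci, seqs = mirna_loci_regions(mirnas, locus_len=80, rng=3)
        return utrs, loci, seqs

    def test_zero_rate_gives_empty_vcf(self, small_world):
        utrs, loci, seqs = small_world
        variants, norm, truth = gen_variants(utrs, loci, seqs, 0.0, 10.0, rng=1)
        assert variants == []

    def test_planted_multiplier_recovered_by_burden_test(self, small_world):
        utrs, loci, seqs = small_world
        variants, _, truth = gen_variants(utrs, loci, seqs, 0.01, 10.0, rng=2)
        sites = truth.items["cpg_site_counts"]
        counts = truth.items["cpg_variant_counts"]
        rep = compare_burden(
            counts["utr"], sites["utr"], max(counts["mirna"], 1), sites["mirna"],
            alternative="greater",
        )
        assert rep["p"] < 0.01 and rep["rate_ratio"] > 2

    def test_null_multiplier_calibrated(self):
        mirnas, _ = gen_mirnas(2, 2, rng=9)
        utrs, _, _, _ = gen_utr_cohort(
            10, mirnas, {"seed": 2}, {"seed": 1.0}, n_species=2, rng=9, utr_len=300
        )
        loci, seqs = mirna_loci_regions(mirnas, locus_len=300, rng=4)
        reject, reps = 0, 200
        for i in range(reps):
            _, _, truth = gen_variants(utrs, loci, seqs, 0.02, 1.0, rng=100 + i)
            sites = truth.items["cpg_site_counts"]
            counts = truth.items["cpg_variant_counts"]
            if counts["utr"] + counts["mirna"] == 0:
                continue
            rep = compare_burden(
                counts["utr"], sites["utr"], counts["mirna"], sites["mirna"]
            )
            if rep["p"] < 0.05:
                reject += 1
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo <= reject <= hi

    def test_normalizers_cover_every_gene(self, small_world):
        utrs, loci, seqs = small_world
        _, norm, _ = gen_variants(utrs, loci, seqs, 0.01, 5.0, rng=3)
        assert set(norm["gene_id"]) == {u.gene_id for u in utrs}
        assert (norm["n_synonymous"] >= 1).all()


class TestGenExpression:
    def test_perfect_negative_coupling_gives_rho_minus_one(self):
        from mirbulge.expression import spearman_profile

        m, genes, _ = gen_expression(
            "mir-x", ["g1"], [], [], n_samples=10, rho_seed=-1.0, rho_bulge=0, rng=0
        )
        assert spearman_profile(m, genes)["g1"] == pytest.approx(-1.0)

    def test_zero_rho_groups_indistinguishable(self, rng):
        from mirbulge.expression import compare_rho_groups, spearman_profile

        reject, reps = 0, 200
        for i in range(reps):
            m, genes, _ = gen_expression(
                "mir-x",
                [f"s{j}" for j in range(30)],
                [f"b{j}" for j in range(30)],
                [],
                n_samples=12,
                rho_seed=0.0,
                rho_bulge=0.0,
                rng=1000 + i,
            )
            rhos = spearman_profile(m, genes)
            rep = compare_rho_groups(
                {
                    "seed": rhos[[f"s{j}" for j in range(30)]],
                    "bulge": rhos[[f"b{j}" for j in range(30)]],
                }
            )
            if rep["pairwise"]["seed|bulge"]["p"] < 0.05:
                reject += 1
        lo, hi = stats.binom.interval(0.999, reps, 0.05)
        assert lo <= reject <= hi


class TestGenTransfection:
    def test_directional_shifts_and_determinism(self):
        fc1, _ = gen_transfection(["a"], ["b"], -0.4, -0.4, 10, rng=5)
        fc2, _ = gen_transfection(["a"], ["b"], -0.4, -0.4, 10, rng=5)
        assert fc1.equals(fc2)
        assert set(fc1.index) == {"a", "b"} | {f"bg{i}" for i in range(10)}


class TestGenChimeras:
    def test_mixture_must_sum_to_one(self, rng):
        mirnas, _ = gen_mirnas(2, 0, rng)
        with pytest.raises(ValueError, match="sums to"):
            gen_chimeras(mirnas, {CANONICAL: 0.5, CG_BULGE: 0.3}, 10, rng)

    def test_single_read_of_requested_class(self, rng):
        mirnas, _ = gen_mirnas(2, 0, rng)
        reads, truth = gen_chimeras(mirnas, {CG_BULGE: 1.0}, 1, rng)
        assert len(reads) == 1
        assert truth.items["reads"][0]["true_class"] == CG_BULGE

    def test_closed_loop_class_recovery(self, rng):
        from mirbulge.clash import classify_reads, split_chimera

        mirnas, _ = gen_mirnas(5, 1, rng)
        mixture = {CANONICAL: 0.3, CG_BULGE: 0.5, UNCLASSIFIED: 0.2}
        reads, truth = gen_chimeras(mirnas, mixture, 200, rng)
        cat = {m.mirna_id: m.mature for m in mirnas}
        seeds = {m.mirna_id: m.seed for m in mirnas}
        classified = classify_reads(
            [split_chimera(rid, seq, cat) for rid, seq in reads], seeds
        )
        by_id = {r.read_id: r.interaction_class for r in classified}
        agree = sum(
            by_id[t["read_id"]] == t["true_class"] for t in truth.items["reads"]
        )
        assert agree == len(reads)  # constructive oracle: exact recovery
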