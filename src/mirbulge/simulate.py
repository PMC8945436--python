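"""Synthetic-data generators with planted ground truth.

Every input the pipeline consumes can be generated here, with the planted
parameters (site positions, per-species retention probabilities, CpG mutation
multipliers, correlation effects, transfection shifts, chimera class
mixtures) returned as a :class:`SyntheticTruth` so recovery tests can close
the loop.  Every generator is a pure function of (parameters, rng seed).

What is emulated: the statistical structure the pipeline must detect —
planted seed/bulge/control sites, i.i.d. per-species site retention, elevated
CpG deamination in UTRs but not miRNA loci, rank-coupled negative
miRNA-target expression, directional transfection shifts, and chimera class
mixtures.  What is not: phylogeny (species are independent retention draws,
not a tree), sequencing error, and real genomic base composition beyond an
optional CG-depleted background.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import clash as clash_mod
from .io import AlignmentBlock, MafRow, Region, UTRRecord, VariantRecord, rna_to_dna
from .targets import (
    SITE_CG_BULGE,
    SITE_RANDOM_BULGE,
    SITE_SEED,
    MiRNARecord,
    enumerate_bulge_patterns,
    extract_seed,
    find_cg_dimers,
    generate_random_bulge_controls,
    make_mirna_record,
    seed_match_pattern,
)

_BASES = np.array(list("ACGT"))
REF_SPECIES = "hg19"


@dataclass
class SyntheticTruth:
    """Planted parameters and per-item ground truth emitted next to data."""

    params: dict = field(default_factory=dict)
    items: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.params, "items": self.items}, fh, indent=1, default=str)


def _rng(rng: np.random.Generator | int) -> np.random.Generator:
    return np.random.default_rng(rng) if isinstance(rng, int) else rng


def _random_dna(rng: np.random.Generator, length: int, cg_depleted: bool = False) -> str:
    seq = rng.choice(_BASES, size=length)
    if cg_depleted:
        # break ~75% of CG dyads, mimicking mammalian CpG observed/expected ~0.25
        s = seq.copy()
        for i in range(length - 1):
            if s[i] == "C" and s[i + 1] == "G" and rng.random() < 0.75:
                s[i + 1] = rng.choice(np.array(list("ACT")))
        seq = s
    return "".join(seq)


# ---------------------------------------------------------------------------
# miRNA catalogs
# ---------------------------------------------------------------------------


def gen_mirnas(
    n_cg: int,
    n_noncg: int,
    rng: np.random.Generator | int,
    seed_len: int = 7,
    mature_len: int = 22,
    tier: str = "vertebrate",
) -> tuple[list[MiRNARecord], pd.DataFrame]:
    """Random mature miRNAs: ``n_cg`` whose seed contains a CG dimer and
    ``n_noncg`` whose seed contains none, plus a conservation-tier table."""
    rng = _rng(rng)
    records: list[MiRNARecord] = []

    def draw(want_cg: bool, ident: str) -> MiRNARecord:
        while True:
            mature = "".join(rng.choice(_BASES, size=mature_len)).replace("T", "U")
            seed = extract_seed(mature, seed_len)
            if want_cg and not find_cg_dimers(seed):
                pos = int(rng.integers(0, seed_len - 1))
                seed = seed[:pos] + "CG" + seed[pos + 2 :]
                mature = mature[0] + seed + mature[1 + seed_len :]
            if bool(find_cg_dimers(extract_seed(mature, seed_len))) == want_cg:
                return make_mirna_record(ident, mature, seed_len, tier)

    for i in range(n_cg):
        records.append(draw(True, f"sim-mir-cg-{i + 1}"))
    for i in range(n_noncg):
        records.append(draw(False, f"sim-mir-{i + 1}"))
    tiers = pd.DataFrame(
        {"mirna_id": [r.mirna_id for r in records], "tier": tier}
    )
    return records, tiers


# ---------------------------------------------------------------------------
# UTR cohort with planted sites and a multi-species alignment
# ---------------------------------------------------------------------------


def gen_utr_cohort(
    n_genes: int,
    mirnas: Sequence[MiRNARecord],
    site_plan: Mapping[str, int],
    retention_probs: Mapping[str, float],
    n_species: int = 23,
    rng: np.random.Generator | int = 0,
    utr_len: int = 500,
    divergence: float = 0.1,
    cg_depleted: bool = False,
    chrom: str = "chr1",
) -> tuple[list[UTRRecord], list[Region], list[AlignmentBlock], SyntheticTruth]:
    """Random-background UTRs with planted sites and an i.i.d.-retention MAF.

    ``site_plan`` gives planted counts per site type (seed / cg_bulge /
    random_bulge); planted sites use the CG-containing miRNAs' seeds.  Each
    non-reference species retains each planted site with its type's retention
    probability, otherwise the site receives one point mutation; background
    positions diverge independently at ``divergence`` per species.
    """
    rng = _rng(rng)
    cg_mirnas = [m for m in mirnas if m.has_cg]
    if not cg_mirnas and any(site_plan.values()):
        raise ValueError("site plan needs at least one CG-containing miRNA")

    seqs = [
        np.array(list(_random_dna(rng, utr_len, cg_depleted))) for _ in range(n_genes)
    ]
    occupied: list[list[tuple[int, int]]] = [[] for _ in range(n_genes)]
    planted: list[dict] = []

    def plant(site_type: str, count: int) -> None:
        for j in range(count):
            mir = cg_mirnas[j % len(cg_mirnas)]
            if site_type == SITE_SEED:
                pat = seed_match_pattern(mir.seed)
            elif site_type == SITE_CG_BULGE:
                opts = enumerate_bulge_patterns(mir.seed)
                pat = opts[int(rng.integers(len(opts)))].pattern
            elif site_type == SITE_RANDOM_BULGE:
                pat = generate_random_bulge_controls(mir.seed, 1, rng)[0].pattern
            else:
                raise ValueError(f"unknown site type {site_type!r}")
            for _try in range(200):
                g = int(rng.integers(n_genes))
                off = int(rng.integers(0, utr_len - len(pat)))
                span = (off - len(pat), off + 2 * len(pat))  # padded, avoids overlap
                if all(e <= span[0] or s >= span[1] for s, e in occupied[g]):
                    break
            else:
                raise RuntimeError("could not place site; increase n_genes/utr_len")
            occupied[g].append((off, off + len(pat)))
            seqs[g][off : off + len(pat)] = list(pat)
            planted.append(
                {
                    "gene": f"gene{g}",
                    "gene_index": g,
                    "offset": off,
                    "site_type": site_type,
                    "pattern": pat,
                    "seed": mir.seed,
                    "mirna_id": mir.mirna_id,
                }
            )

    for site_type, count in site_plan.items():
        plant(site_type, count)

    gap = 100
    utrs, regions, blocks = [], [], []
    species = [REF_SPECIES] + [f"sp{i}" for i in range(1, n_species)]
    for g in range(n_genes):
        start = g * (utr_len + gap)
        seq = "".join(seqs[g])
        utrs.append(
            UTRRecord(
                gene_id=f"gene{g}",
                transcript_id=f"tx{g}",
                sequence=seq,
                chrom=chrom,
                start=start,
                end=start + utr_len,
                strand="+",
            )
        )
        regions.append(Region(chrom, start, start + utr_len, f"gene{g}|tx{g}", "+"))
        sites_here = [p for p in planted if p["gene_index"] == g]
        rows = {
            REF_SPECIES: MafRow(REF_SPECIES, chrom, start, utr_len, "+", 10**8, seq)
        }
        base_idx = np.searchsorted(_BASES, seqs[g])  # ACGT -> 0..3
        for sp in species[1:]:
            arr = seqs[g].copy()
            mutate = rng.random(utr_len) < divergence
            for p in sites_here:  # planted spans handled by retention, not drift
                mutate[p["offset"] : p["offset"] + len(p["pattern"])] = False
            idx = np.flatnonzero(mutate)
            if idx.size:
                arr[idx] = _BASES[(base_idx[idx] + rng.integers(1, 4, idx.size)) % 4]
            for p in sites_here:
                if rng.random() >= retention_probs[p["site_type"]]:
                    k = p["offset"] + int(rng.integers(len(p["pattern"])))
                    arr[k] = _BASES[(base_idx[k] + int(rng.integers(1, 4))) % 4]
            rows[sp] = MafRow(sp, chrom, start, utr_len, "+", 10**8, "".join(arr))
        blocks.append(AlignmentBlock(rows=rows, ref_species=REF_SPECIES))

    truth = SyntheticTruth(
        params={
            "n_genes": n_genes,
            "site_plan": dict(site_plan),
            "retention_probs": dict(retention_probs),
            "n_species": n_species,
            "utr_len": utr_len,
            "divergence": divergence,
        },
        items={"planted_sites": planted, "species": species},
    )
    return utrs, regions, blocks, truth


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------


def _draw_maf(rng: np.random.Generator, rare_fraction: float = 0.9) -> float:
    """Rare-variant-dominated MAF law: 90% below 0.001, rest log-uniform."""
    if rng.random() < rare_fraction:
        return float(rng.uniform(1e-4, 1e-3))
    return float(10 ** rng.uniform(np.log10(1.1e-3), np.log10(0.5)))


def mirna_loci_regions(
    mirnas: Sequence[MiRNARecord],
    chrom: str = "chr2",
    gap: int = 50,
    locus_len: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[Region], dict[str, str]]:
    """Lay miRNA loci (DNA) end to end on their own contig.

    With ``locus_len`` set (pre-miRNA scale, ~80 nt) each mature sequence is
    padded with random hairpin-arm flanks to that length, giving the locus a
    realistic mutational exposure; otherwise the bare mature sequence is used.
    """
    if locus_len is not None and rng is None:
        raise ValueError("padding to locus_len needs an rng")
    rng = _rng(rng) if rng is not None else None
    regions, seqs = [], {}
    pos = 0
    for m in mirnas:
        dna = rna_to_dna(m.mature)
        if locus_len is not None and locus_len > len(dna):
            pad = locus_len - len(dna)
            left = int(rng.integers(0, pad + 1))
            dna = _random_dna(rng, left) + dna + _random_dna(rng, pad - left)
        regions.append(Region(chrom, pos, pos + len(dna), m.mirna_id, "+"))
        seqs[m.mirna_id] = dna
        pos += len(dna) + gap
    return regions, seqs


def gen_variants(
    utrs: Sequence[UTRRecord],
    mirna_loci: Sequence[Region],
    mirna_seqs: Mapping[str, str],
    base_rate: float,
    cpg_multiplier_utr: float,
    rng: np.random.Generator | int = 0,
    rare_fraction: float = 0.9,
) -> tuple[list[VariantRecord], pd.DataFrame, SyntheticTruth]:
    """Plant SNVs: CpG positions in UTRs mutate at ``base_rate × multiplier``
    (C→T / G→A deamination), CpG in miRNA loci and all non-CpG positions at
    ``base_rate``.  Emits per-gene synonymous-count and length normalizers."""
    if cpg_multiplier_utr < 1:
        raise ValueError("cpg_multiplier_utr must be >= 1")
    rng = _rng(rng)
    variants: list[VariantRecord] = []
    cpg_site_counts = {"utr": 0, "mirna": 0}
    cpg_variant_counts = {"utr": 0, "mirna": 0}

    def walk(chrom: str, start: int, seq: str, is_utr: bool) -> None:
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_c, is_g = arr == b"C", arr == b"G"
        in_cpg = np.zeros(len(seq), dtype=bool)
        in_cpg[:-1] |= is_c[:-1] & is_g[1:]
        in_cpg[1:] |= is_g[1:] & is_c[:-1]
        key = "utr" if is_utr else "mirna"
        cpg_site_counts[key] += int(in_cpg.sum())
        cpg_rate = base_rate * (cpg_multiplier_utr if is_utr else 1.0)
        rates = np.where(in_cpg, cpg_rate, base_rate)
        hits = np.flatnonzero(rng.random(len(seq)) < rates)
        for i in hits:
            base = seq[i]
            if in_cpg[i]:
                alt = "T" if base == "C" else "A"
                cpg_variant_counts[key] += 1
            else:
                alt = str(rng.choice([b for b in "ACGT" if b != base]))
            variants.append(
                VariantRecord(chrom, start + int(i), base, alt, _draw_maf(rng, rare_fraction))
            )

    for utr in utrs:
        walk(utr.chrom, utr.start, utr.sequence, True)
    for region in mirna_loci:
        walk(region.chrom, region.start, mirna_seqs[region.name], False)

    normalizers = pd.DataFrame(
        {
            "gene_id": [u.gene_id for u in utrs],
            "n_synonymous": [
                max(1, int(rng.poisson(len(u.sequence) * base_rate))) for u in utrs
            ],
            "gene_length": [len(u.sequence) for u in utrs],
        }
    )
    truth = SyntheticTruth(
        params={
            "base_rate": base_rate,
            "cpg_multiplier_utr": cpg_multiplier_utr,
            "rare_fraction": rare_fraction,
        },
        items={
            "cpg_site_counts": cpg_site_counts,
            "cpg_variant_counts": cpg_variant_counts,
            "n_variants": len(variants),
        },
    )
    return variants, normalizers, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: the Pearson correlation of bivariate
    normals whose Spearman correlation is ``rho_s``."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def gen_expression(
    focal_mirna: str,
    seed_target_genes: Sequence[str],
    bulge_target_genes: Sequence[str],
    background_genes: Sequence[str],
    n_samples: int = 12,
    rho_seed: float = -0.6,
    rho_bulge: float = -0.35,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.Series, pd.DataFrame, SyntheticTruth]:
    """Expression with rank-coupled (Gaussian copula) planted correlations.

    Seed targets track the focal miRNA with population Spearman ``rho_seed``,
    bulge targets with ``rho_bulge``, background genes are independent noise.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if not (-1 <= rho_bulge <= 1 and -1 <= rho_seed <= 1):
        raise ValueError("rho outside [-1, 1]")
    rng = _rng(rng)
    samples = [f"s{i}" for i in range(n_samples)]
    z = rng.standard_normal(n_samples)
    mirna = pd.Series(z, index=samples, name=focal_mirna)

    rows, index = [], []
    for genes, rho in (
        (seed_target_genes, rho_seed),
        (bulge_target_genes, rho_bulge),
        (background_genes, 0.0),
    ):
        r = spearman_to_pearson(rho)
        for g in genes:
            noise = rng.standard_normal(n_samples)
            if abs(r) == 1.0:
                vec = np.sign(r) * z
            else:
                vec = r * z + np.sqrt(1 - r * r) * noise
            rows.append(vec)
            index.append(g)
    genes_df = pd.DataFrame(rows, index=index, columns=samples)
    truth = SyntheticTruth(
        params={
            "rho_seed": rho_seed,
            "rho_bulge": rho_bulge,
            "n_samples": n_samples,
        },
        items={
            "seed_targets": list(seed_target_genes),
            "bulge_targets": list(bulge_target_genes),
            "background": list(background_genes),
        },
    )
    return mirna, genes_df, truth


# ---------------------------------------------------------------------------
# transfection fold changes
# ---------------------------------------------------------------------------


def gen_transfection(
    seed_target_genes: Sequence[str],
    bulge_target_genes: Sequence[str],
    shift_seed: float,
    shift_bulge: float,
    n_background: int = 1000,
    noise_sd: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> tuple[pd.Series, SyntheticTruth]:
    """Log fold changes: noise for background, noise+shift for target groups.

    Negative shift models down-regulation after over-expression; positive,
    up-regulation after knock-down.
    """
    rng = _rng(rng)
    names, values = [], []
    for genes, shift in (
        (seed_target_genes, shift_seed),
        (bulge_target_genes, shift_bulge),
    ):
        names.extend(genes)
        values.extend(rng.normal(shift, noise_sd, size=len(genes)))
    bg = [f"bg{i}" for i in range(n_background)]
    names.extend(bg)
    values.extend(rng.normal(0.0, noise_sd, size=n_background))
    truth = SyntheticTruth(
        params={
            "shift_seed": shift_seed,
            "shift_bulge": shift_bulge,
            "noise_sd": noise_sd,
        },
        items={
            "seed_targets": list(seed_target_genes),
            "bulge_targets": list(bulge_target_genes),
            "background": bg,
        },
    )
    return pd.Series(values, index=names, name="logFC"), truth


# ---------------------------------------------------------------------------
# CLASH chimeras
# ---------------------------------------------------------------------------


def _mixture_counts(
    mixture: Mapping[str, float], n: int
) -> dict[str, int]:
    """Largest-remainder apportionment: proportions honored up to rounding."""
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"class mixture sums to {total}, not 1")
    raw = {c: p * n for c, p in mixture.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: raw[c] - np.floor(raw[c]), reverse=True)[:short]:
        counts[c] += 1
    return counts


def _construct_target_part(
    cls: str,
    mir: MiRNARecord,
    rng: np.random.Generator,
    target_len: int,
) -> str:
    """Build a target part whose classification is exactly ``cls`` (verified
    against :func:`clash.classify_interaction`, the constructive oracle)."""
    seed = mir.seed
    match = seed_match_pattern(seed)
    L = len(match)
    for _ in range(200):
        if cls == clash_mod.UNCLASSIFIED:
            tp = _random_dna(rng, target_len)
        else:
            if cls == clash_mod.CANONICAL:
                core = match
            elif cls == clash_mod.CG_BULGE:
                opts = enumerate_bulge_patterns(seed)
                core = opts[int(rng.integers(len(opts)))].pattern
            elif cls == clash_mod.OTHER_BULGE:
                core = generate_random_bulge_controls(seed, 1, rng)[0].pattern
            elif cls == clash_mod.GU_WOBBLE:
                # replace one WC target base by the wobble partner of the seed base
                positions = [
                    i for i, s in enumerate(rna_to_dna(seed)) if s in "GT"
                ]
                if not positions:
                    raise ValueError(f"seed {seed} admits no G:U wobble")
                i = positions[int(rng.integers(len(positions)))]
                j = L - 1 - i
                wob = "T" if rna_to_dna(seed)[i] == "G" else "G"
                core = match[:j] + wob + match[j + 1 :]
            elif cls == clash_mod.ONE_MISMATCH:
                i = int(rng.integers(L))
                s = rna_to_dna(seed)[L - 1 - i]
                bad = [
                    b
                    for b in "ACGT"
                    if (s, b) not in clash_mod._WC_DNA and (s, b) not in clash_mod._GU_DNA
                ]
                core = match[:i] + str(rng.choice(bad)) + match[i + 1 :]
            else:
                raise ValueError(f"unknown chimera class {cls!r}")
            pad = target_len - len(core)
            left = int(rng.integers(0, pad + 1))
            tp = _random_dna(rng, left) + core + _random_dna(rng, pad - left)
        if clash_mod.classify_interaction(seed, tp) == cls:
            return tp
    raise RuntimeError(f"could not construct a {cls} target part for {mir.mirna_id}")


def gen_chimeras(
    mirnas: Sequence[MiRNARecord],
    class_mixture: Mapping[str, float],
    n_reads: int,
    rng: np.random.Generator | int = 0,
    target_len: int = 30,
) -> tuple[list[tuple[str, str]], SyntheticTruth]:
    """Chimeric reads = mature miRNA (DNA) + constructed target part.

    Classes needing a CG seed (cg_bulge) draw from the CG-containing catalog
    subset; mixture proportions are honored exactly up to rounding.
    """
    rng = _rng(rng)
    cg = [m for m in mirnas if m.has_cg]
    counts = _mixture_counts(class_mixture, n_reads)
    if counts.get(clash_mod.CG_BULGE, 0) and not cg:
        raise ValueError("cg_bulge chimeras need a CG-containing miRNA")
    reads, true_rows = [], []
    i = 0
    for cls, k in counts.items():
        pool = cg if cls == clash_mod.CG_BULGE else list(mirnas)
        for _ in range(k):
            mir = pool[int(rng.integers(len(pool)))]
            tp = _construct_target_part(cls, mir, rng, target_len)
            read_id = f"read{i}"
            reads.append((read_id, rna_to_dna(mir.mature) + tp))
            true_rows.append(
                {"read_id": read_id, "mirna_id": mir.mirna_id, "true_class": cls}
            )
            i += 1
    order = rng.permutation(len(reads))
    reads = [reads[int(j)] for j in order]
    true_rows = [true_rows[int(j)] for j in order]
    truth = SyntheticTruth(
        params={"class_mixture": dict(class_mixture), "n_reads": n_reads},
        items={"reads": true_rows},
    )
    return reads, truth
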