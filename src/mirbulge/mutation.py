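"""MAF-binned, neutrally normalized mutation-rate profiles.

The scientific question: are CpG dinucleotides hypermutable in miRNA *target*
regions (3'UTR binding sites) while protected in the miRNA loci themselves?
Variants are assigned to annotated regions, classified as CpG / non-CpG from
their ±1 nt context (strand-aware: a ref C followed by G, or a ref G preceded
by C), binned by minor allele frequency, and normalized against a neutral
yardstick — the synonymous mutation count and length of the nearby gene:

    normalized = raw_count * 1000 / (n_synonymous * gene_length)

The ×1000 scale keeps the values readable; the product denominator is this
package's modeling choice for combining the two normalizers (the algebra is
documented, not prescribed).

Two comparison statistics are provided.  ``compare_profiles`` runs a
two-sample KS test, by default on the per-variant MAF samples (spectrum
shape).  ``compare_burden`` runs an exact binomial rate-ratio test on CpG
mutation *counts* given CpG site-count exposures — this is the test that
detects a planted rate multiplier, which changes burden but not spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import Region, VariantRecord

DEFAULT_MAF_EDGES = (0.001, 0.005, 0.01, 0.05, 0.1, 0.5)

CLASS_CG = "CG"
CLASS_NONCG = "nonCG"
REGION_MIRNA = "mirna"
REGION_TARGET = "target_site"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class MutationProfile:
    region_class: str
    dinucleotide_class: str
    maf_bin_edges: tuple[float, ...]
    raw_counts: np.ndarray
    n_synonymous: int
    gene_length: float
    mafs: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def normalized_counts(self) -> np.ndarray:
        return normalize_counts(self.raw_counts, self.n_synonymous, self.gene_length)


def assign_variants(
    variants: Sequence[VariantRecord],
    regions: Sequence[Region],
) -> list[tuple[VariantRecord, Region]]:
    """Label each variant with the region containing it; outside-all → dropped.

    Regions are assumed non-overlapping within a class; a variant at the
    half-open end boundary (pos == end) is outside.
    """
    by_chrom: dict[str, list[Region]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    out = []
    for chrom, regs in by_chrom.items():
        regs.sort(key=lambda r: r.start)
        starts = np.array([r.start for r in regs])
        for v in variants:
            if v.chrom != chrom:
                continue
            i = int(np.searchsorted(starts, v.pos0, side="right")) - 1
            if i >= 0 and regs[i].start <= v.pos0 < regs[i].end:
                out.append((v, regs[i]))
    return out


def classify_dinucleotide(
    variant: VariantRecord, region: Region, region_sequence: str
) -> tuple[str, bool, bool]:
    """(CG/nonCG class, is_C_to_T deamination flag, missing-flank warning).

    Context comes from the region's own sequence (genomic, + orientation).
    CpG membership is strand-symmetric: ref C followed by G, or ref G preceded
    by C.  ``is_C_to_T`` is true for C→T on the CpG strand or G→A on its
    complement.  A variant at a region edge with no flank on the needed side
    is classified nonCG with the warning flag set.
    """
    off = variant.pos0 - region.start
    if not (0 <= off < len(region_sequence)):
        raise ValueError("variant outside the supplied region sequence")
    ref = variant.ref
    if region_sequence[off] != ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos0}: region has "
            f"{region_sequence[off]!r}, variant says {ref!r}"
        )
    if ref == "C":
        if off + 1 >= len(region_sequence):
            return CLASS_NONCG, False, True
        is_cg = region_sequence[off + 1] == "G"
        return (CLASS_CG if is_cg else CLASS_NONCG), is_cg and variant.alt == "T", False
    if ref == "G":
        if off == 0:
            return CLASS_NONCG, False, True
        is_cg = region_sequence[off - 1] == "C"
        return (CLASS_CG if is_cg else CLASS_NONCG), is_cg and variant.alt == "A", False
    return CLASS_NONCG, False, False


def bin_by_maf(
    mafs: Sequence[float], bin_edges: Sequence[float] = DEFAULT_MAF_EDGES
) -> np.ndarray:
    """Left-open, right-closed binning of MAFs into (0, e1], (e1, e2], ...

    The edges are the bins' upper bounds (ascending, last one 0.5 by default);
    a MAF outside (0, 0.5] is an error.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size == 0 or np.any(np.diff(edges) <= 0) or edges[0] <= 0:
        raise ValueError("bin edges must be ascending and positive")
    mafs = np.asarray(mafs, dtype=float)
    if mafs.size and (mafs.min() <= 0 or mafs.max() > edges[-1]):
        raise ValueError(f"MAF outside (0, {edges[-1]}]")
    # np.searchsorted with side='left' gives right-closed bins on the edges
    idx = np.searchsorted(edges, mafs, side="left")
    return np.bincount(idx, minlength=edges.size)


def normalize_counts(
    raw_counts: np.ndarray | Sequence[float], n_synonymous: int, gene_length: float
) -> np.ndarray:
    """raw × 1000 / (n_synonymous × gene_length), per bin.

    For pooled profiles ``gene_length`` is the mean length of the pooled genes.
    """
    if n_synonymous < 1:
        raise ValueError(
            "n_synonymous must be >= 1; configure a pseudo-count for genes "
            "without observed synonymous variation"
        )
    if gene_length < 1:
        raise ValueError("gene_length must be >= 1")
    return np.asarray(raw_counts, dtype=float) * 1000.0 / (n_synonymous * gene_length)


def build_profile(
    assigned: Sequence[tuple[VariantRecord, Region]],
    region_sequences: Mapping[str, str],
    region_class: str,
    dinucleotide_class: str,
    n_synonymous: int,
    gene_length: float,
    bin_edges: Sequence[float] = DEFAULT_MAF_EDGES,
) -> MutationProfile:
    """Profile for one (region class, dinucleotide class) cell."""
    mafs = []
    for v, r in assigned:
        cls, _c2t, _warn = classify_dinucleotide(v, r, region_sequences[r.name])
        if cls == dinucleotide_class:
            mafs.append(v.maf)
    return MutationProfile(
        region_class=region_class,
        dinucleotide_class=dinucleotide_class,
        maf_bin_edges=tuple(bin_edges),
        raw_counts=bin_by_maf(mafs, bin_edges),
        n_synonymous=n_synonymous,
        gene_length=gene_length,
        mafs=np.asarray(mafs, dtype=float),
    )


def compare_profiles(
    profile_a: MutationProfile,
    profile_b: MutationProfile,
    on: str = "variants",
) -> dict:
    """Two-sample KS comparison of two mutation profiles.

    ``on='variants'`` (default) compares the per-variant MAF samples;
    ``on='bins'`` compares the per-bin normalized values.  The report states
    which profile has the larger normalized total.
    """
    if profile_a.maf_bin_edges != profile_b.maf_bin_edges:
        raise ValueError("profiles are on different MAF bins")
    if on == "variants":
        a, b = profile_a.mafs, profile_b.mafs
    elif on == "bins":
        a, b = profile_a.normalized_counts, profile_b.normalized_counts
    else:
        raise ValueError(f"unknown comparison basis {on!r}")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty profile")
    res = stats.ks_2samp(a, b)
    tot_a = float(profile_a.normalized_counts.sum())
    tot_b = float(profile_b.normalized_counts.sum())
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "higher_normalized_total": (
            profile_a.region_class if tot_a > tot_b
            else profile_b.region_class if tot_b > tot_a
            else "tie"
        ),
        "normalized_totals": {
            profile_a.region_class: tot_a,
            profile_b.region_class: tot_b,
        },
    }


def compare_burden(
    count_a: int,
    exposure_a: float,
    count_b: int,
    exposure_b: float,
    alternative: str = "two-sided",
) -> dict:
    """Exact binomial rate-ratio test for mutation burden.

    Conditional on the total count, under equal per-site rates the count in
    group A is Binomial(total, exposure_a / (exposure_a + exposure_b));
    exposures are site counts (e.g. number of CpG dyads surveyed). The rate
    ratio a/b is reported (inf when b has no mutations).
    """
    if exposure_a <= 0 or exposure_b <= 0:
        raise ValueError("exposures must be positive")
    total = count_a + count_b
    if total == 0:
        raise ValueError("no mutations in either group")
    p0 = exposure_a / (exposure_a + exposure_b)
    res = stats.binomtest(count_a, total, p0, alternative=alternative)
    rate_a = count_a / exposure_a
    rate_b = count_b / exposure_b
    return {
        "p": float(res.pvalue),
        "rate_a": rate_a,
        "rate_b": rate_b,
        "rate_ratio": (rate_a / rate_b) if rate_b > 0 else float("inf"),
    }
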