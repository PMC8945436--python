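"""Seed extraction, CG-dimer classification, and target-site search.

A mature miRNA's seed is the 5' block starting at position 2 (1-based) of the
mature sequence, length 6 or 7 (default 7, i.e. positions 2-8).  A canonical
seed target is a 3'UTR substring equal to the seed's reverse complement; a
CG-bulge target carries one extra nucleotide inserted, on the target side,
between the C and G that pair the seed's G and C (so the target-side CG dimer
is interrupted by a single bulged base).  Random-bulge patterns — one base
inserted at a random interior position that is *not* a CG gap — serve as the
specificity control.

Unknown bases (``N``) never match anything.  Search is on the UTR sense strand
only; miRNA targeting is strand-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import RNA_ALPHABET, UTRRecord, reverse_complement_dna, rna_to_dna

DEFAULT_SEED_LEN = 7

SITE_SEED = "seed"
SITE_CG_BULGE = "cg_bulge"
SITE_RANDOM_BULGE = "random_bulge"


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA with its seed substring and CG-dimer annotation."""

    mirna_id: str
    mature: str  # RNA
    seed: str
    cg_positions: tuple[int, ...]
    conservation_tier: str = "none"

    @property
    def has_cg(self) -> bool:
        return bool(self.cg_positions)


def make_mirna_record(
    mirna_id: str,
    mature: str,
    seed_len: int = DEFAULT_SEED_LEN,
    conservation_tier: str = "none",
) -> MiRNARecord:
    seed = extract_seed(mature, seed_len)
    return MiRNARecord(
        mirna_id=mirna_id,
        mature=mature.upper().replace("T", "U"),
        seed=seed,
        cg_positions=tuple(find_cg_dimers(seed)),
        conservation_tier=conservation_tier,
    )


@dataclass(frozen=True)
class TargetSite:
    """One predicted binding site on a UTR.

    ``utr_offset`` is the 0-based start of the matched pattern within the UTR
    sequence; for bulge site types ``bulge_gap_index`` is the 0-based index in
    the seed-match pattern *after* which the bulge base was inserted.
    """

    gene_id: str
    utr_offset: int
    site_len: int
    site_type: str
    pattern: str
    source_seed: str
    bulge_base: str = ""
    bulge_gap_index: int = -1
    also_seed_site: bool = False

    def __post_init__(self) -> None:
        if self.site_type == SITE_SEED:
            if self.bulge_base:
                raise ValueError("seed site cannot carry a bulge base")
        elif self.site_type in (SITE_CG_BULGE, SITE_RANDOM_BULGE):
            if len(self.bulge_base) != 1:
                raise ValueError(f"{self.site_type} site needs a 1-nt bulge base")
        else:
            raise ValueError(f"unknown site_type {self.site_type!r}")


@dataclass(frozen=True)
class BulgePattern:
    pattern: str  # DNA, length seed_len + 1
    cg_index: int  # 0-based start of the interrupted CG in the seed-match pattern
    bulge_base: str


def extract_seed(mature: str, seed_len: int = DEFAULT_SEED_LEN) -> str:
    """Seed = mature positions 2..(1+seed_len), 1-based inclusive."""
    if seed_len not in (6, 7):
        raise ValueError(f"seed_len must be 6 or 7, got {seed_len}")
    mature = mature.upper().replace("T", "U")
    if len(mature) < seed_len + 1:
        raise ValueError(
            f"mature sequence of length {len(mature)} too short for seed_len {seed_len}"
        )
    return mature[1 : 1 + seed_len]


def find_cg_dimers(seed: str) -> list[int]:
    """All 0-based indices i with seed[i:i+2] == 'CG' (overlap impossible)."""
    if not seed:
        raise ValueError("empty seed")
    return [i for i in range(len(seed) - 1) if seed[i : i + 2] == "CG"]


def seed_match_pattern(seed: str) -> str:
    """Reverse complement of the (RNA) seed, in DNA alphabet.

    This is the pattern searched on the UTR sense strand.
    """
    seed = seed.upper()
    bad = set(seed) - (RNA_ALPHABET - {"N"})
    if bad:
        raise ValueError(f"non-ACGU character(s) in seed: {sorted(bad)}")
    return reverse_complement_dna(rna_to_dna(seed))


def _scan(pattern: str, utr: UTRRecord) -> Iterable[int]:
    """Yield all (possibly overlapping) match offsets; N never matches."""
    if "N" in pattern:
        return
    hay = utr.sequence
    start = hay.find(pattern)
    while start != -1:
        yield start
        start = hay.find(pattern, start + 1)


def find_seed_targets(seed: str, utrs: Sequence[UTRRecord]) -> list[TargetSite]:
    """Every occurrence of the perfect seed match, one TargetSite each."""
    pattern = seed_match_pattern(seed)
    sites = []
    for utr in utrs:
        for off in _scan(pattern, utr):
            sites.append(
                TargetSite(
                    gene_id=utr.gene_id,
                    utr_offset=off,
                    site_len=len(pattern),
                    site_type=SITE_SEED,
                    pattern=pattern,
                    source_seed=seed,
                )
            )
    return sites


def cg_gap_indices(pattern: str) -> list[int]:
    """Insertion points (0-based, 'after this many leading bases') that fall
    between the C and G of a CG dimer in a seed-match pattern."""
    return [k + 1 for k in range(len(pattern) - 1) if pattern[k : k + 2] == "CG"]


def enumerate_bulge_patterns(seed: str) -> list[BulgePattern]:
    """All CG-gap bulge patterns for a seed; empty when the seed has no CG.

    For each CG occurrence in the seed-match pattern (the target-side CG), four
    patterns are emitted inserting A/C/G/T between that C and G.  Duplicate
    pattern strings arising from multiple CG occurrences are deduplicated
    keeping the first (5'-most) generating gap.
    """
    match = seed_match_pattern(seed)
    out: list[BulgePattern] = []
    seen: set[str] = set()
    for gap in cg_gap_indices(match):
        for base in "ACGT":
            pat = match[:gap] + base + match[gap:]
            if pat not in seen:
                seen.add(pat)
                out.append(BulgePattern(pattern=pat, cg_index=gap - 1, bulge_base=base))
    return out


def generate_random_bulge_controls(
    seed: str,
    n_patterns: int,
    rng: np.random.Generator | int,
    dedup: bool = False,
) -> list[BulgePattern]:
    """Random single-base insertions into the seed-match pattern, as controls.

    The insertion point is uniform over *interior* points (1..L-1) excluding
    any point between a target-side CG dimer — an end insertion would leave the
    perfect seed match intact, and a CG-gap insertion would be the bulge class
    under test.  The inserted base is uniform over ACGT.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    match = seed_match_pattern(seed)
    forbidden = set(cg_gap_indices(match))
    legal = [p for p in range(1, len(match)) if p not in forbidden]
    if not legal:
        raise ValueError(f"no legal insertion point in pattern {match!r}")
    points = rng.choice(legal, size=n_patterns, replace=True)
    bases = rng.choice(list("ACGT"), size=n_patterns, replace=True)
    out, seen = [], set()
    for p, b in zip(points, bases):
        pat = match[: int(p)] + str(b) + match[int(p) :]
        if dedup and pat in seen:
            continue
        seen.add(pat)
        out.append(BulgePattern(pattern=pat, cg_index=int(p) - 1, bulge_base=str(b)))
    return out


def find_bulge_targets(
    seed: str,
    utrs: Sequence[UTRRecord],
    patterns: Sequence[BulgePattern],
    site_type: str = SITE_CG_BULGE,
) -> list[TargetSite]:
    """All occurrences of any bulge pattern, tagged with the generating insertion.

    A bulge match that simultaneously contains the perfect seed match in a
    different frame is kept and flagged ``also_seed_site``.
    """
    seed_pat = seed_match_pattern(seed)
    sites = []
    for utr in utrs:
        for bp in patterns:
            for off in _scan(bp.pattern, utr):
                sites.append(
                    TargetSite(
                        gene_id=utr.gene_id,
                        utr_offset=off,
                        site_len=len(bp.pattern),
                        site_type=site_type,
                        pattern=bp.pattern,
                        source_seed=seed,
                        bulge_base=bp.bulge_base,
                        bulge_gap_index=bp.cg_index + 1,
                        also_seed_site=seed_pat in bp.pattern,
                    )
                )
    return sites


def count_target_genes(sites: Iterable[TargetSite]) -> int:
    """Target number = number of distinct genes with at least one site."""
    return len({s.gene_id for s in sites})


def summarize_mirna(
    mirna: MiRNARecord,
    utrs: Sequence[UTRRecord],
    n_controls: int = 0,
    rng: np.random.Generator | int = 0,
) -> dict:
    """Per-miRNA seed/bulge (and optional random-control) target gene counts."""
    seed_sites = find_seed_targets(mirna.seed, utrs)
    bulge_sites = find_bulge_targets(
        mirna.seed, utrs, enumerate_bulge_patterns(mirna.seed)
    )
    row = {
        "mirna_id": mirna.mirna_id,
        "seed": mirna.seed,
        "has_cg": mirna.has_cg,
        "n_target_genes": count_target_genes(seed_sites),
        "n_target_sites": len(seed_sites),
        "n_bulge_genes": count_target_genes(bulge_sites),
        "n_bulge_sites": len(bulge_sites),
    }
    if n_controls:
        ctrl = find_bulge_targets(
            mirna.seed,
            utrs,
            generate_random_bulge_controls(mirna.seed, n_controls, rng),
            site_type=SITE_RANDOM_BULGE,
        )
        row["n_control_genes"] = count_target_genes(ctrl)
        row["n_control_sites"] = len(ctrl)
    return row
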