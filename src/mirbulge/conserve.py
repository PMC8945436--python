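"""Cross-species conservation of target sites.

A site's conservation rate is the number of aligned species in which the
homologous site is intact, the reference species included (so the rate is
always at least 1).  Two intactness modes are provided because "homologous
target site" admits readings:

* ``exact`` — the species' gap-stripped subsequence under the reference
  columns equals the site pattern (default for seed sites);
* ``pattern`` — the species' subsequence contains *any* pattern of the same
  site class for the same seed, e.g. a bulge site conserved with a different
  bulged base still counts (default for bulge site classes).

Sites that cannot be projected (not fully covered by alignment blocks) are
excluded from scoring rather than scored 0, and reported separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import AlignmentBlock, UTRRecord, reverse_complement_dna
from .targets import (
    SITE_CG_BULGE,
    SITE_RANDOM_BULGE,
    SITE_SEED,
    TargetSite,
    cg_gap_indices,
    enumerate_bulge_patterns,
    seed_match_pattern,
)

MODE_EXACT = "exact"
MODE_PATTERN = "pattern"


@dataclass
class ConservationResult:
    site: TargetSite
    n_species_total: int
    n_species_conserved: int
    intact: dict[str, bool]

    def __post_init__(self) -> None:
        if sum(self.intact.values()) != self.n_species_conserved:
            raise ValueError("intact flags inconsistent with conserved count")
        if not (1 <= self.n_species_conserved <= self.n_species_total):
            raise ValueError(
                f"conserved count {self.n_species_conserved} outside "
                f"[1, {self.n_species_total}]"
            )

    @property
    def rate(self) -> int:
        return self.n_species_conserved


class UnprojectableSite(Exception):
    """The site is not fully covered by the alignment (block gap)."""


def _column_map(gapped: str) -> np.ndarray:
    """colmap[u] = alignment column holding ungapped reference position u."""
    arr = np.frombuffer(gapped.encode(), dtype="S1")
    return np.flatnonzero(arr != b"-")


def project_site(
    site: TargetSite,
    utr: UTRRecord,
    blocks: Sequence[AlignmentBlock],
) -> dict[str, str | None]:
    """Per-species gap-stripped subsequences under the site's reference columns.

    Stitches adjacent blocks with contiguous reference coordinates. A species
    absent from any covering block, or entirely gapped under the site, is
    marked missing (``None``).  Raises :class:`UnprojectableSite` when the
    reference coverage of the site is incomplete.
    """
    if site.utr_offset < 0 or site.utr_offset + site.site_len > len(utr.sequence):
        raise ValueError("site does not lie within the UTR")
    if utr.strand == "+":
        g0 = utr.start + site.utr_offset
    else:
        g0 = utr.end - site.utr_offset - site.site_len
    g1 = g0 + site.site_len

    # collect covering blocks in genomic order
    covering = []
    for block in blocks:
        ref = block.ref
        if ref.chrom and utr.chrom and ref.chrom != utr.chrom:
            continue
        if ref.start < g1 and g0 < ref.start + ref.size:
            covering.append(block)
    covering.sort(key=lambda b: b.ref.start)

    covered = 0
    pieces: dict[str, list[str | None]] = {}
    species_seen: set[str] = set()
    for block in covering:
        ref = block.ref
        lo = max(g0, ref.start)
        hi = min(g1, ref.start + ref.size)
        covered += hi - lo
        colmap = _column_map(ref.text)
        cols = colmap[lo - ref.start : hi - ref.start]
        species_seen.update(block.rows)
        for sp in block.rows:
            chars = "".join(block.rows[sp].text[c] for c in cols).replace("-", "")
            pieces.setdefault(sp, []).append(chars)
        for sp in pieces:
            if sp not in block.rows:
                pieces[sp].append(None)
    if covered != site.site_len:
        raise UnprojectableSite(
            f"site at {utr.chrom}:{g0}-{g1} covered for {covered}/{site.site_len} nt"
        )

    n_blocks_used = sum(
        1 for b in covering if max(g0, b.ref.start) < min(g1, b.ref.start + b.ref.size)
    )
    out: dict[str, str | None] = {}
    for sp in species_seen:
        segs = pieces.get(sp, [])
        if len(segs) != n_blocks_used or any(s is None for s in segs):
            out[sp] = None  # absent from some covering block
            continue
        joined = "".join(segs)  # type: ignore[arg-type]
        if utr.strand == "-":
            joined = reverse_complement_dna(joined)
        out[sp] = joined if joined else None  # fully gapped row -> missing
    return out


def _class_patterns(site_type: str, seed: str) -> set[str]:
    """All patterns of a site class for a seed (for ``pattern`` intactness)."""
    if site_type == SITE_SEED:
        return {seed_match_pattern(seed)}
    match = seed_match_pattern(seed)
    if site_type == SITE_CG_BULGE:
        return {bp.pattern for bp in enumerate_bulge_patterns(seed)}
    if site_type == SITE_RANDOM_BULGE:
        forbidden = set(cg_gap_indices(match))
        return {
            match[:p] + b + match[p:]
            for p in range(1, len(match))
            if p not in forbidden
            for b in "ACGT"
        }
    raise ValueError(f"unknown site_type {site_type!r}")


def site_conservation_rate(
    site: TargetSite,
    projections: Mapping[str, str | None],
    mode: str | None = None,
    ref_species: str = "hg19",
) -> ConservationResult:
    """Count species in which the homologous site is intact.

    ``mode=None`` picks the class default: ``exact`` for seed sites,
    ``pattern`` for bulge classes.
    """
    if mode is None:
        mode = MODE_EXACT if site.site_type == SITE_SEED else MODE_PATTERN
    if mode not in (MODE_EXACT, MODE_PATTERN):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == MODE_PATTERN:
        patterns = _class_patterns(site.site_type, site.source_seed)
    intact: dict[str, bool] = {}
    for sp, sub in projections.items():
        if sp == ref_species:
            intact[sp] = True  # reference carries the site by construction
            continue
        if sub is None:
            continue  # missing species: excluded from the denominator
        if mode == MODE_EXACT:
            intact[sp] = sub == site.pattern
        else:
            intact[sp] = any(p in sub for p in patterns)
    return ConservationResult(
        site=site,
        n_species_total=len(intact),
        n_species_conserved=sum(intact.values()),
        intact=intact,
    )


def conservation_histogram(
    results: Sequence[ConservationResult], site_type: str | None = None
) -> dict[int, int]:
    """Counts of sites per integer conservation rate (optionally one class)."""
    hist: dict[int, int] = {}
    for res in results:
        if site_type is not None and res.site.site_type != site_type:
            continue
        hist[res.rate] = hist.get(res.rate, 0) + 1
    return hist


def compare_site_classes(
    rates_seed: Sequence[int],
    rates_bulge: Sequence[int],
    rates_control: Sequence[int],
) -> dict:
    """Pairwise two-sided rank-sum comparison of conservation-rate groups.

    Groups with fewer than 3 observations are skipped with a warning. The
    report states which class has the higher median in each tested pair.
    """
    groups = {
        "seed": np.asarray(rates_seed, dtype=float),
        "cg_bulge": np.asarray(rates_bulge, dtype=float),
        "random_bulge": np.asarray(rates_control, dtype=float),
    }
    report: dict = {
        "medians": {k: (float(np.median(v)) if v.size else None) for k, v in groups.items()},
        "n": {k: int(v.size) for k, v in groups.items()},
        "pairwise": {},
        "skipped": [],
    }
    names = list(groups)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if groups[a].size < 3 or groups[b].size < 3:
                msg = f"{a} vs {b}: a group has <3 observations, test skipped"
                warnings.warn(msg)
                report["skipped"].append(f"{a}|{b}")
                continue
            res = stats.mannwhitneyu(groups[a], groups[b], alternative="two-sided")
            med_a, med_b = np.median(groups[a]), np.median(groups[b])
            higher = a if med_a > med_b else b if med_b > med_a else "tie"
            report["pairwise"][f"{a}|{b}"] = {
                "p": float(res.pvalue),
                "higher_median": higher,
            }
    return report
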