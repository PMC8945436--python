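"""CLASH chimeric-read analysis.

A CLASH chimeric read carries a mature miRNA ligated to a fragment of its
bound target.  The analysis splits each read into its miRNA and target parts
against a catalog of mature sequences, classifies the miRNA-target interaction
from the seed's pairing to the target part, and contrasts the class
proportions with two resampling nulls:

* shuffle — target parts permuted across miRNA assignments (breaks the
  specific pairing, keeps both marginals);
* scramble — each target part's nucleotides permuted (keeps length and
  composition, destroys all motifs).  The scrambled parts are re-searched for
  the class patterns directly; this reproduces the combinatorial background
  that genome remapping of scrambled reads estimates.

Classification precedence, applied to reads satisfying several patterns:
canonical seed > CG bulge > G:U wobble > single mismatch > other bulge >
unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .targets import (
    cg_gap_indices,
    enumerate_bulge_patterns,
    seed_match_pattern,
)

CANONICAL = "canonical_seed"
CG_BULGE = "cg_bulge"
GU_WOBBLE = "gu_wobble"
ONE_MISMATCH = "one_nt_mismatch"
OTHER_BULGE = "other_bulge"
UNCLASSIFIED = "unclassified"

CLASSES = (CANONICAL, CG_BULGE, GU_WOBBLE, ONE_MISMATCH, OTHER_BULGE, UNCLASSIFIED)
NONCANONICAL_CLASSES = (CG_BULGE, GU_WOBBLE, ONE_MISMATCH, OTHER_BULGE)

_WC_DNA = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU_DNA = {("G", "T"), ("T", "G")}  # seed G : target U, seed U : target G


@dataclass(frozen=True)
class ChimericRead:
    read_id: str
    sequence: str  # full read, DNA
    mirna_id: str = ""  # empty = unassigned
    mirna_part: str = ""
    target_part: str = ""
    interaction_class: str = UNCLASSIFIED
    unassigned_reason: str = ""

    @property
    def assigned(self) -> bool:
        return bool(self.mirna_id)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def split_chimera(
    read_id: str,
    sequence: str,
    mirna_catalog: Mapping[str, str],
    min_prefix: int = 16,
    max_mismatches: int = 1,
    orders: Sequence[str] = ("mirna_first",),
) -> ChimericRead:
    """Assign a read to the unique miRNA matching its prefix (or suffix).

    ``mirna_catalog`` maps miRNA id to mature sequence (RNA or DNA).  A
    catalog entry matches when its first ``min(len(mature), len(read))``
    bases agree with the read end up to ``max_mismatches`` (sequencing errors)
    and at least ``min_prefix`` bases are compared.  Among matches the longest
    match with fewest mismatches wins; an exact tie is ambiguous and the read
    stays unassigned.  Unassignable reads are data, not errors.
    """
    seq = sequence.upper().replace("U", "T")
    candidates: list[tuple[int, int, str, str]] = []  # (-match_len, nmm, id, order)
    for mid, mature in mirna_catalog.items():
        mat = mature.upper().replace("U", "T")
        mlen = min(len(mat), len(seq))
        if mlen < min_prefix:
            continue
        if "mirna_first" in orders:
            nmm = _hamming(seq[:mlen], mat[:mlen])
            if nmm <= max_mismatches:
                candidates.append((-mlen, nmm, mid, "mirna_first"))
        if "mirna_last" in orders:
            nmm = _hamming(seq[-mlen:], mat[:mlen])
            if nmm <= max_mismatches:
                candidates.append((-mlen, nmm, mid, "mirna_last"))
    if not candidates:
        return ChimericRead(read_id, seq, unassigned_reason="no_mirna")
    candidates.sort(key=lambda c: (c[0], c[1]))
    best = candidates[0]
    ties = [c for c in candidates if c[:2] == best[:2]]
    if len({c[2] for c in ties}) > 1:
        return ChimericRead(read_id, seq, unassigned_reason="ambiguous")
    mlen = -best[0]
    if best[3] == "mirna_first":
        mirna_part, target_part = seq[:mlen], seq[mlen:]
    else:
        mirna_part, target_part = seq[-mlen:], seq[:-mlen]
    return ChimericRead(
        read_id, seq, mirna_id=best[2], mirna_part=mirna_part, target_part=target_part
    )


def _window_pairing(seed: str, window: str) -> tuple[int, int, int]:
    """(n_wc, n_gu, n_mismatch) pairing seed 5'→3' against a same-length
    DNA window read 3'→5' (antiparallel): seed position i pairs window
    position L-1-i.  G:U wobble in DNA space is seed G : target T or
    seed U(T) : target G."""
    L = len(seed)
    seed_dna = seed.upper().replace("U", "T")
    wc = gu = mm = 0
    for i in range(L):
        pair = (seed_dna[i], window[L - 1 - i])
        if pair in _WC_DNA:
            wc += 1
        elif pair in _GU_DNA:
            gu += 1
        else:
            mm += 1
    return wc, gu, mm


def _other_bulge_patterns(seed: str) -> set[str]:
    match = seed_match_pattern(seed)
    forbidden = set(cg_gap_indices(match))
    return {
        match[:p] + b + match[p:]
        for p in range(1, len(match))
        if p not in forbidden
        for b in "ACGT"
    }


def classify_interaction(seed: str, target_part: str) -> str:
    """Classify a seed : target-part interaction with the stated precedence.

    canonical = perfect seed match present; cg_bulge = any CG-gap bulge
    pattern present; gu_wobble = some seed-length window pairs with ≥1 G:U and
    no mismatch; one_nt_mismatch = some window with exactly one non-pairing
    position and every other position Watson-Crick; other_bulge = a single
    insertion outside the CG gap; otherwise unclassified.
    """
    tp = target_part.upper().replace("U", "T")
    L = len(seed)
    if seed_match_pattern(seed) in tp:
        return CANONICAL
    if any(bp.pattern in tp for bp in enumerate_bulge_patterns(seed)):
        return CG_BULGE
    best_gu = False
    best_mm = False
    for off in range(len(tp) - L + 1):
        _wc, gu, mm = _window_pairing(seed, tp[off : off + L])
        if mm == 0 and gu >= 1:
            best_gu = True
            break
        if mm == 1 and gu == 0:
            best_mm = True
    if best_gu:
        return GU_WOBBLE
    if best_mm:
        return ONE_MISMATCH
    if any(pat in tp for pat in _other_bulge_patterns(seed)):
        return OTHER_BULGE
    return UNCLASSIFIED


def classify_reads(
    reads: Sequence[ChimericRead], seeds: Mapping[str, str]
) -> list[ChimericRead]:
    """Attach an interaction class to every assigned read with a known seed."""
    out = []
    for read in reads:
        if read.assigned and read.mirna_id in seeds and read.target_part:
            cls = classify_interaction(seeds[read.mirna_id], read.target_part)
        else:
            cls = UNCLASSIFIED
        out.append(replace(read, interaction_class=cls))
    return out


def shuffle_pairs(
    reads: Sequence[ChimericRead], rng: np.random.Generator | int
) -> list[ChimericRead]:
    """Permute target parts across miRNA assignments (shuffle null).

    Preserves the multiset of miRNA ids and of target parts; derangement is
    not enforced.  Only assigned reads participate.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    assigned = [r for r in reads if r.assigned]
    if len(assigned) < 2:
        raise ValueError("need at least 2 assigned reads to shuffle")
    perm = rng.permutation(len(assigned))
    return [
        replace(
            assigned[i],
            target_part=assigned[int(perm[i])].target_part,
            sequence=assigned[i].mirna_part + assigned[int(perm[i])].target_part,
            interaction_class=UNCLASSIFIED,
        )
        for i in range(len(assigned))
    ]


def scramble_reads(
    reads: Sequence[ChimericRead], rng: np.random.Generator | int
) -> list[ChimericRead]:
    """Mononucleotide-shuffle each target part (scramble null).

    Preserves per-read length and base composition exactly.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    out = []
    for read in reads:
        chars = np.array(list(read.target_part))
        scrambled = "".join(chars[rng.permutation(len(chars))]) if len(chars) else ""
        out.append(
            replace(
                read,
                target_part=scrambled,
                sequence=read.mirna_part + scrambled,
                interaction_class=UNCLASSIFIED,
            )
        )
    return out


def class_proportions(reads: Sequence[ChimericRead]) -> dict[str, float]:
    if not reads:
        raise ValueError("empty read set")
    n = len(reads)
    return {c: sum(r.interaction_class == c for r in reads) / n for c in CLASSES}


def enrichment_report(
    real: Sequence[ChimericRead],
    shuffled: Sequence[ChimericRead],
    scrambled: Sequence[ChimericRead],
) -> dict:
    """Class proportions per set, real/null fold enrichments, and the
    non-canonical : canonical ratio in the real set."""
    props = {
        "real": class_proportions(real),
        "shuffle": class_proportions(shuffled),
        "scramble": class_proportions(scrambled),
    }
    folds = {}
    for null in ("shuffle", "scramble"):
        folds[null] = {
            c: (props["real"][c] / props[null][c]) if props[null][c] > 0 else float("inf")
            for c in CLASSES
        }
    canon = props["real"][CANONICAL]
    noncanon = sum(props["real"][c] for c in NONCANONICAL_CLASSES)
    return {
        "proportions": props,
        "fold_enrichment": folds,
        "noncanonical_to_canonical": (noncanon / canon) if canon > 0 else float("inf"),
        "n": {"real": len(real), "shuffle": len(shuffled), "scramble": len(scrambled)},
    }
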