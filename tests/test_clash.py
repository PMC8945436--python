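import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirbulge.clash import (
    CANONICAL,
    CG_BULGE,
    CLASSES,
    GU_WOBBLE,
    ONE_MISMATCH,
    OTHER_BULGE,
    UNCLASSIFIED,
    class_proportions,
    classify_interaction,
    classify_reads,
    enrichment_report,
    scramble_reads,
    shuffle_pairs,
    split_chimera,
)
from mirbulge.simulate import gen_chimeras, gen_mirnas
from mirbulge.targets import make_mirna_record, seed_match_pattern

MIR184 = "UGGACGGAGAACUGAUAAGGGU"  # seed GGACGGA, match TCCGTCC


def catalog(**entries):
    return dict(entries) or {"mir-184": MIR184}


class TestSplitChimera:
    def test_mirna_prefix_plus_target_splits_at_boundary(self):
        target = "TTGACCATGAAATCCGTCCAAGGAT"
        read = MIR184.replace("U", "T") + target
        res = split_chimera("r1", read, {"mir-184": MIR184})
        assert res.mirna_id == "mir-184"
        assert res.mirna_part == MIR184.replace("U", "T")
        assert res.target_part == target
        assert res.mirna_part + res.target_part == res.sequence

    def test_equal_prefix_match_is_ambiguous(self):
        cat = {"a": "ACGUACGUACGUACGUACGU", "b": "ACGUACGUACGUACGUACGU"}
        read = "ACGTACGTACGTACGTACGT" + "TTTTTTTTTT"
        res = split_chimera("r1", read, cat)
        assert not res.assigned and res.unassigned_reason == "ambiguous"

    def test_no_sufficient_match_unassigned(self):
        res = split_chimera("r1", "T" * 40, {"mir-184": MIR184}, min_prefix=16)
        assert not res.assigned and res.unassigned_reason == "no_mirna"

    def test_one_mismatch_tolerated(self):
        read = ("A" + MIR184.replace("U", "T")[1:]) + "CCCCCCCCCC"
        res = split_chimera("r1", read, {"mir-184": MIR184}, max_mismatches=1)
        assert res.mirna_id == "mir-184"


def pairing_oracle(seed, window):
    """Independent per-position pairing classifier for a seed-length window."""
    comp = {"A": "T", "C": "G", "G": "C", "U": "A", "T": "A"}
    wob = {("G", "T"), ("U", "G"), ("T", "G")}
    counts = {"wc": 0, "gu": 0, "mm": 0}
    for i, s in enumerate(seed):
        t = window[len(seed) - 1 - i]
        if comp[s] == t:
            counts["wc"] += 1
        elif (s, t) in wob or (s == "G" and t == "T"):
            counts["gu"] += 1
        else:
            counts["mm"] += 1
    return counts


class TestClassifyInteraction:
    def test_perfect_match_is_canonical(self):
        assert classify_interaction("GGACGGA", "AATCCGTCCAA") == CANONICAL

    def test_cg_gap_insertion_is_cg_bulge(self):
        assert classify_interaction("GGACGGA", "AATCCAGTCCAA") == CG_BULGE

    def test_wobble_window_verified_against_pairing_oracle(self):
        # seed position 0 is G; replace its partner C by T -> one G:U pair
        window = "TCCGTCT"[::-1][::-1]
        window = "TCCGTC" + "T"  # partner of seed[0]=G is window[6]
        cls = classify_interaction("GGACGGA", "AA" + window + "AA")
        oracle = pairing_oracle("GGACGGA", window)
        assert oracle == {"wc": 6, "gu": 1, "mm": 0}
        assert cls == GU_WOBBLE

    def test_single_mismatch_window(self):
        # replace the partner of seed[2]=A (window pos 4) by C: no pair, no wobble
        window = "TCCGCCC"
        oracle = pairing_oracle("GGACGGA", window)
        assert oracle["mm"] == 1
        assert classify_interaction("GGACGGA", "AA" + window + "AA") == ONE_MISMATCH

    def test_non_cg_insertion_is_other_bulge(self):
        # insert A mid-pattern outside the CG gap: TCCG[A]TCC.  Verify with
        # the pairing oracle that no 7-window reads as wobble or one-mismatch,
        # so the insertion class is what remains.
        pattern = "TCCGATCC"
        for off in range(len(pattern) - 6):
            counts = pairing_oracle("GGACGGA", pattern[off : off + 7])
            assert not (counts["mm"] == 0 and counts["gu"] >= 1)
            assert not (counts["mm"] == 1 and counts["gu"] == 0)
        assert classify_interaction("GGACGGA", "GG" + pattern + "TT") == OTHER_BULGE

    def test_garbage_is_unclassified(self):
        assert classify_interaction("GGACGGA", "TTTTTTTTTTTT") == UNCLASSIFIED

    def test_precedence_canonical_beats_bulge(self):
        # target carries both a perfect site and a CG-bulge site
        tp = "TCCGTCC" + "AAA" + "TCCAGTCC"
        assert classify_interaction("GGACGGA", tp) == CANONICAL

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=9, max_size=20))
    def test_classification_is_total_and_single_valued(self, tp):
        cls = classify_interaction("GGACGGA", tp)
        assert cls in CLASSES


class TestNulls:
    @pytest.fixture
    def planted_reads(self, rng):
        mirnas, _ = gen_mirnas(6, 0, rng)
        reads, truth = gen_chimeras(
            mirnas, {CG_BULGE: 1.0}, 60, rng=rng, target_len=30
        )
        cat = {m.mirna_id: m.mature for m in mirnas}
        seeds = {m.mirna_id: m.seed for m in mirnas}
        split = [split_chimera(rid, seq, cat) for rid, seq in reads]
        return classify_reads(split, seeds), seeds

    def test_shuffle_preserves_both_multisets_and_is_seeded(self, planted_reads):
        reads, seeds = planted_reads
        shuf1 = shuffle_pairs(reads, 3)
        shuf2 = shuffle_pairs(reads, 3)
        assert [r.target_part for r in shuf1] == [r.target_part for r in shuf2]
        assert sorted(r.mirna_id for r in shuf1) == sorted(r.mirna_id for r in reads)
        assert sorted(r.target_part for r in shuf1) == sorted(
            r.target_part for r in reads
        )

    def test_shuffle_collapses_planted_bulge_proportion(self, planted_reads):
        reads, seeds = planted_reads
        assert class_proportions(reads)[CG_BULGE] == 1.0
        shuf = classify_reads(shuffle_pairs(reads, 0), seeds)
        # cross-matched seeds only rarely share a bulge pattern
        assert class_proportions(shuf)[CG_BULGE] < 0.5

    def test_scramble_preserves_length_and_composition(self, planted_reads):
        reads, _ = planted_reads
        scram = scramble_reads(reads, 9)
        for before, after in zip(reads, scram):
            assert len(before.target_part) == len(after.target_part)
            assert sorted(before.target_part) == sorted(after.target_part)
        again = scramble_reads(reads, 9)
        assert [r.target_part for r in scram] == [r.target_part for r in again]

    def test_scramble_drops_bulge_proportion_to_background(self, planted_reads):
        reads, seeds = planted_reads
        scram = classify_reads(scramble_reads(reads, 1), seeds)
        # 8-mer pattern by chance: ~ (len-7) * 4^-8 * n_patterns, essentially 0
        assert class_proportions(scram)[CG_BULGE] < 0.1

    def test_two_reads_shuffle_is_seed_determined_permutation(self, planted_reads):
        reads, _ = planted_reads
        two = reads[:2]
        out = shuffle_pairs(two, 0)
        parts = {r.target_part for r in out}
        assert parts == {two[0].target_part, two[1].target_part}


class TestEnrichment:
    def test_planted_mixture_recovered_within_ci(self, rng):
        mirnas, _ = gen_mirnas(6, 2, rng)
        mixture = {CANONICAL: 0.3, CG_BULGE: 0.5, UNCLASSIFIED: 0.2}
        reads, truth = gen_chimeras(mirnas, mixture, 300, rng=rng)
        cat = {m.mirna_id: m.mature for m in mirnas}
        seeds = {m.mirna_id: m.seed for m in mirnas}
        real = classify_reads(
            [split_chimera(rid, seq, cat) for rid, seq in reads], seeds
        )
        props = class_proportions(real)
        for cls, p in mixture.items():
            se = np.sqrt(p * (1 - p) / 300)
            assert abs(props[cls] - p) <= 4 * se + 2 / 300

    def test_real_equal_null_gives_unit_folds(self, rng):
        mirnas, _ = gen_mirnas(4, 0, rng)
        reads, _ = gen_chimeras(mirnas, {CANONICAL: 0.5, CG_BULGE: 0.5}, 40, rng=rng)
        cat = {m.mirna_id: m.mature for m in mirnas}
        seeds = {m.mirna_id: m.seed for m in mirnas}
        real = classify_reads(
            [split_chimera(rid, seq, cat) for rid, seq in reads], seeds
        )
        rep = enrichment_report(real, real, real)
        for null in ("shuffle", "scramble"):
            for cls in (CANONICAL, CG_BULGE):
                assert rep["fold_enrichment"][null][cls] == pytest.approx(1.0)

    def test_planted_noncanonical_ratio_1p7_recovered(self, rng):
        # the published-scale scenario: non-canonical ~1.7x the canonical
        mixture = {
            CANONICAL: 0.37,
            CG_BULGE: 0.40,
            GU_WOBBLE: 0.08,
            ONE_MISMATCH: 0.08,
            OTHER_BULGE: 0.07,
        }
        planted_ratio = (1 - 0.37) / 0.37
        mirnas, _ = gen_mirnas(8, 0, rng)
        reads, _ = gen_chimeras(mirnas, mixture, 300, rng=rng)
        cat = {m.mirna_id: m.mature for m in mirnas}
        seeds = {m.mirna_id: m.seed for m in mirnas}
        real = classify_reads(
            [split_chimera(rid, seq, cat) for rid, seq in reads], seeds
        )
        rep = enrichment_report(real, real, real)
        se = np.sqrt(planted_ratio * (1 + planted_ratio) ** 2 / 300)
        assert abs(rep["noncanonical_to_canonical"] - planted_ratio) <= 3 * se

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            class_proportions([])
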