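import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_utr
from mirbulge.targets import (
    SITE_RANDOM_BULGE,
    cg_gap_indices,
    enumerate_bulge_patterns,
    extract_seed,
    find_bulge_targets,
    find_cg_dimers,
    find_seed_targets,
    generate_random_bulge_controls,
    make_mirna_record,
    seed_match_pattern,
)


def brute_force_occurrences(pattern, haystack):
    """Independent oracle: check every offset by direct comparison."""
    return [
        i
        for i in range(len(haystack) - len(pattern) + 1)
        if haystack[i : i + len(pattern)] == pattern and "N" not in pattern
    ]


class TestSeedExtraction:
    @pytest.mark.parametrize(
        "mature,seed_len,expected",
        [
            ("UGGACGGAGAACUGAUAAGGGU", 7, "GGACGGA"),  # miR-184
            ("UCGUACCGUGAGUAAUAAUGCG", 7, "CGUACCG"),  # miR-126
            ("ACGUACGU", 6, "CGUACG"),
        ],
    )
    def test_seed_is_positions_2_through_seed_len_plus_1(
        self, mature, seed_len, expected
    ):
        assert extract_seed(mature, seed_len) == expected

    def test_too_short_mature_is_an_error(self):
        with pytest.raises(ValueError):
            extract_seed("ACGUACG", 7)

    @pytest.mark.parametrize(
        "seed,expected",
        [("CGUACCG", [0, 5]), ("CUCUAGC", []), ("GC", [])],
    )
    def test_cg_dimer_positions(self, seed, expected):
        assert find_cg_dimers(seed) == expected

    def test_mirna_record_invariants(self):
        rec = make_mirna_record("mir-126", "UCGUACCGUGAGUAAUAAUGCG")
        assert rec.seed == "CGUACCG"
        assert rec.cg_positions == (0, 5)
        assert rec.has_cg


class TestSeedMatchPattern:
    @pytest.mark.parametrize(
        "seed,expected", [("GGACGGA", "TCCGTCC"), ("CGUACCG", "CGGTACG")]
    )
    def test_reverse_complement_in_dna(self, seed, expected):
        assert seed_match_pattern(seed) == expected

    def test_non_acgu_character_is_an_error(self):
        with pytest.raises(ValueError):
            seed_match_pattern("ACGTN")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGU", min_size=2, max_size=7))
    def test_cg_in_seed_implies_cg_in_match(self, seed):
        if find_cg_dimers(seed):
            assert "CG" in seed_match_pattern(seed)


class TestSeedTargetSearch:
    def test_single_planted_site(self):
        utr = make_utr("g1", "AAATCCGTCCAAA")
        sites = find_seed_targets("GGACGGA", [utr])
        assert [s.utr_offset for s in sites] == [3]
        assert sites[0].site_type == "seed"

    def test_no_occurrence_gives_empty_list(self):
        assert find_seed_targets("GGACGGA", [make_utr("g1", "AAAAAAAAAA")]) == []

    def test_overlapping_occurrences_all_reported(self):
        # pattern of seed GGGGGGG is CCCCCCC; CCCCCCCC holds 2 overlapping hits
        utr = make_utr("g1", "ACCCCCCCCA")
        sites = find_seed_targets("GGGGGGG", [utr])
        assert [s.utr_offset for s in sites] == [1, 2]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="ACGU", min_size=7, max_size=7),
        st.text(alphabet="ACGTN", min_size=20, max_size=200),
    )
    def test_agrees_with_brute_force_scan(self, seed, utr_seq):
        utr = make_utr("g1", utr_seq)
        found = [s.utr_offset for s in find_seed_targets(seed, [utr])]
        assert found == brute_force_occurrences(seed_match_pattern(seed), utr_seq)

    def test_every_site_substring_equals_its_pattern(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        utr = make_utr("g1", seq)
        for seed in ("GGACGGA", "CGUACCG", "AACGGAA"):
            sites = find_seed_targets(seed, [utr]) + find_bulge_targets(
                seed, [utr], enumerate_bulge_patterns(seed)
            )
            for s in sites:
                assert seq[s.utr_offset : s.utr_offset + s.site_len] == s.pattern


def brute_force_bulge_patterns(seed):
    """Oracle: all distinct strings made by inserting one base into a CG gap."""
    match = seed_match_pattern(seed)
    out = set()
    for k in range(len(match) - 1):
        if match[k : k + 2] == "CG":
            for b in "ACGT":
                out.add(match[: k + 1] + b + match[k + 1 :])
    return out


class TestBulgePatterns:
    def test_single_cg_seed_gives_four_patterns(self):
        pats = {bp.pattern for bp in enumerate_bulge_patterns("GGACGGA")}
        assert pats == {"TCCAGTCC", "TCCCGTCC", "TCCGGTCC", "TCCTGTCC"}

    def test_seed_without_cg_gives_empty_set(self):
        assert enumerate_bulge_patterns("CUCUAGC") == []

    @pytest.mark.parametrize("seed", ["CGUACCG", "GGACGGA", "AACGGAA", "CCGGUUC"])
    def test_matches_brute_force_enumeration_after_dedup(self, seed):
        got = [bp.pattern for bp in enumerate_bulge_patterns(seed)]
        assert len(got) == len(set(got))
        assert set(got) == brute_force_bulge_patterns(seed)
        assert len(got) <= 4 * len(cg_gap_indices(seed_match_pattern(seed)))

    def test_two_cg_seed_deduplicated_count(self):
        got = {bp.pattern for bp in enumerate_bulge_patterns("CGUACCG")}
        assert got == brute_force_bulge_patterns("CGUACCG")
        assert len(got) == 8


class TestRandomBulgeControls:
    def test_fixed_seed_is_reproducible(self):
        a = generate_random_bulge_controls("GGACGGA", 20, 7)
        b = generate_random_bulge_controls("GGACGGA", 20, 7)
        assert [x.pattern for x in a] == [x.pattern for x in b]

    def test_insertion_points_uniform_over_legal_points(self):
        seed = "GGACGGA"
        match = seed_match_pattern(seed)
        legal = [p for p in range(1, len(match)) if p not in cg_gap_indices(match)]
        draws = generate_random_bulge_controls(seed, 10_000, 11)
        counts = {p: 0 for p in legal}
        for bp in draws:
            counts[bp.cg_index + 1] += 1
        chi = stats.chisquare(list(counts.values()))
        assert chi.pvalue > 0.01

    @pytest.mark.parametrize("seed", ["GGACGGA", "CGUACCG", "UUGUUCG"])
    def test_no_control_inserts_into_a_cg_gap(self, seed):
        match = seed_match_pattern(seed)
        forbidden = set(cg_gap_indices(match))
        for bp in generate_random_bulge_controls(seed, 500, 3):
            point = bp.cg_index + 1
            assert point not in forbidden
            assert 1 <= point <= len(match) - 1
            # re-derive the pattern from the recorded insertion
            assert bp.pattern == match[:point] + bp.bulge_base + match[point:]


class TestBulgeTargetSearch:
    def test_planted_bulge_site_recovered_with_base(self):
        utr = make_utr("g1", "GGTCCAGTCCAA")
        sites = find_bulge_targets(
            "GGACGGA", [utr], enumerate_bulge_patterns("GGACGGA")
        )
        assert len(sites) == 1
        assert sites[0].bulge_base == "A" and sites[0].site_type == "cg_bulge"

    def test_perfect_site_yields_no_bulge_site(self):
        utr = make_utr("g1", "AATCCGTCCAA")
        assert (
            find_bulge_targets("GGACGGA", [utr], enumerate_bulge_patterns("GGACGGA"))
            == []
        )

    def test_planted_mixture_counts_recovered(self, rng):
        seed = "GGACGGA"
        seed_pat = seed_match_pattern(seed)
        # plant only bulge patterns whose string cannot arise from a random
        # (non-CG-gap) insertion: C/G bulges next to a C or G run are ambiguous
        bulge_pats = ["TCCAGTCC", "TCCTGTCC"]
        cg_set = {bp.pattern for bp in enumerate_bulge_patterns(seed)}
        assert set(bulge_pats) <= cg_set
        utrs = []
        n_seed = n_bulge = 0
        for i in range(100):
            # inert A/T background; flank planted patterns with A so no
            # spurious window reconstructs another pattern class
            body = "".join(rng.choice(list("AT"), size=60))
            if i < 30:
                body = body[:10] + "A" + seed_pat + "A" + body[12 + len(seed_pat) :]
                n_seed += 1
            elif i < 80:
                pat = bulge_pats[i % len(bulge_pats)]
                body = body[:10] + "A" + pat + "A" + body[12 + len(pat) :]
                n_bulge += 1
            utrs.append(make_utr(f"g{i}", body))
        assert len(find_seed_targets(seed, utrs)) == n_seed == 30
        found_bulge = find_bulge_targets(
            seed, utrs, enumerate_bulge_patterns(seed)
        )
        assert len(found_bulge) == n_bulge == 50
        controls = find_bulge_targets(
            seed,
            utrs,
            # drop draws whose string coincides with a CG-gap pattern
            [
                bp
                for bp in generate_random_bulge_controls(seed, 50, 5)
                if bp.pattern not in cg_set
            ],
            site_type=SITE_RANDOM_BULGE,
        )
        assert controls == []  # nothing planted for the control class
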