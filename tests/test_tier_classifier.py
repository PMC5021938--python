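import math

import numpy as np
import pytest

from tierscan.alphabet import decode, encode, reverse_complement
from tierscan.motif_models import lenient_full_site_model
from tierscan.scanner import exact_score_distribution, scan
from tierscan.synthetic import gen_background, plant_full_sites, plant_half_sites_and_cooperators
from tierscan.tier_classifier import (
    FullSiteCandidate,
    HalfSiteCandidate,
    classify_full_site,
    classify_sequence,
    classify_sequences,
    core_mismatches,
    find_full_site_candidates,
    find_half_sites,
    hexamer_mismatches,
    resolve_lowest_tier,
    tier_distribution,
)

PERFECT = "AGAACAGGGTGTTCT"


def mutate(window, positions, to="C"):
    w = list(window)
    for p in positions:
        w[p] = "A" if w[p] == to else to
    return "".join(w)


class TestCoreMismatches:
    def test_perfect_window_zero(self):
        assert core_mismatches(PERFECT) == 0

    def test_spacer_is_free(self):
        for spacer in ("AAA", "CCC", "GGG", "TTT", "ACG"):
            assert core_mismatches("AGAACA" + spacer + "TGTTCT") == 0

    def test_single_substitution_at_last_position(self):
        assert core_mismatches("AGAACAGGGTGTTCA") == 1

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="15"):
            core_mismatches("AGAACA")

    def test_ambiguous_letters_rejected(self):
        with pytest.raises(ValueError):
            core_mismatches("AGAACANGGTGTTCT")

    def test_reverse_complement_symmetry_brute_force(self, rng):
        # the consensus is its own reverse complement, so mismatch counts
        # must agree; verified over 10,000 random windows
        letters = np.array(list("ACGT"))
        for _ in range(10_000):
            w = "".join(letters[rng.integers(0, 4, 15)])
            assert core_mismatches(w) == core_mismatches(reverse_complement(w))

    def test_hexamer_breakdown_sums(self, rng):
        letters = np.array(list("ACGT"))
        for _ in range(500):
            w = "".join(letters[rng.integers(0, 4, 15)])
            left, right = hexamer_mismatches(w)
            assert left + right == core_mismatches(w)


class TestClassifyFullSite:
    @pytest.mark.parametrize(
        "n_mut,expected", [(0, 1), (1, 2), (2, 3), (3, 4), (4, None)]
    )
    def test_tier_boundaries(self, n_mut, expected):
        w = mutate(PERFECT, [0, 1, 2, 3][:n_mut])
        assert classify_full_site(w) == expected

    def test_one_hexamer_restriction(self):
        split = mutate(PERFECT, [0, 14])   # one mismatch in each hexamer
        same = mutate(PERFECT, [0, 1])     # both in the left hexamer
        assert classify_full_site(split) == 3
        assert classify_full_site(split, mismatches_one_hexamer=True) is None
        assert classify_full_site(same, mismatches_one_hexamer=True) == 3

    def test_enumeration_counts_by_mismatch_class(self):
        # exhaustive over all 4^12 informative cores via the two-hexamer
        # factorization; expected counts C(12,m)*3^m
        counts = enumerate_core_mismatch_counts()
        for m in range(13):
            assert counts[m] == math.comb(12, m) * 3**m
        assert counts[0] == 1 and counts[1] == 36
        assert counts[2] == 594 and counts[3] == 5940


def enumerate_core_mismatch_counts():
    """Mismatch-class counts over all 4^12 cores (spacer fixed)."""
    hex_counts = np.zeros(7, dtype=np.int64)
    letters = "ACGT"
    for code in range(4096):
        hexamer = "".join(letters[(code >> (2 * k)) & 3] for k in range(6))
        left, _ = hexamer_mismatches(hexamer + "GGG" + "TGTTCT")
        hex_counts[left] += 1
    total = np.zeros(13, dtype=np.int64)
    for ml in range(7):
        for mr in range(7):
            total[ml + mr] += hex_counts[ml] * hex_counts[mr]
    return total


class TestFindHalfSites:
    def test_forward_literal(self):
        (h,) = find_half_sites("TTTAGAACATTT")
        assert (h.start, h.orientation) == (3, "forward")

    def test_reverse_orientation(self):
        (h,) = find_half_sites("TTTTGTTCTTTT")
        assert (h.start, h.orientation) == (3, "reverse")

    def test_full_site_yields_two_candidates(self):
        cands = find_half_sites(PERFECT)
        assert [(c.start, c.orientation) for c in cands] == [
            (0, "forward"),
            (9, "reverse"),
        ]

    def test_candidates_suppressed_by_full_site(self):
        hits = classify_sequence("TT" + PERFECT + "TT")
        assert len(hits) == 1
        assert hits[0].tier == 1
        assert hits[0].start == 2


class TestResolveLowestTier:
    def test_perfect_full_site_alone(self):
        hits = classify_sequence(PERFECT)
        assert [h.tier for h in hits] == [1]
        assert hits[0].core_mismatches == 0

    def test_isolated_half_site(self):
        # right hexamer destroyed by >= 4 core mismatches
        seq = "TTTTT" + "AGAACA" + "GGG" + "AAAAAA" + "TTTTT"
        hits = classify_sequence(seq)
        assert [h.tier for h in hits] == [5]
        assert hits[0].half_site_orientation == "forward"
        assert hits[0].start == 5

    def test_two_planted_sites_tiers_2_and_5(self):
        tier2 = mutate(PERFECT, [2])
        seq = ("T" * 40) + tier2 + ("T" * 40) + "AGAACACCCAAAAAA" + ("T" * 40)
        hits = classify_sequence(seq)
        assert sorted(h.tier for h in hits) == [2, 5]

    def test_mismatched_sequence_ids_rejected(self):
        full = [FullSiteCandidate("chrA", 10, 1, 0, 0, PERFECT)]
        half = [HalfSiteCandidate("chrB", 50, "forward")]
        with pytest.raises(ValueError, match="sequence ids"):
            resolve_lowest_tier(full, half)

    def test_no_position_double_counted(self):
        seq = gen_background(50_000, seed=31)
        hits = classify_sequence(seq)
        spans = []
        for h in hits:
            spans.append((h.start, h.end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert s2 >= e1


class TestTierDistribution:
    def test_empty_input(self):
        summary = tier_distribution([])
        assert summary.counts == {1: 0, 2: 0, 3: 0, 4: 0, 5: 0}
        assert summary.fractions is None
        assert summary.total == 0

    def test_planted_counts_recovered(self):
        seq = gen_background(400_000, seed=41)
        seq, truth = plant_full_sites(seq, {1: 10, 2: 20, 3: 30, 4: 40}, seed=42)
        seq, half_truth = plant_half_sites_and_cooperators(
            seq, 100, seed=43, avoid=[(r.start, r.end) for r in truth.records]
        )
        truth = truth.extend(half_truth)
        hits = classify_sequence(seq, "chr1")
        found = {(h.start, h.tier) for h in hits}
        for r in truth.records:
            assert (r.start, r.planted_tier) in found

    def test_fractions_sum_to_one(self):
        hits = classify_sequence(gen_background(100_000, seed=44))
        summary = tier_distribution(hits)
        assert sum(summary.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert summary.total_full_sites == sum(summary.counts[k] for k in (1, 2, 3, 4))
        assert summary.total_half_sites == summary.counts[5]


class TestStrandInvariance:
    @pytest.mark.parametrize("seed", [51, 52, 53])
    def test_tier_multisets_mirror(self, seed):
        seq = gen_background(30_000, seed=seed)
        seq, _ = plant_full_sites(seq, {1: 2, 2: 2, 3: 2, 4: 2}, seed=seed + 100)
        fwd = classify_sequence(seq)
        rev = classify_sequence(reverse_complement(seq))
        assert sorted(h.tier for h in fwd) == sorted(h.tier for h in rev)
        L = len(seq)
        fwd_full = {(L - h.end, h.tier) for h in fwd if h.tier <= 4}
        rev_full = {(h.start, h.tier) for h in rev if h.tier <= 4}
        assert fwd_full == rev_full

    def test_masked_windows_skipped(self):
        # masking one hexamer base leaves only the intact reverse hexamer
        seq = "TT" + PERFECT.replace("G", "N", 1) + "TT"
        hits = classify_sequence(seq)
        assert [h.tier for h in hits] == [5]
        assert hits[0].half_site_orientation == "reverse"


class TestHammingPssmOracleEquality:
    def test_hamming_equals_uniform_penalty_pssm_scan(self):
        # cross-check route: a consensus-style matrix with a uniform
        # per-position penalty scores every window as a linear function of
        # its mismatch count, so the PSSM hit set at the 3-mismatch score
        # must equal the sliding-window Hamming set
        seq = gen_background(50_000, seed=61)
        model = lenient_full_site_model()
        dist = exact_score_distribution(model)
        lo = model.log_odds
        thr_score = 9 * lo[0, 0] + 3 * lo[0, 1]
        thr_int = int(np.rint(thr_score / dist.granularity))
        p = float(dist.pvalue_of_int(thr_int))
        pssm_hits = {
            h.start
            for h in scan({"s": seq}, model, p, background="uniform", dist=dist)
        }
        hamming = {c.start for c in find_full_site_candidates(seq, "s")}
        assert pssm_hits == hamming
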