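import itertools

import numpy as np
import pytest

from tierscan.alphabet import encode, reverse_complement
from tierscan.motif_models import consensus_to_pssm
from tierscan.scanner import (
    NO_THRESHOLD,
    exact_score_distribution,
    pvalue_to_score_threshold,
    scan,
)
from tierscan.synthetic import gen_background
from conftest import random_model


def brute_force_distribution(model, dist):
    """Independent oracle: enumerate all 4^W windows, bin on dist's lattice."""
    W = model.width
    atoms = np.zeros_like(dist.atom_probs)
    for letters in itertools.product(range(4), repeat=W):
        s_int = sum(int(dist.int_lo[i, b]) for i, b in enumerate(letters))
        p = float(np.prod([model.background[b] for b in letters]))
        atoms[s_int - dist.offset] += p
    return atoms


class TestExactDistribution:
    def test_width_one_uniform_four_atoms(self):
        m = random_width1 = consensus_to_pssm("A", 0.85)
        dist = exact_score_distribution(m)
        probs = [p for p in dist.atom_probs if p > 0]
        assert len(probs) == 2  # 0.25 for A, 0.75 pooled at the shared score
        np.testing.assert_allclose(sorted(probs), [0.25, 0.75])

    def test_width_one_distinct_scores(self, rng):
        m = random_model(rng, 1)
        dist = exact_score_distribution(m)
        nz = dist.atom_probs[dist.atom_probs > 0]
        np.testing.assert_allclose(sorted(nz), sorted(m.background))

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_matches_enumeration(self, rng, width):
        m = random_model(rng, width)
        dist = exact_score_distribution(m)
        oracle = brute_force_distribution(m, dist)
        assert np.abs(dist.atom_probs - oracle).sum() < 1e-9

    def test_atoms_sum_to_one(self, rng):
        dist = exact_score_distribution(random_model(rng, 10))
        assert abs(dist.atom_probs.sum() - 1.0) < 1e-9

    def test_survival_non_increasing_and_starts_at_one(self, rng):
        dist = exact_score_distribution(random_model(rng, 7))
        sv = dist.survival_arr
        assert np.all(np.diff(sv) <= 1e-15)
        assert sv[0] == pytest.approx(1.0, abs=1e-9)

    def test_ideal_model_best_pvalue_closed_form(self, ideal_model):
        dist = exact_score_distribution(ideal_model)
        assert dist.min_pvalue() == pytest.approx(0.25**12, rel=0.01)

    def test_coarse_granularity_warns(self, ideal_model):
        with pytest.warns(RuntimeWarning):
            exact_score_distribution(ideal_model, granularity=1e6)

    def test_granularity_must_be_positive(self, ideal_model):
        with pytest.raises(ValueError):
            exact_score_distribution(ideal_model, granularity=-1.0)


class TestThreshold:
    def test_p_one_gives_minimum_score(self, rng):
        dist = exact_score_distribution(random_model(rng, 5))
        thr = pvalue_to_score_threshold(dist, 1.0)
        assert thr == pytest.approx(dist.scores[0], abs=dist.granularity)

    def test_p_out_of_range_rejected(self, rng):
        dist = exact_score_distribution(random_model(rng, 3))
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                pvalue_to_score_threshold(dist, bad)

    def test_unattainable_p_gives_sentinel(self, ideal_model):
        dist = exact_score_distribution(ideal_model)
        assert pvalue_to_score_threshold(dist, 1e-12) == NO_THRESHOLD

    def test_just_above_best_match_only_perfect_passes(self, ideal_model):
        dist = exact_score_distribution(ideal_model)
        p_best = dist.min_pvalue()
        thr = pvalue_to_score_threshold(dist, p_best * 1.01)
        # only the maximal score clears this threshold
        attained = dist.scores[dist.atom_probs > 0]
        assert np.sum(attained >= thr) == 1

    def test_thresholds_non_increasing_in_p(self, rng):
        dist = exact_score_distribution(random_model(rng, 6))
        ps = np.geomspace(dist.min_pvalue() * 1.01, 1.0, 20)
        thrs = [pvalue_to_score_threshold(dist, p) for p in ps]
        assert all(a >= b - 1e-12 for a, b in zip(thrs, thrs[1:]))


class TestScan:
    def test_planted_round_trip(self, ideal_model):
        seq = gen_background(1000, seed=11)
        planted = "AGAACAGGGTGTTCT"
        seq = seq[:500] + planted + seq[515:]
        hits = scan({"chr": seq}, ideal_model, 4.94e-5, background="uniform")
        starts = [h.start for h in hits]
        assert 500 in starts
        best = next(h for h in hits if h.start == 500)
        assert best.end == 515
        assert best.p_value == pytest.approx(0.25**12, rel=0.01)
        assert best.matched_seq == planted

    def test_all_c_sequence_no_hits(self, ideal_model):
        hits = scan({"c": "C" * 200}, ideal_model, 4.94e-5, background="uniform")
        assert hits == []

    def test_empty_sequence_set(self, ideal_model):
        assert scan({}, ideal_model, 0.01, background="uniform") == []

    def test_model_wider_than_sequence(self, ideal_model):
        assert scan({"s": "ACGT"}, ideal_model, 1.0, background="uniform") == []

    def test_ambiguous_windows_skipped(self, hexamer_model):
        seq = "TTTAGANCATTT" + "AGAACA" + "TT"
        hits = scan({"s": seq}, hexamer_model, 1e-3, background="uniform")
        assert [h.start for h in hits if h.strand == "+"] == [12]

    def test_strand_symmetry_non_palindromic(self, secondary_model):
        seq = gen_background(3000, seed=5)
        hits_fwd = scan({"s": seq}, secondary_model, 1e-3, background="uniform")
        hits_rev = scan(
            {"s": reverse_complement(seq)}, secondary_model, 1e-3,
            background="uniform",
        )
        L = len(seq)
        mirrored = {
            (L - h.end, L - h.start, "-" if h.strand == "+" else "+")
            for h in hits_rev
        }
        original = {(h.start, h.end, h.strand) for h in hits_fwd}
        assert original == mirrored

    def test_hits_sorted(self, hexamer_model):
        seq = gen_background(5000, seed=7)
        hits = scan({"b": seq, "a": seq}, hexamer_model, 0.01, background="uniform")
        keys = [(h.sequence_id, h.start) for h in hits]
        assert keys == sorted(keys)

    def test_pvalue_monotone_in_score(self, secondary_model):
        seq = gen_background(20_000, seed=9)
        hits = scan({"s": seq}, secondary_model, 0.05, background="uniform")
        hits = sorted(hits, key=lambda h: h.score)
        for a, b in zip(hits, hits[1:]):
            assert a.p_value >= b.p_value - 1e-15


class TestScannerInvariants:
    def test_oracle_equality_on_random_sequence(self, rng):
        # 50 kb; non-palindromic width-6 model; brute-force = direct integer
        # scoring of every window against the enumerated survival function
        model = random_model(rng, 6)
        seq = gen_background(50_000, seed=13)
        p = 1e-3
        dist = exact_score_distribution(model)
        hits = scan({"s": seq}, model, p, background=model.background, dist=dist)
        got = {(h.start, h.strand) for h in hits}
        enc = encode(seq)
        expected = set()
        for start in range(len(seq) - 6 + 1):
            w = enc[start : start + 6]
            s_fwd = sum(int(dist.int_lo[i, w[i]]) for i in range(6))
            s_rev = sum(int(dist.int_lo[5 - i, 3 - w[i]]) for i in range(6))
            if dist.pvalue_of_int(s_fwd) <= p:
                expected.add((start, "+"))
            if dist.pvalue_of_int(s_rev) <= p:
                expected.add((start, "-"))
        assert got == expected

    def test_false_positive_rate_within_4_sigma(self, rng):
        # smooth random model: survival at the threshold sits close to the
        # nominal p, so the 2*(L-W+1)*p expectation applies
        model = random_model(rng, 8)
        model = type(model)(
            name="smooth", probs=model.probs, background=np.full(4, 0.25)
        )
        p = 1e-3
        L = 100_000
        seq = gen_background(L, seed=17)
        dist = exact_score_distribution(model)
        thr = pvalue_to_score_threshold(dist, p)
        attained = dist.atom_probs[dist.scores >= thr].sum()
        assert attained > 0.5 * p  # smoothness check for this fixture
        hits = scan({"s": seq}, model, p, background="uniform")
        expected = 2 * (L - model.width + 1) * attained
        assert abs(len(hits) - expected) < 4 * np.sqrt(expected)

    def test_palindromic_deduplication(self, ideal_model):
        seq = gen_background(200_000, seed=19)
        hits = scan({"s": seq}, ideal_model, 4.94e-5, background="uniform")
        keys = [(h.sequence_id, h.start, h.model_name) for h in hits]
        assert len(keys) == len(set(keys))
        assert all(h.strand == "+" for h in hits)

    def test_palindromic_expected_count_one_strand_factor(self, ideal_model):
        p = 1e-4
        L = 500_000
        seq = gen_background(L, seed=23)
        hits = scan({"s": seq}, ideal_model, p, background="uniform")
        dist = exact_score_distribution(ideal_model)
        thr = pvalue_to_score_threshold(dist, p)
        # realized per-window pass probability at the discretized threshold
        attained = dist.atom_probs[dist.scores >= thr].sum()
        expected = (L - 15 + 1) * attained
        assert abs(len(hits) - expected) < 4 * np.sqrt(expected)
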