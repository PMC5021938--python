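import numpy as np
import pytest
from scipy import stats

from tierscan.cooperation import (
    SpacingHistogram,
    compare_anchor_classes,
    spacing_enrichment,
    spacing_histogram,
)
from tierscan.synthetic import (
    gen_background,
    plant_half_sites_and_cooperators,
    synthetic_tiered_hit,
)

GCBOX = "GGGGCGGGG"


def planted_histogram(
    secondary_model, gap_sampler, n=100, seed=0, side="downstream", length=None
):
    # ~525 bp of exclusive room per anchor (site + gap + secondary + spacing)
    length = length or max(70_000, 600 * n + 2_000)
    seq = gen_background(length, seed=seed)
    seq, truth = plant_half_sites_and_cooperators(
        seq,
        n,
        secondary_consensus=GCBOX,
        gap_sampler=gap_sampler,
        seed=seed + 1,
        side=side,
    )
    anchors = [
        synthetic_tiered_hit(r.sequence_id, r.start, 5) for r in truth.records
    ]
    hist = spacing_histogram(
        anchors, secondary_model, {"seq": seq}, secondary_p_threshold=1e-4
    )
    return hist, truth


class TestSpacingHistogram:
    def test_constant_gap_lands_in_one_bin(self, secondary_model):
        hist, truth = planted_histogram(secondary_model, lambda rng: 15, n=60, seed=3)
        assert hist.n_anchors == 60
        # bin [15, 20) downstream holds essentially all the mass
        assert hist.counts["downstream"][3] >= 58
        assert hist.counts["upstream"].sum() <= 2

    def test_no_secondary_all_zero(self, secondary_model):
        seq = gen_background(30_000, seed=5)
        seq, truth = plant_half_sites_and_cooperators(seq, 20, seed=6)
        # background may contain sporadic GC-boxes; use an impossible threshold
        anchors = [
            synthetic_tiered_hit(r.sequence_id, r.start, 5) for r in truth.records
        ]
        hist = spacing_histogram(
            anchors, secondary_model, {"seq": seq}, secondary_p_threshold=1e-12
        )
        assert hist.total() == 0
        assert hist.n_anchors_with_secondary == 0

    def test_uniform_gaps_flat_within_4_sigma(self, secondary_model):
        n = 320
        hist, _ = planted_histogram(
            secondary_model,
            lambda rng: int(rng.integers(0, 160)),
            n=n,
            seed=7,
        )
        counts = hist.pooled_counts()
        total = counts.sum()
        assert total >= n - 5  # nearly every anchor keeps its plant
        expect = total / 32
        sigma = np.sqrt(total * (1 / 32) * (31 / 32))
        assert np.all(np.abs(counts - expect) < 4 * sigma + 1)

    def test_each_anchor_at_most_one_count(self, secondary_model):
        hist, _ = planted_histogram(secondary_model, lambda rng: 15, n=40, seed=9)
        assert hist.total() <= hist.n_anchors
        assert hist.total() == hist.n_anchors_with_secondary

    def test_edge_anchors_dropped_and_counted(self, secondary_model):
        seq = gen_background(2000, seed=11)
        anchors = [synthetic_tiered_hit("seq", 10, 5)]  # 10 bp from the edge
        hist = spacing_histogram(anchors, secondary_model, {"seq": seq})
        assert hist.n_anchors == 0
        assert hist.n_anchors_dropped == 1

    def test_window_smaller_than_bin_rejected(self, secondary_model):
        with pytest.raises(ValueError, match="bin_width"):
            spacing_histogram([], secondary_model, {}, window=3, bin_width=5)

    def test_missing_sequence_rejected(self, secondary_model):
        anchors = [synthetic_tiered_hit("nope", 500, 5)]
        with pytest.raises(KeyError):
            spacing_histogram(anchors, secondary_model, {"seq": "ACGT" * 300})


def manual_histogram(counts_downstream, n_anchors=None):
    hist = SpacingHistogram(anchor_model="a", secondary_model="b")
    hist.counts["downstream"] = np.asarray(counts_downstream, dtype=int)
    hist.n_anchors_with_secondary = int(sum(counts_downstream))
    hist.n_anchors = n_anchors or hist.n_anchors_with_secondary
    return hist


class TestSpacingEnrichment:
    def test_all_gaps_in_one_bin_highly_significant(self):
        counts = [0] * 32
        counts[3] = 100
        res = spacing_enrichment(manual_histogram(counts))
        # raw p equals the exact binomial point mass (1/32)^100 scale
        assert res.raw_p["downstream"][3] <= (1 / 32) ** 99
        assert res.corrected_p["downstream"][3] < 1e-10
        assert ("downstream", 15, 20, res.corrected_p["downstream"][3]) in res.significant

    def test_exactly_uniform_counts_not_significant(self):
        res = spacing_enrichment(manual_histogram([5] * 32))
        assert res.significant == []

    def test_single_gap_not_significant(self):
        counts = [0] * 32
        counts[7] = 1
        res = spacing_enrichment(manual_histogram(counts))
        assert res.significant == []

    def test_empty_histogram_not_an_error(self):
        res = spacing_enrichment(manual_histogram([0] * 32))
        assert res.significant == []
        assert res.modal_gap is None

    def test_raw_p_matches_binomial_tail_oracle(self):
        counts = [0] * 32
        counts[5] = 9
        counts[6] = 21
        hist = manual_histogram(counts)
        res = spacing_enrichment(hist)
        n = 30
        # independent oracle: explicit tail summation of the binomial pmf
        for b, k in ((5, 9), (6, 21)):
            tail = sum(
                stats.binom.pmf(j, n, 1 / 32) for j in range(k, n + 1)
            )
            assert res.raw_p["downstream"][b] == pytest.approx(tail, rel=1e-9)

    def test_corrected_ge_raw(self):
        counts = [3] * 32
        res = spacing_enrichment(manual_histogram(counts))
        assert np.all(res.corrected_p["downstream"] >= res.raw_p["downstream"])

    def test_power_planted_bin_detected(self, secondary_model):
        # 30% of 500 anchors share one bin; the rest are uniform
        def sampler(rng):
            return 15 if rng.random() < 0.3 else int(rng.integers(0, 160))

        for seed in (13, 14, 15):
            seq = gen_background(320_000, seed=seed)
            seq, truth = plant_half_sites_and_cooperators(
                seq, 500, secondary_consensus=GCBOX, gap_sampler=sampler,
                seed=seed + 1,
            )
            anchors = [
                synthetic_tiered_hit(r.sequence_id, r.start, 5)
                for r in truth.records
            ]
            hist = spacing_histogram(anchors, secondary_model, {"seq": seq})
            res = spacing_enrichment(hist)
            sig_bins = [(side, lo) for side, lo, hi, p in res.significant]
            assert ("downstream", 15) in sig_bins


class TestCompareAnchorClasses:
    def test_generator_truth_median_shift(self, secondary_model):
        hist_full, _ = planted_histogram(
            secondary_model, lambda rng: 45, n=80, seed=17
        )
        hist_half, _ = planted_histogram(
            secondary_model, lambda rng: 15, n=80, seed=19
        )
        hist_full.anchor_model = "full"
        hist_half.anchor_model = "half"
        res = compare_anchor_classes(hist_full, hist_half)
        assert res["median_shift"] < 0  # half - full
        assert res["modal_gap_full"] == 45
        assert res["modal_gap_half"] == 15

    def test_identical_histograms_zero_shift(self):
        h1 = manual_histogram([2] * 32, n_anchors=100)
        h2 = manual_histogram([2] * 32, n_anchors=100)
        for h in (h1, h2):
            h.gaps["downstream"] = [10] * 64
        res = compare_anchor_classes(h1, h2)
        assert res["median_shift"] == 0
        assert res["fraction_p"] == pytest.approx(1.0)

    def test_swapping_negates_shift(self, secondary_model):
        hist_a, _ = planted_histogram(secondary_model, lambda rng: 45, n=50, seed=21)
        hist_b, _ = planted_histogram(secondary_model, lambda rng: 15, n=50, seed=23)
        r1 = compare_anchor_classes(hist_a, hist_b)
        r2 = compare_anchor_classes(hist_b, hist_a)
        assert r1["median_shift"] == -r2["median_shift"]
        assert r1["modal_shift"] == -r2["modal_shift"]

    def test_mismatched_settings_rejected(self):
        h1 = manual_histogram([0] * 32)
        h2 = SpacingHistogram(anchor_model="a", secondary_model="other")
        with pytest.raises(ValueError, match="mismatched"):
            compare_anchor_classes(h1, h2)
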