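"""Spaced-motif co-occurrence analysis around anchor sites.

For every anchor site, the best-scoring occurrence of a secondary motif
within a fixed window on either side is located and the edge-to-edge gap
is accumulated into a binned histogram, which is then tested bin-by-bin
against a uniform-placement null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import stats

from .motif_models import MotifModel
from .scanner import exact_score_distribution, scan
from .tier_classifier import TieredHit

__all__ = [
    "SpacingHistogram",
    "CooperationResult",
    "spacing_histogram",
    "spacing_enrichment",
    "compare_anchor_classes",
]

SIDES = ("upstream", "downstream")

DEFAULT_WINDOW = 160
DEFAULT_BIN_WIDTH = 5
DEFAULT_SECONDARY_P = 1e-4


@dataclass
class SpacingHistogram:
    """Binned edge-to-edge gaps between anchors and a secondary motif."""

    anchor_model: str
    secondary_model: str
    window: int = DEFAULT_WINDOW
    bin_width: int = DEFAULT_BIN_WIDTH
    counts: dict = field(default_factory=dict)   # side -> per-bin int array
    n_anchors: int = 0
    n_anchors_with_secondary: int = 0
    n_anchors_dropped: int = 0                   # too close to a sequence edge
    gaps: dict = field(default_factory=dict)     # side -> list of raw gaps

    def __post_init__(self) -> None:
        if self.window < self.bin_width:
            raise ValueError("window must be >= bin_width")
        nb = self.n_bins
        for side in SIDES:
            self.counts.setdefault(side, np.zeros(nb, dtype=int))
            self.gaps.setdefault(side, [])

    @property
    def n_bins(self) -> int:
        return math.ceil(self.window / self.bin_width)

    @property
    def bin_edges(self) -> np.ndarray:
        return np.arange(self.n_bins + 1) * self.bin_width

    def pooled_counts(self) -> np.ndarray:
        return self.counts["upstream"] + self.counts["downstream"]

    def total(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))

    def add(self, side: str, gap: int) -> None:
        if side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        if not 0 <= gap < self.window:
            raise ValueError(f"gap {gap} outside [0, {self.window})")
        self.counts[side][gap // self.bin_width] += 1
        self.gaps[side].append(gap)
        self.n_anchors_with_secondary += 1

    def settings(self) -> tuple:
        return (self.secondary_model, self.window, self.bin_width)


@dataclass
class CooperationResult:
    histogram: SpacingHistogram
    raw_p: dict           # side -> per-bin raw binomial p-values
    corrected_p: dict     # side -> Bonferroni-corrected p-values
    significant: list     # (side, bin_start, bin_end, corrected p)
    modal_gap: Optional[int]
    alpha: float


def _anchor_flanks(anchor: TieredHit, seq_len: int, window: int, sec_w: int):
    """Scan intervals (upstream, downstream) honoring anchor orientation.

    Returns None when the anchor lacks *window* bp of context on either
    side.  Each interval covers gaps in [0, window): a secondary match
    must start/end within window bp of the anchor edge.
    """
    left_lo = anchor.start - window - sec_w + 1
    right_hi = anchor.end + window + sec_w - 1
    if anchor.start - window < 0 or anchor.end + window > seq_len:
        return None
    left = (max(0, left_lo), anchor.start)
    right = (anchor.end, min(seq_len, right_hi))
    # orientation: upstream precedes the anchor in its reading direction
    if anchor.hit.strand == "-":
        return {"upstream": right, "downstream": left}
    return {"upstream": left, "downstream": right}


def spacing_histogram(
    anchors: Iterable[TieredHit],
    secondary: MotifModel,
    sequences: Mapping[str, str],
    window: int = DEFAULT_WINDOW,
    bin_width: int = DEFAULT_BIN_WIDTH,
    secondary_p_threshold: float = DEFAULT_SECONDARY_P,
    anchor_model: str = "anchor",
    gap_mode: str = "edge",
) -> SpacingHistogram:
    """Histogram of gaps from each anchor to its best nearby secondary hit.

    Each anchor contributes at most one count: the best-scoring secondary
    occurrence within +-window bp (ties broken by smaller gap).  *gap_mode*
    'edge' measures edge-to-edge distance (0 = adjacent); 'center' measures
    center-to-center distance minus nothing (binned the same way).
    """
    if window < bin_width:
        raise ValueError("window must be >= bin_width")
    if gap_mode not in ("edge", "center"):
        raise ValueError("gap_mode must be 'edge' or 'center'")
    hist = SpacingHistogram(
        anchor_model=anchor_model,
        secondary_model=secondary.name,
        window=window,
        bin_width=bin_width,
    )
    dist = exact_score_distribution(secondary)
    anchors = list(anchors)
    sec_w = secondary.width
    for anchor in anchors:
        seq = sequences.get(anchor.sequence_id)
        if seq is None:
            raise KeyError(f"anchor sequence {anchor.sequence_id!r} not provided")
        flanks = _anchor_flanks(anchor, len(seq), window, sec_w)
        if flanks is None:
            hist.n_anchors_dropped += 1
            continue
        hist.n_anchors += 1
        best = None  # (score, -gap, side, gap)
        for side, (lo, hi) in flanks.items():
            if hi - lo < sec_w:
                continue
            sub = seq[lo:hi]
            for h in scan(
                {"f": sub},
                secondary,
                secondary_p_threshold,
                background=secondary.background,
                dist=dist,
            ):
                s, e = h.start + lo, h.end + lo
                if gap_mode == "edge":
                    if e <= anchor.start:
                        gap = anchor.start - e
                    elif s >= anchor.end:
                        gap = s - anchor.end
                    else:
                        continue  # overlaps the anchor
                else:
                    gap = abs((s + e) // 2 - anchor.midpoint)
                if not 0 <= gap < window:
                    continue
                key = (h.score, -gap)
                if best is None or key > best[:2]:
                    best = (h.score, -gap, side, gap)
        if best is not None:
            hist.add(best[2], best[3])
    return hist


def spacing_enrichment(
    hist: SpacingHistogram, alpha: float = 0.05
) -> CooperationResult:
    """Per-bin binomial enrichment against uniform placement over bins.

    On each side, a bin with count k out of n gaps observed on that side is
    tested with an upper binomial tail at success probability 1/n_bins;
    Bonferroni correction spans bins x sides.
    """
    nb = hist.n_bins
    n_tests = nb * len(SIDES)
    raw: dict[str, np.ndarray] = {}
    corrected: dict[str, np.ndarray] = {}
    significant = []
    for side in SIDES:
        counts = hist.counts[side]
        n_side = int(counts.sum())
        if n_side == 0:
            raw[side] = np.ones(nb)
            corrected[side] = np.ones(nb)
            continue
        p0 = 1.0 / nb
        pv = stats.binom.sf(counts - 1, n_side, p0)
        raw[side] = pv
        corrected[side] = np.minimum(pv * n_tests, 1.0)
        for b in range(nb):
            if corrected[side][b] < alpha:
                significant.append(
                    (
                        side,
                        int(b * hist.bin_width),
                        int(min((b + 1) * hist.bin_width, hist.window)),
                        float(corrected[side][b]),
                    )
                )
    pooled = hist.pooled_counts()
    modal = None
    if pooled.sum() > 0:
        modal = int(np.argmax(pooled)) * hist.bin_width
    return CooperationResult(
        histogram=hist,
        raw_p=raw,
        corrected_p=corrected,
        significant=significant,
        modal_gap=modal,
        alpha=alpha,
    )


def _median_gap(hist: SpacingHistogram) -> Optional[float]:
    gaps = hist.gaps["upstream"] + hist.gaps["downstream"]
    return float(np.median(gaps)) if gaps else None


def compare_anchor_classes(
    hist_full: SpacingHistogram, hist_half: SpacingHistogram
) -> dict:
    """Modal/median gap shift and secondary-co-occurrence rate difference.

    The shift is reported as half minus full; a negative median shift means
    the secondary motif sits closer to the half-site anchors.
    """
    if hist_full.settings() != hist_half.settings():
        raise ValueError(
            "histograms have mismatched secondary model or window settings"
        )
    from statsmodels.stats.proportion import proportions_ztest

    res_full = spacing_enrichment(hist_full)
    res_half = spacing_enrichment(hist_half)
    med_full = _median_gap(hist_full)
    med_half = _median_gap(hist_half)
    k = [hist_half.n_anchors_with_secondary, hist_full.n_anchors_with_secondary]
    n = [hist_half.n_anchors, hist_full.n_anchors]
    if min(n) > 0 and not (k[0] == k[1] == 0):
        with np.errstate(invalid="ignore"):
            z, p = proportions_ztest(k, n)
        if np.isnan(p):
            z, p = 0.0, 1.0
    else:
        z, p = 0.0, 1.0
    return {
        "modal_gap_full": res_full.modal_gap,
        "modal_gap_half": res_half.modal_gap,
        "modal_shift": (
            None
            if res_full.modal_gap is None or res_half.modal_gap is None
            else res_half.modal_gap - res_full.modal_gap
        ),
        "median_gap_full": med_full,
        "median_gap_half": med_half,
        "median_shift": (
            None
            if med_full is None or med_half is None
            else med_half - med_full
        ),
        "fraction_with_secondary_full": (
            hist_full.n_anchors_with_secondary / hist_full.n_anchors
            if hist_full.n_anchors
            else 0.0
        ),
        "fraction_with_secondary_half": (
            hist_half.n_anchors_with_secondary / hist_half.n_anchors
            if hist_half.n_anchors
            else 0.0
        ),
        "fraction_z": float(z),
        "fraction_p": float(p),
    }
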