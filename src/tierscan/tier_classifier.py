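"""Five-tier degeneracy classification of palindromic dihexamer sites.

Full sites are 15-bp windows compared against the canonical dihexamer
``AGAACAnnnTGTTCT``: tier ``k`` (k = 1..4) means ``k - 1`` mismatches over
the 12 informative positions, the 3-bp spacer being ignored.  Tier 5 is an
isolated perfect hexamer (``AGAACA`` forward or ``TGTTCT`` reverse
orientation) that is not part of any full-site window.  Overlaps are
resolved so that every genomic position contributes to at most one
reported site, always at the lowest (most specific) tier available.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional

import numpy as np

from .alphabet import encode, validate_acgt
from .motif_models import (
    FULL_SITE_CONSENSUS,
    HALF_SITE_CONSENSUS,
    half_site_model,
    lenient_full_site_model,
)
from .scanner import MotifHit, exact_score_distribution

__all__ = [
    "FULL_SITE_WIDTH",
    "HALF_SITE_WIDTH",
    "MAX_CORE_MISMATCHES",
    "TieredHit",
    "TierSummary",
    "core_mismatches",
    "hexamer_mismatches",
    "classify_full_site",
    "find_half_sites",
    "resolve_lowest_tier",
    "classify_sequence",
    "classify_sequences",
    "tier_distribution",
]

FULL_SITE_WIDTH = 15
HALF_SITE_WIDTH = 6
#: Largest informative-position mismatch count still called a full site.
MAX_CORE_MISMATCHES = 3

_CONSENSUS_ENC = encode(FULL_SITE_CONSENSUS)
#: 0-based indices of the informative positions (hexamers; spacer excluded).
INFORMATIVE_POSITIONS = np.array([0, 1, 2, 3, 4, 5, 9, 10, 11, 12, 13, 14])
_LEFT = INFORMATIVE_POSITIONS[:6]
_RIGHT = INFORMATIVE_POSITIONS[6:]

_REVERSE_HEXAMER = "TGTTCT"


@dataclass(frozen=True)
class FullSiteCandidate:
    """A classified 15-bp window prior to overlap resolution."""

    sequence_id: str
    start: int
    tier: int
    left_mismatches: int
    right_mismatches: int
    window: str

    @property
    def end(self) -> int:
        return self.start + FULL_SITE_WIDTH

    @property
    def core_mismatches(self) -> int:
        return self.left_mismatches + self.right_mismatches


@dataclass(frozen=True)
class HalfSiteCandidate:
    """An exact hexamer occurrence prior to overlap resolution."""

    sequence_id: str
    start: int
    orientation: str  # 'forward' (AGAACA) or 'reverse' (TGTTCT on + strand)

    @property
    def end(self) -> int:
        return self.start + HALF_SITE_WIDTH


@dataclass(frozen=True)
class TieredHit:
    """A resolved site with its degeneracy tier and mismatch breakdown."""

    hit: MotifHit
    tier: int
    core_mismatches: Optional[int]        # None for tier 5
    left_hexamer_mismatches: Optional[int]
    right_hexamer_mismatches: Optional[int]
    half_site_orientation: Optional[str]  # tier 5 only

    @property
    def sequence_id(self) -> str:
        return self.hit.sequence_id

    @property
    def start(self) -> int:
        return self.hit.start

    @property
    def end(self) -> int:
        return self.hit.end

    @property
    def midpoint(self) -> int:
        return (self.hit.start + self.hit.end) // 2


@dataclass
class TierSummary:
    counts: dict                      # tier -> count, tiers 1..5
    fractions: Optional[dict]         # None when there are no hits
    total_full_sites: int
    total_half_sites: int

    @property
    def total(self) -> int:
        return self.total_full_sites + self.total_half_sites


def core_mismatches(window: str) -> int:
    """Hamming distance to the canonical dihexamer over the 12 informative
    positions; the spacer (positions 7-9, 1-based) is ignored."""
    left, right = hexamer_mismatches(window)
    return left + right


def hexamer_mismatches(window: str) -> tuple[int, int]:
    """Mismatch counts of the left and right hexamers separately."""
    w = validate_acgt(window, context="window")
    if len(w) != FULL_SITE_WIDTH:
        raise ValueError(
            f"window must be {FULL_SITE_WIDTH} bp, got {len(w)}"
        )
    enc = encode(w)
    left = int(np.count_nonzero(enc[_LEFT] != _CONSENSUS_ENC[_LEFT]))
    right = int(np.count_nonzero(enc[_RIGHT] != _CONSENSUS_ENC[_RIGHT]))
    return left, right


def classify_full_site(
    window: str, mismatches_one_hexamer: bool = False
) -> Optional[int]:
    """Tier 1-4 for windows with 0-3 informative mismatches, else None.

    With *mismatches_one_hexamer*, all mismatches must fall within a single
    hexamer for the window to qualify.
    """
    left, right = hexamer_mismatches(window)
    m = left + right
    if m > MAX_CORE_MISMATCHES:
        return None
    if mismatches_one_hexamer and left > 0 and right > 0:
        return None
    return m + 1


def find_half_sites(
    sequence: str, sequence_id: str = "seq"
) -> list[HalfSiteCandidate]:
    """Every exact ``AGAACA`` (forward) or ``TGTTCT`` (reverse) occurrence."""
    seq = sequence.upper()
    out: list[HalfSiteCandidate] = []
    for motif, orientation in (
        (HALF_SITE_CONSENSUS, "forward"),
        (_REVERSE_HEXAMER, "reverse"),
    ):
        pos = seq.find(motif)
        while pos != -1:
            out.append(HalfSiteCandidate(sequence_id, pos, orientation))
            pos = seq.find(motif, pos + 1)
    out.sort(key=lambda c: c.start)
    return out


def find_full_site_candidates(
    sequence: str,
    sequence_id: str = "seq",
    mismatches_one_hexamer: bool = False,
) -> list[FullSiteCandidate]:
    """All 15-bp windows with <= 3 informative mismatches (vectorized).

    Windows containing any non-ACGT letter (masked regions) are skipped.
    Only the forward frame is examined: the consensus is its own reverse
    complement, so every window scores identically on both strands.
    """
    seq = sequence.upper()
    L = len(seq)
    if L < FULL_SITE_WIDTH:
        return []
    enc = encode(seq)
    n_win = L - FULL_SITE_WIDTH + 1
    ok = np.ones(n_win, dtype=bool)
    left_mm = np.zeros(n_win, dtype=np.int16)
    right_mm = np.zeros(n_win, dtype=np.int16)
    valid = enc < 4
    for i in range(FULL_SITE_WIDTH):
        col = enc[i : i + n_win]
        ok &= valid[i : i + n_win]
        if i in _LEFT:
            left_mm += col != _CONSENSUS_ENC[i]
        elif i in _RIGHT:
            right_mm += col != _CONSENSUS_ENC[i]
    qual = ok & (left_mm + right_mm <= MAX_CORE_MISMATCHES)
    if mismatches_one_hexamer:
        qual &= (left_mm == 0) | (right_mm == 0)
    starts = np.nonzero(qual)[0]
    return [
        FullSiteCandidate(
            sequence_id=sequence_id,
            start=int(s),
            tier=int(left_mm[s] + right_mm[s]) + 1,
            left_mismatches=int(left_mm[s]),
            right_mismatches=int(right_mm[s]),
            window=seq[s : s + FULL_SITE_WIDTH],
        )
        for s in starts
    ]


@lru_cache(maxsize=4)
def _full_site_scoring():
    """Score/p-value lookup per mismatch count under the lenient model."""
    model = lenient_full_site_model()
    dist = exact_score_distribution(model)
    lo = model.log_odds
    match = lo[0, 0]     # informative-position consensus-letter score
    miss = lo[0, 1]      # any other letter
    table = {}
    for m in range(MAX_CORE_MISMATCHES + 1):
        score = (12 - m) * match + m * miss
        s_int = int(np.rint(score / dist.granularity))
        table[m] = (float(s_int * dist.granularity), float(dist.pvalue_of_int(s_int)))
    return model.name, table


@lru_cache(maxsize=4)
def _half_site_scoring():
    model = half_site_model()
    dist = exact_score_distribution(model)
    best = int(dist.int_lo[np.arange(6), encode(HALF_SITE_CONSENSUS)].sum())
    return model.name, (
        float(best * dist.granularity),
        float(dist.pvalue_of_int(best)),
    )


def _full_to_tiered(cand: FullSiteCandidate) -> TieredHit:
    model_name, table = _full_site_scoring()
    m = cand.core_mismatches
    score, pval = table[m]
    hit = MotifHit(
        sequence_id=cand.sequence_id,
        start=cand.start,
        end=cand.end,
        strand="+",
        score=score,
        p_value=pval,
        matched_seq=cand.window,
        model_name=model_name,
    )
    return TieredHit(
        hit=hit,
        tier=cand.tier,
        core_mismatches=m,
        left_hexamer_mismatches=cand.left_mismatches,
        right_hexamer_mismatches=cand.right_mismatches,
        half_site_orientation=None,
    )


def _half_to_tiered(cand: HalfSiteCandidate) -> TieredHit:
    model_name, (score, pval) = _half_site_scoring()
    strand = "+" if cand.orientation == "forward" else "-"
    hit = MotifHit(
        sequence_id=cand.sequence_id,
        start=cand.start,
        end=cand.end,
        strand=strand,
        score=score,
        p_value=pval,
        matched_seq=HALF_SITE_CONSENSUS,
        model_name=model_name,
    )
    return TieredHit(
        hit=hit,
        tier=5,
        core_mismatches=None,
        left_hexamer_mismatches=None,
        right_hexamer_mismatches=None,
        half_site_orientation=cand.orientation,
    )


def _greedy_resolve_full(
    cands: list[FullSiteCandidate],
) -> list[FullSiteCandidate]:
    """Left-to-right resolution keeping the lower tier, then the leftmost."""
    kept: list[FullSiteCandidate] = []
    for cand in sorted(cands, key=lambda c: (c.start, c.tier)):
        conflict = False
        for i in range(len(kept) - 1, -1, -1):
            prev = kept[i]
            if prev.end <= cand.start:
                break
            if cand.tier < prev.tier:
                kept.pop(i)
            else:
                conflict = True
                break
        if not conflict:
            kept.append(cand)
    kept.sort(key=lambda c: c.start)
    return kept


def resolve_lowest_tier(
    full_hits: Iterable[FullSiteCandidate],
    half_hits: Iterable[HalfSiteCandidate],
) -> list[TieredHit]:
    """Merge full-site and half-site candidates into disjoint tiered hits.

    Every hexamer overlapping a kept tier-1..4 window is absorbed into that
    full site; surviving hexamers become tier 5 (greedily de-overlapped).
    """
    full_hits = list(full_hits)
    half_hits = list(half_hits)
    full_ids = {c.sequence_id for c in full_hits}
    half_ids = {c.sequence_id for c in half_hits}
    if full_hits and half_hits and full_ids.isdisjoint(half_ids):
        raise ValueError(
            f"full-site and half-site candidates share no sequence ids "
            f"({sorted(full_ids)} vs {sorted(half_ids)})"
        )
    out: list[TieredHit] = []
    by_seq_full: dict[str, list[FullSiteCandidate]] = {}
    for c in full_hits:
        by_seq_full.setdefault(c.sequence_id, []).append(c)
    by_seq_half: dict[str, list[HalfSiteCandidate]] = {}
    for c in half_hits:
        by_seq_half.setdefault(c.sequence_id, []).append(c)
    for seq_id in sorted(full_ids | half_ids):
        kept_full = _greedy_resolve_full(by_seq_full.get(seq_id, []))
        out.extend(_full_to_tiered(c) for c in kept_full)
        intervals = [(c.start, c.end) for c in kept_full]
        last_end = -1
        for h in sorted(by_seq_half.get(seq_id, []), key=lambda c: c.start):
            if h.start < last_end:
                continue  # overlaps a kept hexamer
            if any(h.start < e and s < h.end for s, e in intervals):
                continue  # absorbed into a full site
            out.append(_half_to_tiered(h))
            last_end = h.end
    out.sort(key=lambda t: (t.sequence_id, t.start, t.tier))
    return out


def classify_sequence(
    sequence: str,
    sequence_id: str = "seq",
    mismatches_one_hexamer: bool = False,
) -> list[TieredHit]:
    """Full 5-tier classification of one sequence."""
    fulls = find_full_site_candidates(
        sequence, sequence_id, mismatches_one_hexamer
    )
    halves = find_half_sites(sequence, sequence_id)
    return resolve_lowest_tier(fulls, halves)


def classify_sequences(
    sequences: Mapping[str, str] | Iterable[tuple],
    mismatches_one_hexamer: bool = False,
) -> list[TieredHit]:
    """Classify a collection of (id, sequence) pairs or a mapping."""
    pairs = sequences.items() if isinstance(sequences, Mapping) else sequences
    out: list[TieredHit] = []
    for seq_id, seq in pairs:
        out.extend(classify_sequence(seq, seq_id, mismatches_one_hexamer))
    out.sort(key=lambda t: (t.sequence_id, t.start, t.tier))
    return out


def tier_distribution(hits: Iterable[TieredHit]) -> TierSummary:
    """Counts and fractions per tier 1..5."""
    counts = {k: 0 for k in range(1, 6)}
    for h in hits:
        if h.tier not in counts:
            raise ValueError(f"invalid tier {h.tier}")
        counts[h.tier] += 1
    total = sum(counts.values())
    fractions = (
        {k: counts[k] / total for k in counts} if total > 0 else None
    )
    return TierSummary(
        counts=counts,
        fractions=fractions,
        total_full_sites=sum(counts[k] for k in range(1, 5)),
        total_half_sites=counts[5],
    )
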