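"""Seeded synthetic fixtures: background sequence, planted tiered sites,
cooperating motifs at controlled spacings, gene models and response tables.

Every generator is a pure function of its parameters and seed.  Planting
uses rejection sampling so that the analysis-side classifier provably
recovers each planted site at its planted tier: no window overlapping a
planted locus may classify better than (or equal and left of) the plant,
and no stray hexamer may steal a planted half site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

import numpy as np

from .alphabet import decode, encode, validate_acgt
from .genome_annotation import GeneRecord
from .downstream_stats import GeneResponseTable, RegionSet
from .motif_models import FULL_SITE_CONSENSUS, HALF_SITE_CONSENSUS
from .scanner import MotifHit
from .tier_classifier import (
    FULL_SITE_WIDTH,
    HALF_SITE_WIDTH,
    INFORMATIVE_POSITIONS,
    MAX_CORE_MISMATCHES,
    TieredHit,
)

__all__ = [
    "PlantRecord",
    "PlantTruth",
    "gen_background",
    "plant_full_sites",
    "plant_half_sites_and_cooperators",
    "gen_gene_model",
    "gen_response_table",
    "gen_density_hits",
    "gen_hitrate_truth",
    "synthetic_tiered_hit",
]

_CONSENSUS_ENC = encode(FULL_SITE_CONSENSUS)
_HEX_FWD = encode(HALF_SITE_CONSENSUS)
_HEX_REV = encode("TGTTCT")
_SPACER = np.array([6, 7, 8])

DEFAULT_EDGE_MARGIN = 160
DEFAULT_MIN_GAP = 30


@dataclass(frozen=True)
class PlantRecord:
    """Ground truth for one planted feature."""

    sequence_id: str
    start: int
    end: int
    strand: str
    planted_tier: int
    mismatch_positions: tuple = ()           # window-relative, 0-based
    gap_to_secondary: Optional[int] = None   # edge-to-edge, bp
    secondary_start: Optional[int] = None
    assigned_gene: Optional[str] = None


@dataclass
class PlantTruth:
    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ivs: dict[str, list] = {}
        for r in self.records:
            if r.planted_tier == 5:
                expected = 0
            else:
                expected = r.planted_tier - 1
            if r.planted_tier != 5 and len(r.mismatch_positions) != expected:
                raise ValueError(
                    f"{r}: tier {r.planted_tier} requires {expected} mismatches"
                )
            ivs.setdefault(r.sequence_id, []).append((r.start, r.end))
        for seq_id, pairs in ivs.items():
            pairs.sort()
            for (s1, e1), (s2, e2) in zip(pairs, pairs[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"planted intervals overlap on {seq_id}: "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def by_tier(self) -> dict:
        out: dict[int, list] = {}
        for r in self.records:
            out.setdefault(r.planted_tier, []).append(r)
        return out

    def extend(self, other: "PlantTruth") -> "PlantTruth":
        return PlantTruth(records=self.records + other.records)


def synthetic_tiered_hit(
    sequence_id: str, start: int, tier: int, strand: str = "+"
) -> TieredHit:
    """A minimal TieredHit for generators that plant coordinates only."""
    width = HALF_SITE_WIDTH if tier == 5 else FULL_SITE_WIDTH
    hit = MotifHit(
        sequence_id=sequence_id,
        start=start,
        end=start + width,
        strand=strand,
        score=0.0,
        p_value=1.0,
        matched_seq="N" * width,
        model_name="synthetic",
    )
    m = None if tier == 5 else tier - 1
    return TieredHit(
        hit=hit,
        tier=tier,
        core_mismatches=m,
        left_hexamer_mismatches=None,
        right_hexamer_mismatches=None,
        half_site_orientation="forward" if tier == 5 else None,
    )


def gen_background(length: int, composition=(0.25, 0.25, 0.25, 0.25), seed: int = 0) -> str:
    """i.i.d. zero-order background sequence."""
    if length <= 0:
        raise ValueError("length must be positive")
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-6:
        raise ValueError("composition must be 4 non-negative frequencies summing to 1")
    comp = comp / comp.sum()
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp)
    return decode(codes)


# ---------------------------------------------------------------------------
# Planting helpers (operate on an int8 code array)
# ---------------------------------------------------------------------------

def _window_core_mismatches(codes: np.ndarray, start: int) -> int:
    w = codes[start : start + FULL_SITE_WIDTH]
    idx = INFORMATIVE_POSITIONS
    return int(np.count_nonzero(w[idx] != _CONSENSUS_ENC[idx]))


def _full_site_free(codes: np.ndarray, lo: int, hi: int, exclude: int = -1) -> bool:
    """True when no full-site-qualifying window starts in [lo, hi]."""
    for s in range(max(0, lo), min(len(codes) - FULL_SITE_WIDTH, hi) + 1):
        if s == exclude:
            continue
        if _window_core_mismatches(codes, s) <= MAX_CORE_MISMATCHES:
            return False
    return True


def _hexamer_free(codes: np.ndarray, lo: int, hi: int, exclude: int = -1) -> bool:
    """True when no exact hexamer (either orientation) starts in [lo, hi]."""
    for s in range(max(0, lo), min(len(codes) - HALF_SITE_WIDTH, hi) + 1):
        if s == exclude:
            continue
        w = codes[s : s + HALF_SITE_WIDTH]
        if np.array_equal(w, _HEX_FWD) or np.array_equal(w, _HEX_REV):
            return False
    return True


def _sample_position(
    rng, length: int, width: int, occupied: list, min_gap: int, edge_margin: int
) -> Optional[int]:
    for _ in range(2000):
        start = int(rng.integers(edge_margin, length - edge_margin - width + 1))
        if all(
            start + width + min_gap <= s or e + min_gap <= start
            for s, e in occupied
        ):
            return start
    return None


def plant_full_sites(
    seq: str,
    counts_per_tier: Mapping[int, int],
    seed: int = 0,
    sequence_id: str = "seq",
    min_gap: int = DEFAULT_MIN_GAP,
    edge_margin: int = DEFAULT_EDGE_MARGIN,
    avoid: Iterable[tuple] = (),
) -> tuple[str, PlantTruth]:
    """Plant full sites with exact per-tier mismatch counts.

    Each site is the canonical dihexamer with ``tier - 1`` informative
    positions mutated (spacer filled randomly).  Rejection sampling
    guarantees that the planted window is the unique full-site-qualifying
    window at its locus, so classification recovers the exact tier.
    """
    for tier in counts_per_tier:
        if tier not in (1, 2, 3, 4):
            raise ValueError(f"full-site tiers are 1..4, got {tier}")
    codes = encode(validate_acgt(seq))
    length = len(codes)
    rng = np.random.default_rng(seed)
    occupied: list[tuple] = [(int(s), int(e)) for s, e in avoid]
    records: list[PlantRecord] = []
    requests = [
        tier for tier in sorted(counts_per_tier) for _ in range(counts_per_tier[tier])
    ]
    for tier in requests:
        n_mm = tier - 1
        planted = False
        for _attempt in range(200):
            start = _sample_position(
                rng, length, FULL_SITE_WIDTH, occupied, min_gap, edge_margin
            )
            if start is None:
                raise ValueError(
                    f"insufficient room to plant {len(requests)} sites in "
                    f"{length} bp (placed {len(records)})"
                )
            saved = codes[start : start + FULL_SITE_WIDTH].copy()
            ok = False
            for _retry in range(50):
                site = _CONSENSUS_ENC.copy()
                site[_SPACER] = rng.integers(0, 4, size=3)
                mm_pos = rng.choice(INFORMATIVE_POSITIONS, size=n_mm, replace=False)
                for p in mm_pos:
                    alt = [b for b in range(4) if b != _CONSENSUS_ENC[p]]
                    site[p] = alt[int(rng.integers(0, 3))]
                codes[start : start + FULL_SITE_WIDTH] = site
                # no overlapping window may also qualify as a full site
                if _full_site_free(
                    codes,
                    start - FULL_SITE_WIDTH + 1,
                    start + FULL_SITE_WIDTH - 1,
                    exclude=start,
                ):
                    ok = True
                    break
                codes[start : start + FULL_SITE_WIDTH] = saved
            if ok:
                occupied.append((start, start + FULL_SITE_WIDTH))
                records.append(
                    PlantRecord(
                        sequence_id=sequence_id,
                        start=start,
                        end=start + FULL_SITE_WIDTH,
                        strand="+",
                        planted_tier=tier,
                        mismatch_positions=tuple(sorted(int(p) for p in mm_pos)),
                    )
                )
                planted = True
                break
        if not planted:
            raise ValueError(f"could not plant a tier-{tier} site cleanly")
    return decode(codes), PlantTruth(records=records)


def plant_half_sites_and_cooperators(
    seq: str,
    n_half: int,
    secondary_consensus: Optional[str] = None,
    gap_sampler: Optional[Callable] = None,
    seed: int = 0,
    sequence_id: str = "seq",
    window: int = 160,
    side: str = "downstream",
    min_gap: Optional[int] = None,
    edge_margin: Optional[int] = None,
    avoid: Iterable[tuple] = (),
) -> tuple[str, PlantTruth]:
    """Plant isolated perfect hexamers, optionally with a secondary motif.

    The hexamer is planted forward (``AGAACA``) and the surrounding 15-bp
    frames are required to stay below full-site quality, so each plant
    classifies as tier 5.  When a secondary consensus is given, one copy is
    planted per anchor at an edge-to-edge gap drawn by ``gap_sampler(rng)``
    on the requested side.
    """
    codes = encode(validate_acgt(seq))
    length = len(codes)
    rng = np.random.default_rng(seed)
    if side not in ("downstream", "upstream"):
        raise ValueError("side must be 'downstream' or 'upstream'")
    sec = encode(validate_acgt(secondary_consensus)) if secondary_consensus else None
    sec_w = len(sec) if sec is not None else 0
    if min_gap is None:
        min_gap = 2 * window + 30 if sec is not None else DEFAULT_MIN_GAP
    if edge_margin is None:
        edge_margin = window + sec_w + 10
    occupied: list[tuple] = [(int(s), int(e)) for s, e in avoid]
    records: list[PlantRecord] = []
    for _ in range(n_half):
        planted = False
        for _attempt in range(500):
            start = _sample_position(
                rng, length, HALF_SITE_WIDTH, occupied, min_gap, edge_margin
            )
            if start is None:
                raise ValueError(
                    f"insufficient room to plant {n_half} half sites in "
                    f"{length} bp (placed {len(records)})"
                )
            gap = int(gap_sampler(rng)) if gap_sampler is not None else None
            if gap is not None and not 0 <= gap < window:
                raise ValueError(f"gap_sampler produced {gap} outside [0, {window})")
            lo = start - FULL_SITE_WIDTH + 1
            hi = start + HALF_SITE_WIDTH - 1
            reach = window + sec_w if sec is not None else 0
            region_off = max(0, min(lo, start - reach))
            region_save = codes[
                region_off : start + HALF_SITE_WIDTH + reach
            ].copy()
            codes[start : start + HALF_SITE_WIDTH] = _HEX_FWD
            sec_start = None
            if sec is not None and gap is not None:
                if side == "downstream":
                    sec_start = start + HALF_SITE_WIDTH + gap
                else:
                    sec_start = start - gap - sec_w
                codes[sec_start : sec_start + sec_w] = sec
            good = (
                _full_site_free(codes, lo, hi, exclude=-1)
                and _hexamer_free(codes, start - HALF_SITE_WIDTH + 1, start + HALF_SITE_WIDTH - 1, exclude=start)
            )
            if good:
                occ_end = (
                    sec_start + sec_w
                    if sec_start is not None and side == "downstream"
                    else start + HALF_SITE_WIDTH
                )
                occ_start = (
                    sec_start
                    if sec_start is not None and side == "upstream"
                    else start
                )
                occupied.append((occ_start, occ_end))
                records.append(
                    PlantRecord(
                        sequence_id=sequence_id,
                        start=start,
                        end=start + HALF_SITE_WIDTH,
                        strand="+",
                        planted_tier=5,
                        gap_to_secondary=gap,
                        secondary_start=sec_start,
                    )
                )
                planted = True
                break
            codes[region_off : region_off + len(region_save)] = region_save
        if not planted:
            raise ValueError("could not plant a half site cleanly")
    return decode(codes), PlantTruth(records=records)


# ---------------------------------------------------------------------------
# Gene models and response tables
# ---------------------------------------------------------------------------

def gen_gene_model(
    n_genes: int,
    chrom_length: int,
    seed: int = 0,
    chrom: str = "chr1",
    min_gene_length: int = 3000,
    max_gene_length: int = 8000,
) -> list[GeneRecord]:
    """Non-overlapping multi-exon genes on both strands, evenly slotted."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    slot = chrom_length // n_genes
    if slot < max_gene_length + 4000:
        raise ValueError(
            f"chromosome of {chrom_length} bp cannot hold {n_genes} genes "
            f"of up to {max_gene_length} bp with flanks"
        )
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        g_len = int(rng.integers(min_gene_length, max_gene_length + 1))
        lo = i * slot + 2000
        hi = (i + 1) * slot - 2000 - g_len
        tx_start = int(rng.integers(lo, max(lo + 1, hi)))
        tx_end = tx_start + g_len
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        # split the body into exons separated by introns
        cuts = np.sort(rng.choice(np.arange(200, g_len - 200, 100), size=2 * n_exons - 2, replace=False))
        bounds = [0, *cuts.tolist(), g_len]
        exons = [
            (tx_start + bounds[2 * j], tx_start + bounds[2 * j + 1])
            for j in range(n_exons)
        ]
        exons = [(s, e) for s, e in exons if e > s]
        cds_start = exons[0][0] + min(100, (exons[0][1] - exons[0][0]) // 2)
        cds_end = exons[-1][1] - min(100, (exons[-1][1] - exons[-1][0]) // 2)
        genes.append(
            GeneRecord(
                chrom=chrom,
                strand=strand,
                tx_start=tx_start,
                tx_end=tx_end,
                exons=exons,
                gene_id=f"gene{i:04d}",
                tx_id=f"tx{i:04d}",
                cds_start=cds_start,
                cds_end=cds_end,
                coding=True,
            )
        )
    return genes


def gen_response_table(
    truth: PlantTruth,
    tier_to_de_prob: Mapping[int, float],
    seed: int = 0,
    provenance: str = "synthetic knockdown",
) -> GeneResponseTable:
    """Mark each site-bearing gene DE with the probability of its best tier.

    Direction is up or down with equal probability; genes whose draw fails
    are recorded as ``ns``.
    """
    rng = np.random.default_rng(seed)
    best_tier: dict[str, int] = {}
    for r in truth.records:
        if r.assigned_gene is None:
            continue
        t = best_tier.get(r.assigned_gene)
        if t is None or r.planted_tier < t:
            best_tier[r.assigned_gene] = r.planted_tier
    directions = {}
    for gene in sorted(best_tier):
        p = float(tier_to_de_prob.get(best_tier[gene], 0.0))
        if rng.random() < p:
            directions[gene] = "up" if rng.random() < 0.5 else "down"
        else:
            directions[gene] = "ns"
    return GeneResponseTable(directions=directions, provenance=provenance)


def gen_hitrate_truth(
    genes_per_tier: int, seed: int = 0, sequence_id: str = "chr1"
) -> PlantTruth:
    """Coordinate-free truth assigning one site-bearing gene per record,
    *genes_per_tier* genes for each tier 1..5 (for hit-rate calibration)."""
    records = []
    pos = 1000
    for tier in range(1, 6):
        width = HALF_SITE_WIDTH if tier == 5 else FULL_SITE_WIDTH
        for i in range(genes_per_tier):
            n_mm = 0 if tier == 5 else tier - 1
            records.append(
                PlantRecord(
                    sequence_id=sequence_id,
                    start=pos,
                    end=pos + width,
                    strand="+",
                    planted_tier=tier,
                    mismatch_positions=tuple(range(n_mm)),
                    assigned_gene=f"t{tier}_gene{i:04d}",
                )
            )
            pos += width + 100
    return PlantTruth(records=records)


def gen_density_hits(
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
    density_in: float,
    density_out: float,
    seed: int = 0,
) -> list[TieredHit]:
    """Poisson-plant site midpoints at the given densities (hits/Mbp)
    inside the region set and uniformly over its complement."""
    rng = np.random.default_rng(seed)
    hits: list[TieredHit] = []
    n_in = rng.poisson(density_in * regions.total_length / 1e6)
    region_lengths = np.array([e - s for _, s, e in regions.intervals], dtype=float)
    if n_in > 0 and len(region_lengths):
        picks = rng.choice(
            len(region_lengths), size=n_in, p=region_lengths / region_lengths.sum()
        )
        for i in picks:
            chrom, s, e = regions.intervals[i]
            pos = int(rng.integers(s, e))
            hits.append(synthetic_tiered_hit(chrom, max(0, pos - 7), 4))
    # complement intervals per chromosome
    comp = []
    for chrom, size in chrom_sizes.items():
        cursor = 0
        for c, s, e in regions.intervals:
            if c != chrom:
                continue
            if s > cursor:
                comp.append((chrom, cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            comp.append((chrom, cursor, size))
    comp_lengths = np.array([e - s for _, s, e in comp], dtype=float)
    n_out = rng.poisson(density_out * comp_lengths.sum() / 1e6) if len(comp) else 0
    if n_out > 0:
        picks = rng.choice(len(comp), size=n_out, p=comp_lengths / comp_lengths.sum())
        for i in picks:
            chrom, s, e = comp[i]
            pos = int(rng.integers(s, e))
            hits.append(synthetic_tiered_hit(chrom, max(0, pos - 7), 4))
    hits.sort(key=lambda h: (h.sequence_id, h.start))
    return hits
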