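"""Region-density statistics and per-tier transcriptional hit rates.

Densities are reported as sites per megabase inside a region set versus
its complement over the covered chromosomes, with an exact binomial test
conditional on the total hit count.  Hit rates cross tiered, gene-assigned
sites with a gene -> direction differential-expression table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genome_annotation import AnnotatedHit
from .tier_classifier import TieredHit

__all__ = [
    "RegionSet",
    "DensityComparison",
    "GeneResponseTable",
    "TierHitRate",
    "density",
    "density_test",
    "permutation_density_test",
    "tier_hit_rate",
    "read_chrom_sizes",
    "read_response_table",
]

MBP = 1_000_000.0


@dataclass
class RegionSet:
    """Named, merged genomic intervals (0-based half-open)."""

    name: str
    intervals: list  # (chrom, start, end)

    def __post_init__(self) -> None:
        merged: list[tuple] = []
        by_chrom: dict[str, list] = {}
        for chrom, s, e in self.intervals:
            s, e = int(s), int(e)
            if s < 0 or s >= e:
                raise ValueError(f"{self.name}: bad interval {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((s, e))
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    merged.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((chrom, cur_s, cur_e))
        self.intervals = merged

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        for c, s, e in self.intervals:
            if c == chrom and s <= pos < e:
                return True
        return False

    @classmethod
    def from_bed(cls, path, name: Optional[str] = None) -> "RegionSet":
        intervals = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                intervals.append((f[0], int(f[1]), int(f[2])))
        return cls(name=name or str(path), intervals=intervals)


@dataclass
class DensityComparison:
    hits_in: int
    hits_out: int
    mbp_in: float
    mbp_out: float
    p_value: Optional[float]  # None when undefined (no hits / empty complement)

    @property
    def density_in(self) -> float:
        return self.hits_in / self.mbp_in if self.mbp_in > 0 else float("nan")

    @property
    def density_out(self) -> float:
        return self.hits_out / self.mbp_out if self.mbp_out > 0 else float("nan")


@dataclass
class GeneResponseTable:
    """gene_id -> direction in {up, down, ns}; unknown genes are absent."""

    directions: dict
    provenance: str = ""

    def __post_init__(self) -> None:
        for g, d in self.directions.items():
            if d not in ("up", "down", "ns"):
                raise ValueError(f"{g}: direction must be up/down/ns, got {d!r}")

    def is_confirmed(self, gene_id: str) -> bool:
        return self.directions.get(gene_id) in ("up", "down")

    def __len__(self) -> int:
        return len(self.directions)


@dataclass
class TierHitRate:
    per_tier: pd.DataFrame       # tier, genes_with_tier, genes_confirmed, hit_rate
    rank_correlation: float      # Spearman rho of hit_rate vs tier index
    rank_p_value: float
    warning: Optional[str] = None


def read_chrom_sizes(path) -> dict:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def read_response_table(path, provenance: str = "") -> GeneResponseTable:
    """TSV with columns gene_id and direction (header optional extras kept)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or "direction" not in df.columns:
        raise ValueError(f"{path}: needs 'gene_id' and 'direction' columns")
    return GeneResponseTable(
        directions=dict(zip(df["gene_id"].astype(str), df["direction"])),
        provenance=provenance,
    )


def density(
    hits: Iterable[TieredHit],
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
) -> DensityComparison:
    """Partition hits by midpoint containment and compare hits/Mbp.

    The complement is the covered genome (chrom_sizes) minus the regions;
    hits on chromosomes absent from chrom_sizes are rejected.
    """
    for chrom, s, e in regions.intervals:
        if chrom not in chrom_sizes:
            raise ValueError(f"region chromosome {chrom!r} not in chrom_sizes")
        if e > chrom_sizes[chrom]:
            raise ValueError(
                f"region {chrom}:{s}-{e} outside chromosome bounds "
                f"({chrom_sizes[chrom]} bp)"
            )
    hits_in = hits_out = 0
    for h in hits:
        if h.sequence_id not in chrom_sizes:
            raise ValueError(
                f"hit chromosome {h.sequence_id!r} not in chrom_sizes"
            )
        if regions.contains(h.sequence_id, h.midpoint):
            hits_in += 1
        else:
            hits_out += 1
    len_in = regions.total_length
    len_out = sum(chrom_sizes.values()) - len_in
    mbp_in, mbp_out = len_in / MBP, len_out / MBP
    if mbp_out <= 0 or (hits_in + hits_out) == 0:
        return DensityComparison(hits_in, hits_out, mbp_in, mbp_out, None)
    p = density_test(hits_in, hits_out, mbp_in, mbp_out)
    return DensityComparison(hits_in, hits_out, mbp_in, mbp_out, p)


def density_test(
    hits_in: int, hits_out: int, mbp_in: float, mbp_out: float
) -> float:
    """Exact two-sided binomial test of the in-region hit count.

    Conditional on n = hits_in + hits_out, the null places each hit inside
    the regions with probability mbp_in / (mbp_in + mbp_out).
    """
    if hits_in < 0 or hits_out < 0:
        raise ValueError("hit counts must be non-negative")
    if mbp_in <= 0 or mbp_out <= 0:
        raise ValueError("region lengths must be positive")
    n = hits_in + hits_out
    if n == 0:
        raise ValueError("no hits: density test undefined")
    p0 = mbp_in / (mbp_in + mbp_out)
    return float(stats.binomtest(hits_in, n, p0, alternative="two-sided").pvalue)


def permutation_density_test(
    hits_in: int,
    n_total: int,
    regions: RegionSet,
    chrom_sizes: Mapping[str, int],
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo cross-check: drop n_total uniform midpoints over the
    covered genome and compare the in-region count to the observed one."""
    rng = np.random.default_rng(seed)
    p0 = regions.total_length / sum(chrom_sizes.values())
    sim = rng.binomial(n_total, p0, size=n_perm)
    exp = n_total * p0
    extreme = np.abs(sim - exp) >= abs(hits_in - exp) - 1e-12
    return float((extreme.sum() + 1) / (n_perm + 1))


def tier_hit_rate(
    annotated: Iterable[AnnotatedHit],
    responses: GeneResponseTable,
    best_tier_only: bool = False,
) -> TierHitRate:
    """Fraction of tier-bearing genes confirmed up or down per tier.

    A gene counts for every tier it bears at least one hit of (or only its
    best tier with *best_tier_only*).  The monotonicity statistic is the
    Spearman rank correlation of hit_rate against tier index.
    """
    genes_by_tier: dict[int, set] = {k: set() for k in range(1, 6)}
    best: dict[str, int] = {}
    for a in annotated:
        if a.gene_id is None:
            continue
        genes_by_tier[a.tier].add(a.gene_id)
        if a.gene_id not in best or a.tier < best[a.gene_id]:
            best[a.gene_id] = a.tier
    if best_tier_only:
        genes_by_tier = {k: set() for k in range(1, 6)}
        for g, k in best.items():
            genes_by_tier[k].add(g)
    warning = None
    if len(responses) == 0:
        warning = "empty response table: all hit rates are 0"
    rows = []
    for k in range(1, 6):
        genes = genes_by_tier[k]
        confirmed = sum(1 for g in genes if responses.is_confirmed(g))
        rows.append(
            {
                "tier": k,
                "genes_with_tier": len(genes),
                "genes_confirmed": confirmed,
                "hit_rate": confirmed / len(genes) if genes else 0.0,
            }
        )
    df = pd.DataFrame(rows)
    populated = df[df["genes_with_tier"] > 0]
    if len(populated) >= 3 and populated["hit_rate"].nunique() > 1:
        rho, pv = stats.spearmanr(populated["tier"], populated["hit_rate"])
    else:
        rho, pv = float("nan"), float("nan")
    return TierHitRate(
        per_tier=df,
        rank_correlation=float(rho),
        rank_p_value=float(pv),
        warning=warning,
    )
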