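"""Annotation of tiered hits against a gene model.

Each hit is assigned exactly one category by the fixed priority
``TSS > TTS > 5'UTR > 3'UTR > exon > intron > non-coding > intergenic``,
with promoter/terminator windows following transcript orientation.  The
hit position used throughout is the midpoint of the motif window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .tier_classifier import TieredHit

__all__ = [
    "CATEGORIES",
    "GeneRecord",
    "AnnotatedHit",
    "AnnotationConfig",
    "read_gene_model",
    "write_bed12",
    "annotate_hit",
    "annotate_hits",
    "category_fractions",
    "tss_fraction_test",
]

#: Categories in priority order (highest first).
CATEGORIES = (
    "TSS",
    "TTS",
    "5'UTR",
    "3'UTR",
    "exon",
    "intron",
    "non-coding",
    "intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass
class GeneRecord:
    """One transcript: body, exon structure and optional CDS."""

    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list            # ordered disjoint (start, end) tuples
    gene_id: str
    tx_id: str
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    coding: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.tx_id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.tx_id}: tx_start must be < tx_end")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e > self.tx_end or s >= e:
                raise ValueError(
                    f"{self.tx_id}: exons must be ordered, disjoint and "
                    f"inside [{self.tx_start}, {self.tx_end})"
                )
            prev_end = e
        if self.coding and self.cds_start is not None:
            if not (self.tx_start <= self.cds_start < self.cds_end <= self.tx_end):
                raise ValueError(f"{self.tx_id}: CDS outside transcript body")

    @property
    def tss(self) -> int:
        """0-based coordinate of the first transcribed base."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tts(self) -> int:
        """0-based coordinate of the last transcribed base."""
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    def signed_offset(self, pos: int, anchor: int) -> int:
        """Offset of *pos* from *anchor* in transcript orientation
        (positive = downstream)."""
        return pos - anchor if self.strand == "+" else anchor - pos

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)


@dataclass
class AnnotationConfig:
    tss_window: tuple = (-1000, 100)
    tts_window: tuple = (-100, 1000)
    end_flank: int = 5000
    max_assoc: int = 100_000


@dataclass(frozen=True)
class AnnotatedHit:
    tiered_hit: TieredHit
    category: str
    gene_id: Optional[str]
    distance_to_tss: Optional[int]

    @property
    def tier(self) -> int:
        return self.tiered_hit.tier


# ---------------------------------------------------------------------------
# Gene model I/O
# ---------------------------------------------------------------------------

def _parse_bed12_line(line: str, lineno: int) -> GeneRecord:
    f = line.rstrip("\n").split("\t")
    if len(f) < 12:
        raise ValueError(f"line {lineno}: BED12 needs 12 fields, got {len(f)}")
    try:
        chrom = f[0]
        start, end = int(f[1]), int(f[2])
        name = f[3]
        strand = f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        n_blocks = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ValueError(f"line {lineno}: malformed BED12 field ({exc})") from None
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise ValueError(f"line {lineno}: block count mismatch")
    exons = [(start + o, start + o + s) for o, s in zip(starts, sizes)]
    coding = thick_end > thick_start
    gene_id = name.split("|")[0]
    return GeneRecord(
        chrom=chrom,
        strand=strand,
        tx_start=start,
        tx_end=end,
        exons=exons,
        gene_id=gene_id,
        tx_id=name,
        cds_start=thick_start if coding else None,
        cds_end=thick_end if coding else None,
        coding=coding,
    )


def _read_gtf(path) -> list[GeneRecord]:
    """Assemble transcripts from GTF exon/CDS lines (1-based inclusive)."""
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    biotype: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"line {lineno}: GTF needs 9 fields, got {len(f)}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = f
            if feature not in ("exon", "CDS"):
                continue
            try:
                start_i, end_i = int(start) - 1, int(end)  # -> 0-based half-open
            except ValueError:
                raise ValueError(f"line {lineno}: non-integer coordinates") from None
            attr = {}
            for part in attrs.rstrip(";").split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                attr[key] = val.strip().strip('"')
            if "transcript_id" not in attr:
                raise ValueError(f"line {lineno}: missing transcript_id attribute")
            txid = attr["transcript_id"]
            meta[txid] = (chrom, strand, attr.get("gene_id", txid))
            if "transcript_biotype" in attr or "gene_biotype" in attr:
                biotype[txid] = attr.get("transcript_biotype") or attr.get(
                    "gene_biotype"
                )
            target = exons if feature == "exon" else cds
            target.setdefault(txid, []).append((start_i, end_i))
    records = []
    for txid, ex in exons.items():
        chrom, strand, gene_id = meta[txid]
        ex = sorted(ex)
        c = sorted(cds.get(txid, []))
        coding = bool(c)
        bt = biotype.get(txid, "protein_coding" if coding else "non_coding")
        records.append(
            GeneRecord(
                chrom=chrom,
                strand=strand,
                tx_start=ex[0][0],
                tx_end=ex[-1][1],
                exons=ex,
                gene_id=gene_id,
                tx_id=txid,
                cds_start=c[0][0] if coding else None,
                cds_end=c[-1][1] if coding else None,
                coding=coding and bt == "protein_coding",
            )
        )
    return records


def read_gene_model(path, format: str = "BED12") -> list[GeneRecord]:
    """Read transcripts from a BED12 or GTF file."""
    fmt = format.upper()
    if fmt == "BED12":
        records = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                records.append(_parse_bed12_line(line, lineno))
    elif fmt == "GTF":
        records = _read_gtf(path)
    else:
        raise ValueError(f"unknown gene model format {format!r}")
    if not records:
        raise ValueError(f"{path}: no transcripts found")
    return records


def write_bed12(records: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            sizes = ",".join(str(e - s) for s, e in r.exons) + ","
            offsets = ",".join(str(s - r.tx_start) for s, e in r.exons) + ","
            thick_s = r.cds_start if r.coding and r.cds_start is not None else r.tx_start
            thick_e = r.cds_end if r.coding and r.cds_end is not None else r.tx_start
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.chrom,
                        r.tx_start,
                        r.tx_end,
                        r.tx_id,
                        0,
                        r.strand,
                        thick_s,
                        thick_e,
                        0,
                        len(r.exons),
                        sizes,
                        offsets,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _transcript_category(pos: int, g: GeneRecord, cfg: AnnotationConfig):
    """(category, |distance to TSS|) of *pos* for one transcript, or None."""
    d_tss = g.signed_offset(pos, g.tss)
    if cfg.tss_window[0] <= d_tss <= cfg.tss_window[1]:
        return "TSS", abs(d_tss)
    d_tts = g.signed_offset(pos, g.tts)
    if cfg.tts_window[0] <= d_tts <= cfg.tts_window[1]:
        return "TTS", abs(d_tss)
    if not (g.tx_start <= pos < g.tx_end):
        return None
    if not g.coding:
        return "non-coding", abs(d_tss)
    if g.in_exon(pos):
        if g.cds_start is not None:
            if pos < g.cds_start:
                return ("5'UTR" if g.strand == "+" else "3'UTR"), abs(d_tss)
            if pos >= g.cds_end:
                return ("3'UTR" if g.strand == "+" else "5'UTR"), abs(d_tss)
        return "exon", abs(d_tss)
    return "intron", abs(d_tss)


def annotate_hit(
    hit: TieredHit,
    genes: list[GeneRecord],
    config: AnnotationConfig | None = None,
) -> AnnotatedHit:
    """Categorize one hit by midpoint and assign a nearest gene."""
    cfg = config or AnnotationConfig()
    pos = hit.midpoint
    chrom = hit.sequence_id
    best = None  # (priority, |d_tss|, gene)
    nearest = None  # (|d_tss|, gene)
    for g in genes:
        if g.chrom != chrom:
            continue
        abs_d = abs(g.signed_offset(pos, g.tss))
        res = _transcript_category(pos, g, cfg)
        if res is not None:
            cat, _ = res
            key = (_PRIORITY[cat], abs_d)
            if best is None or key < (best[0], best[1]):
                best = (_PRIORITY[cat], abs_d, g)
        # gene association: inside the flanked body, or nearest TSS in range
        in_flanked = (
            g.tx_start - cfg.end_flank <= pos < g.tx_end + cfg.end_flank
        )
        if (in_flanked or abs_d <= cfg.max_assoc) and (
            nearest is None or abs_d < nearest[0]
        ):
            nearest = (abs_d, g)
    if best is not None:
        cat = CATEGORIES[best[0]]
        g = best[2]
        return AnnotatedHit(
            tiered_hit=hit,
            category=cat,
            gene_id=g.gene_id,
            distance_to_tss=g.signed_offset(pos, g.tss),
        )
    if nearest is not None:
        g = nearest[1]
        return AnnotatedHit(
            tiered_hit=hit,
            category="intergenic",
            gene_id=g.gene_id,
            distance_to_tss=g.signed_offset(pos, g.tss),
        )
    return AnnotatedHit(
        tiered_hit=hit, category="intergenic", gene_id=None, distance_to_tss=None
    )


def annotate_hits(
    hits: Iterable[TieredHit],
    genes: list[GeneRecord],
    config: AnnotationConfig | None = None,
) -> list[AnnotatedHit]:
    cfg = config or AnnotationConfig()
    return [annotate_hit(h, genes, cfg) for h in hits]


def category_fractions(
    annotated: Iterable[AnnotatedHit], split_by_tier: bool = False
) -> pd.DataFrame:
    """Counts and fractions per category (optionally per tier).

    Fractions are computed within each tier when *split_by_tier* is set,
    and over all hits otherwise; category order follows priority.
    """
    rows = [
        {"tier": a.tier, "category": a.category} for a in annotated
    ]
    df = pd.DataFrame(rows, columns=["tier", "category"])
    if df.empty:
        return pd.DataFrame(columns=["tier", "category", "count", "fraction"])
    if split_by_tier:
        out = (
            df.groupby(["tier", "category"], observed=True)
            .size()
            .rename("count")
            .reset_index()
        )
        out["fraction"] = out.groupby("tier")["count"].transform(
            lambda c: c / c.sum()
        )
    else:
        out = df.groupby("category").size().rename("count").reset_index()
        out["fraction"] = out["count"] / out["count"].sum()
    out["category"] = pd.Categorical(
        out["category"], categories=CATEGORIES, ordered=True
    )
    sort_cols = ["tier", "category"] if split_by_tier else ["category"]
    return out.sort_values(sort_cols).reset_index(drop=True)


def tss_fraction_test(
    annotated_a: Iterable[AnnotatedHit], annotated_b: Iterable[AnnotatedHit]
) -> dict:
    """Two-proportion z-test of TSS-category fractions between two hit sets."""
    from statsmodels.stats.proportion import proportions_ztest

    a = list(annotated_a)
    b = list(annotated_b)
    ka = sum(1 for x in a if x.category == "TSS")
    kb = sum(1 for x in b if x.category == "TSS")
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise ValueError("both hit sets must be non-empty")
    stat, p = proportions_ztest([ka, kb], [na, nb])
    return {
        "fraction_a": ka / na,
        "fraction_b": kb / nb,
        "difference": ka / na - kb / nb,
        "z": float(stat),
        "p_value": float(p) if not np.isnan(p) else 1.0,
    }
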