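"""Readers and writers for the text formats used across the pipeline.

Coordinates are 0-based half-open in BED and in all TSV outputs; every
output file states its convention in a leading comment line.  P-values are
written in full-precision scientific notation.
"""

from __future__ import annotations

import gzip
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .cooperation import SIDES, CooperationResult
from .genome_annotation import AnnotatedHit
from .scanner import MotifHit
from .tier_classifier import TieredHit

COORD_COMMENT = "# coordinates: 0-based half-open\n"


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Multi-record FASTA (plain or gzip) -> {id: sequence}."""
    with _open_text(path) as fh:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hits
# ---------------------------------------------------------------------------

def bed_score(p_value: float) -> int:
    """Browser-friendly score: min(1000, round(-10 * log10 p))."""
    if p_value <= 0:
        return 1000
    return int(min(1000, round(-10.0 * np.log10(p_value))))


def write_hits_bed(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.model_name}\t"
                f"{bed_score(h.p_value)}\t{h.strand}\n"
            )


def write_hits_tsv(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write(
            "sequence_id\tstart\tend\tstrand\tscore\tp_value\t"
            "matched_seq\tmodel_name\n"
        )
        for h in hits:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.score:.6f}\t{h.p_value:.6e}\t{h.matched_seq}\t{h.model_name}\n"
            )


def write_tiered_bed(hits: Iterable[TieredHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        for t in hits:
            fh.write(
                f"{t.sequence_id}\t{t.start}\t{t.end}\tARE_tier{t.tier}\t"
                f"{bed_score(t.hit.p_value)}\t{t.hit.strand}\n"
            )


def write_tiered_tsv(hits: Iterable[TieredHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write(
            "sequence_id\tstart\tend\tstrand\ttier\tcore_mismatches\t"
            "left_hexamer_mismatches\tright_hexamer_mismatches\t"
            "half_site_orientation\tscore\tp_value\tmatched_seq\n"
        )
        for t in hits:
            fh.write(
                "\t".join(
                    str(x) if x is not None else "."
                    for x in (
                        t.sequence_id,
                        t.start,
                        t.end,
                        t.hit.strand,
                        t.tier,
                        t.core_mismatches,
                        t.left_hexamer_mismatches,
                        t.right_hexamer_mismatches,
                        t.half_site_orientation,
                        f"{t.hit.score:.6f}",
                        f"{t.hit.p_value:.6e}",
                        t.hit.matched_seq,
                    )
                )
                + "\n"
            )


def read_tiered_tsv(path) -> list:
    """Read back a tiered-hit TSV written by :func:`write_tiered_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for row in df.itertuples(index=False):
        m = None if str(row.core_mismatches) == "." else int(float(row.core_mismatches))
        lm = (
            None
            if str(row.left_hexamer_mismatches) == "."
            else int(float(row.left_hexamer_mismatches))
        )
        rm = (
            None
            if str(row.right_hexamer_mismatches) == "."
            else int(float(row.right_hexamer_mismatches))
        )
        ori = None if str(row.half_site_orientation) == "." else row.half_site_orientation
        hit = MotifHit(
            sequence_id=str(row.sequence_id),
            start=int(row.start),
            end=int(row.end),
            strand=str(row.strand),
            score=float(row.score),
            p_value=float(row.p_value),
            matched_seq=str(row.matched_seq),
            model_name="tiered",
        )
        out.append(
            TieredHit(
                hit=hit,
                tier=int(row.tier),
                core_mismatches=m,
                left_hexamer_mismatches=lm,
                right_hexamer_mismatches=rm,
                half_site_orientation=ori,
            )
        )
    return out


def write_annotated_tsv(annotated: Iterable[AnnotatedHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write(
            "sequence_id\tstart\tend\ttier\tcategory\tgene_id\tdistance_to_tss\n"
        )
        for a in annotated:
            t = a.tiered_hit
            fh.write(
                "\t".join(
                    str(x) if x is not None else "."
                    for x in (
                        t.sequence_id,
                        t.start,
                        t.end,
                        t.tier,
                        a.category,
                        a.gene_id,
                        a.distance_to_tss,
                    )
                )
                + "\n"
            )


def write_spacing_tsv(result: CooperationResult, path) -> None:
    hist = result.histogram
    with open(path, "w") as fh:
        fh.write(COORD_COMMENT)
        fh.write(
            f"# anchors={hist.n_anchors} with_secondary="
            f"{hist.n_anchors_with_secondary} dropped={hist.n_anchors_dropped}\n"
        )
        fh.write("bin_start\tbin_end\tside\tcount\traw_p\tcorrected_p\n")
        for side in SIDES:
            for b in range(hist.n_bins):
                fh.write(
                    f"{b * hist.bin_width}\t"
                    f"{min((b + 1) * hist.bin_width, hist.window)}\t{side}\t"
                    f"{hist.counts[side][b]}\t{result.raw_p[side][b]:.6e}\t"
                    f"{result.corrected_p[side][b]:.6e}\n"
                )


def read_bed_intervals(path) -> list:
    """BED -> list of (chrom, start, end[, name, score, strand])."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append((f[0], int(f[1]), int(f[2]), *f[3:6]))
    return out
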