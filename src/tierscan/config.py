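"""Run configuration and the end-to-end pipeline driver.

A :class:`RunConfig` is a flat, serializable set of every tunable default
in the package plus the input paths of a run.  ``run_pipeline`` executes
the stages for which inputs are configured and writes a manifest recording
the effective config, seed and per-output row counts, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import io as tio
from .cooperation import spacing_enrichment, spacing_histogram
from .downstream_stats import (
    RegionSet,
    density,
    read_chrom_sizes,
    read_response_table,
    tier_hit_rate,
)
from .genome_annotation import AnnotationConfig, annotate_hits, read_gene_model
from .motif_models import read_meme
from .tier_classifier import classify_sequences, tier_distribution

#: Score thresholds printed for the original study's matrices; they are
#: documented defaults only and carry no claim of numerical equivalence.
REPORTED_P_THRESHOLDS = {
    "ideal": 8.34e-8,
    "lenient": 4.94e-5,
    "extended": 5.52e-5,
}


@dataclass
class RunConfig:
    """Flat configuration; unknown keys are rejected on load."""

    # inputs
    fasta: Optional[str] = None
    genes: Optional[str] = None
    genes_format: str = "BED12"
    regions: Optional[str] = None
    chrom_sizes: Optional[str] = None
    responses: Optional[str] = None
    secondary_motif: Optional[str] = None
    out_dir: str = "tierscan_out"
    # randomness
    seed: int = 0
    # model construction
    match_prob_ideal: float = 0.997
    match_prob_lenient: float = 0.85
    # scanning
    background: str = "auto"
    granularity: Optional[float] = None
    ideal_p_threshold: float = REPORTED_P_THRESHOLDS["ideal"]
    lenient_p_threshold: float = REPORTED_P_THRESHOLDS["lenient"]
    extended_p_threshold: float = REPORTED_P_THRESHOLDS["extended"]
    # tier classification
    mismatches_one_hexamer: bool = False
    # annotation
    tss_upstream: int = -1000
    tss_downstream: int = 100
    tts_upstream: int = -100
    tts_downstream: int = 1000
    end_flank: int = 5000
    max_assoc: int = 100_000
    # spacing
    spacing_window: int = 160
    spacing_bin_width: int = 5
    secondary_p_threshold: float = 1e-4
    spacing_alpha: float = 0.05
    # hit rate
    best_tier_only: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def annotation_config(self) -> AnnotationConfig:
        return AnnotationConfig(
            tss_window=(self.tss_upstream, self.tss_downstream),
            tts_window=(self.tts_upstream, self.tts_downstream),
            end_flank=self.end_flank,
            max_assoc=self.max_assoc,
        )


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for ln in fh if not ln.startswith("#"))


def run_pipeline(config: RunConfig) -> dict:
    """Run classify -> annotate -> spacing -> density -> hitrate as inputs allow.

    Returns the manifest dict (also written to ``manifest.json`` in the
    output directory).  Any stage failure raises with the stage name.
    """
    if config.fasta is None:
        raise ValueError("stage classify: no FASTA configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "outputs": {},
        "stage_seconds": {},
        "summary": {},
    }

    def _record(name: str, path: Path) -> None:
        manifest["outputs"][name] = {
            "path": str(path),
            "rows": _count_rows(path),
        }

    def _stage(name):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stage_seconds"][name] = round(
                    time.perf_counter() - self_inner.t0, 3
                )
                if exc is not None:
                    raise RuntimeError(f"stage {name} failed: {exc}") from exc

        return _Timer()

    with _stage("classify"):
        try:
            sequences = tio.read_fasta(config.fasta)
        except FileNotFoundError:
            raise FileNotFoundError(f"FASTA not found: {config.fasta}")
        tiered = classify_sequences(
            sequences, mismatches_one_hexamer=config.mismatches_one_hexamer
        )
        tio.write_tiered_bed(tiered, out / "tiered.bed")
        tio.write_tiered_tsv(tiered, out / "tiered.tsv")
        _record("tiered_bed", out / "tiered.bed")
        _record("tiered_tsv", out / "tiered.tsv")
        summary = tier_distribution(tiered)
        manifest["summary"]["tier_counts"] = summary.counts

    annotated = None
    if config.genes:
        with _stage("annotate"):
            genes = read_gene_model(config.genes, config.genes_format)
            annotated = annotate_hits(tiered, genes, config.annotation_config())
            tio.write_annotated_tsv(annotated, out / "annotated.tsv")
            _record("annotated_tsv", out / "annotated.tsv")

    if config.secondary_motif:
        with _stage("spacing"):
            secondary = read_meme(config.secondary_motif)[0]
            full_anchors = [t for t in tiered if t.tier <= 4]
            half_anchors = [t for t in tiered if t.tier == 5]
            for label, anchors in (("full", full_anchors), ("half", half_anchors)):
                hist = spacing_histogram(
                    anchors,
                    secondary,
                    sequences,
                    window=config.spacing_window,
                    bin_width=config.spacing_bin_width,
                    secondary_p_threshold=config.secondary_p_threshold,
                    anchor_model=f"ARE_{label}",
                )
                result = spacing_enrichment(hist, alpha=config.spacing_alpha)
                path = out / f"spacing_{label}.tsv"
                tio.write_spacing_tsv(result, path)
                _record(f"spacing_{label}", path)

    if config.regions and config.chrom_sizes:
        with _stage("density"):
            regions = RegionSet.from_bed(config.regions, name="regions")
            sizes = read_chrom_sizes(config.chrom_sizes)
            cmp = density(tiered, regions, sizes)
            path = out / "density.tsv"
            with open(path, "w") as fh:
                fh.write("# densities in hits per Mbp\n")
                fh.write(
                    "hits_in\thits_out\tmbp_in\tmbp_out\t"
                    "density_in\tdensity_out\tp_value\n"
                )
                fh.write(
                    f"{cmp.hits_in}\t{cmp.hits_out}\t{cmp.mbp_in:.6f}\t"
                    f"{cmp.mbp_out:.6f}\t{cmp.density_in:.6f}\t"
                    f"{cmp.density_out:.6f}\t"
                    f"{'NA' if cmp.p_value is None else format(cmp.p_value, '.6e')}\n"
                )
            _record("density", path)

    if config.responses and annotated is not None:
        with _stage("hitrate"):
            responses = read_response_table(config.responses)
            rates = tier_hit_rate(
                annotated, responses, best_tier_only=config.best_tier_only
            )
            path = out / "hitrate.tsv"
            with open(path, "w") as fh:
                fh.write(
                    f"# spearman_rho={rates.rank_correlation:.4f} "
                    f"p={rates.rank_p_value:.4e}\n"
                )
                rates.per_tier.to_csv(fh, sep="\t", index=False)
            _record("hitrate", path)

    config.to_file(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
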