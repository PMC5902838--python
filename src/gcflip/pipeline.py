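"""End-to-end orchestration: catalog -> detect -> stats -> local GC.

Given a phased VCF (and optionally a reference FASTA for the local-GC
analysis), runs the whole detection pipeline under one configuration and
writes the catalog TSV, events TSV, per-category bias summaries, GC
distributions and a run manifest. Reruns with identical inputs, config
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pyfaidx

from gcflip import __version__
from gcflip.bgc_stats import summarize
from gcflip.flipover_detector import (
    OCCURRENCE_CATEGORIES,
    occurrence_bounds,
    scan_population,
    write_events_tsv,
)
from gcflip.haplotype_catalog import (
    build_segments,
    extract_haplotypes,
    rank_haplotypes,
    write_catalog_tsv,
)
from gcflip.local_gc import compare_distributions, default_bins
from gcflip.variant_io import filter_frequent, read_phased_vcf

__all__ = ["RunConfig", "run_pipeline", "build_catalogs"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (thresholds as absolute counts)."""

    vcf: Path
    fasta: Optional[Path] = None
    out_dir: Path = Path("gcflip_out")
    maf_min: float = 0.25
    k: int = 50
    common_min: int = 100
    rare_max: int = 5
    categories: tuple[str, ...] = ("1", "2", "1-2", "1-5")
    flank: int = 50
    bin_width: float = 0.02
    seed: int = 0
    chrom_filter: Optional[tuple[str, ...]] = None
    local_gc: bool = True

    def __post_init__(self) -> None:
        self.vcf = Path(self.vcf)
        self.fasta = Path(self.fasta) if self.fasta is not None else None
        self.out_dir = Path(self.out_dir)
        if self.maf_min < 0 or self.k < 2 or self.common_min < 1 or self.rare_max < 1:
            raise ValueError("thresholds must be positive")
        bad = set(self.categories) - set(OCCURRENCE_CATEGORIES)
        if bad:
            raise ValueError(f"unknown occurrence categories: {sorted(bad)}")
        if self.local_gc and self.fasta is None:
            raise ValueError("local-GC analysis requested but no FASTA given")


def _log(payload: dict) -> None:
    print(json.dumps(payload), file=sys.stderr)


def build_catalogs(config: RunConfig):
    """Read the VCF and build per-segment haplotype catalogs."""
    reader = read_phased_vcf(config.vcf, chrom_filter=config.chrom_filter)
    frequent = list(filter_frequent(reader, maf_min=config.maf_min))
    segments, dropped = build_segments(frequent, k=config.k)
    catalogs = []
    for seg in segments:
        haps = extract_haplotypes(seg, reader.samples)
        catalogs.append(
            rank_haplotypes(
                seg,
                haps,
                reader.samples,
                common_min=config.common_min,
                rare_max=config.rare_max,
            )
        )
    return reader, catalogs, dropped


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict.

    Outputs written to ``config.out_dir``: ``catalog.tsv``, per-category
    ``events_<cat>.tsv`` and ``bias_<cat>.json``, ``gc_distributions.tsv``
    + ``gc_gof.json`` when a FASTA is supplied, and ``manifest.json``.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    reader, catalogs, dropped = build_catalogs(config)
    _log({"stage": "catalog", "segments": len(catalogs), "dropped": dropped})

    catalog_path = out / "catalog.tsv"
    with open(catalog_path, "w") as fh:
        write_catalog_tsv(catalogs, fh)

    outputs = {"catalog": str(catalog_path)}
    events_by_cat = {}
    for cat in config.categories:
        events = scan_population(catalogs, reader.samples, category=cat)
        events_by_cat[cat] = events
        ev_path = out / f"events_{cat}.tsv"
        with open(ev_path, "w") as fh:
            write_events_tsv(events, fh)
        summary = summarize(events, category=cat)
        bias_path = out / f"bias_{cat}.json"
        bias_path.write_text(summary.to_json(indent=2) + "\n")
        outputs[f"events_{cat}"] = str(ev_path)
        outputs[f"bias_{cat}"] = str(bias_path)
        _log({"stage": "detect", "category": cat, "events": len(events)})

    if config.local_gc and config.fasta is not None:
        widest = max(config.categories, key=lambda c: occurrence_bounds(c)[1])
        events = events_by_cat[widest]
        by_class: dict[str, list] = {}
        for e in events:
            by_class.setdefault(e.change_class.value, []).append(e)
        regions = [
            (c.segment.chrom, c.segment.span[0], c.segment.span[1]) for c in catalogs
        ]
        ref = pyfaidx.Fasta(str(config.fasta))
        if by_class:
            dists, gof = compare_distributions(
                by_class,
                ref,
                regions,
                bins=default_bins(config.bin_width),
                seed=config.seed,
                flank=config.flank,
            )
            gc_path = out / "gc_distributions.tsv"
            with open(gc_path, "w") as fh:
                fh.write("class\tbin_low\tbin_high\tdensity\tn\n")
                for label in sorted(dists):
                    d = dists[label]
                    for lo, hi, dens in zip(
                        d.bin_edges[:-1], d.bin_edges[1:], d.densities
                    ):
                        fh.write(
                            f"{label}\t{lo:.4f}\t{hi:.4f}\t{dens:.6f}\t{d.n_sites}\n"
                        )
            gof_path = out / "gc_gof.json"
            gof_path.write_text(
                json.dumps(
                    {
                        label: {
                            "chi2": r.chi2,
                            "df": r.df,
                            "p_value": r.p_value,
                            "n_bins_pooled": r.n_bins_pooled,
                        }
                        for label, r in gof.items()
                    },
                    indent=2,
                )
                + "\n"
            )
            outputs["gc_distributions"] = str(gc_path)
            outputs["gc_gof"] = str(gof_path)

    manifest = {
        "gcflip_version": __version__,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in asdict(config).items()
        },
        "n_individuals": reader.samples.n_individuals,
        "n_segments": len(catalogs),
        "dropped_variants": dropped,
        "skip_counts": dict(reader.skip_counts),
        "outputs": outputs,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
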