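"""Per-segment haplotype extraction and frequency cataloging.

Each chromosome's frequent variants are partitioned into consecutive
segments of a fixed number of variants (default 50). Within a segment every
individual contributes two haplotype strings — one per parental chromosome —
written as 0/1 characters ("0" = reference allele, "1" = alternative
allele). The catalog ranks distinct strings by occurrence and labels them
common (count >= common_min, default 100), rare (count <= rare_max, default
5) or intermediate.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO

from gcflip.variant_io import SampleSet, VariantRecord

__all__ = [
    "Segment",
    "CatalogEntry",
    "HaplotypeCatalog",
    "build_segments",
    "extract_haplotypes",
    "rank_haplotypes",
    "write_catalog_tsv",
]

#: Haplotype occurrence threshold defining a "common haplotype".
DEFAULT_COMMON_MIN = 100
#: Maximum occurrence of a rare ("acceptor" candidate) haplotype.
DEFAULT_RARE_MAX = 5


@dataclass(frozen=True)
class Segment:
    """A run of ``k`` consecutive frequent variants on one chromosome."""

    chrom: str
    index: int  # 1-based ordinal within the chromosome
    variants: tuple[VariantRecord, ...]

    @property
    def k(self) -> int:
        return len(self.variants)

    @property
    def span(self) -> tuple[int, int]:
        """(first, last) 1-based positions covered by the segment."""
        return (self.variants[0].pos, self.variants[-1].pos)


@dataclass(frozen=True)
class CatalogEntry:
    """One distinct haplotype string with its carriers."""

    alleles: str
    count: int
    carriers: tuple[tuple[str, int], ...]  # (individual id, parental index 0/1)

    def label(self, common_min: int, rare_max: int) -> str:
        if self.count >= common_min:
            return "common"
        if self.count <= rare_max:
            return "rare"
        return "intermediate"


@dataclass(frozen=True)
class HaplotypeCatalog:
    """Ranked haplotype table for one segment.

    Entries are ordered by descending occurrence, ties broken
    lexicographically by allele string for determinism. Occurrence counts
    always sum to 2N.
    """

    segment: Segment
    entries: tuple[CatalogEntry, ...]
    common_min: int = DEFAULT_COMMON_MIN
    rare_max: int = DEFAULT_RARE_MAX

    def count_of(self, alleles: str) -> int:
        return self._counts.get(alleles, 0)

    @property
    def _counts(self) -> dict[str, int]:
        d = self.__dict__.get("_counts_cache")
        if d is None:
            d = {e.alleles: e.count for e in self.entries}
            self.__dict__["_counts_cache"] = d
        return d

    @property
    def common_entries(self) -> tuple[CatalogEntry, ...]:
        return tuple(e for e in self.entries if e.count >= self.common_min)

    @property
    def total_haplotypes(self) -> int:
        return sum(e.count for e in self.entries)

    def haplotypes_by_individual(self) -> dict[str, list[Optional[str]]]:
        """Map individual id -> [haplotype of parent 0, haplotype of parent 1]."""
        out: dict[str, list[Optional[str]]] = defaultdict(lambda: [None, None])
        for entry in self.entries:
            for indiv, parent in entry.carriers:
                out[indiv][parent] = entry.alleles
        return dict(out)


def build_segments(
    frequent_variants: Iterable[VariantRecord],
    k: int = 50,
    max_span_bp: Optional[int] = None,
) -> tuple[list[Segment], dict[str, int]]:
    """Partition frequent variants into consecutive blocks of exactly ``k``.

    Variants must arrive sorted by (chrom, pos). Per chromosome, consecutive
    non-overlapping blocks of ``k`` variants become segments, numbered from
    1; a trailing remainder of fewer than ``k`` variants is dropped (the
    detector needs fixed-length strings) and reported in the returned
    per-chromosome drop counts.

    ``max_span_bp``, if given, discards segments whose genomic span exceeds
    the guard (counted under key ``"<chrom>:overspan"``).

    Returns
    -------
    (segments, dropped) : list of Segment, dict of chrom -> dropped variant count
    """
    if k < 2:
        raise ValueError(f"segment size k must be >= 2, got {k}")
    segments: list[Segment] = []
    dropped: dict[str, int] = {}
    buffer: list[VariantRecord] = []
    cur_chrom: Optional[str] = None
    index = 0

    def flush_tail() -> None:
        if cur_chrom is not None and buffer:
            dropped[cur_chrom] = dropped.get(cur_chrom, 0) + len(buffer)

    for rec in frequent_variants:
        if rec.chrom != cur_chrom:
            flush_tail()
            cur_chrom = rec.chrom
            buffer = []
            index = 0
        buffer.append(rec)
        if len(buffer) == k:
            index += 1
            seg = Segment(chrom=cur_chrom, index=index, variants=tuple(buffer))
            if max_span_bp is not None and seg.span[1] - seg.span[0] > max_span_bp:
                key = f"{cur_chrom}:overspan"
                dropped[key] = dropped.get(key, 0) + k
            else:
                segments.append(seg)
            buffer = []
    flush_tail()
    return segments, dropped


def extract_haplotypes(segment: Segment, samples: SampleSet) -> list[str]:
    """The 2N haplotype strings of a segment.

    For each individual, haplotype 0 concatenates the first parental allele
    across the segment's variants and haplotype 1 the second, in sample
    order: output index ``2*i + parent`` for individual ``i``.
    """
    n = samples.n_individuals
    per_variant = [v.sample_alleles for v in segment.variants]
    for v, alleles in zip(segment.variants, per_variant):
        if len(alleles) != n:
            raise ValueError(
                f"variant {v.chrom}:{v.pos} has {len(alleles)} genotypes "
                f"for {n} samples"
            )
    haps: list[str] = []
    for i in range(n):
        for parent in (0, 1):
            haps.append("".join(str(alleles[i][parent]) for alleles in per_variant))
    return haps


def rank_haplotypes(
    segment: Segment,
    haplotypes: Sequence[str],
    samples: SampleSet,
    common_min: int = DEFAULT_COMMON_MIN,
    rare_max: int = DEFAULT_RARE_MAX,
) -> HaplotypeCatalog:
    """Rank the 2N haplotype strings of a segment by occurrence.

    Counts conserve 2N; entries are sorted by descending count, then
    lexicographically by allele string.
    """
    lengths = {len(h) for h in haplotypes}
    if len(lengths) > 1:
        raise ValueError(f"haplotype strings of unequal length: {sorted(lengths)}")
    counts = Counter(haplotypes)
    carriers: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for idx, hap in enumerate(haplotypes):
        carriers[hap].append((samples.sample_ids[idx // 2], idx % 2))
    entries = tuple(
        CatalogEntry(alleles=hap, count=cnt, carriers=tuple(carriers[hap]))
        for hap, cnt in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return HaplotypeCatalog(
        segment=segment, entries=entries, common_min=common_min, rare_max=rare_max
    )


def write_catalog_tsv(catalogs: Iterable[HaplotypeCatalog], out: TextIO) -> None:
    """Serialize catalogs as TSV: chrom, segment, span, haplotype, count, class."""
    out.write("chrom\tsegment\tspan_start\tspan_end\thaplotype\tcount\tclass\n")
    for cat in catalogs:
        seg = cat.segment
        lo, hi = seg.span
        for e in cat.entries:
            out.write(
                f"{seg.chrom}\t{seg.index}\t{lo}\t{hi}\t{e.alleles}\t{e.count}\t"
                f"{e.label(cat.common_min, cat.rare_max)}\n"
            )
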