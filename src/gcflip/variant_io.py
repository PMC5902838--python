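"""Phased VCF and reference FASTA input.

Reads multi-sample phased VCFs (v4.1+) into :class:`VariantRecord` streams,
applying the variant filters the detector requires: biallelic sites only,
fully phased non-missing diploid genotypes, and (downstream) a minor-allele
frequency cutoff. Also provides the fixed-width reference window used for
local GC-content analysis.

Coordinate conventions for the whole package: positions are 1-based
inclusive externally (VCF/FASTA convention); internal arithmetic uses
0-based half-open intervals; every serialized output is 1-based.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pysam

__all__ = [
    "VariantRecord",
    "SampleSet",
    "VcfParseError",
    "PhasedVcfReader",
    "read_phased_vcf",
    "compute_maf",
    "filter_frequent",
    "read_fasta_window",
    "normalize_chrom",
    "AUTOSOME_LABELS",
]

#: Autosome labels accepted by default ("chr" prefixes are normalized away).
AUTOSOME_LABELS = frozenset(str(i) for i in range(1, 23))


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed or has no usable samples."""


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome label."""
    if chrom.lower().startswith("chr"):
        return chrom[3:]
    return chrom


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """One biallelic site with phased per-sample genotypes.

    Attributes
    ----------
    chrom : str
        Normalized chromosome label (no ``chr`` prefix).
    pos : int
        1-based reference position.
    ref_allele, alt_allele : str
        Uppercase allele sequences; exactly two alleles per record.
    af : float
        Alternative-allele frequency in [0, 1].
    sample_alleles : tuple[tuple[int, int], ...]
        Per-sample phased allele pairs (first parental allele, second
        parental allele), each in {0, 1}, in file sample order.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    af: float
    sample_alleles: tuple[tuple[int, int], ...]

    @property
    def is_snp(self) -> bool:
        """True for single-base substitutions, False for indels."""
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def variant_class(self) -> str:
        return "SNP" if self.is_snp else "indel"


@dataclass(frozen=True, slots=True)
class SampleSet:
    """The ordered individuals of a phased VCF."""

    sample_ids: tuple[str, ...]

    @property
    def n_individuals(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        """Each diploid individual contributes two parental haplotypes."""
        return 2 * len(self.sample_ids)


def compute_maf(af: float) -> float:
    """Minor allele frequency: ``min(af, 1 - af)``.

    Raises
    ------
    ValueError
        If ``af`` lies outside [0, 1].
    """
    if not 0.0 <= af <= 1.0:
        raise ValueError(f"allele frequency {af!r} outside [0, 1]")
    return min(af, 1.0 - af)


@dataclass
class PhasedVcfReader:
    """Iterate biallelic, fully phased records of a multi-sample VCF.

    Records that are multi-allelic, or that carry any missing or unphased
    genotype, are skipped and tallied in :attr:`skip_counts` rather than
    raising — tolerant of imperfect inputs without corrupting haplotypes.

    Parameters
    ----------
    path
        Plain or bgzip-compressed VCF.
    chrom_filter
        Restrict to these (normalized) chromosome labels. ``None`` means
        all autosomes; sex chromosomes and MT are never yielded unless
        explicitly requested via ``autosomes_only=False``.
    """

    path: str | Path
    chrom_filter: Optional[frozenset[str]] = None
    autosomes_only: bool = True
    skip_counts: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        try:
            self._vcf = pysam.VariantFile(str(self.path))
        except (OSError, ValueError) as exc:
            raise VcfParseError(f"cannot parse VCF {self.path}: {exc}") from exc
        ids = tuple(self._vcf.header.samples)
        if not ids:
            raise VcfParseError(f"VCF {self.path} contains no samples")
        self.samples = SampleSet(sample_ids=ids)
        if self.chrom_filter is not None:
            self.chrom_filter = frozenset(normalize_chrom(c) for c in self.chrom_filter)

    def __iter__(self) -> Iterator[VariantRecord]:
        n = self.samples.n_individuals
        for rec in self._vcf:
            chrom = normalize_chrom(rec.chrom)
            if self.chrom_filter is not None and chrom not in self.chrom_filter:
                self.skip_counts["chrom_filtered"] += 1
                continue
            if self.autosomes_only and chrom not in AUTOSOME_LABELS:
                self.skip_counts["non_autosome"] += 1
                continue
            alts = rec.alts
            if alts is None or len(alts) != 1:
                self.skip_counts["multiallelic"] += 1
                continue
            pairs = []
            ok = True
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt is None or len(gt) != 2 or gt[0] is None or gt[1] is None:
                    self.skip_counts["missing_gt"] += 1
                    ok = False
                    break
                if not sample.phased:
                    self.skip_counts["unphased"] += 1
                    ok = False
                    break
                pairs.append((gt[0], gt[1]))
            if not ok:
                continue
            af = rec.info.get("AF")
            if af is not None:
                af = float(af[0] if isinstance(af, tuple) else af)
            else:
                af = sum(a + b for a, b in pairs) / (2 * n)
            yield VariantRecord(
                chrom=chrom,
                pos=rec.pos,
                ref_allele=rec.ref.upper(),
                alt_allele=alts[0].upper(),
                af=af,
                sample_alleles=tuple(pairs),
            )


def read_phased_vcf(
    path: str | Path,
    chrom_filter: Optional[Iterable[str]] = None,
    autosomes_only: bool = True,
) -> PhasedVcfReader:
    """Open a phased multi-sample VCF for streaming.

    Returns a :class:`PhasedVcfReader`; its ``samples`` attribute holds the
    :class:`SampleSet` and ``skip_counts`` accumulates rejection tallies
    (``multiallelic``, ``unphased``, ``missing_gt``, ...) as the stream is
    consumed.
    """
    cf = frozenset(chrom_filter) if chrom_filter is not None else None
    return PhasedVcfReader(path, chrom_filter=cf, autosomes_only=autosomes_only)


def filter_frequent(
    records: Iterable[VariantRecord], maf_min: float = 0.25
) -> Iterator[VariantRecord]:
    """Keep variants whose minor allele frequency strictly exceeds ``maf_min``.

    The cutoff is strict (MAF > 25% at the default), so a site at exactly
    the boundary is excluded. Both SNPs and indels pass: haplotype
    construction uses every frequent biallelic variant, and indel acceptor
    sites are rejected later by the detector.
    """
    for rec in records:
        if compute_maf(rec.af) > maf_min:
            yield rec


def read_fasta_window(
    ref,
    chrom: str,
    center_pos: int,
    flank: int = 50,
    include_focal: bool = False,
) -> Optional[str]:
    """Reference bases flanking a site, for local GC-content analysis.

    Returns the ``flank`` bases before ``center_pos`` (1-based) concatenated
    with the ``flank`` bases after it, uppercased. The focal base itself is
    excluded by default, so the window is exactly ``2 * flank`` long
    (``2 * flank + 1`` with ``include_focal=True``).

    Returns ``None`` (window unavailable) when the window would overrun a
    contig edge; callers skip such sites.

    Parameters
    ----------
    ref : pyfaidx.Fasta or mapping of chrom -> sequence string
    """
    seq = ref[chrom]
    length = len(seq)
    start = center_pos - 1 - flank  # 0-based inclusive
    end = center_pos + flank  # 0-based exclusive
    if start < 0 or end > length:
        return None
    window = str(seq[start:end]).upper()
    if not include_focal:
        window = window[:flank] + window[flank + 1 :]
    return window
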